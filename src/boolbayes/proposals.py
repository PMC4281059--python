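"""Chi-square screening of candidate relations and mixture proposals.

For every node, every (parent set, function) combination of arity 1 or 2 is
fitted against the data: the parent-pattern frequencies and the mismatch
rate theta-hat are estimated, expected cell counts are formed for the
2^(arity+1) joint (parents, child) cells, and a Pearson chi-square
goodness-of-fit test (df = 2^arity - 1, accounting for the estimated
pattern probabilities and theta-hat) decides whether the combination fits.
Fitting combinations become *preferential candidates*, weighted by the
reciprocal of theta-hat; the sampler proposes from an annealed mixture of
the weighted preferential multinomial and a uniform distribution over all
legal combinations, with the preferential mixing proportion
lambda_t = max(rho, 1 - t/T) decaying from one to a floor rho.

Screening is a fixed preprocessing step: candidates never change during
the chain, so the mismatch counts of *all* combinations are precomputed
here as dense arrays and reused by the sampler for O(1) score updates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import chi2 as chi2_dist

from .functions import BooleanFunction, enumerate_functions
from .model import DataMatrix

__all__ = [
    "CandidateRelation",
    "ProposalSchedule",
    "NodeProposal",
    "ROOT_MOVE",
    "fit_relation",
    "screen_candidates",
    "build_node_proposal",
    "build_all_proposals",
    "proposal_probability",
    "mixture_draw",
]

#: sentinel candidate meaning "remove all parents" (always legal)
ROOT_MOVE: Tuple[Tuple[int, ...], int] = ((), -1)

_F1 = enumerate_functions(1)
_F2 = enumerate_functions(2)
_T1 = np.array([f.table for f in _F1], dtype=np.int64)  # (2, 2)
_T2 = np.array([f.table for f in _F2], dtype=np.int64)  # (10, 4)


@dataclass(frozen=True)
class CandidateRelation:
    """One screened (parent set, function) combination for a node."""

    node: int
    parent_set: Tuple[int, ...]
    function: BooleanFunction
    theta_hat: float
    chisq_stat: float
    p_value: float
    weight: float
    low_expected: bool = False  # some expected cell count < 1: p-value unreliable


@dataclass(frozen=True)
class ProposalSchedule:
    """Annealing schedule for the preferential/uniform mixture."""

    anneal_length: int
    floor: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 < self.floor <= 1.0):
            raise ValueError("floor must lie in (0, 1]")
        if self.anneal_length < 0:
            raise ValueError("anneal_length must be nonnegative")

    def lam(self, t: int) -> float:
        if self.anneal_length == 0:
            return self.floor
        return max(self.floor, 1.0 - t / self.anneal_length)


def _gof(counts: np.ndarray, tables: np.ndarray, m_eff: int):
    """Vectorized goodness-of-fit over candidate functions.

    counts: (P, 2) observed (pattern, child-value) cell counts, P = 2^arity.
    tables: (F, P) function outputs per pattern.
    Returns mismatch counts k, theta_hat, chi-square stat, p-value and a
    low-expected-count flag, each shape (F,).
    """
    O_mis = np.where(tables == 1, counts[None, :, 0], counts[None, :, 1])
    k = O_mis.sum(axis=1)
    theta = k / m_eff
    r = counts.sum(axis=1).astype(float)  # (P,) pattern totals
    E_mis = r[None, :] * theta[:, None]
    E_mat = r[None, :] * (1.0 - theta)[:, None]
    O_mat = r[None, :] - O_mis
    # cells with zero expectation are skipped in the chi-square sum
    term_mis = np.where(E_mis > 0, (O_mis - E_mis) ** 2 / np.where(E_mis > 0, E_mis, 1.0), 0.0)
    term_mat = np.where(E_mat > 0, (O_mat - E_mat) ** 2 / np.where(E_mat > 0, E_mat, 1.0), 0.0)
    stat = (term_mis + term_mat).sum(axis=1)
    df = counts.shape[0] - 1  # 2^arity - 1 after estimated-parameter correction
    pval = chi2_dist.sf(stat, df)
    low = (((E_mis > 0) & (E_mis < 1)) | ((E_mat > 0) & (E_mat < 1))).any(axis=1)
    return k, theta, stat, pval, low


def _pattern_counts(X: DataMatrix, node: int, parent_set: Sequence[int]) -> np.ndarray:
    """Observed (parent pattern, child value) cell counts, shape (2^d, 2)."""
    P = X.parent_rows()
    y = X.child_rows()[:, node].astype(np.int64)
    if len(parent_set) == 1:
        pat = P[:, parent_set[0]].astype(np.int64)
    else:
        a, b = parent_set
        pat = 2 * P[:, a].astype(np.int64) + P[:, b]
    counts = np.bincount(2 * pat + y, minlength=2 ** (len(parent_set) + 1))
    return counts.reshape(-1, 2)


def _weight(theta_hat: float, m_eff: int) -> float:
    # reciprocal noise-level weight, floored so perfect fits stay finite
    return 1.0 / max(theta_hat, 1.0 / (2.0 * m_eff))


def fit_relation(
    X: DataMatrix, node: int, parent_set: Sequence[int], f: BooleanFunction
) -> CandidateRelation:
    """Goodness-of-fit of the relation ``node = f(parent_set) XOR noise``."""
    parent_set = tuple(sorted(parent_set))
    if node in parent_set:
        raise ValueError("parent set must not contain the node itself")
    if f.arity != len(parent_set):
        raise ValueError("function arity must equal parent-set size")
    if X.m_eff == 0:
        raise ValueError("no usable observations")
    counts = _pattern_counts(X, node, parent_set)
    tables = np.array([f.table], dtype=np.int64)
    k, theta, stat, pval, low = _gof(counts, tables, X.m_eff)
    return CandidateRelation(
        node=node,
        parent_set=parent_set,
        function=f,
        theta_hat=float(theta[0]),
        chisq_stat=float(stat[0]),
        p_value=float(pval[0]),
        weight=_weight(float(theta[0]), X.m_eff),
        low_expected=bool(low[0]),
    )


class NodeTables:
    """Dense per-node arrays over all (parent set, function) combinations.

    k1[p, f]: mismatch count of node = F1[f](p); zero row at p == node.
    k2[a, b, f] (a < b): mismatch count of node = F2[f](a, b).
    w1 / w2 hold preferential weights (zero where the screen rejected).
    """

    def __init__(self, X: DataMatrix, node: int, alpha_screen: float) -> None:
        if not (0.0 < alpha_screen < 1.0):
            raise ValueError("alpha_screen must lie in (0, 1)")
        n, m_eff = X.n, X.m_eff
        self.node, self.n, self.m_eff = node, n, m_eff
        self.alpha_screen = alpha_screen
        self.k1 = np.zeros((n, 2), dtype=np.int64)
        self.th1 = np.zeros((n, 2))
        self.stat1 = np.zeros((n, 2))
        self.pv1 = np.zeros((n, 2))
        self.low1 = np.zeros((n, 2), dtype=bool)
        self.w1 = np.zeros((n, 2))
        self.k2 = np.zeros((n, n, 10), dtype=np.int64)
        self.th2 = np.zeros((n, n, 10))
        self.stat2 = np.zeros((n, n, 10))
        self.pv2 = np.zeros((n, n, 10))
        self.low2 = np.zeros((n, n, 10), dtype=bool)
        self.w2 = np.zeros((n, n, 10))

        for p in range(n):
            if p == node:
                continue
            counts = _pattern_counts(X, node, (p,))
            k, th, st, pv, low = _gof(counts, _T1, m_eff)
            self.k1[p], self.th1[p] = k, th
            self.stat1[p], self.pv1[p], self.low1[p] = st, pv, low
        for a in range(n):
            if a == node:
                continue
            for b in range(a + 1, n):
                if b == node:
                    continue
                counts = _pattern_counts(X, node, (a, b))
                k, th, st, pv, low = _gof(counts, _T2, m_eff)
                self.k2[a, b], self.th2[a, b] = k, th
                self.stat2[a, b], self.pv2[a, b], self.low2[a, b] = st, pv, low
        # mismatch rates >= 1/2 are excluded: under the truncated noise
        # model such a fit belongs to the complement function, which is
        # screened in its own right
        floors = 1.0 / (2.0 * m_eff)
        keep1 = (self.pv1 > alpha_screen) & (self.th1 < 0.5)
        self.w1 = np.where(keep1, 1.0 / np.maximum(self.th1, floors), 0.0)
        keep2 = (self.pv2 > alpha_screen) & (self.th2 < 0.5)
        self.w2 = np.where(keep2, 1.0 / np.maximum(self.th2, floors), 0.0)

    def candidates(self) -> List[CandidateRelation]:
        """The screened combinations as CandidateRelation objects."""
        out: List[CandidateRelation] = []
        n = self.n
        for p in range(n):
            for f in range(2):
                if self.w1[p, f] > 0:
                    out.append(
                        CandidateRelation(
                            self.node, (p,), _F1[f],
                            float(self.th1[p, f]), float(self.stat1[p, f]),
                            float(self.pv1[p, f]), float(self.w1[p, f]),
                            bool(self.low1[p, f]),
                        )
                    )
        for a in range(n):
            for b in range(a + 1, n):
                for f in range(10):
                    if self.w2[a, b, f] > 0:
                        out.append(
                            CandidateRelation(
                                self.node, (a, b), _F2[f],
                                float(self.th2[a, b, f]), float(self.stat2[a, b, f]),
                                float(self.pv2[a, b, f]), float(self.w2[a, b, f]),
                                bool(self.low2[a, b, f]),
                            )
                        )
        return out


def screen_candidates(
    X: DataMatrix, node: int, alpha_screen: float = 0.05
) -> List[CandidateRelation]:
    """All combinations the chi-square screen does NOT reject (p > alpha)."""
    return NodeTables(X, node, alpha_screen).candidates()


class NodeProposal:
    """Mixture proposal for one node's (parent set, function) update.

    Candidates are pairs ``(parents, fid)`` with ``parents`` a sorted tuple
    and ``fid`` an index into enumerate_functions(len(parents)); the
    sentinel ROOT_MOVE proposes removing all parents.  Legality is passed
    as a boolean mask over nodes (True = may serve as a parent, i.e. not
    the node itself and not one of its descendants); a parent set is legal
    iff all its members are allowed.

    A draw first picks a target arity uniformly from {0, 1, 2}; for arity
    >= 1 it samples from lambda_t * preferential + (1 - lambda_t) * uniform
    restricted (renormalized) to the legal combinations.  If no screened
    candidate of the chosen arity is legal the draw falls back to uniform.
    """

    def __init__(self, tables: NodeTables, schedule: ProposalSchedule) -> None:
        self.node = tables.node
        self.n = tables.n
        self.schedule = schedule
        self.tables = tables
        self.w1 = tables.w1
        self.w2 = tables.w2
        self.w1_by_parent = tables.w1.sum(axis=1)  # (n,)
        self.w2_by_pair = tables.w2.sum(axis=2)  # (n, n), upper triangle
        self.w2_by_pair = self.w2_by_pair + self.w2_by_pair.T
        # flat screened-candidate arrays for weighted draws
        p1, f1 = np.nonzero(tables.w1)
        self.s1_p, self.s1_f = p1, f1
        self.s1_w = tables.w1[p1, f1]
        a2, b2, f2 = np.nonzero(tables.w2)
        self.s2_a, self.s2_b, self.s2_f = a2, b2, f2
        self.s2_w = tables.w2[a2, b2, f2]

    @property
    def has_preferential(self) -> bool:
        return len(self.s1_w) + len(self.s2_w) > 0

    def lam(self, t: int) -> float:
        return self.schedule.lam(t)

    # -- helpers ----------------------------------------------------------
    def _legal_totals(self, arity: int, allowed: np.ndarray) -> Tuple[int, float]:
        """(uniform combination count, total preferential weight) over the
        legal combinations of the given arity."""
        na = int(allowed.sum())
        if arity == 1:
            U = 2 * na
            W = float(self.w1_by_parent[allowed].sum()) if U else 0.0
        else:
            U = na * (na - 1) // 2 * 10
            if U:
                av = allowed.astype(float)
                W = float(av @ self.w2_by_pair @ av) / 2.0
            else:
                W = 0.0
        return U, W

    def probability(
        self, candidate: Tuple[Tuple[int, ...], int], t: int, allowed: np.ndarray
    ) -> float:
        """Exact probability that ``draw`` at iteration t yields ``candidate``."""
        if candidate == ROOT_MOVE:
            return 1.0 / 3.0
        parents, fid = candidate
        if any(not allowed[p] for p in parents):
            raise ValueError("candidate is not legal under the allowed mask")
        arity = len(parents)
        U, W = self._legal_totals(arity, allowed)
        if U == 0:
            raise ValueError("candidate arity has no legal combinations")
        if arity == 1:
            w = float(self.w1[parents[0], fid])
        else:
            w = float(self.w2[parents[0], parents[1], fid])
        lam = self.lam(t)
        if W > 0:
            pr = lam * w / W + (1.0 - lam) / U
        else:
            pr = 1.0 / U
        return pr / 3.0

    def draw(
        self, t: int, allowed: np.ndarray, rng: np.random.Generator
    ) -> Optional[Tuple[Tuple[int, ...], int]]:
        """One proposal draw; None signals a null move (no legal combination
        of the chosen arity, so the state is left unchanged)."""
        arity = int(rng.integers(0, 3))
        if arity == 0:
            return ROOT_MOVE
        U, W = self._legal_totals(arity, allowed)
        if U == 0:
            return None
        lam = self.lam(t)
        use_pref = W > 0 and rng.random() < lam
        if arity == 1:
            if use_pref:
                mask = allowed[self.s1_p]
                w = self.s1_w * mask
                j = _weighted_index(w, rng)
                return ((int(self.s1_p[j]),), int(self.s1_f[j]))
            idx = np.flatnonzero(allowed)
            p = int(idx[rng.integers(len(idx))])
            return ((p,), int(rng.integers(2)))
        if use_pref:
            mask = allowed[self.s2_a] & allowed[self.s2_b]
            w = self.s2_w * mask
            j = _weighted_index(w, rng)
            return (
                (int(self.s2_a[j]), int(self.s2_b[j])),
                int(self.s2_f[j]),
            )
        idx = np.flatnonzero(allowed)
        pick = rng.choice(len(idx), size=2, replace=False)
        a, b = sorted(int(idx[i]) for i in pick)
        return ((a, b), int(rng.integers(10)))


def _weighted_index(w: np.ndarray, rng: np.random.Generator) -> int:
    c = np.cumsum(w)
    return int(np.searchsorted(c, rng.random() * c[-1], side="right"))


def build_node_proposal(
    candidates: Sequence[CandidateRelation],
    node: int,
    n: int,
    schedule: ProposalSchedule,
    m_eff: int = 1,
    alpha_screen: float = 0.05,
) -> NodeProposal:
    """Assemble a NodeProposal from an explicit screened-candidate list."""
    tables = NodeTables.__new__(NodeTables)
    tables.node, tables.n, tables.m_eff = node, n, m_eff
    tables.alpha_screen = alpha_screen
    tables.k1 = np.zeros((n, 2), dtype=np.int64)
    tables.w1 = np.zeros((n, 2))
    tables.k2 = np.zeros((n, n, 10), dtype=np.int64)
    tables.w2 = np.zeros((n, n, 10))
    tables.th1 = np.zeros((n, 2))
    tables.th2 = np.zeros((n, n, 10))
    tables.pv1 = np.zeros((n, 2))
    tables.pv2 = np.zeros((n, n, 10))
    tables.stat1 = np.zeros((n, 2))
    tables.stat2 = np.zeros((n, n, 10))
    tables.low1 = np.zeros((n, 2), dtype=bool)
    tables.low2 = np.zeros((n, n, 10), dtype=bool)
    for c in candidates:
        if c.node != node:
            raise ValueError("candidate belongs to a different node")
        fid = _function_index(c.function)
        if len(c.parent_set) == 1:
            tables.w1[c.parent_set[0], fid] = c.weight
            tables.th1[c.parent_set[0], fid] = c.theta_hat
        else:
            a, b = c.parent_set
            tables.w2[a, b, fid] = c.weight
            tables.th2[a, b, fid] = c.theta_hat
    return NodeProposal(tables, schedule)


def _function_index(f: BooleanFunction) -> int:
    fam = _F1 if f.arity == 1 else _F2
    for i, g in enumerate(fam):
        if g.table == f.table:
            return i
    raise ValueError("unknown function")


def build_all_proposals(
    X: DataMatrix, alpha_screen: float, schedule: ProposalSchedule
) -> List[NodeProposal]:
    """Screen every node of the dataset and build its mixture proposal."""
    return [
        NodeProposal(NodeTables(X, node, alpha_screen), schedule)
        for node in range(X.n)
    ]


def proposal_probability(
    p: NodeProposal, candidate, iteration: int, allowed: np.ndarray
) -> float:
    """Module-level alias of NodeProposal.probability."""
    return p.probability(candidate, iteration, allowed)


def mixture_draw(
    p: NodeProposal, iteration: int, allowed: np.ndarray, rng: np.random.Generator
):
    """Module-level alias of NodeProposal.draw."""
    return p.draw(iteration, allowed, rng)
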