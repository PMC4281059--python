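"""Metropolis-within-Gibbs sampling of (topology, functions).

Each sweep visits every node and resamples its entire (parent set,
function) pair in one Metropolis-Hastings step: a candidate is drawn from
the node's annealed mixture proposal restricted to *legal* parent sets
(those keeping the graph acyclic with in-degree <= 2), and accepted with
probability min(1, exp(delta log collapsed posterior) * q_rev / q_fwd).
Resampling the whole pair realizes the add / remove / swap parent moves in
a single move type with a tractable proposal density.

Because the mismatch count of every candidate relation is precomputed
(see proposals.NodeTables), a node update costs O(n) graph work and O(1)
score work regardless of the sample size; the incremental sufficient
statistics are exact integers, so no drift correction is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import exp, log
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.special import betaln

from .functions import BooleanFunction, enumerate_functions
from .model import (
    FUNCTION_CHOICES,
    DataMatrix,
    Hyperparameters,
    SufficientStats,
    log_collapsed_posterior,
    sufficient_stats,
)
from .proposals import (
    ROOT_MOVE,
    NodeProposal,
    NodeTables,
    ProposalSchedule,
    build_all_proposals,
)
from .topology import NetworkModel, Topology

__all__ = [
    "MCMCConfig",
    "ChainTrace",
    "PosteriorSummary",
    "GibbsSampler",
    "run_chain",
    "summarize",
    "legal_candidates",
]

_F = {1: enumerate_functions(1), 2: enumerate_functions(2)}

#: compact chain state: per node (sorted parent tuple, function index or -1)
StateKey = Tuple[Tuple[Tuple[int, ...], int], ...]


@dataclass(frozen=True)
class MCMCConfig:
    """Chain settings; defaults follow the 20,000-sweep / 15,000-burn-in
    protocol with annealing over the first half of the burn-in."""

    iterations: int = 20_000
    burn_in: int = 15_000
    seed: int = 0
    hyper: Hyperparameters = field(default_factory=Hyperparameters)
    alpha_screen: float = 0.05
    schedule: Optional[ProposalSchedule] = None
    init_mode: str = "empty"
    update_order: str = "fixed"

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.iterations):
            raise ValueError("need 0 <= burn_in < iterations")
        if self.init_mode not in ("empty", "random", "preferential"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")
        if self.update_order not in ("fixed", "random"):
            raise ValueError(f"unknown update_order {self.update_order!r}")

    def resolved_schedule(self) -> ProposalSchedule:
        if self.schedule is not None:
            return self.schedule
        return ProposalSchedule(anneal_length=max(self.burn_in // 2, 1), floor=0.1)


class ChainTrace:
    """Recorded chain: one compact state + log posterior per sweep."""

    def __init__(
        self,
        n: int,
        states: List[StateKey],
        log_posteriors: np.ndarray,
        proposed: np.ndarray,
        accepted: np.ndarray,
        config: MCMCConfig,
    ) -> None:
        self.n = n
        self.states = states
        self.log_posteriors = log_posteriors
        self.proposed = proposed
        self.accepted = accepted
        self.config = config

    def __len__(self) -> int:
        return len(self.states)

    def network(self, t: int) -> NetworkModel:
        return state_to_network(self.n, self.states[t])

    @property
    def samples(self) -> List[NetworkModel]:
        """Materialized sampled networks (use sparingly on long traces)."""
        return [self.network(t) for t in range(len(self))]

    def acceptance_rate(self) -> float:
        tot = int(self.proposed.sum())
        return float(self.accepted.sum()) / tot if tot else 0.0


@dataclass(frozen=True)
class PosteriorSummary:
    modal_network: NetworkModel
    relation_frequencies: Tuple[Dict[Tuple[Tuple[int, ...], Tuple[int, ...]], float], ...]
    unique_model_count: int


def state_to_network(n: int, state: StateKey) -> NetworkModel:
    parents = tuple(pa for pa, _ in state)
    funcs: List[Optional[BooleanFunction]] = []
    for pa, fid in state:
        funcs.append(_F[len(pa)][fid] if pa else None)
    return NetworkModel(Topology(n, parents), tuple(funcs))


def network_to_state(model: NetworkModel) -> StateKey:
    out = []
    for i, pa in enumerate(model.topology.parents):
        if not pa:
            out.append(((), -1))
        else:
            f = model.functions[i]
            fam = _F[len(pa)]
            fid = next(j for j, g in enumerate(fam) if g.table == f.table)
            out.append((pa, fid))
    return tuple(out)


def legal_candidates(model: NetworkModel, node: int):
    """Every legal (parent set, function) pair for the node, plus ROOT_MOVE.

    A parent set is legal iff none of its members is a descendant of the
    node (its own in-edges are irrelevant to its descendant set), which
    also makes the legal set identical between a state and any state
    differing only in this node's relation.
    """
    n = model.topology.n
    children: List[List[int]] = [[] for _ in range(n)]
    for i, pa in enumerate(model.topology.parents):
        for p in pa:
            children[p].append(i)
    allowed = _allowed_mask(n, node, children)
    out = {ROOT_MOVE}
    idx = np.flatnonzero(allowed)
    for p in idx:
        for fid in range(2):
            out.add(((int(p),), fid))
    for ia, a in enumerate(idx):
        for b in idx[ia + 1:]:
            for fid in range(10):
                out.add(((int(a), int(b)), fid))
    return out


def _allowed_mask(n: int, node: int, children: Sequence[Sequence[int]]) -> np.ndarray:
    allowed = np.ones(n, dtype=bool)
    allowed[node] = False
    stack = [node]
    seen = {node}
    while stack:
        u = stack.pop()
        for v in children[u]:
            if v not in seen:
                seen.add(v)
                allowed[v] = False
                stack.append(v)
    return allowed


class GibbsSampler:
    """Mutable chain state plus the precomputed score/proposal tables."""

    def __init__(self, X: DataMatrix, config: MCMCConfig) -> None:
        self.X = X
        self.config = config
        self.n = X.n
        self.m_eff = X.m_eff
        self.hyper = config.hyper
        self.rng = np.random.default_rng(config.seed)
        schedule = config.resolved_schedule()
        self.proposals: List[NodeProposal] = build_all_proposals(
            X, config.alpha_screen, schedule
        )
        h = self.hyper
        # per-root Beta evidence term (includes its prior normalizer)
        s = X.child_rows().sum(axis=0).astype(np.int64)
        self.root_term = (
            betaln(s + h.a_root, self.m_eff - s + h.b_root)
            - betaln(h.a_root, h.b_root)
        )
        # truncated noise Beta evidence, tabulated for every root count r
        # and flip count k (already includes the prior normalizers)
        from .model import log_noise_evidence

        self._noise_table = []
        for r in range(self.n + 1):
            M = self.m_eff * (self.n - r)
            ks = np.arange(M + 1)
            self._noise_table.append(log_noise_evidence(ks, M, h))
        self._const = 0.0
        self._log_c = {0: 0.0, 1: log(2.0), 2: log(10.0)}
        self._init_state()

    # -- state ------------------------------------------------------------
    def _init_state(self) -> None:
        mode = self.config.init_mode
        n = self.n
        if mode == "empty":
            parents: List[Tuple[int, ...]] = [() for _ in range(n)]
            fids = [-1] * n
        elif mode == "random":
            from .simulate import GeneratorConfig, random_model, random_topology

            cfg = GeneratorConfig(n=n, m=1, seed=0)
            topo = random_topology(cfg, self.rng)
            model = random_model(topo, self.rng)
            state = network_to_state(model)
            parents = [pa for pa, _ in state]
            fids = [fid for _, fid in state]
        else:  # preferential: greedy best-weight legal candidate per node
            parents = [() for _ in range(n)]
            fids = [-1] * n
            children: List[Set[int]] = [set() for _ in range(n)]
            for node in range(n):
                allowed = _allowed_mask(n, node, [list(c) for c in children])
                best = None
                prop = self.proposals[node]
                for p, fid, w in zip(prop.s1_p, prop.s1_f, prop.s1_w):
                    if allowed[p] and (best is None or w > best[0]):
                        best = (w, (int(p),), int(fid))
                for a, b, fid, w in zip(prop.s2_a, prop.s2_b, prop.s2_f, prop.s2_w):
                    if allowed[a] and allowed[b] and (best is None or w > best[0]):
                        best = (w, (int(a), int(b)), int(fid))
                if best is not None:
                    parents[node] = best[1]
                    fids[node] = best[2]
                    for p in best[1]:
                        children[p].add(node)
        self.parents = parents
        self.fids = fids
        self.children: List[Set[int]] = [set() for _ in range(n)]
        for i, pa in enumerate(parents):
            for p in pa:
                self.children[p].add(i)
        self.k_node = [self._k_lookup(i, parents[i], fids[i]) for i in range(n)]
        self.k_total = sum(self.k_node)
        self.r = sum(1 for pa in parents if not pa)
        self.root_sum = float(
            sum(self.root_term[i] for i in range(n) if not parents[i])
        )
        self.func_sum = -float(sum(self._log_c[len(pa)] for pa in parents))

    def _k_lookup(self, node: int, pa: Tuple[int, ...], fid: int) -> int:
        t = self.proposals[node].tables
        if not pa:
            return 0
        if len(pa) == 1:
            return int(t.k1[pa[0], fid])
        return int(t.k2[pa[0], pa[1], fid])

    def log_posterior(self) -> float:
        return (
            float(self._noise_table[self.r][self.k_total])
            + self._const
            + self.root_sum
            + self.func_sum
        )

    def full_log_posterior(self) -> float:
        """Score recomputed from scratch via the model module (for checks)."""
        model = self.current_network()
        stats = sufficient_stats(self.X, model)
        return log_collapsed_posterior(stats, model, self.hyper)

    def state_key(self) -> StateKey:
        return tuple(zip((tuple(p) for p in self.parents), self.fids))

    def current_network(self) -> NetworkModel:
        return state_to_network(self.n, self.state_key())

    # -- single MH step ---------------------------------------------------
    def step_node(self, node: int, t: int) -> Optional[bool]:
        """One Metropolis-Hastings update of the node's relation.

        Returns True/False for accepted/rejected, or None for a null move
        (the drawn arity had no legal combination).
        """
        allowed = _allowed_mask(self.n, node, self.children)
        prop = self.proposals[node]
        cand = prop.draw(t, allowed, self.rng)
        if cand is None:
            return None
        cur_pa, cur_fid = self.parents[node], self.fids[node]
        new_pa, new_fid = cand
        if new_pa == cur_pa and new_fid == cur_fid:
            return True  # proposing the current relation: delta = 0, q ratio = 1
        q_fwd = prop.probability(cand, t, allowed)
        cur_cand = ROOT_MOVE if not cur_pa else (cur_pa, cur_fid)
        q_rev = prop.probability(cur_cand, t, allowed)
        if q_rev == 0.0:
            return False  # reverse move impossible under a pure-preferential mixture

        k_new_node = self._k_lookup(node, new_pa, new_fid)
        k_new = self.k_total - self.k_node[node] + k_new_node
        was_root = not cur_pa
        is_root = not new_pa
        r_new = self.r + int(is_root) - int(was_root)
        d_root = 0.0
        if is_root and not was_root:
            d_root = float(self.root_term[node])
        elif was_root and not is_root:
            d_root = -float(self.root_term[node])
        d_func = self._log_c[len(cur_pa)] - self._log_c[len(new_pa)]
        delta = (
            float(self._noise_table[r_new][k_new])
            - float(self._noise_table[self.r][self.k_total])
            + d_root
            + d_func
        )
        log_ratio = delta + log(q_rev) - log(q_fwd)
        if log_ratio >= 0.0 or self.rng.random() < exp(log_ratio):
            for p in cur_pa:
                self.children[p].discard(node)
            for p in new_pa:
                self.children[p].add(node)
            self.parents[node] = new_pa
            self.fids[node] = new_fid
            self.k_total = k_new
            self.k_node[node] = k_new_node
            self.r = r_new
            self.root_sum += d_root
            self.func_sum += d_func
            return True
        return False

    # -- full run ---------------------------------------------------------
    def run(self) -> ChainTrace:
        n = self.n
        cfg = self.config
        states: List[StateKey] = []
        lps = np.empty(cfg.iterations)
        proposed = np.zeros(n, dtype=np.int64)
        accepted = np.zeros(n, dtype=np.int64)
        order = np.arange(n)
        for t in range(cfg.iterations):
            if cfg.update_order == "random":
                order = self.rng.permutation(n)
            for node in order:
                res = self.step_node(int(node), t)
                if res is not None:
                    proposed[node] += 1
                    accepted[node] += int(res)
            states.append(self.state_key())
            lps[t] = self.log_posterior()
        return ChainTrace(n, states, lps, proposed, accepted, cfg)


def run_chain(X: DataMatrix, config: MCMCConfig) -> ChainTrace:
    """Screen, initialize, and run one chain; fully seeded and deterministic."""
    if X.m_eff == 0:
        raise ValueError("no usable observations")
    return GibbsSampler(X, config).run()


def summarize(trace: ChainTrace, burn_in: Optional[int] = None) -> PosteriorSummary:
    """Posterior summary over the post-burn-in window: modal network
    (ties: higher recorded log posterior, then first occurrence), per-node
    relation frequencies, and the number of unique sampled models."""
    if burn_in is None:
        burn_in = trace.config.burn_in
    if not (0 <= burn_in < len(trace)):
        raise ValueError("burn_in leaves an empty posterior window")
    counts: Dict[StateKey, List[float]] = {}
    for t in range(burn_in, len(trace)):
        key = trace.states[t]
        lp = float(trace.log_posteriors[t])
        rec = counts.get(key)
        if rec is None:
            counts[key] = [1.0, lp, t]
        else:
            rec[0] += 1.0
            if lp > rec[1]:
                rec[1] = lp
    modal_key = max(counts, key=lambda k: (counts[k][0], counts[k][1], -counts[k][2]))
    total = float(len(trace) - burn_in)
    freqs: List[Dict[Tuple[Tuple[int, ...], Tuple[int, ...]], float]] = [
        {} for _ in range(trace.n)
    ]
    for key, (c, _, _) in counts.items():
        for i, (pa, fid) in enumerate(key):
            table = _F[len(pa)][fid].table if pa else ()
            rel = (pa, table)
            freqs[i][rel] = freqs[i].get(rel, 0.0) + c / total
    return PosteriorSummary(
        modal_network=state_to_network(trace.n, modal_key),
        relation_frequencies=tuple(freqs),
        unique_model_count=len(counts),
    )
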