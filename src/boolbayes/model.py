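"""Likelihood, priors, and the collapsed posterior score.

The data model: each non-root gene equals its Boolean function of its
parents XOR an i.i.d. Bernoulli(theta) noise bit; each root gene is an
independent Bernoulli(p_i).  Conjugate Beta priors on theta and the root
probabilities are integrated out analytically, leaving a *collapsed*
posterior over (topology, functions) alone — the quantity the sampler
targets.  All scores are log-scale and defined up to one additive constant
shared by every model on the same data (the uniform topology prior).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.special import betainc, betaln
from scipy.stats import beta as beta_dist

from .functions import apply_function, enumerate_functions
from .topology import NetworkModel

__all__ = [
    "DataMatrix",
    "Hyperparameters",
    "ParameterSet",
    "SufficientStats",
    "sufficient_stats",
    "log_likelihood",
    "log_collapsed_posterior",
    "log_joint_posterior",
    "estimate_parameters",
    "FUNCTION_CHOICES",
]

#: number of non-degenerate function choices by in-degree
FUNCTION_CHOICES = {0: 1, 1: 2, 2: 10}


@dataclass(frozen=True)
class DataMatrix:
    """An m x n binary observation matrix.

    mode="independent": each row is an independent snapshot; a child's
    parents are read from the same row.
    mode="timeseries": rows form a synchronized time series; a child in row
    j is driven by its parents' values in row j-1, so m-1 transitions are
    usable and row 1 only ever acts as a parent configuration.
    mode="transitions": an explicit list of (parent row, child row) pairs,
    e.g. a random subset of a time series' transitions; ``child_values``
    holds the child rows aligned with ``values``.

    Effective sample size m_eff is the number of usable transitions,
    uniformly for all nodes, roots included.
    """

    values: np.ndarray
    mode: str = "independent"
    names: Optional[Tuple[str, ...]] = None
    child_values: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.int8)
        if v.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if not np.isin(v, (0, 1)).all():
            raise ValueError("data matrix must be binary (0/1) and complete")
        if self.mode not in ("independent", "timeseries", "transitions"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "timeseries" and v.shape[0] < 2:
            raise ValueError("timeseries mode needs at least 2 rows")
        object.__setattr__(self, "values", v)
        if self.mode == "transitions":
            if self.child_values is None:
                raise ValueError("transitions mode requires child_values")
            c = np.asarray(self.child_values, dtype=np.int8)
            if c.shape != v.shape or not np.isin(c, (0, 1)).all():
                raise ValueError("child_values must be binary with the same shape")
            object.__setattr__(self, "child_values", c)
        elif self.child_values is not None:
            raise ValueError("child_values only applies to transitions mode")
        if self.names is not None and len(self.names) != v.shape[1]:
            raise ValueError("names length must equal column count")

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    @property
    def m_eff(self) -> int:
        return self.m - 1 if self.mode == "timeseries" else self.m

    def parent_rows(self) -> np.ndarray:
        """Rows supplying parent values for each usable transition."""
        return self.values[:-1] if self.mode == "timeseries" else self.values

    def child_rows(self) -> np.ndarray:
        """Rows supplying child values for each usable transition."""
        if self.mode == "timeseries":
            return self.values[1:]
        if self.mode == "transitions":
            return self.child_values
        return self.values

    def as_transitions(self) -> "DataMatrix":
        """Explicit (parent row, child row) pair representation."""
        return DataMatrix(
            values=self.parent_rows().copy(),
            mode="transitions",
            names=self.names,
            child_values=self.child_rows().copy(),
        )


@dataclass(frozen=True)
class Hyperparameters:
    """Beta prior constants: theta ~ Beta(alpha_theta, beta_theta)
    truncated to (0, 1/2); each root probability ~ Beta(a_root, b_root).

    The truncation is a model requirement, not a convenience: complementing
    every Boolean function while replacing theta by 1 - theta leaves the
    likelihood invariant, so without theta < 1/2 the posterior has an exact
    twin mode in which every function is negated and the "noise" rate sits
    near one.  Restricting the noise rate below one half breaks that
    symmetry; the prior mean must also sit below one half.
    """

    alpha_theta: float = 1.0
    beta_theta: float = 9.0
    a_root: float = 1.0
    b_root: float = 1.0

    def __post_init__(self) -> None:
        for name in ("alpha_theta", "beta_theta", "a_root", "b_root"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.alpha_theta / (self.alpha_theta + self.beta_theta) >= 0.5:
            raise ValueError("noise prior mean must be below 0.5")


@dataclass(frozen=True)
class ParameterSet:
    """Shared noise rate theta plus one Bernoulli rate per root node."""

    theta: float
    root_probs: Dict[int, float] = field(default_factory=dict)
    theta_is_prior_mean: bool = False  # set when no non-root data informed theta

    def __post_init__(self) -> None:
        if not (0.0 < self.theta < 1.0):
            raise ValueError("theta must lie in (0,1)")
        for i, p in self.root_probs.items():
            if not (0.0 < p < 1.0):
                raise ValueError(f"root probability for node {i} outside (0,1)")


@dataclass(frozen=True)
class SufficientStats:
    """Counts that fully determine likelihood and collapsed posterior.

    k: total noise flips (non-root cells disagreeing with the function
    output); M: total non-root cells = m_eff * (n - r); root_ones: per-root
    count of ones; m_eff: usable observations per node.
    """

    k: int
    M: int
    root_ones: Dict[int, int]
    m_eff: int

    def __post_init__(self) -> None:
        if not (0 <= self.k <= self.M):
            raise ValueError("need 0 <= k <= M")
        for i, s in self.root_ones.items():
            if not (0 <= s <= self.m_eff):
                raise ValueError(f"root_ones[{i}] outside [0, m_eff]")


def sufficient_stats(X: DataMatrix, model: NetworkModel) -> SufficientStats:
    """Mismatch and root-activity counts of ``model`` on ``X``."""
    if X.n != model.topology.n:
        raise ValueError(f"data has {X.n} columns but model has {model.topology.n} nodes")
    P = X.parent_rows()
    C = X.child_rows()
    m_eff = X.m_eff
    k = 0
    root_ones: Dict[int, int] = {}
    for i, pa in enumerate(model.topology.parents):
        if not pa:
            root_ones[i] = int(C[:, i].sum())
            continue
        f = model.functions[i]
        if len(pa) == 1:
            idx = P[:, pa[0]].astype(np.intp)
        else:
            idx = (2 * P[:, pa[0]] + P[:, pa[1]]).astype(np.intp)
        pred = np.asarray(f.table, dtype=np.int8)[idx]
        k += int((pred != C[:, i]).sum())
    M = m_eff * (model.topology.n - len(root_ones))
    return SufficientStats(k=k, M=M, root_ones=root_ones, m_eff=m_eff)


def log_likelihood(stats: SufficientStats, params: ParameterSet) -> float:
    """Full-data log likelihood given (topology, functions) and parameters.

    Two factors: the noise factor theta^k (1-theta)^(M-k) over non-root
    cells, and an independent Bernoulli factor per root node.
    """
    if set(params.root_probs) != set(stats.root_ones):
        raise ValueError("root_probs keys must match the roots in stats")
    th = params.theta
    ll = stats.k * log(th) + (stats.M - stats.k) * log(1.0 - th)
    for i, s in stats.root_ones.items():
        p = params.root_probs[i]
        ll += s * log(p) + (stats.m_eff - s) * log(1.0 - p)
    return ll


def _log_function_prior(model: NetworkModel) -> float:
    """Sum over non-root nodes of log 1/c(|Pa_i|): uniform over the 2 or 10
    non-degenerate choices given the in-degree."""
    out = 0.0
    for pa in model.topology.parents:
        if pa:
            out -= log(FUNCTION_CHOICES[len(pa)])
    return out


def log_noise_evidence(k, M, hyper: Hyperparameters):
    """log of the marginal noise factor: the integral of
    theta^k (1-theta)^(M-k) against the Beta(alpha, beta) prior truncated
    to (0, 1/2).  Vectorized over k.  States whose flip count would demand
    theta > 1/2 are driven to an effectively vetoing score (the incomplete
    Beta mass underflows; it is floored rather than returned as -inf so
    score differences stay finite).
    """
    a = np.asarray(k) + hyper.alpha_theta
    b = np.asarray(M) - np.asarray(k) + hyper.beta_theta
    mass = np.maximum(betainc(a, b, 0.5), 1e-300)
    prior_mass = betainc(hyper.alpha_theta, hyper.beta_theta, 0.5)
    return (
        betaln(a, b)
        + np.log(mass)
        - betaln(hyper.alpha_theta, hyper.beta_theta)
        - np.log(prior_mass)
    )


def log_collapsed_posterior(
    stats: SufficientStats, model: NetworkModel, hyper: Hyperparameters
) -> float:
    """Unnormalized log posterior of (topology, functions) with theta and
    all root probabilities integrated out against their Beta priors.

    Up to one additive constant shared by all models on the same data
    (the uniform topology prior and the marginal data probability).
    """
    lp = log_noise_evidence(stats.k, stats.M, hyper)
    for s in stats.root_ones.values():
        lp += betaln(s + hyper.a_root, stats.m_eff - s + hyper.b_root)
        lp -= betaln(hyper.a_root, hyper.b_root)
    return float(lp + _log_function_prior(model))


def log_joint_posterior(
    stats: SufficientStats,
    model: NetworkModel,
    params: ParameterSet,
    hyper: Hyperparameters,
) -> float:
    """Unnormalized log joint posterior of (topology, functions, parameters);
    integrating its exponential over the parameters recovers the collapsed
    score (tested numerically)."""
    lp = log_likelihood(stats, params)
    if params.theta >= 0.5:
        return float("-inf")  # outside the truncated noise-prior support
    lp += beta_dist.logpdf(params.theta, hyper.alpha_theta, hyper.beta_theta)
    lp -= float(np.log(betainc(hyper.alpha_theta, hyper.beta_theta, 0.5)))
    for i in stats.root_ones:
        lp += beta_dist.logpdf(params.root_probs[i], hyper.a_root, hyper.b_root)
    return float(lp + _log_function_prior(model))


def estimate_parameters(
    stats: SufficientStats, hyper: Hyperparameters
) -> ParameterSet:
    """Posterior-mean parameter estimates conditional on (topology,
    functions): exact under the conjugate Beta-Bernoulli model (with the
    noise posterior renormalized to the truncated support theta < 1/2)."""
    a = stats.k + hyper.alpha_theta
    b = stats.M - stats.k + hyper.beta_theta
    mass = max(float(betainc(a, b, 0.5)), 1e-300)
    mass_up = max(float(betainc(a + 1.0, b, 0.5)), 1e-300)
    theta_hat = a / (a + b) * mass_up / mass
    root_probs = {
        i: (s + hyper.a_root) / (stats.m_eff + hyper.a_root + hyper.b_root)
        for i, s in stats.root_ones.items()
    }
    return ParameterSet(
        theta=float(theta_hat),
        root_probs=root_probs,
        theta_is_prior_mean=(stats.M == 0),
    )


def simulate_node(model: NetworkModel, node: int, parent_values: Tuple[int, ...]) -> int:
    """Deterministic (noise-free) output of a non-root node."""
    f = model.functions[node]
    if f is None:
        raise ValueError(f"node {node} is a root")
    return apply_function(f, parent_values)
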