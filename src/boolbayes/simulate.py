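"""Synthetic network and data generation.

Emulates the simulation design used to benchmark the method: a random
valid topology is drawn by giving each node an in-degree from {0, 1, 2}
and uniformly chosen distinct parents, rejecting and redrawing the whole
network until it is acyclic; each non-root gets a uniformly random
non-degenerate function; parameters are drawn from their priors (or the
noise rate is pinned to a study value such as 0.1 or 0.2); observations
are then generated by pushing Bernoulli roots through the functions and
flipping each non-root cell with probability theta.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple, Union

import numpy as np

from .functions import enumerate_functions
from .model import DataMatrix, Hyperparameters, ParameterSet
from .topology import NetworkModel, Topology, is_valid_topology, topological_order

__all__ = [
    "GeneratorConfig",
    "random_topology",
    "random_model",
    "random_parameters",
    "generate_data",
    "generate_study_instance",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition settings for the generator.

    degree_probs are the in-degree probabilities over {0, 1, 2}; the mass
    on 0 must be positive so the rejection loop terminates.
    """

    n: int = 20
    m: int = 50
    degree_probs: Tuple[float, float, float] = (0.2, 0.4, 0.4)
    theta: Union[float, str] = "sample-from-prior"
    hyper: Hyperparameters = field(default_factory=Hyperparameters)
    mode: str = "independent"
    seed: int = 0

    def __post_init__(self) -> None:
        dp = self.degree_probs
        if len(dp) != 3 or any(p < 0 for p in dp) or abs(sum(dp) - 1.0) > 1e-9:
            raise ValueError("degree_probs must be 3 nonnegative values summing to 1")
        if dp[0] <= 0:
            raise ValueError("degree_probs[0] must be positive (termination)")
        if self.n < 1 or self.m < 1:
            raise ValueError("n and m must be positive")


def random_topology(cfg: GeneratorConfig, rng: np.random.Generator) -> Topology:
    """Draw in-degrees and parents per node; reject-and-restart on cycles."""
    n = cfg.n
    probs = np.asarray(cfg.degree_probs)
    while True:
        parents: List[Tuple[int, ...]] = []
        for i in range(n):
            d = int(rng.choice(3, p=probs))
            d = min(d, n - 1)
            if d == 0:
                parents.append(())
            else:
                others = [j for j in range(n) if j != i]
                pick = rng.choice(len(others), size=d, replace=False)
                parents.append(tuple(sorted(others[j] for j in pick)))
        topo = Topology(n, tuple(parents))
        if is_valid_topology(topo):
            return topo


def random_model(topology: Topology, rng: np.random.Generator) -> NetworkModel:
    """Assign each non-root a uniformly random non-degenerate function."""
    funcs = []
    for pa in topology.parents:
        if not pa:
            funcs.append(None)
        else:
            fam = enumerate_functions(len(pa))
            funcs.append(fam[int(rng.integers(len(fam)))])
    return NetworkModel(topology, tuple(funcs))


def random_parameters(
    topology: Topology,
    hyper: Hyperparameters,
    rng: np.random.Generator,
    theta: Union[float, str] = "sample-from-prior",
) -> ParameterSet:
    """theta from Beta(alpha, beta) unless pinned; root probs from Beta(a, b)."""
    if theta == "sample-from-prior":
        th = float(rng.beta(hyper.alpha_theta, hyper.beta_theta))
        th = min(max(th, 1e-12), 1 - 1e-12)
    else:
        th = float(theta)
    root_probs = {
        i: float(np.clip(rng.beta(hyper.a_root, hyper.b_root), 1e-12, 1 - 1e-12))
        for i in topology.roots()
    }
    return ParameterSet(theta=th, root_probs=root_probs)


def generate_data(
    model: NetworkModel,
    params: ParameterSet,
    m: int,
    mode: str = "independent",
    rng: Optional[np.random.Generator] = None,
) -> DataMatrix:
    """Generate m observations under the noisy Boolean transition model.

    independent: roots ~ Bernoulli(p_i) per row; non-roots (in topological
    order) equal their function output XOR Bernoulli(theta).
    timeseries: row 1 uniform at random; each later row's non-roots are
    driven by the previous row, roots redrawn every step.
    """
    rng = np.random.default_rng() if rng is None else rng
    topo = model.topology
    n = topo.n
    order = topological_order(topo)
    X = np.zeros((m, n), dtype=np.int8)
    if mode == "independent":
        for i in order:
            pa = topo.parents[i]
            if not pa:
                X[:, i] = rng.random(m) < params.root_probs[i]
            else:
                tab = np.asarray(model.functions[i].table, dtype=np.int8)
                idx = X[:, pa[0]].astype(np.intp)
                if len(pa) == 2:
                    idx = 2 * idx + X[:, pa[1]]
                noise = (rng.random(m) < params.theta).astype(np.int8)
                X[:, i] = tab[idx] ^ noise
    elif mode == "timeseries":
        X[0] = rng.integers(0, 2, size=n, dtype=np.int8)
        for j in range(1, m):
            for i in range(n):
                pa = topo.parents[i]
                if not pa:
                    X[j, i] = rng.random() < params.root_probs[i]
                else:
                    vals = tuple(int(X[j - 1, p]) for p in pa)
                    out = model.functions[i](vals)
                    X[j, i] = out ^ int(rng.random() < params.theta)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return DataMatrix(values=X, mode=mode)


def generate_study_instance(
    cfg: GeneratorConfig,
) -> Tuple[NetworkModel, ParameterSet, DataMatrix]:
    """One (truth, parameters, data) triple under the study conditions."""
    rng = np.random.default_rng(cfg.seed)
    topo = random_topology(cfg, rng)
    model = random_model(topo, rng)
    params = random_parameters(topo, cfg.hyper, rng, cfg.theta)
    X = generate_data(model, params, cfg.m, cfg.mode, rng)
    return model, params, X
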