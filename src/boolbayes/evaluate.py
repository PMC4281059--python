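"""Accuracy metrics and the simulation benchmark harness.

The headline metric is the *correct rate* (CR): the fraction of nodes
whose parent set AND Boolean function are both exactly recovered, so
CR = 1 iff the inferred network equals the truth.  Chains are scored by
averaging CR over the post-burn-in samples; predictive performance holds
out a third of the observations and checks the deterministic function
output of each sampled network against the held-out child values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import DataMatrix, Hyperparameters, estimate_parameters, sufficient_stats
from .sampler import ChainTrace, MCMCConfig, network_to_state, run_chain, summarize
from .simulate import (
    GeneratorConfig,
    generate_data,
    random_model,
    random_parameters,
    random_topology,
)
from .topology import NetworkModel

__all__ = [
    "correct_rate",
    "average_correct_rate",
    "train_test_split",
    "prediction_accuracy",
    "run_replicate",
    "run_benchmark",
]


def correct_rate(inferred: NetworkModel, truth: NetworkModel) -> float:
    """Fraction of nodes with both parent set and function table correct."""
    if inferred.topology.n != truth.topology.n:
        raise ValueError("models must have the same number of nodes")
    return _state_cr(network_to_state(inferred), network_to_state(truth))


def _state_cr(state, truth_state) -> float:
    hits = sum(1 for a, b in zip(state, truth_state) if a == b)
    return hits / len(truth_state)


def average_correct_rate(
    trace: ChainTrace, burn_in: Optional[int], truth: NetworkModel
) -> float:
    """Mean correct rate over the post-burn-in sampled networks."""
    if burn_in is None:
        burn_in = trace.config.burn_in
    if not (0 <= burn_in < len(trace)):
        raise ValueError("burn_in leaves an empty posterior window")
    truth_state = network_to_state(truth)
    counts: Dict[tuple, int] = {}
    for t in range(burn_in, len(trace)):
        key = trace.states[t]
        counts[key] = counts.get(key, 0) + 1
    total = len(trace) - burn_in
    return sum(_state_cr(k, truth_state) * c for k, c in counts.items()) / total


def train_test_split(
    X: DataMatrix, fraction: float, rng: np.random.Generator
) -> Tuple[DataMatrix, DataMatrix]:
    """Disjoint random partition of sizes ceil(fraction*units) and the rest.

    Independent data are split by row.  Time-series data are first turned
    into explicit (parent row, child row) transition pairs and split at the
    transition level, so the lag pairing survives the shuffle.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    if X.m < 2:
        raise ValueError("need at least 2 observations to split")
    if X.mode == "timeseries":
        X = X.as_transitions()
    total = X.m
    m_train = int(np.ceil(fraction * total))
    perm = rng.permutation(total)
    tr, te = np.sort(perm[:m_train]), np.sort(perm[m_train:])
    if X.mode == "transitions":
        return (
            DataMatrix(X.values[tr], "transitions", X.names, X.child_values[tr]),
            DataMatrix(X.values[te], "transitions", X.names, X.child_values[te]),
        )
    return (
        DataMatrix(X.values[tr], X.mode, X.names),
        DataMatrix(X.values[te], X.mode, X.names),
    )


def prediction_accuracy(
    trace: ChainTrace, burn_in: Optional[int], X_test: DataMatrix
) -> float:
    """Held-out prediction accuracy of the post-burn-in networks.

    For each sampled network, every non-root node is predicted as its
    deterministic function output on the test rows; the per-node fraction
    of matches is averaged over non-root nodes, then over samples.
    Sampled networks without any non-root node are skipped.
    """
    if burn_in is None:
        burn_in = trace.config.burn_in
    if X_test.m_eff == 0:
        raise ValueError("empty test set")
    P = X_test.parent_rows()
    C = X_test.child_rows()
    m = X_test.m_eff
    rel_cache: Dict[tuple, float] = {}

    def rel_acc(node: int, pa: Tuple[int, ...], fid: int) -> float:
        key = (node, pa, fid)
        acc = rel_cache.get(key)
        if acc is None:
            from .functions import enumerate_functions

            tab = np.asarray(enumerate_functions(len(pa))[fid].table, dtype=np.int8)
            idx = P[:, pa[0]].astype(np.intp)
            if len(pa) == 2:
                idx = 2 * idx + P[:, pa[1]]
            acc = float((tab[idx] == C[:, node]).mean())
            rel_cache[key] = acc
        return acc

    counts: Dict[tuple, int] = {}
    for t in range(burn_in, len(trace)):
        key = trace.states[t]
        counts[key] = counts.get(key, 0) + 1
    total_weight = 0
    acc_sum = 0.0
    skipped = 0
    for key, c in counts.items():
        node_accs = [
            rel_acc(i, pa, fid) for i, (pa, fid) in enumerate(key) if pa
        ]
        if not node_accs:
            skipped += c
            continue
        acc_sum += float(np.mean(node_accs)) * c
        total_weight += c
    if total_weight == 0:
        raise ValueError("no sampled network has a non-root node")
    return acc_sum / total_weight


def run_replicate(
    n: int,
    m: int,
    theta: float,
    iterations: int,
    burn_in: int,
    seed: int,
    with_prediction: bool = False,
    train_fraction: float = 2.0 / 3.0,
    degree_probs: Tuple[float, float, float] = (0.2, 0.4, 0.4),
    hyper: Optional[Hyperparameters] = None,
    init_mode: str = "empty",
    mode: str = "timeseries",
) -> Dict[str, float]:
    """Generate one (network, data) instance, run one chain, score it.

    The default study condition is synchronized time-series data: m
    observations of the network dynamics giving m-1 usable transitions.
    """
    hyper = hyper or Hyperparameters()
    ss = np.random.SeedSequence(seed)
    gen_seed, chain_seed, split_seed = (int(s) for s in ss.generate_state(3) // 2)
    cfg = GeneratorConfig(
        n=n, m=m, degree_probs=degree_probs, theta=theta, hyper=hyper,
        seed=gen_seed, mode=mode,
    )
    rng = np.random.default_rng(gen_seed)
    topo = random_topology(cfg, rng)
    truth = random_model(topo, rng)
    params = random_parameters(topo, hyper, rng, theta)
    X = generate_data(truth, params, m, mode, rng)
    if with_prediction:
        split_rng = np.random.default_rng(split_seed)
        X_train, X_test = train_test_split(X, train_fraction, split_rng)
    else:
        X_train, X_test = X, None
    mcfg = MCMCConfig(
        iterations=iterations,
        burn_in=burn_in,
        seed=chain_seed,
        hyper=hyper,
        init_mode=init_mode,
    )
    trace = run_chain(X_train, mcfg)
    avg_cr = average_correct_rate(trace, burn_in, truth)
    summ = summarize(trace, burn_in)
    modal_cr = correct_rate(summ.modal_network, truth)
    stats = sufficient_stats(X_train, summ.modal_network)
    theta_hat = estimate_parameters(stats, hyper).theta
    rec: Dict[str, float] = {
        "n": n,
        "m": m,
        "theta": theta,
        "avg_cr": avg_cr,
        "modal_cr": modal_cr,
        "theta_hat_modal": theta_hat,
        "unique_models": summ.unique_model_count,
    }
    if with_prediction:
        rec["pred_acc"] = prediction_accuracy(trace, burn_in, X_test)
    return rec


def run_benchmark(
    sample_sizes: Sequence[int],
    noise_levels: Sequence[float],
    replicates: int,
    n: int = 20,
    iterations: int = 20_000,
    burn_in: int = 15_000,
    seed: int = 0,
    with_prediction: bool = False,
    train_fraction: float = 2.0 / 3.0,
    degree_probs: Tuple[float, float, float] = (0.2, 0.4, 0.4),
    hyper: Optional[Hyperparameters] = None,
    mode: str = "timeseries",
) -> Tuple[pd.DataFrame, Dict[Tuple[int, float], List[Dict[str, float]]]]:
    """Replicate the benchmark grid: for each (sample size, noise level)
    cell, generate fresh independent (network, data) pairs, run one chain
    each, and tabulate mean and standard error of the scores.

    Returns the summary table and the per-replicate records keyed by cell.
    One master seed spawns independent per-replicate streams, so each cell
    is reproducible in isolation.
    """
    master = np.random.SeedSequence(seed)
    rows = []
    details: Dict[Tuple[int, float], List[Dict[str, float]]] = {}
    for theta in noise_levels:
        for m in sample_sizes:
            cell_ss = np.random.SeedSequence(
                entropy=master.entropy, spawn_key=(int(m), int(round(theta * 1000)))
            )
            recs = []
            for r, child in enumerate(cell_ss.spawn(replicates)):
                rep_seed = int(child.generate_state(1)[0] // 2)
                recs.append(
                    run_replicate(
                        n, m, theta, iterations, burn_in, rep_seed,
                        with_prediction=with_prediction,
                        train_fraction=train_fraction,
                        degree_probs=degree_probs,
                        hyper=hyper,
                        mode=mode,
                    )
                )
            details[(m, theta)] = recs
            crs = np.array([r["avg_cr"] for r in recs])
            row = {
                "sample_size": m,
                "noise": theta,
                "replicates": replicates,
                "mean_CR": crs.mean(),
                "se_CR": crs.std(ddof=1) / np.sqrt(len(crs)) if len(crs) > 1 else 0.0,
            }
            if with_prediction:
                pa = np.array([r["pred_acc"] for r in recs])
                row["mean_pred_acc"] = pa.mean()
                row["se_pred_acc"] = (
                    pa.std(ddof=1) / np.sqrt(len(pa)) if len(pa) > 1 else 0.0
                )
            rows.append(row)
    return pd.DataFrame(rows), details
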