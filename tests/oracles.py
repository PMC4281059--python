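"""Independent test oracles: brute-force enumeration and numeric quadrature.

Everything here deliberately avoids the package's closed-form scoring paths
(betaln / incomplete-Beta algebra, incremental sufficient statistics) so it
can serve as an independent cross-check.
"""

from itertools import combinations, product

import networkx as nx
import numpy as np
from scipy import integrate
from scipy.special import betainc
from scipy.stats import beta as beta_dist

from boolbayes import Hyperparameters
from boolbayes.functions import enumerate_functions
from boolbayes.model import DataMatrix, SufficientStats, _log_function_prior
from boolbayes.topology import NetworkModel, Topology


def all_models(n):
    """Every valid (topology, functions) pair for a tiny network, via
    explicit product-and-filter with a networkx acyclicity check."""
    per_node = []
    for i in range(n):
        others = [j for j in range(n) if j != i]
        sets = (
            [()]
            + [(p,) for p in others]
            + [tuple(sorted(c)) for c in combinations(others, 2)]
        )
        per_node.append(sets)
    for combo in product(*per_node):
        G = nx.DiGraph()
        G.add_nodes_from(range(n))
        for i, pa in enumerate(combo):
            for p in pa:
                G.add_edge(p, i)
        if not nx.is_directed_acyclic_graph(G):
            continue
        topo = Topology(n, tuple(combo))
        fam = [enumerate_functions(len(pa)) if pa else (None,) for pa in combo]
        for funcs in product(*fam):
            yield NetworkModel(topo, tuple(funcs))


def brute_force_stats(X: DataMatrix, model: NetworkModel) -> SufficientStats:
    """Cell-by-cell mismatch counting with explicit Python loops."""
    P = X.parent_rows()
    C = X.child_rows()
    k = 0
    root_ones = {}
    for i, pa in enumerate(model.topology.parents):
        if not pa:
            root_ones[i] = int(sum(int(v) for v in C[:, i]))
            continue
        f = model.functions[i]
        for j in range(C.shape[0]):
            vals = tuple(int(P[j, p]) for p in pa)
            if f(vals) != int(C[j, i]):
                k += 1
    M = C.shape[0] * (model.topology.n - len(root_ones))
    return SufficientStats(k=k, M=M, root_ones=root_ones, m_eff=C.shape[0])


def quad_log_evidence(stats: SufficientStats, model: NetworkModel, h: Hyperparameters) -> float:
    """log integral of exp(log joint) over (theta, root probs) by adaptive
    1-D quadrature per factor (the joint factorizes by inspection)."""
    k, M, m = stats.k, stats.M, stats.m_eff
    prior_mass = betainc(h.alpha_theta, h.beta_theta, 0.5)
    total = 0.0
    if M > 0:
        def g(th):
            return (
                k * np.log(th)
                + (M - k) * np.log1p(-th)
                + beta_dist.logpdf(th, h.alpha_theta, h.beta_theta)
                - np.log(prior_mass)
            )
        shift = g(min(max((k + 1e-9) / M, 1e-6), 0.499))
        val, _ = integrate.quad(lambda th: np.exp(g(th) - shift), 0, 0.5, limit=200)
        total += np.log(val) + shift
    for s in stats.root_ones.values():
        def gr(p, s=s):
            return (
                s * np.log(p)
                + (m - s) * np.log1p(-p)
                + beta_dist.logpdf(p, h.a_root, h.b_root)
            )
        sh = gr(min(max((s + 0.5) / (m + 1), 1e-6), 1 - 1e-6))
        val, _ = integrate.quad(lambda p: np.exp(gr(p) - sh), 0, 1, limit=200)
        total += np.log(val) + sh
    return float(total + _log_function_prior(model))
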