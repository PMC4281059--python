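"""Likelihood, collapsed posterior, and parameter estimation.

The collapsed score is cross-checked against numeric quadrature of the
joint (the central analytic claim of the model), and the sufficient
statistics against cell-by-cell brute force.
"""

import math

import numpy as np
import pytest
from scipy import integrate

from oracles import brute_force_stats, quad_log_evidence

from boolbayes import (
    DataMatrix,
    GeneratorConfig,
    Hyperparameters,
    ParameterSet,
    SufficientStats,
    estimate_parameters,
    generate_study_instance,
    log_collapsed_posterior,
    log_joint_posterior,
    log_likelihood,
    sufficient_stats,
)
from boolbayes.functions import BooleanFunction
from boolbayes.model import log_noise_evidence
from boolbayes.simulate import generate_data, random_parameters
from boolbayes.topology import NetworkModel, Topology

H = Hyperparameters()

OR = BooleanFunction(2, (0, 1, 1, 1), "a OR b")


def or_toy():
    """3-node toy: c = a OR b, with 8 handwritten observation rows."""
    rows = [
        (0, 0, 0), (0, 1, 1), (1, 0, 1), (1, 1, 1),
        (0, 0, 1), (1, 1, 0), (0, 1, 0), (1, 0, 1),
    ]
    X = DataMatrix(np.array(rows), mode="independent")
    topo = Topology(3, ((), (), (0, 1)))
    model = NetworkModel(topo, (None, None, OR))
    return X, model


def test_sufficient_stats_on_handwritten_toy():
    X, model = or_toy()
    st = sufficient_stats(X, model)
    # rows 5, 6, 7 (0-indexed 4..6) disagree with OR
    assert st.k == 3
    assert st.M == 8
    assert st.root_ones == {0: 4, 1: 4}
    bf = brute_force_stats(X, model)
    assert (st.k, st.M, st.root_ones) == (bf.k, bf.M, bf.root_ones)


def test_noiseless_data_has_zero_mismatches():
    truth, params, _ = generate_study_instance(GeneratorConfig(n=6, m=20, theta=0.1, seed=3))
    clean = ParameterSet(theta=1e-12, root_probs=params.root_probs)
    for mode in ("independent", "timeseries"):
        X = generate_data(truth, clean, 30, mode, np.random.default_rng(0))
        assert sufficient_stats(X, truth).k == 0


def test_all_roots_stats():
    X = DataMatrix(np.ones((10, 2), dtype=int), mode="independent")
    topo = Topology(2, ((), ()))
    model = NetworkModel(topo, (None, None))
    st = sufficient_stats(X, model)
    assert st.M == 0 and st.root_ones == {0: 10, 1: 10}


def test_sufficient_stats_matches_brute_force_on_random_instance(small_instance):
    truth, _, X = small_instance
    st = sufficient_stats(X, truth)
    bf = brute_force_stats(X, truth)
    assert (st.k, st.M, st.root_ones, st.m_eff) == (bf.k, bf.M, bf.root_ones, bf.m_eff)


def test_log_likelihood_cellwise_oracle(small_instance):
    truth, params, X = small_instance
    st = sufficient_stats(X, truth)
    ll = log_likelihood(st, ParameterSet(theta=0.13, root_probs={
        i: 0.4 for i in st.root_ones}))
    # independent cell-by-cell accumulation
    P, C = X.parent_rows(), X.child_rows()
    acc = 0.0
    for i, pa in enumerate(truth.topology.parents):
        for j in range(C.shape[0]):
            if pa:
                pred = truth.functions[i](tuple(int(P[j, p]) for p in pa))
                acc += math.log(0.13) if pred != C[j, i] else math.log(0.87)
            else:
                acc += math.log(0.4) if C[j, i] else math.log(0.6)
    assert ll == pytest.approx(acc, rel=1e-12)


def test_theta_half_noise_part_ignores_k():
    st1 = SufficientStats(k=3, M=40, root_ones={}, m_eff=10)
    st2 = SufficientStats(k=29, M=40, root_ones={}, m_eff=10)
    p = ParameterSet(theta=0.499999999, root_probs={})
    assert log_likelihood(st1, p) == pytest.approx(log_likelihood(st2, p), rel=1e-6)
    assert log_likelihood(st1, p) == pytest.approx(40 * math.log(0.5), rel=1e-6)


def test_collapse_matches_quadrature_small_models():
    for seed in (0, 1, 2):
        truth, _, X = generate_study_instance(GeneratorConfig(n=3, m=30, theta=0.1, seed=seed))
        st = sufficient_stats(X, truth)
        lc = log_collapsed_posterior(st, truth, H)
        lq = quad_log_evidence(st, truth, H)
        assert abs(lc - lq) / abs(lq) < 1e-6


def test_collapse_matches_genuine_2d_quadrature():
    # find a model with exactly one root: then the joint is 2-dimensional
    for seed in range(50):
        truth, _, X = generate_study_instance(GeneratorConfig(n=3, m=20, theta=0.1, seed=seed))
        if len(truth.topology.roots()) == 1:
            break
    st = sufficient_stats(X, truth)
    lc = log_collapsed_posterior(st, truth, H)
    r = next(iter(st.root_ones))

    def joint(th, p):
        return log_joint_posterior(st, truth, ParameterSet(theta=th, root_probs={r: p}), H)

    shift = joint(0.1, min(max(st.root_ones[r] / st.m_eff, 0.01), 0.99))
    val, _ = integrate.dblquad(lambda p, th: np.exp(joint(th, p) - shift), 0, 0.5, 0, 1)
    assert np.log(val) + shift == pytest.approx(lc, abs=1e-6)


def test_joint_outside_truncated_support_is_minus_inf():
    st = SufficientStats(k=2, M=20, root_ones={0: 4}, m_eff=10)
    p = ParameterSet(theta=0.7, root_probs={0: 0.4})
    assert log_joint_posterior(st, _two_node_chain(), p, H) == float("-inf")


def _two_node_chain():
    f = BooleanFunction(1, (0, 1), "a")
    return NetworkModel(Topology(2, ((), (0,))), (None, f))


def test_function_prior_term_is_log10_for_extra_two_parent_node():
    # identical stats, one model has the node as root, the other with two
    # parents: the score difference is exactly -log 10
    st = SufficientStats(k=5, M=80, root_ones={0: 7}, m_eff=20)
    topo_root = Topology(4, ((), (0,), (0,), ()))
    f1 = BooleanFunction(1, (0, 1), "a")
    m_root = NetworkModel(topo_root, (None, f1, f1, None))
    topo_two = Topology(4, ((), (0,), (0,), (1, 2)))
    m_two = NetworkModel(topo_two, (None, f1, f1, OR))
    d = log_collapsed_posterior(st, m_two, H) - log_collapsed_posterior(st, m_root, H)
    assert d == pytest.approx(-math.log(10), abs=1e-12)


def test_flat_root_prior_closed_form():
    # with a = b = 1, a root with count s contributes log(s!(m-s)!/(m+1)!)
    m, s = 12, 5
    st0 = SufficientStats(k=0, M=0, root_ones={}, m_eff=m)
    st1 = SufficientStats(k=0, M=0, root_ones={0: s}, m_eff=m)
    topo0 = Topology(1, ((),))
    model0 = NetworkModel(topo0, (None,))
    d = log_collapsed_posterior(st1, model0, H) - log_collapsed_posterior(st0, model0, H)
    expect = math.log(
        math.factorial(s) * math.factorial(m - s) / math.factorial(m + 1)
    )
    assert d == pytest.approx(expect, rel=1e-12)


def test_collapsed_decreasing_in_k():
    model = _two_node_chain()
    M, m = 50, 50
    prev = None
    for k in range(0, 26):
        st = SufficientStats(k=k, M=M, root_ones={0: 20}, m_eff=m)
        lp = log_collapsed_posterior(st, model, H)
        if prev is not None:
            assert lp < prev
        prev = lp


def test_root_term_additivity():
    model = NetworkModel(Topology(2, ((), ())), (None, None))
    st_a = SufficientStats(k=0, M=0, root_ones={0: 3, 1: 7}, m_eff=15)
    st_b = SufficientStats(k=0, M=0, root_ones={0: 9, 1: 7}, m_eff=15)
    st_c = SufficientStats(k=0, M=0, root_ones={0: 3, 1: 2}, m_eff=15)
    ab = log_collapsed_posterior(st_b, model, H) - log_collapsed_posterior(st_a, model, H)
    # changing root 0 only: root 1's contribution cancels exactly
    st_a1 = SufficientStats(k=0, M=0, root_ones={0: 3, 1: 2}, m_eff=15)
    st_b1 = SufficientStats(k=0, M=0, root_ones={0: 9, 1: 2}, m_eff=15)
    ab1 = log_collapsed_posterior(st_b1, model, H) - log_collapsed_posterior(st_a1, model, H)
    assert ab == pytest.approx(ab1, rel=1e-12)


def test_relabeling_invariance(small_instance):
    truth, params, X = small_instance
    n = truth.topology.n
    perm = np.random.default_rng(9).permutation(n)
    inv = np.argsort(perm)
    # permute data columns and model consistently: new node perm[i] = old i
    Xp = DataMatrix(X.values[:, inv], mode=X.mode)
    parents = [()] * n
    funcs = [None] * n
    for i, pa in enumerate(truth.topology.parents):
        newpa = tuple(sorted(int(perm[p]) for p in pa))
        parents[perm[i]] = newpa
        f = truth.functions[i]
        if f is not None and f.arity == 2 and perm[pa[0]] > perm[pa[1]]:
            t = f.table
            f = BooleanFunction(2, (t[0], t[2], t[1], t[3]), f.label)
        funcs[perm[i]] = f
    mp = NetworkModel(Topology(n, tuple(parents)), tuple(funcs))
    lc = log_collapsed_posterior(sufficient_stats(X, truth), truth, H)
    lcp = log_collapsed_posterior(sufficient_stats(Xp, mp), mp, H)
    assert lc == pytest.approx(lcp, rel=1e-12)


def test_estimate_parameters_closed_forms():
    st = SufficientStats(k=0, M=100, root_ones={}, m_eff=25)
    est = estimate_parameters(st, H)
    assert est.theta == pytest.approx(1.0 / 110.0, rel=1e-9)
    assert not est.theta_is_prior_mean
    m = 20
    st2 = SufficientStats(k=1, M=40, root_ones={0: m // 2}, m_eff=m)
    est2 = estimate_parameters(st2, H)
    assert est2.root_probs[0] == pytest.approx((m / 2 + 1) / (m + 2), rel=1e-12)


def test_estimate_parameters_prior_mean_when_no_evidence():
    st = SufficientStats(k=0, M=0, root_ones={0: 5}, m_eff=10)
    est = estimate_parameters(st, H)
    assert est.theta_is_prior_mean
    # equals the truncated-prior mean computed by independent quadrature
    from scipy.stats import beta as beta_dist
    num, _ = integrate.quad(lambda t: t * beta_dist.pdf(t, 1, 9), 0, 0.5)
    den, _ = integrate.quad(lambda t: beta_dist.pdf(t, 1, 9), 0, 0.5)
    assert est.theta == pytest.approx(num / den, rel=1e-9)


def test_theta_recovery_at_m500():
    truth, params, X = generate_study_instance(
        GeneratorConfig(n=10, m=500, theta=0.1, seed=17, mode="timeseries")
    )
    st = sufficient_stats(X, truth)
    est = estimate_parameters(st, H)
    assert abs(est.theta - 0.1) < 0.03


def test_noise_evidence_vetoes_complement_regime():
    # mismatch count above M/2 implies theta > 1/2: effectively vetoed
    lo = log_noise_evidence(100, 1000, H)
    hi = log_noise_evidence(900, 1000, H)
    assert hi < lo - 300


def test_hyperparameter_validation():
    with pytest.raises(ValueError):
        Hyperparameters(alpha_theta=5, beta_theta=5)  # prior mean not < 0.5
    with pytest.raises(ValueError):
        Hyperparameters(a_root=-1)
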