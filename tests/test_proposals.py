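"""Chi-square screening and the annealed mixture proposal."""

import numpy as np
import pytest

from boolbayes import DataMatrix, GeneratorConfig, generate_study_instance
from boolbayes.functions import BooleanFunction, enumerate_functions
from boolbayes.proposals import (
    ROOT_MOVE,
    NodeTables,
    ProposalSchedule,
    build_node_proposal,
    fit_relation,
    mixture_draw,
    proposal_probability,
    screen_candidates,
    CandidateRelation,
)

OR = BooleanFunction(2, (0, 1, 1, 1), "a OR b")
IDENT = BooleanFunction(1, (0, 1), "a")


def make_relation_data(m, theta, rng, p_a=0.5, p_b=0.5, f=OR):
    a = (rng.random(m) < p_a).astype(int)
    b = (rng.random(m) < p_b).astype(int)
    tab = np.array(f.table)
    y = tab[2 * a + b] ^ (rng.random(m) < theta)
    return DataMatrix(np.column_stack([a, b, y]), mode="independent")


def test_noiseless_relation_has_zero_chisq():
    X = make_relation_data(200, 0.0, np.random.default_rng(0))
    c = fit_relation(X, 2, (0, 1), OR)
    assert c.theta_hat == 0.0
    assert c.chisq_stat == pytest.approx(0.0, abs=1e-12)
    assert c.p_value == pytest.approx(1.0)


def test_theta_hat_estimates_noise_level():
    X = make_relation_data(5000, 0.15, np.random.default_rng(1))
    c = fit_relation(X, 2, (0, 1), OR)
    assert c.theta_hat == pytest.approx(0.15, abs=0.02)
    assert c.weight == pytest.approx(1.0 / c.theta_hat)


def test_true_relation_retained_by_screen():
    # calibration: at alpha = 0.05, m = 300, the true combination survives
    # in >= 90% of replicates at both study noise levels
    for theta in (0.1, 0.2):
        rng = np.random.default_rng(42)
        kept = 0
        reps = 40
        for _ in range(reps):
            X = make_relation_data(300, theta, rng, p_a=0.4, p_b=0.6)
            c = fit_relation(X, 2, (0, 1), OR)
            kept += c.p_value > 0.05
        assert kept >= 0.9 * reps


def test_wrong_parent_pair_mostly_rejected():
    # child driven by its own parents; an unrelated candidate pair with a
    # non-degenerate function is rejected in the large majority of cases
    rng = np.random.default_rng(7)
    rejected = 0
    reps = 20
    for _ in range(reps):
        m = 500
        a = (rng.random(m) < 0.5).astype(int)
        b = (rng.random(m) < 0.5).astype(int)
        tab = np.array(OR.table)
        y = tab[2 * a + b] ^ (rng.random(m) < 0.1)
        c = (rng.random(m) < 0.3).astype(int)
        d = (rng.random(m) < 0.7).astype(int)
        X = DataMatrix(np.column_stack([a, b, y, c, d]), mode="independent")
        rel = fit_relation(X, 2, (3, 4), OR)
        rejected += rel.p_value < 0.05
    assert rejected >= 0.7 * reps


def test_chisq_invariant_under_parent_relabeling():
    rng = np.random.default_rng(3)
    f = BooleanFunction(2, (0, 0, 1, 0), "a AND NOT b")
    X = make_relation_data(400, 0.1, rng, p_a=0.3, p_b=0.6, f=f)
    c1 = fit_relation(X, 2, (0, 1), f)
    # swap columns 0 and 1 and permute the table consistently
    Xs = DataMatrix(X.values[:, [1, 0, 2]], mode="independent")
    t = f.table
    fs = BooleanFunction(2, (t[0], t[2], t[1], t[3]), "swapped")
    c2 = fit_relation(Xs, 2, (0, 1), fs)
    assert c1.chisq_stat == pytest.approx(c2.chisq_stat, rel=1e-12)
    assert c1.theta_hat == pytest.approx(c2.theta_hat, rel=1e-12)


def test_table1_cell_probability_structure():
    # expected count for pattern (0,0) with child 1 under y = OR(a,b) is
    # m * p00_hat * theta_hat
    rng = np.random.default_rng(5)
    X = make_relation_data(400, 0.1, rng)
    from boolbayes.proposals import _gof, _pattern_counts

    counts = _pattern_counts(X, 2, (0, 1))
    tables = np.array([OR.table])
    k, th, stat, pv, low = _gof(counts, tables, X.m_eff)
    p00_hat = counts[0].sum() / X.m_eff
    # reconstruct the (0,0,y=1) expected cell by hand
    expected = X.m_eff * p00_hat * th[0]
    # mismatch cell at pattern 0 is y=1 since OR(0,0)=0
    assert counts[0, 1] == pytest.approx(expected, abs=4 * np.sqrt(expected + 1))


def test_screen_counts_and_limits():
    truth, _, X = generate_study_instance(
        GeneratorConfig(n=8, m=60, theta=0.1, seed=2, mode="timeseries")
    )
    t = NodeTables(X, 0, 0.05)
    n = 8
    # all combinations are fitted: (n-1)*2 one-parent, C(n-1,2)*10 two-parent
    assert int((t.pv1 > 0).sum()) <= (n - 1) * 2
    assert t.k1.shape == (n, 2) and t.k2.shape == (n, n, 10)
    # alpha -> 1 rejects everything
    assert screen_candidates(X, 0, 1 - 1e-12) == []
    # alpha -> 0 keeps every combination whose mismatch rate is below 1/2
    cands = screen_candidates(X, 0, 1e-300)
    expected = int((t.th1[[i for i in range(n) if i != 0]] < 0.5).sum())
    for a in range(n):
        for b in range(a + 1, n):
            if 0 in (a, b):
                continue
            expected += int((t.th2[a, b] < 0.5).sum())
    assert len(cands) == expected
    assert all(c.theta_hat < 0.5 for c in cands)


def test_preferential_weights_normalize():
    sched = ProposalSchedule(anneal_length=10, floor=0.1)
    c1 = CandidateRelation(0, (1,), IDENT, 0.1, 0.0, 0.9, 10.0)
    c2 = CandidateRelation(0, (2,), IDENT, 0.2, 0.0, 0.9, 5.0)
    prop = build_node_proposal([c1, c2], 0, 4, sched, m_eff=50)
    allowed = np.array([False, True, True, True])
    # preferential probabilities 2/3 and 1/3 at lambda = 1
    p1 = prop.probability(((1,), 0), 0, allowed)
    p2 = prop.probability(((2,), 0), 0, allowed)
    assert p1 / p2 == pytest.approx(2.0, rel=1e-12)


def test_probabilities_sum_to_one_over_legal_set():
    truth, _, X = generate_study_instance(
        GeneratorConfig(n=6, m=50, theta=0.1, seed=4, mode="timeseries")
    )
    sched = ProposalSchedule(anneal_length=100, floor=0.1)
    prop = None
    from boolbayes.proposals import build_all_proposals

    prop = build_all_proposals(X, 0.05, sched)[2]
    allowed = np.array([True, True, False, True, False, True])
    for t in (0, 50, 500):
        total = prop.probability(ROOT_MOVE, t, allowed)
        idx = np.flatnonzero(allowed)
        for p in idx:
            for fid in range(2):
                total += prop.probability(((int(p),), fid), t, allowed)
        for i, a in enumerate(idx):
            for b in idx[i + 1:]:
                for fid in range(10):
                    total += prop.probability(((int(a), int(b)), fid), t, allowed)
        assert total == pytest.approx(1.0, rel=1e-12)


def test_draw_frequencies_match_probabilities():
    truth, _, X = generate_study_instance(
        GeneratorConfig(n=5, m=60, theta=0.1, seed=6, mode="timeseries")
    )
    sched = ProposalSchedule(anneal_length=100, floor=0.3)
    from boolbayes.proposals import build_all_proposals

    prop = build_all_proposals(X, 0.05, sched)[0]
    allowed = np.array([False, True, True, True, True])
    rng = np.random.default_rng(11)
    t = 60
    N = 100_000
    counts = {}
    for _ in range(N):
        c = mixture_draw(prop, t, allowed, rng)
        counts[c] = counts.get(c, 0) + 1
    for cand, cnt in counts.items():
        if cand is None:
            continue
        p = proposal_probability(prop, cand, t, allowed)
        se = np.sqrt(p * (1 - p) / N)
        assert abs(cnt / N - p) < max(5 * se, 2e-3)


def test_no_screened_candidates_falls_back_to_uniform():
    sched = ProposalSchedule(anneal_length=10, floor=0.1)
    prop = build_node_proposal([], 0, 4, sched, m_eff=50)
    allowed = np.array([False, True, True, True])
    # at t=0 (lambda=1) draws still come out uniform
    assert not prop.has_preferential
    p = prop.probability(((1,), 0), 0, allowed)
    assert p == pytest.approx((1 / 3) / 6, rel=1e-12)  # 3 parents * 2 funcs


def test_schedule_lambda_bounds():
    sched = ProposalSchedule(anneal_length=100, floor=0.25)
    assert sched.lam(0) == 1.0
    assert sched.lam(50) == pytest.approx(0.5)
    assert sched.lam(100) == 0.25
    assert sched.lam(10_000) == 0.25


def test_screen_is_deterministic_given_data():
    truth, _, X = generate_study_instance(
        GeneratorConfig(n=6, m=50, theta=0.1, seed=8, mode="timeseries")
    )
    a = screen_candidates(X, 3, 0.05)
    b = screen_candidates(X, 3, 0.05)
    assert [(c.parent_set, c.function.table, c.weight) for c in a] == [
        (c.parent_set, c.function.table, c.weight) for c in b
    ]
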