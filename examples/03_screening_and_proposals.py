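"""Chi-square screening of candidate regulators for one gene.

Fits every (parent set, function) combination for a chosen gene, shows
which pass the goodness-of-fit screen, and how the survivors are weighted
in the sampler's preferential proposal distribution.
"""

from boolbayes import GeneratorConfig, generate_study_instance, screen_candidates

truth, params, X = generate_study_instance(
    GeneratorConfig(n=10, m=300, theta=0.1, seed=11, mode="timeseries")
)
node = next(i for i, pa in enumerate(truth.topology.parents) if len(pa) == 2)
true_pa = truth.topology.parents[node]
true_f = truth.functions[node]
print(f"gene {node} is truly regulated as {true_f.label!r} with parents {true_pa}")

cands = screen_candidates(X, node, alpha_screen=0.05)
ntested = (X.n - 1) * 2 + (X.n - 1) * (X.n - 2) // 2 * 10
print(f"{ntested} combinations tested, {len(cands)} pass the screen (p > 0.05)")

for c in sorted(cands, key=lambda c: -c.weight)[:5]:
    mark = " <- truth" if (c.parent_set, c.function.table) == (true_pa, true_f.table) else ""
    print(f"  parents {c.parent_set} {c.function.label!r:22s} "
          f"theta_hat={c.theta_hat:.3f} p={c.p_value:.3f} weight={c.weight:.1f}{mark}")
# The weight is 1/theta_hat: combinations that explain the child with
# fewer mismatches are proposed more often by the sampler.
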