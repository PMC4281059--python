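"""A miniature accuracy benchmark over sample sizes and noise levels.

For each cell, fresh random networks and data are generated, one chain is
run per dataset, and the mean correct rate (with standard error) is
tabulated — a desk-scale version of the published simulation study.
Expect a few minutes of runtime.
"""

from boolbayes import run_benchmark

table, details = run_benchmark(
    sample_sizes=[50, 200],
    noise_levels=[0.1, 0.2],
    replicates=3,
    n=10,
    iterations=2000,
    burn_in=1000,
    seed=0,
)
print(table.to_string(index=False))
# mean_CR rises with the sample size and falls with the noise level; the
# per-replicate records in `details` include modal-network correct rates
# and the conditional noise-rate estimates.
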