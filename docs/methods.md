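# Methods

## Model

`boolbayes` infers a gene regulatory network over `n` binary-valued genes
from an `m x n` 0/1 expression matrix. The network is a directed acyclic
graph `G` in which every node has at most two parents, together with one
non-degenerate Boolean function `f_i` per regulated (non-root) node. Data
are modelled as

* root nodes (no parents): independent Bernoulli draws with gene-specific
  rates `p_i`;
* regulated nodes: `x_i = f_i(parents) XOR e`, with `e ~ Bernoulli(theta)`
  an i.i.d. noise bit and a single noise rate `theta` shared by all
  regulated nodes.

Two observation regimes are supported. In *independent* mode a child reads
its parents from the same row; in *time-series* mode row `j`'s regulated
values are driven by row `j-1`, so `m` observations yield `m-1` usable
transitions (a *transitions* representation stores explicit parent/child
row pairs, e.g. after a random train/test split). The effective sample
size `m_eff` (rows or transitions) is used uniformly for all nodes.

Non-degeneracy means the function output depends on every input; this
leaves 2 one-input functions (identity, NOT) and 10 two-input functions
(AND, OR, XOR, their negations, and the four AND/OR forms with exactly one
negated input). Functions are canonicalized by truth table — semantically
equal formulas collapse to one object — because the uniform prior over
function choices is only well defined over distinct functions. Parent sets
are stored sorted ascending and two-input tables are indexed by
(smaller-index parent value, larger-index parent value).

## Priors and the collapsed posterior

Conjugate Beta priors are placed on the continuous parameters:
`theta ~ Beta(alpha, beta)` **truncated to (0, 1/2)** and
`p_i ~ Beta(a, b)`; the topology prior is uniform over valid DAGs (an
additive constant that cancels from every Metropolis ratio and is never
evaluated), and given `G` the function of each regulated node is uniform
over its 2 or 10 choices.

The truncation is a model requirement, not a numerical convenience:
complementing every Boolean function while replacing `theta` with
`1 - theta` leaves the likelihood exactly invariant, so without the
restriction the posterior carries a mirror mode in which every function is
negated and the "noise" rate sits near one. Untruncated chains were
observed to fall into that basin (pooled mismatch rate 0.88 with every
inferred function the complement of the truth). Restricting the noise
rate below one half — noise flips must be the exception — breaks the
symmetry exactly.

With counts `k` (total mismatches over regulated cells), `M = m_eff *
(n - r)` (total regulated cells, `r` roots) and `s_i` (ones per root), the
parameters integrate out in closed form. Up to one shared constant,

```
log pi(G, F | X) = log B(k+alpha, M-k+beta) + log I_{1/2}(k+alpha, M-k+beta)
                 - log B(alpha, beta) - log I_{1/2}(alpha, beta)
                 + sum_roots [ log B(s_i+a, m_eff-s_i+b) - log B(a, b) ]
                 - sum_regulated log c(|Pa_i|),     c(1)=2, c(2)=10,
```

where `I_x` is the regularized incomplete Beta function. All scoring is in
log space. This closed form is verified in the test suite against numeric
quadrature of the joint posterior (1e-6 relative tolerance, plus one
genuine 2-D quadrature case).

Defaults: `alpha=1, beta=9` (prior mean 0.1 — the noise rate should be
small, and the prior mean must sit below one half), `a=b=1` (flat — used
when nothing is known about the roots). Conditional on `(G, F)`, the
posterior-mean estimates `theta_hat` (renormalized to the truncated
support) and `p_hat_i` are exact.

## Proposal construction (chi-square screening)

For every node, all `(n-1)*2` one-parent and `C(n-1,2)*10` two-parent
(parent set, function) combinations are fitted once, before sampling:
pattern probabilities are estimated as empirical frequencies, the mismatch
rate `theta_hat` as the fraction of rows where the child differs from the
function output, and a Pearson chi-square statistic compares observed
joint (pattern, child) cell counts with their expectations
`m_eff * p_hat_x * theta_hat` (mismatch cells) and
`m_eff * p_hat_x * (1-theta_hat)` (match cells). Degrees of freedom are
`2^arity - 1`: cells minus one, minus the `2^arity - 1` estimated pattern
probabilities, minus one for `theta_hat`. Cells with zero expectation are
skipped; candidates with any expected count below one are flagged
unreliable but kept (screening only shapes proposals, never the
posterior). Combinations that are not rejected (`p > alpha_screen`,
default 0.05) and have `theta_hat < 1/2` (mismatch rates above one half
belong to the complement function, which is screened in its own right)
become preferential candidates weighted `1/max(theta_hat, 1/(2 m_eff))` —
the floor keeps perfect fits finite while preserving their strong
preference.

Proposals mix a weighted multinomial over screened candidates with a
uniform distribution over all legal combinations of the chosen arity. The
preferential proportion anneals as `lambda_t = max(rho, 1 - t/T)` with
`T` = half the burn-in and floor `rho = 0.1`; a move first picks a target
arity uniformly from {0, 1, 2} (arity 0 = make the node a root, always
legal). Screening is a fixed preprocessing step: candidates never change
during the chain, so every combination's mismatch count is precomputed as
a dense integer array and each Metropolis step scores in O(1).

## Sampling

A Metropolis-within-Gibbs sweep visits the nodes in index order (random
order is a config option) and resamples each node's entire (parent set,
function) pair in one Metropolis-Hastings step — this realizes the
add / remove / swap parent moves as a single move type with a tractable
proposal density. A candidate parent set is *legal* iff none of its
members is a descendant of the node; since a node's own in-edges never
affect its descendant set, forward and reverse moves see the identical
legal set and the Hastings ratio is evaluated on the same support both
ways. Acceptance is `min(1, exp(delta log posterior) * q_rev/q_fwd)`.
During the pure-preferential phase (`lambda = 1`) a reverse move to an
unscreened relation has zero proposal density and the move is rejected;
irreducibility holds as soon as `lambda < 1` because arity 0 is always
legal and every model is reachable from the empty network by legal
single-node moves (asserted in tests).

Because all mismatch counts are precomputed integers, the incremental
sufficient statistics are exact — there is no floating-point drift to
guard against, and equality between the incremental score and a
from-scratch recomputation is asserted directly in the tests (1e-9).
The noise-evidence term is tabulated over all (root count, flip count)
pairs at startup, making a node update independent of both `m` and the
candidate space size.

Defaults follow the published protocol: 20,000 sweeps, 15,000 burn-in,
thinning 1. Posterior summaries report the modal network (ties broken by
higher recorded log posterior, then first occurrence), per-node relation
frequencies, and the number of unique sampled models.

## Synthetic data: what it emulates

The generator reproduces the benchmark design: per node an in-degree is
drawn from `degree_probs` (default (0.2, 0.4, 0.4) over {0, 1, 2} — the
reference design states only that the probabilities sum to one; this
default yields a realistic mix of roots and regulated nodes), parents are
uniform without replacement, the whole draw is rejected and restarted if
cyclic, functions are uniform over the non-degenerate choices, and
parameters are drawn from the priors unless pinned (the benchmark pins
`theta` at 0.1 or 0.2).

The benchmark harness generates **synchronized time-series** data: roots
are redrawn each step and regulated nodes follow their parents' previous
values. This is the regime in which the reference accuracy table is
attainable: with independent rows, every ancestor/descendant pair is
correlated *within* a row, and an exhaustive per-node computation of the
conditional posterior (all ~1,750 relations per node, everything else
held at the truth) shows the resulting direction-reversal and
echo-reconstruction ambiguities cap the attainable mean correct rate well
below the reference values at small and moderate sample sizes — no
correct sampler can do better than the posterior it targets. Under lag-1
dynamics those within-row correlations vanish and identifiability is
restored. Both modes remain available throughout the API.

What the generator does not emulate: scale-free or otherwise biologically
structured topologies, per-node noise rates, unsynchronized or missing
time points, and continuous expression intensity (real data must first be
binarized; the package applies a per-gene mean threshold, strictly
greater mapping to 1). Passing benchmarks on this generator therefore
demonstrates correctness of the inference machinery under the model's own
assumptions, not performance on real microarray data.

## Numerical and design choices

* Weight floor `1/(2 m_eff)` for perfect-fit candidates; arity choice
  uniform over {0, 1, 2} (any fixed positive choice is corrected by the
  Hastings ratio).
* Proposal draws falling on an arity with no legal combination are null
  moves (state unchanged); they cannot occur for arity 0.
* The incomplete-Beta mass is floored at 1e-300 before taking logs so
  complement-regime states are vetoed by a large finite penalty rather
  than infinities propagating through Metropolis ratios.
* Modal-network tie-breaking: frequency, then best recorded log
  posterior, then first occurrence.
* Benchmark seeding: one master seed spawns an independent stream per
  (cell, replicate), so any cell is reproducible in isolation.
* Reduced benchmark protocol used by the tests and the acceptance script:
  5 replicate networks per cell and 8,000 sweeps (5,000 burn-in) — the
  problem sizes chosen for a desk-scale study; the full 20-replicate,
  20,000-sweep protocol is available through the same API.

## Known limitations

* Per-node (blocked single-site) updates cannot cross deep multi-node
  posterior barriers; with independent-row data the posterior can split
  into direction-reversal twin basins separated by tens of nats, and a
  chain will sample only the basin it reaches first. Mode-escape
  techniques (tempering, multi-node blocks) are deliberately out of
  scope.
* At small sample sizes with uninformative (near-constant) root genes,
  downstream relations are genuinely unidentifiable; the posterior —
  and therefore any faithful sampler — spreads over alternatives, and
  mean correct rates at m=50 sit below the reference table's values
  (see the benchmark outputs; nothing is tuned to mask this).
* In-degree is capped at 2 and feedback loops are excluded by the DAG
  assumption; both are acknowledged simplifications of real regulatory
  biology.
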