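# Methods

## Rank normalization

Each sample (column) is transformed independently: with N probes, the rank
of probe *i* is `100 · #{j : x_j < x_i} / N`. This is the strict-lower
convention — rank 55 means 55% of the sample's probes have strictly lower
intensity — so ties share the rank of the group's minimum and every value
lies in `[0, 100)`; a sample of all-equal values ranks to all zeros. A
`midrank` tie policy (tied values receive the mean of the positions they
span) is available for heavily tied summaries; both policies coincide on
tie-free data. Ranking is computed over **all** probes of the matrix as
loaded, before any probe→gene collapsing, because the percentile is defined
against the whole array; the pipeline functions enforce this stage order
(rank, then collapse).

Ranks are invariant under positive affine and, more generally, strictly
increasing per-sample transforms, which is the property that makes
cross-cohort comparison meaningful without between-array normalization.

## Coexpression

The coexpression of two genes over a sample set is the Pearson
product-moment correlation of their rank profiles. Correlations on fewer
than 3 samples, or involving a constant vector, are errors rather than
NaNs — this guarantees the greedy loop below can never propagate a
meaningless value. The result is clamped to `[-1, 1]` against floating
round-off.

## Greedy cohort split

The optimization target is the cohort-1 correlation. From cohort 1 = all
samples, each iteration evaluates every member's leave-one-out correlation
and moves the sample whose removal yields the largest increase, stopping
when the best increase is ≤ `tol` (default 1e−12, a float-noise guard) or
when cohort 1 reaches `min_cohort1` (default `max(10, ⌈0.05 n⌉)` — tiny
cohorts produce arbitrarily inflated correlations, so a floor is needed
even though the procedure itself does not require one). The procedure is
strictly greedy: no backtracking, no global subset search, and cohort 2 is
defined purely as the removed remainder.

Determinism: deltas within `1e−9` of the maximum are treated as tied and
the lexicographically smallest sample id moves. The tie window is far below
any scientifically meaningful correlation difference; it exists because
duplicated (x, y) pairs — common on rank data — produce mathematically
equal deltas whose floating-point evaluations differ in the last ulp
depending on summation order.

Two leave-one-out evaluators are provided and interchangeable:

* `exact` (default): each candidate correlation recomputed from scratch,
  O(n) per candidate, O(n²) per iteration;
* `downdate`: the cohort's sufficient statistics (Σx, Σy, Σx², Σy², Σxy)
  are downdated per candidate in O(1), vectorized.

They agree to better than 1e−10 on every tested dataset (the acceptance
suite verifies identical partitions and traces); Monte-Carlo experiments
use `downdate` for speed. A candidate whose removal would leave a constant
vector is excluded from candidacy and logged.

The correlation trace is strictly increasing after index 0 by
construction, so the final cohort-1 correlation always dominates the
full-sample one. At most `n − min_cohort1` iterations run.

### What the split does and does not find

On a half-planted mixture (ρ_in = 0.9, ρ_out = 0, n = 200) the retained
cohort is strongly *enriched* for the planted subpopulation (mean purity
≈ 0.8 at the default floor), but exact membership recovery is impossible
for any method: the Bayes-optimal classifier knowing the true generating
model reaches only ≈ 0.76 two-sided accuracy at these parameters, because
an uncorrelated sample that happens to fall near the regression line is
genuinely indistinguishable from a planted one. Greedy classification
accuracy at the planted size measures ≈ 0.73. Consequences propagate to
survival power: when the planted members carry a hazard ratio of 3, each
greedy cohort is a ≈ 74/26 hazard mixture, the between-cohort contrast
shrinks to roughly HR^0.5 with frailty-type hazard convergence, and the
log-rank power of the cohort comparison is ≈ 0.8 (200-replicate estimate)
rather than the ≈ 1.0 of the single-marker design below.

## Survival analysis

Kaplan–Meier estimation is delegated to lifelines' product-limit fitter;
the curve is reported at the distinct event times with at-risk and event
counts. The two-group log-rank statistic is computed in-package from the
pooled event-time 2×2 tables (`(O₁−E₁)²/V`, χ² on 1 df, two-sided), because
the degenerate contracts matter to the pipeline: zero total events is an
error, and V = 0 (no between-group information, e.g. duplicated groups at
every event time) is reported as statistic 0, p = 1 rather than NaN.
lifelines' `logrank_test` serves as an independent cross-check in the test
suite. Ties between an event and a censoring at the same time follow the
standard convention that the event precedes the censoring.

The single-marker design splits samples at a quantile of the gene's rank
values (default median, configurable); samples strictly above the quantile
are "high". A split leaving either group empty (e.g. constant expression)
is an error suggesting a different cutoff.

## Synthetic data

`simulate_dataset` emulates the statistical structure the analysis
assumes, not any particular platform:

* Exactly `⌊f·n⌋` randomly chosen samples form the interaction
  subpopulation; their focal-pair values are bivariate normal with
  correlation `rho_in` (Cholesky construction), everyone else's with
  `rho_out`. Default f = 0.5, ρ_in = 0.9, ρ_out = 0, n = 200.
* Background probes (default 100) are independent Gaussians; all
  expression marginals are Gaussian with σ = `noise_sigma` (default 1).
  Because the pipeline ranks per sample, marginal shape is irrelevant
  downstream; heavier-tailed marginals are deliberately not the default.
* Survival times are exponential with rate `baseline_hazard ×
  hazard_ratio^{flag}`, the flag marking interaction members, high
  expressers of gene A, or nobody. Default baseline ln2/12 ≈ 0.0578 per
  time unit (median event time 12, months in spirit). Censoring is
  independent exponential at `censoring_rate`, default ln2/36 — a
  realistic ≈ 25% censoring fraction; an administrative cutoff is not
  applied.
* One `SeedSequence` per dataset spawns fixed substreams (assignment,
  focal pair, background, survival, censoring), so outputs are
  bit-reproducible across platforms and any one stage can change without
  perturbing the others' draws.

Not emulated: probe-level effects, batch effects, intensity-dependent
variance, non-proportional hazards, informative censoring. Passing tests
therefore demonstrate the algorithmic and statistical correctness of the
pipeline under its own model assumptions, not robustness to microarray
artefacts.

## Numerical and design choices

* Expression files are parsed with the correctly-rounded string→float64
  converter (not pandas' fast path) so write/read round-trips are
  bit-exact.
* Probe collapsing policies: `max_variance` default (most informative
  single probe; deterministic via lexicographic tie-break), `mean`, and
  `named_probe` for panels where the reporter is known.
* Missing expression values are rejected by default; per-probe mean
  imputation is available behind an explicit switch.
* Sample alignment keeps matrix column order and is idempotent; fewer
  than two shared ids is an error.
* Monte-Carlo problem sizes: 1000 replicates for log-rank calibration,
  500 for the cohort-comparison null, 20 seeds for recovery and power —
  sizes at which binomial error is small relative to the effects checked
  while the full acceptance run stays under a minute.

## Known limitations

* The greedy split optimizes cohort 1 only; it is not a globally optimal
  subset selection, and the achieved correlation is selection-biased
  upward — it must not be read as an estimate of the subpopulation
  correlation, nor tested for significance as if it were pre-specified.
* `min_cohort1` materially shapes the result on noisy data: with a
  near-zero tolerance the trace keeps creeping upward, so the split will
  usually run down to the floor. Choose the floor from the science (the
  smallest cohort worth interpreting), not from the trace.
* Log-rank power statements above assume proportional hazards within each
  generated group; mixtures violate this mildly (see the purity
  discussion).
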