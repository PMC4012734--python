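# coexsurv

Coexpression-and-survival analysis for gene-expression cohorts: per-sample
percentile rank normalization, Pearson coexpression of a gene pair, a greedy
sample-removal algorithm that splits a patient cohort to maximize the pair's
positive correlation, and Kaplan–Meier / log-rank comparison of the resulting
groups. A built-in simulator generates expression matrices with a planted
correlated subpopulation and linked proportional-hazards survival tables, so
the entire pipeline runs and is testable without downloading any data.

## Who is this for

Researchers asking whether two genes (say, a transcription factor and a
candidate target such as p63 and MMP13) are coexpressed in only a subset of
tumours, and whether that putative regulatory interaction carries prognostic
information. Real inputs are a probes × samples expression matrix (TSV, GEO
series-matrix orientation), a per-sample survival table, and an optional
probe → gene map.

## The method

**Rank normalization.** Within each sample, every probe's intensity is
replaced by its percentile rank on a 0–100 scale: rank *r* means *r*% of the
probes in that sample have strictly lower measured values (ties share a
rank). Ranks need no between-array normalization and are invariant to any
monotone per-sample distortion.

**Coexpression.** For genes *x*, *y* with rank profiles over samples
*S*, the coexpression is the Pearson product-moment coefficient
*r(x, y; S)*.

**Greedy cohort split.** Starting from cohort 1 = all samples, each
iteration computes, for every current member *i*, the leave-one-out
correlation *r(x, y; S \ {i})*. The member whose removal maximally
increases the correlation is moved to cohort 2, provided the increase
exceeds a tolerance (default 1e−12); iteration stops when no single removal
helps, or when cohort 1 reaches a floor (default max(10, 5% of *n*)).
Cohort 1 is the correlation-maximized "interaction" group, cohort 2 the
removed "no-interaction" remainder.

**Survival comparison.** Kaplan–Meier curves S(t) = Π(1 − dᵢ/nᵢ) are
estimated per group and compared with the two-group log-rank (Mantel–Cox)
test, χ² = (O₁ − E₁)²/V on 1 df. Two designs are supported: high vs low
expressers of a single gene at a quantile cutoff (default median), and
cohort 1 vs cohort 2 from the greedy split.

## Worked example

```sh
coexsurv simulate --n-samples 200 --seed 42 --out demo/sim
coexsurv coexpr --matrix demo/sim/matrix.tsv --gene-a TP63 --gene-b MMP13
coexsurv interaction-survival --matrix demo/sim/matrix.tsv \
    --surv demo/sim/survival.tsv --gene-a TP63 --gene-b MMP13 \
    --min-cohort1 100 --out demo/run
```

prints

```
wrote demo/sim/matrix.tsv (102 probes x 200 samples)
TP63	MMP13	n=200	r=0.4535
TP63/MMP13	cohort1 n=100 r=0.9786	cohort2 n=100	chi2=0.0202	p=0.8871
```

The simulated cohort plants the TP63/MMP13 correlation (ρ = 0.9) in half of
the 200 samples; over everyone it is diluted to r = 0.45. The greedy split
recovers a 100-sample cohort with r = 0.98, and — because survival was
generated independently of expression here — the log-rank comparison of the
two cohorts is, correctly, far from significant (p = 0.89). `demo/run/`
holds the partition, the per-step correlation trace, per-cohort KM curves
(TSV) and a JSON manifest with config echo and output checksums.

The same analyses are callable as library functions
(`coexsurv.run_coexpr`, `run_marker_survival`, `run_interaction_survival`)
on `ExpressionMatrix` / `SurvivalTable` objects.

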