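# Methods

## The model in brief

`stemscore` builds a stemness-risk gene score (SGS) for transcriptomic
cohorts.  Given a genes × samples expression matrix, a collection of
stemness gene sets and overall-survival follow-up, the pipeline is

1. **ssGSEA** — a per-sample enrichment score (ES) for every gene set,
   normalized across the cohort to NES;
2. **Cox screen** — a univariate proportional-hazards fit of each set's
   NES against survival; sets with Wald p < 0.05 are retained and
   labelled *risk* (HR > 1) or *protective* (HR < 1);
3. **SGS** — per sample, `SGS = Σ_risk NES − Σ_protective NES`;
4. **stratification** — high/low groups at the cohort median SGS;
5. **survival comparison** — Kaplan–Meier curves and the log-rank test
   between the groups.

A single-cell variant scores each cell with the same engine, averages
cells within a patient and splits patients at the median of those means,
with risk/protective directions transferred from a bulk screen (per-cell
survival does not exist, so directions are never re-screened on cells).

## ssGSEA scoring

For one sample, genes are ranked by expression (highest → rank N;
average ranks on ties).  Walking genes in decreasing rank order, the ES
of a set S is the summed gap between the weighted in-set cumulative
distribution (weights rank^α, normalized by the in-set weight total) and
the uniform out-of-set cumulative distribution:

    ES(S) = Σ_{i=1..N} [ CDF_in(i) − CDF_out(i) ].

Because Σ_i cumsum_i(v) = Σ_g v_g·(N+1−pos_g), the ES reduces to a
closed form in the walk positions; `score_all` evaluates it for all sets
and samples with two matrix products.  The test suite checks this
vectorized form against an independent position-by-position walk to
1e-12.

Numerical choices:

* **α = 0.25** by default, the common ssGSEA weighting exponent; it is
  configurable and recorded in output headers.
* **Normalization**: NES = ES / (max ES − min ES) over the whole grid
  (`global_range`), so the NES grid always spans exactly 1.  `none`
  keeps raw ES for oracle comparisons.  For single-cell matrices the
  range is computed within the matrix being scored, not frozen from the
  bulk run; the constant is recorded in the output header.
* **Ties** get average ranks and are walked in canonical lexicographic
  gene order, so scores are invariant to row order — important for
  sparse single-cell input where most genes tie at zero.
* Sets are intersected with the matrix's gene universe; sets with fewer
  than 2 surviving genes are dropped with a warning (too unstable to
  screen), and a set covering the whole universe is an error (the
  out-of-set CDF is undefined).

## Cox screening

Each fit maximizes the univariate partial likelihood by damped
Newton–Raphson from β = 0 (convergence |Δβ| < 1e-9, at most 50
iterations), with the **Efron** tie correction by default and Breslow
available for cross-checks; the two coincide when event times are
unique.  The standard error comes from the observed information and the
p-value is the two-sided Wald test — the default reporting of standard
survival software.  |β| drifting past 15 marks a monotone (separating)
likelihood; such fits are flagged non-converged and the set is dropped
rather than clamped, because a separating fit's direction label is not
trustworthy.  HR = exp(β) throughout, so HR > 1 ⇔ β > 0.

Raw p-values are used (no multiplicity correction): the screen is a
deliberate 5%-type-I filter, and downstream survival analysis is run on
the combined score, not on individual sets.

## Stratification and comparison

The median cutoff uses the analysis cohort's own median (mean of the
middle two scores for even n).  Ties at the cutoff go to **low** — a
patient exactly at the median is not called high-risk; the choice is
deterministic and conservative.  A fixed cutoff can be supplied instead
to apply a training-cohort threshold to a validation cohort.  Group
comparisons of continuous quantities (scores, infiltration levels) use
the two-sided Wilcoxon rank-sum test with tie and continuity
corrections.  Kaplan–Meier estimation and the log-rank test are
delegated to lifelines behind the `survival` module surface; subjects
censored at an event time remain in the risk set for that time, and the
log-rank variance is the hypergeometric form without continuity
correction.

An alternative "optimal cutpoint" stratification (maximizing the
log-rank statistic over candidate cutoffs) is deliberately not
implemented: it contradicts the median rule used everywhere else in this
pipeline and inflates type-I error unless corrected.

## Batch merging and TPM

Cohort merging uses exact per-gene batch-mean centering: subtract the
sample's batch mean, add back the unweighted mean of batch means.  After
the operation all batch means of a gene are equal; within-batch variance
is untouched and the operation is idempotent.  This is the additive
special case of the usual linear-model batch correction — sufficient
here because the pipeline only needs cohorts on a common location, and
rank-based scoring absorbs the rest.  It is intended for log-scale
values (apply after log transformation).  `tpm_transform` converts
counts to transcripts-per-million (columns sum to 1e6) with an optional
log2(TPM+1) step.

## The synthetic generator

Real cohorts of this kind are controlled-access, so the package ships a
generator that emulates the structure the pipeline assumes, with known
truth:

* latent set activities a_{k,s} ~ Normal(0,1) per sample;
* expression x_{g,s} = μ_g + signal_strength·Σ_{k:g∈S_k} a_{k,s} + ε,
  μ_g ~ Normal(6,2) (a log2-like scale), ε ~ Normal(0, noise_sd);
  overlapping sets add;
* survival T_s ~ Exponential(λ0·exp(Σ_k β_k a_{k,s})) — the simplest
  model satisfying the proportional-hazards assumption the screen relies
  on — with independent exponential censoring whose rate is solved by a
  bracketing root find so the expected censored fraction hits the
  target (closed-form, reproducible);
* single-cell mode: patient-level activities equal the planted shift
  (plus optional Normal(0, activity_sd) heterogeneity, off by default so
  that a higher shift always means a higher expected score), per-cell
  Normal noise, then independent Bernoulli dropout.

Defaults, chosen once as a realistic desk-scale stand-in: 1000 genes, 36
disjoint sets of 25 genes (36 mirrors the size of a curated stemness
collection; 25 genes keeps sets proportionate to the reduced gene
universe), signal_strength 1 and noise_sd 1 (per-gene signal-to-noise of
1, aggregated over 25 genes per set), censor_rate 0.3 (typical of
oncology cohorts), baseline hazard 0.1 events per time unit.  One
integer seed drives a single `default_rng` stream; identical parameters
and seed reproduce the dataset bit for bit.

What the generator does **not** emulate: real marker genes or subtype
structure, count-distribution realism (negative-binomial noise,
library-size variation), gene–gene correlation beyond shared set
activity, informative censoring, or batch artifacts.  Passing tests
therefore demonstrate that the machinery is correct and calibrated under
the proportional-hazards model it assumes — not that any particular
biological signature is prognostic in real data.

## Calibration studies and their problem sizes

The test suite and `scripts/acceptance.py` measure, at these sizes:

* null screen retention (36 sets, n = 200, 60–200 cohorts): the
  retained fraction should sit near the nominal 5%;
* direction recovery (planted β = ±0.7, n = 400, 40–100 cohorts):
  the planted sets should be labelled risk/protective nearly always;
* end-to-end power (β = 0.7, n = 400): the median-split log-rank test
  should reject in ≥ 90% of cohorts;
* null log-rank calibration with **fixed, a-priori direction labels**
  (n = 200): rejection near 5% and p-values uniform.  Directions are
  fixed rather than re-screened because screening and testing on the
  same null cohort selects exactly the sets that correlate with survival
  in-sample and would inflate the test by construction; fixing the
  labels reproduces the honest validation-cohort situation in which a
  frozen signature is applied to new data;
* single-cell ordering (shifts 0 vs +2, 200 cells/patient, dropout
  0.5): the shifted patient's mean per-cell SGS is higher in every
  replicate.

## Known limitations

* The Cox screen is univariate by design; no multivariable adjustment
  for clinical covariates, proportional-hazards diagnostics, or FDR
  control.
* Batch centering removes only additive per-gene shifts.
* The ssGSEA engine computes scores and normalization only — no
  permutation NES, leading-edge reporting, or kernel-density (GSVA)
  variant.
* Median stratification on the analysis cohort is data-dependent; for
  external validation, freeze the cutoff with the `cutoff` override.
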