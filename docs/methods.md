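# Methods

`dysreg` implements a differential-regulation ("gene dysregulation")
analysis for two-condition transcriptomes (normal vs tumor), followed by
survival screening and signature construction. This note documents the
models, the defaults and why they were chosen, what the synthetic data
generator does and does not emulate, and the numerical decisions that a
maintainer would otherwise have to reverse-engineer.

## Pipeline model

The analysis treats transcriptional regulation as a per-target linear
model. For a target gene *g* with candidate transcription factors (TFs)
*x₁…x_p*, expression in condition *c* is modeled as

    y_g = α_c + Σ_j β_{jc} x_j + ε,   ε ~ N(0, σ²)

The coefficient β_{jc} is the *regulatory intensity* of TF *j* on target
*g* under condition *c*. A link is *dysregulated* when three criteria
hold simultaneously:

1. the 95% confidence intervals of β in the two conditions are strictly
   disjoint (touching endpoints count as overlap);
2. the target is differentially expressed (|log₂FC| > 1 and
   Benjamini–Hochberg adjusted moderated-t p < 0.05 by default);
3. sign(β_tumor − β_normal) · sign(log₂FC) > 0 — the intensity change and
   the target's expression change point the same way (a zero change on
   either side is inconsistent).

### Stage 1 — preprocessing (`prep`)

RNA-seq input is TPM; values below 1 are treated as missing and genes
missing in strictly more than 20% of samples are dropped (the comparison
is strict by design). Remaining gaps are filled by k-nearest-gene
imputation (default k=10): distances are root-mean-square differences
over mutually observed samples, donors sharing fewer than 3 observed
samples with the target gene are skipped (relaxed to the target's
observed count when it has fewer than 3), and the imputed value is the
unweighted mean of the k nearest donors observed in that sample. Data
are then log₂-transformed (no pseudocount — masking already guarantees
values ≥ 1; microarray data already in log space set `already_log`) and
quantile-normalized (columns mapped onto the mean order-statistic
distribution; ties get the mean of the tied reference values, which makes
the operation idempotent). Microarray tables are first collapsed from
probe to gene level: probes mapping to more than one gene are removed,
and of several probes for one gene the one with the highest mean across
samples is kept (a single maximum value is noise-sensitive; ties break by
probe id).

### Stage 2 — reference network (`refgrn`)

Candidate TF→target links come from scanning promoter sequences
(nominally 1000 bp upstream of the TSS) with TF position weight matrices
on both strands. Scoring is the standard log-odds with pseudocount
regularization, score[i,b] = log₂((f_ib + 0.1·bg_b)/(1.1·bg_b)), against
a 0-order background (estimated from the promoter set unless supplied).
Site p-values are exact: scores are floored onto a 1/100-bit grid and the
null distribution of the window score is obtained by dynamic programming
(per-position convolution of the discretized score distribution). Because
the window score is floored onto the same grid, reported p-values are
conservative. Windows containing N are skipped on both strands and
excluded from the window count.

Per-TF family-wise error is controlled in two levels: the best site
p-value in a promoter with m scanned windows becomes a promoter-level
p = 1 − (1 − p_site)^m (Šidák), and a promoter is selected as a target
when p_promoter < α / n_promoters (Bonferroni), with α = 0.01. This
guarantees P(≥ 1 false target per TF) < α under the null, and the null
simulation in the acceptance suite confirms it. The control is
deliberately conservative: the smallest achievable site p-value of a
width-w motif under a uniform background is 4^(−w), so short motifs
(w ≲ 12) cannot reach significance against hundreds of promoters at all —
a width-16 consensus does, as the positive control in the test suite
shows. TFs with more than 5000 selected targets are trimmed to the 5000
best by site score (ties by promoter p, then target id). The module can
be bypassed entirely by supplying a precomputed edge list.

### Stage 3 — conditional networks (`condgrn`)

For each target, the candidate TFs are filtered by a shadow-feature
selection loop around a regression random forest. Each round appends a
permuted copy of every remaining feature, fits a forest, and credits a
"hit" to features whose importance exceeds the round's maximum shadow
importance; a two-sided binomial test on the cumulative hit counts
(Bonferroni-corrected across all features, α = 0.05) confirms or rejects
features; the loop stops at 100 rounds or when nothing is undecided.
Features still undecided at termination are dropped by default
(`tentative_policy="drop"`), keeping conditional networks sparse; the
alternative policy keeps tentative features whose final importance sits
above the shadow mean.

Two implementation choices matter. First, importance is the forest's
impurity (MDI) importance with 150 trees, `max_features="sqrt"` and
`min_samples_leaf=5`: permutation importance costs an order of magnitude
more per round and did not change recovery on the planted benchmarks,
and MDI is the classic choice for this wrapper. Second, the shadow pool
is padded to the original feature count by cycling permuted copies of the
remaining features. Without padding, the pool shrinks as features are
rejected and its maximum collapses, letting chance-correlated survivors
accumulate hits — on pure-noise problems this confirmed several features
per run; with padding the null run confirms a median of zero.

Per-target seeds derive deterministically from (global seed, target id),
so results do not depend on the order in which targets are processed.

### Stage 4 — intensities (`intensity`)

Within each condition, each target is regressed on the union of its
confirmed TFs across both conditions (identical designs make the two
conditions' coefficients directly comparable; links confirmed in only one
condition still need an estimate in the other to compare intervals).
Regressions run on standardized predictors and centered response;
intensities are reported on the standardized scale (a raw-scale flag
exists).

The initial estimate is a LASSO with the penalty chosen by 5-fold
cross-validation (min-CV rule, folds seeded from the target id). The
de-biasing step forms an approximate inverse covariance M by node-wise
LASSO regressions of each predictor on the rest and corrects

    b_debiased = b_lasso + (1/n) M Xᵀ(y − X b_lasso),
    se_j = σ̂ √((M Σ̂ Mᵀ)_jj / n),

with σ̂² the residual sum of squares divided by (n − support size)
(falling back to n when the support nearly exhausts the sample). 95%
intervals use the Gaussian 1.96 quantile. The node-wise penalty is
λ_node = c·√(log p / n) with c = 0.25, calibrated once on a fixed-design
simulation (n = 100, p = 150, 5 nonzero coefficients, σ = 1): larger
constants (0.5–1.0) leave visible shrinkage bias in the nonzero
coefficients and push coverage to 0.87–0.89, while c = 0.25 gives 0.92
coverage with a 4.9% null rejection rate. Calibration simulations hold
the design fixed across replicates, which also lets M be computed once
per design (`nodewise_inverse` is exposed separately for this reason).

### Stage 5 — dysregulation calls (`dyscall`)

Differential expression uses an empirical-Bayes moderated t: per-gene
variances are shrunk toward a prior (d₀, s₀²) fitted by matching the
moments of log s² through digamma/trigamma inversion, the moderated t has
d₀ + d degrees of freedom, and BH adjustment runs across all tested
genes (not only network targets). The default design is unpaired
two-group; a paired mode (differences within matched pairs) is available.
Setting d₀ = 0 reproduces the ordinary t exactly, which the tests use as
an anchor. The three criteria above are then intersected; output is
ordered by |Δβ| descending.

### Stage 6 — prognostic screen (`survscreen`)

Each dysregulation contributes a gene pair. Four proportional-hazards
model types are fitted per pair — endpoint OS or RFS, each with or
without the clinical covariates age (years, untransformed), gender
(binary) and pathological stage (ordinal 1–4) — and scored by Harrell's C
on the fitting data (usable pairs: strictly shorter time with an observed
event; risk ties count one half; tied times are not usable pairs).
Controls are equal-sized sets of gene pairs drawn without replacement by
four strategies: two random genes; one DEG plus one non-DEG; a random
reference-network edge; a random edge whose target is a DEG. Per
repetition (default 100) the control arm is redrawn and a one-sided
Mann–Whitney test asks whether the dysregulation C-indexes are larger;
the dysregulation arm stays fixed across repetitions. Non-convergent or
separated fits are excluded from the rank tests rather than imputed.

The Cox fitter is an in-package Newton–Raphson maximizer of the partial
likelihood with Efron tie handling, step halving, and internal covariate
standardization; it matches `lifelines` coefficients and standard errors
to 4+ decimals (verified in the tests) and runs a small fit in about a
millisecond, which the screen's tens of thousands of fits require.
Separation is flagged at |standardized β| > 50; the C-index is still
reported (the ranking remains well defined under monotone likelihood) but
flagged fits are excluded from rank tests.

### Stage 7 — signature (`signature`)

The primary dysregulation is the candidate whose full-data OS model (two
genes + clinical covariates) has the largest C-index. Each greedy
iteration evaluates every remaining candidate by adding its genes and
scoring the model with repeated 60/40 train/test splits (default 100;
median test C-index). Splits are shared across candidates within an
iteration — a paired comparison that removes split noise from the
selection. The best candidate joins while the improvement is at least
ΔC = 0.001; the primary is fixed from the full-data fit and not
re-selected under cross-validation. Candidates can be restricted to a
user-supplied gene set (GMT), e.g. plasma-membrane genes.

Risk scores are the fitted linear predictor centered at the training
covariate means, so "negative score" means below-average predicted risk.
Prognosis mode splits at the cohort median (ties go to the low group);
benefit mode splits by sign. Hazard ratios between groups come from a
one-covariate proportional-hazards fit on the group indicator, with the
protective group ("low"/"negative") in the numerator by default.
Time-dependent AUC(t) is the IPCW cumulative/dynamic estimator: cases
(event by t) are weighted by 1/Ĝ(T⁻) with Ĝ the Kaplan–Meier estimate of
the censoring distribution (left-continuous limit); with no censoring it
reduces exactly to the empirical binary AUC, an identity the tests assert.

The benefit-transfer analysis fits an OS model on untreated samples using
the signature genes only (no clinical covariates), scores treated
samples, splits by sign, and compares survival between sign groups
(optionally within one chemotherapy type).

## Synthetic data (`simdata`)

The generator plants the exact structure the pipeline assumes:

- a TF→target network (each target draws `links_per_target` TFs; base
  coefficients ±Uniform(0.3, 0.8));
- dysregulated links (at most one per target) where β_tumor moves by
  ±`effect_size` and the target's tumor intercept shifts by
  `effect_size`·`tf_mean` in the same direction, so the planted
  dysregulation satisfies the direction-consistency criterion by
  construction;
- TF expression i.i.d. Normal(`tf_mean`=2, 1) — the positive mean makes
  an intensity increase raise the target mean;
- exponential survival times with log-hazard linear in the centered
  expression of a chosen gene subset, independent Uniform(0, c_max)
  censoring with c_max bisected so the realized censoring fraction
  matches the requested rate (default 0.3), and an optional treated
  fraction whose hazard is multiplied by exp(−`treatment_benefit`);
- age/gender/stage drawn from simple distributions and not wired into
  the hazard by default.

Profile defaults: `tiny` (10 TFs × 30 targets, 16 pairs, 120-sample
cohort) for smoke tests; `default` (50 TFs × 200 targets ×
3 links/target, 20 planted dysregulations, 32 matched pairs, 300-sample
cohort, noise σ = 0.5, effect size 1.0) as the reference study
condition — 32 pairs matches the discovery-cohort scale this kind of
analysis typically has; `benefit` adds a 45% treated split. The
acceptance checks run the calibration simulations at the sizes stated in
their docstrings (e.g. 20 TFs × 200 promoters × 300 replicates for the
family-wise error check, 200 replicates for interval coverage, 10 seeds
for the end-to-end recovery), with 500 bp promoters in the scan
simulations.

What the generator does **not** emulate: count-level RNA-seq noise
(negative binomial, library-size effects), batch effects, correlated TF
expression, copy-number confounding, non-proportional hazards, or
informative censoring. Passing tests therefore demonstrate correctness of
the machinery and calibration under the assumed model, not robustness to
real-data violations of it.

## Numerical choices and degenerate inputs

- LASSO solver tolerances: 1e-6 relative (coordinate descent), 5000
  iterations; λ = 0 falls back to least squares explicitly.
- Zero-variance genes in the moderated t have their variance floored at
  machine epsilon with a warning; constant regressors are zeroed with a
  warning; constant covariates in a Cox fit raise.
- Quantile normalization of a single sample is a warned no-op.
- All randomness flows from explicit seeds; per-target/per-stage seeds
  derive from CRC32 of the identifier so parallel or reordered execution
  cannot change results. TSV floats are written with a fixed `%.10g`
  format, making every CLI stage byte-reproducible.

## Known limitations

- The reference network sees only proximal promoter sequence; distal
  enhancers, chromatin state and TF cooperativity at the binding level
  are out of scope.
- The two-level family-wise error control is conservative (Bonferroni
  across promoters on top of discrete, floored p-values); with short
  motifs and many promoters its power is limited by the 4^(−w) floor.
- The de-biased intervals are calibrated for the standardized-design
  regime the simulations cover; very high collinearity between TFs will
  widen (not bias) them, but node-wise regression quality degrades.
- The screen computes in-sample C-indexes by design (matching the
  screening procedure it implements); only the signature module uses
  held-out evaluation.
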