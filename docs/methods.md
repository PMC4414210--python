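# Methods

This note documents the models, algorithms and numerical choices behind
`mirsig`, and what the synthetic-study tests do and do not establish about
real data.

## The statistical problem

Given probe-level miRNA counts for two independent cohorts and a
right-censored time-to-distant-metastasis endpoint, the workflow (i)
normalizes counts to standardized expression, (ii) fits a sparse
(L1-penalized) Cox proportional-hazards model on the training cohort, (iii)
summarizes the retained miRNAs as a linear risk score dichotomized at the
training median, and (iv) judges the signature on the validation cohort,
against clinical staging, and against an empirical null of random miRNA
sets.

## Normalization

* **Background correction.** For each sample *s* the threshold is
  t_s = mean + 2·SD of that sample's negative-control probe counts (sample
  SD, n−1 denominator — the convention used everywhere in the package so
  results are bit-reproducible). Corrected values are max(raw − t_s, 0);
  negative-control probes are dropped.
* **Variance stabilization.** A one-parameter generalized log,
  glog2(x; λ) = log2((x + √(x² + λ²))/2), with λ = the median positive
  corrected value of the dataset. This reproduces the essential behaviour of
  model-based variance stabilization — approximately linear near zero,
  → log2(x) for x ≫ λ — without a maximum-likelihood affine calibration; it
  is a deliberate, documented simplification.
* **Standardization.** Per-probe z-scores (mean 0, sample SD 1). Parameters
  can be recomputed per cohort (default) or carried over from training;
  both modes exist because cross-cohort standardization practice is
  genuinely ambiguous, and the cutpoint transfer (training median applied
  to validation scores) is well-defined in either. Zero-variance probes are
  flagged and excluded rather than erroring the run.
* **Expression filter.** Probes are kept when strictly more than 80% of
  training samples have background-corrected values > 0; the strict
  inequality matters at the 100/125 boundary. With the default generator
  this leaves ≈300 of 734 probes.
* **Differential testing.** Welch's unequal-variance t per probe with
  Benjamini–Hochberg step-up adjustment; probes with zero variance in both
  groups are recorded with p = 1 and a `degenerate` flag.

## Survival machinery

All core estimators are implemented in-package and cross-checked in the
test suite against independent implementations (lifelines, statsmodels,
scikit-learn) and brute-force oracles.

* **Cox PH** by Newton–Raphson on the partial likelihood, Efron tie
  handling by default (Breslow by flag); convergence when max |score| <
  1e-8 or the relative log-likelihood change < 1e-10; SEs from the inverse
  observed information; step-halving guarantees ascent. Runaway
  coefficients (|β| > 15, i.e. monotone likelihood / separation) set a
  flag; downstream consumers treat flagged fits as non-informative.
* **Lasso Cox** maximizes pl(β) − λ·Σ|β| (unscaled penalty). The solver is
  IRLS on the Breslow partial likelihood with cyclic coordinate descent and
  soft-thresholding on the weighted least-squares surrogate; the inner
  kernel is JIT-compiled (numba) with a pure-Python fallback. Three
  numerical details matter:
  * an exact KKT check at the origin returns the all-zero solution for
    λ ≥ λ_max = max_j |score_j(0)| — full shrinkage is exact, not rounded;
  * after descent, solutions with ≤ 40 active coordinates get a short
    Newton "polish" on the smooth active-set system score_j(β) = λ·sign(β_j),
    making sparse optima independent of the descent path (warm and cold
    starts agree to ~1e-12). Denser solutions (the weakly penalized end of
    the path, where p far exceeds the event count and the optimum is
    ill-conditioned) are left to coordinate descent with iteration caps;
  * the IRLS loop stops on coefficient stationarity (tolerance 1e-7 for
    single fits) or when the penalized objective improves by less than
    ~1e-3·tol relative — the latter guards the flat-likelihood regime.
* **Penalty selection** by leave-one-out cross-validated partial likelihood
  (Verweij–van Houwelingen): cv(λ) = Σ_i [pl(all; β_{−i}) − pl(−i; β_{−i})],
  fold fits warm-started along a decreasing log-spaced grid from λ_max;
  ties in the maximizer break toward the larger (sparser) λ. The default
  grid is 100 points down to 0.01·λ_max; the end-to-end scripts use a
  20-point grid over the same span as the package's desk-scale setting.
* **Kaplan–Meier / log-rank**: product-limit estimator (censoring at an
  event time counted at risk); k-group log-rank with multivariate
  hypergeometric variance and a pseudo-inverse fallback for degenerate
  covariance.
* **Harrell's C** over usable pairs (earlier time must be an event; score
  ties count ½).
* **D-index** (rank-based scaled HR): scores → ranks → Blom normal order
  statistics Φ⁻¹((r−3/8)/(n+¼)) → divided by κ = √(8/π) → Cox fit; the
  reported value is exp(coef). Invariant under monotone score transforms.
* **Time-dependent ROC**, cumulative-case/dynamic-control with
  Kaplan–Meier redistribution: for cutpoint c,
  sens = (1 − S_{X>c}(t))·P(X>c)/(1 − S(t)),
  1 − spec = S_{X>c}(t)·P(X>c)/S(t), AUC by trapezoid after enforcing a
  monotone ROC path. The KM estimator (not nearest-neighbour smoothing) was
  chosen because it is deterministic and bandwidth-free. Evaluation times
  before the first event yield NaN with a flag.

## Signature discovery and scoring

`SignatureCoxModel.fit()` runs lasso at the LOOCV-selected penalty, ranks
nonzero coefficients by |β|, and keeps the top k, with
k = ⌊events / EVP target⌋ (EVP target 5) unless overridden — 20 events
gives the canonical k = 4. Coefficients are taken directly from the
penalized fit, not refit unpenalized, matching how the published risk-score
equation was formed. The risk score is the plain dot product with
standardized expression; the cutpoint is the training-cohort median (even
n: midpoint of the central order statistics), and RS ≥ cutpoint defines
high risk, including exact ties. The published 4-miRNA model
(+0.417 miR-154-5p, +0.280 miR-449b-5p, −0.653 miR-140-5p,
−0.311 miR-34c-5p) ships as a pre-built results object with an
uncalibrated cutpoint.

## Random-signature null

Random sets (default 10,000 per size 2–10 = 90,000, plus one singleton per
pool miRNA) are drawn uniformly without replacement from the expressed
pool (PCG64; per-size blocks via uniform-key partial argsort, so draws are
reproducible given the seed). Each set is fitted unpenalized on training,
scored, dichotomized at its own training median, and tested by validation
log-rank. Non-convergent or separated fits and degenerate (single-group)
dichotomizations are recorded with a failure flag and excluded from
percentile denominators rather than imputed. Percentiles use ≤ for p
("same or lower") and ≥ for |log HR| (absolute values). Frequency
enrichment weights each member of a significant signature by 1/size — the
per-signature normalization reading — and the top ⌈5% · pool⌉ miRNAs are
flagged (298 → 15).

## Target enrichment

Enrichment is a one-sided hypergeometric upper tail against a custom
background (every gene with ≥ 1 validated edge), with BH adjustment across
tested pathways; pathways are intersected with the background first and
skipped when empty. This replaces a web-service enrichment tool with an
offline, exactly reproducible equivalent of the same custom-background
idea. DEE(g) = (# targeting miRNAs negatively associated with DM) −
(# positively associated); direction labels for signature miRNAs come from
coefficient signs, and for frequency-selected miRNAs from the sign of the
univariate training Cox coefficient (a documented assumption). miRNA ID
matching is exact after case-folding and optional removal of the species
prefix; no family or arm inference is attempted.

## Synthetic-study generator

The generator emulates the study design, not any particular dataset (no
per-probe count distributions are published):

* **Counts.** Negative binomial (var = m + φ·m², shared dispersion
  φ = 0.05) around per-miRNA log-normal means. Expressed probes span
  log2-means 5–12 (~3 orders of magnitude); planted-signature probes sit at
  7–10 so they survive filtering. A dropout block (default 59% of probes,
  so ≈300 of 734 pass the 80% filter) has means between the
  negative-control mean (8) and the mean+2SD background threshold: those
  probes zero out on background correction while negative controls stay
  below the 5th percentile of endogenous probe means. Six positive-control
  probes complete the nCounter-like layout.
* **Survival.** A log-linear Cox model on the standardized latent (pre-
  count) expression of the planted miRNAs: T = b·(−log U / e^lp)^{1/a}
  with Weibull shape a = 1.2 and scale b calibrated by Gauss–Hermite
  quadrature so the marginal 5-year event probability equals the 13% target
  (the cohorts' 87% 5-year distant-relapse-free rate). Censoring is
  independent exponential (rate 0.05/yr) plus an administrative cut at 12
  years. Default planted effects are the published coefficients themselves,
  so the synthetic study carries a realistic, recoverable signal.
* **Clinical covariates** are drawn per cohort with the published frequency
  tables (T/N stage, gender, chemotherapy era difference, age); overall
  stage follows a simplified TNM mapping. Covariates are independent of
  expression by default; a `confound_strength` knob couples N-stage to the
  linear predictor for adjustment and added-value tests.
* Cohorts share the mean grid and true betas but draw independent noise; a
  `cohort_shift_sd` option perturbs validation means to emulate the decade
  gap between accrual periods.

**What passing tests show — and don't.** The generator produces clean NB
counts, exchangeable samples and an exactly proportional-hazards signal.
Real FFPE nCounter data add batch and degradation effects, probe-specific
dispersions, non-proportional hazards and measurement error correlated
across probes; calibration and recovery results here are necessary checks
of the code, not evidence about field performance.

## Problem sizes and runtime

Tests and the acceptance script run on one CPU in minutes: full-scale
discovery uses the 125 × ~300 training matrix with a 20-point LOOCV grid
(~2 min); the evaluated random null is scaled to 1,000 signatures over a
100-miRNA pool (~10 s) while generation counts use the full 90,000 + 298
scheme; recovery and calibration suites use n = 400 × 50 (25 seeds), 1,000
null replicates for type-I error, and n = 1,000 for the null-marker AUC.

## Known limitations

* The glog2 transform is a single-parameter stand-in for full model-based
  variance stabilization; absolute expression values differ from that
  pipeline even though downstream rank-based results are insensitive.
* No time-varying covariates, stratified Cox, competing risks, elastic-net
  variants, or stability selection.
* The five-group stratification is hard-coded to the N0 / N1-2×RS / N3×RS
  partition (originally a judgement call made from inspecting KM curves);
  it is not re-derived from data.
* Weakly penalized lasso solutions (active set > 40) are coordinate-descent
  accurate (~1e-6) rather than polish-exact; the CV-selected region in
  practice is far sparser.
* Dichotomizing at the median discards within-group risk gradation; the
  continuous analyses (Wald test, D-index, AUC) are reported alongside for
  that reason.
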