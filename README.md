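# mirsig

Discovery and evaluation of prognostic miRNA signatures for time-to-event
endpoints, built around the analysis arc used for NanoString nCounter
profiling of nasopharyngeal carcinoma (NPC) cohorts with distant metastasis
(DM) as the endpoint.

## Who this is for

Biostatisticians and computational biologists who want a tested, scriptable
version of the classic count-based prognostic-signature workflow:

1. **Normalization** — per-sample background correction (mean + 2 SD of the
   negative-control probes), generalized-log variance stabilization,
   per-probe standardization, and the ">80% expressed above background"
   probe filter.
2. **Signature discovery** — an L1-penalized (lasso) Cox proportional-hazards
   model fitted to the training cohort, with the penalty chosen by
   leave-one-out cross-validated partial likelihood (Verweij–van
   Houwelingen) and the signature truncated to the top-|coefficient| miRNAs
   under an events-per-variable (EVP ≈ 5) rule.
3. **Risk scoring** — RS_i = Σ_j β_j · z_ij on standardized expression,
   dichotomized at the training-cohort median (high risk ⇔ RS ≥ median).
4. **Evaluation** — Kaplan–Meier curves and log-rank tests, binary and
   continuous Cox hazard ratios, the Royston–Sauerbrei D-index (rank-based
   scaled HR), Harrell's C, time-dependent ROC AUC(t) with Kaplan–Meier
   redistribution of censoring, exhaustive sub-signature comparison,
   Table-style uni/multivariate adjustment for T/N stage, age, gender and
   chemotherapy, and the five-group N-stage × RS stratification.
5. **Random-signature null** — thousands of random miRNA sets evaluated
   train→validation to percentile-rank an observed signature's log-rank p
   and |log HR|, plus size-normalized frequency counting of miRNAs in
   significant random signatures (top 5% selected).
6. **Target enrichment** — miRTarBase-style edge tables, multi-targeted
   genes, Deduced Expression Effect (DEE = #negatively associated −
   #positively associated targeting miRNAs), hypergeometric pathway
   enrichment against the full validated-target background, and
   cross-signature pathway intersection.

Because the original patient cohorts are not public, the package ships a
first-class synthetic-study generator (`mirsig.simulate`) that emulates the
study design — two cohorts (n = 125 / 121), 734 probes with negative
controls, negative-binomial counts over ~3 orders of magnitude, a planted
4-miRNA signature, a Weibull baseline hazard calibrated to a ~13% 5-year
event fraction, and Table-1-like clinical covariates — with stored ground
truth so every stage is testable.

## Worked example

```python
from mirsig import (SimConfig, simulate_cohort, published_signature,
                    evaluate_signature)
from mirsig.normalize import normalize_pipeline

cfg = SimConfig(seed=1)                      # study-scale synthetic cohorts
tr_expr, tr_surv, truth = simulate_cohort(cfg, "train")
va_expr, va_surv, _     = simulate_cohort(cfg, "validation")
tr_z, _ = normalize_pipeline(tr_expr)        # background -> glog2 -> z-score
va_z, _ = normalize_pipeline(va_expr)

model = published_signature()                # the 4-miRNA model
print(model.summary())
model.calibrate_cutpoint(tr_z)               # training-median cutpoint
report = evaluate_signature(model, va_z, va_surv, cohort_label="validation")
print(f"validation HR (high vs low) = {report.binary_hr:.2f}, "
      f"log-rank p = {report.logrank_p:.4f}")
```

prints

```
              coef direction
miR-154-5p   0.417         +
miR-449b-5p  0.280         +
miR-140-5p  -0.653         -
miR-34c-5p  -0.311         -
validation HR (high vs low) = 3.22, log-rank p = 0.0035
```

The printed coefficients are the published risk-score equation; the hazard
ratio and p-value are computed on the seed-1 synthetic validation cohort, in
which the planted per-SD log hazard ratios equal those same coefficients —
so high-risk patients metastasize roughly three times faster, as designed.

For full runs there is also a CLI (`mirsig simulate / normalize / discover /
score / evaluate / null / enrich / run`), driven by a YAML config with a
reproducibility manifest of file hashes and seeds.

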