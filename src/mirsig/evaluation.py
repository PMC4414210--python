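"""Evaluation battery for a fitted risk signature.

For any cohort: Kaplan-Meier curves and log-rank test on the high/low
dichotomization, a binary hazard ratio from a univariate Cox fit on the
group indicator, the continuous per-unit-RS hazard ratio with its Wald
test, the rank-based scaled hazard ratio (D-index), and time-dependent
ROC AUCs.  Also: exhaustive sub-signature comparison, Table-2-style
uni/multivariate adjustment for clinical factors, the five-group
N-stage x RS stratification, and stage/treatment subset analyses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import chain, combinations

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, SurvivalCohort, align_cohort
from .coxph import ConvergenceError, cox_fit
from .signature import SignatureResults, compute_risk_scores, dichotomize
from .survstats import KMCurve, concordance, d_index, km_estimate, logrank_test, time_dependent_roc

DEFAULT_EVAL_TIMES = (1.0, 2.0, 3.0, 4.0, 5.0)


@dataclass
class EvaluationReport:
    """One cohort's evaluation of one signature."""

    cohort_label: str
    n: int
    n_events: int
    cutpoint: float
    binary_hr: float
    binary_hr_ci: tuple[float, float]
    logrank_chi2: float
    logrank_p: float
    continuous_hr: float
    continuous_wald_p: float
    scaled_hr: float  # D-index
    eval_times: list[float]
    auc: list[float]
    km_high: KMCurve | None = field(default=None, repr=False)
    km_low: KMCurve | None = field(default=None, repr=False)
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "cohort_label": self.cohort_label,
            "n": self.n,
            "n_events": self.n_events,
            "cutpoint": self.cutpoint,
            "binary_hr": self.binary_hr,
            "binary_hr_ci": list(self.binary_hr_ci),
            "logrank_chi2": self.logrank_chi2,
            "logrank_p": self.logrank_p,
            "continuous_hr": self.continuous_hr,
            "continuous_wald_p": self.continuous_wald_p,
            "scaled_hr": self.scaled_hr,
            "eval_times": list(self.eval_times),
            "auc": [None if not np.isfinite(a) else float(a) for a in self.auc],
            "flags": self.flags,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationReport":
        return cls(
            cohort_label=d["cohort_label"],
            n=d["n"],
            n_events=d["n_events"],
            cutpoint=d["cutpoint"],
            binary_hr=d["binary_hr"],
            binary_hr_ci=tuple(d["binary_hr_ci"]),
            logrank_chi2=d["logrank_chi2"],
            logrank_p=d["logrank_p"],
            continuous_hr=d["continuous_hr"],
            continuous_wald_p=d["continuous_wald_p"],
            scaled_hr=d["scaled_hr"],
            eval_times=list(d["eval_times"]),
            auc=[np.nan if a is None else a for a in d["auc"]],
            flags=list(d.get("flags", [])),
        )


def evaluate_signature(
    model: SignatureResults,
    expr: ExpressionMatrix,
    surv: SurvivalCohort,
    eval_times=DEFAULT_EVAL_TIMES,
    cohort_label: str = "cohort",
    calibrate: bool = False,
) -> EvaluationReport:
    """Full binary + continuous evaluation of a signature on a cohort."""
    if model.cutpoint is None and not calibrate:
        raise ValueError("model has no calibrated cutpoint; pass calibrate=True on training data")
    expr = align_cohort(expr, surv)
    strat = model.stratify(expr, calibrate=calibrate)
    rs = strat.risk_score.to_numpy()
    time, event = surv.time, surv.event
    group = strat.group.to_numpy()
    flags = []

    high = group == "high"
    if high.sum() == 0 or high.sum() == len(high):
        flags.append("single-risk-group")
    if "single-risk-group" in flags:
        chi2, p_lr = np.nan, np.nan
        hr_bin, ci = np.nan, (np.nan, np.nan)
    else:
        chi2, _, p_lr = logrank_test(time, event, group)
        try:
            fit_bin = cox_fit(high.astype(float)[:, None], time, event)
            hr_bin = float(fit_bin.hr.iloc[0])
            ci_df = fit_bin.conf_int
            ci = (float(ci_df.iloc[0, 0]), float(ci_df.iloc[0, 1]))
            if fit_bin.separation_flag:
                flags.append("binary-cox-separation")
        except (ConvergenceError, ValueError) as exc:
            hr_bin, ci = np.nan, (np.nan, np.nan)
            flags.append(f"binary-cox-failed: {exc}")

    try:
        fit_cont = cox_fit(rs[:, None], time, event)
        hr_cont = float(fit_cont.hr.iloc[0])
        p_cont = float(fit_cont.wald_p.iloc[0])
    except (ConvergenceError, ValueError) as exc:
        hr_cont, p_cont = np.nan, np.nan
        flags.append(f"continuous-cox-failed: {exc}")
    try:
        shr, _, _ = d_index(rs, time, event)
    except ValueError as exc:
        shr = np.nan
        flags.append(f"d-index-failed: {exc}")

    troc = time_dependent_roc(rs, time, event, eval_times)
    km_high = km_estimate(time[high], event[high]) if high.any() else None
    km_low = km_estimate(time[~high], event[~high]) if (~high).any() else None
    return EvaluationReport(
        cohort_label=cohort_label,
        n=surv.n,
        n_events=surv.n_events,
        cutpoint=float(strat.cutpoint),
        binary_hr=hr_bin,
        binary_hr_ci=ci,
        logrank_chi2=float(chi2) if np.isfinite(chi2) else np.nan,
        logrank_p=float(p_lr) if np.isfinite(p_lr) else np.nan,
        continuous_hr=hr_cont,
        continuous_wald_p=p_cont,
        scaled_hr=shr,
        eval_times=[float(t) for t in eval_times],
        auc=list(troc.auc),
        km_high=km_high,
        km_low=km_low,
        flags=flags,
    )


def _nonempty_subsets(items):
    return chain.from_iterable(combinations(items, r) for r in range(1, len(items) + 1))


def subset_comparison(
    model: SignatureResults,
    train_expr: ExpressionMatrix,
    train_surv: SurvivalCohort,
    eval_expr: ExpressionMatrix | None = None,
    eval_surv: SurvivalCohort | None = None,
    eval_times=DEFAULT_EVAL_TIMES,
) -> pd.DataFrame:
    """AUC(t) of every non-empty sub-signature of the model (2^k - 1 rows).

    Each subset is refitted by unpenalized Cox on the training cohort; risk
    scores and AUCs are computed on the evaluation cohort (training cohort
    by default).
    """
    if model.k == 0:
        raise ValueError("empty model")
    if model.k > 10:
        raise ValueError("subset enumeration limited to k <= 10")
    if eval_expr is None:
        eval_expr, eval_surv = train_expr, train_surv
    train_expr = align_cohort(train_expr, train_surv)
    eval_expr = align_cohort(eval_expr, eval_surv)
    rows = []
    for subset in _nonempty_subsets(model.mirna_ids):
        X = train_expr.values.loc[list(subset)].T
        fit = cox_fit(X, train_surv.time, train_surv.event)
        sub_model = SignatureResults(params=fit.params, provenance="subset")
        rs = compute_risk_scores(sub_model, eval_expr)
        troc = time_dependent_roc(rs.to_numpy(), eval_surv.time, eval_surv.event, eval_times)
        row = {"subset": "+".join(subset), "size": len(subset)}
        row.update({f"auc_{t:g}y": a for t, a in zip(troc.eval_times, troc.auc)})
        rows.append(row)
    return pd.DataFrame(rows)


_STAGE_CODING = {
    "t_stage": ({"T1": 0, "T2": 0, "T3": 1, "T4": 1}, "T stage (T1&2 vs T3&4)"),
    "n_stage": ({"N0": 0, "N1": 0, "N2": 1, "N3": 1}, "N stage (N0&1 vs N2&3)"),
}


def build_design_matrix(groups: pd.Series, surv: SurvivalCohort) -> tuple[pd.DataFrame, int]:
    """Table-2-style covariate coding; returns (design, n_removed).

    Patients with unevaluable T or N stage are removed; the count removed
    is reported.  Columns: rs_high, t_stage_high, n_stage_high, age,
    gender_female, no_chemo.
    """
    df = surv.data.copy()
    df["rs_group"] = np.asarray(groups)
    evaluable = df["t_stage"].isin(_STAGE_CODING["t_stage"][0]) & df["n_stage"].isin(
        _STAGE_CODING["n_stage"][0]
    )
    removed = int((~evaluable).sum())
    df = df[evaluable]
    design = pd.DataFrame(
        {
            "rs_high": (df["rs_group"] == "high").astype(float),
            "t_stage_high": df["t_stage"].map(_STAGE_CODING["t_stage"][0]).astype(float),
            "n_stage_high": df["n_stage"].map(_STAGE_CODING["n_stage"][0]).astype(float),
            "age": df["age"].astype(float),
            "gender_female": (df["gender"] == "F").astype(float),
            "no_chemo": (df["chemo"] == 0).astype(float),
        },
        index=df.index,
    )
    return design, removed


def multivariate_analysis(groups: pd.Series, surv: SurvivalCohort) -> dict:
    """Univariate Cox per clinical factor plus one joint multivariate fit.

    Covariate coding mirrors the conventional reporting: RS group (high vs
    low), T stage (T1&2 vs T3&4), N stage (N0&1 vs N2&3), age continuous,
    gender (female vs male), chemotherapy (- vs +).  Returns a dict with a
    combined summary table and the removed-patient count.
    """
    design, removed = build_design_matrix(groups, surv)
    # duplicated covariates make the information matrix singular
    arr = design.to_numpy()
    if np.linalg.matrix_rank(arr - arr.mean(axis=0)) < arr.shape[1]:
        raise ValueError("design matrix is rank deficient (duplicated or collinear covariates)")
    sub = surv.data.loc[design.index]
    time = sub["time_years"].to_numpy(float)
    event = sub["event"].to_numpy(int)
    if (arr.std(axis=0) == 0).any():
        const = list(design.columns[arr.std(axis=0) == 0])
        raise ValueError(f"constant covariates after exclusions: {const}")
    uni_rows = {}
    for col in design.columns:
        fit = cox_fit(design[[col]], time, event)
        s = fit.summary().iloc[0]
        uni_rows[col] = s
    uni = pd.DataFrame(uni_rows).T
    multi_fit = cox_fit(design, time, event)
    multi = multi_fit.summary()
    table = uni.add_prefix("uni_").join(multi.add_prefix("multi_"))
    return {
        "table": table,
        "n_removed": removed,
        "n_used": len(design),
        "multivariate_fit": multi_fit,
    }


FIVE_GROUP_LABELS = (
    "N0",
    "N1/2 & Low-RS",
    "N1/2 & High-RS",
    "N3 & Low-RS",
    "N3 & High-RS",
)


def stratify_5group(groups: pd.Series, n_stage: pd.Series, surv: SurvivalCohort) -> dict:
    """Five risk groups from N-stage and the RS dichotomization.

    1. N0; 2. N1/2 & Low-RS; 3. N1/2 & High-RS; 4. N3 & Low-RS;
    5. N3 & High-RS.  Patients with unevaluable N-stage are excluded (count
    reported).  Returns labels, per-group KM curves, the k-group log-rank
    test, and Harrell's C for the 5-group ordinal score and its
    alternatives (N-stage alone, RS alone).
    """
    n_stage = pd.Series(np.asarray(n_stage), index=range(len(n_stage)))
    groups = pd.Series(np.asarray(groups), index=range(len(groups)))
    valid = n_stage.isin(["N0", "N1", "N2", "N3"])
    n_excluded = int((~valid).sum())
    ns = n_stage[valid]
    gr = groups[valid]
    label = pd.Series(index=ns.index, dtype=object)
    label[ns == "N0"] = "N0"
    mid = ns.isin(["N1", "N2"])
    label[mid & (gr == "low")] = "N1/2 & Low-RS"
    label[mid & (gr == "high")] = "N1/2 & High-RS"
    n3 = ns == "N3"
    label[n3 & (gr == "low")] = "N3 & Low-RS"
    label[n3 & (gr == "high")] = "N3 & High-RS"
    sub = surv.data.loc[label.index]
    time = sub["time_years"].to_numpy(float)
    event = sub["event"].to_numpy(int)
    km = {
        g: km_estimate(time[label == g], event[label == g])
        for g in FIVE_GROUP_LABELS
        if (label == g).any()
    }
    occupied = label.nunique()
    flags = []
    if occupied < 2:
        chi2, df, p = np.nan, 0, np.nan
        flags.append("log-rank undefined: fewer than 2 occupied groups")
    else:
        chi2, df, p = logrank_test(time, event, label.to_numpy())
    ordinal = label.map({g: i + 1 for i, g in enumerate(FIVE_GROUP_LABELS)}).to_numpy(float)
    n_ord = ns.str.lstrip("N").astype(float).to_numpy()
    rs_ord = (gr == "high").astype(float).to_numpy()
    cstats = {}
    for name, score in (
        ("five_group", ordinal),
        ("n_stage_alone", n_ord),
        ("rs_alone", rs_ord),
        ("n_stage_plus_rs", n_ord + 0.5 * rs_ord),
    ):
        try:
            cstats[name] = concordance(score, time, event)
        except ValueError:
            cstats[name] = np.nan
    return {
        "labels": label,
        "km": km,
        "logrank": {"chi2": chi2, "df": df, "p": p},
        "c_statistics": cstats,
        "n_excluded": n_excluded,
        "flags": flags,
    }


def stage_treatment_subsets(
    model: SignatureResults,
    expr: ExpressionMatrix,
    surv: SurvivalCohort,
    eval_times=DEFAULT_EVAL_TIMES,
) -> dict:
    """Signature evaluation within advanced-stage (III/IV) treatment arms.

    Filters to overall stage III/IV, splits radiotherapy-alone vs combined
    chemoradiation, and runs :func:`evaluate_signature` within each arm.
    Arms with fewer than 2 patients per risk group are flagged and skipped.
    """
    expr = align_cohort(expr, surv)
    advanced = surv.data["overall_stage"].isin(["III", "IV"]).to_numpy()
    out = {"n_advanced": int(advanced.sum()), "arms": {}, "flags": []}
    for arm, chemo_val in (("rt_alone", 0), ("crt", 1)):
        mask = advanced & (surv.data["chemo"].to_numpy() == chemo_val)
        if mask.sum() == 0:
            out["flags"].append(f"{arm}: empty subset, skipped")
            continue
        sub_surv = surv.subset(mask)
        sub_expr = expr.subset_samples(sub_surv.patient_ids)
        rs = model.risk_scores(sub_expr)
        strat = dichotomize(rs, model.cutpoint)
        counts = strat.group.value_counts()
        if counts.min() < 2 or counts.size < 2:
            out["flags"].append(f"{arm}: <2 patients per risk group, skipped")
            continue
        out["arms"][arm] = evaluate_signature(
            model, sub_expr, sub_surv, eval_times, cohort_label=arm
        )
    return out
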