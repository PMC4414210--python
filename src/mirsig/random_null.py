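"""Random-signature null-distribution calibration.

Expression datasets are prone to spurious prognostic associations, so an
observed signature is ranked against an empirical null: many random miRNA
sets (plus, optionally, every single miRNA of the pool) are each treated
as a candidate signature — unpenalized Cox fit on the training cohort,
risk scores, dichotomization at the training median, validation-cohort
log-rank test and binary hazard ratio.  The observed signature's p-value
and |log HR| are then percentile-ranked within the null, and miRNAs
over-represented in significant random signatures are extracted by
size-normalized occurrence counting.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, SurvivalCohort, align_cohort
from .coxph import ConvergenceError, cox_fit
from .signature import SignatureResults, compute_risk_scores, dichotomize
from .survstats import logrank_test

DEFAULT_SIZES = tuple(range(2, 11))


def generate_random_signatures(
    pool,
    sizes=DEFAULT_SIZES,
    n_per_size: int = 10000,
    seed: int = 0,
) -> list[tuple[str, ...]]:
    """Uniform without-replacement random miRNA sets, ``n_per_size`` per size.

    With the defaults (sizes 2-10, 10,000 each) this yields exactly 90,000
    signatures.  Deterministic given the seed (PCG64 generator; per-size
    blocks drawn by uniform-key argsort).
    """
    pool = list(pool)
    sizes = list(sizes)
    if any(s > len(pool) for s in sizes):
        raise ValueError("signature size exceeds pool size")
    if any(s < 1 for s in sizes):
        raise ValueError("signature sizes must be >= 1")
    rng = np.random.default_rng([seed, 15485863])
    pool_arr = np.array(pool, dtype=object)
    out: list[tuple[str, ...]] = []
    for s in sizes:
        keys = rng.random((n_per_size, len(pool)))
        picks = np.argpartition(keys, s - 1, axis=1)[:, :s]
        for row in picks:
            out.append(tuple(pool_arr[np.sort(row)]))
    return out


@dataclass
class NullDistribution:
    """Per-signature validation results for the empirical null.

    ``records`` has one row per signature: id, size, members
    (semicolon-joined), validation log-rank p, validation binary HR, and a
    ``converged`` flag.  Non-convergent fits stay in the table but are
    excluded from percentile denominators.
    """

    records: pd.DataFrame
    pool: list[str]
    seed: int | None = None
    observed_threshold: float | None = None

    @property
    def converged(self) -> pd.DataFrame:
        return self.records[self.records["converged"]]

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)

    def manifest(self) -> dict:
        return {
            "seed": self.seed,
            "pool_size": len(self.pool),
            "n_records": int(len(self.records)),
            "n_converged": int(self.records["converged"].sum()),
            "observed_threshold": self.observed_threshold,
        }

    def to_json_manifest(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, indent=1)


def _evaluate_one(
    members,
    train_vals: pd.DataFrame,
    val_vals: pd.DataFrame,
    t_tr,
    e_tr,
    t_va,
    e_va,
):
    X = train_vals.loc[list(members)].T
    try:
        fit = cox_fit(X, t_tr, e_tr)
    except (ConvergenceError, ValueError, np.linalg.LinAlgError):
        return np.nan, np.nan, False
    if fit.separation_flag:
        return np.nan, np.nan, False
    coefs = fit.params
    rs_tr = train_vals.loc[list(members)].T @ coefs.to_numpy()
    cut = float(np.median(rs_tr))
    rs_va = val_vals.loc[list(members)].T @ coefs.to_numpy()
    grp = np.where(rs_va >= cut, "high", "low")
    if (grp == "high").all() or (grp == "low").all():
        return np.nan, np.nan, False
    _, _, p = logrank_test(t_va, e_va, grp)
    try:
        bin_fit = cox_fit((grp == "high").astype(float)[:, None], t_va, e_va)
        hr = float(bin_fit.hr.iloc[0])
        if bin_fit.separation_flag:
            return p, np.nan, False
    except (ConvergenceError, ValueError, np.linalg.LinAlgError):
        return p, np.nan, False
    return p, hr, True


def evaluate_null(
    signatures,
    train_expr: ExpressionMatrix,
    train_surv: SurvivalCohort,
    val_expr: ExpressionMatrix,
    val_surv: SurvivalCohort,
    pool=None,
    include_singletons: bool = False,
    seed: int | None = None,
) -> NullDistribution:
    """Evaluate each signature train->validation and collect the null.

    ``include_singletons`` appends one single-miRNA signature per pool
    member (the "+ individual miRNAs" convention).
    """
    signatures = list(signatures)
    if not signatures:
        raise ValueError("empty signature list")
    train_expr = align_cohort(train_expr, train_surv)
    val_expr = align_cohort(val_expr, val_surv)
    if pool is None:
        pool = sorted({m for sig in signatures for m in sig})
    pool = list(pool)
    all_sigs = signatures + ([(m,) for m in pool] if include_singletons else [])
    t_tr, e_tr = train_surv.time, train_surv.event
    t_va, e_va = val_surv.time, val_surv.event
    train_vals = train_expr.values
    val_vals = val_expr.values
    rows = []
    for i, members in enumerate(all_sigs):
        p, hr, ok = _evaluate_one(members, train_vals, val_vals, t_tr, e_tr, t_va, e_va)
        rows.append(
            {
                "signature_id": f"sig{i + 1:06d}",
                "size": len(members),
                "members": ";".join(members),
                "p": p,
                "hr": hr,
                "converged": ok,
            }
        )
    return NullDistribution(records=pd.DataFrame(rows), pool=pool, seed=seed)


def percentile_rank(
    observed_p: float, observed_hr: float, null: NullDistribution
) -> tuple[float, float]:
    """Percentile of the observed signature within the null, as percentages.

    p percentile: fraction of (converged) null records with p <= observed_p
    ("same or lower"); HR percentile: fraction with |log HR| >= |log
    observed HR| (absolute values, ties count).
    """
    conv = null.converged
    if len(conv) == 0:
        raise ValueError("null distribution has no converged records")
    p_pct = 100.0 * float((conv["p"] <= observed_p).mean())
    log_hr = np.abs(np.log(conv["hr"].to_numpy(dtype=float)))
    hr_pct = 100.0 * float((log_hr >= abs(math.log(observed_hr))).mean())
    return p_pct, hr_pct


def frequency_enrichment(
    null: NullDistribution, significance_threshold: float, top_frac: float = 0.05
) -> pd.DataFrame:
    """Size-normalized miRNA occurrence in significant null signatures.

    Signatures with validation p <= threshold contribute 1/size to each
    member miRNA; totals are ranked and the top ceil(top_frac * pool size)
    miRNAs flagged as selected.  Sum of all normalized counts equals the
    number of significant signatures.
    """
    if not 0 < significance_threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    conv = null.converged
    sig = conv[conv["p"] <= significance_threshold]
    counts = {m: 0.0 for m in null.pool}
    for members, size in zip(sig["members"], sig["size"]):
        w = 1.0 / size
        for m in members.split(";"):
            counts[m] = counts.get(m, 0.0) + w
    table = (
        pd.DataFrame({"mirna_id": list(counts), "normalized_count": list(counts.values())})
        .sort_values(["normalized_count", "mirna_id"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    table["rank"] = np.arange(1, len(table) + 1)
    n_select = math.ceil(top_frac * len(null.pool))
    table["selected"] = table["rank"] <= n_select
    table.attrs["n_significant"] = int(len(sig))
    table.attrs["n_selected"] = n_select
    if len(sig) == 0:
        import warnings

        warnings.warn("no signatures met the significance threshold", stacklevel=2)
    return table
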