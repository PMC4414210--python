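"""Count-to-expression preprocessing for nCounter-style miRNA data.

Pipeline order is fixed: :func:`background_correct` ->
:func:`variance_stabilize` -> :func:`standardize`; each stage refuses
out-of-order input.  Background is the per-sample mean + 2 SD of the
negative-control probe counts; variance stabilization is a single-parameter
generalized-log transform; standardization is the usual per-probe z-score
(optionally reusing training parameters).  Tumour-vs-normal differential
testing uses Welch's t with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix


@dataclass
class NormalizationParams:
    """Parameters learned by the normalization stages.

    background_thresholds : per-sample mean + 2 SD of negative controls
    glog_lambda : generalized-log offset (median positive corrected value)
    center, scale : per-probe standardization parameters
    """

    background_thresholds: pd.Series | None = None
    glog_lambda: float | None = None
    center: pd.Series | None = None
    scale: pd.Series | None = None
    zero_variance_probes: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "background_thresholds": None
            if self.background_thresholds is None
            else self.background_thresholds.to_dict(),
            "glog_lambda": self.glog_lambda,
            "center": None if self.center is None else self.center.to_dict(),
            "scale": None if self.scale is None else self.scale.to_dict(),
            "zero_variance_probes": self.zero_variance_probes,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "NormalizationParams":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            background_thresholds=None
            if payload["background_thresholds"] is None
            else pd.Series(payload["background_thresholds"]),
            glog_lambda=payload["glog_lambda"],
            center=None if payload["center"] is None else pd.Series(payload["center"]),
            scale=None if payload["scale"] is None else pd.Series(payload["scale"]),
            zero_variance_probes=payload.get("zero_variance_probes", []),
        )


def background_correct(matrix: ExpressionMatrix) -> tuple[ExpressionMatrix, NormalizationParams]:
    """Subtract the per-sample negative-control background and clip at zero.

    For each sample ``s`` the threshold is ``mean + 2*SD`` (sample SD,
    n-1 denominator) of that sample's negative-control probe counts; every
    probe value becomes ``max(raw - threshold, 0)``.  Negative-control
    probes are dropped from the output.
    """
    if matrix.stage != "raw":
        raise ValueError(f"background_correct expects raw counts, got stage {matrix.stage!r}")
    neg_ids = matrix.class_probes("negative")
    if len(neg_ids) < 2:
        raise ValueError("need >= 2 negative-control probes to estimate background SD")
    neg = matrix.values.loc[neg_ids]
    thresholds = neg.mean(axis=0) + 2.0 * neg.std(axis=0, ddof=1)
    keep = [p for p in matrix.probe_ids if p not in set(neg_ids)]
    corrected = (matrix.values.loc[keep] - thresholds).clip(lower=0.0)
    out = ExpressionMatrix(
        values=corrected,
        probe_classes=matrix.probe_classes.loc[keep],
        stage="background_corrected",
    )
    return out, NormalizationParams(background_thresholds=thresholds)


def glog2(x, lam: float):
    """Generalized log2: log2((x + sqrt(x^2 + lam^2)) / 2).

    Monotone in ``x``; equals 0 at x = 0 when lam = 2 and approaches
    log2(x) for x >> lam.
    """
    x = np.asarray(x, dtype=float)
    return np.log2((x + np.sqrt(x * x + lam * lam)) / 2.0)


def variance_stabilize(
    matrix: ExpressionMatrix, params: NormalizationParams | None = None
) -> tuple[ExpressionMatrix, NormalizationParams]:
    """Apply a glog2 variance-stabilizing transform.

    The offset ``lambda`` is the median of the positive background-corrected
    values of the dataset (or taken from ``params`` when supplied, allowing
    training-parameter reuse).
    """
    if matrix.stage != "background_corrected":
        raise ValueError(
            f"variance_stabilize expects background-corrected input, got {matrix.stage!r}"
        )
    if params is not None and params.glog_lambda is not None:
        lam = float(params.glog_lambda)
    else:
        arr = matrix.values.to_numpy(dtype=float)
        positive = arr[arr > 0]
        if positive.size == 0:
            raise ValueError("all values are zero; glog lambda undefined")
        lam = float(np.median(positive))
    out = replace(
        matrix,
        values=pd.DataFrame(
            glog2(matrix.values.to_numpy(dtype=float), lam),
            index=matrix.values.index,
            columns=matrix.values.columns,
        ),
        stage="stabilized",
    )
    return out, NormalizationParams(glog_lambda=lam)


def standardize(
    matrix: ExpressionMatrix, params: NormalizationParams | None = None
) -> tuple[ExpressionMatrix, NormalizationParams]:
    """Per-probe z-score (mean-centre, sample-SD scale).

    When ``params`` carries a centre/scale (from a training cohort) they are
    applied as-is; otherwise they are computed from this matrix.  Probes with
    zero variance are flagged in the returned params and excluded from the
    output rather than producing NaNs.
    """
    if matrix.stage != "stabilized":
        raise ValueError(f"standardize expects stabilized input, got {matrix.stage!r}")
    if params is not None and params.center is not None:
        missing = [p for p in matrix.probe_ids if p not in params.center.index]
        if missing:
            raise ValueError(f"supplied params missing probes: {missing[:5]}")
        center = params.center.loc[matrix.probe_ids]
        scale = params.scale.loc[matrix.probe_ids]
        zero_var = list(matrix.values.index[(scale <= 0) | ~np.isfinite(scale)])
    else:
        center = matrix.values.mean(axis=1)
        scale = matrix.values.std(axis=1, ddof=1)
        zero_var = list(matrix.values.index[scale == 0])
    keep = [p for p in matrix.probe_ids if p not in set(zero_var)]
    z = matrix.values.loc[keep].sub(center.loc[keep], axis=0).div(scale.loc[keep], axis=0)
    out = ExpressionMatrix(
        values=z, probe_classes=matrix.probe_classes.loc[keep], stage="standardized"
    )
    return out, NormalizationParams(
        center=center.loc[keep], scale=scale.loc[keep], zero_variance_probes=zero_var
    )


def filter_expressed(
    matrix: ExpressionMatrix,
    cohort_samples=None,
    min_nonzero_frac: float = 0.8,
) -> list[str]:
    """Probes expressed above background in strictly more than
    ``min_nonzero_frac`` of the (training) samples.

    Assessed on background-corrected values (zeros mean expression below
    background); only endogenous probes are considered.
    """
    if matrix.stage != "background_corrected":
        raise ValueError(
            f"filter_expressed expects background-corrected input, got {matrix.stage!r}"
        )
    samples = list(cohort_samples) if cohort_samples is not None else matrix.sample_ids
    if len(samples) == 0:
        raise ValueError("empty sample set")
    sub = matrix.values[samples]
    endo = matrix.probe_classes == "endogenous"
    frac = (sub.loc[endo] > 0).mean(axis=1)
    return list(frac.index[frac > min_nonzero_frac])


def welch_bh_de(group_a: ExpressionMatrix, group_b: ExpressionMatrix) -> pd.DataFrame:
    """Per-probe Welch t-test between two groups with BH adjustment.

    Returns a DataFrame indexed by probe with columns ``t``, ``p``, ``q``
    and ``degenerate`` (True where both groups had zero variance, in which
    case p is recorded as 1).
    """
    from .survstats import bh_fdr

    shared = [p for p in group_a.probe_ids if p in set(group_b.probe_ids)]
    if not shared:
        raise ValueError("no shared probes between groups")
    a = group_a.values.loc[shared].to_numpy(dtype=float)
    b = group_b.values.loc[shared].to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs >= 2 samples")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    # identical constant groups: no evidence of difference
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate | ~np.isfinite(p), 1.0, p)
    q = bh_fdr(p)
    return pd.DataFrame({"t": t, "p": p, "q": q, "degenerate": degenerate}, index=shared)


def normalize_pipeline(
    matrix: ExpressionMatrix, params: NormalizationParams | None = None
) -> tuple[ExpressionMatrix, NormalizationParams]:
    """Run background correction, stabilization and standardization in order.

    ``params`` (if given) supplies the glog lambda and standardization
    centre/scale from a training run; background thresholds are always
    per-sample and recomputed.
    """
    bg, p1 = background_correct(matrix)
    vs, p2 = variance_stabilize(bg, params)
    z, p3 = standardize(vs, params)
    return z, NormalizationParams(
        background_thresholds=p1.background_thresholds,
        glog_lambda=p2.glog_lambda,
        center=p3.center,
        scale=p3.scale,
        zero_variance_probes=p3.zero_variance_probes,
    )
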