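"""Risk-signature discovery and scoring.

`SignatureCoxModel` is the central modelling object: built from a
standardized expression matrix and a survival cohort, its :meth:`fit`
runs the discovery recipe — lasso Cox at the LOOCV-selected penalty,
ranking of nonzero coefficients by absolute value, truncation to k
miRNAs under the events-per-variable rule — and returns a
:class:`SignatureResults` carrying the signature, its risk-score
equation, the training-median cutpoint and a ``summary()`` table.
The published 4-miRNA signature ships as a pre-built results object.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, SurvivalCohort, align_cohort
from .lasso import default_lambda_grid, lambda_max, lasso_cox_fit, loocv_curve

#: coefficients of the published 4-miRNA distant-metastasis signature
PUBLISHED_COEFFICIENTS = {
    "miR-154-5p": 0.417,
    "miR-449b-5p": 0.280,
    "miR-140-5p": -0.653,
    "miR-34c-5p": -0.311,
}


class EmptyModelError(RuntimeError):
    """Lasso retained no variables at the selected penalty."""

    def __init__(self, message: str, cv_curve: pd.Series | None = None):
        super().__init__(message)
        self.cv_curve = cv_curve


@dataclass
class RiskStratification:
    """Continuous risk scores with their high/low dichotomization."""

    risk_score: pd.Series
    group: pd.Series  # "high" / "low"
    cutpoint: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"risk_score": self.risk_score, "group": self.group})


@dataclass
class SignatureResults:
    """A fitted (or published) risk signature.

    ``params`` holds the per-miRNA coefficients on the standardized
    expression scale; the risk score of a patient is the dot product of
    the coefficients with the patient's standardized expression.  The
    cutpoint is the training-cohort median risk score; patients with
    RS >= cutpoint are "high risk".
    """

    params: pd.Series
    cutpoint: float | None = None
    provenance: str = "discovered"
    lambda_star: float | None = None
    n_train: int | None = None
    n_events: int | None = None
    evp: float | None = None
    cv_curve: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if len(self.params) < 1:
            raise ValueError("a signature needs >= 1 miRNA")

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.params.index)

    @property
    def k(self) -> int:
        return len(self.params)

    def summary(self) -> pd.DataFrame:
        """Signature table: miRNA, coefficient, direction of association."""
        tab = pd.DataFrame(
            {
                "coef": self.params,
                "direction": np.where(self.params > 0, "+", "-"),
            }
        )
        tab.attrs.update(
            provenance=self.provenance,
            cutpoint=self.cutpoint,
            lambda_star=self.lambda_star,
            n_train=self.n_train,
            n_events=self.n_events,
            evp=self.evp,
        )
        return tab

    # -- scoring -----------------------------------------------------------
    def risk_scores(self, expr: ExpressionMatrix) -> pd.Series:
        return compute_risk_scores(self, expr)

    def stratify(self, expr: ExpressionMatrix, calibrate: bool = False) -> RiskStratification:
        rs = self.risk_scores(expr)
        if calibrate or self.cutpoint is None:
            strat = dichotomize(rs)
            self.cutpoint = strat.cutpoint
            return strat
        return dichotomize(rs, self.cutpoint)

    def calibrate_cutpoint(self, expr: ExpressionMatrix) -> "SignatureResults":
        """Set the cutpoint to the median risk score of this (training) cohort."""
        self.cutpoint = float(np.median(self.risk_scores(expr)))
        return self

    # -- persistence -------------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "mirnas": self.mirna_ids,
            "coefficients": [float(c) for c in self.params],
            "cutpoint": self.cutpoint,
            "provenance": self.provenance,
            "lambda_star": self.lambda_star,
            "n_train": self.n_train,
            "n_events": self.n_events,
            "evp": self.evp,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SignatureResults":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            params=pd.Series(payload["coefficients"], index=payload["mirnas"], name="coef"),
            cutpoint=payload.get("cutpoint"),
            provenance=payload.get("provenance", "discovered"),
            lambda_star=payload.get("lambda_star"),
            n_train=payload.get("n_train"),
            n_events=payload.get("n_events"),
            evp=payload.get("evp"),
        )


class SignatureCoxModel:
    """L1-penalized Cox model for discovering a k-miRNA risk signature.

    Parameters
    ----------
    expr : ExpressionMatrix
        Standardized expression (stage ``standardized``), probes x samples.
    cohort : SurvivalCohort
        Training follow-up; samples are aligned to the cohort's patients.
    evp_target : float
        Target events-per-variable; signature size defaults to
        floor(events / evp_target), clipped to the nonzero-coefficient count.
    """

    def __init__(self, expr: ExpressionMatrix, cohort: SurvivalCohort, evp_target: float = 5.0):
        if expr.stage != "standardized":
            raise ValueError("expression must be standardized before modelling")
        self.expr = align_cohort(expr, cohort)
        self.cohort = cohort
        self.evp_target = evp_target
        if cohort.n_events < 1:
            raise ValueError("training cohort has zero events")

    @classmethod
    def from_dataframes(
        cls, expr_df: pd.DataFrame, surv_df: pd.DataFrame, evp_target: float = 5.0
    ) -> "SignatureCoxModel":
        """Build from plain DataFrames (probes x samples; survival table)."""
        classes = pd.Series("endogenous", index=expr_df.index)
        expr = ExpressionMatrix(values=expr_df, probe_classes=classes, stage="standardized")
        return cls(expr, SurvivalCohort(surv_df), evp_target=evp_target)

    def fit(
        self,
        k: int | None = None,
        lambda_: float | None = None,
        lambda_grid: np.ndarray | None = None,
        n_lambda: int = 100,
    ) -> SignatureResults:
        """Run the discovery recipe and return the fitted signature.

        ``lambda_`` skips LOOCV tuning; ``k`` overrides the EVP-derived
        signature size.  Coefficients are taken directly from the penalized
        fit (not refit unpenalized).
        """
        X = self.expr.values.T  # samples x probes
        time, event = self.cohort.time, self.cohort.event
        cv = None
        if lambda_ is None:
            if lambda_grid is None:
                lambda_grid = default_lambda_grid(
                    lambda_max(X, time, event), n_lambda=n_lambda
                )
            cv = loocv_curve(X, time, event, lambda_grid)
            best = cv.max()
            lambda_ = float(
                max(cv.index[np.isclose(cv.to_numpy(), best, rtol=0, atol=1e-12)])
            )
        coefs = lasso_cox_fit(X, time, event, lambda_)
        nonzero = coefs[coefs != 0.0]
        if len(nonzero) == 0:
            raise EmptyModelError(
                f"no nonzero coefficients at lambda={lambda_:.4g}", cv_curve=cv
            )
        events = int(event.sum())
        if k is None:
            k = math.floor(events / self.evp_target)
        k = int(np.clip(k, 1, len(nonzero)))
        top = nonzero.reindex(nonzero.abs().sort_values(ascending=False, kind="stable").index)[:k]
        results = SignatureResults(
            params=top,
            provenance="discovered",
            lambda_star=float(lambda_),
            n_train=self.cohort.n,
            n_events=events,
            evp=events / k,
            cv_curve=cv,
        )
        results.calibrate_cutpoint(self.expr)
        return results


def discover_signature(
    train_expr: ExpressionMatrix,
    train_surv: SurvivalCohort,
    evp_target: float = 5.0,
    k_override: int | None = None,
    **fit_kwargs,
) -> SignatureResults:
    """Functional wrapper over :class:`SignatureCoxModel` + :meth:`fit`."""
    return SignatureCoxModel(train_expr, train_surv, evp_target=evp_target).fit(
        k=k_override, **fit_kwargs
    )


def published_signature() -> SignatureResults:
    """The published 4-miRNA signature with its printed coefficients.

    The cutpoint is unset until calibrated on a (training) cohort.
    """
    return SignatureResults(
        params=pd.Series(PUBLISHED_COEFFICIENTS, name="coef"),
        cutpoint=None,
        provenance="published",
    )


def compute_risk_scores(model: SignatureResults, expr: ExpressionMatrix) -> pd.Series:
    """RS_i = sum_j coef_j * standardized expression_ij."""
    missing = [m for m in model.mirna_ids if m not in expr.values.index]
    if missing:
        raise KeyError(f"model miRNAs absent from expression matrix: {missing}")
    sub = expr.values.loc[model.mirna_ids]
    rs = sub.T @ model.params
    return rs.rename("risk_score")


def dichotomize(rs: pd.Series | np.ndarray, cutpoint: float | None = None) -> RiskStratification:
    """Split risk scores at the cutpoint (high iff RS >= cutpoint).

    Without a cutpoint, the median of this vector is used (training
    calibration); for even n the median is the midpoint of the two central
    order statistics.
    """
    rs = pd.Series(rs)
    if len(rs) == 0:
        raise ValueError("empty risk-score vector")
    if not np.isfinite(rs.to_numpy()).all():
        raise ValueError("non-finite risk scores")
    if cutpoint is None:
        cutpoint = float(np.median(rs.to_numpy()))
    group = pd.Series(np.where(rs >= cutpoint, "high", "low"), index=rs.index, name="group")
    return RiskStratification(risk_score=rs, group=group, cutpoint=float(cutpoint))
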