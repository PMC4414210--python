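"""In-memory containers for expression matrices and survival cohorts.

The expression container mirrors an nCounter-style assay: probes carry a
class label (``endogenous``, ``negative`` control, ``positive`` control,
``housekeeping``) and a processing ``stage`` records where the matrix sits
in the normalization pipeline (``raw`` -> ``background_corrected`` ->
``stabilized`` -> ``standardized``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

PROBE_CLASSES = ("endogenous", "negative", "positive", "housekeeping")
STAGES = ("raw", "background_corrected", "stabilized", "standardized")


@dataclass
class ExpressionMatrix:
    """Probes-by-samples expression values with probe-class annotations.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by probe id, columns by sample id.
    probe_classes : pandas.Series
        Probe id -> class, one of :data:`PROBE_CLASSES`.
    stage : str
        Processing stage, one of :data:`STAGES`.
    """

    values: pd.DataFrame
    probe_classes: pd.Series
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        self.probe_classes = self.probe_classes.reindex(self.values.index)
        if self.probe_classes.isna().any():
            missing = list(self.values.index[self.probe_classes.isna()])[:5]
            raise ValueError(f"probes without a class label: {missing}")
        bad = set(self.probe_classes.unique()) - set(PROBE_CLASSES)
        if bad:
            raise ValueError(f"unknown probe classes {sorted(bad)}")
        if self.stage == "raw":
            arr = self.values.to_numpy()
            if (arr < 0).any():
                raise ValueError("raw counts must be non-negative")

    # -- basic views -------------------------------------------------------
    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def class_probes(self, probe_class: str) -> list[str]:
        """Probe ids of a given class, in matrix order."""
        mask = self.probe_classes == probe_class
        return list(self.values.index[mask])

    def subset_probes(self, probe_ids) -> "ExpressionMatrix":
        probe_ids = list(probe_ids)
        missing = [p for p in probe_ids if p not in self.values.index]
        if missing:
            raise KeyError(f"probes absent from matrix: {missing[:5]}")
        return replace(
            self,
            values=self.values.loc[probe_ids],
            probe_classes=self.probe_classes.loc[probe_ids],
        )

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        sample_ids = list(sample_ids)
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing[:5]}")
        return replace(self, values=self.values[sample_ids])

    # -- IO ----------------------------------------------------------------
    def to_tsv(self, path) -> None:
        """Write as TSV: probe_id, probe_class, then one column per sample."""
        out = self.values.copy()
        out.insert(0, "probe_class", self.probe_classes)
        out.index.name = "probe_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path, stage: str = "raw") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col="probe_id")
        classes = df.pop("probe_class")
        return cls(values=df, probe_classes=classes, stage=stage)


REQUIRED_SURVIVAL_COLUMNS = ("patient_id", "time_years", "event")


@dataclass
class SurvivalCohort:
    """Per-patient follow-up for a time-to-event endpoint (distant metastasis).

    ``data`` holds one row per patient with columns ``patient_id``,
    ``time_years`` (> 0), ``event`` (1 = distant metastasis observed,
    0 = censored) plus any clinical covariates (``t_stage``, ``n_stage``,
    ``overall_stage``, ``age``, ``gender``, ``chemo``).
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        for col in REQUIRED_SURVIVAL_COLUMNS:
            if col not in self.data.columns:
                raise ValueError(f"survival table missing column {col!r}")
        t = self.data["time_years"].to_numpy(dtype=float)
        if np.isnan(t).any():
            raise ValueError("missing event times are not allowed")
        if (t <= 0).any():
            raise ValueError("event times must be positive")
        ev = self.data["event"].to_numpy()
        if not np.isin(ev, (0, 1)).all():
            raise ValueError("event indicator must be 0/1")
        self.data = self.data.reset_index(drop=True)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.data["patient_id"])

    @property
    def time(self) -> np.ndarray:
        return self.data["time_years"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=int)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def covariate(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()

    def subset(self, mask) -> "SurvivalCohort":
        return SurvivalCohort(self.data.loc[np.asarray(mask)].reset_index(drop=True))

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "SurvivalCohort":
        return cls(pd.read_csv(Path(path), sep="\t"))


def align_cohort(expr: ExpressionMatrix, cohort: SurvivalCohort) -> ExpressionMatrix:
    """Restrict and order expression columns to the cohort's patients."""
    return expr.subset_samples(cohort.patient_ids)
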