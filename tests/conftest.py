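import numpy as np
import pandas as pd
import pytest

from mirsig import (
    ExpressionMatrix,
    SimConfig,
    SurvivalCohort,
    simulate_cohort,
)
from mirsig.normalize import background_correct, filter_expressed, normalize_pipeline


@pytest.fixture(scope="session")
def small_config():
    """Reduced-size study for fast end-to-end tests (probe count and cohort
    sizes shrunk; signal and rates at the study defaults)."""
    return SimConfig(
        n_train=60,
        n_validation=50,
        n_mirnas=60,
        n_negative_controls=4,
        dropout_frac=0.3,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_cohort(small_config, "train"), simulate_cohort(small_config, "validation")


@pytest.fixture(scope="session")
def small_normalized(small_study):
    """Standardized matrices restricted to the expressed pool, plus cohorts."""
    (tr_expr, tr_surv, tr_truth), (va_expr, va_surv, va_truth) = small_study
    bg, _ = background_correct(tr_expr)
    pool = filter_expressed(bg)
    tr_norm, _ = normalize_pipeline(tr_expr)
    va_norm, _ = normalize_pipeline(va_expr)
    pool = [m for m in pool if m in tr_norm.values.index and m in va_norm.values.index]
    return {
        "train": (tr_norm.subset_probes(pool), tr_surv, tr_truth),
        "validation": (va_norm.subset_probes(pool), va_surv, va_truth),
        "pool": pool,
    }


def make_expression(values: np.ndarray, classes: list[str], stage: str = "raw",
                    probe_ids=None, sample_ids=None) -> ExpressionMatrix:
    """Tiny helper to build matrices in tests."""
    n_probes, n_samples = values.shape
    probe_ids = probe_ids or [f"p{i}" for i in range(n_probes)]
    sample_ids = sample_ids or [f"s{j}" for j in range(n_samples)]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=probe_ids, columns=sample_ids),
        probe_classes=pd.Series(classes, index=probe_ids),
        stage=stage,
    )


def make_cohort(times, events, **covariates) -> SurvivalCohort:
    n = len(times)
    data = {"patient_id": [f"pt{i}" for i in range(n)], "time_years": times, "event": events}
    for name, vals in covariates.items():
        data[name] = vals
    return SurvivalCohort(pd.DataFrame(data))
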