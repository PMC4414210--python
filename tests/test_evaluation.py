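"""Evaluation battery: reports, subsets, multivariate, 5-group, treatment arms."""

import numpy as np
import pandas as pd
import pytest

from mirsig import (
    EvaluationReport,
    SignatureResults,
    SimConfig,
    SurvivalCohort,
    evaluate_signature,
    multivariate_analysis,
    published_signature,
    simulate_cohort,
    stage_treatment_subsets,
    stratify_5group,
    subset_comparison,
)
from mirsig.evaluation import FIVE_GROUP_LABELS, build_design_matrix
from mirsig.normalize import normalize_pipeline
from mirsig.survstats import concordance


@pytest.fixture(scope="module")
def study(small_normalized):
    return small_normalized


def _true_model():
    return published_signature()


class TestEvaluateSignature:
    def test_report_fields_and_serialization(self, study, tmp_path):
        expr, surv, _ = study["train"]
        model = _true_model()
        rep = evaluate_signature(model, expr, surv, cohort_label="training", calibrate=True)
        assert rep.n == surv.n
        assert rep.binary_hr > 0
        assert 0 < rep.logrank_p <= 1
        path = tmp_path / "rep.json"
        rep.to_json(path)
        import json

        back = EvaluationReport.from_dict(json.load(open(path)))
        assert back.binary_hr == pytest.approx(rep.binary_hr)
        assert back.eval_times == rep.eval_times

    def test_requires_calibrated_cutpoint(self, study):
        expr, surv, _ = study["train"]
        model = published_signature()  # no cutpoint yet
        with pytest.raises(ValueError, match="cutpoint"):
            evaluate_signature(model, expr, surv)

    def test_negated_model_inverts_binary_hr(self, study):
        expr, surv, _ = study["train"]
        model = _true_model().calibrate_cutpoint(expr)
        rep = evaluate_signature(model, expr, surv)
        negated = SignatureResults(params=-model.params, cutpoint=-model.cutpoint)
        rep_neg = evaluate_signature(negated, expr, surv)
        # groups swap exactly when no score ties the cutpoint, so HR inverts
        assert rep_neg.binary_hr == pytest.approx(1 / rep.binary_hr, rel=1e-6)
        assert rep_neg.logrank_p == pytest.approx(rep.logrank_p, rel=1e-9)

    def test_validation_hr_above_one_with_planted_signal(self):
        """The true-coefficient model shows HR > 1 on independent validation
        cohorts in most seeds (strong planted signature)."""
        hits = 0
        n_seeds = 12
        for seed in range(n_seeds):
            cfg = SimConfig(
                n_train=120, n_validation=120, n_mirnas=12, n_negative_controls=4,
                signature_ids=("miR-154-5p", "miR-140-5p"),
                signature_betas=(0.75, -0.75), dropout_frac=0.0, seed=700 + seed,
            )
            tr_e, tr_s, _ = simulate_cohort(cfg, "train")
            va_e, va_s, _ = simulate_cohort(cfg, "validation")
            tr_n, _ = normalize_pipeline(tr_e)
            va_n, _ = normalize_pipeline(va_e)
            model = SignatureResults(
                params=pd.Series({"miR-154-5p": 0.75, "miR-140-5p": -0.75})
            ).calibrate_cutpoint(tr_n)
            rep = evaluate_signature(model, va_n, va_s, cohort_label="validation")
            if np.isfinite(rep.binary_hr) and rep.binary_hr > 1:
                hits += 1
        assert hits >= int(0.75 * n_seeds)


class TestSubsetComparison:
    @pytest.mark.parametrize("k", [1, 2, 3, 4, 5, 6])
    def test_row_count_is_two_to_k_minus_one(self, k):
        from mirsig.evaluation import _nonempty_subsets

        assert len(list(_nonempty_subsets(range(k)))) == 2**k - 1

    def test_four_mirna_model_yields_fifteen_rows(self, study):
        expr, surv, _ = study["train"]
        model = _true_model().calibrate_cutpoint(expr)
        table = subset_comparison(model, expr, surv)
        assert len(table) == 15
        assert sorted(table["size"].value_counts().to_dict().items()) == [
            (1, 4), (2, 6), (3, 4), (4, 1),
        ]

    def test_k3_enumeration_oracle(self, study):
        expr, surv, _ = study["train"]
        model = SignatureResults(
            params=published_signature().params.iloc[:3], cutpoint=0.0
        )
        table = subset_comparison(model, expr, surv)
        from itertools import combinations

        expected = set()
        for r in (1, 2, 3):
            for combo in combinations(model.mirna_ids, r):
                expected.add("+".join(combo))
        assert set(table["subset"]) == expected

    def test_single_mirna_subset_matches_evaluate_signature_auc(self, study):
        expr, surv, _ = study["train"]
        mid = "miR-154-5p"
        from mirsig.coxph import cox_fit

        fit = cox_fit(expr.values.loc[[mid]].T, surv.time, surv.event)
        model = SignatureResults(params=fit.params, cutpoint=0.0)
        single = subset_comparison(model, expr, surv)
        assert len(single) == 1
        rep = evaluate_signature(model, expr, surv, calibrate=True)
        for t, auc in zip(rep.eval_times, rep.auc):
            col = f"auc_{t:g}y"
            got = single[col].iloc[0]
            if np.isnan(auc):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(auc, abs=1e-12)

    def test_empty_model_rejected(self, study):
        expr, surv, _ = study["train"]
        with pytest.raises(ValueError):
            SignatureResults(params=pd.Series(dtype=float))


class TestMultivariate:
    def _groups(self, surv, seed=0):
        rng = np.random.default_rng(seed)
        return pd.Series(rng.choice(["high", "low"], surv.n))

    def test_design_matrix_matches_dummy_coding_oracle(self, study):
        _, surv, _ = study["train"]
        groups = self._groups(surv)
        design, removed = build_design_matrix(groups, surv)
        df = surv.data
        keep = df["t_stage"].isin(["T1", "T2", "T3", "T4"]) & df["n_stage"].isin(
            ["N0", "N1", "N2", "N3"]
        )
        assert removed == int((~keep).sum())
        expected_t = df.loc[keep, "t_stage"].isin(["T3", "T4"]).astype(float)
        np.testing.assert_array_equal(design["t_stage_high"].to_numpy(),
                                      expected_t.to_numpy())
        expected_n = df.loc[keep, "n_stage"].isin(["N2", "N3"]).astype(float)
        np.testing.assert_array_equal(design["n_stage_high"].to_numpy(),
                                      expected_n.to_numpy())
        np.testing.assert_array_equal(
            design["gender_female"].to_numpy(),
            (df.loc[keep, "gender"] == "F").astype(float).to_numpy(),
        )

    def test_univariate_and_multivariate_tables(self, study):
        expr, surv, _ = study["train"]
        model = _true_model().calibrate_cutpoint(expr)
        groups = model.stratify(expr).group
        out = multivariate_analysis(groups, surv)
        tab = out["table"]
        assert "rs_high" in tab.index
        assert {"uni_HR", "uni_p", "multi_HR", "multi_p"} <= set(tab.columns)
        assert (tab["uni_HR"] > 0).all()

    def test_duplicated_covariate_rejected(self, study):
        _, surv, _ = study["train"]
        groups = self._groups(surv)
        data = surv.data.copy()
        data["gender"] = np.where(data["chemo"] == 0, "F", "M")  # no_chemo == female
        with pytest.raises(ValueError, match="rank deficient"):
            multivariate_analysis(groups, SurvivalCohort(data))

    def test_adjusted_hr_close_to_unadjusted_without_confounding(self):
        """Clinical covariates independent of expression: the adjusted RS
        hazard ratio stays within ~20% of the unadjusted one (median over
        seeds)."""
        ratios = []
        for seed in range(15):
            cfg = SimConfig(n_train=250, n_validation=4, n_mirnas=10,
                            n_negative_controls=4,
                            signature_ids=("miR-154-5p", "miR-140-5p"),
                            signature_betas=(0.8, -0.8), dropout_frac=0.0,
                            seed=800 + seed)
            expr, surv, _ = simulate_cohort(cfg, "train")
            norm, _ = normalize_pipeline(expr)
            model = SignatureResults(
                params=pd.Series({"miR-154-5p": 0.8, "miR-140-5p": -0.8})
            ).calibrate_cutpoint(norm)
            groups = model.stratify(norm).group
            out = multivariate_analysis(groups, surv)
            tab = out["table"]
            ratios.append(tab.loc["rs_high", "multi_HR"] / tab.loc["rs_high", "uni_HR"])
        assert abs(np.median(ratios) - 1) < 0.2


class TestFiveGroup:
    def test_partition_of_evaluable_patients(self, study):
        _, surv, _ = study["train"]
        rng = np.random.default_rng(3)
        groups = pd.Series(rng.choice(["high", "low"], surv.n))
        out = stratify_5group(groups, surv.data["n_stage"], surv)
        labels = out["labels"]
        assert set(labels.unique()) <= set(FIVE_GROUP_LABELS)
        assert len(labels) + out["n_excluded"] == surv.n
        assert labels.notna().all()

    def test_all_n0_flags_degenerate_logrank(self, study):
        _, surv, _ = study["train"]
        groups = pd.Series(["high"] * surv.n)
        n_stage = pd.Series(["N0"] * surv.n)
        out = stratify_5group(groups, n_stage, surv)
        assert np.isnan(out["logrank"]["p"])
        assert out["flags"]

    def test_unevaluable_n_stage_excluded_with_count(self, study):
        _, surv, _ = study["train"]
        n_stage = surv.data["n_stage"].copy()
        n_stage.iloc[0] = "NX"
        groups = pd.Series(["low"] * surv.n)
        out = stratify_5group(groups, n_stage, surv)
        assert out["n_excluded"] == 1

    def test_five_group_concordance_beats_n_stage_alone_with_planted_risk(self):
        """When hazard rises with both N-stage and the risk score, the
        combined 5-group ordinal discriminates at least as well as N-stage
        alone in most seeds."""
        wins = 0
        n_seeds = 12
        for seed in range(n_seeds):
            cfg = SimConfig(n_train=200, n_validation=4, n_mirnas=10,
                            n_negative_controls=4,
                            signature_ids=("miR-154-5p", "miR-140-5p"),
                            signature_betas=(0.9, -0.9), dropout_frac=0.0,
                            confound_strength=1.5, seed=900 + seed)
            expr, surv, truth = simulate_cohort(cfg, "train")
            norm, _ = normalize_pipeline(expr)
            model = SignatureResults(
                params=pd.Series({"miR-154-5p": 0.9, "miR-140-5p": -0.9})
            ).calibrate_cutpoint(norm)
            groups = model.stratify(norm).group.reset_index(drop=True)
            out = stratify_5group(groups, surv.data["n_stage"], surv)
            c = out["c_statistics"]
            if c["five_group"] >= c["n_stage_alone"]:
                wins += 1
        assert wins >= int(0.8 * n_seeds)


class TestStageTreatmentSubsets:
    def test_filter_count_matches_brute_force(self, study):
        expr, surv, _ = study["train"]
        model = _true_model().calibrate_cutpoint(expr)
        out = stage_treatment_subsets(model, expr, surv)
        expected = surv.data["overall_stage"].isin(["III", "IV"]).sum()
        assert out["n_advanced"] == int(expected)

    def test_empty_arm_flagged_and_skipped(self, study):
        expr, surv, _ = study["train"]
        model = _true_model().calibrate_cutpoint(expr)
        data = surv.data.copy()
        data["chemo"] = 1  # nobody treated with RT alone
        out = stage_treatment_subsets(model, expr, SurvivalCohort(data))
        assert "rt_alone" not in out["arms"]
        assert any("rt_alone" in f for f in out["flags"])

    def test_arm_reports_are_full_evaluations(self, study):
        expr, surv, _ = study["train"]
        model = _true_model().calibrate_cutpoint(expr)
        out = stage_treatment_subsets(model, expr, surv)
        for arm, rep in out["arms"].items():
            assert isinstance(rep, EvaluationReport)
            assert rep.cohort_label == arm
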