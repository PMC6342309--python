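"""Screening, logistic fits, AUC/DeLong, and cross-validation."""

import subprocess

import numpy as np
import pandas as pd
import pytest

import lungheq as lh
from lungheq.errors import DegenerateInputError, ValidationError
from lungheq.risk_models import ScreeningResult, delong_test, find_b1_cutoff

from _oracles import pair_counting_auc


def _symmetric_toy_cohort():
    """Outcome groups with identical covariate distributions → all effects 0."""
    rows = []
    i = 0
    for outcome in ("cancer", "benign"):
        for sex in ("male", "female"):
            for age, brk, b1 in [(60, 0.0, 4000), (70, 500.0, 6000)]:
                row = {
                    "patient_id": f"T{i}", "age": age, "sex": sex,
                    "brinkman_index": brk, "outcome": outcome,
                    "lung_area": 60000.0,
                }
                for t in lh.THRESHOLDS:
                    row[lh.metric_col("laa_pct", t)] = 20.0 if age == 60 else 40.0
                    row[lh.metric_col("b0", t)] = 1000
                    row[lh.metric_col("b1", t)] = b1
                rows.append(row)
                i += 1
    return lh.validate_cohort(pd.DataFrame(rows))


class TestScreening:
    def test_identical_groups_give_p_one(self):
        df = _symmetric_toy_cohort()
        screening = lh.screen_univariate(df)
        assert screening.p("age") == pytest.approx(1.0)
        assert screening.p("b1_880") == pytest.approx(1.0)

    def test_constant_variable_flagged_with_p_one(self):
        df = _symmetric_toy_cohort()
        screening = lh.screen_univariate(df)
        row = screening.table.set_index("variable").loc["b0_950"]
        assert row["constant_flag"] and row["p_value"] == 1.0

    def test_balanced_2x2_has_no_association(self):
        df = _symmetric_toy_cohort()  # sex 50/50 within each outcome
        assert lh.screen_univariate(df).p("sex") > 0.999

    def test_welch_vs_student_switch(self, default_cohort):
        df, _ = default_cohort
        welch = lh.screen_univariate(df, "welch").p("age")
        student = lh.screen_univariate(df, "student").p("age")
        assert welch != student  # different tests, both valid p-values
        assert 0 <= welch <= 1 and 0 <= student <= 1


class TestBestThreshold:
    @staticmethod
    def _screening(b1_ps, laa_ps):
        rows = []
        for t, pb, pl in zip(lh.THRESHOLDS, b1_ps, laa_ps):
            rows.append((lh.metric_col("b1", t), "welch_t", pb, {}, False))
            rows.append((lh.metric_col("laa_pct", t), "welch_t", pl, {}, False))
        return ScreeningResult(pd.DataFrame(
            rows, columns=["variable", "test_name", "p_value", "detail", "constant_flag"]
        ))

    def test_minimum_b1_p_wins(self):
        s = self._screening([0.5, 0.5, 0.01], [0.9, 0.9, 0.9])
        assert lh.select_best_threshold(s) == -880

    def test_tie_falls_back_to_laa_p(self):
        s = self._screening([0.05, 0.05, 0.5], [0.9, 0.1, 0.9])
        assert lh.select_best_threshold(s) == -910

    def test_full_tie_prefers_higher_hu(self):
        s = self._screening([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
        assert lh.select_best_threshold(s) == -880


class TestLogisticFit:
    def test_zero_effect_covariates_on_symmetric_data(self):
        fit = lh.fit_logistic(_symmetric_toy_cohort(), "heq")
        t = fit.term("b1_880")
        assert t.coefficient == pytest.approx(0.0, abs=1e-6)
        assert t.wald_p == pytest.approx(1.0, abs=1e-4)

    def test_aic_matches_hand_computed_log_likelihood(self, default_cohort):
        df, _ = default_cohort
        fit = lh.fit_logistic(df, "heq")
        y = (df.set_index("patient_id").loc[fit.fitted_probability.index, "outcome"]
             == "cancer").astype(float).to_numpy()
        p = fit.fitted_probability.to_numpy()
        llf = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
        k = len(fit.terms) + 1  # + intercept
        assert fit.aic == pytest.approx(2 * k - 2 * llf, rel=1e-10)
        assert ((p > 0) & (p < 1)).all()

    def test_parameter_recovery_within_3_se(self):
        df, truth = lh.generate_cohort(lh.CohortSpec(n_patients=4000, seed=31))
        fit = lh.fit_logistic(df, "heq")
        for name, term in [("sex_male", "sex_male"), ("age", "age"),
                           ("brinkman_index", "brinkman_index"),
                           ("b1_880", "b1_880")]:
            t = fit.term(term)
            assert abs(t.coefficient - truth.coefficients[name]) < 3 * t.standard_error

    def test_bias_shrinks_with_sample_size(self):
        errs = {}
        for n in (500, 5000):
            devs = []
            for seed in range(8):
                df, truth = lh.generate_cohort(lh.CohortSpec(n_patients=n, seed=100 + seed))
                fit = lh.fit_logistic(df, "heq")
                devs.append(fit.term("b1_880").coefficient - truth.coefficients["b1_880"])
            errs[n] = abs(np.mean(devs))
        assert errs[5000] < errs[500] + 1e-5

    def test_single_class_outcome_rejected(self):
        df = _symmetric_toy_cohort()
        df = df[df["outcome"] == "cancer"].copy()
        with pytest.raises(DegenerateInputError):
            lh.fit_logistic(df, "base")


class TestBinarizeAndOddsRatio:
    @pytest.mark.parametrize("value, expected", [(5100, 0), (5101, 1), (0, 0)])
    def test_cutoff_is_strict(self, value, expected):
        assert lh.binarize_b1(value) == expected

    def test_odds_ratio_closed_form(self, default_cohort):
        df, _ = default_cohort
        fit = lh.fit_logistic(df, "heq_b")
        # check against the closed form exp(coef ± 1.959964 SE)
        t = fit.term("b1_880_bin")
        or_, lo, hi = lh.odds_ratio(fit, "b1_880_bin")
        assert or_ == pytest.approx(np.exp(t.coefficient))
        assert lo == pytest.approx(np.exp(t.coefficient - 1.959964 * t.standard_error))
        assert hi == pytest.approx(np.exp(t.coefficient + 1.959964 * t.standard_error))

    def test_null_coefficient_interval(self):
        # OR for coef 0, SE 0.1 has the closed form (1.0, 0.822, 1.217)
        assert np.exp(0.0) == 1.0
        assert np.exp(-1.959964 * 0.1) == pytest.approx(0.822, abs=1e-3)
        assert np.exp(1.959964 * 0.1) == pytest.approx(1.217, abs=1e-3)

    def test_missing_term_lookup(self, default_cohort):
        df, _ = default_cohort
        fit = lh.fit_logistic(df, "base")
        with pytest.raises(KeyError):
            lh.odds_ratio(fit, "b1_880")

    def test_exploratory_cutoff_search_runs(self, default_cohort):
        df, _ = default_cohort
        cutoff = find_b1_cutoff(df)
        assert df["b1_880"].min() <= cutoff <= df["b1_880"].max()


class TestAuc:
    def test_perfect_separation(self):
        assert lh.roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert lh.roc_auc([0.5] * 6, [0, 0, 1, 0, 1, 1]) == 0.5

    def test_six_point_toy_case(self):
        assert lh.roc_auc([1, 2, 3, 4, 5, 6], [0, 0, 1, 0, 1, 1]) == pytest.approx(8 / 9)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            lh.roc_auc([0.1, 0.9], [1, 1])

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 51))
            scores = rng.integers(0, 10, n).astype(float)  # many ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            assert lh.roc_auc(scores, labels) == pytest.approx(
                pair_counting_auc(scores.tolist(), labels.tolist())
            )


class TestDeLong:
    def test_self_comparison_is_null(self, rng):
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        s = rng.normal(size=40)
        comp = delong_test(s, s, y)
        assert comp.delong_z == 0.0 and comp.delong_p == 1.0

    def test_matches_r_proc_on_fixture(self, tmp_path, rng):
        y = (rng.random(60) < 0.5).astype(int)
        y[:2] = [0, 1]
        a = y + rng.normal(0, 1, 60)
        b = y + rng.normal(0, 1.5, 60)
        comp = delong_test(a, b, y)
        csv = tmp_path / "scores.csv"
        np.savetxt(csv, np.column_stack([y, a, b]), delimiter=",",
                   header="y,a,b", comments="")
        rscript = (
            'suppressMessages(library(pROC)); d <- read.csv("%s"); '
            "t <- roc.test(roc(d$y, d$a, quiet=TRUE), roc(d$y, d$b, quiet=TRUE), "
            'method="delong", paired=TRUE); '
            'cat(sprintf("%%.12f %%.12f", t$p.value, t$statistic))' % csv
        )
        out = subprocess.run(["Rscript", "-e", rscript],
                             capture_output=True, text=True, check=True)
        p_r, z_r = map(float, out.stdout.split())
        assert comp.delong_p == pytest.approx(p_r, abs=1e-9)
        assert comp.delong_z == pytest.approx(z_r, abs=1e-9)

    def test_variance_agrees_with_bootstrap(self, rng):
        n = 300
        y = (rng.random(n) < 0.5).astype(int)
        y[:2] = [0, 1]
        s = y + rng.normal(0, 1, n)
        var_delong = delong_test(s, s, y).covariance[0, 0]
        aucs = []
        for _ in range(1000):
            idx = rng.integers(0, n, n)
            if y[idx].min() == y[idx].max():
                continue
            aucs.append(lh.roc_auc(s[idx], y[idx]))
        var_boot = np.var(aucs, ddof=1)
        assert var_delong == pytest.approx(var_boot, rel=0.15)

    def test_mismatched_patient_sets_rejected(self, default_cohort):
        df, _ = default_cohort
        fit_a = lh.fit_logistic(df, "base")
        fit_b = lh.fit_logistic(df.iloc[:-5], "heq")
        with pytest.raises(DegenerateInputError):
            lh.delong_compare(fit_a, fit_b, df.set_index("patient_id")["outcome"])


class TestCrossValidation:
    def test_same_seed_reproduces_folds_and_auc(self, default_cohort):
        df, _ = default_cohort
        a = lh.crossvalidate(df, "heq", k=10, seed=3)
        b = lh.crossvalidate(df, "heq", k=10, seed=3)
        assert a.fold_assignment.equals(b.fold_assignment)
        assert a.auc == b.auc

    def test_folds_partition_patients(self, default_cohort):
        df, _ = default_cohort
        cv = lh.crossvalidate(df, "base", k=10, seed=1)
        assert (cv.fold_assignment >= 0).all()
        assert cv.oof_probability.notna().all()
        assert len(cv.oof_probability) == len(df)

    def test_strong_signal_yields_near_perfect_pooled_auc(self):
        # b1 dominates the outcome; pooled out-of-fold AUC approaches 1
        df, _ = lh.generate_cohort(
            lh.CohortSpec(n_patients=1000, coef_b1=0.002, coef_sex_male=0,
                          coef_age=0, coef_brinkman=0, seed=13)
        )
        cv = lh.crossvalidate(df, "heq", k=5, seed=0)
        assert cv.auc > 0.95

    def test_cv_auc_not_above_apparent_on_average(self):
        deltas = []
        for seed in range(20):
            df, _ = lh.generate_cohort(lh.CohortSpec(n_patients=300, seed=200 + seed))
            fit = lh.fit_logistic(df, "heq")
            y = (df["outcome"] == "cancer").astype(float).to_numpy()
            apparent = lh.roc_auc(fit.fitted_probability.to_numpy(), y)
            cv = lh.crossvalidate(df, "heq", k=10, seed=seed)
            deltas.append(apparent - cv.auc)
        assert np.mean(deltas) >= 0

    def test_aic_drops_when_planted_covariate_added(self):
        hits = 0
        for seed in range(20):
            df, _ = lh.generate_cohort(lh.CohortSpec(n_patients=2000, seed=300 + seed))
            base = lh.fit_logistic(df, "base")
            heq = lh.fit_logistic(df, "heq")
            hits += heq.aic < base.aic
        assert hits >= 19

    def test_k_below_two_rejected(self, default_cohort):
        df, _ = default_cohort
        with pytest.raises(ValidationError):
            lh.crossvalidate(df, "base", k=1, seed=0)
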