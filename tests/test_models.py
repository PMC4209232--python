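"""Risk-model machinery: logistic fits (cross-checked against statsmodels),
c-statistic, stepwise selection and bootstrap retention."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import logit

import riskprofiler as rp
from riskprofiler import glm, models
from riskprofiler.config import SelectionConfig


def _sim_binary(rng, n, specs, intercept=-2.0):
    """Independent binary covariates with given (prevalence, OR) and a
    logistic outcome."""
    X = pd.DataFrame({name: rng.binomial(1, prev, n)
                      for name, (prev, _) in specs.items()})
    lp = intercept + sum(np.log(orr) * X[name]
                         for name, (_, orr) in specs.items())
    y = rng.binomial(1, 1 / (1 + np.exp(-lp)))
    return X, y


class TestFitLogistic:
    def test_matches_statsmodels_to_machine_precision(self):
        rng = np.random.default_rng(0)
        X, y = _sim_binary(rng, 2000, {"a": (0.3, 2.0), "b": (0.5, 0.7),
                                       "c": (0.1, 1.0)})
        ours = rp.fit_logistic(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(ours.coefficients.to_numpy(),
                                   ref.params.to_numpy(), atol=1e-8)
        np.testing.assert_allclose(ours.se.to_numpy(), ref.bse.to_numpy(),
                                   atol=1e-8)
        np.testing.assert_allclose(ours.pvalues.to_numpy(),
                                   ref.pvalues.to_numpy(), atol=1e-8)

    def test_two_by_two_closed_form(self):
        # exposed: 30 events / 70 non-events; unexposed: 10 / 90
        x = np.repeat([1, 1, 0, 0], [30, 70, 10, 90])
        y = np.repeat([1, 0, 1, 0], [30, 70, 10, 90])
        fit = rp.fit_logistic(pd.DataFrame({"x": x}), y)
        assert fit.odds_ratios["x"] == pytest.approx((30 * 90) / (70 * 10),
                                                     rel=1e-6)

    def test_intercept_only_closed_form(self):
        y = np.repeat([1, 0], [40, 60])
        fit = rp.fit_logistic(pd.DataFrame(index=range(100)), y)
        assert fit.coefficients["intercept"] == pytest.approx(logit(0.4),
                                                              abs=1e-8)

    def test_null_covariate_or_near_one(self):
        rng = np.random.default_rng(1)
        X, y = _sim_binary(rng, 10000, {"x": (0.5, 1.0)})
        fit = rp.fit_logistic(X, y)
        # 3 standard errors on the log-odds scale
        assert abs(fit.coefficients["x"]) < 3 * fit.se["x"]

    def test_separation_flagged_not_raised_in_raw_path(self):
        y = np.repeat([0, 1], 20)
        X = pd.DataFrame({"x": y.astype(float)})
        fit, _ = models._fit_raw(X, y.astype(float))
        assert not fit.converged
        with pytest.raises(models.FitFailure):
            rp.fit_logistic(X, y)

    def test_constant_zero_column_rejected(self):
        X = pd.DataFrame({"x": np.zeros(50)})
        with pytest.raises(ValueError, match="constant-zero"):
            rp.fit_logistic(X, np.repeat([0, 1], 25))


def _brute_force_c(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    conc = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                conc += 1
            elif p == q:
                ties += 1
    return (conc + 0.5 * ties) / (len(pos) * len(neg))


class TestCStatistic:
    @pytest.mark.parametrize("scores, labels, expected", [
        ([0.9, 0.1], [1, 0], 1.0),
        ([0.5, 0.5, 0.5], [1, 0, 1], 0.5),
        ([0.2, 0.4, 0.6, 0.8], [0, 1, 0, 1], 0.75),
    ])
    def test_worked_examples(self, scores, labels, expected):
        assert rp.c_statistic(np.array(scores), np.array(labels)) == expected

    def test_equals_brute_force_exactly_including_ties(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(4, 200))
            # coarse grid forces many ties
            scores = rng.choice(np.linspace(0, 1, 7), n)
            labels = rng.binomial(1, 0.4, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert rp.c_statistic(scores, labels) == _brute_force_c(scores, labels)

    @given(st.lists(st.floats(-5, 5), min_size=4, max_size=60),
           st.floats(0.1, 3.0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_invariant_under_monotone_transform(self, raw, slope):
        # round to a coarse grid so exp() is strictly monotone in floats
        # (it keeps distinct scores distinct and tied scores tied)
        scores = np.round(np.asarray(raw), 3)
        labels = (np.arange(len(scores)) % 2).astype(int)
        transformed = np.exp(slope * scores)      # strictly increasing
        assert rp.c_statistic(scores, labels) == pytest.approx(
            rp.c_statistic(transformed, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            rp.c_statistic(np.array([0.1, 0.2]), np.array([1, 1]))


class TestStepwise:
    def test_empty_candidates_returns_forced_only(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"age": rng.normal(70, 10, 500),
                          "gender_female": rng.binomial(1, 0.5, 500)})
        y = rng.binomial(1, 0.2, 500)
        sel, pvals, ok = rp.stepwise_select(X, y, {})
        assert sel == [] and ok

    def test_strong_predictor_selected(self):
        rng = np.random.default_rng(3)
        X, y = _sim_binary(rng, 2000, {"strong": (0.3, 3.0), "noise": (0.3, 1.0)})
        X["age"] = rng.normal(70, 10, 2000)
        X["gender_female"] = rng.binomial(1, 0.5, 2000)
        sel, pvals, ok = rp.stepwise_select(
            X, y, {"strong": ("strong",), "noise": ("noise",)})
        assert "strong" in sel and ok

    def test_null_simulation_mostly_forced_only(self):
        """With one unassociated candidate at alpha 0.05, the selection
        should return the forced-only model in ~95% of datasets."""
        rng = np.random.default_rng(4)
        hits = 0
        for _ in range(40):
            X, y = _sim_binary(rng, 1000, {"noise": (0.3, 1.0)})
            X["age"] = rng.normal(70, 10, 1000)
            X["gender_female"] = rng.binomial(1, 0.5, 1000)
            sel, _, ok = rp.stepwise_select(X, y, {"noise": ("noise",)})
            hits += (sel == [])
        assert hits >= 0.90 * 40

    def test_deterministic_tie_break_by_name(self):
        rng = np.random.default_rng(5)
        X, y = _sim_binary(rng, 1500, {"a": (0.3, 2.5)})
        X["b"] = X["a"]                       # identical twin column
        X["age"] = rng.normal(70, 10, 1500)
        X["gender_female"] = rng.binomial(1, 0.5, 1500)
        sel, _, ok = rp.stepwise_select(X, y, {"a": ("a",), "b": ("b",)})
        assert sel == ["a"]                   # alphabetical tie-break


class TestBootstrapStepwise:
    def test_reproducible_given_seed(self, small_ami_cohort):
        cands = {"diabetes": ("diabetes",), "hypertension": ("hypertension",),
                 "heart_failure": ("heart_failure",)}
        cfg = SelectionConfig(n_bootstrap=25, seed=11)
        y = small_ami_cohort["outcome"].to_numpy()
        r1 = rp.bootstrap_stepwise(small_ami_cohort, y, cands, cfg)
        r2 = rp.bootstrap_stepwise(small_ami_cohort, y, cands, cfg)
        pd.testing.assert_series_equal(r1.frequencies, r2.frequencies)
        assert r1.retained == r2.retained

    def test_zero_retain_fraction_keeps_anything_ever_selected(self):
        rng = np.random.default_rng(6)
        X, y = _sim_binary(rng, 1200, {"a": (0.3, 2.0), "b": (0.3, 1.0)})
        X["age"] = rng.normal(70, 10, 1200)
        X["gender_female"] = rng.binomial(1, 0.5, 1200)
        res = rp.bootstrap_stepwise(
            X, y, {"a": ("a",), "b": ("b",)},
            SelectionConfig(n_bootstrap=40, retain_fraction=0, seed=7))
        ever = [k for k, v in res.frequencies.items() if v > 0]
        assert res.retained == sorted(ever)

    def test_forced_covariates_have_no_frequency(self, small_ami_cohort):
        cands = {"diabetes": ("diabetes",)}
        res = rp.bootstrap_stepwise(
            small_ami_cohort, small_ami_cohort["outcome"].to_numpy(), cands,
            SelectionConfig(n_bootstrap=10, seed=1))
        assert set(res.frequencies.index) == {"diabetes"}

    def test_unstable_data_raises(self):
        # candidate == outcome separates every resample
        y = np.repeat([0, 1], 25)
        X = pd.DataFrame({"x": y.astype(float),
                          "age": np.linspace(60, 80, 50),
                          "gender_female": np.tile([0, 1], 25)})
        with pytest.raises(models.FitFailure, match="converged"):
            rp.bootstrap_stepwise(X, y, {"x": ("x",)},
                                  SelectionConfig(n_bootstrap=10, seed=2))


class TestModelPair:
    def test_a_equals_b_gives_zero_delta_c(self):
        rng = np.random.default_rng(8)
        X, y = _sim_binary(rng, 2000, {"a": (0.3, 2.0)})
        X["age"] = rng.normal(70, 10, 2000)
        X["gender_female"] = rng.binomial(1, 0.5, 2000)
        cands = {"a": ("a",)}
        pair = rp.build_model_pair(X, y, cands, cands,
                                   SelectionConfig(n_bootstrap=15, seed=3))
        assert pair.delta_c == 0.0

    def test_extra_true_signal_raises_apparent_c(self):
        rng = np.random.default_rng(9)
        X, y = _sim_binary(rng, 4000, {"a": (0.3, 2.0), "extra": (0.25, 4.0)})
        X["age"] = rng.normal(70, 10, 4000)
        X["gender_female"] = rng.binomial(1, 0.5, 4000)
        pair = rp.build_model_pair(
            X, y, {"a": ("a",)}, {"a": ("a",), "extra": ("extra",)},
            SelectionConfig(n_bootstrap=15, seed=4))
        assert "extra" in pair.selection_b.retained
        assert pair.delta_c > 0

    def test_a_not_subset_of_b_rejected(self):
        X = pd.DataFrame({"a": [0, 1] * 20, "age": range(40),
                          "gender_female": [0, 1] * 20})
        with pytest.raises(ValueError, match="subset"):
            rp.build_model_pair(X, np.tile([0, 1], 20), {"a": ("a",)}, {},
                                SelectionConfig(n_bootstrap=2))

    def test_report_layout(self, small_ami_cohort):
        y = small_ami_cohort["outcome"].to_numpy()
        ca = {"diabetes": ("diabetes",), "heart_failure": ("heart_failure",)}
        cb = ca | {"sbp": ("sbp_le100", "sbp_missing")}
        pair = rp.build_model_pair(small_ami_cohort, y, ca, cb,
                                   SelectionConfig(n_bootstrap=12, seed=5))
        rep = models.model_report(pair, small_ami_cohort, y)
        assert rep["covariate"].iloc[-1] == "c_statistic"
        assert {"crude_or", "adjusted_or_discharge", "adjusted_or_full"} \
            <= set(rep.columns)
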