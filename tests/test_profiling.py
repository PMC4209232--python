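"""Direct standardisation, K correction, funnel limits/classification and
the random-intercept sensitivity model."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import riskprofiler as rp
from riskprofiler import profiling
from riskprofiler.config import ProfilingConfig
from riskprofiler.profiling import (StandardisationResult, center_covariates,
                                    fit_hospital_model)


def _null_cohort(rng, m=8, nj=150, rate=0.2, covs=True):
    n = m * nj
    df = pd.DataFrame({
        "hospital_id": np.repeat([f"H{j}" for j in range(m)], nj),
        "outcome": rng.binomial(1, rate, n),
    })
    if covs:
        df["age"] = rng.normal(70, 10, n)
        df["gender_female"] = rng.binomial(1, 0.5, n)
    return df


class TestCentering:
    def test_examples_and_idempotence(self):
        X = pd.DataFrame({"ones": np.ones(10),
                          "b": np.repeat([1.0, 0.0], [4, 6])})
        Xc, means = center_covariates(X)
        assert (Xc["ones"] == 0).all() and means["ones"] == 1
        assert set(np.round(Xc["b"].unique(), 10)) == {0.6, -0.4}
        Xcc, _ = center_covariates(Xc)
        np.testing.assert_allclose(Xcc.to_numpy(), Xc.to_numpy(), atol=1e-12)
        # means allow exact reconstruction
        np.testing.assert_allclose((Xc + means).to_numpy(), X.to_numpy())


class TestBackTransformAndK:
    @pytest.mark.parametrize("estimate, k, expected", [
        (0.0, 1.0, 0.5),
        (logit(0.2), 1.0, 0.2),
        (0.0, 1.2, 0.6),
    ])
    def test_back_transform(self, estimate, k, expected):
        assert rp.back_transform(estimate, k) == pytest.approx(expected, 1e-9)

    def test_k_arithmetic(self):
        assert rp.correction_k(np.r_[0.5, 0.5], np.r_[10, 10], 10) == 1.0
        assert rp.correction_k(np.r_[0.2, 0.4], np.r_[100, 100], 75) == \
            pytest.approx(1.25)
        # scale invariance
        assert rp.correction_k(np.r_[0.2, 0.4], np.r_[200, 200], 150) == \
            pytest.approx(1.25)

    @pytest.mark.parametrize("kw", [
        dict(p=np.r_[0.0, 0.0], n=np.r_[5, 5], total_events=3),
        dict(p=np.r_[0.2, 0.2], n=np.r_[5, 5], total_events=0),
    ])
    def test_k_invalid_inputs(self, kw):
        with pytest.raises(ValueError):
            rp.correction_k(kw["p"], kw["n"], kw["total_events"])

    def test_negative_k_rejected_in_back_transform(self):
        with pytest.raises(ValueError):
            rp.back_transform(0.0, -1.0)


class TestHospitalModel:
    def test_saturated_closed_form(self):
        rng = np.random.default_rng(0)
        df = _null_cohort(rng, m=5, nj=100, covs=False)
        est, flagged = fit_hospital_model(df[[]], df["hospital_id"],
                                          df["outcome"].to_numpy())
        obs = df.groupby("hospital_id")["outcome"].mean()
        np.testing.assert_allclose(est.to_numpy(),
                                   logit(obs.to_numpy()), atol=1e-8)
        assert not flagged.any()

    def test_constant_covariate_equals_no_covariate_case(self):
        rng = np.random.default_rng(1)
        df = _null_cohort(rng, m=4, nj=80, covs=False)
        df["const"] = 1.0
        Xc, _ = center_covariates(df[["const"]])
        est_const, _ = fit_hospital_model(Xc, df["hospital_id"],
                                          df["outcome"].to_numpy())
        est_none, _ = fit_hospital_model(df[[]], df["hospital_id"],
                                         df["outcome"].to_numpy())
        np.testing.assert_allclose(est_const.to_numpy(), est_none.to_numpy(),
                                   atol=1e-10)

    def test_identical_hospitals_get_equal_estimates(self):
        base = pd.DataFrame({"outcome": np.r_[np.ones(20), np.zeros(80)]})
        df = pd.concat([base.assign(hospital_id="A"),
                        base.assign(hospital_id="B")], ignore_index=True)
        est, _ = fit_hospital_model(df[[]], df["hospital_id"],
                                    df["outcome"].to_numpy())
        assert est["A"] == pytest.approx(est["B"], abs=1e-10)
        assert est["A"] == pytest.approx(logit(0.2), abs=1e-8)

    def test_zero_event_hospital_flagged_and_penalised(self):
        rng = np.random.default_rng(2)
        df = _null_cohort(rng, m=3, nj=60, covs=False)
        df.loc[df["hospital_id"] == "H0", "outcome"] = 0
        est, flagged = fit_hospital_model(df[[]], df["hospital_id"],
                                          df["outcome"].to_numpy())
        assert flagged["H0"] and not flagged["H1"]
        assert np.isfinite(est["H0"])


class TestStandardise:
    def test_conservation_identity(self, small_ami_cohort):
        covs = ["age", "gender_female", "diabetes", "heart_failure",
                "sbp_le100", "sbp_missing", "diuretics"]
        res = rp.standardise(small_ami_cohort, covs)
        assert res.conservation_error() < 1e-8

    def test_no_covariates_reproduces_observed_rates(self, small_ami_cohort):
        res = rp.standardise(small_ami_cohort, [])
        assert res.k == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_allclose(res.table["adjusted_proportion"],
                                   res.table["observed_rate"], atol=1e-6)

    def test_low_volume_hospitals_excluded(self):
        rng = np.random.default_rng(3)
        df = _null_cohort(rng, m=4, nj=100, covs=False)
        small = pd.DataFrame({"hospital_id": ["tiny"] * 5,
                              "outcome": [0, 1, 0, 0, 0]})
        res = rp.standardise(pd.concat([df, small], ignore_index=True), [],
                             ProfilingConfig(min_volume=10))
        assert list(res.excluded["hospital_id"]) == ["tiny"]
        assert "tiny" not in set(res.table["hospital_id"])

    def test_true_outlier_hospital_has_maximal_adjusted_rate(self):
        rng = np.random.default_rng(4)
        m, nj = 10, 400
        hosp = np.repeat([f"H{j}" for j in range(m)], nj)
        age = rng.normal(70, 10, m * nj)
        shift = np.where(hosp == "H7", 1.0, 0.0)
        lp = logit(0.12) + 0.05 * (age - 70) + shift
        df = pd.DataFrame({"hospital_id": hosp, "age": age,
                           "outcome": rng.binomial(1, expit(lp))})
        res = rp.standardise(df, ["age"])
        top = res.table.loc[res.table["adjusted_proportion"].idxmax(),
                            "hospital_id"]
        assert top == "H7"


class TestFunnel:
    def test_normal_limit_arithmetic(self):
        lo, hi = rp.funnel_limits(0.5, np.array([100.0]), 0.95)
        assert lo[0] == pytest.approx(0.402, abs=5e-4)
        assert hi[0] == pytest.approx(0.598, abs=5e-4)

    def test_halfwidth_scales_as_inverse_sqrt_n(self):
        lo1, hi1 = rp.funnel_limits(0.3, np.array([100.0]), 0.95)
        lo4, hi4 = rp.funnel_limits(0.3, np.array([400.0]), 0.95)
        assert (hi4 - lo4)[0] == pytest.approx((hi1 - lo1)[0] / 2, rel=1e-9)

    def test_clipping_at_zero(self):
        lo, _ = rp.funnel_limits(0.05, np.array([10.0]), 0.95)
        assert lo[0] == 0.0

    def test_binomial_option_within_unit_interval(self):
        lo, hi = rp.funnel_limits(0.1, np.arange(10, 500, 37, dtype=float),
                                  0.998, method="binomial")
        assert (lo >= 0).all() and (hi <= 1).all() and (hi >= lo).all()

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            rp.funnel_limits(0.0, np.array([10.0]), 0.95)

    def _result_from_values(self, values, n):
        m = len(values)
        tbl = pd.DataFrame({
            "hospital_id": [f"H{j}" for j in range(m)],
            "n": n, "observed_events": (np.asarray(values) * n).astype(int),
            "observed_rate": values, "estimate": logit(np.asarray(values)),
            "p_uncorrected": values, "adjusted_proportion": values,
            "flagged": False,
        })
        events = float(np.sum(np.asarray(values) * n))
        return StandardisationResult(
            table=tbl, k=1.0, total_events=events,
            covariate_means=pd.Series(dtype=float),
            overall_rate=events / (m * n), excluded=pd.DataFrame())

    def test_point_exactly_on_limit_is_inside(self):
        target = 0.2
        n = 100
        _, hi = rp.funnel_limits(target, np.array([float(n)]), 0.95)
        res = self._result_from_values([target, float(hi[0])], n)
        chart = rp.classify_hospitals(res, target=target)
        assert list(chart.points["classification"]) == ["inside", "inside"]

    def test_extreme_point_is_outside_998_high(self):
        res = self._result_from_values([0.2, 0.9], 200)
        chart = rp.classify_hospitals(res, target=0.2)
        row = chart.points.iloc[1]
        assert row["classification"] == "outside_998"
        assert row["direction"] == "high"

    def test_null_coverage_is_roughly_nominal(self):
        """~5% of hospitals under the null fall outside the 95% limits."""
        rng = np.random.default_rng(7)
        m, nj, rate = 400, 250, 0.15
        values = rng.binomial(nj, rate, m) / nj
        res = self._result_from_values(values.tolist(), nj)
        chart = rp.classify_hospitals(res, target=rate)
        frac_out = (chart.points["classification"] != "inside").mean()
        assert 0.02 < frac_out < 0.09


class TestRankAgreement:
    def _profile(self, values, classes=None):
        df = pd.DataFrame({"hospital_id": [f"H{j}" for j in range(len(values))],
                           "value": values})
        df["classification"] = classes if classes is not None else "inside"
        return df

    def test_identical_profiles(self):
        p = self._profile([0.1, 0.2, 0.3])
        rho, concord = rp.rank_agreement(p, p)
        assert rho == 1.0 and concord == 1.0

    def test_reversed_ranking(self):
        a = self._profile([0.1, 0.2, 0.3, 0.4])
        b = self._profile([0.4, 0.3, 0.2, 0.1])
        rho, _ = rp.rank_agreement(a, b)
        assert rho == -1.0

    def test_independent_profiles_near_zero(self):
        rng = np.random.default_rng(8)
        a = self._profile(rng.random(60))
        b = self._profile(rng.random(60))
        rho, _ = rp.rank_agreement(a, b)
        assert abs(rho) < 0.3

    def test_mismatched_hospitals_rejected(self):
        a = self._profile([0.1, 0.2])
        b = self._profile([0.1, 0.2, 0.3])
        with pytest.raises(ValueError, match="different hospital"):
            rp.rank_agreement(a, b)


class TestMultilevel:
    def test_degenerate_no_heterogeneity(self):
        rng = np.random.default_rng(9)
        df = _null_cohort(rng, m=30, nj=150, rate=0.15, covs=False)
        res = rp.multilevel_sensitivity(df, [])
        assert res.sd < 0.1
        # shrunken estimates collapse to the overall mean log-odds
        spread = res.shrunken_logodds.max() - res.shrunken_logodds.min()
        assert spread < 0.2

    def test_requires_two_hospitals(self):
        df = pd.DataFrame({"hospital_id": ["A"] * 10,
                           "outcome": [0, 1] * 5})
        with pytest.raises(ValueError):
            rp.multilevel_sensitivity(df, [])

    def test_shrunken_ranking_tracks_fixed_effects_under_strong_signal(self):
        rng = np.random.default_rng(10)
        m, nj = 25, 250
        u = rng.normal(0, 0.6, m)
        hosp = np.repeat(np.arange(m), nj)
        y = rng.binomial(1, expit(logit(0.15) + u[hosp]))
        df = pd.DataFrame({"hospital_id": [f"H{j:02d}" for j in hosp],
                           "outcome": y})
        mlm = rp.multilevel_sensitivity(df, [])
        fixed = rp.standardise(df, []).table.set_index("hospital_id")["estimate"]
        rho = pd.Series(mlm.shrunken_logodds).corr(fixed, method="spearman")
        assert rho > 0.9
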