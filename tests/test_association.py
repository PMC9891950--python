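"""Modified Poisson and mixed-model association estimates."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from frailtraj import association as A
from frailtraj._errors import DataError

from conftest import CATEGORY_LABELS, ELSA_COUNTS, HRS_COUNTS, expand_counts


def grouped_fit(counts):
    rows = A.grouped_counts_to_rows(counts, labels=CATEGORY_LABELS)
    return A.fit_modified_poisson(rows, weight="weight",
                                  reference=CATEGORY_LABELS[0])


class TestModifiedPoisson:
    def test_two_by_two_rr_is_ratio_of_proportions(self):
        rows = A.grouped_counts_to_rows([(20, 100), (45, 150)], ["ref", "exp"])
        fit = A.fit_modified_poisson(rows, weight="weight", reference="ref")
        assert fit.term("exp")["rr"] == pytest.approx((45 / 150) / (20 / 100),
                                                      rel=1e-9)

    def test_equal_proportions_give_unit_rr_and_closed_form_se(self):
        p = 0.2
        rows = A.grouped_counts_to_rows([(40, 200), (60, 300)], ["ref", "exp"])
        fit = A.fit_modified_poisson(rows, weight="weight", reference="ref")
        assert fit.term("exp")["rr"] == pytest.approx(1.0, rel=1e-10)
        se_expected = np.sqrt((1 - p) / 60 + (1 - p) / 40)
        assert fit.term("exp")["se"] == pytest.approx(se_expected, rel=1e-9)

    def test_saturated_sandwich_matches_binomial_closed_form(self):
        # var(log RR) = (1-p1)/e1 + (1-p0)/e0 for a saturated grouped model
        for counts in (ELSA_COUNTS, HRS_COUNTS):
            fit = grouped_fit(counts)
            e0, t0 = counts[0]
            for j, name in ((1, CATEGORY_LABELS[1]), (2, CATEGORY_LABELS[2])):
                e1, t1 = counts[j]
                se = np.sqrt((1 - e1 / t1) / e1 + (1 - e0 / t0) / e0)
                assert fit.term(name)["se"] == pytest.approx(se, rel=1e-8)

    def test_grouped_and_individual_paths_agree(self):
        for counts in (ELSA_COUNTS, HRS_COUNTS):
            g = grouped_fit(counts)
            ind = A.fit_modified_poisson(expand_counts(counts),
                                         reference=CATEGORY_LABELS[0])
            assert np.allclose(g.coef, ind.coef, atol=1e-10)
            assert np.allclose(g.robust_se, ind.robust_se, atol=1e-10)

    def test_agrees_with_statsmodels_glm_hc0(self):
        # independent route: Poisson GLM with HC0 on the expanded rows
        d = expand_counts(ELSA_COUNTS)
        X = pd.get_dummies(d["exposure"], drop_first=True).astype(float)
        X = sm.add_constant(X)
        glm = sm.GLM(d["outcome"], X, family=sm.families.Poisson()).fit(
            cov_type="HC0")
        ours = A.fit_modified_poisson(d, reference=CATEGORY_LABELS[0])
        assert np.allclose(ours.coef, glm.params.to_numpy(), atol=1e-7)
        assert np.allclose(ours.robust_se, glm.bse.to_numpy(), atol=1e-7)

    def test_zero_reference_events_rejected(self):
        rows = A.grouped_counts_to_rows([(0, 100), (10, 100)], ["ref", "exp"])
        with pytest.raises(DataError, match="reference"):
            A.fit_modified_poisson(rows, weight="weight", reference="ref")

    def test_non_binary_outcome_rejected(self):
        d = pd.DataFrame({"outcome": [0.0, 2.0], "exposure": ["a", "b"]})
        with pytest.raises(DataError):
            A.fit_modified_poisson(d)

    def test_adjustment_covariate_shifts_estimate(self):
        rng = np.random.default_rng(0)
        n = 2000
        conf = rng.normal(size=n)
        x = (rng.random(n) < 1 / (1 + np.exp(-conf))).astype(float)
        y = (rng.random(n) < 0.1 * np.exp(0.8 * conf)).astype(float)
        d = pd.DataFrame({"outcome": y, "exposure": x, "conf": conf})
        crude = A.fit_modified_poisson(d, categorical=False)
        adj = A.fit_modified_poisson(d, categorical=False, covariates=("conf",))
        # adjusting for the common cause attenuates the spurious RR
        assert abs(np.log(adj.term("exposure")["rr"])) < abs(
            np.log(crude.term("exposure")["rr"]))


class TestTrend:
    def test_two_categories_trend_equals_pairwise_rr(self):
        rows = A.grouped_counts_to_rows([(20, 100), (45, 150)], [0, 1])
        pair = A.fit_modified_poisson(rows, weight="weight", reference=0)
        d = rows.copy()
        trend = A.trend_and_increment(d, exposure="exposure", weight="weight")
        assert trend.term("_x")["rr"] == pytest.approx(pair.term("1")["rr"],
                                                       rel=1e-8)

    def test_per_increment_scaling(self):
        rng = np.random.default_rng(1)
        d = pd.DataFrame({
            "outcome": (rng.random(500) < 0.2).astype(float),
            "risk_pct": rng.uniform(0, 30, 500),
        })
        per1 = A.trend_and_increment(d, exposure="risk_pct", scale=1.0)
        per10 = A.trend_and_increment(d, exposure="risk_pct", scale=10.0)
        assert per10.term("_x")["rr"] == pytest.approx(
            per1.term("_x")["rr"] ** 10, rel=1e-6)

    def test_single_level_exposure_rejected(self):
        d = pd.DataFrame({"outcome": [0.0, 1.0], "exposure": [1.0, 1.0]})
        with pytest.raises(DataError):
            A.trend_and_increment(d)


def lmm_frame(slopes, n=90, waves=4, noise_sd=0.0, re_sd=(0.0, 0.0), seed=0):
    rng = np.random.default_rng(seed)
    cats = list(slopes)
    rows = []
    for i in range(n):
        cat = cats[i % len(cats)]
        b0 = 30.0 + (i % 7) + rng.normal(0, re_sd[0])
        b1 = slopes[cat] + rng.normal(0, re_sd[1])
        for w in range(waves):
            t = 2.0 * w
            rows.append({
                "participant_id": i, "wave_index": w,
                "years_since_baseline": t, "exposure": cat,
                "y": b0 + b1 * t + rng.normal(0, noise_sd),
            })
    return pd.DataFrame(rows)


class TestLmm:
    def test_noise_free_contrasts_exact(self):
        d = lmm_frame({"a": 0.0, "b": -0.2, "c": -0.4})
        fit = A.fit_lmm_slopes(d, outcome="y", exposure="exposure",
                               reference="a")
        assert fit.slope_contrast("b:time")["beta"] == pytest.approx(-0.2, abs=1e-6)
        assert fit.slope_contrast("c:time")["beta"] == pytest.approx(-0.4, abs=1e-6)

    def test_balanced_contrast_equals_ols_interaction(self):
        d = lmm_frame({"a": 0.0, "b": -0.3}, n=120, noise_sd=1.0,
                      re_sd=(3.0, 0.1), seed=2)
        fit = A.fit_lmm_slopes(d, outcome="y", exposure="exposure",
                               reference="a", toeplitz=False)
        X = np.column_stack([
            np.ones(len(d)), (d["exposure"] == "b").astype(float),
            d["years_since_baseline"],
            (d["exposure"] == "b").astype(float) * d["years_since_baseline"],
        ])
        ols = np.linalg.lstsq(X, d["y"].to_numpy(), rcond=None)[0]
        # balanced design: GLS point estimate coincides with OLS
        assert fit.slope_contrast("b:time")["beta"] == pytest.approx(ols[3], abs=1e-4)

    def test_parameter_recovery_over_seeds(self):
        target = -0.3
        ests = []
        for seed in range(12):
            d = lmm_frame({"a": 0.0, "b": target}, n=160, noise_sd=1.2,
                          re_sd=(4.0, 0.12), seed=seed)
            fit = A.fit_lmm_slopes(d, outcome="y", exposure="exposure",
                                   reference="a", toeplitz=False)
            ests.append(fit.slope_contrast("b:time")["beta"])
        mc_se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert np.mean(ests) == pytest.approx(target, abs=4 * mc_se + 1e-3)

    def test_null_type_i_error_near_nominal(self):
        # identical generation across categories: Wald test rejects ~5%
        rejections = 0
        n_sims = 120
        for seed in range(n_sims):
            d = lmm_frame({"a": 0.0, "b": 0.0}, n=80, waves=4, noise_sd=1.0,
                          re_sd=(2.0, 0.1), seed=1000 + seed)
            fit = A.fit_lmm_slopes(d, outcome="y", exposure="exposure",
                                   reference="a", toeplitz=False)
            if fit.slope_contrast("b:time")["p"] < 0.05:
                rejections += 1
        rate = rejections / n_sims
        assert 0.005 <= rate <= 0.12

    def test_toeplitz_recovers_lag_correlation_sign(self):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(250):
            b0 = rng.normal(0, 2)
            e = rng.normal(0, 1, 5)
            # moving-average residuals induce positive lag-1 correlation
            resid = e[1:] + 0.9 * e[:-1]
            for w in range(4):
                rows.append({"participant_id": i, "wave_index": w,
                             "years_since_baseline": 2.0 * w, "exposure": "a" if i % 2 else "b",
                             "y": b0 + resid[w]})
        fit = A.fit_lmm_slopes(pd.DataFrame(rows), outcome="y",
                               exposure="exposure", reference="a")
        assert fit.toeplitz_rho[1] > 0.1
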