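"""Discrimination, reclassification, calibration and net-benefit metrics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from frailtraj import evaluation as E
from frailtraj._errors import DataError


def brute_force_auc(scores, y):
    """Exhaustive pair counting: concordant pairs + half ties."""
    scores = np.asarray(scores, float)
    y = np.asarray(y, float)
    num = den = 0.0
    for i in np.where(y == 1)[0]:
        for j in np.where(y == 0)[0]:
            den += 1
            if scores[i] > scores[j]:
                num += 1
            elif scores[i] == scores[j]:
                num += 0.5
    return num / den


class TestAuc:
    def test_perfect_separation(self):
        assert E.auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1])["auc"] == 1.0

    def test_all_tied_scores_give_half(self):
        assert E.auc([5, 5, 5, 5], [0, 1, 0, 1])["auc"] == 0.5

    def test_small_vector_with_tie_matches_pair_counting(self):
        scores = [1, 2, 2, 3, 4, 4]
        y = [0, 0, 1, 0, 1, 1]
        assert E.auc(scores, y)["auc"] == pytest.approx(
            brute_force_auc(scores, y), abs=1e-12)

    def test_exhaustive_small_vectors_with_ties(self):
        # every score vector of length 4 over a 3-letter alphabet, every
        # two-class outcome assignment
        for scores in itertools.product((0.0, 0.5, 1.0), repeat=4):
            for ybits in range(1, 15):  # both classes present
                y = [(ybits >> k) & 1 for k in range(4)]
                assert E.auc(list(scores), y)["auc"] == pytest.approx(
                    brute_force_auc(scores, y), abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.integers(2, 8), st.data())
    def test_midrank_equals_pair_counting_up_to_n8(self, n, data):
        scores = data.draw(st.lists(st.sampled_from([0.0, 0.25, 0.5, 1.0]),
                                    min_size=n, max_size=n))
        y = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
        if sum(y) in (0, n):
            return
        assert E.auc(scores, y)["auc"] == pytest.approx(
            brute_force_auc(scores, y), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=60)
        y = (rng.random(60) < 0.4).astype(int)
        a1 = E.auc(s, y)["auc"]
        a2 = E.auc(np.exp(2 * s) + 5, y)["auc"]
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_unit_weights_match_unweighted(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=80)
        y = (rng.random(80) < 0.3).astype(int)
        assert E.weighted_auc(s, y, np.ones(80))["auc"] == pytest.approx(
            E.auc(s, y)["auc"], abs=1e-12)

    def test_weighted_auc_equals_pair_weight_products(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=25)
        y = (rng.random(25) < 0.4).astype(int)
        if y.sum() in (0, 25):
            y[0], y[1] = 0, 1
        w = rng.uniform(0.5, 3.0, 25)
        num = den = 0.0
        for i in np.where(y == 1)[0]:
            for j in np.where(y == 0)[0]:
                den += w[i] * w[j]
                if s[i] > s[j]:
                    num += w[i] * w[j]
                elif s[i] == s[j]:
                    num += 0.5 * w[i] * w[j]
        assert E.weighted_auc(s, y, w)["auc"] == pytest.approx(num / den,
                                                               abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(DataError):
            E.auc([1, 2, 3], [1, 1, 1])


class TestDeLong:
    def test_self_comparison_null(self):
        rng = np.random.default_rng(3)
        s = rng.normal(size=50)
        y = (rng.random(50) < 0.5).astype(int)
        res = E.delong_compare(s, s, y)
        assert res["difference"] == 0.0
        assert res["p"] == 1.0

    def test_monotone_transform_gives_zero_difference(self):
        rng = np.random.default_rng(4)
        s = rng.normal(size=40)
        y = (rng.random(40) < 0.4).astype(int)
        res = E.delong_compare(s, np.tanh(s) * 3 + 1, y)
        assert res["difference"] == pytest.approx(0.0, abs=1e-12)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(DataError):
            E.delong_compare([1, 2], [1, 2, 3], [0, 1])

    def test_z_agrees_with_bootstrap_of_auc_difference(self):
        # small-sample oracle: the paired bootstrap SD of the AUC
        # difference should be close to the DeLong variance estimate
        rng = np.random.default_rng(6)
        n = 30
        y = np.array([1] * 12 + [0] * 18)
        a = rng.normal(y * 1.0, 1.0)
        b = rng.normal(y * 0.6, 1.0)
        res = E.delong_compare(a, b, y)
        boots = []
        for _ in range(4000):
            idx = rng.integers(0, n, n)
            if y[idx].min() == y[idx].max():
                continue
            boots.append(E.auc(a[idx], y[idx])["auc"]
                         - E.auc(b[idx], y[idx])["auc"])
        se_boot = np.std(boots, ddof=1)
        se_delong = abs(res["difference"] / res["z"])
        assert se_delong == pytest.approx(se_boot, rel=0.25)


class TestReclassification:
    def test_identical_risks_null(self):
        r = np.array([0.1, 0.4, 0.7, 0.2])
        y = [0, 1, 1, 0]
        out = E.reclassification_metrics(r, r.copy(), y)
        assert out["nri"] == 0.0 and out["idi"] == 0.0

    def test_maximum_continuous_nri(self):
        risk_a = np.array([0.3, 0.3, 0.3, 0.3])
        risk_b = np.array([0.5, 0.5, 0.1, 0.1])  # events up, non-events down
        out = E.reclassification_metrics(risk_a, risk_b, [1, 1, 0, 0])
        assert out["nri"] == pytest.approx(2.0)

    def test_eight_subject_hand_worked_table(self):
        risk_a = np.array([0.10, 0.20, 0.30, 0.40, 0.15, 0.25, 0.35, 0.45])
        risk_b = np.array([0.20, 0.15, 0.50, 0.40, 0.10, 0.30, 0.25, 0.40])
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        out = E.reclassification_metrics(risk_a, risk_b, y)
        # events: up, down, up, same -> P(up|ev)=1/2, P(down|ev)=1/4
        # non-events: down, up, down, down -> P(down|ne)=3/4, P(up|ne)=1/4
        assert out["nri"] == pytest.approx((0.5 - 0.25) + (0.75 - 0.25))
        slope_a = risk_a[y == 1].mean() - risk_a[y == 0].mean()
        slope_b = risk_b[y == 1].mean() - risk_b[y == 0].mean()
        assert out["idi"] == pytest.approx(slope_b - slope_a, abs=1e-15)

    def test_idi_identity_holds_on_random_data(self):
        rng = np.random.default_rng(7)
        ra, rb = rng.random(500), rng.random(500)
        y = (rng.random(500) < 0.3).astype(int)
        out = E.reclassification_metrics(ra, rb, y)
        assert out["idi"] == pytest.approx(
            out["discrimination_slope_b"] - out["discrimination_slope_a"],
            abs=1e-12)

    def test_no_events_rejected(self):
        with pytest.raises(DataError):
            E.reclassification_metrics([0.1], [0.2], [0])


class TestCalibration:
    def test_perfect_risks_give_zero_brier(self):
        y = np.array([0, 1, 1, 0, 1])
        out = E.calibration_brier(y.astype(float), y)
        assert out["brier"] == 0.0

    def test_constant_half_risk_gives_quarter_brier(self):
        y = np.array([0, 1] * 20)
        out = E.calibration_brier(np.full(40, 0.5), y)
        assert out["brier"] == pytest.approx(0.25)

    def test_bins_calibrated_on_logistic_data(self):
        rng = np.random.default_rng(8)
        p = 1 / (1 + np.exp(-rng.normal(0, 1.5, 5000)))
        y = (rng.random(5000) < p).astype(int)
        out = E.calibration_brier(p, y, n_bins=10)
        tab = out["calibration"]
        assert tab["n"].sum() == 5000
        for _, row in tab.iterrows():
            if row["n"] < 50:
                continue
            se = np.sqrt(row["mean_predicted"] * (1 - row["mean_predicted"])
                         / row["n"])
            assert abs(row["observed_rate"] - row["mean_predicted"]) < 4 * se + 0.02

    def test_out_of_range_risks_rejected(self):
        with pytest.raises(DataError):
            E.calibration_brier([1.2], [1])


class TestDecisionCurve:
    def test_treat_none_is_zero_and_classify_none_scores_zero(self):
        y = np.array([0, 1, 0, 1, 1])
        tab = E.decision_curve(np.zeros(5), y, thresholds=[0.1, 0.3, 0.5])
        assert (tab["treat_none"] == 0.0).all()
        assert (tab["net_benefit"] == 0.0).all()  # nobody crosses a threshold > 0

    def test_treat_all_closed_form(self):
        rng = np.random.default_rng(9)
        y = (rng.random(200) < 0.3).astype(int)
        prev = y.mean()
        tab = E.decision_curve(rng.random(200), y, thresholds=[0.05, 0.2, 0.4])
        for _, row in tab.iterrows():
            t = row["threshold"]
            assert row["treat_all"] == pytest.approx(
                prev - (1 - prev) * t / (1 - t), abs=1e-12)

    def test_perfect_scores_reach_prevalence(self):
        y = np.array([0] * 70 + [1] * 30)
        risks = y * 0.9 + 0.05
        tab = E.decision_curve(risks, y, thresholds=[0.1, 0.3, 0.5, 0.8])
        assert np.allclose(tab["net_benefit"], 0.3)

    def test_ten_subject_hand_computation_at_t02(self):
        risks = np.array([0.05, 0.15, 0.25, 0.30, 0.10, 0.22, 0.18, 0.40,
                          0.08, 0.21])
        y = np.array([0, 0, 1, 1, 0, 0, 0, 1, 0, 1])
        tab = E.decision_curve(risks, y, thresholds=[0.2])
        # treated: risks >= 0.2 -> indices 2,3,5,7,9: TP=4, FP=1
        nb = 4 / 10 - (1 / 10) * (0.2 / 0.8)
        assert tab["net_benefit"].iloc[0] == pytest.approx(nb, abs=1e-12)

    def test_threshold_bounds_enforced(self):
        with pytest.raises(DataError):
            E.decision_curve([0.5], [0, 1], thresholds=[1.0])


class TestEvaluateMarkers:
    def test_full_report_structure(self):
        rng = np.random.default_rng(10)
        n = 400
        y = (rng.random(n) < 0.25).astype(int)
        s_old = rng.normal(y * 0.8, 1)
        s_new = rng.normal(y * 1.3, 1)
        rep = E.evaluate_markers(s_old, s_new, y)
        assert 0 <= rep.auc_a["auc"] <= 1
        assert rep.auc_b["auc"] > rep.auc_a["auc"]
        assert rep.delong["difference"] == pytest.approx(
            rep.auc_b["auc"] - rep.auc_a["auc"], abs=1e-12)
        assert rep.calibration_a["n"].sum() == n
        d = rep.to_dict()
        assert set(d) >= {"auc_a", "auc_b", "delong", "reclassification",
                          "brier_a", "brier_b", "decision_curve"}
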