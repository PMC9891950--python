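"""Predictive-utility battery: discrimination, reclassification,
calibration and net benefit.

Implements the metrics conventionally used to compare two risk markers
for a binary outcome:

* AUC by the midrank (tie-aware) Mann-Whitney estimator, with a DeLong
  structural-components CI; an inverse-probability-weighted variant uses
  weight products over case/control pairs;
* the paired DeLong test for the difference of two AUCs on the same
  individuals (for weighted data, where DeLong theory is undefined, a
  stratified-bootstrap p-value is reported instead and labelled as such);
* continuous net reclassification improvement (any risk movement counts),
  integrated discrimination improvement, and per-marker discrimination
  slope (IDI == difference of discrimination slopes, asserted);
* calibration deciles of predicted risk with observed event rates, and
  the Brier score;
* decision-curve analysis: net benefit NB(t) = TP/n - FP/n * t/(1-t)
  against treat-all and treat-none strategies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from ._errors import DataError

__all__ = [
    "auc", "delong_compare", "weighted_auc", "reclassification_metrics",
    "calibration_brier", "decision_curve", "evaluate_markers", "EvalReport",
]


def _check_binary(outcomes) -> np.ndarray:
    y = np.asarray(outcomes, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise DataError("outcomes must be binary 0/1")
    if y.min() == y.max():
        raise DataError("both outcome classes must be present")
    return y


def _midrank_auc(scores, y) -> float:
    r = rankdata(scores)  # midranks handle ties (+1/2 per tied pair)
    n1 = int(y.sum())
    n0 = len(y) - n1
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _delong_components(scores, y):
    """Per-subject structural components V10 (cases), V01 (controls)."""
    x = np.asarray(scores, dtype=float)
    cases = x[y == 1]
    controls = x[y == 0]
    m, n = len(cases), len(controls)
    all_r = rankdata(np.concatenate([cases, controls]))
    r_cases = rankdata(cases)
    r_controls = rankdata(controls)
    a = _midrank_auc(x, y)
    v10 = (all_r[:m] - r_cases) / n
    v01 = 1.0 - (all_r[m:] - r_controls) / m
    return a, v10, v01


def auc(scores, outcomes, weights=None, alpha: float = 0.05):
    """AUC with a CI.

    Unweighted: midrank Mann-Whitney estimate, DeLong variance.
    Weighted: weight-product pair estimator; CI by normal approximation
    on weighted structural components (approximate).
    """
    y = _check_binary(outcomes)
    if weights is None:
        a, v10, v01 = _delong_components(scores, y)
        var = v10.var(ddof=1) / len(v10) + v01.var(ddof=1) / len(v01)
        z = norm.ppf(1 - alpha / 2)
        half = z * np.sqrt(max(var, 0.0))
        return {"auc": a, "ci_low": max(a - half, 0.0),
                "ci_high": min(a + half, 1.0), "se": float(np.sqrt(max(var, 0.0)))}
    return weighted_auc(scores, outcomes, weights, alpha)


def weighted_auc(scores, outcomes, weights, alpha: float = 0.05):
    """IPW AUC: sum of weight products over concordant pairs (+half ties)
    divided by the total case-control weight product."""
    y = _check_binary(outcomes)
    w = np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise DataError("weights must be positive")
    x = np.asarray(scores, dtype=float)
    cases, controls = x[y == 1], x[y == 0]
    wc, wn = w[y == 1], w[y == 0]

    # sort controls; cumulative weights give sum over s_control < s_case
    order = np.argsort(controls, kind="mergesort")
    sc, swn = controls[order], wn[order]
    cum = np.concatenate([[0.0], np.cumsum(swn)])
    lo = np.searchsorted(sc, cases, side="left")
    hi = np.searchsorted(sc, cases, side="right")
    below = cum[lo]
    tied = cum[hi] - cum[lo]
    num = float((wc * (below + 0.5 * tied)).sum())
    den = float(wc.sum() * wn.sum())
    a = num / den

    # per-case / per-control weighted placement values for an approximate CI
    v10 = (below + 0.5 * tied) / wn.sum()
    order_c = np.argsort(cases, kind="mergesort")
    sca, swc = cases[order_c], wc[order_c]
    cumc = np.concatenate([[0.0], np.cumsum(swc)])
    lo0 = np.searchsorted(sca, controls, side="left")
    hi0 = np.searchsorted(sca, controls, side="right")
    above = cumc[-1] - cumc[hi0]
    tied0 = cumc[hi0] - cumc[lo0]
    v01 = (above + 0.5 * tied0) / wc.sum()

    def wvar(v, wt):
        mu = np.average(v, weights=wt)
        return np.average((v - mu) ** 2, weights=wt) / max(len(v) - 1, 1)

    var = wvar(v10, wc) + wvar(v01, wn)
    z = norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(max(var, 0.0))
    return {"auc": a, "ci_low": max(a - half, 0.0), "ci_high": min(a + half, 1.0),
            "se": float(np.sqrt(max(var, 0.0)))}


def delong_compare(scores_a, scores_b, outcomes):
    """Paired DeLong test for AUC_a - AUC_b on the same individuals."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if len(scores_a) != len(scores_b):
        raise DataError("paired markers must score the same individuals")
    y = _check_binary(outcomes)
    a1, v10_1, v01_1 = _delong_components(scores_a, y)
    a2, v10_2, v01_2 = _delong_components(scores_b, y)
    m, n = len(v10_1), len(v01_1)
    s10 = np.cov(np.vstack([v10_1, v10_2]), ddof=1)
    s01 = np.cov(np.vstack([v01_1, v01_2]), ddof=1)
    cov = s10 / m + s01 / n
    d = a1 - a2
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var <= 0:
        z = 0.0
        p = 1.0
    else:
        z = d / np.sqrt(var)
        p = float(2 * norm.sf(abs(z)))
    return {"auc_a": a1, "auc_b": a2, "difference": d, "z": float(z), "p": p}


def bootstrap_delta_auc_p(scores_a, scores_b, outcomes, weights,
                          n_boot: int = 1000, seed: int = 0):
    """Stratified-bootstrap two-sided p for the weighted AUC difference.

    Used for IPW-weighted comparisons, where the DeLong covariance theory
    is not defined; clearly labelled as a bootstrap p in reports.
    """
    y = _check_binary(outcomes)
    rng = np.random.default_rng(seed)
    idx1 = np.where(y == 1)[0]
    idx0 = np.where(y == 0)[0]
    obs = (weighted_auc(scores_a, y, weights)["auc"]
           - weighted_auc(scores_b, y, weights)["auc"])
    deltas = np.empty(n_boot)
    sa, sb = np.asarray(scores_a, float), np.asarray(scores_b, float)
    w = np.asarray(weights, float)
    for b in range(n_boot):
        s1 = rng.choice(idx1, len(idx1), replace=True)
        s0 = rng.choice(idx0, len(idx0), replace=True)
        sel = np.concatenate([s1, s0])
        ysel = np.concatenate([np.ones(len(s1)), np.zeros(len(s0))])
        deltas[b] = (weighted_auc(sa[sel], ysel, w[sel])["auc"]
                     - weighted_auc(sb[sel], ysel, w[sel])["auc"])
    se = deltas.std(ddof=1)
    if se == 0:
        return {"difference": obs, "p": 1.0, "method": "stratified bootstrap"}
    z = obs / se
    return {"difference": obs, "p": float(2 * norm.sf(abs(z))),
            "method": "stratified bootstrap"}


def reclassification_metrics(risk_a, risk_b, outcomes):
    """Continuous NRI, IDI and per-marker discrimination slopes for the
    move from marker a (old) to marker b (new).

    Risks are on [0, 1].  NRI counts any risk movement; IDI equals the
    difference of discrimination slopes (asserted to 1e-12).
    """
    ra = np.asarray(risk_a, dtype=float)
    rb = np.asarray(risk_b, dtype=float)
    if ((ra < 0) | (ra > 1) | (rb < 0) | (rb > 1)).any():
        raise DataError("risks must lie in [0,1]")
    y = _check_binary(outcomes)
    ev, ne = y == 1, y == 0

    up, down = rb > ra, rb < ra
    nri_events = float(up[ev].mean() - down[ev].mean())
    nri_nonevents = float(down[ne].mean() - up[ne].mean())
    nri = nri_events + nri_nonevents

    slope_a = float(ra[ev].mean() - ra[ne].mean())
    slope_b = float(rb[ev].mean() - rb[ne].mean())
    idi = float((rb[ev].mean() - ra[ev].mean()) - (rb[ne].mean() - ra[ne].mean()))
    assert abs(idi - (slope_b - slope_a)) < 1e-12, "IDI identity violated"

    return {
        "nri": nri, "nri_events": nri_events, "nri_nonevents": nri_nonevents,
        "idi": idi, "discrimination_slope_a": slope_a,
        "discrimination_slope_b": slope_b,
    }


def calibration_brier(risks, outcomes, n_bins: int = 10):
    """Decile calibration table plus Brier score.

    Bins are deciles of predicted risk; an empty bin is merged with its
    neighbour and flagged in the table.
    """
    r = np.asarray(risks, dtype=float)
    if ((r < 0) | (r > 1)).any():
        raise DataError("risks must lie in [0,1]")
    y = np.asarray(outcomes, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise DataError("outcomes must be binary 0/1")
    brier = float(np.mean((r - y) ** 2))

    qs = np.quantile(r, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(qs)
    merged = len(edges) - 1 < n_bins
    if len(edges) < 2:
        edges = np.array([edges[0] - 1e-12, edges[0] + 1e-12])
    bin_idx = np.clip(np.searchsorted(edges, r, side="right") - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        m = bin_idx == b
        rows.append({
            "bin": b, "n": int(m.sum()),
            "mean_predicted": float(r[m].mean()) if m.any() else np.nan,
            "observed_rate": float(y[m].mean()) if m.any() else np.nan,
            "merged_bins": merged,
        })
    table = pd.DataFrame(rows)
    return {"brier": brier, "calibration": table}


def decision_curve(risks, outcomes, thresholds=None):
    """Net-benefit table over a threshold grid, with treat-all and
    treat-none reference strategies."""
    r = np.asarray(risks, dtype=float)
    y = _check_binary(outcomes)
    if thresholds is None:
        thresholds = np.arange(0.01, 0.60, 0.01)
    thresholds = np.asarray(thresholds, dtype=float)
    if (thresholds >= 1).any() or (thresholds <= 0).any():
        raise DataError("thresholds must lie strictly inside (0,1)")
    n = len(y)
    prev = y.mean()
    rows = []
    for t in thresholds:
        treat = r >= t
        tp = float((treat & (y == 1)).sum()) / n
        fp = float((treat & (y == 0)).sum()) / n
        odds = t / (1 - t)
        rows.append({
            "threshold": t,
            "net_benefit": tp - fp * odds,
            "treat_all": prev - (1 - prev) * odds,
            "treat_none": 0.0,
        })
    return pd.DataFrame(rows)


@dataclass
class EvalReport:
    """Full comparison of two risk markers for one binary outcome."""

    auc_a: dict
    auc_b: dict
    delong: dict
    reclassification: dict
    brier_a: float
    brier_b: float
    calibration_a: pd.DataFrame
    calibration_b: pd.DataFrame
    decision_curve: pd.DataFrame
    n: int = 0
    weighted: bool = False

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "weighted": self.weighted,
            "auc_a": self.auc_a,
            "auc_b": self.auc_b,
            "delong": self.delong,
            "reclassification": self.reclassification,
            "brier_a": self.brier_a,
            "brier_b": self.brier_b,
            "calibration_a": self.calibration_a.to_dict(orient="records"),
            "calibration_b": self.calibration_b.to_dict(orient="records"),
            "decision_curve": self.decision_curve.to_dict(orient="records"),
        }


def evaluate_markers(
    score_a, score_b, outcomes, weights=None, n_bins: int = 10,
    thresholds=None, bootstrap_seed: int = 0,
) -> EvalReport:
    """Run the full battery comparing marker a (old) vs marker b (new).

    Scores are risk percentages or any monotone risk scores; for
    reclassification/calibration/decision curves they are rescaled to
    [0, 1] by treating them as percentages when any value exceeds 1.
    """
    sa = np.asarray(score_a, dtype=float)
    sb = np.asarray(score_b, dtype=float)
    y = _check_binary(outcomes)
    ra = sa / 100.0 if np.nanmax(sa) > 1.0 else sa
    rb = sb / 100.0 if np.nanmax(sb) > 1.0 else sb
    ra = np.clip(ra, 0.0, 1.0)
    rb = np.clip(rb, 0.0, 1.0)

    if weights is None:
        a_a = auc(sa, y)
        a_b = auc(sb, y)
        dl = delong_compare(sb, sa, y)  # difference is new - old
    else:
        a_a = weighted_auc(sa, y, weights)
        a_b = weighted_auc(sb, y, weights)
        dl = bootstrap_delta_auc_p(sb, sa, y, weights, seed=bootstrap_seed)

    recl = reclassification_metrics(ra, rb, y)
    cal_a = calibration_brier(ra, y, n_bins)
    cal_b = calibration_brier(rb, y, n_bins)
    dca = decision_curve(rb, y, thresholds)
    return EvalReport(
        auc_a=a_a, auc_b=a_b, delong=dl, reclassification=recl,
        brier_a=cal_a["brier"], brier_b=cal_b["brier"],
        calibration_a=cal_a["calibration"], calibration_b=cal_b["calibration"],
        decision_curve=dca, n=len(y), weighted=weights is not None,
    )
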