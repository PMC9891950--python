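"""Inverse-probability-of-inclusion weights and covariate balance.

Study exclusions (baseline disease, baseline frailty, incomplete risk
data, loss to follow-up) can make the analysed sample unrepresentative.
The standard correction reweights each included participant by the
inverse of their estimated probability of inclusion, from a binary
logistic model on baseline covariates.  Balance between included and
excluded participants is summarised by absolute standardized mean
differences (SMDs) before and after weighting — the numbers behind a
Love plot.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._errors import ConfigurationError, DataError

__all__ = ["ipw_weights", "balance_smd"]


def ipw_weights(
    data: pd.DataFrame,
    inclusion: str = "included",
    covariates: tuple = ("age", "sex_male", "sbp", "tc"),
    truncate_percentile: float | None = 99.0,
) -> pd.DataFrame:
    """Inclusion-probability weights for the included rows.

    Fits logistic regression of the inclusion flag on ``covariates`` over
    all rows, then returns a frame (index = included rows' index) with
    the fitted probability and weight 1/p, truncated at the given weight
    percentile (None disables truncation).
    """
    y = data[inclusion].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise DataError("inclusion flag must be binary 0/1")
    if y.min() == y.max():
        # everyone included: weights are identically 1/mean(included) = 1
        p = np.full(len(data), y.mean() if y.mean() > 0 else 1.0)
        fitted = p
    else:
        if len(covariates) == 0:
            X = np.ones((len(data), 1))  # intercept-only: p = inclusion rate
        else:
            X = sm.add_constant(data[list(covariates)].to_numpy(dtype=float))
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception as err:  # statsmodels raises on perfect separation
            raise ConfigurationError(
                f"inclusion model failed ({err}); consider reducing the "
                "covariate set"
            ) from err
        if not np.isfinite(res.params).all() or np.abs(res.params).max() > 25:
            raise ConfigurationError(
                "perfect separation in the inclusion model; reduce covariates"
            )
        fitted = res.predict(X)
    out = data.loc[y == 1].copy()
    p_inc = fitted[y == 1]
    w = 1.0 / np.clip(p_inc, 1e-10, 1.0)
    cap = None
    if truncate_percentile is not None:
        cap = float(np.percentile(w, truncate_percentile))
        w = np.minimum(w, cap)
    out["inclusion_probability"] = p_inc
    out["ipw"] = w
    out.attrs["weight_cap"] = cap
    return out


def _smd_continuous(x1, x0, w1=None, w0=None, pooled_sd=None):
    m1 = np.average(x1, weights=w1)
    m0 = np.average(x0, weights=w0)
    if pooled_sd is None:
        v1 = np.var(x1, ddof=1) if len(x1) > 1 else 0.0
        v0 = np.var(x0, ddof=1) if len(x0) > 1 else 0.0
        pooled_sd = np.sqrt((v1 + v0) / 2)
    if pooled_sd == 0:
        return np.nan, m1, m0, pooled_sd
    return abs(m1 - m0) / pooled_sd, m1, m0, pooled_sd


def balance_smd(
    data: pd.DataFrame,
    inclusion: str = "included",
    covariates: tuple = ("age", "sex_male", "sbp", "tc"),
    weights: str | pd.Series | None = None,
    binary_covariates: tuple = (),
) -> pd.DataFrame:
    """Absolute SMD per covariate between included and excluded rows.

    Continuous: |mean1 - mean0| / pooled SD; binary: |p1 - p0| /
    sqrt[(p1(1-p1) + p0(1-p0))/2].  When ``weights`` is given, a weighted
    SMD column is added using weighted means over the included group with
    the *same* pooled-SD denominator as the unweighted SMD (so weighted
    and unweighted values are on one scale, as in a Love plot).
    """
    if len(covariates) == 0:
        raise ConfigurationError("at least one covariate is required")
    inc = data[inclusion].to_numpy(dtype=float) == 1.0
    w_inc = None
    if weights is not None:
        w_series = data[weights] if isinstance(weights, str) else weights
        w_inc = np.asarray(w_series, dtype=float)
        if len(w_inc) == len(data):
            w_inc = w_inc[inc]
        if (w_inc <= 0).any() or len(w_inc) != int(inc.sum()):
            raise DataError("weights must be positive, one per included row")

    rows = []
    for cov in covariates:
        x = data[cov].to_numpy(dtype=float)
        x1, x0 = x[inc], x[~inc]
        is_binary = cov in binary_covariates or set(np.unique(x[~np.isnan(x)])) <= {0.0, 1.0}
        if is_binary:
            p1, p0 = x1.mean(), x0.mean()
            denom = np.sqrt((p1 * (1 - p1) + p0 * (1 - p0)) / 2)
            smd = abs(p1 - p0) / denom if denom > 0 else np.nan
            m1, m0, sd = p1, p0, denom
        else:
            smd, m1, m0, sd = _smd_continuous(x1, x0)
        row = {"covariate": cov, "mean_included": m1, "mean_excluded": m0,
               "smd_unweighted": smd}
        if w_inc is not None:
            m1w = np.average(x1, weights=w_inc)
            row["smd_weighted"] = abs(m1w - m0) / sd if (sd and sd > 0) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
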