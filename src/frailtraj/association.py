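"""Association models: modified Poisson risk ratios and mixed-model slopes.

Modified Poisson regression fits a Poisson log-link model to a *binary*
outcome and replaces the model-based variance with the robust (HC0
sandwich) estimator, yielding risk ratios with valid standard errors.
Grouped data (events/total per stratum) and individual rows give
identical results: the grouped path expands strata with frequency
weights and codes the sandwich explicitly,

    cov = B M B,  B = (X' W X)^{-1},  M = sum_i w_i s_i s_i',
    s_i = (y_i - mu_i) x_i ,

which coincides with HC0 on the expanded individual-level design.

The longitudinal physical-function models are linear mixed models with a
random intercept and random time slope per participant and, optionally,
Toeplitz-structured residual correlation across waves (correlation
depending only on the lag between wave indices).  The marginal
formulation

    y_i ~ N( X_i beta ,  Z_i G Z_i' + sigma^2 R_i(rho) )

is fitted by direct maximum likelihood: the fixed effects are profiled
out by GLS at each variance-parameter value and the profile likelihood
is maximised with scipy.  Inference is large-sample Wald (no small-sample
degrees-of-freedom correction; with thousands of participants its effect
is negligible, and output flags the convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

from ._errors import ConfigurationError, ConvergenceError, DataError

__all__ = [
    "ModPoissonFit", "LmmFit",
    "fit_modified_poisson", "grouped_counts_to_rows",
    "trend_and_increment", "fit_lmm_slopes",
]

_Z95 = 1.959963984540054


# ======================================================================
# modified Poisson

@dataclass
class ModPoissonFit:
    """Risk-ratio fit: term names, log-RR estimates, robust SEs, Wald CIs."""

    terms: list
    coef: np.ndarray       # log-RR scale, includes intercept first
    robust_se: np.ndarray
    n: int
    events: int

    @property
    def rr(self) -> np.ndarray:
        return np.exp(self.coef)

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        z = norm.ppf(1 - alpha / 2)
        lo = np.exp(self.coef - z * self.robust_se)
        hi = np.exp(self.coef + z * self.robust_se)
        return np.column_stack([lo, hi])

    @property
    def pvalues(self) -> np.ndarray:
        z = self.coef / self.robust_se
        return 2 * norm.sf(np.abs(z))

    def summary_frame(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame({
            "term": self.terms,
            "log_rr": self.coef,
            "robust_se": self.robust_se,
            "rr": self.rr,
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
            "p": self.pvalues,
        })

    def term(self, name: str) -> dict:
        i = self.terms.index(name)
        ci = self.conf_int()
        return {"rr": float(self.rr[i]), "ci_low": float(ci[i, 0]),
                "ci_high": float(ci[i, 1]), "se": float(self.robust_se[i]),
                "p": float(self.pvalues[i])}


def grouped_counts_to_rows(counts: Sequence[tuple], labels: Sequence[str] | None = None
                           ) -> pd.DataFrame:
    """Expand (events, total) strata into weighted binary rows.

    ``counts`` is a sequence of (events, total); the first stratum is the
    reference category.  Returns columns outcome, exposure, weight.
    """
    rows = []
    for j, (events, total) in enumerate(counts):
        if events > total:
            raise DataError(f"stratum {j}: events {events} exceed total {total}")
        label = labels[j] if labels else j
        rows.append({"outcome": 1.0, "exposure": label, "weight": float(events)})
        rows.append({"outcome": 0.0, "exposure": label, "weight": float(total - events)})
    return pd.DataFrame(rows)


def _poisson_irls(X, y, w, max_iter=200, tol=1e-10):
    """Weighted Poisson (log link) ML by IRLS; returns beta."""
    n, p = X.shape
    beta = np.zeros(p)
    mean_y = np.average(y, weights=w)
    beta[0] = np.log(max(mean_y, 1e-10))
    for _ in range(max_iter):
        eta = X @ beta
        mu = np.exp(np.clip(eta, -30, 30))
        W = w * mu
        z = eta + (y - mu) / mu
        XtWX = X.T @ (X * W[:, None])
        XtWz = X.T @ (W * z)
        try:
            new = np.linalg.solve(XtWX, XtWz)
        except np.linalg.LinAlgError as err:
            raise ConvergenceError(f"singular IRLS system: {err}") from err
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    else:
        raise ConvergenceError("Poisson IRLS did not converge")
    return beta


def _sandwich(X, y, w, beta):
    mu = np.exp(X @ beta)
    W = w * mu
    bread = np.linalg.inv(X.T @ (X * W[:, None]))
    score = (w * (y - mu))[:, None] * X  # per-row weighted score contributions
    meat = X.T @ ((w * (y - mu) ** 2)[:, None] * X)
    cov = bread @ meat @ bread
    return cov


def fit_modified_poisson(
    data: pd.DataFrame,
    outcome: str = "outcome",
    exposure: str = "exposure",
    covariates: Sequence[str] = (),
    weight: str | None = None,
    reference=None,
    categorical: bool = True,
) -> ModPoissonFit:
    """Poisson log-link ML on a binary outcome with the HC0 sandwich.

    ``data`` holds individual rows or frequency-weighted grouped rows
    (``weight`` column); both give identical estimates and robust SEs.
    With ``categorical=True`` the exposure is dummy-coded against
    ``reference`` (default: the lowest / first level); otherwise it
    enters as a single numeric column.  Additional adjustment covariates
    enter linearly.
    """
    y = data[outcome].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise DataError("modified Poisson requires a binary 0/1 outcome")
    w = (data[weight].to_numpy(dtype=float) if weight is not None
         else np.ones(len(data)))
    if (w < 0).any():
        raise DataError("negative weights")

    cols = [np.ones(len(data))]
    names = ["intercept"]
    if categorical:
        levels = list(pd.unique(data[exposure]))
        if reference is None:
            reference = sorted(levels, key=str)[0] if all(
                isinstance(l, str) for l in levels) else min(levels)
        if reference not in levels:
            raise ConfigurationError(f"reference level {reference!r} not present")
        others = [l for l in levels if l != reference]
        others = sorted(others, key=str)
        ref_events = float(w[(data[exposure] == reference).to_numpy() & (y == 1.0)].sum())
        if ref_events == 0:
            raise DataError("zero events in the reference category: RR undefined")
        for lvl in others:
            cols.append((data[exposure] == lvl).to_numpy(dtype=float))
            names.append(str(lvl))
    else:
        x = data[exposure].to_numpy(dtype=float)
        if np.unique(x).size < 2:
            raise DataError("exposure needs at least 2 distinct levels")
        cols.append(x)
        names.append(exposure)
    for c in covariates:
        cols.append(data[c].to_numpy(dtype=float))
        names.append(c)
    X = np.column_stack(cols)

    keep = w > 0
    beta = _poisson_irls(X[keep], y[keep], w[keep])
    if np.max(np.abs(beta)) > 25:
        raise ConvergenceError("separation suspected: diverging coefficients")
    cov = _sandwich(X[keep], y[keep], w[keep], beta)
    se = np.sqrt(np.diag(cov))
    return ModPoissonFit(
        terms=names, coef=beta, robust_se=se,
        n=int(round(w.sum())), events=int(round(w[y == 1.0].sum())),
    )


def trend_and_increment(
    data: pd.DataFrame,
    outcome: str = "outcome",
    exposure: str = "exposure",
    weight: str | None = None,
    scale: float = 1.0,
    covariates: Sequence[str] = (),
) -> ModPoissonFit:
    """Single-slope modified Poisson: RR per unit of the coded exposure.

    For the linear-trend test, code ordered categories 0/1/2; for a
    per-10% risk increment pass the risk percentage with ``scale=10``.
    """
    d = data.copy()
    d["_x"] = d[exposure].astype(float) / scale
    return fit_modified_poisson(
        d, outcome=outcome, exposure="_x", weight=weight, categorical=False,
        covariates=covariates,
    )


# ======================================================================
# linear mixed models with Toeplitz residual correlation

@dataclass
class LmmFit:
    """Marginal-ML mixed-model fit.

    Fixed effects cover intercept, exposure main effects, time, and
    exposure-by-time interactions; the interaction coefficients are the
    per-year slope contrasts vs the reference category.
    """

    terms: list
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    n_participants: int
    n_obs: int
    random_cov: np.ndarray        # 2x2 G: intercept/slope variances+cov
    sigma2: float                 # residual variance
    toeplitz_rho: np.ndarray      # residual correlation by lag (rho[0]=1)
    converged: bool
    fallback_independent: bool = False
    inference: str = "large-sample Wald (no small-sample df correction)"

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        z = norm.ppf(1 - alpha / 2)
        return np.column_stack([self.coef - z * self.se, self.coef + z * self.se])

    @property
    def pvalues(self) -> np.ndarray:
        return 2 * norm.sf(np.abs(self.coef / self.se))

    def summary_frame(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame({
            "term": self.terms, "estimate": self.coef, "se": self.se,
            "ci_low": ci[:, 0], "ci_high": ci[:, 1], "p": self.pvalues,
        })

    def slope_contrast(self, name: str) -> dict:
        i = self.terms.index(name)
        ci = self.conf_int()
        return {"beta": float(self.coef[i]), "ci_low": float(ci[i, 0]),
                "ci_high": float(ci[i, 1]), "p": float(self.pvalues[i])}


def _toeplitz_corr(lags: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """Correlation matrix from lag correlations rho[1..L] (rho[0] = 1)."""
    L = len(rho) - 1
    out = np.ones((len(lags), len(lags)))
    for a in range(len(lags)):
        for b in range(len(lags)):
            lag = abs(int(lags[a] - lags[b]))
            out[a, b] = 1.0 if lag == 0 else (rho[lag] if lag <= L else 0.0)
    return out


def _lmm_neg_profile_ll(params, patterns, n_lags, use_toeplitz):
    """Profile (over beta) negative log-likelihood of the marginal model.

    ``patterns`` batches participants sharing an observation pattern
    (identical times/waves): each entry is (times, waves, X (m,T,p),
    y (m,T)), so V is factorised once per pattern, not per participant.
    Parameters: Cholesky of G (log-diagonal), log residual SD, Toeplitz
    lag correlations.
    """
    l11 = np.exp(params[0])
    l21 = params[1]
    l22 = np.exp(params[2])
    Lc = np.array([[l11, 0.0], [l21, l22]])
    G = Lc @ Lc.T
    sigma2 = np.exp(2 * params[3])
    # lag correlations mapped through tanh so the optimiser is unconstrained
    rho = (np.concatenate([[1.0], 0.95 * np.tanh(params[4:4 + n_lags])])
           if use_toeplitz else np.array([1.0]))

    XtVX = 0.0
    XtVy = 0.0
    ldet = 0.0
    yVy = 0.0
    n_total = 0
    for times, waves, X, y in patterns:
        m, T, p = X.shape
        Z = np.column_stack([np.ones(T), times])
        R = _toeplitz_corr(waves, rho) if use_toeplitz else np.eye(T)
        V = Z @ G @ Z.T + sigma2 * R
        try:
            c = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return np.inf, None, None
        # whiten all participants of this pattern at once
        sol_X = np.linalg.solve(c, X.transpose(1, 0, 2).reshape(T, m * p))
        sol_X = sol_X.reshape(T, m, p)
        sol_y = np.linalg.solve(c, y.T)  # T x m
        ldet += 2.0 * m * np.log(np.diag(c)).sum()
        XtVX = XtVX + np.einsum("tmp,tmq->pq", sol_X, sol_X)
        XtVy = XtVy + np.einsum("tmp,tm->p", sol_X, sol_y)
        yVy += float((sol_y * sol_y).sum())
        n_total += m * T
    try:
        beta = np.linalg.solve(XtVX, XtVy)
    except np.linalg.LinAlgError:
        return np.inf, None, None
    quad = yVy - XtVy @ beta
    ll = -0.5 * (n_total * np.log(2 * np.pi) + ldet + quad)
    return -ll, beta, XtVX


def fit_lmm_slopes(
    data: pd.DataFrame,
    outcome: str,
    exposure: str = "exposure",
    time: str = "years_since_baseline",
    participant: str = "participant_id",
    categorical: bool = True,
    reference=None,
    toeplitz: bool = True,
    toeplitz_lags: int | None = None,
    wave: str = "wave_index",
) -> LmmFit:
    """Mixed model ``outcome ~ exposure + time + exposure:time`` with a
    random intercept and random time slope per participant and (default)
    Toeplitz residual correlation across waves.

    The exposure-by-time coefficients are the per-year rate-of-change
    contrasts vs the reference category.  When the Toeplitz fit fails to
    produce a positive-definite covariance, the model is refitted with
    independent residuals and flagged (``fallback_independent``).
    """
    d = data[[participant, time, outcome] + ([wave] if wave in data.columns else [])
             + [exposure]].dropna(subset=[outcome, exposure]).copy()
    if len(d) == 0:
        raise DataError("no observed outcome rows")
    if wave not in d.columns:
        spacing = np.diff(np.unique(d[time]))
        step = spacing.min() if len(spacing) else 1.0
        d[wave] = np.rint(d[time] / max(step, 1e-9)).astype(int)

    cols = [np.ones(len(d))]
    names = ["intercept"]
    t = d[time].to_numpy(dtype=float)
    if categorical:
        levels = list(pd.unique(d[exposure]))
        if reference is None:
            reference = sorted(levels, key=str)[0] if all(
                isinstance(l, str) for l in levels) else min(levels)
        others = sorted([l for l in levels if l != reference], key=str)
        for lvl in others:
            ind = (d[exposure] == lvl).to_numpy(dtype=float)
            cols.append(ind)
            names.append(str(lvl))
        cols.append(t)
        names.append("time")
        for lvl in others:
            ind = (d[exposure] == lvl).to_numpy(dtype=float)
            cols.append(ind * t)
            names.append(f"{lvl}:time")
    else:
        x = d[exposure].to_numpy(dtype=float)
        cols.extend([x, t, x * t])
        names.extend([exposure, "time", f"{exposure}:time"])
    Xall = np.column_stack(cols)
    yall = d[outcome].to_numpy(dtype=float)
    waves_all = d[wave].to_numpy()

    pids, inv = np.unique(d[participant].to_numpy(), return_inverse=True)
    by_pattern: dict = {}
    for i in range(len(pids)):
        m = inv == i
        order = np.argsort(waves_all[m])
        key = tuple(np.round(t[m][order], 9)) + tuple(waves_all[m][order])
        by_pattern.setdefault(key, []).append(
            (Xall[m][order], yall[m][order], t[m][order], waves_all[m][order])
        )
    patterns = []
    for members in by_pattern.values():
        X = np.stack([mm[0] for mm in members])
        y = np.stack([mm[1] for mm in members])
        times = members[0][2]
        waves = members[0][3]
        patterns.append((times, waves, X, y))

    n_waves = int(pd.Series(waves_all).nunique())
    if toeplitz_lags is None:
        toeplitz_lags = max(n_waves - 1, 0)
    use_toeplitz = toeplitz and toeplitz_lags >= 1

    sd_y = max(np.std(yall), 1e-6)
    x0 = np.concatenate([
        [np.log(0.5 * sd_y), 0.0, np.log(0.05 * sd_y), np.log(0.5 * sd_y)],
        np.zeros(toeplitz_lags if use_toeplitz else 0),
    ])

    def obj(p):
        return _lmm_neg_profile_ll(p, patterns, toeplitz_lags, use_toeplitz)[0]

    def solve(x_start):
        # Nelder-Mead is robust to the occasional non-PD (inf) evaluation;
        # a quasi-Newton polish sharpens the optimum
        r1 = minimize(obj, x_start, method="Nelder-Mead",
                      options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
        r2 = minimize(obj, r1.x, method="BFGS",
                      options={"maxiter": 200})
        return r2 if np.isfinite(r2.fun) and r2.fun <= r1.fun else r1

    res = solve(x0)
    fallback = False
    if use_toeplitz and not np.isfinite(res.fun):
        warnings.warn("Toeplitz residual fit failed; falling back to "
                      "independent residuals", RuntimeWarning)
        fallback = True
        use_toeplitz = False
        x0 = x0[:4]
        res = solve(x0)

    nll, beta, XtVX = _lmm_neg_profile_ll(res.x, patterns, toeplitz_lags, use_toeplitz)
    if beta is None:
        raise ConvergenceError("mixed model failed to produce a valid fit")
    cov_beta = np.linalg.inv(XtVX)
    se = np.sqrt(np.diag(cov_beta))

    l11 = np.exp(res.x[0]); l21 = res.x[1]; l22 = np.exp(res.x[2])
    Lc = np.array([[l11, 0.0], [l21, l22]])
    G = Lc @ Lc.T
    sigma2 = float(np.exp(2 * res.x[3]))
    rho = (np.concatenate([[1.0], 0.95 * np.tanh(res.x[4:4 + toeplitz_lags])])
           if use_toeplitz else np.array([1.0]))

    return LmmFit(
        terms=names, coef=beta, se=se, loglik=-float(nll),
        n_participants=len(pids), n_obs=len(d),
        random_cov=G, sigma2=sigma2, toeplitz_rho=rho,
        converged=bool(res.success), fallback_independent=fallback,
    )
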