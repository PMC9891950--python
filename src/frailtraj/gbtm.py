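"""Group-based trajectory modelling (GBTM) for bounded longitudinal outcomes.

GBTM assumes the population is a finite mixture of latent groups, each
following its own polynomial mean trajectory over time:

    y_it | group k  ~  CensNormal( poly_k(t_it), sigma ;  bounds )

with a shared (default) or per-group residual SD.  For a frailty index the
outcome lives in [0, 1], so the default outcome distribution is a normal
censored at the bounds: observations at a bound contribute the tail mass
(e.g. Phi((L - mu)/sigma) at the lower bound) rather than a density — the
convention of the classic trajectory-modelling software for bounded
scales.  A plain-normal mode is available for speed.

Estimation maximises the observed-data log-likelihood

    sum_i log sum_k pi_k prod_t f(y_it | beta_k, sigma)

* censored mode: L-BFGS-B on (betas, log sigma, group logits) with
  analytic gradients;
* plain-normal mode: EM with closed-form weighted polynomial regression
  in the M-step (log-likelihood asserted non-decreasing per iteration).

Multiple restarts are initialised from perturbed k-means on
per-participant OLS intercept/slope summaries; the best log-likelihood is
kept.  Model selection across group counts / polynomial orders is by BIC.
Groups are labelled by the fitted mean at the final observation time:
lowest -> "stable", middle -> "moderate", highest -> "accelerated" when
K = 3, generic ordinal labels otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import log_ndtr, logsumexp
from scipy.optimize import minimize
from scipy.stats import norm

from ._errors import ConfigurationError, ConvergenceError

__all__ = ["GbtmSpec", "GbtmFit", "fit_gbtm", "select_model",
           "assign_and_label", "diagnostics"]

_SIGMA_FLOOR = 1e-4
_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass
class GbtmSpec:
    """Estimation settings for a single GBTM fit."""

    k_groups: int = 3
    poly_orders: int | Sequence[int] = 2
    censored: bool = True
    censor_bounds: tuple[float, float] = (0.0, 1.0)
    shared_sigma: bool = True
    max_iter: int = 500
    tol: float = 1e-6
    n_restarts: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.k_groups < 1:
            raise ConfigurationError("k_groups must be >= 1")
        lo, hi = self.censor_bounds
        if not lo < hi:
            raise ConfigurationError("censor lower bound must be below upper")
        orders = self.orders
        if any(d < 0 for d in orders):
            raise ConfigurationError("polynomial degrees must be >= 0")

    @property
    def orders(self) -> list[int]:
        if isinstance(self.poly_orders, int):
            return [self.poly_orders] * self.k_groups
        if len(self.poly_orders) != self.k_groups:
            raise ConfigurationError("need one polynomial order per group")
        return list(self.poly_orders)


@dataclass
class GbtmFit:
    """Fitted mixture: per-group polynomial coefficients (FI vs years),
    membership probabilities, residual SD(s), posterior matrix and
    diagnostics."""

    beta: list  # per-group coefficient arrays, ascending degree
    pi: np.ndarray
    sigma: np.ndarray  # length K (shared sigma repeated)
    loglik: float
    n_params: int
    n_participants: int
    posterior: np.ndarray  # N x K
    assignment: np.ndarray  # modal group index per participant
    participant_ids: np.ndarray
    converged: bool
    spec: GbtmSpec
    labels: list = field(default_factory=list)
    restart_logliks: list = field(default_factory=list)

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_params * np.log(self.n_participants)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def k_groups(self) -> int:
        return len(self.beta)

    def mean_at(self, years: float, k: int) -> float:
        lo, hi = self.spec.censor_bounds
        v = float(np.polynomial.polynomial.polyval(years, self.beta[k]))
        return float(np.clip(v, lo, hi))

    def group_sizes(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.k_groups)

    def to_dict(self) -> dict:
        return {
            "beta": [b.tolist() for b in self.beta],
            "pi": self.pi.tolist(),
            "sigma": self.sigma.tolist(),
            "loglik": self.loglik,
            "bic": self.bic,
            "aic": self.aic,
            "n_params": self.n_params,
            "n_participants": int(self.n_participants),
            "labels": list(self.labels),
            "converged": bool(self.converged),
            "group_sizes": self.group_sizes().tolist(),
            "spec": {
                "k_groups": self.spec.k_groups,
                "poly_orders": self.spec.orders,
                "censored": self.spec.censored,
                "shared_sigma": self.spec.shared_sigma,
                "seed": self.spec.seed,
            },
        }


# ----------------------------------------------------------------------
# data preparation

def _prepare(panel: pd.DataFrame):
    d = panel[["participant_id", "years_since_baseline", "fi"]].dropna(subset=["fi"])
    if len(d) == 0:
        raise ConfigurationError("panel has no observed FI values")
    pids, idx = np.unique(d["participant_id"].to_numpy(), return_inverse=True)
    y = d["fi"].to_numpy(dtype=float)
    t = d["years_since_baseline"].to_numpy(dtype=float)
    return y, t, idx, pids


def _designs(t: np.ndarray, orders: Sequence[int]):
    dmax = max(orders)
    powers = np.vander(t, dmax + 1, increasing=True)  # 1, t, t^2, ...
    return [powers[:, : d + 1] for d in orders]


# ----------------------------------------------------------------------
# censored-normal observed-data likelihood with analytic gradient

def censored_normal_loglik(y, mu, sigma, bounds):
    """Per-observation log-likelihood of a normal censored at ``bounds``.

    Interior points contribute the density; points at (or beyond) a bound
    contribute the tail mass below/above it.
    """
    lo, hi = bounds
    z_lo = (lo - mu) / sigma
    z_hi = (mu - hi) / sigma
    interior = -0.5 * ((y - mu) / sigma) ** 2 - np.log(sigma) - _LOG_SQRT_2PI
    out = np.where(y <= lo, log_ndtr(z_lo), np.where(y >= hi, log_ndtr(z_hi), interior))
    return out


def _cens_terms(y, mu, sigma, bounds):
    """loglik, d/dmu, d/dlog(sigma) per observation (censored normal)."""
    lo, hi = bounds
    at_lo = y <= lo
    at_hi = y >= hi
    inter = ~(at_lo | at_hi)

    ll = np.empty_like(y)
    dmu = np.empty_like(y)
    dls = np.empty_like(y)

    z = (y[inter] - mu[inter]) / sigma
    ll[inter] = -0.5 * z**2 - np.log(sigma) - _LOG_SQRT_2PI
    dmu[inter] = z / sigma
    dls[inter] = z**2 - 1.0

    if at_lo.any():
        zl = (lo - mu[at_lo]) / sigma
        logcdf = log_ndtr(zl)
        ratio = np.exp(norm.logpdf(zl) - logcdf)  # phi/Phi, stable
        ll[at_lo] = logcdf
        dmu[at_lo] = -ratio / sigma
        dls[at_lo] = -zl * ratio
    if at_hi.any():
        zh = (mu[at_hi] - hi) / sigma
        logcdf = log_ndtr(zh)
        ratio = np.exp(norm.logpdf(zh) - logcdf)
        ll[at_hi] = logcdf
        dmu[at_hi] = ratio / sigma
        dls[at_hi] = -zh * ratio
    return ll, dmu, dls


def _pack(betas, log_sigmas, logits):
    return np.concatenate([np.concatenate(betas), log_sigmas, logits])


def _unpack(theta, orders, K, shared_sigma):
    betas, pos = [], 0
    for d in orders:
        betas.append(theta[pos: pos + d + 1])
        pos += d + 1
    n_sig = 1 if shared_sigma else K
    log_sigmas = theta[pos: pos + n_sig]
    pos += n_sig
    logits = theta[pos:]
    return betas, log_sigmas, logits


def _neg_loglik_and_grad(theta, y, Xs, idx, N, spec):
    K = spec.k_groups
    orders = spec.orders
    betas, log_sigmas, logits = _unpack(theta, orders, K, spec.shared_sigma)
    sigmas = np.maximum(np.exp(log_sigmas), _SIGMA_FLOOR)
    sig_k = sigmas.repeat(K) if spec.shared_sigma else sigmas
    full_logits = np.append(logits, 0.0)
    log_pi = full_logits - logsumexp(full_logits)

    M = y.shape[0]
    S = np.zeros((N, K))
    ll_obs = np.empty((M, K))
    dmu_obs = np.empty((M, K))
    dls_obs = np.empty((M, K))
    for k in range(K):
        mu = Xs[k] @ betas[k]
        s = sig_k[k]
        if spec.censored:
            ll_k, dmu_k, dls_k = _cens_terms(y, mu, s, spec.censor_bounds)
        else:
            z = (y - mu) / s
            ll_k = -0.5 * z**2 - np.log(s) - _LOG_SQRT_2PI
            dmu_k = z / s
            dls_k = z**2 - 1.0
        ll_obs[:, k] = ll_k
        dmu_obs[:, k] = dmu_k
        dls_obs[:, k] = dls_k
        np.add.at(S[:, k], idx, ll_k)

    a = log_pi[None, :] + S
    ll_i = logsumexp(a, axis=1)
    loglik = float(ll_i.sum())
    resp = np.exp(a - ll_i[:, None])  # N x K responsibilities

    w_obs = resp[idx, :]  # M x K
    grad_parts = []
    for k in range(K):
        grad_parts.append(Xs[k].T @ (w_obs[:, k] * dmu_obs[:, k]))
    if spec.shared_sigma:
        g_ls = np.array([(w_obs * dls_obs).sum()])
    else:
        g_ls = (w_obs * dls_obs).sum(axis=0)
    pi = np.exp(log_pi)
    g_logits = (resp.sum(axis=0) - N * pi)[:-1]

    grad = np.concatenate([np.concatenate(grad_parts), g_ls, g_logits])
    return -loglik, -grad


def _posteriors(theta, y, Xs, idx, N, spec):
    K = spec.k_groups
    betas, log_sigmas, logits = _unpack(theta, spec.orders, K, spec.shared_sigma)
    sigmas = np.maximum(np.exp(log_sigmas), _SIGMA_FLOOR)
    sig_k = sigmas.repeat(K) if spec.shared_sigma else sigmas
    full_logits = np.append(logits, 0.0)
    log_pi = full_logits - logsumexp(full_logits)
    S = np.zeros((N, K))
    for k in range(K):
        mu = Xs[k] @ betas[k]
        if spec.censored:
            ll_k = censored_normal_loglik(y, mu, sig_k[k], spec.censor_bounds)
        else:
            z = (y - mu) / sig_k[k]
            ll_k = -0.5 * z**2 - np.log(sig_k[k]) - _LOG_SQRT_2PI
        np.add.at(S[:, k], idx, ll_k)
    a = log_pi[None, :] + S
    ll_i = logsumexp(a, axis=1)
    resp = np.exp(a - ll_i[:, None])
    return float(ll_i.sum()), resp, betas, sigmas, np.exp(log_pi)


# ----------------------------------------------------------------------
# initialisation: k-means on per-participant OLS (intercept, slope)

def _participant_summaries(y, t, idx, N):
    out = np.zeros((N, 2))
    for i in range(N):
        m = idx == i
        ti, yi = t[m], y[m]
        if len(yi) >= 2 and np.ptp(ti) > 0:
            A = np.vstack([np.ones_like(ti), ti]).T
            coef, *_ = np.linalg.lstsq(A, yi, rcond=None)
            out[i] = coef
        else:
            out[i] = (yi.mean(), 0.0)
    return out


def _kmeans_init(summ, K, rng, perturb):
    z = (summ - summ.mean(axis=0)) / np.maximum(summ.std(axis=0), 1e-12)
    # seed centers at quantiles of the intercept+slope score, then Lloyd steps
    score = z.sum(axis=1)
    qs = np.quantile(score, (np.arange(K) + 0.5) / K)
    centers = np.array([z[np.argmin(np.abs(score - q))] for q in qs], dtype=float)
    centers = centers + perturb * rng.normal(size=centers.shape)
    for _ in range(15):
        d2 = ((z[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        lab = d2.argmin(axis=1)
        for k in range(K):
            if (lab == k).any():
                centers[k] = z[lab == k].mean(axis=0)
    return lab


def _initial_theta(y, t, idx, N, spec, rng, restart):
    K = spec.k_groups
    orders = spec.orders
    summ = _participant_summaries(y, t, idx, N)
    lab = _kmeans_init(summ, K, rng, perturb=0.0 if restart == 0 else 0.5)
    betas, resid_ss, n_obs = [], 0.0, 0
    for k in range(K):
        m = np.isin(idx, np.where(lab == k)[0])
        d = orders[k]
        if m.sum() > d:
            X = np.vander(t[m], d + 1, increasing=True)
            coef, *_ = np.linalg.lstsq(X, y[m], rcond=None)
            resid = y[m] - X @ coef
            resid_ss += float(resid @ resid)
            n_obs += int(m.sum())
        else:
            coef = np.zeros(d + 1)
            coef[0] = y.mean()
        betas.append(coef)
    sigma0 = max(np.sqrt(resid_ss / max(n_obs, 1)), 5 * _SIGMA_FLOOR)
    n_sig = 1 if spec.shared_sigma else K
    log_sigmas = np.full(n_sig, np.log(sigma0))
    shares = np.maximum(np.bincount(lab, minlength=K) / N, 1e-3)
    logits = np.log(shares / shares[-1])[:-1]
    return _pack(betas, log_sigmas, logits)


# ----------------------------------------------------------------------
# EM path (plain-normal mode)

def _em_fit(theta0, y, Xs, idx, N, spec):
    K = spec.k_groups
    betas, log_sigmas, logits = _unpack(theta0, spec.orders, K, spec.shared_sigma)
    sigmas = np.maximum(np.exp(log_sigmas), _SIGMA_FLOOR)
    full = np.append(logits, 0.0)
    pi = np.exp(full - logsumexp(full))
    M = len(y)
    prev_ll = -np.inf
    converged = False
    for it in range(spec.max_iter):
        sig_k = sigmas.repeat(K) if spec.shared_sigma else sigmas
        S = np.zeros((N, K))
        for k in range(K):
            mu = Xs[k] @ betas[k]
            z = (y - mu) / sig_k[k]
            ll_k = -0.5 * z**2 - np.log(sig_k[k]) - _LOG_SQRT_2PI
            np.add.at(S[:, k], idx, ll_k)
        a = np.log(np.maximum(pi, 1e-300))[None, :] + S
        ll_i = logsumexp(a, axis=1)
        ll = float(ll_i.sum())
        # EM guarantees monotone likelihood; tolerate only rounding noise
        assert ll >= prev_ll - 1e-8 * max(1.0, abs(prev_ll)), (
            f"EM log-likelihood decreased: {prev_ll} -> {ll}"
        )
        resp = np.exp(a - ll_i[:, None])
        if abs(ll - prev_ll) < spec.tol:
            converged = True
            prev_ll = ll
            break
        prev_ll = ll
        # M-step
        w_obs = resp[idx, :]
        ss = np.zeros(K)
        for k in range(K):
            w = w_obs[:, k]
            Xw = Xs[k] * w[:, None]
            XtX = Xs[k].T @ Xw
            Xty = Xw.T @ y
            betas[k] = np.linalg.solve(XtX + 1e-10 * np.eye(XtX.shape[0]), Xty)
            resid = y - Xs[k] @ betas[k]
            ss[k] = float(w @ resid**2)
        if spec.shared_sigma:
            sigmas = np.array([max(np.sqrt(ss.sum() / M), _SIGMA_FLOOR)])
        else:
            wk = w_obs.sum(axis=0)
            sigmas = np.maximum(np.sqrt(ss / np.maximum(wk, 1e-12)), _SIGMA_FLOOR)
        pi = resp.mean(axis=0)
    logits = np.log(np.maximum(pi, 1e-12) / max(pi[-1], 1e-12))[:-1]
    theta = _pack(betas, np.log(sigmas), logits)
    return theta, prev_ll, converged


# ----------------------------------------------------------------------
# public fitting API

def fit_gbtm(panel: pd.DataFrame, spec: GbtmSpec) -> GbtmFit:
    """Maximum-likelihood GBTM fit of an FI panel.

    ``panel`` needs columns participant_id, years_since_baseline, fi
    (missing FI rows are dropped; every participant must retain >= 1
    observation).  Raises :class:`ConvergenceError` (carrying the best
    fit so far) if no restart converges.
    """
    y, t, idx, pids = _prepare(panel)
    N = len(pids)
    # fit on unit-scaled time for optimiser conditioning; coefficients are
    # rescaled back to per-year units afterwards
    t_scale = max(float(np.abs(t).max()), 1.0)
    ts = t / t_scale
    Xs = _designs(ts, spec.orders)
    rng = np.random.default_rng(spec.seed)

    best = None
    restart_lls = []
    for restart in range(max(spec.n_restarts, 1)):
        theta0 = _initial_theta(y, ts, idx, N, spec, rng, restart)
        if spec.censored:
            res = minimize(
                _neg_loglik_and_grad, theta0, args=(y, Xs, idx, N, spec),
                jac=True, method="L-BFGS-B",
                options={"maxiter": spec.max_iter, "ftol": spec.tol * 1e-2,
                         "gtol": 1e-8},
            )
            theta, ll, ok = res.x, -float(res.fun), bool(res.success)
        else:
            theta, ll, ok = _em_fit(theta0, y, Xs, idx, N, spec)
        restart_lls.append(ll)
        if best is None or ll > best[1] + 1e-10:
            best = (theta, ll, ok)

    theta, ll, ok = best
    ll_check, resp, betas, sigmas, pi = _posteriors(theta, y, Xs, idx, N, spec)
    betas = [np.asarray(b) / t_scale ** np.arange(len(b)) for b in betas]
    assignment = resp.argmax(axis=1)

    n_sig = 1 if spec.shared_sigma else spec.k_groups
    n_params = sum(d + 1 for d in spec.orders) + n_sig + (spec.k_groups - 1)
    fit = GbtmFit(
        beta=[np.asarray(b, dtype=float) for b in betas],
        pi=pi,
        sigma=sigmas.repeat(spec.k_groups) if spec.shared_sigma else sigmas,
        loglik=ll_check,
        n_params=n_params,
        n_participants=N,
        posterior=resp,
        assignment=assignment,
        participant_ids=pids,
        converged=ok,
        spec=spec,
        restart_logliks=restart_lls,
    )
    floor = max(2.0 / N, 0.005)
    if (fit.pi < floor).any():
        warnings.warn(
            f"degenerate group: membership probability below {floor:.3f} "
            f"(pi = {np.round(fit.pi, 4)})",
            RuntimeWarning,
        )
    if not ok:
        raise ConvergenceError(
            "GBTM failed to converge in all restarts", best_fit=fit
        )
    return fit


def select_model(
    panel: pd.DataFrame,
    k_range: Sequence[int] = (1, 2, 3, 4, 5),
    order_range: Sequence[int] = (2,),
    spec_defaults: GbtmSpec | None = None,
):
    """Fit all (K, order) candidates and return the BIC-optimal fit plus
    the candidate table (K, order, loglik, bic, min pi, min APP)."""
    if len(list(k_range)) == 0:
        raise ConfigurationError("k_range must be non-empty")
    base = spec_defaults or GbtmSpec()
    rows, best = [], None
    for K in k_range:
        for order in order_range:
            spec = GbtmSpec(
                k_groups=K, poly_orders=order, censored=base.censored,
                censor_bounds=base.censor_bounds, shared_sigma=base.shared_sigma,
                max_iter=base.max_iter, tol=base.tol,
                n_restarts=base.n_restarts, seed=base.seed,
            )
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    fit = fit_gbtm(panel, spec)
            except ConvergenceError as err:
                fit = err.best_fit
                rows.append({"k": K, "order": order, "converged": False,
                             "loglik": fit.loglik if fit else np.nan,
                             "bic": fit.bic if fit else np.nan,
                             "min_pi": np.nan, "min_app": np.nan})
                continue
            diag = diagnostics(fit)
            rows.append({
                "k": K, "order": order, "converged": True,
                "loglik": fit.loglik, "bic": fit.bic,
                "min_pi": float(fit.pi.min()),
                "min_app": float(np.nanmin(diag["app"].to_numpy(dtype=float))),
            })
            if best is None or fit.bic < best.bic:
                best = fit
    table = pd.DataFrame(rows)
    if best is None:
        raise ConvergenceError("no GBTM candidate converged", best_fit=None)
    return best, table


def assign_and_label(fit: GbtmFit, panel: pd.DataFrame) -> GbtmFit:
    """Order groups by fitted mean FI at the final observation time and
    attach labels (stable / moderate / accelerated when K = 3).

    Reordering makes labels invariant to the arbitrary group indexing of
    the optimiser; ties in the final fitted mean are broken by the fitted
    slope at that time.
    """
    t_final = float(panel["years_since_baseline"].max())
    K = fit.k_groups
    finals = np.array([fit.mean_at(t_final, k) for k in range(K)])
    dcoef = [np.polynomial.polynomial.polyder(fit.beta[k]) for k in range(K)]
    slopes = np.array([
        float(np.polynomial.polynomial.polyval(t_final, d)) if len(d) else 0.0
        for d in dcoef
    ])
    order = np.lexsort((slopes, finals))

    inv = np.empty(K, dtype=int)
    inv[order] = np.arange(K)
    fit.beta = [fit.beta[k] for k in order]
    fit.pi = fit.pi[order]
    fit.sigma = fit.sigma[order]
    fit.posterior = fit.posterior[:, order]
    fit.assignment = inv[fit.assignment]
    if K == 3:
        fit.labels = ["stable", "moderate", "accelerated"]
    else:
        fit.labels = [f"group_{k + 1}" for k in range(K)]
        if K != 1:
            warnings.warn(
                f"{K} groups fitted; using generic ordinal labels", RuntimeWarning
            )
    return fit


def diagnostics(fit: GbtmFit) -> pd.DataFrame:
    """Adequacy table: average posterior probability (APP) of the assigned
    group and odds of correct classification (OCC) per group."""
    K = fit.k_groups
    rows = []
    for k in range(K):
        mask = fit.assignment == k
        if not mask.any():
            rows.append({"group": k, "n": 0, "app": np.nan, "occ": np.nan})
            continue
        app = float(fit.posterior[mask, k].mean())
        pi_k = float(fit.pi[k])
        if app >= 1.0 or pi_k >= 1.0:
            occ = np.inf if app >= 1.0 and pi_k < 1.0 else np.nan
        else:
            occ = (app / (1 - app)) / (pi_k / (1 - pi_k))
        rows.append({"group": k, "n": int(mask.sum()), "app": app, "occ": occ})
    return pd.DataFrame(rows)
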