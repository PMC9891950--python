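"""Trajectory-model checks: likelihood oracles, recovery, selection,
labelling and diagnostics."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from frailtraj import gbtm
from frailtraj._errors import ConfigurationError
from frailtraj.gbtm import (
    GbtmFit, GbtmSpec, assign_and_label, censored_normal_loglik, diagnostics,
    fit_gbtm, select_model,
)


def make_panel(y, t, pid):
    return pd.DataFrame({"participant_id": pid, "years_since_baseline": t,
                         "fi": y})


def quiet_fit(panel, spec):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return fit_gbtm(panel, spec)


class TestCensoredLikelihood:
    def test_interior_equals_normal_density(self):
        y = np.array([0.3])
        ll = censored_normal_loglik(y, np.array([0.25]), 0.1, (0.0, 1.0))
        assert ll[0] == pytest.approx(stats.norm.logpdf(0.3, 0.25, 0.1), abs=1e-12)

    def test_bound_mass_matches_numeric_integration(self):
        # an observation at the lower bound contributes the full normal
        # mass below it; quadrature over the latent scale is the oracle
        mu, sigma = 0.04, 0.05
        ll = censored_normal_loglik(np.array([0.0]), np.array([mu]), sigma,
                                    (0.0, 1.0))[0]
        mass, _ = integrate.quad(lambda x: stats.norm.pdf(x, mu, sigma),
                                 -np.inf, 0.0)
        assert ll == pytest.approx(np.log(mass), abs=1e-8)

    def test_upper_bound_mass(self):
        mu, sigma = 0.97, 0.04
        ll = censored_normal_loglik(np.array([1.0]), np.array([mu]), sigma,
                                    (0.0, 1.0))[0]
        mass, _ = integrate.quad(lambda x: stats.norm.pdf(x, mu, sigma),
                                 1.0, np.inf)
        assert ll == pytest.approx(np.log(mass), abs=1e-8)


class TestSingleGroup:
    def test_noise_free_quadratic_recovered_to_1e8(self):
        # least-squares limit of the likelihood: one group, interior values
        truth = np.array([0.2, 0.01, 0.001])
        t = np.tile(np.arange(7) * 2.0, 30)
        pid = np.repeat(np.arange(30), 7)
        y = np.polynomial.polynomial.polyval(t, truth)
        fit = quiet_fit(make_panel(y, t, pid),
                        GbtmSpec(k_groups=1, poly_orders=2, censored=False,
                                 n_restarts=1, seed=0))
        assert np.allclose(fit.beta[0], truth, atol=1e-8)
        assert fit.sigma[0] >= 1e-4  # guarded by the floor

    def test_em_path_monotone_loglik(self):
        # the plain-normal EM asserts monotonicity internally each iteration
        rng = np.random.default_rng(0)
        t = np.tile(np.arange(5) * 2.0, 50)
        pid = np.repeat(np.arange(50), 5)
        y = 0.2 + 0.01 * t + rng.normal(0, 0.05, len(t))
        fit = quiet_fit(make_panel(y, t, pid),
                        GbtmSpec(k_groups=2, poly_orders=1, censored=False,
                                 n_restarts=2, seed=0))
        assert fit.converged


class TestTwoGroups:
    def test_well_separated_groups_fully_recovered(self):
        # two linear trajectories 10 sigma apart: assignment is certain
        rng = np.random.default_rng(4)
        n, waves, sigma = 200, 8, 0.02
        split = rng.random(n) < 0.4
        t = np.tile(np.arange(waves) * 1.0, n)
        pid = np.repeat(np.arange(n), waves)
        mu = np.where(split[pid], 0.2 + 0.01 * t, 0.5 + 0.02 * t)
        y = np.clip(mu + rng.normal(0, sigma, len(t)), 0, 1)
        fit = quiet_fit(make_panel(y, t, pid),
                        GbtmSpec(k_groups=2, poly_orders=1, n_restarts=2, seed=0))
        fit = assign_and_label(fit, make_panel(y, t, pid))
        # group 0 (lower final value) must be exactly the split==True set
        assigned_low = fit.assignment == 0
        assert (assigned_low == split).all()
        lo, hi = stats.binom.ppf([0.025, 0.975], n, 0.4) / n
        assert lo <= fit.pi[0] <= hi


class TestSelection:
    def test_white_noise_selects_one_group(self):
        rng = np.random.default_rng(11)
        t = np.tile(np.arange(5) * 2.0, 150)
        pid = np.repeat(np.arange(150), 5)
        y = np.clip(0.3 + rng.normal(0, 0.05, len(t)), 0, 1)
        best, table = select_model(make_panel(y, t, pid), k_range=(1, 2, 3),
                                   order_range=(1,),
                                   spec_defaults=GbtmSpec(n_restarts=2, seed=0))
        assert best.k_groups == 1
        assert best.bic <= table["bic"].min() + 1e-9

    def test_best_bic_is_minimum_of_candidates(self):
        rng = np.random.default_rng(3)
        t = np.tile(np.arange(6) * 2.0, 80)
        pid = np.repeat(np.arange(80), 6)
        grp = pid % 2
        y = np.clip(0.1 + 0.25 * grp + 0.01 * t + rng.normal(0, 0.04, len(t)), 0, 1)
        best, table = select_model(make_panel(y, t, pid), k_range=(1, 2, 3),
                                   order_range=(1,),
                                   spec_defaults=GbtmSpec(n_restarts=2, seed=0))
        assert best.bic == pytest.approx(table["bic"].min())

    def test_empty_k_range_rejected(self):
        with pytest.raises(ConfigurationError):
            select_model(make_panel(np.array([0.1]), np.array([0.0]),
                                    np.array([0])), k_range=())


def toy_fit(posterior, pi, beta=None, sigma=None, labels=()):
    posterior = np.asarray(posterior, dtype=float)
    K = posterior.shape[1]
    spec = GbtmSpec(k_groups=K, poly_orders=1, n_restarts=1)
    return GbtmFit(
        beta=beta or [np.array([0.1 * (k + 1), 0.01]) for k in range(K)],
        pi=np.asarray(pi, dtype=float),
        sigma=np.full(K, 0.05) if sigma is None else sigma,
        loglik=0.0, n_params=3 * K, n_participants=posterior.shape[0],
        posterior=posterior, assignment=posterior.argmax(axis=1),
        participant_ids=np.arange(posterior.shape[0]), converged=True,
        spec=spec, labels=list(labels),
    )


class TestLabelling:
    def test_modal_assignment_is_argmax(self):
        fit = toy_fit([[0.1, 0.2, 0.7]], [1 / 3] * 3)
        assert fit.assignment[0] == 2

    def test_ordering_by_final_fitted_value(self):
        panel = make_panel(np.array([0.1, 0.2]), np.array([0.0, 12.0]),
                           np.array([0, 0]))
        # curves ending at 0.45 < 0.15 < 0.25 in given index order
        fit = toy_fit(np.eye(3), [1 / 3] * 3,
                      beta=[np.array([0.45, 0.0]), np.array([0.15, 0.0]),
                            np.array([0.25, 0.0])])
        fit = assign_and_label(fit, panel)
        assert fit.labels == ["stable", "moderate", "accelerated"]
        finals = [fit.mean_at(12.0, k) for k in range(3)]
        assert finals == sorted(finals)

    def test_label_switching_invariance(self):
        panel = make_panel(np.array([0.1]), np.array([10.0]), np.array([0]))
        post = np.array([[0.7, 0.2, 0.1], [0.1, 0.8, 0.1], [0.2, 0.2, 0.6]])
        betas = [np.array([0.4, 0.0]), np.array([0.1, 0.0]), np.array([0.2, 0.0])]
        fit_a = assign_and_label(
            toy_fit(post, [0.4, 0.35, 0.25], beta=[b.copy() for b in betas]), panel)
        perm = [2, 0, 1]
        fit_b = assign_and_label(
            toy_fit(post[:, perm], np.array([0.4, 0.35, 0.25])[perm],
                    beta=[betas[k].copy() for k in perm]), panel)
        assert fit_a.labels == fit_b.labels
        assert np.array_equal(fit_a.assignment, fit_b.assignment)
        assert np.allclose(fit_a.posterior, fit_b.posterior)

    def test_non_three_groups_get_generic_labels(self):
        panel = make_panel(np.array([0.1]), np.array([10.0]), np.array([0]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = assign_and_label(
                toy_fit(np.eye(2), [0.5, 0.5],
                        beta=[np.array([0.3, 0.0]), np.array([0.1, 0.0])]), panel)
        assert fit.labels == ["group_1", "group_2"]


class TestDiagnostics:
    def test_certain_posteriors_give_app_one(self):
        fit = toy_fit(np.eye(3)[[0, 1, 2, 0]], [0.5, 0.25, 0.25])
        d = diagnostics(fit)
        assert (d["app"] == 1.0).all()

    def test_uninformative_posteriors_give_occ_one(self):
        pi = np.array([0.6, 0.4])
        post = np.tile(pi, (10, 1))
        fit = toy_fit(post, pi)
        d = diagnostics(fit)
        # every participant is assigned to the majority group with APP = pi_1
        assert d.loc[0, "app"] == pytest.approx(0.6)
        assert d.loc[0, "occ"] == pytest.approx(1.0)

    def test_hand_worked_four_participant_table(self):
        post = np.array([[0.9, 0.1], [0.8, 0.2], [0.3, 0.7], [0.4, 0.6]])
        pi = np.array([0.55, 0.45])
        fit = toy_fit(post, pi)
        d = diagnostics(fit)
        app1 = (0.9 + 0.8) / 2                      # assigned to group 0
        app2 = (0.7 + 0.6) / 2                      # assigned to group 1
        occ1 = (app1 / (1 - app1)) / (0.55 / 0.45)
        occ2 = (app2 / (1 - app2)) / (0.45 / 0.55)
        assert d["app"].tolist() == pytest.approx([app1, app2])
        assert d["occ"].tolist() == pytest.approx([occ1, occ2])

    def test_empty_group_reported_missing(self):
        post = np.array([[0.9, 0.1], [0.8, 0.2]])
        fit = toy_fit(post, [0.9, 0.1])
        d = diagnostics(fit)
        assert np.isnan(d.loc[1, "app"])


class TestFitInvariants:
    def test_posterior_rows_sum_to_one_and_bic_identity(self, small_cohort):
        from frailtraj.frailty_index import compute_fi_panel
        cohort, _ = small_cohort
        panel = compute_fi_panel(cohort)
        fit = quiet_fit(panel, GbtmSpec(k_groups=2, poly_orders=1,
                                        n_restarts=1, seed=0))
        assert np.allclose(fit.posterior.sum(axis=1), 1.0, atol=1e-10)
        assert fit.bic == pytest.approx(
            -2 * fit.loglik + fit.n_params * np.log(fit.n_participants))
        assert fit.pi.sum() == pytest.approx(1.0, abs=1e-10)


class TestParameterRecovery:
    def test_three_class_recovery_across_seeds(self):
        # estimated mixing proportions and curves stay near truth over
        # repeated simulated cohorts
        truth_polys = [np.array([0.08, 0.004]), np.array([0.12, 0.018])]
        truth_pi = np.array([0.7, 0.3])
        sigma = 0.05
        pis, b0s = [], []
        for seed in range(8):
            rng = np.random.default_rng(100 + seed)
            n, waves = 300, 7
            z = (rng.random(n) < truth_pi[1]).astype(int)
            t = np.tile(np.arange(waves) * 2.0, n)
            pid = np.repeat(np.arange(n), waves)
            mu = np.polynomial.polynomial.polyval(t, truth_polys[0].T)
            mu2 = np.polynomial.polynomial.polyval(t, truth_polys[1].T)
            y = np.clip(np.where(z[pid] == 1, mu2, mu)
                        + rng.normal(0, sigma, len(t)), 0, 1)
            fit = quiet_fit(make_panel(y, t, pid),
                            GbtmSpec(k_groups=2, poly_orders=1,
                                     n_restarts=2, seed=0))
            fit = assign_and_label(fit, make_panel(y, t, pid))
            pis.append(fit.pi[1])
            b0s.append(fit.beta[1][0])
        # simulation-based interval: mean within 4 MC standard errors
        assert np.mean(pis) == pytest.approx(
            truth_pi[1], abs=4 * np.std(pis, ddof=1) / np.sqrt(len(pis)) + 0.01)
        assert np.mean(b0s) == pytest.approx(
            truth_polys[1][0], abs=4 * np.std(b0s, ddof=1) / np.sqrt(len(b0s)) + 0.005)
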