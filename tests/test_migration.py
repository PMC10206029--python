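"""Daily-emigrant state-space model: likelihood components and fitting."""

import numpy as np
import pytest
import scipy.stats as st
from scipy.special import expit, logit

from lhprod import inference
from lhprod.errors import ValidationError
from lhprod.migration import (MigrationParams, TrapDataset,
                              _MigrationModel, bootstrap_window_totals,
                              capture_probability, catch_nll, fit_migration,
                              log_daily_abundance, markrecap_nll, rw_ar1_nll)
from lhprod.simulate import SyntheticConfig, simulate_trap_dataset


def _params(Y=2, T=10, W=2, **kw):
    base = dict(
        mu_m=np.full(Y, 3.0), sigma_delta=0.1, sigma_eps=0.3, rho_eps=0.5,
        nb_phi=0.2, beta0_p=0.0, beta1_p=0.0, sigma_iota=0.3,
        sigma_kappa=0.3, sigma_nu=0.3, sigma_xi=0.3,
        delta=np.zeros(T), eps=np.zeros((Y, T)), iota=np.zeros(Y),
        kappa=np.zeros(Y), nu=np.zeros(W), xi=np.zeros((Y, W)),
    )
    base.update(kw)
    return MigrationParams(**base)


class TestLogDailyAbundance:
    def test_all_effects_zero(self):
        p = _params()
        assert log_daily_abundance(p, 0, 0) == 3.0
        assert np.exp(log_daily_abundance(p, 0, 0)) == pytest.approx(20.0855,
                                                                     abs=1e-3)

    def test_cancellation(self):
        p = _params()
        p.delta[3] = 0.5
        p.eps[1, 3] = -0.5
        assert log_daily_abundance(p, 3, 1) == pytest.approx(3.0)

    def test_outside_season_raises(self):
        with pytest.raises(ValueError):
            log_daily_abundance(_params(T=10), 10, 0)

    def test_matches_generator_truth(self, small_trap):
        """Constructing params from the generator's latent effects
        reproduces the simulated log abundance exactly (round trip)."""
        cfg, ds, truth = small_trap
        Y, T, W = ds.n_years, ds.n_days, ds.n_weeks
        p = _params(Y=Y, T=T, W=W, mu_m=truth["mu_m"],
                    delta=truth["delta"] - truth["delta"][0],
                    eps=truth["eps"] + truth["delta"][0],
                    iota=truth["iota"], kappa=truth["kappa"],
                    nu=truth["nu"][:W], xi=truth["xi"][:, :W])
        for (t, y) in [(0, 0), (5, 1), (T - 1, 2)]:
            assert log_daily_abundance(p, t, y) == pytest.approx(
                np.log(truth["m"][y, t]), rel=1e-12)


class TestRwAr1Nll:
    def test_rho_zero_is_iid_normal(self):
        rng = np.random.default_rng(0)
        eps = rng.normal(0, 0.3, (2, 12))
        p = _params(T=12, eps=eps, rho_eps=1e-12, sigma_delta=0.5)
        nll = rw_ar1_nll(p)
        iid = -st.norm.logpdf(eps, 0, 0.3).sum()
        rw = -st.norm.logpdf(np.diff(p.delta), 0, 0.5).sum()
        assert nll == pytest.approx(iid + rw, abs=1e-8)

    def test_two_day_hand_case(self):
        """Single year, two days, hand-evaluated Gaussian log-pdfs."""
        p = _params(Y=1, T=2, delta=np.array([0.0, 0.2]),
                    eps=np.array([[0.1, -0.3]]), sigma_delta=0.1,
                    sigma_eps=0.3, rho_eps=0.5)
        s0 = 0.3 / np.sqrt(1 - 0.25)
        expected = -(st.norm.logpdf(0.2, 0, 0.1)
                     + st.norm.logpdf(0.1, 0, s0)
                     + st.norm.logpdf(-0.3, 0.5 * 0.1, 0.3))
        assert rw_ar1_nll(p) == pytest.approx(expected, abs=1e-10)

    def test_rho_out_of_range(self):
        with pytest.raises(ValidationError):
            _params(rho_eps=1.0)

    def test_stationary_initial_sd(self):
        """The initial eps term uses the stationary SD sigma/sqrt(1-rho^2):
        its NLL contribution at eps_1 = 0 is the normalizing constant."""
        p = _params(Y=1, T=2, rho_eps=0.8, sigma_eps=0.3,
                    eps=np.zeros((1, 2)))
        s0 = 0.3 / np.sqrt(1 - 0.64)
        expected = -(st.norm.logpdf(0, 0, 0.1) * 0  # no delta increment term
                     + st.norm.logpdf(0.0, 0, s0)
                     + st.norm.logpdf(0.0, 0, 0.3)
                     + st.norm.logpdf(0.0, 0, 0.1))
        assert rw_ar1_nll(p) == pytest.approx(expected, abs=1e-10)


class TestCaptureProbability:
    def test_all_terms_zero(self):
        assert capture_probability(_params(), 0, 0, 0.0) == 0.5

    def test_intercept_only(self):
        p = _params(iota=np.array([float(logit(0.2)), 0.0]))
        assert capture_probability(p, 0, 0, 0.0) == pytest.approx(0.2)

    def test_discharge_slope(self):
        p = _params(kappa=np.array([1.0, 0.0]))
        assert capture_probability(p, 0, 0, 1.0) == pytest.approx(
            float(expit(1.0)), abs=1e-9)
        assert capture_probability(p, 0, 0, 1.0) == pytest.approx(0.7311,
                                                                  abs=1e-4)

    def test_in_unit_interval(self, rng):
        p = _params(iota=rng.normal(0, 2, 2), kappa=rng.normal(0, 2, 2),
                    nu=rng.normal(0, 2, 2), xi=rng.normal(0, 2, (2, 2)))
        for t, y in [(0, 0), (8, 1)]:
            val = capture_probability(p, t, y, 1.3)
            assert 0.0 < val < 1.0


def _toy_dataset(Y=2, T=10, catch=None, operating=None, trials=None):
    days = np.arange(100, 100 + T)
    years = np.arange(2000, 2000 + Y)
    if operating is None:
        operating = np.ones((Y, T), dtype=bool)
    if catch is None:
        catch = np.where(operating, 4.0, np.nan)
    discharge = np.full((Y, T), 5.0)
    discharge += np.arange(T)[None, :] * 0.1  # nonzero spread for Z-scoring
    kw = {}
    if trials is not None:
        td, ty, n, k = trials
        kw = dict(trial_day=td, trial_year=ty, released=n, recaptured=k)
    return TrapDataset(stream="s", age_class="subyearling", days=days,
                       years=years, catch=catch, operating=operating,
                       discharge=discharge, **kw)


class TestCatchNll:
    def test_poisson_limit(self):
        """As phi -> 0 the NB likelihood approaches Poisson at the same
        mean (checked per count against scipy.stats.poisson)."""
        from lhprod.migration import _nb_nll

        mu = 2.0
        for c in range(11):
            nb = _nb_nll(float(c), mu, 1e-9)
            pois = -st.poisson.logpmf(c, mu)
            assert abs(nb - pois) < 1e-6

    def test_direct_pmf_oracle(self):
        """Single day: NB NLL matches scipy's nbinom pmf with r = 1/phi,
        p = r/(r + mu) to 1e-10."""
        from lhprod.migration import _nb_nll

        mu, phi, c = 4.0, 0.5, 3
        r = 1 / phi
        expected = -st.nbinom.logpmf(c, r, r / (r + mu))
        assert _nb_nll(c, mu, phi) == pytest.approx(expected, abs=1e-10)

    def test_all_outage_days_contribute_nothing(self):
        ds = _toy_dataset(operating=np.zeros((2, 10), dtype=bool))
        assert catch_nll(_params(), ds) == 0.0

    def test_variance_exceeds_mean_penalizes_overdispersion(self):
        """NB with phi > 0 has variance above the mean, so extreme counts
        are less surprising than under Poisson."""
        from lhprod.migration import _nb_nll

        assert _nb_nll(30.0, 4.0, 0.5) < -st.poisson.logpmf(30, 4.0)


class TestMarkRecapNll:
    def test_hand_binomial(self):
        ds = _toy_dataset(trials=(np.array([100]), np.array([2000]),
                                  np.array([2]), np.array([1])))
        p = _params()  # p = 0.5 everywhere
        assert markrecap_nll(p, ds) == pytest.approx(-np.log(0.5), abs=1e-9)

    def test_no_trials_zero(self):
        assert markrecap_nll(_params(), _toy_dataset()) == 0.0

    def test_k_greater_than_n_rejected(self):
        with pytest.raises(ValidationError):
            _toy_dataset(trials=(np.array([100]), np.array([2000]),
                                 np.array([5]), np.array([7])))

    def test_intercept_mle_matches_closed_form(self):
        """Maximizing the trial likelihood over a common intercept gives
        logit(k_total / n_total) (closed-form binomial MLE)."""
        from scipy.optimize import minimize_scalar

        td = np.array([100, 104, 103, 106])
        ty = np.array([2000, 2000, 2001, 2001])
        n = np.array([50, 80, 60, 40])
        k = np.array([5, 9, 4, 6])
        ds = _toy_dataset(trials=(td, ty, n, k))

        def nll(b):
            p = _params(iota=np.array([b, b]), kappa=np.zeros(2))
            return markrecap_nll(p, ds)

        res = minimize_scalar(nll, bounds=(-6, 2), method="bounded")
        assert res.x == pytest.approx(float(logit(k.sum() / n.sum())),
                                      abs=1e-4)


def test_joint_nll_year_permutation_symmetry(small_trap):
    """Permuting year labels together with all year-indexed effects leaves
    the joint NLL unchanged (years are exchangeable given their effects)."""
    _, ds, _ = small_trap
    model = _MigrationModel(ds)
    theta, u0 = model.start_values()
    rng = np.random.default_rng(2)
    u = u0 + 0.1 * rng.standard_normal(model.n_random)
    f0 = model.joint_nll(theta, u)
    perm = np.array([2, 0, 1])
    ds2 = TrapDataset(
        stream=ds.stream, age_class=ds.age_class, days=ds.days,
        years=ds.years, catch=ds.catch[perm], operating=ds.operating[perm],
        discharge=ds.discharge[perm],
        trial_day=ds.trial_day,
        trial_year=ds.years[np.argsort(perm)][
            np.searchsorted(ds.years, ds.trial_year)],
        released=ds.released, recaptured=ds.recaptured)
    model2 = _MigrationModel(ds2)
    r = model.unpack_random(u)
    u2 = np.concatenate([
        r["delta"][1:], r["eps"][perm].ravel(), r["iota"][perm],
        r["kappa"][perm], r["nu"], r["xi"][perm].ravel()])
    theta2 = theta.copy()
    theta2[:3] = theta[:3][perm]
    assert model2.joint_nll(theta2, u2) == pytest.approx(f0, rel=1e-10)


class TestFitMigration:
    def test_requires_years_and_trials(self):
        ds = _toy_dataset()
        ds1 = TrapDataset(stream="s", age_class="subyearling",
                          days=ds.days, years=ds.years[:1],
                          catch=ds.catch[:1], operating=ds.operating[:1],
                          discharge=ds.discharge[:1])
        with pytest.raises(ValidationError):
            fit_migration(ds1)
        with pytest.raises(ValidationError):
            fit_migration(ds)  # no trials

    def test_small_fit_smoke(self, small_trap):
        cfg, ds, truth = small_trap
        fit = fit_migration(ds, covariance="none")
        assert fit.result.converged
        assert np.all(fit.m_hat > 0)
        ok = np.isfinite(fit.p_hat)
        assert np.all((fit.p_hat[ok] > 0) & (fit.p_hat[ok] < 1))
        # estimated abundance tracks truth on the log scale
        err = np.log(fit.m_hat) - np.log(truth["m"])
        assert abs(err.mean()) < 0.5
        assert fit.result.nll < 1e9

    def test_p_forced_to_one_recovers_catch_profile(self):
        """With capture probability ~1 and tiny observation noise, the
        estimated abundance is close to the observed catches."""
        cfg = SyntheticConfig(
            n_years=3, subyearling_season=(80, 139),
            yearling_season=(430, 459), mode_days=(100, 115, 130, 440),
            mode_sds=(8.0, 8.0, 6.0, 10.0), seed=17, beta0_p=6.0,
            beta1_p=0.0, sigma_iota=0.01, sigma_kappa=0.01, sigma_nu=0.01,
            sigma_xi=0.01, nb_phi=1e-4, outage_prob=0.0, trials_per_year=6,
            released_per_trial=400)
        ds, truth = simulate_trap_dataset(cfg, age_class="subyearling")
        fit = fit_migration(ds, covariance="none")
        obs = ds.operating & (ds.catch > 0)
        logdiff = np.log(fit.m_hat[obs]) - np.log(ds.catch[obs])
        assert np.median(np.abs(logdiff)) < 0.25


@pytest.fixture(scope="module")
def fitted(small_trap):
    _, ds, truth = small_trap
    return fit_migration(ds, covariance="none"), truth


class TestBootstrapWindowTotals:
    def _zero_cov_fit(self, fit):
        import copy

        f = copy.copy(fit)
        r = copy.copy(fit.result)
        r.cov = np.zeros((fit.model.n_fixed,) * 2)
        f.result = r
        return f

    def test_zero_covariance_degenerate(self, fitted):
        """Zero parameter covariance: log-SD is 0 and the log-mean is the
        log of the point-estimate window total."""
        fit, _ = fitted
        f0 = self._zero_cov_fit(fit)
        summ = bootstrap_window_totals(f0, [("spring0", 80, 110),
                                            ("summer0", 111, 139)],
                                       n_draws=50, seed=1)
        assert np.all(summ["log_sd"] == 0.0)
        days = fit.dataset.days
        msk = (days >= 80) & (days <= 110)
        expected = np.log(fit.m_hat[:, msk].sum(axis=1))
        got = summ[summ.lhp == "spring0"].sort_values("brood_year")
        assert np.allclose(got["log_mean"], expected, rtol=1e-10)

    def test_single_day_window(self, fitted):
        fit, _ = fitted
        f0 = self._zero_cov_fit(fit)
        summ = bootstrap_window_totals(f0, [("spring0", 90, 90)], n_draws=10,
                                       seed=2)
        ti = list(fit.dataset.days).index(90)
        assert np.allclose(summ["log_mean"],
                           np.log(fit.m_hat[:, ti]), rtol=1e-10)

    def test_empty_window_errors(self, fitted):
        fit, _ = fitted
        with pytest.raises(ValidationError):
            bootstrap_window_totals(fit, [("spring1", 430, 459)], n_draws=10,
                                    seed=0)

    def test_seeded_and_spread(self, small_trap):
        _, ds, _ = small_trap
        fit = fit_migration(ds)  # with covariance
        w = [("spring0", 80, 110), ("summer0", 111, 139)]
        a = bootstrap_window_totals(fit, w, n_draws=300, seed=9)
        b = bootstrap_window_totals(fit, w, n_draws=300, seed=9)
        assert np.allclose(a["log_mean"], b["log_mean"])
        assert np.all(a["log_sd"] > 0)
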