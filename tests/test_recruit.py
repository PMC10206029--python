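"""Generalized Beverton-Holt production model: likelihood pieces, penalty
construction, factor structure and predictions."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
from scipy import integrate

from lhprod.errors import ValidationError
from lhprod.recruit import (COVARIATE_SETS, LHP_LABELS, RecruitConfig,
                            RecruitData, RecruitParams, _RecruitModel,
                            bh_modified, fit_recruit, hyper_penalty_nll,
                            observation_nll, predict_curves,
                            process_error_nll, recruit_joint_nll)
from lhprod.simulate import SyntheticConfig, simulate_recruit_tables


class TestBhModified:
    def test_density_independent_line(self):
        assert bh_modified(5.0, 2.0, 1.0, 1e12) == pytest.approx(10.0,
                                                                 rel=1e-9)

    def test_hand_case(self):
        # alpha*S^gamma = 1*10^2 = 100; 100 / (1 + 100/100) = 50
        assert bh_modified(10.0, 1.0, 2.0, 100.0) == pytest.approx(50.0)

    def test_saturation(self):
        assert bh_modified(1e8, 1.0, 1.0, 100.0) == pytest.approx(100.0,
                                                                  rel=1e-6)

    def test_zero_spawners(self):
        assert bh_modified(0.0, 3.0, 1.3, 500.0) == 0.0

    @pytest.mark.parametrize("alpha,jmax", [(0.5, 100.0), (8.0, 2e4)])
    def test_classic_bh_at_gamma_one(self, alpha, jmax):
        S = np.linspace(0.0, 200.0, 41)
        expected = alpha * S / (1 + alpha * S / jmax)
        assert np.allclose(bh_modified(S, alpha, 1.0, jmax), expected,
                           rtol=1e-12)

    def test_property_monotone_bounded_hypothesis(self):
        """Property: for any positive parameters, the curve is
        non-decreasing in S, bounded by Jmax, and exact classic
        Beverton-Holt at gamma = 1."""
        from hypothesis import given, settings
        from hypothesis import strategies as hst

        @settings(max_examples=40, deadline=None, derandomize=True)
        @given(alpha=hst.floats(0.01, 50), gamma=hst.floats(0.2, 2.5),
               jmax=hst.floats(10.0, 1e5))
        def check(alpha, gamma, jmax):
            S = np.geomspace(0.01, 1e5, 60)
            out = bh_modified(S, alpha, gamma, jmax)
            assert np.all(np.diff(out) >= -1e-9 * jmax)
            assert np.all(out <= jmax * (1 + 1e-12))

        check()

    def test_monotone_and_bounded(self, rng):
        for _ in range(10):
            a = rng.uniform(0.1, 20)
            g = rng.uniform(0.3, 2.0)
            j = rng.uniform(50, 5000)
            S = np.linspace(0.01, 1e4, 300)
            out = bh_modified(S, a, g, j)
            assert np.all(np.diff(out) >= -1e-9)
            assert np.all(out <= j + 1e-9)

    def test_nonpositive_parameters_rejected(self):
        for bad in [dict(alpha=-1.0), dict(gamma=0.0), dict(jmax=-5.0)]:
            kw = dict(alpha=1.0, gamma=1.0, jmax=10.0)
            kw.update(bad)
            with pytest.raises(ValidationError):
                bh_modified(1.0, **kw)


def _tiny_params(n_s=2, n_y=3, **kw):
    base = dict(
        streams=["a", "b"][:n_s], years=np.arange(2000, 2000 + n_y),
        alpha=np.full((4, n_s), 10.0), gamma=np.ones((4, n_s)),
        jmax=np.full((4, n_s), 1.5e4), mu_alpha=np.full(4, np.log(10.0)),
        mu_gamma=np.zeros(4), mu_jmax=np.full(4, np.log(1.5e4)),
        sigma_alpha=np.full(4, 0.3), sigma_gamma=np.full(4, 0.2),
        sigma_jmax=np.full(4, 0.3), tau_gamma=np.full(4, 0.4),
        tau_jmax=np.full(4, 0.4), lam=1.0, lam_gamma=1.0, lam_jmax=1.0,
        lam_eta=1.0, nu_jmax=1.5e4,
        beta={"spring0": {"winter1": 0.0},
              "summer0": {"winter1": 0.0, "summer1": 0.0},
              "fall0": {"winter1": 0.0, "summer1": 0.0},
              "spring1": {"winter1": 0.0, "summer1": 0.0, "winter2": 0.0}},
        loadings=np.zeros((4, n_s)), sigma_eta=np.full((4, n_s), 0.3),
        omega=np.zeros(n_y), eta=np.zeros((4, n_y, n_s)),
        log_spawners=np.full((n_y, n_s), np.log(10.0)),
    )
    base.update(kw)
    return RecruitParams(**base)


def _tiny_data(params, emi_rows, redd_rows=()):
    emi = pd.DataFrame(emi_rows, columns=["lhp", "brood_year", "stream",
                                          "log_mean", "log_sd"])
    redds = pd.DataFrame(list(redd_rows) or None,
                         columns=["year", "stream", "redds"])
    cov = pd.DataFrame(
        [(s, int(y), 0.0, 0.0, 0.0) for s in params.streams
         for y in params.years],
        columns=["stream", "brood_year", "winter1", "summer1", "winter2"])
    km = {s: 1.0 for s in params.streams}
    return RecruitData(emigrants=emi, redds=redds, habitat_km=km,
                       covariates=cov)


class TestPenalties:
    def test_hypermean_penalty_centers_natural_scale_at_one(self):
        """The mu_gamma penalty N(-tau^2/2, tau) centers exp(mu_gamma) at 1
        (lognormal mean identity E e^X = e^{m + s^2/2}): the argmin of the
        penalty is -tau^2/2, and Monte-Carlo draws confirm the identity."""
        # huge hyper-SD so the stream-level gamma terms do not pull mu_gamma
        p = _tiny_params(sigma_gamma=np.full(4, 1e6))
        tau = p.tau_gamma[0]
        grid = np.linspace(-0.5, 0.5, 2001)
        vals = []
        for mg in grid:
            p.mu_gamma[0] = mg
            vals.append(hyper_penalty_nll(p))
        argmin = grid[np.argmin(vals)]
        assert argmin == pytest.approx(-tau ** 2 / 2, abs=1e-3)
        rng = np.random.default_rng(0)
        draws = rng.normal(-tau ** 2 / 2, tau, 200_000)
        assert np.exp(draws).mean() == pytest.approx(1.0, abs=0.01)

    def test_jmax_penalty_centers_at_nu(self):
        p = _tiny_params()
        tau = p.tau_jmax[0]
        rng = np.random.default_rng(1)
        draws = rng.normal(np.log(p.nu_jmax) - tau ** 2 / 2, tau, 200_000)
        assert np.exp(draws).mean() / p.nu_jmax == pytest.approx(1.0,
                                                                 abs=0.01)

    def test_tau_to_zero_pins_hypermean(self):
        """As tau -> 0 the penalty pins mu_gamma at -tau^2/2 ~ 0: the NLL
        at a displaced hypermean explodes."""
        p = _tiny_params(tau_gamma=np.full(4, 1e-3))
        p.mu_gamma[0] = 0.1
        displaced = hyper_penalty_nll(p)
        p.mu_gamma[0] = -p.tau_gamma[0] ** 2 / 2
        pinned = hyper_penalty_nll(p)
        assert displaced - pinned > 1e3


class TestProcessError:
    def test_zero_beta_and_loadings_iid(self):
        rng = np.random.default_rng(3)
        eta = rng.normal(0, 0.3, (4, 3, 2))
        p = _tiny_params(eta=eta)
        data = _tiny_data(p, [("spring0", 2000, "a", 2.0, 0.5)])
        nll = process_error_nll(p, data)
        expected = (-st.norm.logpdf(eta, 0, 0.3).sum()
                    - st.norm.logpdf(p.omega, 0, 1).sum())
        assert nll == pytest.approx(expected, abs=1e-8)

    def test_covariate_mismatch_names_lhp(self):
        p = _tiny_params()
        p.beta["fall0"] = {"winter1": 0.0}  # summer1 missing
        data = _tiny_data(p, [("spring0", 2000, "a", 2.0, 0.5)])
        with pytest.raises(ValidationError, match="fall0"):
            process_error_nll(p, data)

    def test_factor_reflection_symmetry(self):
        """Flipping the signs of all loadings and the latent factor leaves
        the likelihood unchanged (why the first loading's sign is fixed)."""
        rng = np.random.default_rng(4)
        p = _tiny_params(loadings=rng.normal(0.4, 0.1, (4, 2)),
                         omega=rng.normal(0, 1, 3),
                         eta=rng.normal(0, 0.2, (4, 3, 2)))
        rows = [("spring0", 2000, "a", 2.3, 0.4),
                ("spring1", 2001, "b", 1.7, 0.3)]
        data = _tiny_data(p, rows)
        before = (process_error_nll(p, data) + observation_nll(p, data))
        p.loadings = -p.loadings
        p.omega = -p.omega
        after = (process_error_nll(p, data) + observation_nll(p, data))
        assert after == pytest.approx(before, rel=1e-12)

    def test_rank_one_factor_covariance(self):
        """Two series sharing the annual factor have cross-covariance
        l1 * l2 (rank-1 structure), checked on generator output."""
        cfg = SyntheticConfig(n_years=400, first_brood_year=1800,
                              streams={"a": 10.0, "b": 8.0}, seed=31,
                              subyearling_season=(60, 179),
                              yearling_season=(430, 489),
                              mode_days=(90, 120, 160, 450),
                              beta_winter1=(0.0, 0.0, 0.0, 0.0),
                              beta_summer1=(0.0, 0.0, 0.0),
                              beta_winter2=0.0)
        emi, redds, cov, habitat, truth = simulate_recruit_tables(cfg)
        rec = truth["recruitment"]
        load = truth["params"]["loadings"]
        e1 = rec[(rec.lhp == "spring0") & (rec.stream == "a")
                 ].sort_values("brood_year")["eps_J"].to_numpy()
        e2 = rec[(rec.lhp == "summer0") & (rec.stream == "b")
                 ].sort_values("brood_year")["eps_J"].to_numpy()
        expected = load[0, 0] * load[1, 1]
        emp = np.cov(e1, e2)[0, 1]
        se = 1.5 / np.sqrt(400)  # rough Monte-Carlo scale
        assert abs(emp - expected) < 3 * se


class TestObservation:
    def test_hand_gaussian_term(self):
        """M-bar* = 2, log J = 1, sigma = 1: the penalty term is
        0.5 + log(sqrt(2 pi)) ~ 1.4189."""
        p = _tiny_params(alpha=np.full((4, 2), np.e),
                         jmax=np.full((4, 2), 1e12),
                         log_spawners=np.zeros((3, 2)))
        data = _tiny_data(p, [("spring0", 2000, "a", 2.0, 1.0)])
        nll = observation_nll(p, data)
        assert nll == pytest.approx(0.5 + np.log(np.sqrt(2 * np.pi)),
                                    abs=1e-9)

    def test_exact_match_leaves_normalizer(self):
        p = _tiny_params(alpha=np.full((4, 2), np.e),
                         jmax=np.full((4, 2), 1e12),
                         log_spawners=np.zeros((3, 2)))
        data = _tiny_data(p, [("spring0", 2000, "a", 1.0, 0.7)])
        assert observation_nll(p, data) == pytest.approx(
            np.log(0.7 * np.sqrt(2 * np.pi)), abs=1e-9)

    def test_missing_sigma_rejected(self):
        p = _tiny_params()
        with pytest.raises(ValidationError):
            _tiny_data(p, [("spring0", 2000, "a", 2.0, np.nan)])


@pytest.fixture(scope="module")
def small():
    cfg = SyntheticConfig(n_years=6, streams={"a": 10.0, "b": 8.0},
                          seed=41, subyearling_season=(60, 179),
                          yearling_season=(430, 489),
                          mode_days=(90, 120, 160, 450))
    emi, redds, cov, habitat, _ = simulate_recruit_tables(cfg)
    data = RecruitData(emigrants=emi, redds=redds, habitat_km=habitat,
                       covariates=cov)
    return _RecruitModel(data, RecruitConfig(estimate_lambdas=False))


class TestPackedModel:

    def test_eta_marginalization_matches_quadrature(self, small):
        """The analytic integration of the idiosyncratic error equals 1-D
        quadrature of the explicit obs x prior product for one cell."""
        m_obs, pred0, sig_m, sig_e = 2.1, 1.4, 0.25, 0.4

        def integrand(eta):
            return (st.norm.pdf(m_obs, pred0 + eta, sig_m)
                    * st.norm.pdf(eta, 0, sig_e))

        val, _ = integrate.quad(integrand, -5, 5, epsabs=1e-13)
        packed = st.norm.logpdf(m_obs, pred0, np.hypot(sig_m, sig_e))
        assert packed == pytest.approx(np.log(val), abs=1e-9)

    def test_conditional_eta_minimizes_explicit_joint(self, small):
        """params() recovers eta as the conditional mode: perturbing any
        eta away from it increases the explicit (unmarginalized) NLL."""
        theta, u0 = small.start_values()
        params = small.params(theta, u0)
        data = small.data
        cfg = RecruitConfig(estimate_lambdas=False)
        base = recruit_joint_nll(params, data, cfg)
        k = np.unravel_index(np.argmax(np.abs(params.eta)), params.eta.shape)
        for delta in (-0.05, 0.05):
            params.eta[k] += delta
            assert recruit_joint_nll(params, data, cfg) > base
            params.eta[k] -= delta

    def test_joint_nll_finite_and_gradient_consistent(self, small, rng):
        theta, u0 = small.start_values()
        u = u0 + 0.05 * rng.standard_normal(small.n_random)
        f = small.joint_nll(theta, u)
        assert np.isfinite(f)
        g = small.grad_random(theta, u)
        for i in rng.choice(small.n_random, 10, replace=False):
            h = 1e-6
            up, um = u.copy(), u.copy()
            up[i] += h
            um[i] -= h
            fd = (small.joint_nll(theta, up) - small.joint_nll(theta, um)) / (2 * h)
            assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-6)


class TestPredict:
    shapes = pd.DataFrame([
        ("spring0", "a", 8.0, 1.5, 12000.0),
        ("summer0", "a", 10.0, 1.0, 9000.0),
        ("fall0", "a", 20.0, 1.0, 1480.0),
        ("spring1", "a", 60.0, 0.4, 2500.0),
    ], columns=["lhp", "stream", "alpha", "gamma", "jmax"])

    def test_proportions_sum_to_one(self):
        out = predict_curves(self.shapes, np.linspace(0.5, 60, 40))
        sums = out.groupby("S_per_km")["proportion"].sum()
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_young_proportion_monotone_when_gamma_exceeds_one(self):
        """gamma_young > 1 with gamma_old < 1: the younger LHP's share of
        emigrants is non-decreasing in spawner density."""
        grid = np.linspace(0.5, 60, 200)
        out = predict_curves(self.shapes, grid)
        prop = out[out.lhp == "spring0"].sort_values("S_per_km")[
            "proportion"].to_numpy()
        assert np.all(np.diff(prop) >= -1e-9)
        old = out[out.lhp == "spring1"].sort_values("S_per_km")[
            "proportion"].to_numpy()
        assert np.all(np.diff(old) <= 1e-9)

    def test_single_lhp_degenerate(self):
        one = self.shapes.iloc[[0]]
        out = predict_curves(one, np.linspace(1, 30, 10))
        assert np.allclose(out["proportion"], 1.0)

    def test_prediction_interval_contains_point(self):
        psd = {(l, "a"): 0.4 for l in LHP_LABELS}
        out = predict_curves(self.shapes, np.linspace(1, 30, 5), psd)
        assert np.all(out["pi_lo"] <= out["J_per_km"] + 1e-12)
        assert np.all(out["pi_hi"] >= out["J_per_km"] - 1e-12)


def test_fit_recruit_requires_streams_and_years():
    cfg = SyntheticConfig(n_years=6, streams={"a": 10.0, "b": 8.0}, seed=1,
                          subyearling_season=(60, 179),
                          yearling_season=(430, 489),
                          mode_days=(90, 120, 160, 450))
    emi, redds, cov, habitat, _ = simulate_recruit_tables(cfg)
    solo = emi[emi.stream == "a"]
    data = RecruitData(emigrants=solo, redds=redds,
                       habitat_km={"a": 10.0}, covariates=cov)
    with pytest.raises(ValidationError):
        fit_recruit(data)
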