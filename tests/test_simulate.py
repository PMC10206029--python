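"""Synthetic-data generator: seeding, degenerate limits, and the statistical
structure the estimation models assume."""

import numpy as np
import pytest
from scipy.special import expit, logit

from lhprod.errors import ConfigError
from lhprod.simulate import (SyntheticConfig, _ar1, nb_sample,
                             simulate_dataset, simulate_recruit_tables,
                             simulate_trap_dataset)

TINY = dict(
    n_years=3,
    streams={"a": 10.0, "b": 8.0},
    subyearling_season=(60, 179),
    yearling_season=(430, 489),
    mode_days=(90, 120, 160, 450),
    mode_sds=(10.0, 12.0, 8.0, 10.0),
    trials_per_year=4,
)


class TestConfigValidation:
    def test_rho_out_of_range_names_field(self):
        with pytest.raises(ConfigError, match="rho_eps"):
            SyntheticConfig(rho_eps=1.2)

    def test_nonpositive_habitat_names_stream(self):
        with pytest.raises(ConfigError, match="habitat_length_km"):
            SyntheticConfig(streams={"chiwawa": -1.0})

    def test_overlapping_seasons_rejected(self):
        with pytest.raises(ConfigError, match="season"):
            SyntheticConfig(subyearling_season=(60, 440),
                            yearling_season=(430, 549))


def test_same_seed_bit_identical_different_seed_differs():
    a = simulate_dataset(SyntheticConfig(**TINY, seed=5))
    b = simulate_dataset(SyntheticConfig(**TINY, seed=5))
    c = simulate_dataset(SyntheticConfig(**TINY, seed=6))
    ka = ("a", "subyearling")
    assert np.array_equal(a.trap[ka].catch, b.trap[ka].catch,
                          equal_nan=True)
    assert np.array_equal(a.redds["redds"], b.redds["redds"])
    assert not np.array_equal(a.trap[ka].catch, c.trap[ka].catch,
                              equal_nan=True)


def test_flat_profile_when_all_process_noise_zero():
    """sigma_eps = sigma_delta = 0 and no seasonal template: each year's
    daily log abundance is flat at mu_m."""
    cfg = SyntheticConfig(**TINY, seed=1, sigma_eps=0.0, sigma_delta=0.0,
                          profile_scale=0.0)
    ds, truth = simulate_trap_dataset(cfg, age_class="subyearling")
    log_m = np.log(truth["m"])
    for y in range(cfg.n_years):
        assert np.allclose(log_m[y], truth["mu_m"][y], atol=1e-12)


def test_deterministic_observation_switch():
    """With p = 1 forced and the deterministic switch on, catch equals
    round(m) on operating days."""
    cfg = SyntheticConfig(**TINY, seed=2, beta0_p=30.0, beta1_p=0.0,
                          sigma_iota=0.0, sigma_kappa=0.0, sigma_nu=0.0,
                          sigma_xi=0.0, deterministic_obs=True,
                          outage_prob=0.0)
    ds, truth = simulate_trap_dataset(cfg, age_class="subyearling")
    assert np.allclose(truth["p"], 1.0)
    assert np.array_equal(ds.catch, np.round(truth["m"]))


def test_poisson_limit_of_catch_noise():
    """p = 1 and phi -> 0: catches are Poisson around latent abundance, so
    the mean ratio catch/m is ~1 and variance ~ mean."""
    cfg = SyntheticConfig(**TINY, seed=3, beta0_p=30.0, sigma_iota=0.0,
                          sigma_kappa=0.0, sigma_nu=0.0, sigma_xi=0.0,
                          nb_phi=0.0, outage_prob=0.0)
    ds, truth = simulate_trap_dataset(cfg, age_class="subyearling")
    ratio = np.nansum(ds.catch) / truth["m"].sum()
    assert abs(ratio - 1.0) < 0.02


def test_catch_marks_and_outages():
    sim = simulate_dataset(SyntheticConfig(**TINY, seed=7, outage_prob=0.05))
    for ds in sim.trap.values():
        obs = ds.operating
        assert np.all(np.isnan(ds.catch[~obs]))
        vals = ds.catch[obs]
        assert np.all(vals >= 0) and np.all(vals == np.round(vals))
        assert np.all(ds.recaptured <= ds.released)


def test_four_timing_modes_in_daily_series():
    """The pooled daily-abundance series has four local maxima near the
    configured mode days (smoothed, on the brood-cycle axis)."""
    cfg = SyntheticConfig(n_years=4, seed=11)
    sim = simulate_dataset(cfg)
    acc = {}
    for (stream, age), m in sim.truth.m.items():
        days = sim.trap[(stream, age)].days
        for ti, d in enumerate(days):
            acc.setdefault(int(d), []).append(m[:, ti].mean())
    days = np.array(sorted(acc))
    series = np.array([np.mean(acc[d]) for d in days])
    kern = np.ones(9) / 9
    sm = np.convolve(series, kern, mode="same")
    maxima = [days[i] for i in range(4, len(sm) - 4)
              if sm[i] == sm[i - 4:i + 5].max() and sm[i] > 0.01 * sm.max()]
    # collapse plateaus
    distinct = []
    for d in maxima:
        if not distinct or d - distinct[-1] > 20:
            distinct.append(d)
    assert len(distinct) == 4
    for d, mode in zip(distinct, cfg.mode_days):
        assert abs(d - mode) <= 15


def test_nb_sample_mean_variance():
    """Monte-Carlo mean/variance of NB catches match mu and mu + mu^2 phi."""
    rng = np.random.default_rng(0)
    mu, phi, n = 8.0, 0.3, 40_000
    draws = nb_sample(rng, np.full(n, mu), phi)
    assert abs(draws.mean() - mu) / mu < 0.02
    var_expect = mu + mu ** 2 * phi
    assert abs(draws.var() - var_expect) / var_expect < 0.07
    # Poisson limit
    draws0 = nb_sample(rng, np.full(n, mu), 0.0)
    assert abs(draws0.var() - mu) / mu < 0.05


def test_ar1_autocorrelation_and_stationarity():
    rng = np.random.default_rng(1)
    x = _ar1(rng, (200, 400), 0.7, 0.3)
    flat = x[:, 1:].ravel()
    lag = x[:, :-1].ravel()
    r = np.corrcoef(flat, lag)[0, 1]
    assert abs(r - 0.7) < 0.02
    # marginal variance constant across t at sigma^2/(1-rho^2)
    v = x.var(axis=0)
    target = 0.3 ** 2 / (1 - 0.7 ** 2)
    assert abs(v[0] - target) / target < 0.25
    assert abs(v[-1] - target) / target < 0.25


def test_recapture_fraction_matches_inverse_logit():
    """With all capture random effects off, the pooled recapture fraction
    approaches logit^{-1}(beta0) within binomial error."""
    p_true = 0.12
    cfg = SyntheticConfig(**{**TINY, "trials_per_year": 40}, seed=4,
                          beta0_p=float(logit(p_true)), beta1_p=0.0,
                          sigma_iota=0.0, sigma_kappa=0.0, sigma_nu=0.0,
                          sigma_xi=0.0, released_per_trial=200)
    ds, _ = simulate_trap_dataset(cfg, age_class="subyearling")
    frac = ds.recaptured.sum() / ds.released.sum()
    n_tot = ds.released.sum()
    se = np.sqrt(p_true * (1 - p_true) / n_tot)
    assert abs(frac - p_true) < 4 * se


def test_redd_observation_lognormal_sd():
    cfg = SyntheticConfig(n_years=200, first_brood_year=1900,
                          streams={"a": 10.0}, seed=9,
                          subyearling_season=(60, 179),
                          yearling_season=(430, 489),
                          mode_days=(90, 120, 160, 450),
                          couple_recruitment=False)
    sim = simulate_dataset(cfg)
    merged = sim.redds.merge(sim.truth.spawners, on=["year", "stream"])
    err = np.log(merged["redds"] / merged["S_total"])
    assert abs(err.std() - 0.1) < 0.02
    assert abs(err.mean()) < 0.02


def test_coupled_window_totals_consistency():
    """Coupled mode: daily abundances sum exactly to the recruitment-layer
    window totals, and those equal J_per_km * habitat length."""
    sim = simulate_dataset(SyntheticConfig(**TINY, seed=13))
    wt = sim.truth.window_totals.set_index(["lhp", "brood_year", "stream"])
    rec = sim.truth.recruitment.set_index(["lhp", "brood_year", "stream"])
    for key, row in wt.iterrows():
        expected = rec.loc[key, "J_per_km"] * sim.habitat[key[2]]
        assert row["M"] == pytest.approx(expected, rel=1e-9)
    for m in sim.truth.m.values():
        assert np.all(m > 0)


def test_recruit_tables_generator():
    emi, redds, cov, habitat, truth = simulate_recruit_tables(
        SyntheticConfig(**TINY, seed=21))
    assert len(emi) == 4 * 3 * 2  # lhp x years x streams
    assert set(emi.columns) >= {"lhp", "brood_year", "stream", "log_mean",
                                "log_sd"}
    # covariates Z-scored within stream
    g = cov.groupby("stream")[["winter1", "summer1", "winter2"]].mean()
    assert np.all(np.abs(g.to_numpy()) < 1e-8)
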