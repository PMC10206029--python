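"""Seeded synthetic datasets with the statistical structure the pipeline assumes.

The generator emulates a multi-stream juvenile salmonid monitoring program:

* seasonal multi-modal emigration with four timing modes on a single
  brood-cycle day axis (day 1 = Jan 1 of the first calendar year after
  spawning; yearling days exceed 365), with no emigration in the winter gap
  between the subyearling and yearling trap seasons;
* a random-walk seasonal log-abundance profile with stationary AR(1) annual
  deviations around it;
* discharge-dependent binomial trap efficiency with year and week random
  effects, negative-binomial daily catches, and trap outage gaps;
* mark-recapture trials (releases/recaptures) on scheduled days;
* log-normally observed spawner (redd) counts, and modified Beverton-Holt
  emigrant production with rank-1-factor-correlated, covariate-driven
  process errors.

Two generation modes are provided.  The *literal* migration layer draws the
daily model exactly as the estimation model assumes (year mean + random-walk
profile + AR(1) deviations), which is what parameter-recovery tests need.
The *coupled* whole-pipeline mode instead sets window totals from the
spawner-recruit layer and distributes them over days within windows, so that
all three stages cohere end to end (the single year-mean daily model cannot
represent arbitrary per-window totals exactly; this is deliberate, mild model
misspecification of the kind field data carries).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from lhprod.errors import ConfigError
from lhprod.migration import TrapDataset

__all__ = [
    "LHP_LABELS",
    "SyntheticConfig",
    "TruthRecord",
    "SimulatedData",
    "simulate_dataset",
    "simulate_trap_dataset",
    "simulate_recruit_tables",
    "nb_sample",
]

LHP_LABELS = ("spring0", "summer0", "fall0", "spring1")

_LOG15 = float(np.log(15.0))


@dataclass
class SyntheticConfig:
    """True parameter values and design of the synthetic monitoring program.

    Defaults are the stated synthetic world of this package: three streams,
    eight brood years, four emigration modes (brood-cycle days 100/200/290
    for subyearlings, 470 for yearlings), trap efficiency around 8% with a
    negative discharge effect, and recruitment shape parameters matching the
    fitted pattern of the study system (accelerating spring-subyearling
    production, decelerating yearling production).
    """

    n_years: int = 8
    first_brood_year: int = 2000
    streams: dict = field(default_factory=lambda: {
        "chiwawa": 32.0, "nason": 22.0, "white": 16.0})
    seed: int = 0

    # seasons & timing (brood-cycle days, inclusive)
    subyearling_season: tuple = (60, 299)
    yearling_season: tuple = (430, 549)
    mode_days: tuple = (100, 200, 290, 470)
    mode_sds: tuple = (14.0, 30.0, 12.0, 18.0)
    mode_weights: tuple = (0.35, 0.30, 0.15, 0.20)

    # migration layer (literal mode)
    mu_m_mean: float = 4.5
    mu_m_sd: float = 0.5
    profile_scale: float = 1.0
    sigma_delta: float = 0.03
    sigma_eps: float = 0.3
    rho_eps: float = 0.7
    nb_phi: float = 0.05

    # capture probability
    beta0_p: float = -2.44  # logit(0.08)
    beta1_p: float = -0.5
    sigma_iota: float = 0.3
    sigma_kappa: float = 0.15
    sigma_nu: float = 0.3
    sigma_xi: float = 0.2

    # recruitment layer (per-LHP hypermeans, per-km scale)
    alpha_mean: tuple = (60.0, 40.0, 25.0, 60.0)
    gamma_mean: tuple = (1.5, 1.1, 1.0, 0.4)
    jmax_mean: tuple = (12_000.0, 9_000.0, 1_480.0, 2_500.0)
    stream_sd_alpha: float = 0.3
    stream_sd_gamma: float = 0.08
    stream_sd_jmax: float = 0.3
    beta_winter1: tuple = (0.37, 0.10, -0.13, -0.22)
    beta_summer1: tuple = (0.05, -0.14, -0.05)  # summer0, fall0, spring1
    beta_winter2: float = -0.10  # spring1 only
    loading_mean: float = 0.35
    loading_sd: float = 0.10
    sigma_eta: float = 0.25

    # spawners
    spawner_log_mean: float = _LOG15  # per-km
    spawner_log_sd: float = 0.7
    redd_obs_sd: float = 0.1

    # discharge (m^3/s): seasonal template x lognormal daily noise
    discharge_base: float = 3.0
    freshet_day: int = 140
    freshet_sd: float = 35.0
    freshet_amp: float = 25.0
    autumn_day: int = 300
    autumn_sd: float = 25.0
    autumn_amp: float = 8.0
    discharge_noise_sd: float = 0.15

    # outages & mark-recapture design
    outage_prob: float = 0.02
    outage_mean_len: float = 3.0
    trials_per_year: int = 12
    released_per_trial: int = 100

    # switches
    couple_recruitment: bool = True
    deterministic_obs: bool = False
    mstar_obs_sd: float = 0.1  # direct emigrant-summary generation

    def __post_init__(self):
        self.validate()

    def validate(self):
        for name in ("sigma_delta", "sigma_eps", "nb_phi", "sigma_iota",
                     "sigma_kappa", "sigma_nu", "sigma_xi", "sigma_eta",
                     "stream_sd_alpha", "stream_sd_gamma", "stream_sd_jmax",
                     "redd_obs_sd", "mstar_obs_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if abs(self.rho_eps) >= 1:
            raise ConfigError("rho_eps must satisfy |rho_eps| < 1")
        for s, km in self.streams.items():
            if km <= 0:
                raise ConfigError(f"streams[{s!r}]: habitat_length_km must be > 0")
        if self.n_years < 1:
            raise ConfigError("n_years must be >= 1")
        s0, s1 = self.subyearling_season
        y0, y1 = self.yearling_season
        if not (s0 < s1 < y0 < y1):
            raise ConfigError(
                "subyearling_season must precede yearling_season (winter gap)")
        m = self.mode_days
        if not (s0 <= m[0] < m[1] < m[2] <= s1 and y0 <= m[3] <= y1):
            raise ConfigError(
                "mode_days must place three modes in the subyearling season "
                "and one in the yearling season")
        if not 0 <= self.outage_prob < 1:
            raise ConfigError("outage_prob must be in [0, 1)")

    def replace(self, **kw):
        return dataclasses.replace(self, **kw)

    def brood_years(self):
        return np.arange(self.first_brood_year,
                         self.first_brood_year + self.n_years)

    def true_generation_windows(self):
        """Window bounds used to allocate recruitment totals over days:
        boundaries halfway between adjacent subyearling modes."""
        s0, s1 = self.subyearling_season
        y0, y1 = self.yearling_season
        m = self.mode_days
        c1 = (m[0] + m[1]) // 2
        c2 = (m[1] + m[2]) // 2
        return [("spring0", s0, c1), ("summer0", c1 + 1, c2),
                ("fall0", c2 + 1, s1), ("spring1", y0, y1)]

    def params_dict(self):
        d = dataclasses.asdict(self)
        d["streams"] = dict(self.streams)
        return d


@dataclass
class TruthRecord:
    """Every latent quantity generated, keyed like the estimation outputs."""

    m: dict  # (stream, age) -> (Y, T) latent daily abundance
    p: dict  # (stream, age) -> (Y, T) daily capture probability
    migration: dict  # (stream, age) -> dict of generating effects
    window_totals: pd.DataFrame  # lhp, brood_year, stream, M
    recruitment: pd.DataFrame | None  # lhp, brood_year, stream, J_per_km, eps_J
    omega: np.ndarray | None
    spawners: pd.DataFrame  # year, stream, S_per_km, S_total
    covariates: pd.DataFrame | None
    params: dict


@dataclass
class SimulatedData:
    trap: dict  # (stream, age_class) -> TrapDataset
    redds: pd.DataFrame  # year, stream, redds
    discharge: pd.DataFrame  # stream, date, discharge_cms
    habitat: dict  # stream -> km
    truth: TruthRecord


# ----------------------------------------------------------------------
# elementary samplers
# ----------------------------------------------------------------------


def nb_sample(rng, mu, phi):
    """Negative-binomial draws with mean mu, variance mu + mu^2 * phi, via
    the gamma-Poisson mixture; collapses to Poisson as phi -> 0."""
    mu = np.asarray(mu, dtype=float)
    if phi < 1e-12:
        return rng.poisson(mu)
    r = 1.0 / phi
    lam = rng.gamma(shape=r, scale=mu / r)
    return rng.poisson(lam)


def _ar1(rng, shape, rho, sigma):
    """Stationary AR(1) series along the last axis."""
    shape = tuple(np.atleast_1d(shape))
    out = np.zeros(shape)
    if sigma == 0.0:
        return out
    n = shape[-1]
    out[..., 0] = rng.normal(0.0, sigma / np.sqrt(1 - rho ** 2), shape[:-1])
    for t in range(1, n):
        out[..., t] = rho * out[..., t - 1] + rng.normal(0.0, sigma, shape[:-1])
    return out


def _random_walk(rng, n, sigma):
    """Random walk pinned to 0 at the first day."""
    if sigma == 0.0:
        return np.zeros(n)
    steps = rng.normal(0.0, sigma, n - 1)
    return np.concatenate([[0.0], np.cumsum(steps)])


def _season_template(cfg, days, age_class):
    """Log of the multi-modal emigration profile over the given days,
    shifted so the first day is 0 (the daily model's reference-day
    convention)."""
    days = np.asarray(days, dtype=float)
    idx = [3] if age_class == "yearling" else [0, 1, 2]
    dens = np.zeros_like(days)
    for h in idx:
        w, m, s = cfg.mode_weights[h], cfg.mode_days[h], cfg.mode_sds[h]
        dens += w * np.exp(-0.5 * ((days - m) / s) ** 2) / s
    logd = np.log(np.maximum(dens, 1e-300))
    return cfg.profile_scale * (logd - logd[0])


# ----------------------------------------------------------------------
# discharge, spawners, covariates
# ----------------------------------------------------------------------


def _simulate_discharge(cfg, rng):
    """Daily discharge per stream: snowmelt freshet + autumn rain peak times
    lognormal noise, over all calendar years the pipeline needs."""
    y0 = cfg.first_brood_year
    years = np.arange(y0, y0 + cfg.n_years + 2)
    frames = []
    for si, stream in enumerate(cfg.streams):
        scale = 1.0 + 0.4 * si  # streams differ in size
        for year in years:
            dates = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
            doy = dates.dayofyear.to_numpy().astype(float)
            tmpl = (cfg.discharge_base
                    + cfg.freshet_amp * np.exp(
                        -0.5 * ((doy - cfg.freshet_day) / cfg.freshet_sd) ** 2)
                    + cfg.autumn_amp * np.exp(
                        -0.5 * ((doy - cfg.autumn_day) / cfg.autumn_sd) ** 2))
            noise = np.exp(rng.normal(0.0, cfg.discharge_noise_sd, doy.size))
            frames.append(pd.DataFrame({
                "stream": stream, "date": dates,
                "discharge_cms": scale * tmpl * noise,
            }))
    return pd.concat(frames, ignore_index=True)


def _simulate_spawners(cfg, rng):
    rows = []
    for stream, km in cfg.streams.items():
        s_perkm = np.exp(rng.normal(cfg.spawner_log_mean, cfg.spawner_log_sd,
                                    cfg.n_years))
        for y, yr in enumerate(cfg.brood_years()):
            rows.append((int(yr), stream, float(s_perkm[y]),
                         float(s_perkm[y] * km)))
    return pd.DataFrame(rows, columns=["year", "stream", "S_per_km", "S_total"])


def _observe_redds(spawners, cfg, rng):
    obs = spawners.copy()
    noise = np.exp(rng.normal(0.0, cfg.redd_obs_sd, len(obs)))
    obs["redds"] = obs["S_total"] * noise
    return obs[["year", "stream", "redds"]]


def _covariates_from_discharge(discharge, brood_years):
    """Stream-discharge covariates per (stream, brood year): log max daily
    discharge of winter 1 (Nov-Feb) and winter 2, mean daily discharge of
    summer 1 (Jun-Sep); Z-scored within stream across brood years."""
    dis = discharge.copy()
    dis["date"] = pd.to_datetime(dis["date"])
    rows = []
    for stream, g in dis.groupby("stream"):
        g = g.set_index("date").sort_index()
        for y in brood_years:
            w1 = g.loc[f"{y}-11-01":f"{y + 1}-02-28", "discharge_cms"]
            s1 = g.loc[f"{y + 1}-06-01":f"{y + 1}-09-30", "discharge_cms"]
            w2 = g.loc[f"{y + 1}-11-01":f"{y + 2}-02-28", "discharge_cms"]
            rows.append((stream, int(y),
                         np.log(w1.max()) if len(w1) else np.nan,
                         s1.mean() if len(s1) else np.nan,
                         np.log(w2.max()) if len(w2) else np.nan))
    cov = pd.DataFrame(rows, columns=["stream", "brood_year",
                                      "winter1", "summer1", "winter2"])
    for c in ("winter1", "summer1", "winter2"):
        cov[c] = cov.groupby("stream")[c].transform(
            lambda x: (x - x.mean()) / (x.std(ddof=0) or 1.0))
    return cov


# ----------------------------------------------------------------------
# recruitment layer
# ----------------------------------------------------------------------


def _beta_table(cfg):
    """Per-LHP covariate coefficients on the (winter1, summer1, winter2)
    design; zeros encode covariates excluded for that LHP."""
    b = np.zeros((4, 3))
    b[:, 0] = cfg.beta_winter1
    b[1:, 1] = cfg.beta_summer1
    b[3, 2] = cfg.beta_winter2
    return b


def _simulate_recruitment(cfg, rng, spawners, covariates):
    """Per-stream shape parameters, latent factor, process errors and
    emigrant totals for each LHP x brood year x stream."""
    from lhprod.recruit import bh_modified

    streams = list(cfg.streams)
    n_s, n_y = len(streams), cfg.n_years
    la = np.log(cfg.alpha_mean)[:, None] + rng.normal(
        0.0, cfg.stream_sd_alpha, (4, n_s))
    lg = np.log(cfg.gamma_mean)[:, None] + rng.normal(
        0.0, cfg.stream_sd_gamma, (4, n_s))
    lj = np.log(cfg.jmax_mean)[:, None] + rng.normal(
        0.0, cfg.stream_sd_jmax, (4, n_s))
    loadings = rng.normal(cfg.loading_mean, cfg.loading_sd, (4, n_s))
    loadings[0, 0] = abs(loadings[0, 0])  # sign convention of the factor
    omega = rng.normal(0.0, 1.0, n_y)
    eta = rng.normal(0.0, cfg.sigma_eta, (4, n_y, n_s))
    beta = _beta_table(cfg)
    cov = covariates.set_index(["stream", "brood_year"])
    spw = spawners.set_index(["year", "stream"])
    rows = []
    for h, lhp in enumerate(LHP_LABELS):
        for yi, yr in enumerate(cfg.brood_years()):
            for si, stream in enumerate(streams):
                x = cov.loc[(stream, yr), ["winter1", "summer1", "winter2"]]
                xb = float(np.asarray(x, dtype=float) @ beta[h])
                s_perkm = spw.loc[(yr, stream), "S_per_km"]
                j_exp = bh_modified(s_perkm, np.exp(la[h, si]),
                                    np.exp(lg[h, si]), np.exp(lj[h, si]))
                eps = xb + omega[yi] * loadings[h, si] + eta[h, yi, si]
                rows.append((lhp, int(yr), stream, float(j_exp), float(eps),
                             float(j_exp * np.exp(eps))))
    rec = pd.DataFrame(rows, columns=["lhp", "brood_year", "stream",
                                      "J_expected_per_km", "eps_J",
                                      "J_per_km"])
    truth_params = dict(
        log_alpha=la, log_gamma=lg, log_jmax=lj, loadings=loadings,
        beta=beta, sigma_eta=cfg.sigma_eta,
    )
    return rec, omega, truth_params


# ----------------------------------------------------------------------
# migration layer
# ----------------------------------------------------------------------


def _cycle_dates(year, days):
    """ISO dates for brood-cycle days of a given brood year (day 1 = Jan 1
    of brood_year + 1)."""
    origin = pd.Timestamp(f"{year + 1}-01-01")
    return origin + pd.to_timedelta(np.asarray(days) - 1, unit="D")


def _stream_discharge_matrix(discharge, stream, years, days):
    dis = discharge[discharge["stream"] == stream].set_index("date")
    dis.index = pd.to_datetime(dis.index)
    out = np.empty((len(years), len(days)))
    for yi, yr in enumerate(years):
        dates = _cycle_dates(yr, days)
        out[yi] = dis.reindex(dates)["discharge_cms"].to_numpy()
    return out


def _simulate_outages(cfg, rng, Y, T):
    """Geometric-run outage gaps: each day starts a gap with outage_prob."""
    op = np.ones((Y, T), dtype=bool)
    if cfg.outage_prob <= 0:
        return op
    for y in range(Y):
        t = 0
        while t < T:
            if rng.random() < cfg.outage_prob:
                run = 1 + rng.geometric(1.0 / max(cfg.outage_mean_len, 1.0))
                op[y, t:t + run] = False
                t += run
            else:
                t += 1
    return op


def _capture_layer(cfg, rng, Y, T, discharge):
    vals = discharge[np.isfinite(discharge)]
    mu, sd = float(vals.mean()), float(vals.std()) or 1.0
    Dz = (discharge - mu) / sd
    W = (T + 6) // 7
    iota = rng.normal(cfg.beta0_p, cfg.sigma_iota, Y)
    kappa = rng.normal(cfg.beta1_p, cfg.sigma_kappa, Y)
    nu = rng.normal(0.0, cfg.sigma_nu, W)
    xi = rng.normal(0.0, cfg.sigma_xi, (Y, W))
    w = np.arange(T) // 7
    logitp = iota[:, None] + kappa[:, None] * Dz + nu[w][None, :] + xi[:, w]
    p = 1.0 / (1.0 + np.exp(-logitp))
    effects = dict(iota=iota, kappa=kappa, nu=nu, xi=xi)
    return p, effects


def _observe_catches(cfg, rng, m, p, operating):
    mu_c = m * p
    if cfg.deterministic_obs:
        catch = np.round(m * p)
    else:
        catch = nb_sample(rng, mu_c, cfg.nb_phi).astype(float)
    catch = np.where(operating, catch, np.nan)
    return catch


def _schedule_trials(cfg, rng, Y, T, operating, p):
    td, ty, rel, rec = [], [], [], []
    if cfg.trials_per_year <= 0:
        return (np.empty(0, int),) * 2 + (np.empty(0, int),) * 2
    sched = np.linspace(0, T - 1, cfg.trials_per_year).astype(int)
    for y in range(Y):
        for t in sched:
            tt = t
            while tt < T and not operating[y, tt]:
                tt += 1
            if tt >= T:
                continue
            n = cfg.released_per_trial
            k = rng.binomial(n, p[y, tt])
            td.append(tt)
            ty.append(y)
            rel.append(n)
            rec.append(k)
    return (np.array(td, int), np.array(ty, int),
            np.array(rel, int), np.array(rec, int))


def _literal_daily_layer(cfg, rng, days, age_class, Y):
    """Daily latent abundance drawn exactly from the estimation model's
    process equations."""
    T = len(days)
    mu_m = rng.normal(cfg.mu_m_mean, cfg.mu_m_sd, Y)
    delta = _season_template(cfg, days, age_class) + _random_walk(
        rng, T, cfg.sigma_delta)
    eps = _ar1(rng, (Y, T), cfg.rho_eps, cfg.sigma_eps)
    log_m = mu_m[:, None] + delta[None, :] + eps
    return np.exp(log_m), dict(mu_m=mu_m, delta=delta, eps=eps)


def _coupled_daily_layer(cfg, rng, days, age_class, Y, window_totals):
    """Distribute recruitment-layer window totals over days: mode-shaped
    share times a shared random-walk roughness and AR(1) year deviations."""
    T = len(days)
    rough = _random_walk(rng, T, cfg.sigma_delta)
    eps = _ar1(rng, (Y, T), cfg.rho_eps, cfg.sigma_eps)
    m = np.zeros((Y, T))
    windows = [w for w in cfg.true_generation_windows()
               if (w[0] == "spring1") == (age_class == "yearling")]
    for lab, t0, tf in windows:
        h = LHP_LABELS.index(lab)
        msk = (days >= t0) & (days <= tf)
        dens = np.exp(-0.5 * ((days[msk] - cfg.mode_days[h])
                              / cfg.mode_sds[h]) ** 2)
        share = dens[None, :] * np.exp(rough[None, msk] + eps[:, msk])
        share = share / share.sum(axis=1, keepdims=True)
        for yi in range(Y):
            m[yi, msk] = window_totals[(lab, yi)] * share[yi]
    truth = dict(rough=rough, eps=eps)
    return m, truth


# ----------------------------------------------------------------------
# public entry points
# ----------------------------------------------------------------------


def simulate_trap_dataset(cfg: SyntheticConfig, stream=None,
                          age_class="subyearling", rng=None,
                          discharge=None):
    """One stream x age-class trap dataset drawn from the literal daily
    model; returns (TrapDataset, truth dict)."""
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if stream is None:
        stream = next(iter(cfg.streams))
    lo, hi = (cfg.yearling_season if age_class == "yearling"
              else cfg.subyearling_season)
    days = np.arange(lo, hi + 1)
    years = cfg.brood_years()
    Y, T = len(years), len(days)
    if discharge is None:
        discharge = _simulate_discharge(cfg, rng)
    dmat = _stream_discharge_matrix(discharge, stream, years, days)
    m, mig_truth = _literal_daily_layer(cfg, rng, days, age_class, Y)
    p, cap_truth = _capture_layer(cfg, rng, Y, T, dmat)
    operating = _simulate_outages(cfg, rng, Y, T)
    catch = _observe_catches(cfg, rng, m, p, operating)
    td, ty, rel, rec = _schedule_trials(cfg, rng, Y, T, operating, p)
    ds = TrapDataset(
        stream=stream, age_class=age_class, days=days, years=years,
        catch=catch, operating=operating, discharge=dmat,
        trial_day=days[td] if td.size else np.empty(0, int),
        trial_year=years[ty] if ty.size else np.empty(0, int),
        released=rel, recaptured=rec,
    )
    truth = dict(m=m, p=p, **mig_truth, **cap_truth)
    return ds, truth


def simulate_dataset(cfg: SyntheticConfig) -> SimulatedData:
    """Full coupled synthetic monitoring program.

    Recruitment layer first (spawners, covariates, process errors, window
    totals per LHP x brood year x stream), then the daily migration and
    observation layers per stream x age-class, with window totals allocated
    over days.  Reproducible: the same seed yields bit-identical outputs.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    discharge = _simulate_discharge(cfg, rng)
    spawners = _simulate_spawners(cfg, rng)
    redds = _observe_redds(spawners, cfg, rng)
    covariates = _covariates_from_discharge(discharge, cfg.brood_years())
    years = cfg.brood_years()
    Y = cfg.n_years

    recruitment, omega, rec_params = (None, None, None)
    if cfg.couple_recruitment:
        recruitment, omega, rec_params = _simulate_recruitment(
            cfg, rng, spawners, covariates)
        rec_idx = recruitment.set_index(["lhp", "brood_year", "stream"])

    trap, m_truth, p_truth, mig_truth = {}, {}, {}, {}
    window_rows = []
    for stream, km in cfg.streams.items():
        for age_class in ("subyearling", "yearling"):
            lo, hi = (cfg.yearling_season if age_class == "yearling"
                      else cfg.subyearling_season)
            days = np.arange(lo, hi + 1)
            T = len(days)
            dmat = _stream_discharge_matrix(discharge, stream, years, days)
            if cfg.couple_recruitment:
                totals = {}
                for lab, t0, tf in cfg.true_generation_windows():
                    if (lab == "spring1") != (age_class == "yearling"):
                        continue
                    for yi, yr in enumerate(years):
                        j = rec_idx.loc[(lab, int(yr), stream), "J_per_km"]
                        totals[(lab, yi)] = float(j) * km
                m, tr = _coupled_daily_layer(cfg, rng, days, age_class, Y,
                                             totals)
            else:
                m, tr = _literal_daily_layer(cfg, rng, days, age_class, Y)
            p, cap = _capture_layer(cfg, rng, Y, T, dmat)
            operating = _simulate_outages(cfg, rng, Y, T)
            catch = _observe_catches(cfg, rng, m, p, operating)
            td, ty, rel, rec = _schedule_trials(cfg, rng, Y, T, operating, p)
            key = (stream, age_class)
            trap[key] = TrapDataset(
                stream=stream, age_class=age_class, days=days, years=years,
                catch=catch, operating=operating, discharge=dmat,
                trial_day=days[td] if td.size else np.empty(0, int),
                trial_year=years[ty] if ty.size else np.empty(0, int),
                released=rel, recaptured=rec,
            )
            m_truth[key], p_truth[key] = m, p
            mig_truth[key] = {**tr, **cap}
            for lab, t0, tf in cfg.true_generation_windows():
                if (lab == "spring1") != (age_class == "yearling"):
                    continue
                msk = (days >= t0) & (days <= tf)
                for yi, yr in enumerate(years):
                    window_rows.append((lab, int(yr), stream,
                                        float(m[yi, msk].sum())))

    truth = TruthRecord(
        m=m_truth, p=p_truth, migration=mig_truth,
        window_totals=pd.DataFrame(
            window_rows, columns=["lhp", "brood_year", "stream", "M"]),
        recruitment=recruitment, omega=omega, spawners=spawners,
        covariates=covariates,
        params={**cfg.params_dict(),
                **({"recruitment_truth": {
                    k: np.asarray(v).tolist() if not np.isscalar(v) else v
                    for k, v in rec_params.items()}}
                   if rec_params else {})},
    )
    return SimulatedData(trap=trap, redds=redds, discharge=discharge,
                         habitat=dict(cfg.streams), truth=truth)


def simulate_recruit_tables(cfg: SyntheticConfig, rng=None):
    """Direct generation of Step-3 inputs (emigrant summaries, redds,
    covariates) without the daily trap layer, for spawner-recruit recovery
    studies.

    The emigrant summary log-mean is the true log window total plus
    N(0, mstar_obs_sd) noise, with the known SD carried as sigma^M-bar*.
    Returns (emigrants, redds, covariates, habitat, truth).
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    discharge = _simulate_discharge(cfg, rng)
    spawners = _simulate_spawners(cfg, rng)
    redds = _observe_redds(spawners, cfg, rng)
    covariates = _covariates_from_discharge(discharge, cfg.brood_years())
    recruitment, omega, rec_params = _simulate_recruitment(
        cfg, rng, spawners, covariates)
    km = pd.Series(cfg.streams)
    rec = recruitment.copy()
    rec["M_total"] = rec["J_per_km"] * rec["stream"].map(km)
    rec["log_mean"] = (np.log(rec["M_total"])
                       + rng.normal(0.0, cfg.mstar_obs_sd, len(rec)))
    rec["log_sd"] = cfg.mstar_obs_sd if cfg.mstar_obs_sd > 0 else 1e-3
    emigrants = rec[["lhp", "brood_year", "stream", "log_mean", "log_sd"]]
    truth = dict(recruitment=recruitment, omega=omega, spawners=spawners,
                 params=rec_params)
    return emigrants, redds, covariates, dict(cfg.streams), truth
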