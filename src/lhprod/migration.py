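"""Step 1: state-space model of daily emigrant abundance past a screw trap.

One model per stream x age-class.  The latent daily emigrant abundance on
season day ``t`` of year ``y`` is

.. math:: \\log m_{t,y} = \\mu^m_y + \\delta_t + \\epsilon_{t,y},

with a year mean, a cross-year seasonal profile :math:`\\delta` modeled as a
random walk (:math:`\\delta_1 = 0`), and stationary AR(1) year-specific
deviations :math:`\\epsilon` (innovation SD :math:`\\sigma_\\epsilon`,
autocorrelation :math:`\\rho`, stationary initial SD
:math:`\\sigma_\\epsilon/\\sqrt{1-\\rho^2}`).

Trap capture probability is a logit-linear function of Z-scored daily
discharge with year intercepts/slopes and week effects,

.. math:: \\mathrm{logit}\\, p_{t,y} = \\iota_y + \\kappa_y D_{t,y}
    + \\nu_{w(t)} + \\xi_{w(t),y},

where :math:`\\iota_y \\sim N(\\beta_0, \\sigma_\\iota)`, :math:`\\kappa_y \\sim
N(\\beta_1, \\sigma_\\kappa)`, and the week effects are zero-mean.  Catches are
negative binomial with mean :math:`m p` and variance :math:`\\mu + \\mu^2
\\phi` (the overdispersion scale ``phi`` multiplies, so the Poisson limit is
``phi -> 0``); mark-recapture trials are binomial with the capture
probability of the release day.  Outage days contribute no catch likelihood,
but the process model spans them so abundance is interpolated by the process
prior.

Estimation integrates over (delta, eps, iota, kappa, nu, xi) by Laplace
approximation and maximizes the marginal likelihood over (mu_m, sigma_delta,
sigma_eps, rho, phi, beta0, beta1 and the four random-effect SDs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import expit, gammaln, xlogy

from lhprod import inference
from lhprod.errors import ValidationError

__all__ = [
    "TrapDataset",
    "MigrationParams",
    "MigrationFit",
    "log_daily_abundance",
    "rw_ar1_nll",
    "capture_probability",
    "catch_nll",
    "markrecap_nll",
    "capture_prior_nll",
    "migration_joint_nll",
    "fit_migration",
    "bootstrap_window_totals",
]

_LOG2PI = np.log(2.0 * np.pi)


# ----------------------------------------------------------------------
# data container
# ----------------------------------------------------------------------


@dataclass
class TrapDataset:
    """Daily trap catches, operation mask, discharge and mark-recapture
    trials for one stream x age-class.

    Arrays are indexed ``[year, day]`` over consecutive brood-cycle days
    ``days`` and brood years ``years``.  ``catch`` is NaN exactly where the
    trap was not operating.  ``trial_day``/``trial_year`` give the release
    day (brood-cycle day value) and brood year of each mark-recapture trial.
    """

    stream: str
    age_class: str
    days: np.ndarray
    years: np.ndarray
    catch: np.ndarray
    operating: np.ndarray
    discharge: np.ndarray
    trial_day: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    trial_year: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    released: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    recaptured: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    def __post_init__(self):
        self.days = np.asarray(self.days, dtype=int)
        self.years = np.asarray(self.years, dtype=int)
        self.catch = np.asarray(self.catch, dtype=float)
        self.operating = np.asarray(self.operating, dtype=bool)
        self.discharge = np.asarray(self.discharge, dtype=float)
        for name in ("trial_day", "trial_year", "released", "recaptured"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=int))
        self.validate()

    # -- shape helpers --------------------------------------------------

    @property
    def n_days(self):
        return self.days.size

    @property
    def n_years(self):
        return self.years.size

    @property
    def week(self):
        """7-day block index from season start, common across years."""
        return (self.days - self.days[0]) // 7

    @property
    def n_weeks(self):
        return int(self.week[-1]) + 1

    def validate(self):
        if self.age_class not in ("subyearling", "yearling"):
            raise ValidationError(f"unknown age_class {self.age_class!r}")
        if np.any(np.diff(self.days) != 1):
            raise ValidationError("days must be consecutive")
        Y, T = self.n_years, self.n_days
        for name in ("catch", "operating", "discharge"):
            if getattr(self, name).shape != (Y, T):
                raise ValidationError(f"{name} must have shape (n_years, n_days)")
        obs = self.operating & np.isfinite(self.catch)
        if np.any(self.operating != obs):
            raise ValidationError("catch must be present exactly on operating days")
        c = self.catch[obs]
        if np.any(c < 0):
            raise ValidationError("negative catch")
        if np.any(c != np.round(c)):
            raise ValidationError("catches must be integers")
        if not np.all(np.isfinite(self.discharge[self.operating])):
            raise ValidationError("discharge must be finite on operating days")
        if np.any(self.recaptured < 0) or np.any(self.released < 0):
            raise ValidationError("negative mark-recapture counts")
        bad = np.nonzero(self.recaptured > self.released)[0]
        if bad.size:
            raise ValidationError(
                f"recaptured > released in trial row {bad[0]}"
            )
        for d, y in zip(self.trial_day, self.trial_year):
            if d not in self.days or y not in self.years:
                raise ValidationError(
                    f"mark-recapture trial at day {d}, year {y} outside dataset"
                )

    # -- derived arrays used by the likelihood --------------------------

    def discharge_z(self):
        """Discharge Z-scored over operating days across all years (the
        pooling level for the capture-probability covariate)."""
        vals = self.discharge[self.operating]
        mu, sd = float(np.mean(vals)), float(np.std(vals))
        if sd == 0.0:
            sd = 1.0
        return (self.discharge - mu) / sd

    def trial_indices(self):
        t_idx = np.searchsorted(self.days, self.trial_day)
        y_idx = np.searchsorted(self.years, self.trial_year)
        return t_idx, y_idx


# ----------------------------------------------------------------------
# parameters
# ----------------------------------------------------------------------


@dataclass
class MigrationParams:
    """Full parameter set (fixed effects + random-effect values)."""

    mu_m: np.ndarray  # (Y,)
    sigma_delta: float
    sigma_eps: float
    rho_eps: float
    nb_phi: float
    beta0_p: float
    beta1_p: float
    sigma_iota: float
    sigma_kappa: float
    sigma_nu: float
    sigma_xi: float
    delta: np.ndarray  # (T,), delta[0] == 0
    eps: np.ndarray  # (Y, T)
    iota: np.ndarray  # (Y,)
    kappa: np.ndarray  # (Y,)
    nu: np.ndarray  # (W,)
    xi: np.ndarray  # (Y, W)

    def __post_init__(self):
        self.mu_m = np.atleast_1d(np.asarray(self.mu_m, dtype=float))
        self.delta = np.asarray(self.delta, dtype=float)
        self.eps = np.atleast_2d(np.asarray(self.eps, dtype=float))
        self.iota = np.atleast_1d(np.asarray(self.iota, dtype=float))
        self.kappa = np.atleast_1d(np.asarray(self.kappa, dtype=float))
        self.nu = np.atleast_1d(np.asarray(self.nu, dtype=float))
        self.xi = np.atleast_2d(np.asarray(self.xi, dtype=float))
        self.validate()

    def validate(self):
        for name in ("sigma_delta", "sigma_eps", "nb_phi", "sigma_iota",
                     "sigma_kappa", "sigma_nu", "sigma_xi"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if abs(self.rho_eps) >= 1:
            raise ValidationError("|rho_eps| must be < 1")
        if self.delta.size and self.delta[0] != 0.0:
            raise ValidationError("delta[0] must be 0 (reference day)")


def log_daily_abundance(params: MigrationParams, t: int, y: int) -> float:
    """log m_{t,y} = mu_m[y] + delta[t] + eps[t,y] at season-day index t."""
    T = params.delta.size
    if not 0 <= t < T:
        raise ValueError(f"day index {t} outside season (0..{T - 1})")
    return float(params.mu_m[y] + params.delta[t] + params.eps[y, t])


def capture_probability(params: MigrationParams, t: int, y: int,
                        discharge_z: float) -> float:
    """Inverse-logit of the four-term linear predictor on season day t."""
    w = t // 7
    b = (params.iota[y] + params.kappa[y] * discharge_z
         + params.nu[w] + params.xi[y, w])
    return float(expit(b))


def rw_ar1_nll(params: MigrationParams) -> float:
    """Negative log density of the seasonal random walk (delta) and the
    stationary AR(1) year deviations (eps), constants included."""
    params.validate()
    T = params.delta.size
    if T < 2:
        raise ValidationError("need >= 2 days in season")
    sd_d, sd_e, rho = params.sigma_delta, params.sigma_eps, params.rho_eps
    dd = np.diff(params.delta)
    nll = 0.5 * np.sum((dd / sd_d) ** 2) + dd.size * (np.log(sd_d) + 0.5 * _LOG2PI)
    s0 = sd_e / np.sqrt(1.0 - rho ** 2)
    e = params.eps
    nll += 0.5 * np.sum((e[:, 0] / s0) ** 2) + e.shape[0] * (
        np.log(s0) + 0.5 * _LOG2PI
    )
    innov = e[:, 1:] - rho * e[:, :-1]
    nll += 0.5 * np.sum((innov / sd_e) ** 2) + innov.size * (
        np.log(sd_e) + 0.5 * _LOG2PI
    )
    return float(nll)


def capture_prior_nll(params: MigrationParams) -> float:
    """Gaussian priors of the capture-probability random effects."""
    out = 0.0
    for x, mean, sd in (
        (params.iota, params.beta0_p, params.sigma_iota),
        (params.kappa, params.beta1_p, params.sigma_kappa),
        (params.nu, 0.0, params.sigma_nu),
        (params.xi, 0.0, params.sigma_xi),
    ):
        x = np.asarray(x, dtype=float)
        out += 0.5 * np.sum(((x - mean) / sd) ** 2) + x.size * (
            np.log(sd) + 0.5 * _LOG2PI
        )
    return float(out)


def _nb_nll(c, mu, phi):
    """Elementwise negative binomial NLL with variance mu + mu^2 * phi.

    For phi below ~1e-8 the gammaln difference loses precision, so the
    Poisson limit with its O(phi) correction is used instead (the two
    branches agree to ~1e-10 at the switch point).
    """
    if phi < 1e-8:
        c = np.asarray(c, dtype=float)
        pois = mu - xlogy(c, mu) + gammaln(c + 1.0)
        corr = (c * (c - 1.0) / 2.0 - c * mu + mu ** 2 / 2.0) * phi
        return pois - corr
    r = 1.0 / phi
    ll = (
        gammaln(c + r) - gammaln(r) - gammaln(c + 1.0)
        - r * np.log1p(mu * phi)
        + xlogy(c, mu) - xlogy(c, r + mu)
    )
    return -ll


def catch_nll(params: MigrationParams, dataset: TrapDataset) -> float:
    """Negative binomial catch likelihood over operating days."""
    obs = dataset.operating & np.isfinite(dataset.catch)
    if not obs.any():
        return 0.0
    c = dataset.catch[obs]
    if np.any(c < 0):
        raise ValidationError("negative catch")
    yi, ti = np.nonzero(obs)
    Dz = dataset.discharge_z()
    a = params.mu_m[yi] + params.delta[ti] + params.eps[yi, ti]
    w = ti // 7
    b = (params.iota[yi] + params.kappa[yi] * Dz[yi, ti]
         + params.nu[w] + params.xi[yi, w])
    mu = np.exp(a) * expit(b)
    return float(np.sum(_nb_nll(c, mu, params.nb_phi)))


def markrecap_nll(params: MigrationParams, dataset: TrapDataset) -> float:
    """Binomial likelihood of the mark-recapture trials (release-day p)."""
    if dataset.released.size == 0:
        return 0.0
    if np.any(dataset.recaptured > dataset.released):
        raise ValidationError("recaptured > released")
    ti, yi = dataset.trial_indices()
    Dz = dataset.discharge_z()
    w = ti // 7
    b = (params.iota[yi] + params.kappa[yi] * Dz[yi, ti]
         + params.nu[w] + params.xi[yi, w])
    n, k = dataset.released, dataset.recaptured
    ll = (
        gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)
        + k * b - n * np.logaddexp(0.0, b)
    )
    return float(-np.sum(ll))


def migration_joint_nll(params: MigrationParams, dataset: TrapDataset) -> float:
    """Joint NLL: process priors + capture priors + catch + mark-recapture."""
    return (
        rw_ar1_nll(params)
        + capture_prior_nll(params)
        + catch_nll(params, dataset)
        + markrecap_nll(params, dataset)
    )


# ----------------------------------------------------------------------
# packed mixed-model machinery
# ----------------------------------------------------------------------


class _MigrationModel:
    """Index bookkeeping plus analytic derivatives for the inner problem."""

    def __init__(self, dataset: TrapDataset):
        self.data = dataset
        Y, T, W = dataset.n_years, dataset.n_days, dataset.n_weeks
        self.Y, self.T, self.W = Y, T, W
        # random-effect layout
        self.sl_delta = slice(0, T - 1)
        self.sl_eps = slice(T - 1, T - 1 + Y * T)
        o = T - 1 + Y * T
        self.sl_iota = slice(o, o + Y)
        self.sl_kappa = slice(o + Y, o + 2 * Y)
        self.sl_nu = slice(o + 2 * Y, o + 2 * Y + W)
        self.sl_xi = slice(o + 2 * Y + W, o + 2 * Y + W + Y * W)
        self.n_random = o + 2 * Y + W + Y * W
        self.n_fixed = Y + 10
        # observation index arrays
        obs = dataset.operating & np.isfinite(dataset.catch)
        self.oy, self.ot = np.nonzero(obs)
        self.c = dataset.catch[self.oy, self.ot]
        Dz = dataset.discharge_z()
        self.D = Dz[self.oy, self.ot]
        self.ow = self.ot // 7
        tt, ty = dataset.trial_indices()
        self.tt, self.ty = tt, ty
        self.tw = tt // 7
        self.tD = Dz[ty, tt]
        self.n_rel = dataset.released.astype(float)
        self.k_rec = dataset.recaptured.astype(float)
        # global indices used in Hessian assembly (delta index -1 => fixed)
        self.gi_delta = np.where(self.ot >= 1, self.ot - 1, -1)
        self.gi_eps = (T - 1) + self.oy * T + self.ot
        self.gi_iota = self.sl_iota.start + self.oy
        self.gi_kappa = self.sl_kappa.start + self.oy
        self.gi_nu = self.sl_nu.start + self.ow
        self.gi_xi = self.sl_xi.start + self.oy * W + self.ow
        self.ti_iota = self.sl_iota.start + self.ty
        self.ti_kappa = self.sl_kappa.start + self.ty
        self.ti_nu = self.sl_nu.start + self.tw
        self.ti_xi = self.sl_xi.start + self.ty * W + self.tw

    # -- fixed-effect packing -------------------------------------------

    def fixed_names(self):
        return (
            [f"mu_m[{y}]" for y in self.data.years]
            + ["sigma_delta", "sigma_eps", "rho_eps", "nb_phi",
               "beta0_p", "beta1_p", "sigma_iota", "sigma_kappa",
               "sigma_nu", "sigma_xi"]
        )

    def transforms(self):
        return (
            ["identity"] * self.Y
            + ["log", "log", "atanh", "log", "identity", "identity",
               "log", "log", "log", "log"]
        )

    def unpack_fixed(self, theta):
        Y = self.Y
        return dict(
            mu_m=np.asarray(theta[:Y], dtype=float),
            sd_d=np.exp(theta[Y]),
            sd_e=np.exp(theta[Y + 1]),
            rho=np.tanh(theta[Y + 2]),
            phi=np.exp(theta[Y + 3]),
            b0=theta[Y + 4],
            b1=theta[Y + 5],
            sd_i=np.exp(theta[Y + 6]),
            sd_k=np.exp(theta[Y + 7]),
            sd_n=np.exp(theta[Y + 8]),
            sd_x=np.exp(theta[Y + 9]),
        )

    def unpack_random(self, u):
        Y, T, W = self.Y, self.T, self.W
        delta = np.concatenate([[0.0], u[self.sl_delta]])
        eps = u[self.sl_eps].reshape(Y, T)
        return dict(
            delta=delta,
            eps=eps,
            iota=u[self.sl_iota],
            kappa=u[self.sl_kappa],
            nu=u[self.sl_nu],
            xi=u[self.sl_xi].reshape(Y, W),
        )

    def params(self, theta, u) -> MigrationParams:
        f = self.unpack_fixed(theta)
        r = self.unpack_random(u)
        return MigrationParams(
            mu_m=f["mu_m"], sigma_delta=f["sd_d"], sigma_eps=f["sd_e"],
            rho_eps=f["rho"], nb_phi=f["phi"], beta0_p=f["b0"],
            beta1_p=f["b1"], sigma_iota=f["sd_i"], sigma_kappa=f["sd_k"],
            sigma_nu=f["sd_n"], sigma_xi=f["sd_x"], delta=r["delta"],
            eps=r["eps"], iota=r["iota"], kappa=r["kappa"], nu=r["nu"],
            xi=r["xi"],
        )

    # -- linear predictors ----------------------------------------------

    def _predictors(self, f, r):
        a = f["mu_m"][self.oy] + r["delta"][self.ot] + r["eps"][self.oy, self.ot]
        b = (r["iota"][self.oy] + r["kappa"][self.oy] * self.D
             + r["nu"][self.ow] + r["xi"][self.oy, self.ow])
        bt = (r["iota"][self.ty] + r["kappa"][self.ty] * self.tD
              + r["nu"][self.tw] + r["xi"][self.ty, self.tw])
        return a, b, bt

    # -- joint NLL -------------------------------------------------------

    def joint_nll(self, theta, u):
        f = self.unpack_fixed(theta)
        r = self.unpack_random(u)
        sd_d, sd_e, rho = f["sd_d"], f["sd_e"], f["rho"]
        nll = 0.0
        dd = np.diff(r["delta"])
        nll += 0.5 * np.sum((dd / sd_d) ** 2) + dd.size * (
            np.log(sd_d) + 0.5 * _LOG2PI)
        s0 = sd_e / np.sqrt(1.0 - rho ** 2)
        e = r["eps"]
        nll += 0.5 * np.sum((e[:, 0] / s0) ** 2) + self.Y * (
            np.log(s0) + 0.5 * _LOG2PI)
        innov = e[:, 1:] - rho * e[:, :-1]
        nll += 0.5 * np.sum((innov / sd_e) ** 2) + innov.size * (
            np.log(sd_e) + 0.5 * _LOG2PI)
        for x, mean, sd in ((r["iota"], f["b0"], f["sd_i"]),
                            (r["kappa"], f["b1"], f["sd_k"]),
                            (r["nu"], 0.0, f["sd_n"]),
                            (r["xi"], 0.0, f["sd_x"])):
            nll += 0.5 * np.sum(((x - mean) / sd) ** 2) + x.size * (
                np.log(sd) + 0.5 * _LOG2PI)
        a, b, bt = self._predictors(f, r)
        if np.any(a > 60.0):
            return np.inf
        mu = np.exp(a) * expit(b)
        nll += np.sum(_nb_nll(self.c, mu, f["phi"]))
        if bt.size:
            nll += -np.sum(self.k_rec * bt - self.n_rel * np.logaddexp(0.0, bt))
        return float(nll) if np.isfinite(nll) else np.inf

    # -- observation-term derivatives -----------------------------------

    def _obs_derivs(self, f, r):
        """First/second derivatives of the NB terms wrt (a, b)."""
        a, b, _ = self._predictors(f, r)
        p = expit(b)
        mu = np.exp(np.minimum(a, 60.0)) * p
        mu = np.maximum(mu, 1e-300)
        rphi = 1.0 / f["phi"]
        L1 = (rphi + self.c) / (rphi + mu) - self.c / mu
        L2 = self.c / mu ** 2 - (rphi + self.c) / (rphi + mu) ** 2
        q = 1.0 - p
        da = L1 * mu
        db = L1 * mu * q
        waa = L2 * mu ** 2 + L1 * mu
        wab = L2 * mu ** 2 * q + L1 * mu * q
        wbb = L2 * (mu * q) ** 2 + L1 * mu * q * (1.0 - 2.0 * p)
        return da, db, waa, wab, wbb

    def grad_random(self, theta, u):
        f = self.unpack_fixed(theta)
        r = self.unpack_random(u)
        Y, T, W = self.Y, self.T, self.W
        sd_d, sd_e, rho = f["sd_d"], f["sd_e"], f["rho"]
        g = np.zeros(self.n_random)
        # RW prior on delta
        dd = np.diff(r["delta"]) / sd_d ** 2
        gfull = np.zeros(T)
        gfull[:-1] -= dd
        gfull[1:] += dd
        # AR(1) prior on eps
        e = r["eps"]
        ge = np.zeros((Y, T))
        s0sq = sd_e ** 2 / (1.0 - rho ** 2)
        ge[:, 0] += e[:, 0] / s0sq
        innov = (e[:, 1:] - rho * e[:, :-1]) / sd_e ** 2
        ge[:, 1:] += innov
        ge[:, :-1] -= rho * innov
        gi = (r["iota"] - f["b0"]) / f["sd_i"] ** 2
        gk = (r["kappa"] - f["b1"]) / f["sd_k"] ** 2
        gn = r["nu"] / f["sd_n"] ** 2
        gx = r["xi"] / f["sd_x"] ** 2
        # observation terms
        da, db, _, _, _ = self._obs_derivs(f, r)
        np.add.at(gfull, self.ot, da)
        np.add.at(ge, (self.oy, self.ot), da)
        np.add.at(gi, self.oy, db)
        np.add.at(gk, self.oy, db * self.D)
        np.add.at(gn, self.ow, db)
        np.add.at(gx, (self.oy, self.ow), db)
        # mark-recapture terms
        if self.tt.size:
            _, _, bt = self._predictors(f, r)
            dbt = self.n_rel * expit(bt) - self.k_rec
            np.add.at(gi, self.ty, dbt)
            np.add.at(gk, self.ty, dbt * self.tD)
            np.add.at(gn, self.tw, dbt)
            np.add.at(gx, (self.ty, self.tw), dbt)
        g[self.sl_delta] = gfull[1:]
        g[self.sl_eps] = ge.ravel()
        g[self.sl_iota] = gi
        g[self.sl_kappa] = gk
        g[self.sl_nu] = gn
        g[self.sl_xi] = gx.ravel()
        return g

    def hess_random(self, theta, u):
        f = self.unpack_fixed(theta)
        r = self.unpack_random(u)
        Y, T, W = self.Y, self.T, self.W
        sd_d, sd_e, rho = f["sd_d"], f["sd_e"], f["rho"]
        rows, cols, vals = [], [], []

        def add(rr, cc, vv):
            rows.append(np.asarray(rr, dtype=np.int64))
            cols.append(np.asarray(cc, dtype=np.int64))
            vals.append(np.asarray(vv, dtype=float))

        # RW prior (free indices 0..T-2 <-> delta[1..T-1])
        idx = np.arange(T - 1)
        dprec = np.full(T - 1, 2.0 / sd_d ** 2)
        dprec[-1] = 1.0 / sd_d ** 2
        add(idx, idx, dprec)
        if T > 2:
            off = np.full(T - 2, -1.0 / sd_d ** 2)
            add(idx[:-1], idx[1:], off)
            add(idx[1:], idx[:-1], off)
        # AR(1) prior per year (tridiagonal blocks)
        base = (T - 1) + np.arange(Y)[:, None] * T
        diag = np.full(T, (1.0 + rho ** 2) / sd_e ** 2)
        diag[0] = diag[-1] = 1.0 / sd_e ** 2
        eidx = (base + np.arange(T)[None, :]).ravel()
        add(eidx, eidx, np.tile(diag, Y))
        off = np.full(T - 1, -rho / sd_e ** 2)
        e1 = (base + np.arange(T - 1)[None, :]).ravel()
        e2 = (base + np.arange(1, T)[None, :]).ravel()
        add(e1, e2, np.tile(off, Y))
        add(e2, e1, np.tile(off, Y))
        # diagonal priors of capture random effects
        for slc, sd in ((self.sl_iota, f["sd_i"]), (self.sl_kappa, f["sd_k"]),
                        (self.sl_nu, f["sd_n"]), (self.sl_xi, f["sd_x"])):
            j = np.arange(slc.start, slc.stop)
            add(j, j, np.full(j.size, 1.0 / sd ** 2))
        # NB observation blocks: 6 coordinates per observation
        _, _, waa, wab, wbb = self._obs_derivs(f, r)
        gidx = [self.gi_delta, self.gi_eps, self.gi_iota, self.gi_kappa,
                self.gi_nu, self.gi_xi]
        coef = [np.ones_like(self.D), np.ones_like(self.D),
                np.ones_like(self.D), self.D,
                np.ones_like(self.D), np.ones_like(self.D)]
        group = [0, 0, 1, 1, 1, 1]
        wsel = {0: waa, 1: wab, 2: wbb}
        for i in range(6):
            for j in range(6):
                w = wsel[group[i] + group[j]]
                v = coef[i] * coef[j] * w
                ri, cj = gidx[i], gidx[j]
                if i == 0 or j == 0:
                    m = (ri >= 0) & (cj >= 0)
                    add(ri[m], cj[m], v[m])
                else:
                    add(ri, cj, v)
        # binomial trial blocks: 4 coordinates
        if self.tt.size:
            _, _, bt = self._predictors(f, r)
            pt = expit(bt)
            wt = self.n_rel * pt * (1.0 - pt)
            tidx = [self.ti_iota, self.ti_kappa, self.ti_nu, self.ti_xi]
            tcoef = [np.ones_like(self.tD), self.tD,
                     np.ones_like(self.tD), np.ones_like(self.tD)]
            for i in range(4):
                for j in range(4):
                    add(tidx[i], tidx[j], tcoef[i] * tcoef[j] * wt)
        H = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n_random, self.n_random),
        )
        return H.tocsc()

    # -- starting values -------------------------------------------------

    def start_values(self):
        d = self.data
        theta = np.zeros(self.n_fixed)
        tot_rel = self.n_rel.sum()
        p0 = (self.k_rec.sum() + 0.5) / (tot_rel + 1.0) if tot_rel else 0.1
        p0 = float(np.clip(p0, 1e-3, 1 - 1e-3))
        b0 = float(np.log(p0 / (1 - p0)))
        with np.errstate(divide="ignore", invalid="ignore"):
            logc = np.log((d.catch + 0.5) / p0)
        obs = d.operating & np.isfinite(d.catch)
        mu0 = np.array([
            np.mean(logc[y][obs[y]]) if obs[y].any() else 0.0
            for y in range(self.Y)
        ])
        prof = np.zeros(self.T)
        for t in range(self.T):
            col = logc[:, t][obs[:, t]] - mu0[obs[:, t]]
            prof[t] = np.mean(col) if col.size else 0.0
        kern = np.ones(7) / 7.0
        prof = np.convolve(prof, kern, mode="same")
        prof -= prof[0]
        Y = self.Y
        # mu_m is the level at the anchor day (delta[0] = 0): remove the
        # profile's mean from the per-year mean level
        theta[:Y] = mu0 - prof.mean()
        theta[Y] = np.log(max(np.std(np.diff(prof)), 0.05))
        theta[Y + 1] = np.log(0.3)
        theta[Y + 2] = np.arctanh(0.5)
        theta[Y + 3] = np.log(0.1)
        theta[Y + 4] = b0
        theta[Y + 5] = 0.0
        theta[Y + 6 : Y + 10] = np.log(0.3)
        u0 = np.zeros(self.n_random)
        u0[self.sl_delta] = prof[1:]
        u0[self.sl_iota] = b0
        return theta, u0

    def build_spec(self):
        return inference.MixedModelSpec(
            joint_nll=self.joint_nll,
            n_fixed=self.n_fixed,
            n_random=self.n_random,
            grad_random=self.grad_random,
            hess_random=self.hess_random,
            transforms=self.transforms(),
            fixed_names=self.fixed_names(),
        )


@dataclass
class MigrationFit:
    """Fitted daily-emigrant model plus per-day abundance/capture estimates."""

    dataset: TrapDataset
    result: inference.FitResult
    params: MigrationParams
    m_hat: np.ndarray  # (Y, T)
    p_hat: np.ndarray  # (Y, T), NaN where discharge missing
    model: _MigrationModel

    def daily_estimates(self) -> pd.DataFrame:
        d = self.dataset
        yy, tt = np.meshgrid(np.arange(d.n_years), np.arange(d.n_days),
                             indexing="ij")
        return pd.DataFrame({
            "stream": d.stream,
            "age_class": d.age_class,
            "brood_year": d.years[yy.ravel()],
            "day": d.days[tt.ravel()],
            "m_hat": self.m_hat.ravel(),
            "p_hat": self.p_hat.ravel(),
        })


def fit_migration(dataset: TrapDataset, tol=1e-4, covariance="fd-marginal",
                  max_iter=300) -> MigrationFit:
    """Fit the daily-emigrant state-space model for one stream x age-class.

    Maximizes the Laplace-approximated marginal likelihood over the fixed
    effects; requires >= 2 years of data and >= 1 mark-recapture trial (the
    capture level is otherwise unidentified).
    """
    if dataset.n_years < 2:
        raise ValidationError("need >= 2 years of trap data")
    if dataset.released.size < 1:
        raise ValidationError("need >= 1 mark-recapture trial")
    model = _MigrationModel(dataset)
    spec = model.build_spec()
    theta0, u0 = model.start_values()
    res = inference.fit(spec, theta0, tol=tol, covariance=covariance,
                        random_start=u0, max_iter=max_iter)
    params = model.params(res.fixed, res.random_mode)
    r = model.unpack_random(res.random_mode)
    log_m = params.mu_m[:, None] + r["delta"][None, :] + r["eps"]
    m_hat = np.exp(log_m)
    Dz = dataset.discharge_z()
    w = np.arange(dataset.n_days) // 7
    b = (r["iota"][:, None] + r["kappa"][:, None] * Dz
         + r["nu"][w][None, :] + r["xi"][:, w])
    p_hat = expit(b)
    p_hat[~np.isfinite(Dz)] = np.nan
    return MigrationFit(dataset=dataset, result=res, params=params,
                        m_hat=m_hat, p_hat=p_hat, model=model)


def bootstrap_window_totals(fit: MigrationFit, windows, n_draws=10_000,
                            seed=0, chunk=2_000) -> pd.DataFrame:
    """Parametric bootstrap of LHP window totals M_{h,y}.

    Draws parameter sets from the multivariate normal defined by the fit's
    estimates and covariance (fixed effects), shifts the random-effect modes
    by the implicit-function linearization du/dtheta and adds conditional
    Gaussian noise with covariance H_uu^{-1}, then sums daily abundances
    within each window (Equations of the daily model + window sums).  Returns
    one row per (lhp, brood_year) with the log-mean M-bar* and log-SD
    sigma^M-bar* across draws.

    Windows are taken from an :class:`lhprod.delineation.LhpWindows`-like
    object restricted to this dataset's age class; a window with no overlap
    with the dataset's season raises.
    """
    d = fit.dataset
    model = fit.model
    res = fit.result
    labels, starts, ends = _window_arrays(windows)
    masks = []
    for lab, t0, tf in zip(labels, starts, ends):
        m = (d.days >= t0) & (d.days <= tf)
        if not m.any():
            raise ValidationError(
                f"window {lab} [{t0}, {tf}] does not overlap the "
                f"{d.age_class} season"
            )
        masks.append(m)
    if res.cov is None:
        raise ValueError("fit has no covariance; rerun with covariance")

    theta_hat = res.fixed
    u_hat = res.random_mode
    Y, T = model.Y, model.T
    point_logm = (
        model.unpack_fixed(theta_hat)["mu_m"][:, None]
        + model.unpack_random(u_hat)["delta"][None, :]
        + model.unpack_random(u_hat)["eps"]
    )
    degenerate = not np.any(res.cov)
    if degenerate:
        out = []
        for lab, m in zip(labels, masks):
            M = np.exp(point_logm)[:, m].sum(axis=1)
            for yi, yr in enumerate(d.years):
                out.append((lab, int(yr), d.stream, float(np.log(M[yi])), 0.0))
        return pd.DataFrame(
            out, columns=["lhp", "brood_year", "stream", "log_mean", "log_sd"]
        )

    spec = model.build_spec()
    H_uu = sp.csc_matrix(spec.hess_random(theta_hat, u_hat))
    lu, _, _ = inference._factor_spd(H_uu)
    # du/dtheta via central FD of the analytic u-gradient
    n_t = theta_hat.size
    H_ut = np.empty((model.n_random, n_t))
    for i in range(n_t):
        h = 1e-4 * max(1.0, abs(theta_hat[i]))
        tp = theta_hat.copy()
        tm = theta_hat.copy()
        tp[i] += h
        tm[i] -= h
        H_ut[:, i] = (spec.grad_random(tp, u_hat)
                      - spec.grad_random(tm, u_hat)) / (2 * h)
    B = -lu.solve(H_ut)
    # dense Cholesky of H_uu for conditional sampling
    L = np.linalg.cholesky(H_uu.toarray())
    rng = np.random.default_rng(seed)
    theta_draws = inference.mvn_bootstrap_draws(res, n_draws,
                                               rng.integers(2 ** 31))
    logs = {lab: [] for lab in labels}
    from scipy.linalg import solve_triangular

    for lo in range(0, n_draws, chunk):
        td = theta_draws[lo:lo + chunk]
        nc = td.shape[0]
        z = rng.standard_normal((model.n_random, nc))
        noise = solve_triangular(L.T, z, lower=False)
        u_star = u_hat[:, None] + B @ (td - theta_hat).T + noise
        mu_star = td[:, :Y]  # (nc, Y)
        delta_star = np.vstack(
            [np.zeros(nc), u_star[model.sl_delta]])  # (T, nc)
        eps_star = u_star[model.sl_eps].reshape(Y, T, nc)
        log_m = (mu_star.T[:, None, :] + delta_star[None, :, :] + eps_star)
        m = np.exp(np.minimum(log_m, 60.0))
        for lab, msk in zip(labels, masks):
            M = m[:, msk, :].sum(axis=1)  # (Y, nc)
            logs[lab].append(np.log(np.maximum(M, 1e-300)))
    out = []
    for lab in labels:
        logM = np.concatenate(logs[lab], axis=1)  # (Y, n_draws)
        mbar = logM.mean(axis=1)
        sbar = logM.std(axis=1, ddof=1)
        for yi, yr in enumerate(d.years):
            out.append((lab, int(yr), d.stream, float(mbar[yi]),
                        float(sbar[yi])))
    return pd.DataFrame(
        out, columns=["lhp", "brood_year", "stream", "log_mean", "log_sd"]
    )


def _window_arrays(windows):
    """Accept LhpWindows or an iterable of (label, t0, tf)."""
    if hasattr(windows, "labels"):
        return list(windows.labels), list(windows.starts), list(windows.ends)
    labels, starts, ends = [], [], []
    for lab, t0, tf in windows:
        labels.append(lab)
        starts.append(int(t0))
        ends.append(int(tf))
    return labels, starts, ends
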