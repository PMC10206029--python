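"""Step 3: penalized hierarchical generalized Beverton-Holt production model.

Annual emigrant production of each life-history pathway (LHP) ``h`` in
stream ``s`` from female spawners ``S`` (both per km of spawning habitat)
follows the Myers generalization of the Beverton-Holt model,

.. math:: J_{h,y,s} = \\frac{\\alpha_{h,s} S_{y,s}^{\\gamma_{h,s}}}
    {1 + \\alpha_{h,s} S_{y,s}^{\\gamma_{h,s}} / J^{max}_{h,s}}
    \\exp(\\epsilon^J_{h,y,s}),

which is accelerating (positive density dependence) for ``gamma > 1``,
decelerating for ``gamma < 1`` with finite ``Jmax``, and collapses to the
density-independent line when ``gamma = 1`` and ``Jmax -> infinity``.  The
three shape parameters are lognormal across streams within LHP, and the log
hypermeans of ``gamma`` and ``Jmax`` carry normal penalties centered (on the
natural scale, via the lognormal mean identity E e^X = e^{m + s^2/2}) at 1
and at a large constant ``nu_Jmax`` respectively, so the data must earn any
density dependence.  Penalty SDs ``tau`` and the hyperdistribution SDs carry
exponential regularization.

Process errors decompose into stream-discharge covariate effects, a shared
annual latent factor with per-(LHP, stream) loadings (rank-1 cross-series
correlation), and independent noise:

.. math:: \\epsilon^J_{h,y,s} = x_{h,y,s}' \\beta^\\epsilon_h
    + \\omega_y l_{h,s} + \\eta_{h,y,s}.

Observations enter as penalties: bootstrap emigrant summaries
:math:`\\bar M^*` are normal around ``log J`` with their bootstrap SD, and
redd counts are lognormal around latent spawners with SD 0.1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import expit

from lhprod import inference
from lhprod.errors import ValidationError

__all__ = [
    "LHP_LABELS",
    "COVARIATE_SETS",
    "RecruitData",
    "RecruitConfig",
    "RecruitParams",
    "RecruitFit",
    "bh_modified",
    "hyper_penalty_nll",
    "process_error_nll",
    "observation_nll",
    "recruit_joint_nll",
    "fit_recruit",
    "predict",
    "predict_curves",
]

_LOG2PI = np.log(2.0 * np.pi)

LHP_LABELS = ("spring0", "summer0", "fall0", "spring1")

#: discharge covariates entering each LHP's process error: first-winter log
#: max flow for all; first-summer mean flow for all but spring subyearlings
#: (which emigrate before summer); second-winter log max flow for yearlings.
COVARIATE_SETS = {
    "spring0": ("winter1",),
    "summer0": ("winter1", "summer1"),
    "fall0": ("winter1", "summer1"),
    "spring1": ("winter1", "summer1", "winter2"),
}


def bh_modified(S, alpha, gamma, jmax):
    """Generalized (Myers) Beverton-Holt: alpha * S^gamma / (1 + alpha *
    S^gamma / Jmax).  S = 0 maps to 0; parameters must be positive."""
    alpha = np.asarray(alpha, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    jmax = np.asarray(jmax, dtype=float)
    if np.any(alpha <= 0) or np.any(gamma <= 0) or np.any(jmax <= 0):
        raise ValidationError("alpha, gamma and Jmax must all be > 0")
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValidationError("spawners must be >= 0")
    with np.errstate(over="ignore"):
        num = alpha * S ** gamma
        out = np.where(np.isfinite(num), num / (1.0 + num / jmax), jmax)
    return out if out.ndim else float(out)


# ----------------------------------------------------------------------
# data and configuration
# ----------------------------------------------------------------------


@dataclass
class RecruitData:
    """Inputs to the spawner-to-emigrant model.

    ``emigrants``: one row per (lhp, brood_year, stream) with the bootstrap
    log-mean ``log_mean`` (absolute scale) and log-SD ``log_sd`` of the
    window total.  ``redds``: (year, stream, redds).  ``covariates``:
    (stream, brood_year, winter1, summer1, winter2), Z-scored within stream.
    ``habitat_km`` maps stream to spawning-habitat length; spawners and
    emigrants are scaled per km internally.
    """

    emigrants: pd.DataFrame
    redds: pd.DataFrame
    habitat_km: dict
    covariates: pd.DataFrame

    def __post_init__(self):
        need = {"lhp", "brood_year", "stream", "log_mean", "log_sd"}
        if not need.issubset(self.emigrants.columns):
            raise ValidationError(
                f"emigrants table missing columns {sorted(need - set(self.emigrants.columns))}")
        if not {"year", "stream", "redds"}.issubset(self.redds.columns):
            raise ValidationError("redds table needs (year, stream, redds)")
        if not {"stream", "brood_year"}.issubset(self.covariates.columns):
            raise ValidationError(
                "covariates table needs (stream, brood_year, ...)")
        if self.emigrants["log_sd"].isna().any() or (
                self.emigrants["log_sd"] < 0).any():
            raise ValidationError(
                "missing or negative sigma^M-bar* (log_sd) in emigrants")
        for s, km in self.habitat_km.items():
            if km <= 0:
                raise ValidationError(f"habitat_km[{s!r}] must be > 0")
        unknown = set(self.emigrants["stream"]) - set(self.habitat_km)
        if unknown:
            raise ValidationError(f"streams without habitat length: {sorted(unknown)}")

    @property
    def streams(self):
        return sorted(set(self.emigrants["stream"]))

    @property
    def years(self):
        return np.array(sorted(set(self.emigrants["brood_year"].astype(int))))


@dataclass
class RecruitConfig:
    """Tunables of the production model.

    ``nu_jmax`` (default 1.5e4 per km) centers the Jmax hypermean penalty
    above any plausible observed abundance; ``spawner_obs_sd`` = 0.1 is the
    redd-count lognormal observation SD (~10% CV).  The exponential penalty
    rates lambda are fixed at 1 per unit scale by default: maximizing
    jointly over an exponential rate and the scales it penalizes is
    degenerate (the rate runs away as the scales shrink), so self-tuned
    rates are offered (``estimate_lambdas=True``) but not recommended.
    """

    nu_jmax: float = 1.5e4
    spawner_obs_sd: float = 0.1
    estimate_lambdas: bool = False
    lam: float = 1.0
    lam_gamma: float = 1.0
    lam_jmax: float = 1.0
    lam_eta: float = 1.0


# ----------------------------------------------------------------------
# explicit parameter container + likelihood components
# ----------------------------------------------------------------------


@dataclass
class RecruitParams:
    """Natural-scale parameter set (fixed effects + random-effect values)."""

    streams: list
    years: np.ndarray
    alpha: np.ndarray  # (4, n_s)
    gamma: np.ndarray
    jmax: np.ndarray
    mu_alpha: np.ndarray  # (4,) log-scale hypermeans
    mu_gamma: np.ndarray
    mu_jmax: np.ndarray
    sigma_alpha: np.ndarray  # (4,)
    sigma_gamma: np.ndarray
    sigma_jmax: np.ndarray
    tau_gamma: np.ndarray  # (4,)
    tau_jmax: np.ndarray
    lam: float
    lam_gamma: float
    lam_jmax: float
    lam_eta: float
    nu_jmax: float
    beta: dict  # lhp -> {covariate: coefficient}
    loadings: np.ndarray  # (4, n_s)
    sigma_eta: np.ndarray  # (4, n_s)
    omega: np.ndarray  # (n_y,)
    eta: np.ndarray  # (4, n_y, n_s)
    log_spawners: np.ndarray  # (n_y, n_s), per km

    def validate(self):
        for name in ("alpha", "gamma", "jmax", "sigma_alpha", "sigma_gamma",
                     "sigma_jmax", "tau_gamma", "tau_jmax", "sigma_eta"):
            if np.any(np.asarray(getattr(self, name)) <= 0):
                raise ValidationError(f"{name} must be > 0")
        for name in ("lam", "lam_gamma", "lam_jmax", "lam_eta", "nu_jmax"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.loadings[0, 0] < 0:
            raise ValidationError(
                "first factor loading must be positive (sign convention)")


def _norm_nll(x, mean, sd):
    x = np.asarray(x, dtype=float)
    return float(np.sum(0.5 * ((x - mean) / sd) ** 2)
                 + x.size * (np.log(sd) + 0.5 * _LOG2PI)) if x.size else 0.0


def hyper_penalty_nll(params: RecruitParams) -> float:
    """Hyperdistribution terms and regularizing penalties.

    Lognormal hyperdistributions of (alpha, gamma, Jmax) across streams;
    normal penalties keeping exp(mu_gamma) centered at 1 and exp(mu_jmax) at
    nu_jmax (means -tau^2/2 and log nu - tau^2/2, SDs tau); exponential
    penalties on the taus and on all hyper-SDs and idiosyncratic SDs.
    """
    params.validate()
    nll = 0.0
    for h in range(4):
        nll += _norm_nll(np.log(params.alpha[h]), params.mu_alpha[h],
                         params.sigma_alpha[h])
        nll += _norm_nll(np.log(params.gamma[h]), params.mu_gamma[h],
                         params.sigma_gamma[h])
        nll += _norm_nll(np.log(params.jmax[h]), params.mu_jmax[h],
                         params.sigma_jmax[h])
        tg, tj = params.tau_gamma[h], params.tau_jmax[h]
        nll += _norm_nll(params.mu_gamma[h], -tg ** 2 / 2.0, tg)
        nll += _norm_nll(params.mu_jmax[h],
                         np.log(params.nu_jmax) - tj ** 2 / 2.0, tj)
        for sd, rate in ((params.sigma_alpha[h], params.lam),
                         (params.sigma_gamma[h], params.lam),
                         (params.sigma_jmax[h], params.lam),
                         (tg, params.lam_gamma), (tj, params.lam_jmax)):
            nll += rate * sd - np.log(rate)
    nll += float(np.sum(params.lam_eta * params.sigma_eta
                        - np.log(params.lam_eta)))
    return float(nll)


def process_error_nll(params: RecruitParams, data: RecruitData) -> float:
    """Gaussian terms of the latent-variable process-error model: the
    idiosyncratic errors eta given their SDs, and the standard-normal latent
    factor omega.  Validates that each LHP's coefficient set matches its
    covariate design."""
    for lhp, want in COVARIATE_SETS.items():
        have = tuple(sorted(params.beta.get(lhp, {})))
        if have != tuple(sorted(want)):
            raise ValidationError(
                f"covariate mismatch for LHP {lhp}: expected {sorted(want)}, "
                f"got {sorted(have)}")
    nll = 0.0
    for h in range(4):
        for si in range(len(params.streams)):
            nll += _norm_nll(params.eta[h, :, si], 0.0,
                             params.sigma_eta[h, si])
    nll += _norm_nll(params.omega, 0.0, 1.0)
    return float(nll)


def _process_error_mean(params, data, lhp, year, stream):
    h = LHP_LABELS.index(lhp)
    si = params.streams.index(stream)
    yi = int(np.searchsorted(params.years, year))
    cov = data.covariates.set_index(["stream", "brood_year"])
    xb = 0.0
    for name, b in params.beta[lhp].items():
        xb += b * float(cov.loc[(stream, year), name])
    return xb + params.omega[yi] * params.loadings[h, si]


def observation_nll(params: RecruitParams, data: RecruitData,
                    spawner_obs_sd=0.1) -> float:
    """Log-normal observation penalties for emigrant summaries and redds.

    The emigrant penalty is normal on the log scale: M-bar* ~ N(log J,
    sigma^M-bar*), with log J = log BH(S) + x'beta + omega*l + eta.  Redd
    counts are lognormal around latent spawners with SD ``spawner_obs_sd``.
    """
    nll = 0.0
    for row in data.emigrants.itertuples():
        if not np.isfinite(row.log_sd) or row.log_sd <= 0:
            raise ValidationError(
                f"missing sigma^M-bar* for ({row.lhp}, {row.brood_year}, "
                f"{row.stream})")
        h = LHP_LABELS.index(row.lhp)
        si = params.streams.index(row.stream)
        yi = int(np.searchsorted(params.years, row.brood_year))
        km = data.habitat_km[row.stream]
        s_perkm = np.exp(params.log_spawners[yi, si])
        logj = (np.log(bh_modified(s_perkm, params.alpha[h, si],
                                   params.gamma[h, si], params.jmax[h, si]))
                + _process_error_mean(params, data, row.lhp, row.brood_year,
                                      row.stream)
                + params.eta[h, yi, si])
        mstar = row.log_mean - np.log(km)
        nll += _norm_nll(np.array([mstar]), logj, row.log_sd)
    for row in data.redds.itertuples():
        if row.stream not in params.streams or int(row.year) not in set(
                params.years.tolist()):
            continue
        si = params.streams.index(row.stream)
        yi = int(np.searchsorted(params.years, int(row.year)))
        s_obs = np.log(row.redds / data.habitat_km[row.stream])
        nll += _norm_nll(np.array([s_obs]), params.log_spawners[yi, si],
                         spawner_obs_sd)
        nll += s_obs  # lognormal Jacobian of the observed count
    return float(nll)


def recruit_joint_nll(params: RecruitParams, data: RecruitData,
                      config: RecruitConfig | None = None) -> float:
    config = config or RecruitConfig()
    return (hyper_penalty_nll(params)
            + process_error_nll(params, data)
            + observation_nll(params, data, config.spawner_obs_sd))


# ----------------------------------------------------------------------
# packed mixed-model machinery
# ----------------------------------------------------------------------


class _RecruitModel:
    """Vectorized joint NLL with analytic random-effect derivatives.

    The idiosyncratic errors eta enter the emigrant penalty linearly with a
    Gaussian prior, so they are integrated in closed form: each observation's
    SD becomes sqrt(sigma_Mbar*^2 + sigma_eta^2).  The Laplace approximation
    is exact for such linear-Gaussian effects, so the marginal likelihood is
    identical to carrying eta in the Laplace block, at a fraction of the
    cost; the conditional eta modes are recovered afterwards.  The remaining
    random effects (latent spawners, the annual factor, the penalized
    hypermeans and the stream shape parameters) are integrated by Laplace.
    """

    def __init__(self, data: RecruitData, config: RecruitConfig):
        self.data = data
        self.config = config
        self.streams = data.streams
        self.years = data.years
        n_s, n_y, n_h = len(self.streams), len(self.years), 4
        self.n_s, self.n_y, self.n_h = n_s, n_y, n_h
        self.km = np.array([data.habitat_km[s] for s in self.streams])
        # random-effect layout (eta integrated analytically, not packed)
        self.off_ls = 0
        self.off_om = n_y * n_s
        self.off_mug = self.off_om + n_y
        self.off_muj = self.off_mug + n_h
        self.off_la = self.off_muj + n_h
        self.off_lg = self.off_la + n_h * n_s
        self.off_lj = self.off_lg + n_h * n_s
        self.n_random = self.off_lj + n_h * n_s
        # fixed-effect layout
        names, trans = [], []
        for lab in LHP_LABELS:
            names.append(f"mu_alpha[{lab}]")
            trans.append("identity")
        for pre in ("sigma_alpha", "sigma_gamma", "sigma_jmax",
                    "tau_gamma", "tau_jmax"):
            for lab in LHP_LABELS:
                names.append(f"{pre}[{lab}]")
                trans.append("log")
        self.i_lam = None
        if config.estimate_lambdas:
            self.i_lam = len(names)
            for nm in ("lam", "lam_gamma", "lam_jmax", "lam_eta"):
                names.append(nm)
                trans.append("log")
        self.i_beta = len(names)
        for lab in LHP_LABELS:
            names.append(f"beta_winter1[{lab}]")
            trans.append("identity")
        for lab in ("summer0", "fall0", "spring1"):
            names.append(f"beta_summer1[{lab}]")
            trans.append("identity")
        names.append("beta_winter2[spring1]")
        trans.append("identity")
        self.i_load = len(names)
        for h, lab in enumerate(LHP_LABELS):
            for s in self.streams:
                names.append(f"loading[{lab},{s}]")
                trans.append("log" if (h == 0 and s == self.streams[0])
                             else "identity")
        self.i_sige = len(names)
        for lab in LHP_LABELS:
            for s in self.streams:
                names.append(f"sigma_eta[{lab},{s}]")
                trans.append("log")
        self.n_fixed = len(names)
        self.names, self.trans = names, trans

        # observation arrays
        emi = data.emigrants
        smap = {s: i for i, s in enumerate(self.streams)}
        ymap = {int(y): i for i, y in enumerate(self.years)}
        self.oh = emi["lhp"].map({l: i for i, l in enumerate(LHP_LABELS)}
                                 ).to_numpy()
        self.oy = emi["brood_year"].astype(int).map(ymap).to_numpy()
        self.os = emi["stream"].map(smap).to_numpy()
        self.mstar = (emi["log_mean"].to_numpy()
                      - np.log(self.km[self.os]))
        self.sig = emi["log_sd"].to_numpy().astype(float)
        self.sig = np.maximum(self.sig, 1e-4)
        cov = data.covariates.set_index(["stream", "brood_year"])
        X = np.zeros((len(emi), 3))
        for i, row in enumerate(emi.itertuples()):
            x = cov.loc[(row.stream, int(row.brood_year))]
            X[i, 0] = x["winter1"]
            X[i, 1] = x["summer1"] if LHP_LABELS[self.oh[i]] != "spring0" else 0.0
            X[i, 2] = x["winter2"] if LHP_LABELS[self.oh[i]] == "spring1" else 0.0
        if not np.all(np.isfinite(X)):
            raise ValidationError("non-finite covariate values")
        self.X = X
        # redd observations
        red = data.redds[data.redds["year"].astype(int).isin(ymap)
                         & data.redds["stream"].isin(smap)]
        self.ry = red["year"].astype(int).map(ymap).to_numpy()
        self.rs = red["stream"].map(smap).to_numpy()
        self.r_obs = np.log(red["redds"].to_numpy()
                            / self.km[self.rs])
        self.sd_S = config.spawner_obs_sd
        # global obs indices
        self.gi_ls = self.off_ls + self.oy * n_s + self.os
        self.gi_om = self.off_om + self.oy
        self.gi_la = self.off_la + self.oh * n_s + self.os
        self.gi_lg = self.off_lg + self.oh * n_s + self.os
        self.gi_lj = self.off_lj + self.oh * n_s + self.os

    # -- packing helpers -------------------------------------------------

    def unpack_fixed(self, theta):
        n_h, n_s = self.n_h, self.n_s
        c = self.config
        out = dict(
            mua=np.asarray(theta[:4], dtype=float),
            siga=np.exp(theta[4:8]),
            sigg=np.exp(theta[8:12]),
            sigj=np.exp(theta[12:16]),
            taug=np.exp(theta[16:20]),
            tauj=np.exp(theta[20:24]),
        )
        if self.i_lam is not None:
            lams = np.exp(theta[self.i_lam:self.i_lam + 4])
        else:
            lams = np.array([c.lam, c.lam_gamma, c.lam_jmax, c.lam_eta])
        out["lams"] = lams
        raw = np.asarray(theta[self.i_beta:self.i_beta + 8], dtype=float)
        out["bw1"] = raw[:4]
        out["bs1"] = np.array([0.0, raw[4], raw[5], raw[6]])
        out["bw2"] = np.array([0.0, 0.0, 0.0, raw[7]])
        load = np.array(theta[self.i_load:self.i_load + n_h * n_s],
                        dtype=float)
        load[0] = np.exp(load[0])
        out["load"] = load.reshape(n_h, n_s)
        out["sige"] = np.exp(
            np.asarray(theta[self.i_sige:self.i_sige + n_h * n_s],
                       dtype=float)).reshape(n_h, n_s)
        return out

    def unpack_random(self, u):
        n_h, n_y, n_s = self.n_h, self.n_y, self.n_s
        return dict(
            ls=u[self.off_ls:self.off_om].reshape(n_y, n_s),
            om=u[self.off_om:self.off_mug],
            mug=u[self.off_mug:self.off_muj],
            muj=u[self.off_muj:self.off_la],
            la=u[self.off_la:self.off_lg].reshape(n_h, n_s),
            lg=u[self.off_lg:self.off_lj].reshape(n_h, n_s),
            lj=u[self.off_lj:].reshape(n_h, n_s),
        )

    def params(self, theta, u) -> RecruitParams:
        f = self.unpack_fixed(theta)
        r = self.unpack_random(u)
        # conditional modes of the analytically-integrated idiosyncratic
        # errors: Gaussian shrinkage of the observation residual
        pred0, _, _, _, _ = self._pred_terms(f, r)
        sigev = f["sige"][self.oh, self.os]
        shrink = sigev ** 2 / (self.sig ** 2 + sigev ** 2)
        eta3 = np.zeros((self.n_h, self.n_y, self.n_s))
        eta3[self.oh, self.oy, self.os] = (self.mstar - pred0) * shrink
        beta = {}
        for h, lab in enumerate(LHP_LABELS):
            b = {"winter1": float(f["bw1"][h])}
            if lab != "spring0":
                b["summer1"] = float(f["bs1"][h])
            if lab == "spring1":
                b["winter2"] = float(f["bw2"][h])
            beta[lab] = b
        return RecruitParams(
            streams=self.streams, years=self.years,
            alpha=np.exp(r["la"]), gamma=np.exp(r["lg"]),
            jmax=np.exp(r["lj"]), mu_alpha=f["mua"], mu_gamma=r["mug"],
            mu_jmax=r["muj"], sigma_alpha=f["siga"], sigma_gamma=f["sigg"],
            sigma_jmax=f["sigj"], tau_gamma=f["taug"], tau_jmax=f["tauj"],
            lam=float(f["lams"][0]), lam_gamma=float(f["lams"][1]),
            lam_jmax=float(f["lams"][2]), lam_eta=float(f["lams"][3]),
            nu_jmax=self.config.nu_jmax, beta=beta, loadings=f["load"],
            sigma_eta=f["sige"], omega=r["om"], eta=eta3,
            log_spawners=r["ls"],
        )

    # -- likelihood ------------------------------------------------------

    def _pred_terms(self, f, r):
        """Observation predictors with eta integrated out: returns the
        prediction (without eta), the BH pieces and the total obs SD."""
        lsv = r["ls"][self.oy, self.os]
        lav = r["la"][self.oh, self.os]
        lgv = r["lg"][self.oh, self.os]
        ljv = r["lj"][self.oh, self.os]
        gam = np.exp(lgv)
        q = lav + gam * lsv
        u0 = q - ljv
        sg = expit(u0)
        g = q - np.logaddexp(0.0, u0)
        xb = (self.X[:, 0] * f["bw1"][self.oh]
              + self.X[:, 1] * f["bs1"][self.oh]
              + self.X[:, 2] * f["bw2"][self.oh])
        lv = f["load"][self.oh, self.os]
        pred = g + xb + r["om"][self.oy] * lv
        return pred, gam, lsv, sg, lv

    def _obs_sd(self, f):
        sigev = f["sige"][self.oh, self.os]
        return np.sqrt(self.sig ** 2 + sigev ** 2)

    def joint_nll(self, theta, u):
        f = self.unpack_fixed(theta)
        r = self.unpack_random(u)
        nll = 0.0
        # observation penalties (eta marginalized into the SD)
        pred, _, _, _, _ = self._pred_terms(f, r)
        sd = self._obs_sd(f)
        res = self.mstar - pred
        nll += np.sum(0.5 * (res / sd) ** 2 + np.log(sd) + 0.5 * _LOG2PI)
        rS = self.r_obs - r["ls"][self.ry, self.rs]
        nll += np.sum(0.5 * (rS / self.sd_S) ** 2 + np.log(self.sd_S)
                      + 0.5 * _LOG2PI + self.r_obs)
        # latent-factor prior
        nll += np.sum(0.5 * r["om"] ** 2 + 0.5 * _LOG2PI)
        # hyperdistributions of the shape parameters
        for key, mu, sd in (("la", f["mua"], f["siga"]),
                            ("lg", r["mug"], f["sigg"]),
                            ("lj", r["muj"], f["sigj"])):
            z = (r[key] - mu[:, None]) / sd[:, None]
            nll += np.sum(0.5 * z ** 2 + np.log(sd[:, None]) + 0.5 * _LOG2PI)
        # hypermean penalties (natural-scale centering at 1 and nu_jmax)
        tg, tj = f["taug"], f["tauj"]
        nll += np.sum(0.5 * ((r["mug"] + tg ** 2 / 2) / tg) ** 2
                      + np.log(tg) + 0.5 * _LOG2PI)
        cj = np.log(self.config.nu_jmax) - tj ** 2 / 2
        nll += np.sum(0.5 * ((r["muj"] - cj) / tj) ** 2 + np.log(tj)
                      + 0.5 * _LOG2PI)
        # exponential regularization
        lam, lamg, lamj, lame = f["lams"]
        nll += np.sum(lam * (f["siga"] + f["sigg"] + f["sigj"])
                      - 3 * np.log(lam))
        nll += np.sum(lamg * tg - np.log(lamg))
        nll += np.sum(lamj * tj - np.log(lamj))
        nll += np.sum(lame * f["sige"] - np.log(lame))
        return float(nll) if np.isfinite(nll) else np.inf

    def grad_random(self, theta, u):
        f = self.unpack_fixed(theta)
        r = self.unpack_random(u)
        n_s = self.n_s
        g = np.zeros(self.n_random)
        pred, gam, lsv, sg, lv = self._pred_terms(f, r)
        sd = self._obs_sd(f)
        c0 = -(self.mstar - pred) / sd ** 2
        one = 1.0 - sg
        np.add.at(g, self.gi_ls, c0 * gam * one)
        np.add.at(g, self.gi_la, c0 * one)
        np.add.at(g, self.gi_lg, c0 * gam * lsv * one)
        np.add.at(g, self.gi_lj, c0 * sg)
        np.add.at(g, self.gi_om, c0 * lv)
        # redd penalty
        np.add.at(g, self.off_ls + self.ry * n_s + self.rs,
                  -(self.r_obs - r["ls"][self.ry, self.rs]) / self.sd_S ** 2)
        # priors
        g[self.off_om:self.off_mug] += r["om"]
        zla = (r["la"] - f["mua"][:, None]) / f["siga"][:, None] ** 2
        zlg = (r["lg"] - r["mug"][:, None]) / f["sigg"][:, None] ** 2
        zlj = (r["lj"] - r["muj"][:, None]) / f["sigj"][:, None] ** 2
        g[self.off_la:self.off_lg] += zla.ravel()
        g[self.off_lg:self.off_lj] += zlg.ravel()
        g[self.off_lj:] += zlj.ravel()
        tg, tj = f["taug"], f["tauj"]
        g[self.off_mug:self.off_muj] += (-zlg.sum(axis=1)
                                         + (r["mug"] + tg ** 2 / 2) / tg ** 2)
        cj = np.log(self.config.nu_jmax) - tj ** 2 / 2
        g[self.off_muj:self.off_la] += (-zlj.sum(axis=1)
                                        + (r["muj"] - cj) / tj ** 2)
        return g

    def hess_random(self, theta, u):
        f = self.unpack_fixed(theta)
        r = self.unpack_random(u)
        n_h, n_y, n_s = self.n_h, self.n_y, self.n_s
        rows, cols, vals = [], [], []

        def add(rr, cc, vv):
            rows.append(np.asarray(rr, dtype=np.int64))
            cols.append(np.asarray(cc, dtype=np.int64))
            vals.append(np.asarray(vv, dtype=float))

        pred, gam, lsv, sg, lv = self._pred_terms(f, r)
        sd = self._obs_sd(f)
        res = self.mstar - pred
        one = 1.0 - sg
        isig2 = 1.0 / sd ** 2
        # d pred and d u0 in coordinate order [ls, la, lg, lj, om]
        gidx = [self.gi_ls, self.gi_la, self.gi_lg, self.gi_lj, self.gi_om]
        ones = np.ones_like(gam)
        v = [gam * one, one, gam * lsv * one, sg, lv]
        w = [gam, ones, gam * lsv, -ones, np.zeros_like(gam)]
        c_v = isig2                      # from (1/sd^2) v v'
        c_w = res * sg * one * isig2     # + (r sg(1-sg)/sd^2) w w'
        for i in range(5):
            for j in range(5):
                val = v[i] * v[j] * c_v + w[i] * w[j] * c_w
                add(gidx[i], gidx[j], val)
        # -(r(1-sg)/sd^2) * Q2, Q2 = d^2 q: (lg,lg)=gam*ls, (lg,ls)=(ls,lg)=gam
        cq = -res * one * isig2
        add(self.gi_lg, self.gi_lg, cq * gam * lsv)
        add(self.gi_lg, self.gi_ls, cq * gam)
        add(self.gi_ls, self.gi_lg, cq * gam)
        # redd penalty
        ridx = self.off_ls + self.ry * n_s + self.rs
        add(ridx, ridx, np.full(ridx.size, 1.0 / self.sd_S ** 2))
        # priors (diagonals and hypermean couplings)
        j = np.arange(self.off_om, self.off_mug)
        add(j, j, np.ones(j.size))
        j = np.arange(self.off_la, self.off_lg)
        add(j, j, np.repeat(1.0 / f["siga"] ** 2, n_s))
        for off, sd, moff, tau, in ((self.off_lg, f["sigg"], self.off_mug,
                                     f["taug"]),
                                    (self.off_lj, f["sigj"], self.off_muj,
                                     f["tauj"])):
            j = np.arange(off, off + n_h * n_s)
            prec = np.repeat(1.0 / sd ** 2, n_s)
            add(j, j, prec)
            m = moff + np.repeat(np.arange(n_h), n_s)
            add(j, m, -prec)
            add(m, j, -prec)
            mm = moff + np.arange(n_h)
            add(mm, mm, n_s / sd ** 2 + 1.0 / tau ** 2)
        H = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n_random, self.n_random))
        return H.tocsc()

    # -- starts ----------------------------------------------------------

    def start_values(self):
        """Data-informed starts: latent spawners at the redd observations,
        per-LHP gamma and covariate coefficients from a log-log regression of
        the density-independent residuals, shape intercepts at the residual
        means."""
        n_h, n_y, n_s = self.n_h, self.n_y, self.n_s
        theta = np.zeros(self.n_fixed)
        u = np.zeros(self.n_random)
        ls0 = np.full((n_y, n_s), np.log(10.0))
        ls0[self.ry, self.rs] = self.r_obs
        u[self.off_ls:self.off_om] = ls0.ravel()
        lsv = ls0[self.oy, self.os]
        resid = self.mstar - lsv  # log(M/S): log alpha under gamma = 1
        lg0 = np.zeros(n_h)
        beta0 = np.zeros((n_h, 3))
        for h in range(n_h):
            m = self.oh == h
            if m.sum() >= 8:
                # mstar = la + gamma*ls + x'b  (Jmax ignored at start)
                A = np.column_stack([np.ones(m.sum()), lsv[m], self.X[m]])
                coef, *_ = np.linalg.lstsq(A, self.mstar[m], rcond=None)
                lg0[h] = np.clip(np.log(max(coef[1], 0.05)), -1.0, 0.7)
                beta0[h] = np.clip(coef[2:], -1.0, 1.0)
        la0 = np.zeros((n_h, n_s))
        cnt = np.zeros((n_h, n_s))
        np.add.at(la0, (self.oh, self.os),
                  self.mstar - np.exp(lg0[self.oh]) * lsv)
        np.add.at(cnt, (self.oh, self.os), 1.0)
        la0 = np.where(cnt > 0, la0 / np.maximum(cnt, 1.0), 0.0)
        u[self.off_la:self.off_lg] = la0.ravel()
        u[self.off_lg:self.off_lj] = np.repeat(lg0, n_s)
        u[self.off_mug:self.off_muj] = lg0
        u[self.off_lj:] = np.log(self.config.nu_jmax)
        u[self.off_muj:self.off_la] = np.log(self.config.nu_jmax)
        theta[:4] = la0.mean(axis=1)
        theta[4:16] = -2.5   # hyper-SDs (log scale)
        theta[16:24] = -2.0  # penalty taus
        if self.i_lam is not None:
            theta[self.i_lam:self.i_lam + 4] = 0.0
        theta[self.i_beta:self.i_beta + 4] = beta0[:, 0]
        theta[self.i_beta + 4:self.i_beta + 7] = beta0[1:, 1]
        theta[self.i_beta + 7] = beta0[3, 2]
        theta[self.i_load] = np.log(0.3)
        theta[self.i_load + 1:self.i_load + n_h * n_s] = 0.3
        theta[self.i_sige:] = np.log(0.3)
        return theta, u

    def build_spec(self):
        # floor the penalty/hyper SDs at e^-3.5 ~ 0.03: below that they are
        # statistically indistinguishable from zero (a 3% band on a
        # lognormal scale) but the profile likelihood stays nearly flat and
        # the outer quasi-Newton would creep toward -inf
        bounds = [(-3.5, 4.0) if t == "log" else (None, None)
                  for t in self.trans]
        return inference.MixedModelSpec(
            joint_nll=self.joint_nll, n_fixed=self.n_fixed,
            n_random=self.n_random, grad_random=self.grad_random,
            hess_random=self.hess_random, transforms=self.trans,
            fixed_names=self.names, bounds=bounds,
        )


@dataclass
class RecruitFit:
    """Fitted spawner-to-emigrant model."""

    data: RecruitData
    config: RecruitConfig
    result: inference.FitResult
    params: RecruitParams
    model: _RecruitModel

    def shape_params(self) -> pd.DataFrame:
        rows = []
        for h, lab in enumerate(LHP_LABELS):
            for si, s in enumerate(self.params.streams):
                rows.append((lab, s, self.params.alpha[h, si],
                             self.params.gamma[h, si],
                             self.params.jmax[h, si]))
        return pd.DataFrame(rows, columns=["lhp", "stream", "alpha", "gamma",
                                           "jmax"])

    def hypermeans(self, level=0.95) -> pd.DataFrame:
        """Natural-scale hypermean estimates of gamma and Jmax with Wald
        intervals from the joint-precision covariance (these hypermeans are
        penalized random effects)."""
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2)
        m = self.model
        idx = np.concatenate([np.arange(m.off_mug, m.off_muj),
                              np.arange(m.off_muj, m.off_la)])
        if self.result.cov is None:
            raise ValueError("fit has no covariance")
        sds = inference.conditional_random_sd(
            m.build_spec(), self.result.fixed, self.result.random_mode,
            self.result.cov, idx)
        rows = []
        for k, lab in enumerate(LHP_LABELS):
            mg = self.params.mu_gamma[k]
            rows.append((lab, "gamma", float(np.exp(mg)),
                         float(np.exp(mg - z * sds[k])),
                         float(np.exp(mg + z * sds[k]))))
        for k, lab in enumerate(LHP_LABELS):
            mj = self.params.mu_jmax[k]
            s = sds[4 + k]
            rows.append((lab, "jmax", float(np.exp(mj)),
                         float(np.exp(mj - z * s)), float(np.exp(mj + z * s))))
        return pd.DataFrame(rows, columns=["lhp", "parameter", "estimate",
                                           "lo", "hi"])

    def spawner_range(self):
        """Observed per-km latent-spawner range (prediction data range)."""
        s = np.exp(self.params.log_spawners)
        return float(s.min()), float(s.max())


def fit_recruit(data: RecruitData, config: RecruitConfig | None = None,
                tol=1e-4, covariance="joint-schur", max_iter=150
                ) -> RecruitFit:
    """Fit the hierarchical production model by Laplace-approximated maximum
    marginal likelihood.

    Latent spawners, the annual factor, idiosyncratic errors, shape
    parameters and the gamma/Jmax hypermeans are random effects; hyper-SDs,
    penalty parameters, covariate coefficients, loadings and idiosyncratic
    SDs (and optionally the penalty rates) are fixed effects.  At least two
    streams are required; five or more brood years are recommended.
    """
    config = config or RecruitConfig()
    if len(data.streams) < 2:
        raise ValidationError("need >= 2 streams for hierarchical shape "
                              "parameters")
    if len(data.years) < 3:
        raise ValidationError("need >= 3 brood years")
    model = _RecruitModel(data, config)
    spec = model.build_spec()
    theta0, u0 = model.start_values()
    res = inference.fit(spec, theta0, tol=tol, covariance=covariance,
                        random_start=u0, max_iter=max_iter)
    params = model.params(res.fixed, res.random_mode)
    return RecruitFit(data=data, config=config, result=res, params=params,
                      model=model)


def predict_curves(shapes: pd.DataFrame, spawner_grid,
                   process_sd: dict | None = None) -> pd.DataFrame:
    """Expected emigrants per km and LHP proportions over a spawner grid.

    ``shapes`` has columns (lhp, stream, alpha, gamma, jmax); predictions
    are for an average year (process error 0, covariates at their
    within-stream means).  ``process_sd`` optionally maps (lhp, stream) to
    the process-error SD for a lognormal 95% prediction interval.
    """
    spawner_grid = np.asarray(spawner_grid, dtype=float)
    rows = []
    for stream, grp in shapes.groupby("stream", sort=False):
        J = {}
        for row in grp.itertuples():
            J[row.lhp] = bh_modified(spawner_grid, row.alpha, row.gamma,
                                     row.jmax)
        total = np.sum([J[l] for l in J], axis=0)
        for lab in J:
            prop = np.divide(J[lab], total, out=np.zeros_like(total),
                             where=total > 0)
            lo = hi = np.full_like(prop, np.nan)
            if process_sd is not None:
                sd = process_sd.get((lab, stream), np.nan)
                lo = J[lab] * np.exp(-1.96 * sd)
                hi = J[lab] * np.exp(1.96 * sd)
            for i, s in enumerate(spawner_grid):
                rows.append((stream, lab, float(s), float(J[lab][i]),
                             float(prop[i]), float(lo[i]), float(hi[i])))
    return pd.DataFrame(rows, columns=["stream", "lhp", "S_per_km",
                                       "J_per_km", "proportion", "pi_lo",
                                       "pi_hi"])


def predict(fit: RecruitFit, spawner_grid=None, interval=True
            ) -> pd.DataFrame:
    """Figure-style predictions from a fit: expected abundance and
    proportion of each LHP versus spawners per km (average year)."""
    lo, hi = fit.spawner_range()
    if spawner_grid is None:
        spawner_grid = np.linspace(max(lo, 1e-3), hi, 50)
    else:
        spawner_grid = np.asarray(spawner_grid, dtype=float)
        if spawner_grid.min() < 0.5 * lo or spawner_grid.max() > 2.0 * hi:
            warnings.warn(
                "spawner grid extends well beyond the data range; "
                "predictions are extrapolations", UserWarning)
    psd = None
    if interval:
        psd = {}
        for h, lab in enumerate(LHP_LABELS):
            for si, s in enumerate(fit.params.streams):
                psd[(lab, s)] = float(np.sqrt(
                    fit.params.loadings[h, si] ** 2
                    + fit.params.sigma_eta[h, si] ** 2))
    return predict_curves(fit.shape_params(), spawner_grid, psd)
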