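"""Readers/writers for the pipeline's CSV/JSON interfaces.

CSV is the interchange standard for all tabular inputs/outputs and JSON for
parameters and manifests.  Dates are ISO-8601 and discharge is in m^3/s.
Trap tables use calendar dates; the brood-cycle day axis (day 1 = Jan 1 of
the first calendar year after spawning) is reconstructed at load time:
subyearlings caught in calendar year c belong to brood c-1 at day-of-year d;
yearlings belong to brood c-2 at day 365 + d.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from lhprod import inference
from lhprod.errors import ValidationError
from lhprod.migration import MigrationFit, TrapDataset, _MigrationModel

__all__ = [
    "PipelineConfig",
    "write_trap_tables",
    "read_trap_tables",
    "read_tables",
    "write_simulated_inputs",
    "migration_fit_to_dict",
    "migration_fit_from_dict",
]


def _cycle_day(dates, age_class):
    dates = pd.to_datetime(dates)
    doy = dates.dt.dayofyear
    if age_class == "yearling":
        return dates.dt.year - 2, doy + 365
    return dates.dt.year - 1, doy


def _cycle_date(brood_year, day):
    origin = pd.Timestamp(f"{int(brood_year) + 1}-01-01")
    return origin + pd.Timedelta(days=int(day) - 1)


def write_trap_tables(trap: dict, out_dir):
    """Write the standard catch and mark-recapture CSVs for a dict of
    TrapDatasets keyed (stream, age_class)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    crows, trows = [], []
    for (stream, age), ds in trap.items():
        for yi, yr in enumerate(ds.years):
            for ti, day in enumerate(ds.days):
                crows.append((
                    _cycle_date(yr, day).date().isoformat(), stream, age,
                    ds.catch[yi, ti] if np.isfinite(ds.catch[yi, ti]) else "",
                    bool(ds.operating[yi, ti]), ds.discharge[yi, ti]))
        for d, y, n, k in zip(ds.trial_day, ds.trial_year, ds.released,
                              ds.recaptured):
            trows.append((_cycle_date(y, d).date().isoformat(), stream, age,
                          int(n), int(k)))
    catches = pd.DataFrame(crows, columns=[
        "date", "stream", "age_class", "catch", "operating", "discharge_cms"])
    trials = pd.DataFrame(trows, columns=[
        "date", "stream", "age_class", "released", "recaptured"])
    catches.to_csv(out_dir / "catches.csv", index=False)
    trials.to_csv(out_dir / "trials.csv", index=False)
    return out_dir / "catches.csv", out_dir / "trials.csv"


def read_trap_tables(catches_csv, trials_csv=None) -> dict:
    """Read catch/trial CSVs into TrapDatasets keyed (stream, age_class).

    Validates as it goes; errors carry a row reference.  An absent or empty
    yearling table is allowed (the pipeline then proceeds subyearling-only).
    """
    cat = pd.read_csv(catches_csv)
    need = {"date", "stream", "age_class", "catch", "operating",
            "discharge_cms"}
    missing = need - set(cat.columns)
    if missing:
        raise ValidationError(
            f"{catches_csv}: missing columns {sorted(missing)}")
    if trials_csv is not None and Path(trials_csv).exists():
        tri = pd.read_csv(trials_csv)
        tneed = {"date", "stream", "age_class", "released", "recaptured"}
        tmissing = tneed - set(tri.columns)
        if tmissing:
            raise ValidationError(
                f"{trials_csv}: missing columns {sorted(tmissing)}")
        bad = tri.index[tri["recaptured"] > tri["released"]]
        if len(bad):
            raise ValidationError(
                f"{trials_csv} row {bad[0]}: recaptured > released")
    else:
        tri = pd.DataFrame(columns=["date", "stream", "age_class",
                                    "released", "recaptured"])
    out = {}
    for (stream, age), g in cat.groupby(["stream", "age_class"]):
        by, day = _cycle_day(g["date"], age)
        g = g.assign(brood_year=by, day=day)
        years = np.array(sorted(g["brood_year"].unique()))
        days = np.arange(g["day"].min(), g["day"].max() + 1)
        Y, T = len(years), len(days)
        catch = np.full((Y, T), np.nan)
        operating = np.zeros((Y, T), dtype=bool)
        discharge = np.full((Y, T), np.nan)
        yi = np.searchsorted(years, g["brood_year"].to_numpy())
        ti = np.searchsorted(days, g["day"].to_numpy())
        cvals = pd.to_numeric(g["catch"], errors="coerce").to_numpy()
        catch[yi, ti] = cvals
        operating[yi, ti] = g["operating"].astype(bool).to_numpy()
        discharge[yi, ti] = g["discharge_cms"].to_numpy()
        catch[~operating] = np.nan
        tg = tri[(tri["stream"] == stream) & (tri["age_class"] == age)]
        if len(tg):
            tby, tday = _cycle_day(tg["date"], age)
            out[(stream, age)] = TrapDataset(
                stream=stream, age_class=age, days=days, years=years,
                catch=catch, operating=operating, discharge=discharge,
                trial_day=tday.to_numpy(), trial_year=tby.to_numpy(),
                released=tg["released"].to_numpy(),
                recaptured=tg["recaptured"].to_numpy())
        else:
            out[(stream, age)] = TrapDataset(
                stream=stream, age_class=age, days=days, years=years,
                catch=catch, operating=operating, discharge=discharge)
    return out


def read_tables(config) -> tuple:
    """Read the five input tables of a :class:`PipelineConfig`; returns
    (trap datasets, redds, discharge, habitat lengths)."""
    trap = read_trap_tables(config.catches_csv, config.trials_csv)
    redds = pd.read_csv(config.redds_csv)
    if not {"year", "stream", "redds"}.issubset(redds.columns):
        raise ValidationError(f"{config.redds_csv}: needs (year, stream, redds)")
    discharge = pd.read_csv(config.discharge_csv)
    habitat_df = pd.read_csv(config.habitat_csv)
    if not {"stream", "habitat_km"}.issubset(habitat_df.columns):
        raise ValidationError(
            f"{config.habitat_csv}: needs (stream, habitat_km)")
    habitat = dict(zip(habitat_df["stream"], habitat_df["habitat_km"]))
    known = set(habitat)
    for name, df in (("catches", pd.DataFrame({"stream": [k[0] for k in trap]})),
                     ("redds", redds), ("discharge", discharge)):
        unknown = set(df["stream"]) - known
        if unknown:
            raise ValidationError(
                f"{name} table references streams missing from habitat "
                f"table: {sorted(unknown)}")
    ages = {a for (_, a) in trap}
    if "yearling" not in ages:
        import warnings

        warnings.warn("no yearling trap data; proceeding subyearling-only",
                      UserWarning)
    return trap, redds, discharge, habitat


def write_simulated_inputs(sim, out_dir):
    """Write a SimulatedData bundle as the standard input CSVs plus the
    truth record (CSV bundle + JSON of true parameters)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_trap_tables(sim.trap, out_dir)
    sim.redds.to_csv(out_dir / "redds.csv", index=False)
    sim.discharge.assign(
        date=pd.to_datetime(sim.discharge["date"]).dt.date
    ).to_csv(out_dir / "discharge.csv", index=False)
    pd.DataFrame({"stream": list(sim.habitat),
                  "habitat_km": list(sim.habitat.values())}
                 ).to_csv(out_dir / "habitat.csv", index=False)
    truth_dir = out_dir / "truth"
    truth_dir.mkdir(exist_ok=True)
    sim.truth.window_totals.to_csv(truth_dir / "window_totals.csv",
                                   index=False)
    sim.truth.spawners.to_csv(truth_dir / "spawners.csv", index=False)
    if sim.truth.recruitment is not None:
        sim.truth.recruitment.to_csv(truth_dir / "recruitment.csv",
                                     index=False)
    if sim.truth.covariates is not None:
        sim.truth.covariates.to_csv(truth_dir / "covariates.csv", index=False)
    with open(truth_dir / "true_params.json", "w") as fh:
        json.dump(_jsonable(sim.truth.params), fh, indent=1)
    return out_dir


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def migration_fit_to_dict(fit: MigrationFit) -> dict:
    r = fit.result
    return {
        "stream": fit.dataset.stream,
        "age_class": fit.dataset.age_class,
        "fixed": r.fixed.tolist(),
        "fixed_names": r.fixed_names,
        "fixed_natural": r.fixed_natural.tolist(),
        "random_mode": r.random_mode.tolist(),
        "cov": None if r.cov is None else r.cov.tolist(),
        "nll": r.nll,
        "grad_norm": r.grad_norm,
        "converged": r.converged,
        "n_iter": r.n_iter,
        "boundary": r.boundary,
        "cov_method": r.cov_method,
    }


def migration_fit_from_dict(dataset: TrapDataset, d: dict) -> MigrationFit:
    """Rebuild a MigrationFit (including its model machinery) from the
    serialized estimate; used for stage caching."""
    from scipy.special import expit

    model = _MigrationModel(dataset)
    spec = model.build_spec()
    theta = np.asarray(d["fixed"], dtype=float)
    u = np.asarray(d["random_mode"], dtype=float)
    res = inference.FitResult(
        spec=spec, fixed=theta, fixed_natural=np.asarray(d["fixed_natural"]),
        fixed_names=list(d["fixed_names"]), random_mode=u, nll=d["nll"],
        cov=None if d["cov"] is None else np.asarray(d["cov"]),
        grad_norm=d["grad_norm"], converged=d["converged"],
        n_iter=d["n_iter"], message="cached", boundary=list(d["boundary"]),
        cov_method=d.get("cov_method", "fd-marginal"))
    params = model.params(theta, u)
    r = model.unpack_random(u)
    m_hat = np.exp(params.mu_m[:, None] + r["delta"][None, :] + r["eps"])
    Dz = dataset.discharge_z()
    w = np.arange(dataset.n_days) // 7
    b = (r["iota"][:, None] + r["kappa"][:, None] * Dz
         + r["nu"][w][None, :] + r["xi"][:, w])
    p_hat = expit(b)
    p_hat[~np.isfinite(Dz)] = np.nan
    return MigrationFit(dataset=dataset, result=res, params=params,
                        m_hat=m_hat, p_hat=p_hat, model=model)


@dataclass
class PipelineConfig:
    """Paths, seeds and tunables for the end-to-end pipeline."""

    output_dir: str = "results/pipeline"
    seed: int = 1
    simulate: bool = True
    synthetic: dict = field(default_factory=dict)
    catches_csv: str | None = None
    trials_csv: str | None = None
    redds_csv: str | None = None
    habitat_csv: str | None = None
    discharge_csv: str | None = None
    n_draws: int = 2000
    mixture_pooling: str = "mean"
    mixture_seed: int = 0
    nu_jmax: float = 1.5e4
    estimate_lambdas: bool = False
    spawner_obs_sd: float = 0.1
    migration_tol: float = 1e-4
    recruit_tol: float = 1e-4
    cache: bool = True
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self):
        return dataclasses.asdict(self)

    def config_hash(self):
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def validate_paths(self):
        if self.simulate:
            return
        for name in ("catches_csv", "redds_csv", "habitat_csv",
                     "discharge_csv"):
            p = getattr(self, name)
            if p is None or not Path(p).exists():
                raise ValidationError(f"{name}: path missing or nonexistent "
                                      f"({p})")
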