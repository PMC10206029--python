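"""Orchestration of the three-stage pipeline with stage caching.

Stages: (optional) simulate -> fit-migration (per stream x age-class) ->
delineate -> bootstrap -> fit-recruit -> predict.  Every artifact is written
under the run directory with a manifest (package/library versions, seed,
config hash, stage timings).  Fitted migration models are serialized and
reused on rerun when the inputs and configuration are unchanged.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

import lhprod
from lhprod import delineation, io, migration, recruit, simulate
from lhprod.errors import ValidationError

__all__ = ["run_pipeline", "STAGES"]

STAGES = ("simulate", "fit-migration", "delineate", "bootstrap",
          "fit-recruit", "predict")

log = logging.getLogger("lhprod")


def run_pipeline(config: io.PipelineConfig, until="predict") -> dict:
    """Run the pipeline up to (and including) stage ``until``.

    Returns a dict of in-memory artifacts; files land under
    ``config.output_dir``.  Deterministic given the config seed.
    """
    if until not in STAGES:
        raise ValidationError(f"unknown stage {until!r}")
    logging.basicConfig(level=getattr(logging, config.log_level, 20),
                        format="%(levelname)s %(name)s: %(message)s")
    t_start = time.time()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings = {}
    manifest = {
        "package": "lhprod",
        "version": lhprod.__version__,
        "versions": _lib_versions(),
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stages": [],
        "files": [],
    }
    arts = {}
    stop = STAGES.index(until)

    # -- simulate / load -------------------------------------------------
    t0 = time.time()
    if config.simulate:
        syn = simulate.SyntheticConfig(
            **{"seed": config.seed, **config.synthetic})
        sim = simulate.simulate_dataset(syn)
        in_dir = io.write_simulated_inputs(sim, out_dir / "inputs")
        arts["truth"] = sim.truth
        config.catches_csv = str(in_dir / "catches.csv")
        config.trials_csv = str(in_dir / "trials.csv")
        config.redds_csv = str(in_dir / "redds.csv")
        config.habitat_csv = str(in_dir / "habitat.csv")
        config.discharge_csv = str(in_dir / "discharge.csv")
    config.validate_paths()
    trap, redds, discharge, habitat = io.read_tables(config)
    arts.update(trap=trap, redds=redds, discharge=discharge, habitat=habitat)
    timings["simulate"] = time.time() - t0
    manifest["stages"].append("simulate")
    if stop < 1:
        return _finish(manifest, timings, out_dir, arts, t_start)

    # -- Step 1: daily-emigrant models ----------------------------------
    t0 = time.time()
    fits = {}
    fit_dir = out_dir / "migration"
    fit_dir.mkdir(exist_ok=True)
    input_hash = _file_hash(config.catches_csv, config.trials_csv)
    for key, ds in sorted(trap.items()):
        stream, age = key
        tag = f"{stream}_{age}"
        cache_file = fit_dir / f"fit_{tag}.json"
        cache_key = f"{input_hash}:{config.migration_tol}"
        fit = None
        if config.cache and cache_file.exists():
            d = json.loads(cache_file.read_text())
            if d.get("cache_key") == cache_key:
                fit = io.migration_fit_from_dict(ds, d)
                log.info("stage fit-migration: cached %s", tag)
        if fit is None:
            log.info("stage fit-migration: fitting %s", tag)
            fit = migration.fit_migration(ds, tol=config.migration_tol)
            d = io.migration_fit_to_dict(fit)
            d["cache_key"] = cache_key
            cache_file.write_text(json.dumps(d))
        fits[key] = fit
        fit.daily_estimates().to_csv(fit_dir / f"daily_{tag}.csv",
                                     index=False)
        manifest["files"] += [str(cache_file), str(fit_dir / f"daily_{tag}.csv")]
    arts["migration_fits"] = fits
    timings["fit-migration"] = time.time() - t0
    manifest["stages"].append("fit-migration")
    if stop < 2:
        return _finish(manifest, timings, out_dir, arts, t_start)

    # -- Step 2: delineation --------------------------------------------
    t0 = time.time()
    days, pooled = delineation.pooled_daily_series(
        fits.values(), mode=config.mixture_pooling)
    mix = delineation.fit_day_mixture(days, pooled, seed=config.mixture_seed)
    sub_season = (min(d.days.min() for (s, a), d in trap.items()
                      if a == "subyearling"),
                  max(d.days.max() for (s, a), d in trap.items()
                      if a == "subyearling"))
    if any(a == "yearling" for (_, a) in trap):
        yr_season = (min(d.days.min() for (s, a), d in trap.items()
                         if a == "yearling"),
                     max(d.days.max() for (s, a), d in trap.items()
                         if a == "yearling"))
    else:
        yr_season = (sub_season[1] + 100, sub_season[1] + 200)
    windows = delineation.make_windows(mix, sub_season, yr_season)
    windows.to_frame().to_csv(out_dir / "lhp_windows.csv", index=False)
    with open(out_dir / "mixture_fit.json", "w") as fh:
        json.dump({"means": mix.means.tolist(), "sds": mix.sds.tolist(),
                   "weights": mix.weights.tolist(), "loglik": mix.loglik,
                   "n_iter": mix.n_iter}, fh, indent=1)
    arts["windows"] = windows
    arts["mixture"] = mix
    timings["delineate"] = time.time() - t0
    manifest["stages"].append("delineate")
    manifest["files"] += [str(out_dir / "lhp_windows.csv"),
                          str(out_dir / "mixture_fit.json")]
    if stop < 3:
        return _finish(manifest, timings, out_dir, arts, t_start)

    # -- bootstrap window totals ----------------------------------------
    t0 = time.time()
    summaries = []
    for i, (key, fit) in enumerate(sorted(fits.items())):
        _, age = key
        w = windows.for_age(age)
        summaries.append(migration.bootstrap_window_totals(
            fit, w, n_draws=config.n_draws,
            seed=config.seed * 1000 + i))
    emigrants = pd.concat(summaries, ignore_index=True)
    emigrants.to_csv(out_dir / "emigrant_summary.csv", index=False)
    arts["emigrants"] = emigrants
    timings["bootstrap"] = time.time() - t0
    manifest["stages"].append("bootstrap")
    manifest["files"].append(str(out_dir / "emigrant_summary.csv"))
    if stop < 4:
        return _finish(manifest, timings, out_dir, arts, t_start)

    # -- Step 3: spawner-to-emigrant model ------------------------------
    t0 = time.time()
    brood_years = sorted(emigrants["brood_year"].unique())
    covariates = simulate._covariates_from_discharge(
        discharge, np.asarray(brood_years, dtype=int))
    rdata = recruit.RecruitData(emigrants=emigrants, redds=redds,
                                habitat_km=habitat, covariates=covariates)
    rconfig = recruit.RecruitConfig(
        nu_jmax=config.nu_jmax, spawner_obs_sd=config.spawner_obs_sd,
        estimate_lambdas=config.estimate_lambdas)
    rfit = recruit.fit_recruit(rdata, rconfig, tol=config.recruit_tol)
    rfit.shape_params().to_csv(out_dir / "recruit_shape_params.csv",
                               index=False)
    rfit.hypermeans().to_csv(out_dir / "recruit_hypermeans.csv", index=False)
    arts["recruit_fit"] = rfit
    timings["fit-recruit"] = time.time() - t0
    manifest["stages"].append("fit-recruit")
    manifest["files"] += [str(out_dir / "recruit_shape_params.csv"),
                          str(out_dir / "recruit_hypermeans.csv")]
    if stop < 5:
        return _finish(manifest, timings, out_dir, arts, t_start)

    # -- predictions -----------------------------------------------------
    t0 = time.time()
    preds = recruit.predict(rfit)
    preds.to_csv(out_dir / "lhp_predictions.csv", index=False)
    arts["predictions"] = preds
    timings["predict"] = time.time() - t0
    manifest["stages"].append("predict")
    manifest["files"].append(str(out_dir / "lhp_predictions.csv"))
    return _finish(manifest, timings, out_dir, arts, t_start)


def _finish(manifest, timings, out_dir, arts, t_start):
    manifest["timings_s"] = {k: round(v, 3) for k, v in timings.items()}
    manifest["total_s"] = round(time.time() - t_start, 3)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    for stage, dt in timings.items():
        log.info("stage %s: %.1fs", stage, dt)
    arts["manifest"] = manifest
    arts["output_dir"] = out_dir
    return arts


def _lib_versions():
    import pandas
    import scipy

    return {"numpy": np.__version__, "scipy": scipy.__version__,
            "pandas": pandas.__version__}


def _file_hash(*paths):
    import hashlib

    h = hashlib.sha256()
    for p in paths:
        if p and Path(p).exists():
            h.update(Path(p).read_bytes())
    return h.hexdigest()[:16]
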