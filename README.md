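# lhprod

Density- and environment-dependent production of juvenile life-history
pathways (LHPs) in stream-rearing salmonids, estimated from rotary-screw-trap
monitoring data.

Juvenile Chinook salmon leave their natal stream along four timing pathways
— spring, summer and fall of their first year, or the following spring as
yearlings — and the mix of pathways shifts with the density of spawners and
with stream discharge.  Quantifying those shifts takes three linked
inferences, each of which this package implements as a tested, reusable
component:

1. **Daily emigrant abundance** (`lhprod.migration`) — a state-space model
   per stream × age class: latent daily abundance
   `log m_{t,y} = mu_y + delta_t + eps_{t,y}` with a random-walk seasonal
   profile and stationary AR(1) year deviations; discharge-dependent trap
   capture probability `logit p = iota_y + kappa_y D + nu_w + xi_{w,y}`
   informed by binomial mark–recapture trials; negative-binomial catches
   with variance `mu + mu^2 phi`.  Fit by maximum marginal likelihood with
   a Laplace approximation over the random effects.
2. **LHP delineation** (`lhprod.delineation`) — a four-component normal
   mixture over the pooled daily series on the brood-cycle day axis;
   window cutoffs at the interior minima of the fitted density; window
   totals `M_{h,y,s}`, with uncertainty from a multivariate-normal
   parametric bootstrap of the stage-1 fit.
3. **Spawner-to-emigrant production** (`lhprod.recruit`) — a hierarchical
   generalized (Myers) Beverton–Holt model per LHP and stream,

       J = alpha S^gamma / (1 + alpha S^gamma / Jmax) * exp(eps),

   where `gamma > 1` means accelerating (positive density-dependent)
   production and `gamma < 1` with finite `Jmax` decelerating production.
   Penalties center the hypermeans at density independence (`gamma` at 1,
   `Jmax` at 15,000/km) so the data must earn any density dependence.
   Process errors carry winter/summer discharge covariates, a shared
   annual latent factor (rank-1 correlation across series), and
   independent noise.

`lhprod.simulate` generates seeded synthetic monitoring programs with this
full structure (the package's test bed); `lhprod.inference` is the generic
Laplace/mixed-model machinery; `lhprod.io` + `lhprod.pipeline` + the
`lhprod` CLI orchestrate the stages.

## Worked example

The numbered scripts under `analysis/` run the pipeline on the default
synthetic program (three streams, eight brood years) and cache stages under
`results/analysis`:

```bash
python analysis/01_simulate_monitoring_program.py
python analysis/02_fit_daily_emigrants.py
python analysis/03_delineate_lhps.py
python analysis/04_bootstrap_window_totals.py
python analysis/05_fit_stock_recruit.py
python analysis/06_predict_lhp_prevalence.py
```

Step 3 prints the delineated windows (seed 1):

```
timing mixture components (brood-cycle day):
  mean  100.5  sd  14.2  weight 0.548
  mean  201.4  sd  22.9  weight 0.324
  mean  285.5  sd   8.6  weight 0.080
  mean  470.4  sd  16.1  weight 0.048
emigration windows:
    lhp  t0  tf
spring0  60 144
summer0 145 261
  fall0 262 299
spring1 429 549
```

— the four mixture components sit on the generator's timing modes
(days 100/200/290/470) and the cutoffs split the season at the density
minima between them.  Step 4 reports that the bootstrap intervals cover
the generator's true log window totals at rate 0.95 (median log error
−0.017).  Step 5 prints the density-dependence hypermeans: this synthetic
world generated spring subyearlings with accelerating production (`gamma`
1.5) and spring yearlings with strongly decelerating production (`gamma`
0.4); at the eight-year scale the fit recovers the yearling signal
decisively (`exp(mu_gamma)` = 0.26) while the subyearling acceleration is
not yet separable from 1 (estimate 1.008 with a wide interval — eight
brood years is deliberately little data; the 50-year recovery tests in
`tests/test_acceptance.py` detect both).  Step 6 accordingly shows the
yearling pathway's share of emigrants falling as spawner density rises
(e.g. 0.088 → 0.019 in the largest stream) while the subyearling pathways
gain.

The same pipeline is scriptable (`lhprod run-all --config cfg.yaml
--seed 1`) or callable directly:

```python
from lhprod.io import PipelineConfig
from lhprod.pipeline import run_pipeline

arts = run_pipeline(PipelineConfig(seed=1, synthetic={"n_years": 8}))
arts["recruit_fit"].hypermeans()   # exp(mu_gamma), exp(mu_Jmax) with CIs
arts["predictions"]                # abundance & proportion vs spawners
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the entire pipeline from scratch — simulating the monitoring
program, fitting the six daily-emigrant models, delineating the windows,
bootstrapping the window totals, fitting the hierarchical production model
and writing the prediction curves — with all randomness derived from
`--seed`, and writes its result JSON to `--out` (pipeline artifacts land
next to it under `pipeline/`).

See `docs/methods.md` for the model details, numerical choices, and what
the synthetic world does and does not emulate.
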