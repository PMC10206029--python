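"""Shared configuration of the demonstration analysis.

The numbered scripts run the three-stage pipeline on the default synthetic
monitoring program: three natal streams, eight brood years, four emigration
timing modes, screw-trap efficiency around 8% with a negative discharge
effect, and recruitment shape parameters with accelerating spring-subyearling
production (gamma 1.5) and decelerating yearling production (gamma 0.4).
Stages are cached under results/analysis, so each script reuses the work of
the previous ones.
"""

from lhprod.io import PipelineConfig


def analysis_config(seed=1):
    return PipelineConfig(
        output_dir="results/analysis",
        seed=seed,
        simulate=True,
        synthetic={"n_years": 8},
        n_draws=2000,
        estimate_lambdas=False,
    )
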