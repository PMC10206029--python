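"""Step 1: fit the daily-emigrant state-space model per stream x age-class.

Each fit maximizes the Laplace-approximated marginal likelihood over the
year means, process SDs, AR(1) coefficient, NB overdispersion and capture
coefficients, integrating over the seasonal profile, daily deviations and
capture random effects.  Prints the capture-probability intercept/slope and
overall abundance scale per dataset.
"""

import sys

import numpy as np

sys.path.insert(0, "analysis")
from pipeline_config import analysis_config

from lhprod.pipeline import run_pipeline


def main():
    arts = run_pipeline(analysis_config(), until="fit-migration")
    print("fitted daily-emigrant models:")
    for (stream, age), fit in sorted(arts["migration_fits"].items()):
        nat = dict(zip(fit.result.fixed_names, fit.result.fixed_natural))
        total = fit.m_hat.sum() / fit.dataset.n_years
        print(f"  {stream:8s} {age:11s} beta0_p {nat['beta0_p']: .2f} "
              f"beta1_p {nat['beta1_p']: .2f} rho {nat['rho_eps']: .2f} "
              f"phi {nat['nb_phi']:.3f}  mean emigrants/yr {total:,.0f}")
    print(f"daily estimates under {arts['output_dir']}/migration/")


if __name__ == "__main__":
    main()
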