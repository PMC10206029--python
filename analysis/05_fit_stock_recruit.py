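"""Step 3: fit the penalized hierarchical Beverton-Holt production model.

Emigrant summaries and redd counts (both per km of spawning habitat) inform
a generalized Beverton-Holt curve per LHP and stream, with lognormal
hyperdistributions across streams, penalties that center gamma at 1 and
Jmax at 15,000/km unless the data argue otherwise, discharge covariates on
the process errors, and a shared annual latent factor.
"""

import sys

import numpy as np

sys.path.insert(0, "analysis")
from pipeline_config import analysis_config

from lhprod.pipeline import run_pipeline


def main():
    arts = run_pipeline(analysis_config(), until="fit-recruit")
    fit = arts["recruit_fit"]
    hm = fit.hypermeans()
    print("hypermean density-dependence parameters (natural scale):")
    print(hm.round(3).to_string(index=False))
    print("discharge coefficients (winter 1):")
    for lab in ("spring0", "summer0", "fall0", "spring1"):
        print(f"  {lab:8s} {fit.params.beta[lab]['winter1']: .3f}")
    print(f"shape parameters under {arts['output_dir']}/"
          "recruit_shape_params.csv")


if __name__ == "__main__":
    main()
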