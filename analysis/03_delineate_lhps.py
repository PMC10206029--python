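"""Step 2: delineate the four life-history pathways from emigration timing.

Pools the estimated daily abundances across streams and years (cross-year
mean), fits a four-component normal mixture to the abundance-weighted day
values, and places window cutoffs at the interior minima of the fitted
density.
"""

import sys

sys.path.insert(0, "analysis")
from pipeline_config import analysis_config

from lhprod.pipeline import run_pipeline


def main():
    arts = run_pipeline(analysis_config(), until="delineate")
    mix = arts["mixture"]
    print("timing mixture components (brood-cycle day):")
    for m, s, w in zip(mix.means, mix.sds, mix.weights):
        print(f"  mean {m:6.1f}  sd {s:5.1f}  weight {w:.3f}")
    print("emigration windows:")
    print(arts["windows"].to_frame().to_string(index=False))


if __name__ == "__main__":
    main()
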