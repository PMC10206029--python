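"""Generate the synthetic monitoring program and write its input tables.

Produces daily screw-trap catches, mark-recapture trials, redd counts,
daily discharge and habitat lengths for three streams over eight brood
years, plus the truth record (latent daily abundances, window totals,
process errors) used by downstream comparisons.
"""

import sys

sys.path.insert(0, "analysis")
from pipeline_config import analysis_config

from lhprod.pipeline import run_pipeline


def main():
    arts = run_pipeline(analysis_config(), until="simulate")
    truth = arts["truth"]
    n_catch = sum(int((~__import__("numpy").isnan(d.catch)).sum())
                  for d in arts["trap"].values())
    print(f"wrote inputs under {arts['output_dir']}/inputs")
    print(f"  {len(arts['trap'])} stream x age-class trap datasets, "
          f"{n_catch} observed catch days")
    print(f"  {len(arts['redds'])} redd counts, "
          f"{len(truth.window_totals)} true LHP window totals")


if __name__ == "__main__":
    main()
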