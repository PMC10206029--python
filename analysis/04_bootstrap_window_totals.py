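"""Parametric bootstrap of LHP window totals.

Draws parameter sets from the multivariate normal defined by each migration
fit's estimates and covariance, propagates them (with the conditional
random-effect distribution) to daily abundances, and summarizes each
(LHP, brood year, stream) window total as a log-mean and log-SD — the
observation penalties of the spawner-recruit model.
"""

import sys

import numpy as np

sys.path.insert(0, "analysis")
from pipeline_config import analysis_config

from lhprod.pipeline import run_pipeline


def main():
    arts = run_pipeline(analysis_config(), until="bootstrap")
    emi = arts["emigrants"]
    print(f"bootstrap summaries for {len(emi)} (lhp, brood year, stream) "
          f"cells; median log-SD {emi['log_sd'].median():.3f}")
    truth = arts["truth"].window_totals.set_index(
        ["lhp", "brood_year", "stream"])
    joined = emi.set_index(["lhp", "brood_year", "stream"]).join(truth)
    err = joined["log_mean"] - np.log(joined["M"])
    cover = (np.abs(err) <= 1.96 * joined["log_sd"]).mean()
    print(f"interval coverage of true log totals: {cover:.2f} "
          f"(median log error {err.median(): .3f})")


if __name__ == "__main__":
    main()
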