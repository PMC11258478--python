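"""Dose-response of sleep duration against the four age metrics.

Runs the full pipeline through the association stage: categorical
contrasts against the 7 h/day reference, median-substitution trend
tests, and restricted-cubic-spline curves with nonlinearity Wald tests.
Writes the association tables under results/associations/ and prints the
spline verdicts (the U-shape finding).
"""

import sys
from pathlib import Path

import pandas as pd

from sleepbioage.pipeline import PipelineConfig, run_pipeline
from sleepbioage.report import write_report

OUT = Path(__file__).resolve().parent.parent / "results" / "associations"


def run(seed: int = 20240001) -> None:
    cfg = PipelineConfig(seed=seed, run_stratified=False, run_sensitivity=False,
                         run_mediation=False)
    run_pipeline(cfg, OUT)
    write_report(OUT)
    rcs = pd.read_csv(OUT / "association_rcs.tsv", sep="\t")
    print("restricted cubic spline nonlinearity tests:")
    print(rcs[["outcome", "p_overall", "p_nonlinear", "significant_nonlinear"]]
          .to_string(index=False))
    curves = pd.read_csv(OUT / "rcs_curves.tsv", sep="\t")
    for outcome, c in curves.groupby("outcome"):
        argmin = c.loc[c["estimate"].idxmin(), "hours"]
        print(f"{outcome}: curve minimum at {argmin:.2f} h/day")


if __name__ == "__main__":
    run(int(sys.argv[1]) if len(sys.argv) > 1 else 20240001)
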