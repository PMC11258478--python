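"""Generate the synthetic study cohorts.

Writes a reference cohort (with Gompertz mortality follow-up, for metric
training), a target cohort (sleep exposures, mediators, covariates), and
a genotype dosage matrix with its SNP weight table, all as TSV under
results/cohorts/. Prints the cohort sizes and the share of the target in
each sleep-duration category.
"""

import sys
from pathlib import Path

from sleepbioage.cli import main as cli_main
from sleepbioage.cohorts import generate_target_cohort
from sleepbioage.config import SyntheticConfig
from sleepbioage.exposure import categorize_sleep_durations

OUT = Path(__file__).resolve().parent.parent / "results" / "cohorts"


def run(seed: int = 20240001) -> None:
    sys.argv = ["sleepbioage", "simulate", "--seed", str(seed), "--out", str(OUT)]
    try:
        cli_main(standalone_mode=False)
    except SystemExit:
        pass
    target = generate_target_cohort(SyntheticConfig(seed=seed))
    shares = (
        categorize_sleep_durations(target["sleep_hours"]).value_counts(normalize=True)
    )
    print(f"wrote cohorts to {OUT}")
    print("sleep-duration category shares:")
    print(shares.round(3).to_string())


if __name__ == "__main__":
    run(int(sys.argv[1]) if len(sys.argv) > 1 else 20240001)
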