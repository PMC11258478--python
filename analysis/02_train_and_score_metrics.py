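"""Train the four predicted-age metrics and score the target cohort.

Fits KDM, PhenoAge, HD, and the AL quartile thresholds on the reference
cohort, scores the target cohort, and appends age-acceleration residuals.
Writes trained_models.json and the scored participant table under
results/metrics/, and prints the per-metric summary statistics.
"""

import sys
from pathlib import Path

from sleepbioage.cohorts import generate_reference_cohort, generate_target_cohort
from sleepbioage.config import SyntheticConfig
from sleepbioage.pipeline import PipelineConfig, score_metrics, train_metrics

OUT = Path(__file__).resolve().parent.parent / "results" / "metrics"


def run(seed: int = 20240001) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = PipelineConfig(seed=seed)
    reference = generate_reference_cohort(cfg.synthetic)
    models = train_metrics(reference, cfg)
    models.to_json(str(OUT / "trained_models.json"))
    target = score_metrics(generate_target_cohort(cfg.synthetic), models, cfg)
    target.to_csv(OUT / "scored_target.tsv", sep="\t", index=False)
    print(f"trained on n={len(reference)} ({int(reference['death'].sum())} deaths); "
          f"scored n={len(target)}")
    cols = ["hd", "phenoage", "kdm", "al", "phenoage_residual", "kdm_residual"]
    print(target[cols].describe().loc[["mean", "std", "min", "max"]].round(3))


if __name__ == "__main__":
    run(int(sys.argv[1]) if len(sys.argv) > 1 else 20240001)
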