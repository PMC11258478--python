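"""Human-readable summary of a completed pipeline run."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .exposure import CATEGORY_LABELS

SECTION_FILES = {
    "exclusions": "exclusion_ledger.tsv",
    "metrics": "trained_models.json",
    "associations": "association_category.tsv",
    "strata": "stratified_interactions.tsv",
    "mediation": "mediation.tsv",
}


def write_report(output_dir: str | Path, path: str | Path | None = None) -> str:
    """Render ``report.md`` from a run's tables.

    Sections whose stage was disabled are omitted cleanly; files that a
    completed stage should have produced but did not are listed at the top.
    """
    out = Path(output_dir)
    path = Path(path) if path is not None else out / "report.md"
    lines = ["# Sleep duration and predicted-age metrics: run summary", ""]

    present = {k: (out / f).exists() for k, f in SECTION_FILES.items()}

    if present["exclusions"]:
        lines += ["## Exclusions", ""]
        ledger = pd.read_csv(out / SECTION_FILES["exclusions"], sep="\t")
        lines += [ledger.to_markdown(index=False), ""]

    if present["metrics"]:
        with open(out / SECTION_FILES["metrics"]) as fh:
            doc = json.load(fh)
        lines += ["## Trained metrics", ""]
        lines += [
            f"- reference cohort: n = {doc['training_summary']['n']}, "
            f"ages {doc['training_summary']['age_min']:.1f}-"
            f"{doc['training_summary']['age_max']:.1f}, "
            f"{doc['training_summary']['events']} deaths",
            f"- KDM biomarkers retained: {len(doc['kdm']['biomarkers'])} "
            f"(excluded: {doc['kdm']['excluded'] or 'none'})",
            f"- Gompertz shape: {doc['phenoage']['gamma']:.4f} per year",
            "",
        ]

    if present["associations"]:
        lines += ["## Associations (beta vs 7 h/day reference)", ""]
        cat = pd.read_csv(out / SECTION_FILES["associations"], sep="\t")
        cat = cat[cat["term"].str.startswith("sleep[")].copy()
        cat["category"] = (
            cat["term"].str.extract(r"sleep\[(.+)\]")[0].map(CATEGORY_LABELS)
        )
        show = cat[["outcome", "category", "beta", "ci_low", "ci_high", "p"]]
        lines += [show.round(4).to_markdown(index=False), ""]
        rcs_path = out / "association_rcs.tsv"
        if rcs_path.exists():
            rcs = pd.read_csv(rcs_path, sep="\t")
            lines += ["### Dose-response (restricted cubic spline)", "",
                      rcs.round(6).to_markdown(index=False), ""]

    if present["strata"]:
        lines += ["## Stratified analyses", ""]
        strat = pd.read_csv(out / SECTION_FILES["strata"], sep="\t")
        lines += [strat.round(4).to_markdown(index=False), ""]

    if present["mediation"]:
        lines += ["## Mediation through CysC and GGT", ""]
        med = pd.read_csv(out / SECTION_FILES["mediation"], sep="\t")
        lines += [med.round(4).to_markdown(index=False), ""]
        if med.get("note", pd.Series(dtype=str)).fillna("").str.len().gt(0).any():
            lines += ["Entries marked NA have a total effect near zero, so the "
                      "proportion mediated is undefined.", ""]

    missing = [
        f for k, f in SECTION_FILES.items()
        if not present[k] and k in ("exclusions", "associations")
    ]
    if missing:
        lines.insert(2, "Missing expected outputs: " + ", ".join(missing))
        lines.insert(3, "")

    text = "\n".join(lines)
    path.write_text(text)
    return str(path)
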