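"""End-to-end screening run: claims in, tidy report tables out.

Glues the pipeline stages together for the command-line interface: read
and validate claims, build the cohort, run the detector, and write
prevalence, rank, sample-summary and chronic-anticholinergic CSVs plus a
run manifest recording the catalog version and row counts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from datetime import date
from pathlib import Path

import yaml

from .burden import chronic_users_to_frame, summarize_chronic_users
from .catalog import BeersCatalog, load_catalog
from .cohort import StudyWindow, build_cohort
from .engine import detect_all, events_to_frame
from .io import DialectConfig, read_deaths, read_dispensing
from .reporting import (
    annual_prevalence,
    percent,
    prevalence_to_frame,
    rank_pims,
    ranks_to_frame,
    summarize_sample,
)


@dataclass(frozen=True)
class PipelineConfig:
    """Run configuration (the YAML file the CLI reads)."""

    dialect: DialectConfig = DialectConfig()
    window: StudyWindow = StudyWindow()
    top_k: int = 6
    min_rank_percent: float | None = 2.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        dialect = DialectConfig(**doc.get("dialect", {}))
        win = doc.get("window", {})
        window = StudyWindow(
            start=date.fromisoformat(win["start"]) if "start" in win else StudyWindow().start,
            end=date.fromisoformat(win["end"]) if "end" in win else StudyWindow().end,
        )
        return cls(
            dialect=dialect,
            window=window,
            top_k=int(doc.get("top_k", 6)),
            min_rank_percent=doc.get("min_rank_percent", 2.0),
        )


def run_pipeline(
    claims_path: str | Path,
    outdir: str | Path,
    deaths_path: str | Path | None = None,
    catalog: BeersCatalog | str | Path | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> dict:
    """Run the full screen and write report CSVs; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not isinstance(catalog, BeersCatalog):
        catalog = load_catalog(catalog)

    records = read_dispensing(claims_path, config.dialect)
    deaths = read_deaths(deaths_path, config.dialect) if deaths_path else []
    cohort = build_cohort(records, deaths, config.window)
    events = detect_all(cohort, records, catalog)

    cells = annual_prevalence(events, cohort)
    for category in ("AVOID", "CAUTION", "ANTICHOLINERGIC"):
        cells.extend(annual_prevalence(events, cohort, category, stratum=category))
    prevalence_to_frame(cells).to_csv(outdir / "prevalence.csv", index=False)

    rank_rows = []
    for year in config.window.years:
        for category in ("AVOID", "CAUTION"):
            rank_rows.extend(
                rank_pims(events, year, category, config.top_k, config.min_rank_percent)
            )
    ranks_to_frame(rank_rows).to_csv(outdir / "ranks.csv", index=False)

    summaries = [summarize_sample(cohort, events)]
    summaries += [summarize_sample(cohort, events, y) for y in config.window.years]
    import pandas as pd

    pd.DataFrame(summaries).to_csv(outdir / "sample_summary.csv", index=False)

    histories: dict[str, list] = {}
    for r in records:
        if r.patient_id in cohort:
            histories.setdefault(r.patient_id, []).append(r)
    final_year = config.window.end.year
    users, frequencies = summarize_chronic_users(histories, final_year, catalog)
    chronic_users_to_frame(users).to_csv(
        outdir / "chronic_anticholinergics.csv", index=False
    )
    freq_rows = [
        {
            "class": name,
            "n": n,
            "percent": percent(n, len(users)) if users else 0.0,
        }
        for name, n in frequencies.items()
    ]
    pd.DataFrame(freq_rows).to_csv(
        outdir / "chronic_anticholinergic_classes.csv", index=False
    )

    events_to_frame(events).to_csv(outdir / "events.csv", index=False)

    config_hash = hashlib.sha256(repr(config).encode()).hexdigest()[:16]
    manifest = {
        "catalog_version": catalog.version_tag,
        "config_hash": config_hash,
        "n_claims_rows": len(records),
        "n_death_rows": len(deaths),
        "n_cohort_patients": len(cohort.patients),
        "n_events": len(events),
        "n_chronic_anticholinergic_users": len(users),
        "window": [config.window.start.isoformat(), config.window.end.isoformat()],
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
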