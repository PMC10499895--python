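"""Pipeline orchestration: validated run configuration and stage execution.

Stages run in dependency order; every report embeds the config hash and the
seed so deterministic stages are byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable

import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import annotation, catalog, clusters, simulate
from .clusters import Region

__all__ = ["RunConfig", "StageError", "run_pipeline", "load_config", "DEFAULT_REGIONS"]

DEFAULT_REGIONS = (Region(220_000, 229_182, "cluster1"), Region(119_000, 155_100, "cluster2"))

STAGE_ORDER = ("simulate", "catalog", "clusters", "overlap")


class StageError(RuntimeError):
    """A selected stage cannot run (missing input or upstream product)."""


class RegionSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    start: int
    end: int
    label: str = ""


class RunConfig(BaseModel):
    """Validated pipeline configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    catalog_path: str | None = None          # None -> packaged fixture
    tracks: dict[str, str] = Field(default_factory=dict)
    window_width: int = 40
    regions: list[RegionSpec] = Field(default_factory=lambda: [
        RegionSpec(start=r.start, end=r.end, label=r.label) for r in DEFAULT_REGIONS])
    vicinity: int = 30
    seed: int = 0
    simulate_n: int = 0
    outdir: str = "fusionbreak_run"

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def validate_paths(self) -> None:
        paths = [self.catalog_path, *self.tracks.values()]
        missing = [p for p in paths if p is not None and not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")


def load_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(data)


def run_pipeline(config: RunConfig, stages: Iterable[str] | None = None) -> dict:
    """Run the selected stages and return (and write) the report bundle."""
    selected = set(STAGE_ORDER) if stages is None else set(stages)
    unknown = selected - set(STAGE_ORDER)
    if unknown:
        raise StageError(f"unknown stages: {sorted(unknown)}")
    config.validate_paths()

    outdir = Path(config.outdir) / config.config_hash()
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": config.config_hash(), "seed": config.seed, "stages": {}}

    cat = None
    if selected & {"catalog", "clusters", "overlap"}:
        cat = (catalog.load_catalog(config.catalog_path) if config.catalog_path
               else catalog.load_packaged_catalog())

    if "simulate" in selected:
        cohort = simulate.simulate_cohort(config.simulate_n, seed=config.seed)
        paths = cohort.write(outdir / "simulated")
        report["stages"]["simulate"] = {
            "n": config.simulate_n, **{k: str(v) for k, v in paths.items()}}

    if "catalog" in selected:
        report["stages"]["catalog"] = catalog.catalog_summary(cat)

    if "clusters" in selected:
        positions = cat.positions("TCF3")
        win = clusters.max_coverage_window(positions, config.window_width)
        members = [cat.breaks_for("TCF3")[i] for i in win.member_indices]
        regions = [Region(r.start, r.end, r.label) for r in config.regions]
        counts = clusters.count_in_regions(cat.breaks_for("PBX1"), regions)
        report["stages"]["clusters"] = {
            "tcf3_window": {
                "start": win.window_start, "width": win.width, "count": win.count,
                "orientations": {
                    o: sum(b.orientation == o for b in members)
                    for o in catalog.ORIENTATIONS},
            },
            "pbx1_regions": counts.by_region,
            "pbx1_outside": counts.outside,
        }

    if "overlap" in selected:
        overlap_report = {}
        for name, track_path in config.tracks.items():
            track = annotation.load_track(track_path)
            for gene in catalog.GENES:
                positions = cat.positions(gene)
                count, pct = annotation.fraction_overlapping(
                    positions, track, config.vicinity)
                overlap_report[f"{name}:{gene}"] = {"count": count, "percent": pct}
        report["stages"]["overlap"] = overlap_report

    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
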