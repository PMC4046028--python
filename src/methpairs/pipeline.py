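"""End-to-end orchestration: recode -> region finding -> quantify/test ->
rank -> export, plus the run manifest that makes a run reproducible."""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

from . import __version__
from .probeset import ClassMap, MTransformConfig, ProbeSet
from .regions import RegionFinderConfig, find_regions
from .reporting import (ReportConfig, export_bed, export_region_stats,
                        export_tables, plot_region)
from .stats import RegionStats, TestConfig, compute_region_stats, rank_regions


def run_pipeline(ps: ProbeSet, class_map: ClassMap,
                 rf_cfg: RegionFinderConfig | None = None,
                 test_cfg: TestConfig | None = None,
                 mcfg: MTransformConfig | None = None,
                 n_jobs: int = 1) -> list[RegionStats]:
    """Run the analysis phases on an already-parsed ProbeSet and return the
    ranked per-region results (no file output)."""
    rf_cfg = rf_cfg or RegionFinderConfig()
    test_cfg = test_cfg or TestConfig()
    ps.recode(class_map)
    regions = find_regions(ps, rf_cfg)
    stats = compute_region_stats(regions, ps, test_cfg, mcfg, n_jobs=n_jobs)
    return rank_regions(stats)


def export_results(ranked: list[RegionStats], ps: ProbeSet,
                   report_cfg: ReportConfig,
                   mcfg: MTransformConfig | None = None) -> dict:
    """Write tables, BED, per-region stats files and (optionally) plots."""
    outdir = Path(report_cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = export_tables(ranked, ps, report_cfg)
    bed = export_bed(ranked, outdir / "regions.bed")
    for rs in ranked:
        export_region_stats(
            rs, ps, outdir / f"region_{rs.region.region_id}_stats.txt", mcfg)
    plots = []
    if report_cfg.make_plots:
        for rs in ranked:
            if rs.relevant:  # plots for relevant + significant regions
                plots.append(plot_region(rs, ps, report_cfg, mcfg))
    return {"tables": tables, "bed": bed, "plots": plots}


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir: str | Path, *, inputs: dict[str, str | Path],
                   config: dict, seed: int | None = None) -> Path:
    """Run manifest: resolved configuration, input checksums, package
    version, seed and timestamp — sufficient to reproduce the run."""
    manifest = {
        "package": "methpairs",
        "version": __version__,
        "python": platform.python_version(),
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "inputs": {name: {"path": str(p), "sha256": _sha256(p)}
                   for name, p in inputs.items() if p is not None},
        "config": config,
    }
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
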