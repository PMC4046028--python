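"""Density-based discovery of class-homogeneous genomic regions.

A region of interest satisfies three criteria: (1) neighbouring probes lie
within ``d_min`` bp of each other, (2) the region contains at least ``n_min``
probes with a non-missing value in every sample, and (3) all probes carry the
same functional class.  Probes annotated to more than one class can appear in
regions of several classes; regions from different classes covering exactly
the same probes are merged into one region with a combined class label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .probeset import ProbeSet, chrom_sort_key


@dataclass(frozen=True)
class RegionFinderConfig:
    """d_min: max gap (bp, inclusive) between adjacent probes in a region.
    n_min: min probes with a non-missing beta, required for every sample."""

    d_min: int = 200
    n_min: int = 4

    def __post_init__(self) -> None:
        if self.d_min < 1:
            raise ValueError(f"d_min must be >= 1, got {self.d_min}")
        if self.n_min < 1:
            raise ValueError(f"n_min must be >= 1, got {self.n_min}")


@dataclass
class Region:
    """Maximal same-class probe run.  Coordinates are 1-based probe positions
    (start/end = min/max position); ``classes`` has one label except after
    merging of identical cross-class regions.  ``region_id`` is assigned after
    the final sort and is specific to one run of the finder."""

    region_id: str
    chrom: str
    start: int
    end: int
    probe_ids: tuple[str, ...]
    classes: tuple[str, ...]
    probe_indices: tuple[int, ...] = field(default=(), repr=False)

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)


def _runs_within_gap(positions: np.ndarray, d_min: int) -> list[slice]:
    """Maximal runs of consecutive indices whose gaps are all <= d_min."""
    if len(positions) == 0:
        return []
    breaks = np.flatnonzero(np.diff(positions) > d_min)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks + 1, [len(positions)]))
    return [slice(s, e) for s, e in zip(starts, ends)]


def find_regions(ps: ProbeSet, cfg: RegionFinderConfig | None = None,
                 merge: bool = True) -> list[Region]:
    """Scan each analysis class independently, per chromosome in genomic
    order, and emit maximal runs whose consecutive gaps are <= d_min and
    whose per-sample non-missing probe count is >= n_min.

    Run boundaries are defined by all probes of the class regardless of
    missingness — spacing is a property of the array, not of one sample's
    QC — and the per-sample floor is applied to whole runs afterwards, so
    the filter can only drop runs, never split them.
    """
    cfg = cfg or RegionFinderConfig()
    probes = ps.probes
    if "analysis_classes" not in probes.columns:
        raise ValueError("ProbeSet must be recoded before region finding")
    if len(probes) == 0:
        return []

    classes = sorted({c for ac in probes["analysis_classes"] for c in ac})
    nonmissing = ~np.isnan(ps.beta)
    positions = probes["position"].to_numpy()
    chroms = probes["chrom"].to_numpy()
    probe_ids = probes["probe_id"].to_numpy()

    raw: list[Region] = []
    for cls in classes:
        in_cls = np.array([cls in ac for ac in probes["analysis_classes"]])
        cls_idx = np.flatnonzero(in_cls)
        # probes are already in canonical (chrom, position, probe_id) order
        for chrom in pd.unique(chroms[cls_idx]):
            idx = cls_idx[chroms[cls_idx] == chrom]
            for run in _runs_within_gap(positions[idx], cfg.d_min):
                ridx = idx[run]
                if len(ridx) < cfg.n_min:
                    continue
                per_sample = nonmissing[ridx].sum(axis=0)
                if (per_sample < cfg.n_min).any():
                    continue
                raw.append(Region(
                    region_id="",
                    chrom=str(chrom),
                    start=int(positions[ridx].min()),
                    end=int(positions[ridx].max()),
                    probe_ids=tuple(probe_ids[ridx]),
                    classes=(cls,),
                    probe_indices=tuple(int(i) for i in ridx),
                ))
    if merge:
        raw = merge_identical_regions(raw, _assign_ids=False)
    return _sort_and_label(raw)


def merge_identical_regions(regions: list[Region],
                            _assign_ids: bool = True) -> list[Region]:
    """Collapse regions with identical (chrom, probe set) into one region
    whose class label is the sorted union; all others pass through.  The
    output is re-sorted by (chrom, start, end) and relabelled."""
    groups: dict[tuple[str, frozenset[str]], list[Region]] = {}
    for r in regions:
        groups.setdefault((r.chrom, frozenset(r.probe_ids)), []).append(r)
    merged = []
    for members in groups.values():
        first = members[0]
        if len(members) == 1:
            merged.append(first)
        else:
            classes = tuple(sorted({c for m in members for c in m.classes}))
            merged.append(Region(
                region_id="", chrom=first.chrom, start=first.start,
                end=first.end, probe_ids=first.probe_ids, classes=classes,
                probe_indices=first.probe_indices))
    if _assign_ids:
        return _sort_and_label(merged)
    return merged


def _sort_and_label(regions: list[Region]) -> list[Region]:
    regions = sorted(regions, key=lambda r: (
        chrom_sort_key(r.chrom), r.start, r.end, r.classes))
    return [
        Region(region_id=f"R{i:06d}", chrom=r.chrom, start=r.start, end=r.end,
               probe_ids=r.probe_ids, classes=r.classes,
               probe_indices=r.probe_indices)
        for i, r in enumerate(regions, start=1)
    ]


def tune_parameters(ps: ProbeSet, d_grid, n_grid, n_jobs: int = 1) -> pd.DataFrame:
    """Sweep the (d_min, n_min) grid and report, per combination, the number
    of regions after merging and the fraction of class-annotated probes
    included in at least one region.

    Results are independent of ``n_jobs`` (rows are assembled in grid order).
    """
    d_grid = list(d_grid)
    n_grid = list(n_grid)
    if not d_grid or not n_grid:
        raise ValueError("tuning grids must be non-empty")

    annotated = ps.annotated_mask()
    n_annotated = int(annotated.sum())
    grid = [(d, n) for d in d_grid for n in n_grid]

    def _one(d: int, n: int) -> tuple[int, int, int, float]:
        regions = find_regions(ps, RegionFinderConfig(d_min=d, n_min=n))
        covered: set[int] = set()
        for r in regions:
            covered.update(r.probe_indices)
        frac = len(covered) / n_annotated if n_annotated else 0.0
        return d, n, len(regions), frac

    if n_jobs != 1:
        from joblib import Parallel, delayed
        rows = Parallel(n_jobs=n_jobs)(delayed(_one)(d, n) for d, n in grid)
    else:
        rows = [_one(d, n) for d, n in grid]
    return pd.DataFrame(rows, columns=["d_min", "n_min", "n_regions",
                                       "probe_fraction"])
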