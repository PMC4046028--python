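"""Serialisation of region results: ranked TSV/HTML tables (all / relevant /
significant), BED6 intervals, genome-browser links, per-region statistics
files and per-region methylation plots, plus ad-hoc interval querying.

Coordinate conventions: internally positions are 1-based inclusive point
coordinates (array-manifest convention); BED output is 0-based half-open;
UCSC links are 1-based with a "chr" prefix; Ensembl region strings are
1-based without the prefix.  All outputs are byte-identical across repeated
runs on the same input and configuration.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .probeset import MTransformConfig, ProbeSet
from .regions import Region, RegionFinderConfig
from .stats import RegionStats, TestConfig, region_medians, test_regions

logger = logging.getLogger(__name__)


@dataclass
class ReportConfig:
    output_dir: str | Path = "methpairs_out"
    genome_build: str = "hg19"
    make_plots: bool = False
    plot_flank_bp: int = 10_000
    annotation_gff: str | Path | None = None
    table_formats: tuple[str, ...] = ("tsv", "html")

    def __post_init__(self) -> None:
        if self.plot_flank_bp < 0:
            raise ValueError("plot_flank_bp must be >= 0")
        bad = set(self.table_formats) - {"tsv", "html"}
        if bad:
            raise ValueError(f"unknown table format(s): {sorted(bad)}")


def _strip_chr(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def _with_chr(chrom: str) -> str:
    return chrom if chrom.lower().startswith("chr") else f"chr{chrom}"


def browser_links(region: Region, genome_build: str = "hg19") -> tuple[str, str]:
    """(Ensembl URL, UCSC URL) for the region's genomic interval."""
    c_ens = _strip_chr(region.chrom)
    c_ucsc = _with_chr(region.chrom)
    ensembl = (
        "https://grch37.ensembl.org" if genome_build in ("hg19", "GRCh37")
        else "https://www.ensembl.org")
    ensembl_url = (f"{ensembl}/Homo_sapiens/Location/View?"
                   f"r={c_ens}:{region.start}-{region.end}")
    ucsc_url = ("https://genome.ucsc.edu/cgi-bin/hgTracks?"
                f"db={genome_build}&position={c_ucsc}:{region.start}-{region.end}")
    return ensembl_url, ucsc_url


def _fmt(x, nd: int = 6) -> str:
    """Stable numeric formatting shared by all text outputs."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    return f"{float(x):.{nd}g}"


def results_table(ranked: list[RegionStats], sample_names: list[str],
                  genome_build: str = "hg19") -> pd.DataFrame:
    """Flat table of per-region results, one row per region, ranked order."""
    pairs = [(i, j) for i in range(len(sample_names))
             for j in range(i + 1, len(sample_names))]
    rows = []
    for rs in ranked:
        r = rs.region
        ens, ucsc = browser_links(r, genome_build)
        row: dict[str, object] = {
            "region_id": r.region_id,
            "chrom": r.chrom,
            "start": r.start,
            "end": r.end,
            "n_probes": r.n_probes,
            "classes": ";".join(r.classes),
        }
        for k, s in enumerate(sample_names):
            row[f"median_beta_{s}"] = _fmt(rs.median_beta[k], 4)
        for k, s in enumerate(sample_names):
            row[f"median_M_{s}"] = _fmt(rs.median_M[k], 4)
        for i, j in pairs:
            row[f"dM_{sample_names[i]}_vs_{sample_names[j]}"] = \
                _fmt(rs.delta_M[i, j], 4)
        row.update({
            "max_abs_dM": _fmt(rs.max_abs_delta_M, 4),
            "p_raw": _fmt(rs.p_raw),
            "p_adjusted": _fmt(rs.p_adjusted),
            "tested": str(rs.tested),
            "relevant": str(rs.relevant),
            "significant": str(rs.significant),
            "ensembl_url": ens,
            "ucsc_url": ucsc,
        })
        rows.append(row)
    if not rows:  # header-only table with the full schema
        cols = (["region_id", "chrom", "start", "end", "n_probes", "classes"]
                + [f"median_beta_{s}" for s in sample_names]
                + [f"median_M_{s}" for s in sample_names]
                + [f"dM_{sample_names[i]}_vs_{sample_names[j]}" for i, j in pairs]
                + ["max_abs_dM", "p_raw", "p_adjusted", "tested", "relevant",
                   "significant", "ensembl_url", "ucsc_url"])
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)


def export_tables(ranked: list[RegionStats], ps: ProbeSet,
                  cfg: ReportConfig) -> dict[str, list[Path]]:
    """Write the all / relevant / significant tables in each requested format.

    Returns a mapping from table name to the list of files written.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    subsets = {
        "all": ranked,
        "relevant": [rs for rs in ranked if rs.relevant],
        "significant": [rs for rs in ranked if rs.significant],
    }
    written: dict[str, list[Path]] = {}
    for name, subset in subsets.items():
        table = results_table(subset, ps.sample_names, cfg.genome_build)
        files = []
        if "tsv" in cfg.table_formats:
            path = outdir / f"regions_{name}.tsv"
            table.to_csv(path, sep="\t", index=False)
            files.append(path)
        if "html" in cfg.table_formats:
            path = outdir / f"regions_{name}.html"
            path.write_text(_html_page(name, table, cfg))
            files.append(path)
        written[name] = files
    return written


def _html_page(name: str, table: pd.DataFrame, cfg: ReportConfig) -> str:
    df = table.copy()
    for col in ("ensembl_url", "ucsc_url"):
        if col in df.columns and len(df):
            label = col.split("_")[0].capitalize()
            df[col] = df[col].map(lambda u: f'<a href="{u}">{label}</a>')
    if len(df):
        df.insert(0, "links", [
            f'<a href="region_{rid}_stats.txt">stats</a>'
            + (f' <a href="region_{rid}.png">plot</a>' if cfg.make_plots else "")
            for rid in df["region_id"]])
    body = df.to_html(index=False, escape=False, border=0)
    return (
        "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
        f"<title>{name} regions</title>"
        "<style>table{border-collapse:collapse;font:13px sans-serif}"
        "td,th{border:1px solid #ccc;padding:3px 6px}</style></head>\n"
        f"<body><h1>{name.capitalize()} regions ({len(table)})</h1>\n"
        f"{body}\n</body></html>\n")


def bed_score(rs: RegionStats) -> int:
    if rs.p_adjusted is None:
        return 0
    p = max(rs.p_adjusted, 1e-100)
    return min(1000, int(round(-10.0 * math.log10(p))))


def export_bed(regions: list[RegionStats], path: str | Path) -> Path:
    """BED6: 0-based half-open interval, region id, -10*log10(p_adj) score
    capped at 1000 (0 for untested regions), strand '.'."""
    path = Path(path)
    with open(path, "w") as fh:
        for rs in regions:
            r = rs.region
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.region_id}\t"
                     f"{bed_score(rs)}\t.\n")
    return path


def read_bed(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None,
                       names=["chrom", "start", "end", "name", "score",
                              "strand"],
                       dtype={"chrom": str})


def export_region_stats(rs: RegionStats, ps: ProbeSet, path: str | Path,
                        mcfg: MTransformConfig | None = None) -> Path:
    """Plain-text per-region statistics: interval, per-probe values,
    per-sample medians, dM matrix and test results."""
    from .stats import _probe_indices
    r = rs.region
    idx = _probe_indices(r, ps)
    beta = ps.beta[idx]
    m = ps.m_values(mcfg)[idx]
    names = ps.sample_names
    lines = [
        f"region_id\t{r.region_id}",
        f"interval\t{r.chrom}:{r.start}-{r.end}",
        f"classes\t{';'.join(r.classes)}",
        f"n_probes\t{r.n_probes}",
        "",
        "# per-probe beta values",
        "probe_id\tposition\t" + "\t".join(names),
    ]
    positions = ps.probes["position"].to_numpy()[idx]
    for k, pid in enumerate(r.probe_ids):
        lines.append(pid + f"\t{positions[k]}\t"
                     + "\t".join(_fmt(v, 4) for v in beta[k]))
    lines += ["", "# per-probe M values",
              "probe_id\tposition\t" + "\t".join(names)]
    for k, pid in enumerate(r.probe_ids):
        lines.append(pid + f"\t{positions[k]}\t"
                     + "\t".join(_fmt(v, 4) for v in m[k]))
    lines += ["", "# per-sample medians", "sample\tmedian_beta\tmedian_M"]
    for k, s in enumerate(names):
        lines.append(f"{s}\t{_fmt(rs.median_beta[k], 4)}"
                     f"\t{_fmt(rs.median_M[k], 4)}")
    lines += ["", "# pairwise delta-M (row minus column)",
              "\t" + "\t".join(names)]
    for a, s in enumerate(names):
        lines.append(s + "\t" + "\t".join(_fmt(v, 4) for v in rs.delta_M[a]))
    lines += ["", "# test results",
              f"tested\t{rs.tested}",
              f"p_raw\t{_fmt(rs.p_raw)}",
              f"p_adjusted\t{_fmt(rs.p_adjusted)}",
              f"relevant\t{rs.relevant}",
              f"significant\t{rs.significant}"]
    if rs.pairwise_p is not None:
        lines += ["", "# pairwise Mann-Whitney p (raw)",
                  "\t" + "\t".join(names)]
        for a, s in enumerate(names):
            lines.append(s + "\t"
                         + "\t".join(_fmt(v) for v in rs.pairwise_p[a]))
    if rs.warning:
        lines += ["", f"warning\t{rs.warning}"]
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


def plot_region(rs: RegionStats, ps: ProbeSet, cfg: ReportConfig,
                mcfg: MTransformConfig | None = None) -> Path:
    """Two-panel figure (beta in [0,1]; M unbounded) of per-probe methylation
    against genomic position, one series per sample, with an optional
    transcript track read from a local GFF3/GTF."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from .stats import _probe_indices

    r = rs.region
    idx = _probe_indices(r, ps)
    pos = ps.probes["position"].to_numpy()[idx]
    beta = ps.beta[idx]
    m = ps.m_values(mcfg)[idx]

    transcripts = []
    if cfg.annotation_gff is not None:
        try:
            transcripts = _gff_transcripts(
                cfg.annotation_gff, r.chrom,
                r.start - cfg.plot_flank_bp, r.end + cfg.plot_flank_bp)
        except Exception as e:  # unreadable GFF: plot without the track
            logger.warning("could not read %s (%s); plotting without "
                           "transcript track", cfg.annotation_gff, e)

    n_rows = 3 if transcripts else 2
    fig, axes = plt.subplots(
        n_rows, 1, figsize=(7, 2.4 * n_rows), sharex=True,
        gridspec_kw={"height_ratios": [3, 3, 1][:n_rows]})
    for k, s in enumerate(ps.sample_names):
        ok = ~np.isnan(beta[:, k])
        axes[0].plot(pos[ok], beta[ok, k], "o-", ms=4, label=s)
        axes[1].plot(pos[ok], m[ok, k], "o-", ms=4, label=s)
    axes[0].set_ylabel("beta")
    axes[0].set_ylim(-0.05, 1.05)
    axes[0].legend(fontsize=8)
    axes[1].set_ylabel("M")
    if transcripts:
        for i, (name, t_start, t_end) in enumerate(transcripts):
            axes[2].plot([t_start, t_end], [i, i], lw=3)
            axes[2].text(t_start, i + 0.15, name, fontsize=7)
        axes[2].set_yticks([])
        axes[2].set_ylabel("transcripts")
    axes[-1].set_xlabel(f"position on {r.chrom} (bp)")
    fig.suptitle(f"{r.region_id} {r.chrom}:{r.start}-{r.end}")
    fig.tight_layout()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / f"region_{r.region_id}.png"
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path


def _gff_transcripts(path, chrom, lo, hi) -> list[tuple[str, int, int]]:
    """Transcript/gene features overlapping [lo, hi] from a GFF3/GTF file."""
    out = []
    want = {"transcript", "mRNA", "gene"}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] not in want:
                continue
            if _strip_chr(f[0]) != _strip_chr(chrom):
                continue
            s, e = int(f[3]), int(f[4])
            if e < lo or s > hi:
                continue
            name = f[8].split(";")[0].split("=")[-1].split('"')[-2] \
                if '"' in f[8] else f[8].split(";")[0].split("=")[-1]
            out.append((name, s, e))
    return out


def query_interval(ps: ProbeSet, chrom: str, start: int, end: int,
                   cfg: TestConfig | None = None,
                   rf_cfg: RegionFinderConfig | None = None,
                   mcfg: MTransformConfig | None = None) -> RegionStats | None:
    """Quantify/test an arbitrary genomic interval with the same machinery.

    Builds an ad-hoc region from every probe (any class) in [start, end].
    Returns None when the interval contains no probes.  An interval where
    some sample has fewer than n_min non-missing probes is reported untested
    with a warning rather than rejected.
    """
    cfg = cfg or TestConfig()
    rf_cfg = rf_cfg or RegionFinderConfig()
    probes = ps.probes
    mask = ((probes["chrom"].map(_strip_chr) == _strip_chr(chrom))
            & (probes["position"] >= start) & (probes["position"] <= end))
    idx = np.flatnonzero(mask.to_numpy())
    if idx.size == 0:
        logger.warning("no probes in %s:%d-%d", chrom, start, end)
        return None
    positions = probes["position"].to_numpy()[idx]
    region = Region(
        region_id="query", chrom=str(chrom),
        start=int(positions.min()), end=int(positions.max()),
        probe_ids=tuple(probes["probe_id"].to_numpy()[idx]),
        classes=("query",),
        probe_indices=tuple(int(i) for i in idx))
    counts = (~np.isnan(ps.beta[idx])).sum(axis=0)
    if (counts == 0).any():
        sample = ps.sample_names[int(np.argmin(counts))]
        logger.warning("sample %r has no non-missing probes in the interval; "
                       "medians unavailable", sample)
        return None
    rs = region_medians(region, ps, mcfg)
    if (counts < rf_cfg.n_min).any():
        rs.warning = (f"some sample has < {rf_cfg.n_min} non-missing probes; "
                      "interval not tested")
        rs.tested = rs.relevant = rs.significant = False
        return rs
    test_regions([rs], ps, cfg, mcfg)
    return rs
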