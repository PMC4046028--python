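"""Seeded synthetic methylation datasets with planted DMRs and known truth.

The generator emulates the layout statistics that matter to the region
finder and the tests: probes clustered on the genome with small intra-cluster
gaps and large inter-cluster gaps, functional-class labels, a bimodal
baseline M distribution (hypo-/hyper-methylated compartments), planted
per-cluster M-value offsets restricted to one sample, Gaussian probe-level
noise on the M scale, and missing values.  Beta values are obtained from M by
the inverse logit2, so they always lie strictly inside (0, 1).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .probeset import (ClassMap, ProbeSet, beta_from_m, chrom_sort_key)
from .stats import RegionStats


@dataclass
class SyntheticConfig:
    """Defaults give ~320 probe clusters over 4 chromosomes, two samples,
    cluster sizes 8-12 probes, intra-cluster gaps 20-150 bp (regionable at
    d_min = 200) and inter-cluster gaps 1-5 kb (never bridged), baseline M
    from an equal mixture of N(-3, 1) and N(+3, 1) with the hypo/hyper
    compartment drawn per cluster (regional coherence), probe-level noise
    sd 0.5 on the M scale, planted |dM| = 3 offsets in 10% of clusters and
    2% missing values."""

    seed: int = 0
    n_chroms: int = 4
    probes_per_chrom: int = 800
    intra_cluster_gap_range: tuple[int, int] = (20, 150)
    inter_cluster_gap_range: tuple[int, int] = (1_000, 5_000)
    cluster_size_range: tuple[int, int] = (8, 12)
    class_labels: tuple[str, ...] = ("gene", "tss", "island")
    multi_membership_prob: float = 0.1
    n_samples: int = 2
    baseline_means: tuple[float, float] = (-3.0, 3.0)
    baseline_sds: tuple[float, float] = (1.0, 1.0)
    baseline_weight: float = 0.5
    planted_dmr_fraction: float = 0.1
    planted_delta_M: float = 3.0
    noise_sd_M: float = 0.5
    missing_rate: float = 0.02

    def __post_init__(self) -> None:
        for name in ("intra_cluster_gap_range", "inter_cluster_gap_range",
                     "cluster_size_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must satisfy 0 < lo <= hi")
        for name in ("multi_membership_prob", "planted_dmr_fraction",
                     "missing_rate", "baseline_weight"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.noise_sd_M < 0:
            raise ValueError("noise_sd_M must be >= 0")


@dataclass
class TruthRegion:
    chrom: str
    start: int
    end: int
    probe_ids: tuple[str, ...]
    true_delta_M: float
    affected_sample: str


TruthSet = list


def generate_dataset(cfg: SyntheticConfig) -> tuple[ProbeSet, list[TruthRegion]]:
    """Generate a ProbeSet (already recoded) and the list of planted truth
    regions.  Fully reproducible from ``cfg.seed``: one PRNG stream drives
    layout, classes, baseline, planting, noise and missingness."""
    rng = np.random.default_rng(cfg.seed)
    sample_names = [f"sample{k + 1}" for k in range(cfg.n_samples)]

    rows = []
    clusters: list[dict] = []
    pid = itertools.count(1)
    for ci in range(cfg.n_chroms):
        chrom = str(ci + 1)
        pos = 10_000
        n_probes = 0
        while n_probes < cfg.probes_per_chrom:
            size = int(rng.integers(cfg.cluster_size_range[0],
                                    cfg.cluster_size_range[1] + 1))
            size = min(size, cfg.probes_per_chrom - n_probes)
            label = cfg.class_labels[
                int(rng.integers(len(cfg.class_labels)))]
            members = []
            for k in range(size):
                if k > 0:
                    pos += int(rng.integers(cfg.intra_cluster_gap_range[0],
                                            cfg.intra_cluster_gap_range[1] + 1))
                probe_id = f"cg{next(pid):08d}"
                extra = frozenset()
                if rng.random() < cfg.multi_membership_prob:
                    others = [c for c in cfg.class_labels if c != label]
                    extra = frozenset(
                        {others[int(rng.integers(len(others)))]})
                rows.append({"probe_id": probe_id, "chrom": chrom,
                             "position": pos,
                             "raw_classes": frozenset({label}) | extra})
                members.append((probe_id, len(rows) - 1))
            clusters.append({"chrom": chrom, "probes": members,
                             "label": label})
            n_probes += size
            pos += int(rng.integers(cfg.inter_cluster_gap_range[0],
                                    cfg.inter_cluster_gap_range[1] + 1))

    probes = pd.DataFrame(rows)
    n = len(probes)
    # methylation is regionally coherent: the hypo/hyper compartment is a
    # property of the cluster, with probe-level scatter around it
    baseline = np.empty(n)
    for cl in clusters:
        comp = 0 if rng.random() < cfg.baseline_weight else 1
        row_idx = [ri for _, ri in cl["probes"]]
        baseline[row_idx] = rng.normal(
            cfg.baseline_means[comp], cfg.baseline_sds[comp], len(row_idx))
    m = np.tile(baseline[:, None], (1, cfg.n_samples))

    truth: list[TruthRegion] = []
    n_planted = int(round(cfg.planted_dmr_fraction * len(clusters)))
    planted_idx = (rng.choice(len(clusters), size=n_planted, replace=False)
                   if n_planted else np.array([], dtype=int))
    for ci in np.sort(planted_idx):
        cl = clusters[ci]
        sample_k = int(rng.integers(cfg.n_samples))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        delta = sign * cfg.planted_delta_M
        row_idx = [ri for _, ri in cl["probes"]]
        m[row_idx, sample_k] += delta
        positions = probes["position"].iloc[row_idx]
        truth.append(TruthRegion(
            chrom=cl["chrom"], start=int(positions.min()),
            end=int(positions.max()),
            probe_ids=tuple(p for p, _ in cl["probes"]),
            true_delta_M=delta,
            affected_sample=sample_names[sample_k]))

    if cfg.noise_sd_M > 0:
        m = m + rng.normal(0.0, cfg.noise_sd_M, m.shape)
    beta = beta_from_m(m)
    if cfg.missing_rate > 0:
        beta[rng.random(beta.shape) < cfg.missing_rate] = np.nan

    ps = ProbeSet(probes, beta, sample_names)
    # class labels here are already analysis-level; keep them as-is
    ps.recode(ClassMap(mapping={c: c for c in cfg.class_labels}))
    return ps, truth


def evaluate_recovery(truth: list[TruthRegion], called: list[RegionStats],
                      overlap_rule: str = "shared_probe") -> dict:
    """Score significant calls against the planted truth.

    A truth region is recovered iff a significant call shares at least one
    probe with it (default rule) or, under ``reciprocal``, iff the shared
    probe count is >= half of both regions.  Sensitivity = recovered / truth;
    precision = true-positive calls / significant calls; both NaN when the
    denominator is zero.
    """
    sig = [rs for rs in called if rs.significant]

    def overlaps(t: TruthRegion, rs: RegionStats) -> bool:
        if rs.region.chrom != t.chrom:
            return False
        shared = len(set(t.probe_ids) & set(rs.region.probe_ids))
        if overlap_rule == "shared_probe":
            return shared >= 1
        if overlap_rule == "reciprocal":
            return (shared * 2 >= len(t.probe_ids)
                    and shared * 2 >= rs.region.n_probes)
        raise ValueError(f"unknown overlap rule {overlap_rule!r}")

    hits = []
    recovered = 0
    for t in truth:
        hit = any(overlaps(t, rs) for rs in sig)
        recovered += hit
        hits.append({"chrom": t.chrom, "start": t.start, "end": t.end,
                     "true_delta_M": t.true_delta_M, "recovered": hit})
    tp_calls = sum(any(overlaps(t, rs) for t in truth) for rs in sig)
    sensitivity = recovered / len(truth) if truth else float("nan")
    precision = tp_calls / len(sig) if sig else float("nan")
    return {"sensitivity": sensitivity, "precision": precision,
            "n_truth": len(truth), "n_significant": len(sig),
            "n_recovered": recovered, "hits": pd.DataFrame(hits)}


def write_dataset(ps: ProbeSet, truth: list[TruthRegion],
                  outdir: str | Path) -> dict[str, Path]:
    """Write the dataset in the same delimited-text formats the parser
    reads: annotation TSV + beta TSV, truth as TSV and BED."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # write 450K-manifest-style raw labels so the default recode scheme
    # (gene/tss/island grouping) reproduces the generator's classes
    manifest_label = {"gene": ("Body", 0), "tss": ("TSS200", 0),
                      "island": ("Island", 1)}
    gene_col, island_col = [], []
    for rc in ps.probes["raw_classes"]:
        cols: tuple[list[str], list[str]] = ([], [])
        for label in sorted(rc):
            raw, which = manifest_label.get(label, (label, 0))
            cols[which].append(raw)
        gene_col.append(";".join(cols[0]))
        island_col.append(";".join(cols[1]))
    ann = pd.DataFrame({
        "IlmnID": ps.probes["probe_id"],
        "CHR": ps.probes["chrom"],
        "MAPINFO": ps.probes["position"],
        "UCSC_RefGene_Group": gene_col,
        "Relation_to_UCSC_CpG_Island": island_col,
    })
    ann_path = outdir / "annotation.tsv"
    ann.to_csv(ann_path, sep="\t", index=False)
    bet = pd.DataFrame(ps.beta, columns=ps.sample_names)
    bet.insert(0, "IlmnID", ps.probes["probe_id"])
    beta_path = outdir / "beta.tsv"
    bet.to_csv(beta_path, sep="\t", index=False, float_format="%.6f")
    truth_df = pd.DataFrame(
        [{"chrom": t.chrom, "start": t.start, "end": t.end,
          "n_probes": len(t.probe_ids), "true_delta_M": t.true_delta_M,
          "affected_sample": t.affected_sample} for t in truth])
    truth_path = outdir / "truth.tsv"
    truth_df.to_csv(truth_path, sep="\t", index=False)
    bed_path = outdir / "truth.bed"
    with open(bed_path, "w") as fh:
        for i, t in enumerate(sorted(truth, key=lambda t: (
                chrom_sort_key(t.chrom), t.start)), start=1):
            fh.write(f"{t.chrom}\t{t.start - 1}\t{t.end}\tT{i:06d}\t0\t.\n")
    return {"annotation": ann_path, "beta": beta_path,
            "truth": truth_path, "truth_bed": bed_path}
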