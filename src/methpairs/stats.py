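"""Quantification and testing of per-region methylation differences.

For every region the per-sample medians of beta and M are computed, together
with all pairwise differences of median M (dM).  A region whose largest
absolute pairwise dM strictly exceeds the screening threshold (default 1.4,
the upper bound of the 0.4-1.4 effect-size range recommended for M-values)
is formally tested: Mann-Whitney U on the probe-level M-values of the two
samples when n = 2, Kruskal-Wallis across all samples when n > 2, with
pairwise post-hoc MWU tests when the omnibus p <= 0.05.  P-values of the
tested regions are adjusted for multiple testing (Benjamini-Hochberg FDR by
default); a region is *relevant* if it passed the screen and *significant*
if additionally its adjusted p <= alpha.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .probeset import MTransformConfig, ProbeSet
from .regions import Region

ADJUST_METHODS = ("BH", "bonferroni", "none")


@dataclass(frozen=True)
class TestConfig:
    """dM: minimum absolute median-M difference (strict) to trigger testing.
    alpha: significance level on the adjusted p (inclusive).
    adjust_method: "BH", "bonferroni" or "none".
    kw_gate: omnibus Kruskal-Wallis p threshold for post-hoc pairwise tests."""

    dM: float = 1.4
    alpha: float = 0.05
    adjust_method: str = "BH"
    kw_gate: float = 0.05

    def __post_init__(self) -> None:
        if self.dM < 0:
            raise ValueError("dM must be >= 0")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not (0 < self.kw_gate < 1):
            raise ValueError("kw_gate must be in (0, 1)")
        if self.adjust_method not in ADJUST_METHODS:
            raise ValueError(
                f"adjust_method must be one of {ADJUST_METHODS}")


@dataclass
class RegionStats:
    """Per-region descriptive statistics, test results and flags."""

    region: Region
    median_beta: np.ndarray          # (n_samples,)
    median_M: np.ndarray             # (n_samples,)
    delta_M: np.ndarray              # (n_samples, n_samples), antisymmetric
    max_abs_delta_M: float
    tested: bool = False
    p_raw: float | None = None
    p_adjusted: float | None = None
    pairwise_p: np.ndarray | None = None
    relevant: bool = False
    significant: bool = False
    n_probes_per_sample: np.ndarray | None = None
    warning: str | None = None


def region_medians(region: Region, ps: ProbeSet,
                   mcfg: MTransformConfig | None = None) -> RegionStats:
    """Per-sample medians of non-missing beta and M over the region's probes,
    plus the pairwise matrix of median-M differences."""
    idx = _probe_indices(region, ps)
    beta = ps.beta[idx]
    m = ps.m_values(mcfg)[idx]
    counts = (~np.isnan(beta)).sum(axis=0)
    if (counts == 0).any():
        sample = ps.sample_names[int(np.argmin(counts))]
        raise ValueError(
            f"region {region.region_id or '<ad hoc>'}: sample {sample!r} has "
            "no non-missing probes (violated upstream n_min contract)")
    median_beta = np.nanmedian(beta, axis=0)
    median_m = np.nanmedian(m, axis=0)
    delta = median_m[:, None] - median_m[None, :]
    return RegionStats(
        region=region,
        median_beta=median_beta,
        median_M=median_m,
        delta_M=delta,
        max_abs_delta_M=float(np.abs(delta).max()),
        n_probes_per_sample=counts,
    )


def _probe_indices(region: Region, ps: ProbeSet) -> np.ndarray:
    if region.probe_indices:
        return np.asarray(region.probe_indices, dtype=int)
    lookup = {p: i for i, p in enumerate(ps.probes["probe_id"])}
    try:
        return np.array([lookup[p] for p in region.probe_ids], dtype=int)
    except KeyError as e:
        raise ValueError(f"region probe {e.args[0]!r} not in ProbeSet")


def mann_whitney_u(x, y) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact distribution when both groups are small (min size <= 8) and there
    are no ties; otherwise the tie-corrected normal approximation with
    continuity correction.  Exactness matters at the default region floor of
    four probes per sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("Mann-Whitney U requires non-empty groups")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    if not has_ties and min(x.size, y.size) <= 8:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(min(res.pvalue, 1.0))


def kruskal_wallis(groups) -> float:
    """Kruskal-Wallis p-value (chi-square approximation, tie-corrected)
    across >= 3 groups; with 2 groups use Mann-Whitney U instead."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("Kruskal-Wallis requires >= 3 groups; use "
                         "mann_whitney_u for two samples")
    if any(g.size == 0 for g in groups):
        raise ValueError("Kruskal-Wallis requires non-empty groups")
    if all(np.array_equal(g, groups[0]) for g in groups[1:]):
        return 1.0  # zero rank separation; scipy raises on all-identical data
    try:
        return float(min(sps.kruskal(*groups).pvalue, 1.0))
    except ValueError:  # all values identical across groups
        return 1.0


def adjust_pvalues(p, method: str = "BH") -> np.ndarray:
    """Multiple-testing adjustment mapped back to input order.

    BH is the step-up FDR procedure q_(i) = min_{j>=i} m p_(j) / j capped at
    1; Bonferroni multiplies by m and caps; "none" passes through.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "none":
        return p.copy()
    sm_method = {"BH": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if sm_method is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=sm_method)[1]


def test_regions(regions_with_stats: list[RegionStats], ps: ProbeSet,
                 cfg: TestConfig | None = None,
                 mcfg: MTransformConfig | None = None) -> list[RegionStats]:
    """Screen, test, adjust and flag a list of RegionStats (in place).

    The screen is strict (max |dM| > cfg.dM); the multiple-testing family is
    the set of tested regions, since untested regions carry no p-value.
    Post-hoc pairwise p-values are reported raw — the omnibus p drives the
    significance flag.
    """
    cfg = cfg or TestConfig()
    m = ps.m_values(mcfg)
    n = ps.n_samples

    tested_idx: list[int] = []
    for i, rs in enumerate(regions_with_stats):
        rs.tested = rs.max_abs_delta_M > cfg.dM
        rs.relevant = rs.tested
        rs.p_raw = rs.p_adjusted = None
        rs.pairwise_p = None
        rs.significant = False
        if not rs.tested:
            continue
        tested_idx.append(i)
        idx = _probe_indices(rs.region, ps)
        groups = [m[idx, j][~np.isnan(m[idx, j])] for j in range(n)]
        if n == 2:
            rs.p_raw = mann_whitney_u(groups[0], groups[1])
        else:
            rs.p_raw = kruskal_wallis(groups)
            if rs.p_raw <= cfg.kw_gate:
                pw = np.full((n, n), np.nan)
                for a, b in itertools.combinations(range(n), 2):
                    pw[a, b] = pw[b, a] = mann_whitney_u(groups[a], groups[b])
                rs.pairwise_p = pw

    if tested_idx:
        adj = adjust_pvalues(
            [regions_with_stats[i].p_raw for i in tested_idx],
            cfg.adjust_method)
        for i, q in zip(tested_idx, adj):
            rs = regions_with_stats[i]
            rs.p_adjusted = float(q)
            rs.significant = rs.relevant and rs.p_adjusted <= cfg.alpha
    return regions_with_stats


def rank_regions(stats: list[RegionStats]) -> list[RegionStats]:
    """Order for reporting: significant regions first (ascending adjusted p,
    ties by descending max |dM|, then region id), then relevant-but-not-
    significant by descending max |dM|, then the rest in genomic order."""
    def key(item):
        i, rs = item
        if rs.significant:
            return (0, rs.p_adjusted, -rs.max_abs_delta_M, rs.region.region_id)
        if rs.relevant:
            return (1, -rs.max_abs_delta_M, rs.region.region_id, "")
        return (2, i, "", "")
    return [rs for _, rs in sorted(enumerate(stats), key=lambda t: key(t))]


def compute_region_stats(regions: list[Region], ps: ProbeSet,
                         cfg: TestConfig | None = None,
                         mcfg: MTransformConfig | None = None,
                         n_jobs: int = 1) -> list[RegionStats]:
    """Medians + testing for a list of regions (the quantify/test phase)."""
    if n_jobs != 1:
        from joblib import Parallel, delayed
        stats = Parallel(n_jobs=n_jobs)(
            delayed(region_medians)(r, ps, mcfg) for r in regions)
    else:
        stats = [region_medians(r, ps, mcfg) for r in regions]
    return test_regions(list(stats), ps, cfg, mcfg)
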