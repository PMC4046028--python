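import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from methpairs import (RegionFinderConfig, adjust_pvalues,
                       compute_region_stats, find_regions, kruskal_wallis,
                       mann_whitney_u, rank_regions, region_medians)
from methpairs.stats import TestConfig as StatsConfig
from methpairs.stats import test_regions as screen_and_test
from methpairs.probeset import beta_from_m
from methpairs.regions import Region
from methpairs.stats import RegionStats

from conftest import make_probeset


def mwu_exact_oracle(x, y):
    """Two-sided exact Mann-Whitney p by full enumeration of all
    C(m+n, m) group assignments of the pooled (tie-free) values."""
    pooled = sorted(x) + sorted(y)
    m = len(x)

    def u_of(subset):
        xs = sorted(subset)
        # U = number of (x, y) pairs with x > y
        rest = list(pooled)
        for v in xs:
            rest.remove(v)
        return sum(1 for a in xs for b in rest if a > b)

    u_obs = u_of(x)
    total = 0
    as_extreme = 0
    mn = m * (len(pooled) - m)
    obs_dev = abs(u_obs - mn / 2)
    for comb in itertools.combinations(pooled, m):
        total += 1
        if abs(u_of(comb) - mn / 2) >= obs_dev - 1e-12:
            as_extreme += 1
    return as_extreme / total


def bh_step_up_oracle(p):
    """Independent Benjamini-Hochberg step-up: q_(i) = min_{j>=i} m p_(j)/j."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = math.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = min(running, 1.0)
    return q


class TestMannWhitney:
    def test_canonical_separated_groups(self):
        assert mann_whitney_u([1, 2, 3, 4], [5, 6, 7, 8]) \
            == pytest.approx(2 / 70)

    def test_rank_invariance_under_shift(self):
        p1 = mann_whitney_u([1, 2, 3, 4], [5, 6, 7, 8])
        p2 = mann_whitney_u([1, 2, 3, 4], [11, 12, 13, 14])
        assert p1 == p2

    def test_identical_multisets_p_one(self):
        assert mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4]) == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    @pytest.mark.parametrize("sizes", [(2, 3), (3, 3), (4, 4), (4, 5),
                                       (5, 5), (6, 6)])
    def test_exact_matches_enumeration_oracle(self, sizes):
        rng = np.random.default_rng(sum(sizes))
        for _ in range(5):
            vals = rng.permutation(np.arange(1, sum(sizes) + 1, dtype=float))
            x, y = vals[:sizes[0]], vals[sizes[0]:]
            assert mann_whitney_u(x, y) \
                == pytest.approx(mwu_exact_oracle(list(x), list(y)))


class TestKruskalWallis:
    def test_identical_groups_p_one(self):
        g = [1.0, 2.0, 3.0, 4.0]
        assert kruskal_wallis([g, g, g]) == 1.0

    def test_closed_form_fixture(self):
        # ranks equal values; H = 12/(N(N+1)) sum n_i (Rbar_i - Rbar)^2
        # = 12/156 * (4*16 + 0 + 4*16) = 9.8462; p = chi2.sf(H, 2)
        p = kruskal_wallis([[1, 2, 3, 4], [5, 6, 7, 8], [9, 10, 11, 12]])
        from scipy.stats import chi2
        assert p == pytest.approx(chi2.sf(9.84615384615, df=2), rel=1e-6)
        assert p == pytest.approx(0.0073, abs=2e-4)

    def test_group_order_irrelevant(self):
        g = [[1, 5, 9], [2, 6, 10], [3, 7, 11.0]]
        assert kruskal_wallis(g) == kruskal_wallis(g[::-1])

    def test_two_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], [3, 4]])


class TestAdjust:
    def test_bh_step_up_fixture(self):
        out = adjust_pvalues([0.01, 0.02, 0.03, 0.04], "BH")
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_identity(self):
        for method in ("BH", "bonferroni", "none"):
            assert adjust_pvalues([0.05], method) == pytest.approx([0.05])

    def test_bonferroni(self):
        assert np.allclose(adjust_pvalues([0.01, 0.5], "bonferroni"),
                           [0.02, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.5], "BH")

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    @settings(deadline=None, derandomize=True)
    def test_bh_matches_independent_step_up(self, p):
        assert np.allclose(adjust_pvalues(p, "BH"), bh_step_up_oracle(p))

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    @settings(deadline=None, derandomize=True)
    def test_bh_monotone_and_at_least_raw(self, p):
        q = adjust_pvalues(p, "BH")
        assert (q >= np.asarray(p) - 1e-12).all()
        order_p = np.argsort(np.asarray(p), kind="stable")
        assert (np.diff(q[order_p]) >= -1e-12).all()


def constant_beta_ps(beta_a, beta_b, n_probes=4):
    beta = np.column_stack([np.full(n_probes, beta_a),
                            np.full(n_probes, beta_b)])
    positions = [100 + 150 * i for i in range(n_probes)]
    return make_probeset(positions, beta)


class TestRegionStats:
    def test_constant_sample_medians(self):
        ps = constant_beta_ps(0.8, 0.5)
        [region] = find_regions(ps)
        rs = region_medians(region, ps)
        assert rs.median_M == pytest.approx([2.0, 0.0])
        assert rs.delta_M[0, 1] == pytest.approx(2.0)
        assert rs.max_abs_delta_M == pytest.approx(2.0)

    def test_identical_samples_zero_delta(self):
        ps = constant_beta_ps(0.6, 0.6)
        [region] = find_regions(ps)
        rs = region_medians(region, ps)
        assert np.allclose(rs.delta_M, 0.0)

    def test_median_midpoint_convention(self):
        # M values {0,1,2,3} against a constant 0 -> median 1.5
        beta = np.column_stack([beta_from_m(np.array([0.0, 1, 2, 3])),
                                np.full(4, 0.5)])
        ps = make_probeset([100, 200, 300, 400], beta)
        [region] = find_regions(ps)
        rs = region_medians(region, ps)
        assert rs.median_M[0] == pytest.approx(1.5)

    def test_delta_antisymmetric(self):
        ps = constant_beta_ps(0.9, 0.2)
        [region] = find_regions(ps)
        rs = region_medians(region, ps)
        assert np.allclose(rs.delta_M, -rs.delta_M.T)


class TestTestRegions:
    def _stats_for(self, beta_a_vals, beta_b_vals, **cfg_kwargs):
        beta = np.column_stack([beta_a_vals, beta_b_vals])
        positions = [100 + 150 * i for i in range(len(beta_a_vals))]
        ps = make_probeset(positions, beta)
        regions = find_regions(ps)
        return compute_region_stats(regions, ps,
                                    StatsConfig(**cfg_kwargs)), ps

    def test_exact_threshold_not_tested(self):
        # max |dM| exactly equal to the screen -> strict ">" excludes it
        ps = constant_beta_ps(beta_from_m(1.4), 0.5)
        [region] = find_regions(ps)
        rs = region_medians(region, ps)
        assert rs.max_abs_delta_M == pytest.approx(1.4)
        rs.max_abs_delta_M = 1.4  # pin the boundary against fp round-trip
        screen_and_test([rs], ps, StatsConfig(dM=1.4))
        assert not rs.tested and not rs.relevant and rs.p_raw is None

    def test_two_sample_mwu_and_m_eq_1_adjustment(self):
        a = beta_from_m(np.array([1.0, 2, 3, 4]))
        b = beta_from_m(np.array([5.0, 6, 7, 8]))
        stats, _ = self._stats_for(a, b)
        [rs] = stats
        assert rs.tested and rs.relevant
        assert rs.p_raw == pytest.approx(2 / 70)
        assert rs.p_adjusted == pytest.approx(rs.p_raw)  # BH with m=1
        assert rs.significant

    def test_three_samples_kw_gate_blocks_posthoc(self):
        # n=3 with weak separation: omnibus p > 0.05 -> no pairwise matrix
        rng = np.random.default_rng(0)
        m = rng.normal(0, 1, size=(6, 3))
        m[:, 2] += 2.0  # triggers the dM screen but KW stays weak-ish
        beta = beta_from_m(m)
        ps = make_probeset([100 + 100 * i for i in range(6)], beta)
        regions = find_regions(ps, RegionFinderConfig(n_min=4))
        stats = compute_region_stats(
            regions, ps, StatsConfig(dM=0.5, kw_gate=1e-6))
        [rs] = stats
        assert rs.tested and rs.p_raw is not None
        assert rs.pairwise_p is None  # gate not met

    def test_three_samples_posthoc_when_gate_met(self):
        m = np.column_stack([np.arange(1.0, 7), np.arange(11.0, 17),
                             np.arange(21.0, 27)])
        beta = beta_from_m(m / 4)  # keep inside clip range
        ps = make_probeset([100 + 100 * i for i in range(6)], beta)
        regions = find_regions(ps, RegionFinderConfig(n_min=4))
        [rs] = compute_region_stats(regions, ps, StatsConfig(dM=1.0))
        assert rs.pairwise_p is not None
        assert rs.pairwise_p[0, 1] == pytest.approx(
            mann_whitney_u(m[:, 0] / 4, m[:, 1] / 4))
        assert np.isnan(rs.pairwise_p[0, 0])

    def test_adjustment_family_is_tested_regions_only(self):
        # two clusters: one strong effect, one null; BH m=1 over the single
        # tested region leaves its p unadjusted
        a = np.concatenate([beta_from_m(np.array([1.0, 2, 3, 4])),
                            np.full(4, 0.5)])
        b = np.concatenate([beta_from_m(np.array([5.0, 6, 7, 8])),
                            np.full(4, 0.5)])
        beta = np.column_stack([a, b])
        pos = [100, 200, 300, 400, 5000, 5100, 5200, 5300]
        ps = make_probeset(pos, beta)
        regions = find_regions(ps)
        stats = compute_region_stats(regions, ps, StatsConfig())
        tested = [rs for rs in stats if rs.tested]
        assert len(tested) == 1 and len(stats) == 2
        assert tested[0].p_adjusted == pytest.approx(tested[0].p_raw)

    def test_shift_invariance(self):
        rng = np.random.default_rng(5)
        m = rng.normal(0, 1, size=(5, 2))
        m[:, 1] += 2.0
        res = []
        for shift in (0.0, 1.0):
            beta = beta_from_m(m + shift)
            ps = make_probeset([100 + 100 * i for i in range(5)], beta)
            [rs] = compute_region_stats(
                find_regions(ps), ps, StatsConfig(dM=1.0))
            res.append(rs)
        assert res[0].p_raw == pytest.approx(res[1].p_raw)
        assert res[0].max_abs_delta_M == pytest.approx(res[1].max_abs_delta_M)
        assert res[0].significant == res[1].significant

    def test_significance_chain(self, planted_dataset):
        ps, _ = planted_dataset
        stats = compute_region_stats(find_regions(ps), ps, StatsConfig())
        n_all = len(stats)
        n_rel = sum(rs.relevant for rs in stats)
        n_sig = sum(rs.significant for rs in stats)
        assert n_sig <= n_rel <= n_all
        for rs in stats:
            if rs.significant:
                assert rs.relevant and rs.tested
            if rs.tested:
                assert rs.p_adjusted >= rs.p_raw - 1e-12


class TestRank:
    def _rs(self, rid, significant=False, relevant=False, p_adj=None,
            max_dm=0.0):
        region = Region(rid, "1", 1, 9, ("p",), ("gene",))
        return RegionStats(region=region, median_beta=np.zeros(2),
                           median_M=np.zeros(2), delta_M=np.zeros((2, 2)),
                           max_abs_delta_M=max_dm, tested=relevant,
                           p_adjusted=p_adj, relevant=relevant,
                           significant=significant)

    def test_significant_by_ascending_adjusted_p(self):
        a = self._rs("R1", True, True, 0.03, 1.0)
        b = self._rs("R2", True, True, 0.01, 1.0)
        assert [r.region.region_id for r in rank_regions([a, b])] \
            == ["R2", "R1"]

    def test_ties_broken_by_effect_size(self):
        a = self._rs("R1", True, True, 0.01, 2.2)
        b = self._rs("R2", True, True, 0.01, 3.1)
        assert [r.region.region_id for r in rank_regions([a, b])] \
            == ["R2", "R1"]

    def test_untested_keep_genomic_order(self):
        rs = [self._rs(f"R{i}") for i in (3, 1, 2)]
        assert [r.region.region_id for r in rank_regions(rs)] \
            == ["R3", "R1", "R2"]

    def test_relevant_between_significant_and_rest(self):
        sig = self._rs("R1", True, True, 0.01, 2.0)
        rel = self._rs("R2", False, True, 0.9, 5.0)
        plain = self._rs("R3")
        assert [r.region.region_id
                for r in rank_regions([plain, rel, sig])] \
            == ["R1", "R2", "R3"]


def test_config_validation():
    with pytest.raises(ValueError):
        StatsConfig(alpha=0.0)
    with pytest.raises(ValueError):
        StatsConfig(dM=-1)
    with pytest.raises(ValueError):
        StatsConfig(adjust_method="holm")
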