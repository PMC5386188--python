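"""EHH decay, iHH integration, iHS standardization, the windowed sweep rule
and bifurcation trees."""

import math

import numpy as np
import pytest

from diffsweep import (
    SweepConfig,
    bifurcation_tree,
    call_sweep_windows,
    ehh,
    ihh,
    ihs_scan,
    simulate_sweep,
    standardize_ihs,
)
from diffsweep.selection import EhhProfile
from conftest import make_matrix


def profile(positions, values, core_pos, sl="reached_cutoff", sr="reached_cutoff"):
    return EhhProfile(
        core_id="c", core_allele="derived", core_pos=core_pos,
        positions=np.asarray(positions, dtype=np.int64),
        ehh=np.asarray(values, dtype=float),
        status_left=sl, status_right=sr, n_carriers=4,
    )


class TestEhh:
    def test_core_value_is_one(self):
        haps = np.array([[1, 1, 1, 1, 0, 0]] * 2, dtype=np.uint8)
        m = make_matrix(haps, pops=["P1"] * 3)
        p = ehh(m, 0, "derived", direction="right")
        assert p.ehh[0] == 1.0

    def test_two_two_split_gives_one_third(self):
        # 4 derived carriers split 2/2 at the first flanking SNP
        haps = np.array(
            [
                [1, 1, 1, 1, 0, 0],
                [0, 0, 1, 1, 0, 1],
            ],
            dtype=np.uint8,
        )
        m = make_matrix(haps, pops=["P1"] * 3)
        p = ehh(m, 0, "derived", direction="right", cutoff=0.5)
        assert p.ehh[1] == pytest.approx(2 / 6)

    def test_identical_carriers_hit_edge_at_one(self):
        haps = np.zeros((5, 6), dtype=np.uint8)
        haps[2] = [1, 1, 1, 1, 0, 0]
        m = make_matrix(haps, pops=["P1"] * 3)
        p = ehh(m, 2, "derived")
        assert p.status_left == "hit_edge"
        assert p.status_right == "hit_edge"
        np.testing.assert_array_equal(p.ehh, np.ones(5))

    def test_large_gap_truncates(self):
        haps = np.array(
            [[1, 1, 1, 1, 0, 0], [0, 1, 0, 1, 0, 0]], dtype=np.uint8
        )
        m = make_matrix(haps, pops=["P1"] * 3, positions=[1000, 900_000])
        p = ehh(m, 0, "derived", direction="right", max_gap_bp=200_000)
        assert p.status_right == "hit_gap"
        assert len(p.ehh) == 1  # nothing beyond the core

    def test_fewer_than_two_carriers_rejected(self):
        haps = np.array([[1, 0, 0, 0, 0, 0]], dtype=np.uint8)
        m = make_matrix(haps, pops=["P1"] * 3)
        with pytest.raises(ValueError, match="carrier"):
            ehh(m, 0, "derived")

    def test_monotone_nonincreasing_outward(self):
        cfg = SweepConfig(
            seed=13, s=0.0, n_loci=60, region_bp=500_000,
            pop_size=400, n_founders=80, burnin_generations=40, n_haplotypes=60,
        )
        m, _ = simulate_sweep(cfg)
        for idx in (10, 30, 50):
            d = m.derived_row(idx).mean()
            if min(d, 1 - d) < 0.1:
                continue
            for allele in ("ancestral", "derived"):
                p = ehh(m, idx, allele, cutoff=0.0)  # run to the edges
                core_i = int(np.searchsorted(p.positions, p.core_pos))
                right = p.ehh[core_i:]
                left = p.ehh[: core_i + 1][::-1]
                assert (np.diff(right) <= 1e-12).all()
                assert (np.diff(left) <= 1e-12).all()


class TestIhh:
    def test_rectangle_limit(self):
        # constant EHH 1 over 1000 bp right, immediate truncation left
        p = profile([1000, 2000], [1.0, 1.0], core_pos=1000)
        assert ihh(p) == pytest.approx(1000.0)

    def test_linear_decline_matches_fine_grid_oracle(self):
        xs = np.arange(1000, 2001, 100)
        ys = 1.0 + (xs - 1000) / 1000.0 * (0.05 - 1.0)  # linear 1 -> 0.05
        p = profile(list(xs), list(ys), core_pos=1000)
        # independent oracle: 1-bp Riemann midpoint integration
        grid = np.arange(1000, 2000)
        fine = np.interp(grid + 0.5, xs, ys).sum()
        assert ihh(p) == pytest.approx(fine, rel=1e-6)

    def test_zero_width_profile(self):
        p = profile([500], [1.0], core_pos=500)
        assert ihh(p) == 0.0

    def test_edge_truncated_profile_is_flagged_invalid(self):
        p = profile([500, 600], [1.0, 0.9], core_pos=500, sr="hit_edge")
        assert not p.valid
        assert ihh(p) > 0  # value still returned


class TestStandardizeIhs:
    def test_two_symmetric_points(self):
        ihs, _ = standardize_ihs(np.array([-1.0, 1.0]), np.array([0.5, 0.52]), n_bins=20, min_bin_count=1)
        np.testing.assert_allclose(sorted(ihs), [-1.0, 1.0], atol=1e-12)

    def test_degenerate_bin_yields_nan(self):
        ihs, _ = standardize_ihs(np.array([2.0, 2.0, 2.0]), np.array([0.5, 0.5, 0.5]))
        assert np.isnan(ihs).all()

    def test_sparse_bins_merge_into_neighbours(self):
        u = np.concatenate([np.linspace(-1, 1, 30), [5.0]])
        d = np.concatenate([np.full(30, 0.30), [0.95]])  # lone SNP in a far bin
        ihs, bins = standardize_ihs(u, d, n_bins=20, min_bin_count=10)
        assert len(np.unique(bins)) == 1  # everything merged into one bin
        assert np.isfinite(ihs).all()

    def test_per_bin_moments_after_standardization(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=400)
        d = rng.uniform(0.06, 0.94, size=400)
        ihs, bins = standardize_ihs(u, d)
        for b in np.unique(bins):
            sel = bins == b
            assert abs(ihs[sel].mean()) < 1e-12
            assert ihs[sel].std() == pytest.approx(1.0, abs=1e-12)


class TestCallSweepWindows:
    def test_seven_hits_in_one_window_flags(self):
        v = np.zeros(60)
        v[:7] = 3.0  # all within the first 50-SNP window
        call = call_sweep_windows(v, cutoff=2.0)
        assert call.flagged
        assert call.best_window_hits == 7

    def test_six_hits_never_flag(self):
        v = np.zeros(60)
        v[::10] = 3.0  # 6 hits
        assert not call_sweep_windows(v, cutoff=2.0).flagged

    def test_spread_hits_do_not_flag(self):
        # 7 significant SNPs spaced every 50 positions: no 50-window holds 7
        v = np.zeros(300)
        v[::50] = 3.0
        assert not call_sweep_windows(v, cutoff=2.0).flagged

    def test_short_gene_single_window(self):
        v = np.full(10, 3.0)
        call = call_sweep_windows(v, cutoff=2.0, window_size=50, min_hits=7)
        assert call.flagged
        assert call.n_scored_loci == 10

    def test_empty_gene(self):
        call = call_sweep_windows([], cutoff=2.0)
        assert not call.flagged
        assert call.n_scored_loci == 0

    def test_negative_values_count_via_absolute_value(self):
        v = np.zeros(50)
        v[:7] = -3.0
        assert call_sweep_windows(v, cutoff=2.5).flagged


class TestBifurcationTree:
    def test_identical_carriers_never_branch(self):
        haps = np.zeros((5, 6), dtype=np.uint8)
        haps[0] = [1, 1, 1, 1, 0, 0]
        m = make_matrix(haps, pops=["P1"] * 3)
        t = bifurcation_tree(m, 0, "derived", "right")
        assert t.n_leaves == 1
        assert t.root.count == 4

    def test_split_counts_are_conserved(self):
        haps = np.array(
            [
                [1, 1, 1, 1, 0, 0],  # core: 4 carriers
                [0, 0, 1, 1, 1, 0],  # splits 2/2
                [0, 1, 0, 0, 0, 0],  # splits the first pair 1/1
            ],
            dtype=np.uint8,
        )
        m = make_matrix(haps, pops=["P1"] * 3)
        t = bifurcation_tree(m, 0, "derived", "right")
        leaves = sorted(
            n.count
            for n in _walk(t.root)
            if not n.children
        )
        assert leaves == [1, 1, 2]
        for node in _walk(t.root):
            if node.children:
                assert sum(c.count for c in node.children) == node.count

    def test_sweep_derived_tree_branches_less_than_ancestral(self):
        cfg = SweepConfig(
            seed=21, n_loci=60, region_bp=500_000, pop_size=800,
            n_founders=160, burnin_generations=40, n_haplotypes=80,
        )
        m, truth = simulate_sweep(cfg)
        foc = truth["focal_index"]
        td = bifurcation_tree(m, foc, "derived", "right", max_snps=10)
        ta = bifurcation_tree(m, foc, "ancestral", "right", max_snps=10)
        # normalize by carrier count: the swept side stays far more homogeneous
        assert td.n_leaves / td.root.count < ta.n_leaves / ta.root.count


def _walk(node):
    yield node
    for c in node.children:
        yield from _walk(c)


class TestIhsScanTable:
    def test_reasons_and_maf_filter(self):
        cfg = SweepConfig(
            seed=5, s=0.0, n_loci=40, region_bp=400_000, pop_size=400,
            n_founders=80, burnin_generations=30, n_haplotypes=40,
        )
        m, _ = simulate_sweep(cfg)
        tab = ihs_scan(m)
        assert set(tab.columns) >= {"id", "pos", "daf", "ihh_a", "ihh_d", "u", "ihs", "valid", "reason"}
        maf = np.minimum(tab["daf"], 1 - tab["daf"])
        assert (maf[tab["reason"] == "maf"] <= 0.05).all()
        assert tab.loc[tab["valid"], "ihs"].notna().all()
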