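"""F_ST components, gene-level aggregation, DAF patterns, empirical cutoffs
and AMOVA, each checked against an independent oracle where one exists."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diffsweep import (
    DafProfile,
    FstComponents,
    amova,
    classify_daf_pattern,
    daf,
    empirical_cutoff,
    gene_wa_fst,
    locus_fst,
    matrix_locus_fst,
)
from conftest import make_matrix


def fst_oracle(counts):
    """Weir-Cockerham haploid components in exact rational arithmetic."""
    r = len(counts)
    n = [Fraction(c[0]) for c in counts]
    p = [Fraction(c[1], c[0]) for c in counts]
    n_bar = sum(n) / r
    n_c = (r * n_bar - sum(ni**2 for ni in n) / (r * n_bar)) / (r - 1)
    p_bar = sum(ni * pi for ni, pi in zip(n, p)) / (r * n_bar)
    s2 = sum(ni * (pi - p_bar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * n_bar)
    b = (n_bar / (n_bar - 1)) * (p_bar * (1 - p_bar) - Fraction(r - 1, r) * s2)
    a = (n_bar / n_c) * (s2 - b / n_bar)
    theta = a / (a + b) if a + b != 0 else None
    return a, b, theta


class TestLocusFst:
    def test_fixed_same_allele_is_undefined(self):
        c = locus_fst([(50, 0), (60, 0)])
        assert math.isnan(c.theta)

    def test_fixed_opposite_alleles_is_one(self):
        c = locus_fst([(100, 100), (100, 0)])
        assert c.b == pytest.approx(0.0, abs=1e-15)
        assert c.theta == pytest.approx(1.0, abs=1e-12)

    def test_exact_rational_oracle_example(self):
        # two pops of 8 haplotypes at p = 0.75 / 0.25
        got = locus_fst([(8, 6), (8, 2)])
        a, b, theta = fst_oracle([(8, 6), (8, 2)])
        assert got.a == pytest.approx(float(a), abs=1e-12)
        assert got.b == pytest.approx(float(b), abs=1e-12)
        assert got.theta == pytest.approx(float(theta), abs=1e-12)

    @given(
        st.lists(
            st.tuples(st.integers(2, 30), st.integers(0, 30)).map(
                lambda t: (t[0], min(t[1], t[0]))
            ),
            min_size=2,
            max_size=5,
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_oracle_and_is_order_invariant(self, counts):
        got = locus_fst(counts)
        a, b, theta = fst_oracle(counts)
        assert got.a == pytest.approx(float(a), abs=1e-10)
        assert got.b == pytest.approx(float(b), abs=1e-10)
        if theta is None:
            assert math.isnan(got.theta)
        else:
            assert got.theta == pytest.approx(float(theta), abs=1e-10)
        rev = locus_fst(list(reversed(counts)))
        if not math.isnan(got.theta):
            assert rev.theta == pytest.approx(got.theta, abs=1e-12)

    def test_single_population_rejected(self):
        with pytest.raises(ValueError):
            locus_fst([(10, 5)])

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError):
            locus_fst([(1, 1), (10, 5)])

    def test_internally_monomorphic_differing_pops_give_theta_one(self):
        c = locus_fst([(4, 4), (6, 0), (8, 8)])
        assert c.theta == pytest.approx(1.0, abs=1e-12)


class TestGeneWaFst:
    def test_single_locus_identity(self):
        c = locus_fst([(8, 6), (8, 2)])
        g = gene_wa_fst([c])
        assert g.wa_fst == pytest.approx(c.theta, abs=1e-15)

    def test_ratio_of_sums_arithmetic(self):
        comps = [
            FstComponents("l1", a=0.1, b=0.1, theta=0.5),
            FstComponents("l2", a=0.0, b=0.2, theta=0.0),
        ]
        g = gene_wa_fst(comps)
        assert g.wa_fst == pytest.approx(0.25, abs=1e-15)
        assert g.n_loci == 2

    def test_constant_per_locus_ratio_is_preserved(self):
        # every locus has a/(a+b) = 0.2 with different denominators
        comps = [
            FstComponents(f"l{i}", a=0.2 * w, b=0.8 * w, theta=0.2)
            for i, w in enumerate([0.1, 1.0, 5.0])
        ]
        assert gene_wa_fst(comps).wa_fst == pytest.approx(0.2, abs=1e-12)

    def test_all_undefined(self):
        comps = [FstComponents("l1", a=0.0, b=0.0, theta=float("nan"))]
        g = gene_wa_fst(comps)
        assert math.isnan(g.wa_fst)
        assert g.n_loci == 1

    def test_prop_high(self):
        comps = [
            FstComponents("l1", 0.1, 0.1, 0.5),
            FstComponents("l2", 0.0, 0.2, 0.0),
        ]
        assert gene_wa_fst(comps, cutoff=0.5).prop_high == pytest.approx(0.5)


class TestDaf:
    def test_frequencies_and_unpolarized(self):
        haps = np.zeros((2, 10), dtype=np.uint8)
        haps[0, :3] = 1  # 3 of 10 derived
        haps[1, :4] = 1
        m = make_matrix(haps, pops=["P1"] * 5)
        m = m.with_ancestral(["ref", "unknown"])
        profiles = daf(m)
        assert profiles[0].freqs["P1"] == pytest.approx(0.3)
        assert profiles[1].pattern == "unpolarized"
        assert profiles[1].freqs == {}

    def test_alt_ancestral_flips_polarity(self):
        haps = np.array([[1, 1, 1, 0, 0, 0, 0, 0, 0, 0]], dtype=np.uint8)
        m = make_matrix(haps, pops=["P1"] * 5, ancestral="alt")
        assert daf(m)[0].freqs["P1"] == pytest.approx(0.7)


class TestClassifyDafPattern:
    def test_african_high(self):
        p = DafProfile("rs1871534", {"YRI": 0.983, "CEU": 0.006, "CHB": 0.000}, "other")
        assert classify_daf_pattern(p) == "african_high"

    def test_nonafrican_high(self):
        p = DafProfile("rs1047626", {"YRI": 0.080, "CEU": 0.750, "CHB": 0.964}, "other")
        assert classify_daf_pattern(p, low_thr=0.1, high_thr=0.1) == "nonafrican_high"

    def test_intermediate_is_other(self):
        p = DafProfile("x", {"YRI": 0.5, "CEU": 0.5, "CHB": 0.5}, "other")
        assert classify_daf_pattern(p) == "other"

    def test_missing_reference_population(self):
        p = DafProfile("x", {"YRI": 0.5, "CEU": 0.5}, "other")
        with pytest.raises(ValueError, match="CHB"):
            classify_daf_pattern(p)


class TestEmpiricalCutoff:
    def test_top5_of_1_to_100(self):
        assert empirical_cutoff(np.arange(1.0, 101.0), 0.05) == 96.0

    def test_constant_vector(self):
        assert empirical_cutoff([0.3] * 7, 0.01) == 0.3

    def test_inverse_cdf_convention_on_two_values(self):
        assert empirical_cutoff([0.0, 1.0], 0.5) == 1.0

    def test_nan_excluded_and_empty_rejected(self):
        assert empirical_cutoff([np.nan, 2.0, 1.0], 0.5) == 2.0
        with pytest.raises(ValueError):
            empirical_cutoff([np.nan], 0.1)


def amova_ss_oracle(haps, pop_of_hap, group_of_pop):
    """Direct sums-of-squares from the pairwise-distance definition."""
    n = haps.shape[1]
    d2 = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d2[i, j] = np.sum(haps[:, i] != haps[:, j])
    def ss(cols):
        return sum(d2[i, j] for i in cols for j in cols if i < j) / len(cols)
    all_cols = list(range(n))
    pops = sorted(set(pop_of_hap))
    groups = sorted(set(group_of_pop.values()))
    pop_cols = {p: [i for i in all_cols if pop_of_hap[i] == p] for p in pops}
    grp_cols = {
        g: [i for i in all_cols if group_of_pop[pop_of_hap[i]] == g] for g in groups
    }
    ss_total = ss(all_cols)
    ss_wp = sum(ss(c) for c in pop_cols.values())
    ss_wg = sum(ss(c) for c in grp_cols.values())
    return ss_total, ss_wg - ss_wp, ss_total - ss_wg, ss_wp


class TestAmova:
    def test_all_variance_between_groups(self):
        # two populations in two groups, each fixed for a distinct haplotype
        haps = np.zeros((4, 8), dtype=np.uint8)
        haps[:, 4:] = 1
        m = make_matrix(
            haps, pops=["P1", "P1", "P2", "P2"], groups={"P1": "G1", "P2": "G2"}
        )
        res = amova(m, n_perm=20, seed=0)
        assert res.proportions[0] == pytest.approx(1.0, abs=1e-9)
        assert res.phi_st == pytest.approx(1.0, abs=1e-9)

    def test_no_variance_is_degenerate(self):
        haps = np.ones((3, 8), dtype=np.uint8)
        m = make_matrix(
            haps, pops=["P1", "P1", "P2", "P2"], groups={"P1": "G1", "P2": "G2"}
        )
        res = amova(m, n_perm=10, seed=0)
        assert math.isnan(res.phi_st)
        assert math.isnan(res.p_value)

    def test_three_population_toy_matches_ss_oracle(self):
        rng = np.random.default_rng(5)
        haps = rng.integers(0, 2, size=(12, 12)).astype(np.uint8)
        pops = ["P1", "P1", "P2", "P2", "P3", "P3"]
        groups = {"P1": "G1", "P2": "G1", "P3": "G2"}
        m = make_matrix(haps, pops=pops, groups=groups)
        res = amova(m, n_perm=30, seed=1)
        pop_of_hap = [p for p in pops for _ in range(2)]
        ss_total, ss_ap, ss_ag, ss_wp = amova_ss_oracle(haps, pop_of_hap, groups)
        # within-population component straight from the SS definition
        assert res.sigma_c == pytest.approx(ss_wp / (12 - 3), abs=1e-9)
        # decomposition is exhaustive
        assert ss_ag + ss_ap + ss_wp == pytest.approx(ss_total, abs=1e-9)
        # proportions sum to one
        assert sum(res.proportions) == pytest.approx(1.0, abs=1e-9)

    def test_permutation_invariance_of_locus_fst_over_matrix(self):
        rng = np.random.default_rng(2)
        haps = rng.integers(0, 2, size=(5, 12)).astype(np.uint8)
        m = make_matrix(haps, pops=["P1", "P1", "P1", "P2", "P2", "P2"])
        thetas = [c.theta for c in matrix_locus_fst(m)]
        # swapping the two population labels must not change theta
        m2 = make_matrix(haps, pops=["P2", "P2", "P2", "P1", "P1", "P1"])
        thetas2 = [c.theta for c in matrix_locus_fst(m2)]
        np.testing.assert_allclose(thetas, thetas2, atol=1e-12)
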