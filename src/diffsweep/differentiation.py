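"""Population differentiation: locus-specific F_ST, gene-level weighted-average
F_ST, derived-allele-frequency patterns, empirical genome-wide cutoffs, and a
simplified AMOVA on haplotype Hamming distances.

F_ST follows the Weir-Cockerham variance-component estimator applied to
haploid samples: phased haplotypes are treated as 2N haploid observations, so
the heterozygosity-correction terms of the diploid estimator vanish.  With
``r`` populations, haplotype counts ``n_i`` and alternate/derived allele
frequencies ``p_i``::

    n_bar = sum(n_i) / r
    n_c   = (r*n_bar - sum(n_i^2)/(r*n_bar)) / (r - 1)
    p_bar = sum(n_i * p_i) / (r * n_bar)
    s2    = sum(n_i * (p_i - p_bar)^2) / ((r - 1) * n_bar)
    b     = (n_bar/(n_bar - 1)) * (p_bar*(1 - p_bar) - ((r - 1)/r) * s2)
    a     = (n_bar/n_c) * (s2 - b/n_bar)
    theta = a / (a + b)

``theta`` is undefined (NaN) at monomorphic loci; negative estimates are
reported as-is (an estimator property, not clamped by default).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .core import HaplotypeMatrix

logger = logging.getLogger("diffsweep")


@dataclass
class FstComponents:
    """Per-locus Weir-Cockerham variance components and their ratio."""

    locus_id: str
    a: float  # between-population component
    b: float  # within-population component
    theta: float  # a/(a+b), NaN when a+b == 0

    @property
    def defined(self) -> bool:
        return not math.isnan(self.theta)


@dataclass
class GeneFst:
    gene: str
    wa_fst: float  # ratio-of-sums theta over the gene's loci (NaN if undefined)
    n_loci: int
    prop_high: float  # fraction of defined loci with theta >= cutoff (NaN if no cutoff)


@dataclass
class DafProfile:
    locus_id: str
    freqs: dict[str, float]  # population (or group) -> derived allele frequency
    pattern: str = "unpolarized"  # african_high | nonafrican_high | other | unpolarized


@dataclass
class AmovaResult:
    sigma_a: float  # among groups
    sigma_b: float  # among populations within groups
    sigma_c: float  # within populations
    proportions: tuple[float, float, float]
    phi_ct: float
    phi_sc: float
    phi_st: float
    p_value: float
    n_perm: int


# ---------------------------------------------------------------------------
# locus-level F_ST
# ---------------------------------------------------------------------------

def locus_fst(
    counts: Sequence[tuple[int, int]], locus_id: str = ""
) -> FstComponents:
    """Weir-Cockerham components from per-population (n_i, c_i) allele counts.

    ``n_i`` is the number of haplotypes sampled in population i and ``c_i``
    the number carrying the alternate (or derived) allele.  Requires at least
    two populations with n_i >= 2 each.
    """
    r = len(counts)
    if r < 2:
        raise ValueError("locus_fst needs >= 2 populations")
    n = np.array([c[0] for c in counts], dtype=float)
    c = np.array([c[1] for c in counts], dtype=float)
    if (n < 2).any():
        raise ValueError("each population needs >= 2 haplotypes")
    if ((c < 0) | (c > n)).any():
        raise ValueError("allele count outside [0, n]")
    p = c / n
    n_bar = n.sum() / r
    n_c = (r * n_bar - (n**2).sum() / (r * n_bar)) / (r - 1)
    p_bar = (n * p).sum() / (r * n_bar)
    s2 = (n * (p - p_bar) ** 2).sum() / ((r - 1) * n_bar)
    b = (n_bar / (n_bar - 1.0)) * (p_bar * (1.0 - p_bar) - ((r - 1.0) / r) * s2)
    a = (n_bar / n_c) * (s2 - b / n_bar)
    denom = a + b
    theta = a / denom if denom > 0 else float("nan")
    return FstComponents(locus_id=locus_id, a=float(a), b=float(b), theta=float(theta))


def matrix_locus_fst(
    matrix: HaplotypeMatrix, grouping: str = "population"
) -> list[FstComponents]:
    """Locus F_ST for every variant of a matrix, demes = populations or groups."""
    labels = matrix.population_of_haplotypes(grouping)
    uniq = sorted(set(labels))
    cols = [np.flatnonzero(labels == u) for u in uniq]
    out = []
    for i, v in enumerate(matrix.variants):
        row = matrix.haplotypes[i]
        counts = [(len(ix), int(row[ix].sum())) for ix in cols]
        out.append(locus_fst(counts, locus_id=v.id))
    return out


def gene_wa_fst(
    components: Iterable[FstComponents],
    gene: str = "",
    cutoff: float | None = None,
    method: str = "ratio_of_sums",
) -> GeneFst:
    """Gene-level weighted-average F_ST over the gene's loci.

    The default combines loci as a ratio of sums, ``sum(a) / sum(a + b)`` over
    loci with positive total variance — the standard multi-locus weighting in
    which each locus contributes proportionally to its total variance.  A
    plain mean of per-locus ratios is available for sensitivity analysis
    (``method="mean_of_ratios"``).
    """
    comps = list(components)
    defined = [c for c in comps if c.a + c.b > 0]
    if not defined:
        wa = float("nan")
    elif method == "ratio_of_sums":
        wa = sum(c.a for c in defined) / sum(c.a + c.b for c in defined)
    elif method == "mean_of_ratios":
        wa = float(np.mean([c.theta for c in defined]))
    else:
        raise ValueError(f"unknown method {method!r}")
    if cutoff is None:
        prop = float("nan")
    elif defined:
        prop = sum(c.theta >= cutoff for c in defined) / len(defined)
    else:
        prop = float("nan")
    return GeneFst(gene=gene, wa_fst=wa, n_loci=len(comps), prop_high=prop)


# ---------------------------------------------------------------------------
# derived allele frequencies
# ---------------------------------------------------------------------------

def daf(matrix: HaplotypeMatrix, grouping: str = "population") -> list[DafProfile]:
    """Per-locus derived allele frequency by population (or continental group).

    Loci without a known ancestral state are emitted with an empty frequency
    map and pattern ``"unpolarized"``.
    """
    labels = matrix.population_of_haplotypes(grouping)
    uniq = sorted(set(labels))
    cols = {u: np.flatnonzero(labels == u) for u in uniq}
    out = []
    for i, v in enumerate(matrix.variants):
        if not v.polarized:
            out.append(DafProfile(locus_id=v.id, freqs={}, pattern="unpolarized"))
            continue
        row = matrix.derived_row(i)
        freqs = {u: float(row[ix].mean()) for u, ix in cols.items()}
        out.append(DafProfile(locus_id=v.id, freqs=freqs, pattern="other"))
    return out


def classify_daf_pattern(
    profile: DafProfile,
    african: str = "YRI",
    nonafrican: Sequence[str] = ("CEU", "CHB"),
    low_thr: float = 0.05,
    high_thr: float = 0.05,
) -> str:
    """Label a DAF profile by its continental contrast.

    ``african_high``: derived allele at frequency >= ``high_thr`` in the
    African reference and < ``low_thr`` in every non-African reference;
    ``nonafrican_high`` is the mirrored condition; anything else is
    ``other``.  Unpolarized profiles stay ``unpolarized``.
    """
    if profile.pattern == "unpolarized" and not profile.freqs:
        return "unpolarized"
    if not (0 <= low_thr <= high_thr <= 1):
        raise ValueError("thresholds must satisfy 0 <= low_thr <= high_thr <= 1")
    for pop in (african, *nonafrican):
        if pop not in profile.freqs:
            raise ValueError(f"population {pop!r} absent from DAF profile")
    afr = profile.freqs[african]
    non = [profile.freqs[p] for p in nonafrican]
    if afr >= high_thr and all(f < low_thr for f in non):
        return "african_high"
    if afr < low_thr and all(f >= high_thr for f in non):
        return "nonafrican_high"
    return "other"


# ---------------------------------------------------------------------------
# empirical cutoffs
# ---------------------------------------------------------------------------

def empirical_cutoff(values: Sequence[float] | np.ndarray, q: float) -> float:
    """Empirical upper-tail cutoff: the smallest of the top ``ceil(q*n)`` values.

    This is the inverse-CDF (type-1) order statistic at level 1-q: with the
    defined values sorted ascending, the element at index ``n - ceil(q*n)``.
    NaNs (undefined theta) are excluded.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("no defined values")
    v = np.sort(v)
    k = math.ceil(q * v.size)
    return float(v[v.size - k])


# ---------------------------------------------------------------------------
# AMOVA (simplified Excoffier-style reimplementation)
# ---------------------------------------------------------------------------

def _hamming_distance_matrix(h: np.ndarray) -> np.ndarray:
    """Pairwise count of allele differences between haplotype columns."""
    x = h.T.astype(np.int32)  # haplotypes x variants
    # Hamming for binary data via inner products
    ones = x @ x.T
    tot = x.sum(axis=1)
    d = tot[:, None] + tot[None, :] - 2 * ones
    return d.astype(float)


def amova(
    matrix: HaplotypeMatrix,
    n_perm: int = 999,
    seed: int = 0,
) -> AmovaResult:
    """Hierarchical analysis of molecular variance on haplotype distances.

    Sums of squared pairwise Hamming distances are partitioned into
    among-group, among-population-within-group and within-population
    components; variance components follow the standard unequal-size
    coefficients and the Phi statistics are their ratios.  The p-value for
    the among-group component is obtained by permuting whole populations
    across groups ``n_perm`` times (add-one convention).
    """
    pops = matrix.population_of_haplotypes("population")
    pop_list = sorted(set(pops))
    group_of = {p: matrix.panel.group_of[p] for p in pop_list}
    groups = sorted(set(group_of.values()))
    if len(groups) < 2:
        raise ValueError("AMOVA needs >= 2 groups")
    d2 = _hamming_distance_matrix(matrix.haplotypes)
    pop_cols = {p: np.flatnonzero(pops == p) for p in pop_list}

    obs = _amova_components(d2, pop_cols, group_of)
    sigma_a, sigma_b, sigma_c = obs
    total = sigma_a + sigma_b + sigma_c
    if total <= 0:
        return AmovaResult(
            0.0, 0.0, 0.0, (0.0, 0.0, 0.0),
            float("nan"), float("nan"), float("nan"), float("nan"), n_perm,
        )
    props = (sigma_a / total, sigma_b / total, sigma_c / total)
    phi_ct = sigma_a / total
    phi_st = (sigma_a + sigma_b) / total
    phi_sc = sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) > 0 else float("nan")

    rng = np.random.default_rng(seed)
    group_sizes = [sum(1 for p in pop_list if group_of[p] == g) for g in groups]
    obs_prop = props[0]
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(pop_list))
        perm_group_of = {}
        k = 0
        for g, sz in zip(groups, group_sizes):
            for j in range(sz):
                perm_group_of[pop_list[perm[k]]] = g
                k += 1
        pa, pb, pc = _amova_components(d2, pop_cols, perm_group_of)
        ptot = pa + pb + pc
        if ptot > 0 and pa / ptot >= obs_prop - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return AmovaResult(
        sigma_a, sigma_b, sigma_c, props, phi_ct, phi_sc, phi_st, p, n_perm
    )


def _amova_components(
    d2: np.ndarray,
    pop_cols: dict[str, np.ndarray],
    group_of: dict[str, str],
) -> tuple[float, float, float]:
    """Variance components (among-group, among-pop-in-group, within-pop).

    ``d2`` holds squared inter-haplotype distances (for binary SNP haplotypes
    the Hamming count plays the role of the squared Euclidean distance).
    """
    n_total = d2.shape[0]
    pops = list(pop_cols)
    groups = sorted(set(group_of.values()))
    n_pop = {p: len(ix) for p, ix in pop_cols.items()}
    grp_cols = {
        g: np.concatenate([pop_cols[p] for p in pops if group_of[p] == g])
        for g in groups
    }

    def ss_within(cols: np.ndarray) -> float:
        sub = d2[np.ix_(cols, cols)]
        return sub.sum() / (2.0 * len(cols))

    ss_total = d2.sum() / (2.0 * n_total)
    ss_wp = sum(ss_within(ix) for ix in pop_cols.values())
    ss_wg = sum(ss_within(ix) for ix in grp_cols.values())
    ss_ap = ss_wg - ss_wp  # among populations within groups
    ss_ag = ss_total - ss_wg  # among groups

    n_groups = len(groups)
    n_pops = len(pops)
    df_ag = n_groups - 1
    df_ap = n_pops - n_groups
    df_wp = n_total - n_pops

    sigma_c = ss_wp / df_wp if df_wp > 0 else 0.0

    sum_n2_over_group = sum(
        sum(n_pop[p] ** 2 for p in pops if group_of[p] == g) / len(grp_cols[g])
        for g in groups
    )
    sum_n2 = sum(n_pop[p] ** 2 for p in pops)
    sum_g2 = sum(len(ix) ** 2 for ix in grp_cols.values())

    if df_ap > 0:
        n_prime = (n_total - sum_n2_over_group) / df_ap
        sigma_b = (ss_ap / df_ap - sigma_c) / n_prime if n_prime > 0 else 0.0
    else:
        sigma_b = 0.0
    n_dprime = (sum_n2_over_group - sum_n2 / n_total) / df_ag
    n_tprime = (n_total - sum_g2 / n_total) / df_ag
    sigma_a = (ss_ag / df_ag - sigma_c - n_dprime * sigma_b) / n_tprime
    return float(sigma_a), float(sigma_b), float(sigma_c)
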