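"""Haplotype-based selection scanning: EHH, integrated haplotype homozygosity,
standardized iHS, the windowed sweep-calling rule, and bifurcation trees.

EHH at a flanking SNP x is the probability that two randomly chosen carriers
of the core allele are identical over the interval from the core to x::

    EHH(x) = sum_h C(n_h, 2) / C(n, 2)

where the sum runs over the distinct extended haplotypes among the n core
carriers.  iHH integrates EHH against physical position from the core out to
the point where EHH drops below a cutoff (0.05 by default); iHS is
``ln(iHH_ancestral / iHH_derived)``, standardized to zero mean and unit
standard deviation within derived-allele-frequency bins.  A strongly
negative iHS marks an unusually long haplotype around the *derived* allele —
the signature of an incomplete sweep favouring it; a strongly positive score
marks hitchhiking of the ancestral allele.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import GeneRegion, HaplotypeMatrix
from .differentiation import empirical_cutoff

logger = logging.getLogger("diffsweep")

DEFAULT_EHH_CUTOFF = 0.05
DEFAULT_MAX_GAP_BP = 200_000


@dataclass
class EhhProfile:
    """EHH decay around one core allele, possibly in both directions."""

    core_id: str
    core_allele: str  # "ancestral" or "derived"
    core_pos: int
    positions: np.ndarray  # ascending, includes the core position
    ehh: np.ndarray  # aligned with positions; 1.0 at the core
    status_left: str | None  # reached_cutoff | hit_edge | hit_gap | None
    status_right: str | None
    n_carriers: int

    @property
    def valid(self) -> bool:
        """True when both directions were truncated by the EHH cutoff."""
        return self.status_left == "reached_cutoff" and self.status_right == "reached_cutoff"


@dataclass
class SweepCall:
    """Result of the windowed sweep rule on one gene in one population."""

    gene: str
    population: str
    n_scored_loci: int
    best_window_start: int
    best_window_hits: int
    flagged: bool


@dataclass
class BifNode:
    pos: int  # extent position of this branch
    count: int
    children: list["BifNode"] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        if not self.children:
            return 1
        return sum(c.n_leaves for c in self.children)

    def to_dict(self) -> dict:
        return {
            "pos": int(self.pos),
            "count": int(self.count),
            "children": [c.to_dict() for c in self.children],
        }


@dataclass
class BifurcationTree:
    core_id: str
    core_allele: str
    direction: str
    root: BifNode

    @property
    def n_leaves(self) -> int:
        return self.root.n_leaves


# ---------------------------------------------------------------------------
# EHH
# ---------------------------------------------------------------------------

def _carrier_columns(
    matrix: HaplotypeMatrix, core_idx: int, allele: str, columns: np.ndarray | None
) -> np.ndarray:
    row = matrix.derived_row(core_idx)
    if columns is not None:
        base = np.asarray(columns)
    else:
        base = np.arange(matrix.n_haplotypes)
    want = 1 if allele == "derived" else 0
    if allele not in ("ancestral", "derived"):
        raise ValueError(f"allele must be 'ancestral' or 'derived', got {allele!r}")
    return base[row[base] == want]


def _chrom_block(matrix: HaplotypeMatrix, core_idx: int) -> np.ndarray:
    chrom = matrix.variants[core_idx].chrom
    return np.flatnonzero(np.array([v.chrom for v in matrix.variants]) == chrom)


def _extend_one_direction(
    h: np.ndarray,
    positions: np.ndarray,
    start: int,
    carriers: np.ndarray,
    step: int,
    cutoff: float,
    max_gap_bp: int,
) -> tuple[list[int], list[float], str]:
    """Walk outward from ``start`` refining haplotype groups SNP by SNP."""
    n = len(carriers)
    pair_denom = n * (n - 1)
    group = np.zeros(n, dtype=np.int64)
    pos_out: list[int] = []
    ehh_out: list[float] = []
    i = start
    prev_pos = positions[start]
    while True:
        i += step
        if i < 0 or i >= len(positions):
            return pos_out, ehh_out, "hit_edge"
        if abs(int(positions[i]) - int(prev_pos)) > max_gap_bp:
            return pos_out, ehh_out, "hit_gap"
        prev_pos = positions[i]
        col = h[i, carriers]
        _, group = np.unique(group * 2 + col, return_inverse=True)
        counts = np.bincount(group)
        val = float((counts * (counts - 1)).sum() / pair_denom)
        pos_out.append(int(positions[i]))
        ehh_out.append(val)
        if val < cutoff:
            return pos_out, ehh_out, "reached_cutoff"


def ehh(
    matrix: HaplotypeMatrix,
    core: str | int,
    allele: str,
    direction: str = "both",
    cutoff: float = DEFAULT_EHH_CUTOFF,
    max_gap_bp: int = DEFAULT_MAX_GAP_BP,
    columns: np.ndarray | None = None,
) -> EhhProfile:
    """EHH decay profile around a core allele.

    ``core`` is a variant id or index; the core variant must be polarized.
    Extension in each direction stops when EHH falls below ``cutoff``
    (status ``reached_cutoff``), at the chromosome-block edge (``hit_edge``)
    or at an inter-SNP gap larger than ``max_gap_bp`` (``hit_gap``).
    ``columns`` restricts the computation to a haplotype subset (e.g. one
    population).
    """
    core_idx = matrix.variant_index(core) if isinstance(core, str) else core
    block = _chrom_block(matrix, core_idx)
    return _ehh_in_block(
        matrix, core_idx, allele, block, cutoff, max_gap_bp, columns, direction
    )


def _ehh_in_block(
    matrix: HaplotypeMatrix,
    core_idx: int,
    allele: str,
    block: np.ndarray,
    cutoff: float,
    max_gap_bp: int,
    columns: np.ndarray | None,
    direction: str = "both",
) -> EhhProfile:
    carriers = _carrier_columns(matrix, core_idx, allele, columns)
    if len(carriers) < 2:
        raise ValueError(
            f"EHH undefined: {len(carriers)} carrier(s) of the {allele} allele "
            f"at {matrix.variants[core_idx].id}"
        )
    local = int(np.searchsorted(block, core_idx))
    h = matrix.haplotypes[block, :]
    positions = matrix.positions[block]
    core_pos = int(positions[local])

    status_left = status_right = None
    lpos: list[int] = []
    lehh: list[float] = []
    rpos: list[int] = []
    rehh: list[float] = []
    if direction in ("left", "both"):
        lpos, lehh, status_left = _extend_one_direction(
            h, positions, local, carriers, -1, cutoff, max_gap_bp
        )
    if direction in ("right", "both"):
        rpos, rehh, status_right = _extend_one_direction(
            h, positions, local, carriers, +1, cutoff, max_gap_bp
        )
    if direction not in ("left", "right", "both"):
        raise ValueError(f"direction must be left/right/both, got {direction!r}")
    all_pos = np.array(lpos[::-1] + [core_pos] + rpos, dtype=np.int64)
    all_ehh = np.array(lehh[::-1] + [1.0] + rehh, dtype=float)
    return EhhProfile(
        core_id=matrix.variants[core_idx].id,
        core_allele=allele,
        core_pos=core_pos,
        positions=all_pos,
        ehh=all_ehh,
        status_left=status_left,
        status_right=status_right,
        n_carriers=len(carriers),
    )


def ihh(profile: EhhProfile, baseline: float = 0.0) -> float:
    """Integrated haplotype homozygosity: trapezoidal area of EHH vs bp.

    Integrates ``max(EHH - baseline, 0)`` from the core out to the
    truncation point in each available direction and sums the two sides.
    The value is returned regardless of truncation status; callers must
    treat profiles that hit an edge or gap as invalid for standardization
    (see :attr:`EhhProfile.valid`).
    """
    core_i = int(np.searchsorted(profile.positions, profile.core_pos))
    y = np.maximum(profile.ehh - baseline, 0.0)
    x = profile.positions.astype(float)
    left = float(np.trapezoid(y[: core_i + 1], x[: core_i + 1]))
    right = float(np.trapezoid(y[core_i:], x[core_i:]))
    return left + right


# ---------------------------------------------------------------------------
# iHS
# ---------------------------------------------------------------------------

def standardize_ihs(
    u: np.ndarray,
    daf: np.ndarray,
    n_bins: int = 20,
    min_bin_count: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Standardize unadjusted scores within equal-width DAF bins.

    Returns ``(ihs, bin_index)``.  Bins with fewer than ``min_bin_count``
    SNPs are merged into the nearest occupied neighbour (logged); a bin with
    zero spread yields NaN scores for its members.
    """
    u = np.asarray(u, dtype=float)
    daf = np.asarray(daf, dtype=float)
    bins = np.minimum((daf * n_bins).astype(int), n_bins - 1)
    n_merged = 0
    while True:
        uniq, counts = np.unique(bins, return_counts=True)
        if len(uniq) <= 1:
            break
        small = np.flatnonzero(counts < min_bin_count)
        if small.size == 0:
            break
        j = int(small[0])
        if j == 0:
            target = uniq[1]
        elif j == len(uniq) - 1:
            target = uniq[j - 1]
        else:
            right_gap = uniq[j + 1] - uniq[j]
            left_gap = uniq[j] - uniq[j - 1]
            target = uniq[j + 1] if right_gap <= left_gap else uniq[j - 1]
        bins[bins == uniq[j]] = target
        n_merged += 1
    if n_merged:
        logger.info("standardize_ihs: merged %d sparse DAF bins", n_merged)
    ihs = np.full_like(u, np.nan)
    for b in np.unique(bins):
        sel = bins == b
        mu = u[sel].mean()
        sd = u[sel].std()  # population sd: the bin is the reference distribution
        if sd > 0:
            ihs[sel] = (u[sel] - mu) / sd
        else:
            logger.info("standardize_ihs: bin %d has zero spread, scores undefined", b)
    return ihs, bins


def ihs_scan(
    matrix: HaplotypeMatrix,
    population: str | None = None,
    maf_min: float = 0.05,
    cutoff: float = DEFAULT_EHH_CUTOFF,
    max_gap_bp: int = DEFAULT_MAX_GAP_BP,
    n_bins: int = 20,
    min_bin_count: int = 10,
) -> pd.DataFrame:
    """Per-SNP iHS over a matrix (optionally within one population).

    Returns a DataFrame with columns id, chrom, pos, daf, ihh_a, ihh_d, u,
    bin, ihs, valid, reason.  A SNP is scored only if it is polarized, its
    minor allele frequency strictly exceeds ``maf_min``, and both cores'
    EHH profiles truncate by reaching the EHH cutoff (not an edge or gap) —
    edge-truncated integrals would be deflated and bias the standardization.
    """
    cols = matrix.columns_for(population) if population is not None else None
    n_haps = len(cols) if cols is not None else matrix.n_haplotypes
    chroms = np.array([v.chrom for v in matrix.variants])
    all_pos = matrix.positions
    blocks = {c: np.flatnonzero(chroms == c) for c in dict.fromkeys(chroms)}
    rows = []
    for i, v in enumerate(matrix.variants):
        rec = {
            "id": v.id, "chrom": v.chrom, "pos": v.pos,
            "daf": np.nan, "ihh_a": np.nan, "ihh_d": np.nan, "u": np.nan,
            "valid": False, "reason": "",
        }
        if not v.polarized:
            rec["reason"] = "unpolarized"
            rows.append(rec)
            continue
        drow = matrix.derived_row(i)
        d = float(drow.mean() if cols is None else drow[cols].mean())
        rec["daf"] = d
        if min(d, 1.0 - d) <= maf_min:
            rec["reason"] = "maf"
            rows.append(rec)
            continue
        block = blocks[v.chrom]
        prof_a = _ehh_in_block(
            matrix, i, "ancestral", block, cutoff, max_gap_bp, cols
        )
        prof_d = _ehh_in_block(
            matrix, i, "derived", block, cutoff, max_gap_bp, cols
        )
        ihh_a = ihh(prof_a)
        ihh_d = ihh(prof_d)
        rec["ihh_a"], rec["ihh_d"] = ihh_a, ihh_d
        if not (prof_a.valid and prof_d.valid):
            rec["reason"] = "edge_or_gap"
            rows.append(rec)
            continue
        if ihh_a <= 0 or ihh_d <= 0:
            rec["reason"] = "zero_ihh"
            rows.append(rec)
            continue
        rec["u"] = math.log(ihh_a / ihh_d)
        rec["valid"] = True
        rows.append(rec)
    df = pd.DataFrame(rows)
    df["bin"] = -1
    df["ihs"] = np.nan
    sel = df["valid"].to_numpy()
    if sel.any():
        ihs_vals, bin_idx = standardize_ihs(
            df.loc[sel, "u"].to_numpy(),
            df.loc[sel, "daf"].to_numpy(),
            n_bins=n_bins,
            min_bin_count=min_bin_count,
        )
        df.loc[sel, "ihs"] = ihs_vals
        df.loc[sel, "bin"] = bin_idx
        undef = sel & df["ihs"].isna().to_numpy()
        df.loc[undef, "valid"] = False
        df.loc[undef, "reason"] = "degenerate_bin"
    df.attrs["population"] = population
    df.attrs["n_haplotypes"] = n_haps
    return df


# ---------------------------------------------------------------------------
# sweep calling
# ---------------------------------------------------------------------------

def call_sweep_windows(
    ihs_values: Sequence[float] | np.ndarray,
    cutoff: float,
    window_size: int = 50,
    min_hits: int = 7,
    gene: str = "",
    population: str = "",
) -> SweepCall:
    """Windowed sweep rule on a gene's scored SNPs in positional order.

    A gene is flagged when any window of ``window_size`` consecutive scored
    SNPs (stride 1) contains at least ``min_hits`` loci with
    ``|iHS| >= cutoff``; genes with fewer scored SNPs than the window size
    are evaluated as a single window.
    """
    v = np.asarray(ihs_values, dtype=float)
    v = v[~np.isnan(v)]
    n = v.size
    if n == 0:
        return SweepCall(gene, population, 0, 0, 0, False)
    hits = (np.abs(v) >= cutoff).astype(int)
    w = min(window_size, n)
    counts = np.convolve(hits, np.ones(w, dtype=int), mode="valid")
    best = int(np.argmax(counts))
    return SweepCall(
        gene=gene,
        population=population,
        n_scored_loci=n,
        best_window_start=best,
        best_window_hits=int(counts[best]),
        flagged=bool(counts[best] >= min_hits),
    )


def ihs_significance_cutoff(ihs_values: Sequence[float] | np.ndarray, q: float = 0.05) -> float:
    """Genome-wide |iHS| significance cutoff: empirical top-q of |iHS|."""
    v = np.abs(np.asarray(ihs_values, dtype=float))
    return empirical_cutoff(v, q)


def sweep_scan(
    matrix: HaplotypeMatrix,
    genes: Sequence[GeneRegion],
    population: str | None = None,
    q: float = 0.05,
    window_size: int = 50,
    min_hits: int = 7,
    **ihs_kwargs,
) -> tuple[pd.DataFrame, float, list[SweepCall]]:
    """iHS scan plus the windowed sweep rule over a set of gene regions.

    The significance cutoff is the empirical top-``q`` of |iHS| over *all*
    scored SNPs of the analyzed genome, shared across genes.
    """
    table = ihs_scan(matrix, population=population, **ihs_kwargs)
    scored = table[table["valid"]]
    if scored.empty:
        raise ValueError("no scored SNPs in the genome; cannot set a cutoff")
    cut = ihs_significance_cutoff(scored["ihs"].to_numpy(), q)
    calls = []
    for g in genes:
        sub = scored[
            (scored["chrom"] == g.chrom)
            & (scored["pos"] >= g.flanked_start)
            & (scored["pos"] <= g.flanked_end)
        ].sort_values("pos")
        calls.append(
            call_sweep_windows(
                sub["ihs"].to_numpy(), cut, window_size, min_hits,
                gene=g.name, population=population or "ALL",
            )
        )
    return table, cut, calls


# ---------------------------------------------------------------------------
# bifurcation trees
# ---------------------------------------------------------------------------

def bifurcation_tree(
    matrix: HaplotypeMatrix,
    core: str | int,
    allele: str,
    direction: str,
    max_snps: int | None = None,
    columns: np.ndarray | None = None,
) -> BifurcationTree:
    """Haplotype bifurcation tree outward from a core allele.

    The root holds all core-allele carriers; moving outward SNP by SNP, a
    branch splits only at SNPs that are polymorphic among its haplotypes.
    Counts are conserved at every split.
    """
    if direction not in ("left", "right"):
        raise ValueError("direction must be 'left' or 'right'")
    core_idx = matrix.variant_index(core) if isinstance(core, str) else core
    carriers = _carrier_columns(matrix, core_idx, allele, columns)
    if len(carriers) < 1:
        raise ValueError("no carriers of the core allele")
    block = _chrom_block(matrix, core_idx)
    local = int(np.searchsorted(block, core_idx))
    h = matrix.haplotypes[block, :]
    positions = matrix.positions[block]
    step = -1 if direction == "left" else 1
    root = BifNode(pos=int(positions[local]), count=len(carriers))
    frontier: list[tuple[BifNode, np.ndarray]] = [(root, carriers)]
    i = local
    taken = 0
    while True:
        i += step
        if i < 0 or i >= len(positions):
            break
        if max_snps is not None and taken >= max_snps:
            break
        taken += 1
        new_frontier: list[tuple[BifNode, np.ndarray]] = []
        for node, idx in frontier:
            col = h[i, idx]
            if col.min() == col.max():  # monomorphic in this branch: extend
                node.pos = int(positions[i])
                new_frontier.append((node, idx))
            else:
                for a in (0, 1):
                    sub = idx[col == a]
                    child = BifNode(pos=int(positions[i]), count=len(sub))
                    node.children.append(child)
                    new_frontier.append((child, sub))
        frontier = new_frontier
    return BifurcationTree(
        core_id=matrix.variants[core_idx].id,
        core_allele=allele,
        direction=direction,
        root=root,
    )
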