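"""Gene-set permutation enrichment tests.

Two tests share one resampling engine: random gene sets of the candidate
size are drawn without replacement from a genome-wide gene universe
(candidates included by default), the set statistic is recomputed on each
draw, and the observed statistic is ranked against the null vector.

Two empirical p-value conventions are reported side by side: the plain tail
index ``#{null >= observed} / n_perm`` and the add-one convention
``(#{null >= observed} + 1) / (n_perm + 1)``, which cannot be zero.  The
default output uses the add-one convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

logger = logging.getLogger("diffsweep")


@dataclass
class GeneUniverse:
    """Per-gene locus-level annotations for enrichment resampling.

    ``thetas`` maps each gene to its per-locus F_ST vector (NaN = undefined);
    ``nsnp`` and ``pattern`` optionally flag, per locus, non-synonymous
    status and the African-high/non-African-low DAF pattern.
    """

    thetas: dict[str, np.ndarray]
    nsnp: dict[str, np.ndarray] | None = None
    pattern: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        for name, th in self.thetas.items():
            self.thetas[name] = np.asarray(th, dtype=float)
        for extra in (self.nsnp, self.pattern):
            if extra is not None:
                for name in self.thetas:
                    if name not in extra:
                        raise ValueError(f"gene {name!r} missing locus annotation")
                    if len(extra[name]) != len(self.thetas[name]):
                        raise ValueError(f"gene {name!r}: annotation length mismatch")

    @property
    def genes(self) -> list[str]:
        return list(self.thetas)


@dataclass
class EnrichmentResult:
    observed: float
    null: np.ndarray
    p_tail: float  # #{null >= observed} / n_perm  (tail-index convention)
    p_default: float  # (#{null >= observed} + 1) / (n_perm + 1)
    n_perm: int
    seed: int
    n_redrawn: int = 0


def high_fst_proportion(
    universe: GeneUniverse, genes: Sequence[str], cutoff: float
) -> float:
    """Fraction of the gene set's defined-theta loci with theta >= cutoff."""
    pooled = np.concatenate([universe.thetas[g] for g in genes])
    pooled = pooled[~np.isnan(pooled)]
    if pooled.size == 0:
        raise ValueError("gene set has no loci with defined theta")
    return float((pooled >= cutoff).sum() / pooled.size)


def geneset_permutation_test(
    candidates: Sequence[str],
    universe: GeneUniverse,
    stat: Callable[[Sequence[str]], float],
    n_perm: int = 10_000,
    seed: int = 0,
    exclude_candidates: bool = False,
) -> EnrichmentResult:
    """Permutation test of a gene-set statistic against random same-size sets.

    Each replicate draws ``len(candidates)`` distinct genes uniformly from
    the universe (candidates included unless ``exclude_candidates``) and
    recomputes ``stat``.  Replicates on which ``stat`` raises or returns NaN
    are redrawn (and counted) so the null vector always has length
    ``n_perm``.  A fixed seed makes the null vector bit-reproducible.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    names = universe.genes
    if exclude_candidates:
        names = [g for g in names if g not in set(candidates)]
    k = len(candidates)
    if k > len(names):
        raise ValueError("candidate set larger than universe")
    for g in candidates:
        if g not in universe.thetas:
            raise ValueError(f"candidate gene {g!r} not in universe")
    observed = stat(list(candidates))
    rng = np.random.default_rng(seed)
    names_arr = np.array(names)
    null = np.empty(n_perm, dtype=float)
    n_redrawn = 0
    for i in range(n_perm):
        while True:
            draw = names_arr[rng.choice(len(names_arr), size=k, replace=False)]
            try:
                val = stat(list(draw))
            except ValueError:
                val = float("nan")
            if np.isnan(val):
                n_redrawn += 1
                continue
            null[i] = val
            break
    if n_redrawn:
        logger.info("geneset_permutation_test: redrew %d degenerate replicates", n_redrawn)
    n_ge = int((null >= observed).sum())
    return EnrichmentResult(
        observed=float(observed),
        null=null,
        p_tail=n_ge / n_perm,
        p_default=(n_ge + 1) / (n_perm + 1),
        n_perm=n_perm,
        seed=seed,
        n_redrawn=n_redrawn,
    )


def nsnp_pattern_enrichment(
    candidates: Sequence[str],
    universe: GeneUniverse,
    fst_cutoff: float,
    n_perm: int = 10_000,
    seed: int = 0,
    exclude_candidates: bool = False,
) -> EnrichmentResult:
    """Enrichment of African-high pattern nSNPs among high-F_ST loci.

    The set statistic is the number of non-synonymous loci carrying the
    African-high DAF pattern divided by the number of loci with
    ``theta >= fst_cutoff``, pooled over the gene set.  The universe must
    carry ``nsnp`` and ``pattern`` locus flags.
    """
    if universe.nsnp is None or universe.pattern is None:
        raise ValueError("universe lacks nsnp/pattern locus annotations")

    def stat(genes: Sequence[str]) -> float:
        th = np.concatenate([universe.thetas[g] for g in genes])
        ns = np.concatenate([universe.nsnp[g] for g in genes]).astype(bool)
        pat = np.concatenate([universe.pattern[g] for g in genes]).astype(bool)
        denom = int((th >= fst_cutoff).sum())  # NaN compares False
        if denom == 0:
            return float("nan")
        return float((ns & pat).sum() / denom)

    return geneset_permutation_test(
        candidates, universe, stat, n_perm=n_perm, seed=seed,
        exclude_candidates=exclude_candidates,
    )
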