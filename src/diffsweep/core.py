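"""Shared data model: variants, panels, gene regions and the phased haplotype matrix.

The package operates on fully phased, fully imputed biallelic SNP data, so the
haplotype matrix is a dense binary array with no missing entries: rows are
variants (sorted by position within a chromosome), columns are haplotypes
(two consecutive columns per diploid sample).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger("diffsweep")

ANCESTRAL_STATES = ("ref", "alt", "unknown")


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNP with an optional polarization.

    ``ancestral`` records which of the two alleles is ancestral: ``"ref"``,
    ``"alt"`` or ``"unknown"``.  Derived-allele statistics (DAF, iHS) skip
    variants whose ancestral state is unknown.
    """

    chrom: str
    pos: int
    id: str
    ref: str
    alt: str
    ancestral: str = "unknown"

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError(f"{self.id}: empty allele")
        if self.ref == self.alt:
            raise ValueError(f"{self.id}: ref == alt ({self.ref})")
        if self.pos < 1:
            raise ValueError(f"{self.id}: pos must be >= 1, got {self.pos}")
        if self.ancestral not in ANCESTRAL_STATES:
            raise ValueError(f"{self.id}: bad ancestral state {self.ancestral!r}")

    @property
    def polarized(self) -> bool:
        return self.ancestral != "unknown"

    @property
    def derived_allele(self) -> str:
        """Base letter of the derived allele (requires a polarized variant)."""
        if self.ancestral == "ref":
            return self.alt
        if self.ancestral == "alt":
            return self.ref
        raise ValueError(f"{self.id}: ancestral state unknown")


@dataclass(frozen=True)
class PopulationPanel:
    """Sample -> population and population -> continental-group mapping."""

    population_of: Mapping[str, str]
    group_of: Mapping[str, str]

    def __post_init__(self) -> None:
        for sample, pop in self.population_of.items():
            if pop not in self.group_of:
                raise ValueError(f"population {pop!r} (sample {sample!r}) has no group")
        counts: dict[str, int] = {}
        for pop in self.population_of.values():
            counts[pop] = counts.get(pop, 0) + 1
        for pop in self.group_of:
            if counts.get(pop, 0) < 1:
                raise ValueError(f"population {pop!r} has no samples")

    @property
    def populations(self) -> list[str]:
        return sorted(set(self.population_of.values()))

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.group_of.values()))

    def samples_in(self, population: str) -> list[str]:
        return [s for s, p in self.population_of.items() if p == population]


@dataclass(frozen=True)
class GeneRegion:
    """A named genomic interval, 1-based inclusive, with a symmetric flank."""

    name: str
    chrom: str
    start: int
    end: int
    flank_bp: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.name}: start {self.start} > end {self.end}")
        if self.flank_bp < 0:
            raise ValueError(f"{self.name}: negative flank")

    @property
    def flanked_start(self) -> int:
        return max(1, self.start - self.flank_bp)

    @property
    def flanked_end(self) -> int:
        return self.end + self.flank_bp

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.flanked_start <= pos <= self.flanked_end


class HaplotypeMatrix:
    """Phased binary allele matrix (variants x haplotypes).

    Entry ``(v, h)`` is 0 for the REF allele and 1 for the ALT allele of
    variant ``v`` on haplotype ``h``.  Two consecutive columns belong to each
    diploid sample.  ``meta`` carries ingestion statistics (skip counts etc.).
    """

    def __init__(
        self,
        variants: Sequence[VariantRecord],
        haplotypes: np.ndarray,
        sample_of: Sequence[str],
        panel: PopulationPanel,
        meta: dict | None = None,
    ) -> None:
        haplotypes = np.asarray(haplotypes, dtype=np.uint8)
        if haplotypes.ndim != 2:
            raise ValueError("haplotypes must be 2-D (variants x haplotypes)")
        if haplotypes.shape[0] != len(variants):
            raise ValueError(
                f"{len(variants)} variants but {haplotypes.shape[0]} matrix rows"
            )
        if haplotypes.shape[1] != len(sample_of):
            raise ValueError("sample_of length must equal haplotype column count")
        if not np.isin(haplotypes, (0, 1)).all():
            raise ValueError("haplotype matrix entries must be 0/1 (no missing data)")
        counts: dict[str, int] = {}
        for s in sample_of:
            counts[s] = counts.get(s, 0) + 1
        for s, c in counts.items():
            if c != 2:
                raise ValueError(f"sample {s!r} has {c} haplotypes (need exactly 2)")
            if s not in panel.population_of:
                raise ValueError(f"sample {s!r} absent from panel")
        last: dict[str, int] = {}
        for v in variants:
            if v.chrom in last and v.pos <= last[v.chrom]:
                raise ValueError(
                    f"variants not strictly increasing on {v.chrom} at pos {v.pos}"
                )
            last[v.chrom] = v.pos
        self.variants = list(variants)
        self.haplotypes = haplotypes
        self.sample_of = list(sample_of)
        self.panel = panel
        self.meta = dict(meta or {})
        self._index = {v.id: i for i, v in enumerate(self.variants)}

    # -- basic geometry -------------------------------------------------
    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def samples(self) -> list[str]:
        return self.sample_of[::2]

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    def variant_index(self, variant_id: str) -> int:
        try:
            return self._index[variant_id]
        except KeyError:
            raise KeyError(f"variant {variant_id!r} not in matrix") from None

    # -- grouping -------------------------------------------------------
    def population_of_haplotypes(self, grouping: str = "population") -> np.ndarray:
        """Per-column population (or continental group) label."""
        pops = [self.panel.population_of[s] for s in self.sample_of]
        if grouping == "population":
            return np.array(pops)
        if grouping == "group":
            return np.array([self.panel.group_of[p] for p in pops])
        raise ValueError(f"grouping must be 'population' or 'group', got {grouping!r}")

    def columns_for(self, label: str, grouping: str = "population") -> np.ndarray:
        return np.flatnonzero(self.population_of_haplotypes(grouping) == label)

    # -- subsetting -----------------------------------------------------
    def subset_region(self, region: GeneRegion) -> "HaplotypeMatrix":
        keep = [
            i for i, v in enumerate(self.variants) if region.contains(v.chrom, v.pos)
        ]
        return self.subset_variants(keep)

    def subset_variants(self, indices: Iterable[int]) -> "HaplotypeMatrix":
        idx = list(indices)
        return HaplotypeMatrix(
            [self.variants[i] for i in idx],
            self.haplotypes[idx, :],
            self.sample_of,
            self.panel,
            meta=self.meta,
        )

    def with_ancestral(self, states: Sequence[str]) -> "HaplotypeMatrix":
        if len(states) != self.n_variants:
            raise ValueError("one ancestral state per variant required")
        variants = [replace(v, ancestral=s) for v, s in zip(self.variants, states)]
        return HaplotypeMatrix(
            variants, self.haplotypes, self.sample_of, self.panel, meta=self.meta
        )

    # -- allele frequencies ---------------------------------------------
    def alt_counts(self, columns: np.ndarray | None = None) -> np.ndarray:
        h = self.haplotypes if columns is None else self.haplotypes[:, columns]
        return h.sum(axis=1)

    def derived_row(self, variant_index: int) -> np.ndarray:
        """Binary row recoded so 1 = derived allele (variant must be polarized)."""
        v = self.variants[variant_index]
        row = self.haplotypes[variant_index]
        if v.ancestral == "ref":
            return row
        if v.ancestral == "alt":
            return 1 - row
        raise ValueError(f"{v.id}: ancestral state unknown")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HaplotypeMatrix):
            return NotImplemented
        return (
            self.variants == other.variants
            and self.sample_of == other.sample_of
            and self.panel == other.panel
            and np.array_equal(self.haplotypes, other.haplotypes)
        )

    def __repr__(self) -> str:
        return (
            f"HaplotypeMatrix({self.n_variants} variants x "
            f"{self.n_haplotypes} haplotypes, "
            f"{len(self.panel.populations)} populations)"
        )
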