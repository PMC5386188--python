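"""Haplotype spectra over chosen SNP subsets and frequency-vs-environment
regression.

A haplotype spectrum collapses each phased haplotype to the string of its
allele letters at an ordered SNP subset (e.g. the non-synonymous SNPs of a
gene) and tabulates per-population counts and frequencies.  The regression
relates one haplotype's per-population frequency to an environmental
covariate (e.g. prevalence of inadequate zinc intake) by ordinary least
squares.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core import HaplotypeMatrix

logger = logging.getLogger("diffsweep")


@dataclass
class HaplotypeSpectrum:
    snp_ids: list[str]
    counts: dict[str, dict[str, int]]  # population -> allele string -> count
    freqs: dict[str, dict[str, float]]  # population -> allele string -> frequency

    def frequency_of(self, haplotype: str) -> dict[str, float]:
        """Per-population frequency of one allele string (0 where absent)."""
        return {pop: self.freqs[pop].get(haplotype, 0.0) for pop in self.freqs}

    @property
    def haplotypes(self) -> list[str]:
        """All distinct allele strings, most common first (pooled)."""
        pooled: dict[str, int] = {}
        for c in self.counts.values():
            for hap, n in c.items():
                pooled[hap] = pooled.get(hap, 0) + n
        return sorted(pooled, key=lambda h: (-pooled[h], h))


@dataclass
class EnvRegressionResult:
    n: int
    slope: float
    intercept: float
    r2: float
    p_value: float
    pairs: dict[str, tuple[float, float]]  # population -> (frequency, covariate)


def haplotype_spectrum(
    matrix: HaplotypeMatrix,
    snp_ids: Sequence[str],
    letters: str = "bases",
) -> HaplotypeSpectrum:
    """Per-population haplotype composition over an ordered SNP subset.

    With ``letters="bases"`` (default) each haplotype is rendered as its
    REF/ALT base letters in the given SNP order, matching the field's usual
    notation; ``letters="binary"`` renders 0/1 instead (useful for synthetic
    data without base semantics).
    """
    idx = [matrix.variant_index(s) for s in snp_ids]  # KeyError names the SNP
    sub = matrix.haplotypes[idx, :]  # snps x haplotypes
    labels = matrix.population_of_haplotypes("population")
    counts: dict[str, dict[str, int]] = {}
    for pop in sorted(set(labels)):
        cols = np.flatnonzero(labels == pop)
        tab: dict[str, int] = {}
        for c in cols:
            alleles = sub[:, c]
            if letters == "bases":
                s = "".join(
                    matrix.variants[i].alt if a else matrix.variants[i].ref
                    for i, a in zip(idx, alleles)
                )
            elif letters == "binary":
                s = "".join(str(int(a)) for a in alleles)
            else:
                raise ValueError(f"letters must be 'bases' or 'binary', got {letters!r}")
            tab[s] = tab.get(s, 0) + 1
        counts[pop] = tab
    freqs = {
        pop: {h: n / sum(tab.values()) for h, n in tab.items()}
        for pop, tab in counts.items()
    }
    return HaplotypeSpectrum(snp_ids=list(snp_ids), counts=counts, freqs=freqs)


def env_correlation(
    freqs: Mapping[str, float],
    covariate: Mapping[str, float],
) -> EnvRegressionResult:
    """OLS of an environmental covariate on a haplotype's frequency.

    Populations present in only one of the two maps are dropped with a
    warning; at least three shared populations are required.  Returns the
    slope, intercept, R-squared and the two-sided p-value for the slope from
    the t distribution with n-2 degrees of freedom.
    """
    shared = sorted(set(freqs) & set(covariate))
    dropped = sorted(set(freqs) ^ set(covariate))
    if dropped:
        logger.warning("env_correlation: dropping unmatched populations %s", dropped)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared populations, have {len(shared)}")
    x = np.array([freqs[p] for p in shared], dtype=float)
    y = np.array([covariate[p] for p in shared], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in haplotype frequency; R^2 undefined")
    if np.ptp(y) == 0:
        # constant covariate: flat fit, no association
        return EnvRegressionResult(
            n=len(shared), slope=0.0, intercept=float(y[0]), r2=0.0,
            p_value=1.0, pairs={p: (float(freqs[p]), float(covariate[p])) for p in shared},
        )
    fit = stats.linregress(x, y)
    return EnvRegressionResult(
        n=len(shared),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        pairs={p: (float(freqs[p]), float(covariate[p])) for p in shared},
    )
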