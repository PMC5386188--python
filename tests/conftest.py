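"""Shared fixtures: small hand-built matrices and on-disk VCF fixtures."""

from __future__ import annotations

import numpy as np
import pytest

from diffsweep.core import (
    GeneRegion,
    HaplotypeMatrix,
    PopulationPanel,
    VariantRecord,
)


def make_matrix(
    haps: np.ndarray,
    pops: list[str],
    groups: dict[str, str] | None = None,
    positions: list[int] | None = None,
    chrom: str = "1",
    ancestral: str = "ref",
    ref: str = "A",
    alt: str = "G",
) -> HaplotypeMatrix:
    """Build a HaplotypeMatrix from a (variants x haplotypes) 0/1 array.

    ``pops`` gives one population label per *sample* (= per haplotype pair).
    """
    haps = np.asarray(haps, dtype=np.uint8)
    n_var, n_hap = haps.shape
    assert n_hap == 2 * len(pops)
    if positions is None:
        positions = [1000 * (i + 1) for i in range(n_var)]
    variants = [
        VariantRecord(
            chrom=chrom, pos=positions[i], id=f"v{i}", ref=ref, alt=alt,
            ancestral=ancestral,
        )
        for i in range(n_var)
    ]
    samples = [f"S{j}" for j in range(len(pops))]
    pop_of = dict(zip(samples, pops))
    if groups is None:
        groups = {p: "G1" for p in set(pops)}
    panel = PopulationPanel(population_of=pop_of, group_of=groups)
    sample_of = [s for s in samples for _ in range(2)]
    return HaplotypeMatrix(variants, haps, sample_of, panel)


@pytest.fixture
def tiny_panel_file(tmp_path):
    p = tmp_path / "panel.tsv"
    p.write_text(
        "sample\tpopulation\tgroup\n"
        "NA1\tYRI\tAFR\nNA2\tYRI\tAFR\nNA3\tCEU\tEUR\n"
    )
    return p


@pytest.fixture
def tiny_vcf_file(tmp_path):
    """3 samples; 2 phased biallelic SNPs, 1 multiallelic, 1 unphased."""
    p = tmp_path / "tiny.vcf"
    p.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "##contig=<ID=4>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tNA1\tNA2\tNA3\n"
        "4\t42003671\trs1047626\tA\tG\t.\tPASS\t.\tGT\t0|0\t0|1\t1|1\n"
        "4\t42003700\tmulti\tA\tG,T\t.\tPASS\t.\tGT\t0|0\t0|1\t0|2\n"
        "4\t42003800\tunph\tC\tT\t.\tPASS\t.\tGT\t0/1\t0|1\t1|1\n"
        "4\t42003900\trs2\tC\tT\t.\tPASS\t.\tGT\t1|0\t0|0\t0|1\n"
    )
    return p
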