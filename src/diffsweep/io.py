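"""Readers and writers for the package's external formats.

VCF ingestion goes through cyvcf2; panel, gene-table and ancestral-allele
files are plain TSV read with pandas.  Coordinates are 1-based inclusive
internally (the VCF convention); BED input (0-based half-open) is converted
at the reader boundary.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import GeneRegion, HaplotypeMatrix, PopulationPanel, VariantRecord

logger = logging.getLogger("diffsweep")

_BASES = frozenset("ACGT")


def _is_biallelic_snp(ref: str, alts: list[str]) -> bool:
    return (
        len(alts) == 1
        and len(ref) == 1
        and len(alts[0]) == 1
        and ref.upper() in _BASES
        and alts[0].upper() in _BASES
        and ref.upper() != alts[0].upper()
    )


def read_phased_vcf(
    path: str | Path,
    panel: PopulationPanel,
    region: GeneRegion | None = None,
) -> HaplotypeMatrix:
    """Read a phased VCF into a :class:`HaplotypeMatrix`.

    Only strictly biallelic SNPs with a fully phased, non-missing GT are
    retained; multiallelic records, indels and records with unphased or
    missing genotypes are skipped and counted (``matrix.meta``).  If
    ``region`` is given, records are restricted to it (flank included).

    Raises
    ------
    ValueError
        If the VCF has no GT FORMAT field, or if a VCF sample is absent
        from ``panel``.
    """
    path = str(path)
    vcf = VCF(path, gts012=False)
    if "##FORMAT=<ID=GT" not in vcf.raw_header:
        raise ValueError(f"{path}: VCF has no GT FORMAT field")
    samples = list(vcf.samples)
    for s in samples:
        if s not in panel.population_of:
            raise ValueError(f"VCF sample {s!r} absent from panel")

    variants: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    skipped = {"multiallelic_or_indel": 0, "unphased_or_missing": 0, "outside_region": 0}
    for rec in vcf:
        if not _is_biallelic_snp(rec.REF, rec.ALT):
            skipped["multiallelic_or_indel"] += 1
            continue
        chrom = rec.CHROM
        pos = rec.POS
        if region is not None and not region.contains(chrom, pos):
            skipped["outside_region"] += 1
            continue
        gts = rec.genotypes  # [[a0, a1, phased], ...]
        row = np.empty(2 * len(samples), dtype=np.uint8)
        ok = True
        for i, g in enumerate(gts):
            if len(g) != 3 or not g[2] or g[0] < 0 or g[1] < 0:
                ok = False
                break
            row[2 * i] = g[0]
            row[2 * i + 1] = g[1]
        if not ok:
            skipped["unphased_or_missing"] += 1
            continue
        vid = rec.ID if rec.ID else f"{chrom}:{pos}"
        variants.append(
            VariantRecord(chrom=chrom, pos=pos, id=vid, ref=rec.REF, alt=rec.ALT[0])
        )
        rows.append(row)
    vcf.close()
    for key, n in skipped.items():
        if n:
            logger.info("read_phased_vcf(%s): skipped %d %s records", path, n, key)
    sample_of = [s for s in samples for _ in range(2)]
    haps = (
        np.vstack(rows) if rows else np.empty((0, 2 * len(samples)), dtype=np.uint8)
    )
    return HaplotypeMatrix(variants, haps, sample_of, panel, meta={"skipped": skipped})


def attach_ancestral(
    matrix: HaplotypeMatrix, annot: dict[str, str]
) -> HaplotypeMatrix:
    """Set each variant's ancestral state from an id -> base annotation.

    Matching is case-insensitive; a base matching neither allele, or a
    missing annotation, yields ``"unknown"`` (counted in ``meta``).
    """
    states: list[str] = []
    n_unknown = 0
    for v in matrix.variants:
        base = annot.get(v.id, "").strip().upper()
        if base == v.ref.upper():
            states.append("ref")
        elif base == v.alt.upper():
            states.append("alt")
        else:
            states.append("unknown")
            n_unknown += 1
    out = matrix.with_ancestral(states)
    out.meta["n_ancestral_unknown"] = n_unknown
    if n_unknown:
        logger.info("attach_ancestral: %d variants left unpolarized", n_unknown)
    return out


def read_panel(path: str | Path) -> PopulationPanel:
    """Read a sample panel TSV with columns (sample, population, group)."""
    df = _read_tsv(path, ["sample", "population", "group"])
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
        raise ValueError(f"duplicate sample id {dup!r} in panel {path}")
    group_of: dict[str, str] = {}
    for pop, grp in zip(df["population"], df["group"]):
        if pop in group_of and group_of[pop] != grp:
            raise ValueError(f"population {pop!r} mapped to two groups")
        group_of[pop] = grp
    return PopulationPanel(
        population_of=dict(zip(df["sample"], df["population"])), group_of=group_of
    )


def read_gene_table(path: str | Path, fmt: str = "tsv") -> list[GeneRegion]:
    """Read a gene coordinate table.

    ``fmt="tsv"`` expects columns (name, chrom, start, end) with 1-based
    inclusive coordinates; ``fmt="bed"`` expects BED columns
    (chrom, start, end, name) with 0-based half-open coordinates, converted
    on read.  An empty file yields an empty list with a warning.
    """
    if fmt == "tsv":
        df = _read_tsv(path, ["name", "chrom", "start", "end"])
        if df.empty:
            logger.warning("gene table %s is empty", path)
            return []
        return [
            GeneRegion(name=str(r.name), chrom=str(r.chrom), start=int(r.start), end=int(r.end))
            for r in df.itertuples(index=False)
        ]
    if fmt == "bed":
        df = _read_tsv(path, ["chrom", "start", "end", "name"], header_probe="chrom")
        if df.empty:
            logger.warning("gene table %s is empty", path)
            return []
        return [
            GeneRegion(
                name=str(r.name), chrom=str(r.chrom), start=int(r.start) + 1, end=int(r.end)
            )
            for r in df.itertuples(index=False)
        ]
    raise ValueError(f"unknown gene table format {fmt!r}")


def read_ancestral_table(path: str | Path) -> dict[str, str]:
    """Read an ancestral-allele annotation TSV with columns (id, base)."""
    df = _read_tsv(path, ["id", "base"])
    return dict(zip(df["id"].astype(str), df["base"].astype(str)))


def _read_tsv(
    path: str | Path, columns: list[str], header_probe: str | None = None
) -> pd.DataFrame:
    """Read a TSV that may or may not carry a header row naming ``columns``."""
    probe = header_probe or columns[0]
    path = Path(path)
    if path.stat().st_size == 0:
        return pd.DataFrame(columns=columns)
    first = path.open().readline().split("\t")[0].strip().lstrip("#")
    if first == probe:
        df = pd.read_csv(path, sep="\t")
        df.columns = [c.lstrip("#") for c in df.columns]
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        return df[columns]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < len(columns):
        raise ValueError(f"{path}: expected {len(columns)} columns, got {df.shape[1]}")
    df = df.iloc[:, : len(columns)]
    df.columns = columns
    return df


# ---------------------------------------------------------------------------
# writers (plain-text emission; used by the fixture bundle and the CLI)
# ---------------------------------------------------------------------------

def write_vcf(matrix: HaplotypeMatrix, path: str | Path) -> None:
    """Write the matrix as an uncompressed phased VCF v4.2."""
    samples = matrix.samples
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=diffsweep\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(v.chrom for v in matrix.variants):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        h = matrix.haplotypes
        for i, v in enumerate(matrix.variants):
            gts = "\t".join(
                f"{h[i, 2 * j]}|{h[i, 2 * j + 1]}" for j in range(len(samples))
            )
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}\n")


def write_panel(panel: PopulationPanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tpopulation\tgroup\n")
        for s, p in panel.population_of.items():
            fh.write(f"{s}\t{p}\t{panel.group_of[p]}\n")


def write_gene_bed(regions: list[GeneRegion], path: str | Path) -> None:
    """Write regions as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.name}\n")


def write_ancestral_table(matrix: HaplotypeMatrix, path: str | Path) -> None:
    """Write the per-variant ancestral bases (unknowns written as '.')."""
    with open(path, "w") as fh:
        fh.write("id\tbase\n")
        for v in matrix.variants:
            if v.ancestral == "ref":
                base = v.ref
            elif v.ancestral == "alt":
                base = v.alt
            else:
                base = "."
            fh.write(f"{v.id}\t{base}\n")
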