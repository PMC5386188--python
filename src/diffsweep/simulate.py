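"""Synthetic phased-haplotype generators with known truth.

Two generators cover the two signal classes the pipeline detects:

* :func:`simulate_structure` draws multi-population allele frequencies from
  the Balding-Nichols model — per locus an ancestral frequency p is drawn
  uniformly within bounds and each population's frequency from
  ``Beta(p(1-F)/F, (1-p)(1-F)/F)``, so F is the expected F_ST-like
  divergence — then samples haplotypes independently per locus.  It emulates
  allele-frequency differentiation, not linkage disequilibrium.

* :func:`simulate_sweep` runs a discrete-generation haploid Wright-Fisher
  population with single-crossover recombination over a finite region,
  started from a small founder pool (standing variation, no new mutation).
  After a neutral burn-in that builds realistic haplotype sharing, an
  optional beneficial mutation (multiplicative fitness 1+s) is introduced at
  the central locus and the run continues until it reaches a target
  frequency, producing the long shared haplotypes iHS detects.  If the
  beneficial allele is lost the sweep phase restarts from the post-burn-in
  state with an incremented sub-seed (``default_rng([seed, attempt])``), so
  runs remain reproducible.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import GeneRegion, HaplotypeMatrix, PopulationPanel, VariantRecord
from . import io as dio

logger = logging.getLogger("diffsweep")


@dataclass(frozen=True)
class StructureConfig:
    """Balding-Nichols population-structure generator settings."""

    n_pops: int = 2
    haps_per_pop: int = 200
    n_loci: int = 5000
    target_f: float = 0.1  # drift parameter F per population
    freq_bounds: tuple[float, float] = (0.05, 0.95)
    spacing_bp: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.target_f < 1:
            raise ValueError("target_f must be in [0, 1)")
        if self.haps_per_pop < 2:
            raise ValueError("need >= 2 haplotypes per population")
        lo, hi = self.freq_bounds
        if not 0 < lo < hi < 1:
            raise ValueError("freq_bounds must satisfy 0 < lo < hi < 1")


@dataclass(frozen=True)
class SweepConfig:
    """Forward Wright-Fisher sweep generator settings.

    ``recomb_rate`` is the per-generation, per-bp crossover probability
    (1e-8 is the human genome-wide average; the default is mildly elevated
    so EHH decays within the simulated region).  ``s`` is the selection
    coefficient on the focal derived allele; ``s = 0`` gives a neutral
    panel.  ``pop_size`` is the haploid population size N.
    """

    n_haplotypes: int = 200
    n_loci: int = 100
    region_bp: int = 3_000_000
    recomb_rate: float = 2e-8
    s: float = 0.05
    target_freq: float = 0.7
    pop_size: int = 16000
    n_founders: int = 3200
    burnin_generations: int = 300
    max_generations: int = 5000
    max_attempts: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError("s must be >= 0")
        if not 0 < self.target_freq <= 1:
            raise ValueError("target_freq must be in (0, 1]")
        if self.pop_size < self.n_haplotypes:
            raise ValueError("pop_size must be >= n_haplotypes")


def _config_hash(cfg) -> str:
    payload = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=list)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _make_variants(
    chrom: str, positions: np.ndarray, prefix: str
) -> list[VariantRecord]:
    return [
        VariantRecord(
            chrom=chrom, pos=int(p), id=f"{prefix}{k:06d}",
            ref="A", alt="G", ancestral="ref",
        )
        for k, p in enumerate(positions)
    ]


# ---------------------------------------------------------------------------
# Balding-Nichols structure
# ---------------------------------------------------------------------------

def simulate_structure(
    cfg: StructureConfig,
    gene_layout: list[int] | None = None,
    groups: dict[str, str] | None = None,
) -> tuple[HaplotypeMatrix, dict]:
    """Multi-population haplotypes under the Balding-Nichols model.

    ``gene_layout`` partitions the loci into contiguous gene blocks (its
    entries must sum to ``n_loci``); gene regions are recorded in the truth
    dict.  The ancestral allele is always REF, so matrices are fully
    polarized and the ALT frequency is the derived allele frequency.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.freq_bounds
    L, P, H = cfg.n_loci, cfg.n_pops, cfg.haps_per_pop
    p_anc = rng.uniform(lo, hi, size=L)
    if cfg.target_f == 0:
        p_pop = np.tile(p_anc, (P, 1))
    else:
        f = cfg.target_f
        alpha = p_anc * (1 - f) / f
        beta = (1 - p_anc) * (1 - f) / f
        p_pop = rng.beta(alpha, beta, size=(P, L))
    haps = np.empty((L, P * H), dtype=np.uint8)
    for j in range(P):
        draws = rng.random(size=(L, H)) < p_pop[j][:, None]
        haps[:, j * H : (j + 1) * H] = draws.astype(np.uint8)

    positions = (np.arange(L) + 1) * cfg.spacing_bp
    variants = _make_variants("1", positions, "snp")
    pop_names = [f"POP{j + 1}" for j in range(P)]
    if groups is None:
        groups = {p: f"GRP{j + 1}" for j, p in enumerate(pop_names)}
    samples = []
    pop_of = {}
    for j, pop in enumerate(pop_names):
        for k in range(H // 2):
            sid = f"{pop}_S{k:04d}"
            samples.append(sid)
            pop_of[sid] = pop
    if H % 2:
        raise ValueError("haps_per_pop must be even (diploid samples)")
    panel = PopulationPanel(population_of=pop_of, group_of=groups)
    sample_of = [s for s in samples for _ in range(2)]
    matrix = HaplotypeMatrix(variants, haps, sample_of, panel)

    gene_regions = []
    if gene_layout is not None:
        if sum(gene_layout) != L:
            raise ValueError("gene_layout must sum to n_loci")
        start = 0
        for gi, n in enumerate(gene_layout):
            block = positions[start : start + n]
            gene_regions.append(
                GeneRegion(
                    name=f"gene{gi + 1:03d}", chrom="1",
                    start=int(block[0]), end=int(block[-1]),
                )
            )
            start += n
    truth = {
        "kind": "structure",
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "target_f": cfg.target_f,
        "ancestral_freqs": p_anc.tolist(),
        "genes": [dataclasses.asdict(g) for g in gene_regions],
    }
    return matrix, truth


# ---------------------------------------------------------------------------
# forward Wright-Fisher sweep
# ---------------------------------------------------------------------------

def _next_generation(
    pop: np.ndarray,
    positions: np.ndarray,
    region_bp: int,
    recomb_rate: float,
    fitness: np.ndarray | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """One Wright-Fisher generation with single-crossover recombination."""
    n = pop.shape[0]
    if fitness is None:
        p1 = rng.integers(0, n, size=n)
    else:
        w = fitness / fitness.sum()
        p1 = rng.choice(n, size=n, p=w)
    child = pop[p1].copy()
    rec_prob = recomb_rate * region_bp
    rec = np.flatnonzero(rng.random(n) < rec_prob)
    if rec.size:
        if fitness is None:
            p2 = rng.integers(0, n, size=rec.size)
        else:
            p2 = rng.choice(n, size=rec.size, p=fitness / fitness.sum())
        breaks = rng.integers(1, region_bp + 1, size=rec.size)
        for i, j, bp in zip(rec, p2, breaks):
            k = int(np.searchsorted(positions, bp))
            child[i, k:] = pop[j, k:]
    return child


def simulate_sweep(cfg: SweepConfig) -> tuple[HaplotypeMatrix, dict]:
    """Haploid Wright-Fisher panel, optionally with a partial sweep.

    Returns the sampled matrix and a truth dict recording the focal locus
    index, generations elapsed in the sweep phase, the final focal
    frequency and the number of restart attempts.
    """
    rng = np.random.default_rng(cfg.seed)
    positions = np.sort(
        rng.choice(cfg.region_bp, size=cfg.n_loci, replace=False)
    ).astype(np.int64) + 1
    founder_freq = rng.uniform(0.1, 0.9, size=cfg.n_loci)
    founders = (
        rng.random((cfg.n_founders, cfg.n_loci)) < founder_freq[None, :]
    ).astype(np.uint8)
    pop = founders[rng.integers(0, cfg.n_founders, size=cfg.pop_size)].copy()
    for _ in range(cfg.burnin_generations):
        pop = _next_generation(pop, positions, cfg.region_bp, cfg.recomb_rate, None, rng)

    focal = cfg.n_loci // 2
    generations = 0
    attempts = 0
    final_freq = float(pop[:, focal].mean())
    if cfg.s > 0:
        base = pop.copy()
        done = False
        for attempt in range(cfg.max_attempts):
            attempts = attempt + 1
            srng = np.random.default_rng([cfg.seed, attempt])
            pop = base.copy()
            pop[:, focal] = 0
            pop[srng.integers(0, cfg.pop_size), focal] = 1
            g = 0
            while g < cfg.max_generations:
                fitness = 1.0 + cfg.s * pop[:, focal].astype(float)
                pop = _next_generation(
                    pop, positions, cfg.region_bp, cfg.recomb_rate, fitness, srng
                )
                g += 1
                freq = pop[:, focal].mean()
                if freq == 0:
                    break
                if freq >= cfg.target_freq:
                    done = True
                    break
            if done:
                generations = g
                final_freq = float(pop[:, focal].mean())
                break
        if not done:
            raise RuntimeError(
                f"sweep did not fix within {cfg.max_attempts} attempts"
            )
        if attempts > 1:
            logger.info("simulate_sweep: %d attempts before sweep succeeded", attempts)
        sample_rng = srng
    else:
        sample_rng = rng

    take = sample_rng.choice(cfg.pop_size, size=cfg.n_haplotypes, replace=False)
    haps = pop[take].T.copy()  # loci x haplotypes

    variants = _make_variants("1", positions, "sw")
    n_samples = cfg.n_haplotypes // 2
    if cfg.n_haplotypes % 2:
        raise ValueError("n_haplotypes must be even (diploid samples)")
    samples = [f"SIM_S{k:04d}" for k in range(n_samples)]
    panel = PopulationPanel(
        population_of={s: "SIM" for s in samples}, group_of={"SIM": "SIMGRP"}
    )
    sample_of = [s for s in samples for _ in range(2)]
    matrix = HaplotypeMatrix(variants, haps, sample_of, panel)
    truth = {
        "kind": "sweep" if cfg.s > 0 else "neutral",
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "focal_index": focal,
        "focal_id": variants[focal].id,
        "focal_pos": int(positions[focal]),
        "s": cfg.s,
        "generations": generations,
        "attempts": attempts,
        "final_focal_freq": final_freq,
        "sampled_focal_freq": float(haps[focal].mean()),
    }
    return matrix, truth


def simulate_sweep_panel(
    template: SweepConfig,
    n_neutral: int = 20,
    include_sweep: bool = True,
    seed: int = 0,
) -> tuple[HaplotypeMatrix, dict]:
    """A multi-gene scan panel: independent neutral genes plus one swept gene.

    Each gene is a separate Wright-Fisher run (its own chromosome) built from
    ``template`` with a per-gene sub-seed derived from ``seed``; neutral
    genes use ``s = 0`` and the last gene (if ``include_sweep``) carries the
    template's selection coefficient.  All genes share one sample panel, so
    the result behaves like a small multi-chromosome genome for iHS
    scanning.
    """
    gene_cfgs = []
    for gi in range(n_neutral):
        gene_cfgs.append(("neutral", dataclasses.replace(template, s=0.0)))
    if include_sweep:
        gene_cfgs.append(("sweep", template))
    matrices = []
    gene_truths = []
    regions = []
    for gi, (kind, cfg) in enumerate(gene_cfgs):
        sub_seed = int(
            np.random.SeedSequence([seed, gi]).generate_state(1)[0] % (2**31)
        )
        cfg = dataclasses.replace(cfg, seed=sub_seed)
        gm, gt = simulate_sweep(cfg)
        chrom = f"g{gi + 1:02d}"
        variants = [
            dataclasses.replace(v, chrom=chrom, id=f"{chrom}_{v.id}")
            for v in gm.variants
        ]
        gm = HaplotypeMatrix(variants, gm.haplotypes, gm.sample_of, gm.panel)
        gt["focal_id"] = f"{chrom}_{gt['focal_id']}"
        gt["gene"] = chrom
        matrices.append(gm)
        gene_truths.append(gt)
        regions.append(
            GeneRegion(name=chrom, chrom=chrom, start=1, end=cfg.region_bp)
        )
    base = matrices[0]
    variants = [v for m in matrices for v in m.variants]
    haps = np.vstack([m.haplotypes for m in matrices])
    matrix = HaplotypeMatrix(variants, haps, base.sample_of, base.panel)
    truth = {
        "kind": "sweep_panel",
        "seed": seed,
        "config_hash": _config_hash(template),
        "genes": [dataclasses.asdict(r) for r in regions],
        "gene_truths": gene_truths,
        "sweep_gene": regions[-1].name if include_sweep else None,
        "focal_id": gene_truths[-1]["focal_id"] if include_sweep else None,
    }
    return matrix, truth


# ---------------------------------------------------------------------------
# fixture bundles
# ---------------------------------------------------------------------------

def write_fixture_bundle(
    matrix: HaplotypeMatrix,
    truth: dict,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write VCF + panel + gene BED + ancestral TSV + truth JSON.

    The bundle round-trips through the readers in :mod:`diffsweep.io`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "haplotypes.vcf",
        "panel": out / "panel.tsv",
        "genes": out / "genes.bed",
        "ancestral": out / "ancestral.tsv",
        "truth": out / "truth.json",
    }
    dio.write_vcf(matrix, paths["vcf"])
    dio.write_panel(matrix.panel, paths["panel"])
    genes = [
        GeneRegion(**{k: g[k] for k in ("name", "chrom", "start", "end")})
        for g in truth.get("genes", [])
    ]
    dio.write_gene_bed(genes, paths["genes"])
    dio.write_ancestral_table(matrix, paths["ancestral"])
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return paths


def read_fixture_bundle(out_dir: str | Path) -> tuple[HaplotypeMatrix, dict]:
    """Re-ingest a bundle written by :func:`write_fixture_bundle`."""
    out = Path(out_dir)
    panel = dio.read_panel(out / "panel.tsv")
    matrix = dio.read_phased_vcf(out / "haplotypes.vcf", panel)
    annot = dio.read_ancestral_table(out / "ancestral.tsv")
    matrix = dio.attach_ancestral(matrix, annot)
    with open(out / "truth.json") as fh:
        truth = json.load(fh)
    return matrix, truth
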