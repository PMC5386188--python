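"""End-to-end orchestration: one YAML config drives ingest (or simulation),
differentiation, enrichment, selection scanning and haplotype analysis, with
a machine-readable report and a reproducibility manifest.

Every default is echoed into the manifest, and the manifest records the
config, all seeds and the SHA-256 of every input file, which together
reproduce the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import GeneRegion, HaplotypeMatrix
from . import io as dio
from .differentiation import (
    daf,
    empirical_cutoff,
    gene_wa_fst,
    matrix_locus_fst,
)
from .enrichment import GeneUniverse, geneset_permutation_test, high_fst_proportion
from .haplotypes import env_correlation, haplotype_spectrum
from .selection import sweep_scan
from .simulate import (
    StructureConfig,
    SweepConfig,
    simulate_structure,
    simulate_sweep_panel,
    write_fixture_bundle,
)

logger = logging.getLogger("diffsweep")

DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "fst": {"grouping": "population", "quantiles": [0.01, 0.05]},
    "enrichment": {"n_perm": 1000, "exclude_candidates": False},
    "ihs": {"maf_min": 0.05, "q": 0.05, "window_size": 50, "min_hits": 7},
}


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return _fill_defaults(cfg)


def _fill_defaults(cfg: dict) -> dict:
    out = dict(cfg)
    for key, val in DEFAULTS.items():
        if isinstance(val, dict):
            out[key] = {**val, **cfg.get(key, {})}
        else:
            out.setdefault(key, val)
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _jsonable(x):
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, float) and np.isnan(x):
        return None
    return x


def _load_inputs(cfg: dict, out_dir: Path) -> tuple[HaplotypeMatrix, HaplotypeMatrix, list[GeneRegion], dict]:
    """Return (differentiation matrix, selection matrix, genes, manifest entry)."""
    if "simulate" in cfg:
        sim = cfg["simulate"]
        seed = int(cfg["seed"])
        entry: dict = {"mode": "simulate"}
        s_cfg = dict(sim.get("structure", {}))
        n_genes = int(s_cfg.pop("genes", 24))
        struct = StructureConfig(**{**s_cfg, "seed": seed})
        layout = _gene_layout(struct.n_loci, n_genes)
        m_diff, truth_s = simulate_structure(struct, gene_layout=layout)
        genes = [
            GeneRegion(**{k: g[k] for k in ("name", "chrom", "start", "end")})
            for g in truth_s["genes"]
        ]
        entry["structure"] = dataclasses.asdict(struct)
        p_cfg = dict(sim.get("sweep_panel", {}))
        n_neutral = int(p_cfg.pop("n_neutral", 20))
        tmpl = SweepConfig(**{**p_cfg, "seed": seed})
        m_sel, truth_p = simulate_sweep_panel(tmpl, n_neutral=n_neutral, seed=seed)
        entry["sweep_panel"] = {
            "template": dataclasses.asdict(tmpl),
            "n_neutral": n_neutral,
            "truth": {
                "sweep_gene": truth_p["sweep_gene"],
                "focal_id": truth_p["focal_id"],
            },
        }
        sel_genes = [
            GeneRegion(**{k: g[k] for k in ("name", "chrom", "start", "end")})
            for g in truth_p["genes"]
        ]
        bundle = write_fixture_bundle(m_diff, truth_s, out_dir / "data")
        entry["bundle"] = {k: str(p) for k, p in bundle.items()}
        return m_diff, m_sel, genes + sel_genes, entry

    inputs = cfg["inputs"]
    panel = dio.read_panel(inputs["panel"])
    matrix = dio.read_phased_vcf(inputs["vcf"], panel)
    if "ancestral" in inputs:
        matrix = dio.attach_ancestral(matrix, dio.read_ancestral_table(inputs["ancestral"]))
    fmt = "bed" if str(inputs["genes"]).endswith(".bed") else "tsv"
    genes = dio.read_gene_table(inputs["genes"], fmt=fmt)
    entry = {
        "mode": "files",
        "hashes": {k: _sha256(Path(v)) for k, v in inputs.items()},
    }
    return matrix, matrix, genes, entry


def _gene_layout(n_loci: int, n_genes: int) -> list[int]:
    base = n_loci // n_genes
    layout = [base] * n_genes
    for i in range(n_loci - base * n_genes):
        layout[i] += 1
    return layout


def _stage_differentiation(matrix: HaplotypeMatrix, genes: list[GeneRegion], cfg: dict, out_dir: Path) -> dict:
    fcfg = cfg["fst"]
    comps = matrix_locus_fst(matrix, grouping=fcfg["grouping"])
    thetas = np.array([c.theta for c in comps])
    cutoffs = {
        str(q): empirical_cutoff(thetas, float(q)) for q in fcfg["quantiles"]
    }
    top_cut = cutoffs[str(fcfg["quantiles"][0])]
    per_locus = pd.DataFrame(
        {
            "id": [v.id for v in matrix.variants],
            "chrom": [v.chrom for v in matrix.variants],
            "pos": [v.pos for v in matrix.variants],
            "a": [c.a for c in comps],
            "b": [c.b for c in comps],
            "theta": thetas,
        }
    )
    per_locus.to_csv(out_dir / "locus_fst.tsv", sep="\t", index=False)
    gene_rows = []
    gene_thetas: dict[str, np.ndarray] = {}
    for g in genes:
        sel = (
            (per_locus["chrom"] == g.chrom)
            & (per_locus["pos"] >= g.flanked_start)
            & (per_locus["pos"] <= g.flanked_end)
        )
        sub = [comps[i] for i in np.flatnonzero(sel.to_numpy())]
        if not sub:
            continue
        gf = gene_wa_fst(sub, gene=g.name, cutoff=top_cut)
        gene_rows.append(
            {"gene": g.name, "n_loci": gf.n_loci, "wa_fst": gf.wa_fst, "prop_high": gf.prop_high}
        )
        gene_thetas[g.name] = per_locus.loc[sel, "theta"].to_numpy()
    pd.DataFrame(gene_rows).to_csv(out_dir / "gene_fst.tsv", sep="\t", index=False)
    return {
        "n_loci": len(comps),
        "cutoffs": cutoffs,
        "genes": {r["gene"]: {"wa_fst": r["wa_fst"], "n_loci": r["n_loci"]} for r in gene_rows},
        "_gene_thetas": gene_thetas,
    }


def _stage_enrichment(diff_report: dict, cfg: dict, out_dir: Path) -> dict:
    candidates = cfg.get("candidates")
    if not candidates:
        return {"skipped": "no candidate gene set configured"}
    ecfg = cfg["enrichment"]
    universe = GeneUniverse(thetas=dict(diff_report["_gene_thetas"]))
    cutoff = float(diff_report["cutoffs"][str(cfg["fst"]["quantiles"][0])])
    result = geneset_permutation_test(
        candidates,
        universe,
        stat=lambda gs: high_fst_proportion(universe, gs, cutoff),
        n_perm=int(ecfg["n_perm"]),
        seed=int(cfg["seed"]),
        exclude_candidates=bool(ecfg["exclude_candidates"]),
    )
    np.savetxt(out_dir / "enrichment_null.tsv", result.null, fmt="%.8g")
    return {
        "observed": result.observed,
        "p_tail": result.p_tail,
        "p_default": result.p_default,
        "n_perm": result.n_perm,
        "fst_cutoff": cutoff,
    }


def _stage_selection(matrix: HaplotypeMatrix, genes: list[GeneRegion], cfg: dict, out_dir: Path) -> dict:
    icfg = cfg["ihs"]
    chroms = {v.chrom for v in matrix.variants}
    sel_genes = [g for g in genes if g.chrom in chroms]
    out: dict = {"populations": {}}
    for pop in matrix.panel.populations:
        table, cut, calls = sweep_scan(
            matrix,
            sel_genes,
            population=pop,
            q=float(icfg["q"]),
            window_size=int(icfg["window_size"]),
            min_hits=int(icfg["min_hits"]),
            maf_min=float(icfg["maf_min"]),
        )
        table.to_csv(out_dir / f"ihs_{pop}.tsv", sep="\t", index=False)
        pd.DataFrame([dataclasses.asdict(c) for c in calls]).to_csv(
            out_dir / f"sweep_calls_{pop}.tsv", sep="\t", index=False
        )
        out["populations"][pop] = {
            "cutoff": cut,
            "n_scored": int(table["valid"].sum()),
            "flagged_genes": sorted(c.gene for c in calls if c.flagged),
        }
    return out


def _stage_haplotype(matrix: HaplotypeMatrix, cfg: dict, out_dir: Path) -> dict:
    hcfg = cfg.get("haplotype")
    if not hcfg:
        return {"skipped": "no haplotype analysis configured"}
    snp_ids = hcfg["snp_ids"]
    letters = hcfg.get("letters", "bases")
    spec = haplotype_spectrum(matrix, snp_ids, letters=letters)
    rows = [
        {"population": pop, "haplotype": hap, "count": n, "frequency": spec.freqs[pop][hap]}
        for pop, tab in spec.counts.items()
        for hap, n in sorted(tab.items())
    ]
    pd.DataFrame(rows).to_csv(out_dir / "haplotype_spectrum.tsv", sep="\t", index=False)
    out: dict = {"n_haplotype_classes": len(spec.haplotypes)}
    if "covariate" in hcfg:
        target = hcfg.get("target_haplotype", "auto")
        if target == "auto":
            target = spec.haplotypes[0]
        reg = env_correlation(spec.frequency_of(target), hcfg["covariate"])
        out["regression"] = {
            "haplotype": target,
            "n": reg.n,
            "slope": reg.slope,
            "intercept": reg.intercept,
            "r2": reg.r2,
            "p_value": reg.p_value,
        }
    return out


def run_differentiation_scan(cfg: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    return _run(cfg, out_dir, stages=("differentiation", "enrichment"))


def run_selection_scan(cfg: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    return _run(cfg, out_dir, stages=("selection",))


def run_full(cfg: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    return _run(cfg, out_dir, stages=("differentiation", "enrichment", "selection", "haplotype"))


def _run(cfg: dict | str | Path, out_dir, stages) -> dict:
    if not isinstance(cfg, dict):
        cfg = load_config(cfg)
    else:
        cfg = _fill_defaults(cfg)
    out = Path(out_dir if out_dir is not None else cfg.get("out_dir", "diffsweep_out"))
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config": _jsonable(cfg), "stages": []}
    report: dict = {"seed": cfg["seed"]}
    try:
        stage = "ingest"
        m_diff, m_sel, genes, entry = _load_inputs(cfg, out)
        manifest["inputs"] = _jsonable(entry)
        manifest["stages"].append(stage)
        diff_rep: dict = {}
        if "differentiation" in stages:
            stage = "differentiation"
            diff_rep = _stage_differentiation(m_diff, genes, cfg, out)
            report["differentiation"] = {
                k: _jsonable(v) for k, v in diff_rep.items() if not k.startswith("_")
            }
            manifest["stages"].append(stage)
        if "enrichment" in stages:
            stage = "enrichment"
            if not diff_rep:
                diff_rep = _stage_differentiation(m_diff, genes, cfg, out)
            report["enrichment"] = _jsonable(_stage_enrichment(diff_rep, cfg, out))
            manifest["stages"].append(stage)
        if "selection" in stages:
            stage = "selection"
            report["selection"] = _jsonable(_stage_selection(m_sel, genes, cfg, out))
            manifest["stages"].append(stage)
        if "haplotype" in stages:
            stage = "haplotype"
            report["haplotype"] = _jsonable(_stage_haplotype(m_diff, cfg, out))
            manifest["stages"].append(stage)
    except Exception as exc:  # noqa: BLE001 - abort with stage name + partial manifest
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        raise StageError(stage, exc) from exc
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return report
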