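# diffsweep

Population differentiation and selective-sweep scanning on phased haplotypes.

`diffsweep` is a toolkit for the classic candidate-gene population-genetics
workflow: given phased biallelic SNP genotypes for several populations, it
asks (i) which loci and genes are unusually differentiated between
populations, (ii) whether a candidate gene set carries more highly
differentiated variants than random gene sets, (iii) whether any gene shows
the long-haplotype signature of a recent partial selective sweep, and
(iv) whether the frequency of a particular haplotype tracks an environmental
covariate across populations. It is aimed at researchers studying local
adaptation in humans or other diploid species — for example, divergence of
micronutrient-transporter genes across continental groups.

## What it computes

**Locus-specific F_ST.** Per-SNP Weir–Cockerham variance components on
haploid samples (phased haplotypes are 2N haploid observations): with `r`
demes, haplotype counts `n_i` and allele frequencies `p_i`,

    b     = (n̄/(n̄−1)) · (p̄(1−p̄) − ((r−1)/r)·s²)        (within-deme)
    a     = (n̄/n_c) · (s² − b/n̄)                         (between-deme)
    θ̂     = a / (a + b)

Gene-level **WA-F_ST** combines loci as a ratio of sums, `Σa / Σ(a+b)`.
Empirical genome-wide cutoffs (top 1%, top 5% of θ̂) define "highly
differentiated" loci. A simplified AMOVA partitions haplotype Hamming
distances into among-group / among-population / within-population components
with Φ statistics and a label-permutation p-value.

**Gene-set permutation enrichment.** The proportion of high-F_ST SNPs in a
candidate set is ranked against the same statistic on randomly drawn
same-size gene sets; a second test does the same for non-synonymous SNPs
carrying an African-high / non-African-low derived-allele-frequency pattern.
Both the plain tail index `#{null ≥ obs}/n` and the add-one convention
`(#{null ≥ obs}+1)/(n+1)` are reported.

**EHH / iHS selection scan.** Extended haplotype homozygosity around a core
allele, `EHH(x) = Σ_h C(n_h,2)/C(n,2)`, is integrated against physical
position to iHH; `iHS = ln(iHH_ancestral / iHH_derived)`, standardized
within derived-allele-frequency bins. A gene is called as a sweep candidate
when any window of 50 consecutive scored SNPs contains ≥7 loci with |iHS| at
or above the genome-wide top-5% cutoff. Haplotype bifurcation trees
visualise the decay of the core haplotype.

**Haplotype spectra and environment regression.** Haplotype composition
over a chosen SNP subset (e.g. a gene's non-synonymous SNPs) per population,
and OLS of an environmental covariate on one haplotype's per-population
frequency.

**Synthetic data.** Balding–Nichols multi-population structure (known
target F_ST) and a forward Wright–Fisher simulator with recombination and a
selected focal allele (known sweep truth), so the whole pipeline is testable
without any data download.

## Worked example

```python
import numpy as np
import diffsweep as ds

# two populations diverged at F = 0.1, 200 haplotypes each, 5000 SNPs
cfg = ds.StructureConfig(n_pops=2, haps_per_pop=200, n_loci=5000,
                         target_f=0.1, seed=42)
matrix, truth = ds.simulate_structure(cfg)

comps = ds.matrix_locus_fst(matrix)              # per-SNP (a, b, theta)
genome = ds.gene_wa_fst(comps, gene="genome")    # ratio-of-sums theta
thetas = np.array([c.theta for c in comps])
print(f"genome-wide WA-F_ST: {genome.wa_fst:.4f}")
print(f"top-1% cutoff: {ds.empirical_cutoff(thetas, 0.01):.4f}   "
      f"top-5% cutoff: {ds.empirical_cutoff(thetas, 0.05):.4f}")

# haplotype frequency (%) vs prevalence of inadequate zinc intake (%)
res = ds.env_correlation({"CHB": 96.4, "CEU": 76.5, "YRI": 8.0},
                         {"CHB": 11.0, "CEU": 9.6, "YRI": 21.0})
print(f"slope={res.slope:.4f}  R2={res.r2:.3f}  p={res.p_value:.3f}")
```

prints

```
genome-wide WA-F_ST: 0.1040
top-1% cutoff: 0.4685   top-5% cutoff: 0.3133
slope=-0.1269  R2=0.896  p=0.209
```

The estimator recovers the simulated divergence (θ̂ ≈ 0.10 for a target
F = 0.1); the cutoffs are the order statistics below which 99% and 95% of
locus estimates fall; and across the three reference populations the
zinc-deficiency prevalence falls by ≈0.13 percentage points per percentage
point of haplotype frequency (R² = 0.896; with only three populations the
slope is not significant at n = 3).

A full pipeline run — ingest or simulate, F_ST, enrichment, iHS scan, sweep
calls, haplotype spectrum — is driven by one YAML config:

```bash
diffsweep run --config config.yaml --out results/
```

See `diffsweep --help` for the individual subcommands (`fst`, `amova`,
`enrich`, `ihs`, `sweep-call`, `bifurcate`, `hapspec`, `envcorr`,
`simulate`).

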