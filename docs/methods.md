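# Methods

This note documents the statistical models implemented in `diffsweep`, the
conventions and tunable parameters that matter, what the synthetic-data
generators do and do not emulate, and the numerical choices made where the
design was genuinely open.

## Data model

All statistics operate on a `HaplotypeMatrix`: a dense binary matrix of
biallelic SNPs × phased haplotypes with no missing entries, plus a panel
mapping samples to populations and populations to continental groups. This
mirrors fully phased, fully imputed reference data. Consequences:

- Only strictly biallelic SNPs enter the matrix; multiallelic records and
  indels are dropped at the VCF reader and counted, since every downstream
  statistic is defined on biallelic SNPs. Records with unphased or missing
  genotypes are likewise skipped and counted.
- Coordinates are 1-based inclusive internally (the VCF convention). BED
  input (0-based half-open) is converted at the reader boundary.
- Ancestral states are attached from an id → base annotation with
  case-insensitive matching; a base matching neither allele yields
  `unknown`. Unpolarized variants are kept but excluded from
  derived-allele-frequency and iHS analyses rather than imputed.

## Locus-specific and gene-level F_ST

Locus F_ST uses the Weir–Cockerham variance-component estimator applied to
haploid samples. Because the data model is fully phased, each diploid
contributes two haploid observations and the heterozygosity-correction
terms of the diploid estimator vanish. The estimator is unbiased but not
range-restricted: monomorphic loci have undefined θ̂ (returned as NaN) and
slightly negative estimates occur at weakly differentiated loci; they are
reported as-is. An optional clamp-at-zero is available for summaries but is
off by default, since clamping biases multi-locus averages upward.

Gene-level WA-F_ST is the ratio of sums Σa/Σ(a+b) over the gene's loci with
positive total variance — the standard multi-locus weighting in which each
locus contributes in proportion to its total variance. A mean-of-ratios
variant exists for sensitivity analysis; it weights noisy low-variance loci
equally and is not the default.

Either the populations or the continental groups can serve as demes; the
default is populations (the finer grouping).

**Empirical cutoffs.** The top-q cutoff of a genome-wide vector of θ̂ is the
smallest value of the top ⌈qn⌉ order statistics (inverse-CDF, type-1
quantile), computed after dropping undefined values. This convention is an
exact order statistic, reproducible without interpolation ambiguity; on
`1..100` with q = 0.05 it returns 96.

**AMOVA.** The simplified AMOVA partitions squared pairwise distances
between haplotypes into among-group, among-population-within-group and
within-population sums of squares, converts them to variance components with
the standard unequal-sample-size coefficients, and reports Φ_CT, Φ_SC and
Φ_ST. The distance is the Hamming count over the gene's SNPs — the default
choice for SNP haplotypes when no mutation model is imposed. The p-value
for the among-group component permutes whole populations across groups
(add-one convention). With zero total variance all components are zero and
the Φ statistics are undefined.

## Gene-set permutation enrichment

Random gene sets of the candidate size are drawn uniformly without
replacement from the gene universe; by default the candidates themselves are
not excluded from the universe (an `exclude_candidates` option covers the
alternative). Replicates whose statistic is undefined — for example a set
with no high-F_ST loci in the denominator — are redrawn and counted, so the
null vector always has exactly `n_perm` entries and a fixed seed reproduces
it bit for bit.

Two p-value conventions are reported side by side: the plain tail index
`#{null ≥ obs}/n_perm`, and the add-one convention
`(#{null ≥ obs}+1)/(n_perm+1)`, which cannot be zero and is the default
output. Ties count toward the tail in both. A practical consequence,
verified in the calibration tests: with a continuous set statistic the
add-one p-value is uniform on its lattice under the null, while with a
coarsely discrete statistic (a proportion over few loci) ties between
observed and null replicates make it conservative. The calibration check
therefore uses the mean locus θ̂ — continuous, hence tie-free — as its set
statistic.

The "African-high" DAF pattern used by the nSNP enrichment test is
operationalized as: derived-allele frequency below `low_thr` (default 0.05)
in every non-African reference population and at least `high_thr` (default
0.05, i.e. merely "not low") in the African reference. Only the low-side
constraint is explicit in the motivating analyses; the high-side default is
deliberately conservative and configurable.

## EHH, iHH and iHS

EHH around a core allele at distance x is the probability that two randomly
chosen carrier haplotypes are identical over the interval from the core to
x. It is computed by refining haplotype groups SNP by SNP outward, so it is
exactly non-increasing with distance. Extension stops when EHH falls below
a cutoff (default 0.05), at the chromosome edge, or at an inter-SNP gap
larger than `max_gap_bp` (default 200 kb).

iHH is the trapezoidal integral of EHH against physical position (no
genetic map is assumed; a per-bp map can be supplied by transforming
positions), summed over both directions, integrating EHH itself from the
core to the truncation point. A baseline-subtraction variant
(`baseline=cutoff`) is available. SNPs whose extension hits an edge or a
gap on either side for either core allele are excluded from standardization:
their integrals are truncated by the window, not by haplotype decay, and
would deflate the score.

The unstandardized score is `u = ln(iHH_A/iHH_D)`. Scores are standardized
to zero mean and unit variance (population SD) within 20 equal-width
derived-allele-frequency bins; bins with fewer than 10 SNPs are merged into
the nearest occupied neighbour. Only SNPs with minor allele frequency
strictly above 0.05 and a known ancestral state are scored. The sign
convention follows the definition: a sweep on the derived allele elongates
derived-core haplotypes, inflates iHH_D and drives iHS strongly negative;
large positive scores indicate hitchhiking of the ancestral allele.

**Sweep calling.** The genome-wide significance cutoff is the empirical
top-5% of |iHS| over all scored SNPs of the analyzed genome, shared across
genes. A gene is flagged when any window of 50 consecutive scored SNPs
contains at least 7 significant loci; genes with fewer than 50 scored SNPs
are evaluated as one window. Note the rule's false-positive rate grows with
the number of scored SNPs per gene — with ~300 scored SNPs even independent
5%-rate hits produce a qualifying window in roughly one gene in five — so
cross-gene comparisons should hold scored-SNP counts roughly comparable.

## Haplotype spectra and environment regression

Haplotype spectra render each haplotype as its REF/ALT base letters over an
ordered SNP subset (a 0/1 rendering exists for synthetic data without base
semantics) and tabulate per-population counts and frequencies. The
environment regression is ordinary least squares of the covariate on the
haplotype frequency; R², the slope and its two-sided t-test p-value
(n−2 df) are reported. Populations present in only one of the two tables
are dropped with a warning; at least three shared populations are required,
and R² equals the squared Pearson correlation, so it is symmetric in the
two variables.

## Synthetic-data generators

**Structure.** The Balding–Nichols generator draws, per locus, an ancestral
frequency p uniformly within bounds (default 0.05–0.95) and each
population's frequency from Beta(p(1−F)/F, (1−p)(1−F)/F), then samples
haplotype alleles independently. F = 0 degenerates to copying p exactly.
The ancestral allele is REF by construction, so matrices are fully
polarized and the truth record stores the ancestral frequencies. This
generator emulates allele-frequency divergence only: loci are exchangeable
and there is **no linkage disequilibrium**, so it supports F_ST, DAF,
enrichment and AMOVA testing but not haplotype-length statistics. With the
default study conditions (2 populations × 200 haplotypes, 5000 loci,
F = 0.1) the genome-wide ratio-of-sums θ̂ recovers F within ±0.02.

**Sweeps.** The sweep generator runs a discrete-generation haploid
Wright–Fisher population with single-crossover recombination over a finite
region. Standing variation comes from a founder pool (no new mutation
during the run); after a neutral burn-in that builds haplotype sharing, a
single beneficial mutant (multiplicative fitness 1+s) is introduced at the
central locus and the run continues until its frequency reaches the target,
after which haplotypes are sampled without replacement. If the mutant is
lost, the sweep phase restarts from the saved post-burn-in state with a
sub-seed derived as `default_rng([seed, attempt])`, keeping runs
reproducible. Neutral panels use s = 0.

Default conditions: sample 200 haplotypes from N = 16,000; 100 SNPs over a
3 Mb region; r = 2×10⁻⁸ crossovers/bp/generation (the human genome-wide
average is ≈1×10⁻⁸); 3200 founders; 300 burn-in generations; s = 0.05 with
target focal frequency 0.7. The population and founder-pool sizes are
deliberately large relative to the burn-in: in smaller or more drifted
regimes, identical-by-descent founder cliques put a floor on EHH above the
0.05 truncation cutoff (invalidating SNPs wholesale) and act as
pseudo-sweeps that inflate the neutral false-flag rate of the window rule.
The chosen regime keeps the neutral IBD plateau well below the EHH cutoff
while the sweep's star-shaped genealogy still spans several hundred kb.
What this generator does **not** emulate: new mutation, gene conversion,
variable recombination maps, demographic change, and the deep (≫ burn-in)
coalescent tail of real genealogies; absolute iHH magnitudes are therefore
not comparable to real data even though the standardized iHS contrast is.

`simulate_sweep_panel` concatenates independent gene runs (each its own
chromosome) into a small scan genome: by default 20 neutral genes plus one
swept gene, sharing one sample panel. Positions are drawn uniformly and
deduplicated so EHH gap handling is exercised.

All generators are pure functions of (config, seed); fixture bundles (VCF,
panel TSV, gene BED, ancestral TSV, truth JSON with seed and config hash)
round-trip exactly through the package readers.

## Validation experiments and problem sizes

The test suite and `scripts/acceptance.py` run the following studies, sized
to complete in well under a minute each on one CPU:

1. **F_ST exact oracle** — every two-population configuration with
   n₁, n₂ ≤ 10 against exact rational arithmetic (agreement to 1e−12).
2. **Balding–Nichols recovery** — F = 0.1, 2 × 200 haplotypes, 5000 loci;
   genome-wide θ̂ within [0.08, 0.12].
3. **iHS standardization** — ≥1000 scored neutral SNPs from the sweep-panel
   generator; every occupied DAF bin has |mean| < 0.05 and SD within
   [0.95, 1.05] (exact up to floating point by construction, so this checks
   the scan produces enough valid SNPs and bins are occupied).
4. **Sweep detection** — one swept gene (s = 0.05, focal frequency ≈ 0.7,
   200 haplotypes) among 20 neutral genes; the swept gene must be flagged
   with a negative focal iHS and at most 2 neutral genes flagged, at the
   genome-wide top-5% |iHS| cutoff.
5. **Permutation calibration** — 500 random candidate draws give add-one
   p-values consistent with Uniform(0,1) (KS p > 0.01), and the Monte-Carlo
   p matches an exhaustive enumeration over all two-gene subsets of a
   six-gene toy universe.
6. **Window-rule oracle** — 1000 random significance patterns (lengths
   10–300, 0–20 hits) against brute-force window enumeration.
7. **Worked regression** — the three-population haplotype-frequency /
   zinc-deficiency example against closed-form OLS in exact arithmetic.

## Known limitations

- The haploid treatment assumes phasing is exact; phasing errors in real
  data would deflate EHH and are not modelled.
- The AMOVA is the Hamming-distance special case; arbitrary distance
  matrices and within-individual components are out of scope.
- Gene-length- or SNP-density-matched null gene sets are not implemented;
  random same-size sets follow the motivating analysis design.
- The window sweep rule's sensitivity to scored-SNP density (see above) is
  inherited from its definition; per-gene scored counts are reported so
  users can judge comparability.
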