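# Methods

## Model and procedure

At a heterozygous biallelic SNP covered by `n = ref_count + alt_count`
ATAC-seq reads, the null hypothesis of equal allelic accessibility is
that the alternative-allele read count is Binomial(n, 0.5). The test
statistic is the exact two-sided tail doubling

    p = P(X ≤ k) + P(X ≥ n − k),  k = min(ref_count, alt_count),

clamped to 1. For Binomial(n, 0.5) the pmf is symmetric, so this
coincides with the "sum of outcomes with pmf ≤ observed" definition;
implementing the rule explicitly removes any dependence on a particular
library's tie handling (the equality with `scipy.stats.binomtest` is
asserted in the tests). Tail sums are computed from exact cdf/sf
evaluations — no normal approximation — and are never reported as 0, so
−log transforms stay finite.

Benjamini–Hochberg adjustment (step-up, q_(i) = min_{j≥i} p_(j)·n/j,
clamped to 1, ties preserved) is computed **per cell type over exactly
the set of SNPs being tested** — the qualified SNPs inside cleaned
peaks — never pooled across cell types. The call rule is strict:
`is_asoc ⇔ q < 0.05`. Strictness at the boundary is a documented
convention; it is the conservative reading of an FDR threshold "at"
0.05.

One count pair per SNP per cell type is tested (a merged pileup across
donors); no haplotype-level aggregation across SNPs is attempted.

### Qualification filters

Retained SNPs are heterozygous (0/1, phased 0|1 accepted), autosomal
(chrX/Y/MT and any non-canonical/decoy contig excluded; `chr1`/`1`
dialects are normalized), present in dbSNP (an input flag, not a live
lookup), with depth ≥ 20 and both allele counts ≥ 2. DP is defined as
`ref_count + alt_count`, not the aligner's total over all bases,
because the binomial test consumes exactly these two counts; if your
upstream DP includes other bases, re-derive it from the allelic depths.
Each rejected SNP is charged to the first failing rule in the fixed
order genotype → chromosome → dbSNP → depth → allele count, making the
filter report deterministic; the accounting identity
`n_input = n_pass + Σ rejections` always holds.

### Genomic context

Intervals are half-open zero-based; SNP positions 1-based (a SNP at p
is inside [s, e) iff s ≤ p−1 < e). Peaks overlapping a blacklist
interval by ≥ 1 bp are dropped whole, never trimmed, keeping peak
identity stable. TSS distance is a strand-agnostic point distance to
the nearest TSS on the same chromosome; bins are promoter-proximal
(≤ 5 kb, inclusive), distal (> 50 kb, strict), intermediate otherwise.
The boundary inclusivity is a configurable convention. Nested-peak
assignment takes the first containing peak in (chrom, start, end) sort
order.

### GWAS integration

A locus is a row of the index-SNP table; proxies come solely from the
LD table (symmetrized on load, best r² per pair), with the inclusive
threshold r² ≥ 0.8 — no window heuristic is applied, and an index SNP
missing from the LD table keeps a singleton proxy set with a warning. A
locus is hit when ≥ 1 proxy-set member is an ASoC SNP; a SNP proxying
several loci is reported under each. Target genes come from a
point-in-interval join of SNP positions against ABC enhancer–gene
links; multiple links give multiple rows.

`set_enrichment` is transparent plumbing: fold =
(|A∩B|/|A|)/(|B|/|U|) with a one-sided Fisher exact p, or a permutation
p from resampling |A|-sized sets (the overlap of a uniform resample is
exactly hypergeometric, which is how the permutation is vectorized; the
+1-smoothed estimator keeps p > 0). It is **not** a heritability- or
LD-aware enrichment model, and its folds are not comparable to
hierarchical-model enrichments computed on real GWAS data.

## The synthetic-data generator

The generator emulates the data the analysis consumes, not the assay:

- depth ~ 20 + Poisson(40) by default (mean 60). The shift guarantees
  every SNP clears the DP ≥ 20 filter, so filter behaviour and test
  power can be probed independently; lower the shift to exercise the
  depth filter. This default is a plausible stand-in for deep ATAC-seq
  libraries, not a fit to any empirical depth distribution.
- alt_count ~ BetaBinomial(n, θ, ρ) with shapes a = θ(1−ρ)/ρ,
  b = (1−θ)(1−ρ)/ρ; ρ = 0 is pure binomial. θ = 0.5 for null SNPs; a
  planted fraction π_asoc of SNPs gets θ = θ_asoc (scalar or uniform
  interval; θ = 1 is allowed and stays degenerate).
- reference bias is multiplicative capture bias: effective
  θ′ = θ/(θ + (1−θ)·b_ref), the logit-shift model; b_ref = 1 recovers θ.
- annotation: disjoint fixed-width peaks apportioned to chromosomes by
  length; a stated fraction receives a blacklist interval planted
  strictly inside the peak, so planted overlap counts are exact. TSS
  positions are uniform.
- GWAS/LD: loci with index SNPs and a stated number of proxies, r²
  drawn from a constant or uniform interval (LD is drawn, not derived
  from haplotypes).
- a single seeded `numpy` Generator threads through all draws;
  identical (config, seed) gives byte-identical outputs.

`simulate_study` additionally plants coincidences for end-to-end
recovery: GWAS proxies and ABC enhancers are placed on simulated SNPs
whose **emitted** counts pass the qualification filters, survive
blacklist cleaning, and satisfy the Bonferroni-level bound
p·n_snps < 0.05 — which implies a BH discovery at FDR 0.05 regardless
of the rest of the p-value distribution. This makes recovery of the
planted loci and SNP→gene assignments exact and deterministic rather
than probabilistic. Planted enhancers are clipped between neighbouring
SNP positions (and background enhancers avoid all SNPs), so the planted
assignments are the only ones.

### What passing tests do and do not show

The simulator reproduces the count-level statistical structure: null
symmetry, overdispersion, reference bias, peak placement, LD-proxy
bookkeeping. It does not simulate reads, alignment, mapping bias at the
read level, genotyping error, donor structure, or correlated SNPs in
LD. Calibration results on synthetic data therefore validate the
inference machinery, not the upstream processing of real libraries:
with ρ > 0 the plain binomial test is anti-conservative (the acceptance
FDR bound is stated at ρ = 0, and a ρ = 0.01 run is checked for
precision/recall rather than nominal calibration), and real data
quality hinges on upstream bias correction that is out of scope here.

## Numerical and design choices

- Allelic ratio is reported as ref_count/depth (volcano-plot
  convention); the QC flag fires when the pooled mean ratio deviates
  from 0.5 by > 0.02 (default margin, configurable).
- Degenerate inputs: depth-0 SNPs are a contract violation for the
  caller (filter upstream); empty tables flow through every operation;
  an empty locus table yields an undefined (null) hit fraction rather
  than 0.
- BH on an empty vector returns an empty vector; p ∉ (0, 1] is a
  validation error.
- Problem sizes in the test and acceptance runs (20,000 SNPs, 50 seeds
  for FDR calibration, 5,000 SNPs per power-grid cell) were chosen so
  Monte-Carlo standard errors are small relative to the margins being
  checked.

## Known limitations

- The binomial test ignores overdispersion by design; ρ in the
  simulator exists to probe robustness, not to be fitted. A
  beta-binomial test is deliberately out of scope.
- θ recovered from called true positives is upward-biased at moderate
  depth (winner's curse); the selection-bias check is run at depth 200
  where the bias is < 0.01.
- LD r² values are sampled, not derived from population haplotypes, so
  proxy sets have no genomic correlation structure.
- `set_enrichment` folds are not comparable to TORUS/sLDSC-style
  enrichment estimates.
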