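# asoc — allele-specific open chromatin mapping

`asoc` identifies regulatory variants that change chromatin accessibility.
At a heterozygous SNP inside an ATAC-seq peak, reads carrying the two
alleles should be sampled equally; a variant that alters accessibility on
one haplotype skews that ratio. The package tests this allelic imbalance
(ASoC: allele-specific open chromatin), restricts it to open chromatin,
and links the resulting functional SNPs to GWAS risk loci and target
genes. It is aimed at regulatory-genomics analysts working with
heterozygous-SNP allelic read counts from ATAC-seq (e.g. iPSC-derived
microglia, astrocytes or neurons), and ships a seeded synthetic-data
generator so every step can be validated against planted ground truth.

## The statistical core

For a SNP with `ref_count = x_r`, `alt_count = x_a`, depth `n = x_r + x_a`,
the null of equal allelic accessibility is tested with the exact two-sided
binomial test

    p = P(X ≤ k) + P(X ≥ n − k),   k = min(x_r, x_a),   X ~ Binomial(n, ½),

clamped to 1 (no normal approximation; for a symmetric pmf this equals the
"sum of outcomes no more likely than the observed" convention). p-values
across all qualified SNPs of one cell type are adjusted with the
Benjamini–Hochberg step-up procedure, and SNPs with q < 0.05 are called
ASoC. Qualification filters follow the standard protocol: biallelic
heterozygous genotype (0/1), autosomes only, dbSNP membership,
DP = x_r + x_a ≥ 20, and both allele counts ≥ 2.

Downstream, ASoC SNPs are intersected with GWAS risk loci expanded to
their LD proxies (r² ≥ 0.8) and assigned target genes by point-in-interval
joins against activity-by-contact (ABC) enhancer–gene links.

The simulator draws alternative-allele counts from a beta-binomial with
mean θ and overdispersion ρ (shapes a = θ(1−ρ)/ρ, b = (1−θ)(1−ρ)/ρ;
ρ → 0 is pure binomial), plants a fraction π of true-ASoC SNPs with
θ ≠ 0.5, and can inject multiplicative reference-mapping bias
θ′ = θ / (θ + (1−θ)·b_ref).

## Worked example

```python
import asoc

cfg = asoc.SimConfig(n_snps=5000, pi_asoc=0.1, theta_asoc=0.75, seed=42)
study = asoc.simulate_study(cfg, n_loci=10, n_planted_loci=3, n_planted_abc=4)
res = asoc.run_pipeline(study.counts, peaks=study.peaks, blacklist=study.blacklist,
                        tss=study.tss, gwas=study.gwas, ld=study.ld, abc=study.abc)
print("qualified SNPs:", res.filter_report.n_pass, "of", res.filter_report.n_input)
print("tested in open chromatin:", len(res.results))
print("ASoC calls (FDR < 0.05):", len(res.asoc))
truth = study.truth.set_index("snp_id")["is_asoc"]
print("empirical FDR:", round(float((~truth.loc[res.asoc['snp_id']]).mean()), 3))
print("pooled allelic ratio:", round(res.qc.pooled_mean_ratio, 3))
print("GWAS loci hit:", res.coloc.n_loci_with_asoc, "of", res.coloc.n_loci_total)
print(res.target_genes.to_string(index=False))
```

prints

```
qualified SNPs: 5000 of 5000
tested in open chromatin: 4752
ASoC calls (FDR < 0.05): 412
empirical FDR: 0.022
pooled allelic ratio: 0.473
GWAS loci hit: 3 of 10
    snp_id   target_gene  abc_score
snp0000006 targetgene003     0.1843
snp0001330 targetgene002     0.3964
snp0002012 targetgene000     0.1329
snp0003937 targetgene001     0.3918
```

All 5000 simulated SNPs pass qualification (the default depth model is
20 + Poisson(40), so DP ≥ 20 always holds); 4752 fall inside cleaned
peaks. Of those, 412 are called ASoC, with an empirical false-discovery
proportion of 0.022 against the planted truth — inside the nominal 0.05.
The pooled allelic ratio of 0.473 reflects the planted 10% of SNPs with
alternative-allele fraction 0.75 (0.9·0.5 + 0.1·0.25), not reference
bias. The three GWAS loci whose proxy sets were planted on detectable
ASoC SNPs are recovered exactly, as are the four planted enhancer–gene
assignments.

A CLI mirrors the library: `asoc sim counts|annot|gwas`, `asoc filter`,
`asoc call`, `asoc qc`, `asoc context`, `asoc coloc`, `asoc enrich`,
`asoc share`. Try `asoc --help`.

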