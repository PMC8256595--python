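# sunlipid

Seed-oil lipidome annotation and mixed-linear-model GWAS for panels of
inbred oilseed (sunflower-type) lines.

Breeding for oil quality needs two things joined up: quantitative lipid
phenotypes — which fatty acids (FAs) and triacylglycerides (TAGs) a seed
contains, and in what relative amounts — and the genetic variants that
control them. `sunlipid` implements the full desk-side pipeline between a
UPLC-MS peak list plus a genotype VCF on one end and candidate genes on the
other:

1. **Lipid annotation** (`sunlipid.lipids`) — blank-sample filtering,
   enumeration of FA (C10:0–C28:0, ≤6 double bonds) and TAG (30–85 total
   acyl carbons, 0–12 double bonds) sum compositions, exact-mass adduct
   matching ([M−H]⁻ for FAs; [M+H]⁺, [M+Na]⁺, [M+K]⁺, [M+NH₄]⁺ for TAGs) at
   a ppm tolerance with ppm = |m₁−m₂| / max(m₁,m₂) × 10⁶, an automated
   retention-time "net pattern" filter, category annotation against a lipid
   database, and per-class normalization to relative abundances (% of class
   total per sample).
2. **Replication ANOVA** (`sunlipid.anova`) — per-lipid two-way
   fixed-effects partitioning, `abundance ~ line + year + line:year`, with
   BH correction, variance-component fractions, and a classical MDS summary
   on 1 − Spearman-ρ distances between sample profiles.
3. **Population genetics** (`sunlipid.popgen`) — genotype QC (depth
   masking DP > 4, missingness < 0.3, MAF filters), centered-IBS kinship
   K = WWᵀ / (2Σpⱼ(1−pⱼ)), PCA on dosages, LD r² vs distance with a
   smoothed decay curve and half-decay distance, confidence-interval
   haplotype blocks (two-locus EM for D′ on unphased dosages), Nei's
   standard genetic distance, and a permutation test of genotyping
   concordance across platforms.
4. **Mixed-model GWAS** (`sunlipid.gwas`) — the single-locus MLM
   Y = SNP + PCs + covariates + u + e with u ~ N(0, σ²g K): REML variance
   components estimated once per trait on the eigendecomposition of K and
   held fixed for the per-SNP generalized-least-squares scan (P3D), an
   LD-block Bonferroni threshold (α / number of blocks, e.g.
   0.05/5000 = 10⁻⁵), QQ/Manhattan tables with the genomic-inflation
   factor λ, and joint variance-explained estimation for SNP sets.
5. **Enrichment** (`sunlipid.enrichment`) — gene–block interval overlap
   and a one-sided Fisher exact test for pathway-gene enrichment.
6. **Synthetic data** (`sunlipid.synthetic`) — generators with known
   ground truth for all of the above: structured genotypes with local LD,
   planted QTL, replicated line×year traits with chosen variance
   fractions, and MS peak tables with adduct multiplicity, ppm mass error
   and contaminants. Every estimator in the package is validated by
   recovering what these generators plant.

## Worked example

```python
import numpy as np
from sunlipid import (SimConfig, simulate_genotypes, simulate_phenotypes,
                      simulate_peak_table, annotate_peaks,
                      kinship_centered_ibs, pca_genotypes, fit_null_model,
                      association_scan, build_design, fisher_enrichment,
                      block_bonferroni_threshold)

# printed-count enrichment: 44,144 annotated genes, 429 in the oil
# pathway, 124 inside significant LD blocks, 4 in both
odds, p = fisher_enrichment(44_144, 429, 124, 4)
print(f"enrichment: OR={odds:.2f}, one-sided p={p:.3f}")
print(f"threshold: {block_bonferroni_threshold(5000, 0.05):.0e}")

cfg = SimConfig(n_lines=300, n_snps=1000, n_chroms=5,
                qtl_spec=[(500, "oleic_pct", 0.45)], h2=0.5, seed=11)
geno = simulate_genotypes(cfg)
peaks, truth = simulate_peak_table(cfg)
species = annotate_peaks(peaks)
print(f"annotated {len(species)} of {len(peaks)} peaks "
      f"({(species.lipid_class == 'TAG').sum()} TAGs, "
      f"{(species.lipid_class == 'FA').sum()} FAs)")

traits, _ = simulate_phenotypes(geno, cfg)
kinship = kinship_centered_ibs(geno)
pcs, _ = pca_genotypes(geno, n_pcs=3)
X = build_design(traits, pcs=pcs, factors=("collection", "batch"),
                 continuous=("weight", "istd"))
y = traits["oleic_pct"].to_numpy()
null = fit_null_model(y, X, kinship)
print(f"null model: h2 = {null.h2:.2f}")
scan = association_scan(geno, y, X, null_model=null, min_maf=0.01)
top = scan.loc[scan["p"].idxmin()]
print(f"top SNP: {top.chrom}:{top.pos}  beta={top.beta:.2f}  p={top.p:.2e}")
print(f"planted QTL: {geno.chrom[500]}:{geno.pos[500]}")
```

prints

```
enrichment: OR=3.42, one-sided p=0.033
threshold: 1e-05
annotated 195 of 245 peaks (168 TAGs, 27 FAs)
null model: h2 = 0.49
top SNP: chr3:18534679  beta=0.62  p=5.53e-09
planted QTL: chr3:18534679
```

The enrichment odds ratio says oil-pathway genes are ~3.4× over-represented
among genes inside trait-associated LD blocks. The annotation step finds
every true species (the 50 unannotated peaks are the planted contaminants),
the REML null model recovers the planted heritability of 0.5, and the scan's
strongest association is exactly the planted QTL, far below the 10⁻⁵
block-Bonferroni threshold.

A command-line interface mirrors the library:
`sunlipid simulate | annotate | anova | kinship | ld | blocks | gwas | enrich`
(see `sunlipid --help`).

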