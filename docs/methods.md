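# Methods

This note documents the models implemented in `sunlipid`, the defaults and
the reasoning behind them, what the synthetic-data generators do and do not
emulate, and the numerical choices that matter for reproducing results.

## Lipid annotation

**Enumeration.** Fatty acids are enumerated over chain lengths 10–28 with
0–6 double bonds (133 species, formula C_c H_{2c−2d} O₂); triacylglycerides
over 30–85 total acyl carbons with 0–12 double bonds (728 species, formula
C_{c+3} H_{2c−2d+2} O₆ — glycerol plus three acyls minus three waters).
The double-bond grid is not pruned for chemical feasibility: an exhaustive
grid costs nothing and guarantees no true species is excluded a priori.
Isomers (sn-position, acyl-chain split) are never resolved; exact mass
cannot distinguish them, so a species is a *sum composition* N:D.

**Masses and adducts.** Monoisotopic masses use fixed constants
(C 12, H 1.007825032, O 15.994914620, N 14.003074004 Da). Adduct m/z values
are ion masses — the electron mass is included, so a proton is
1.007276 Da — with shifts −H −1.007276, +H +1.007276, +Na +22.989218,
+K +38.963158, +NH₄ +18.033823. All ions are singly charged. FAs ionize as
[M−H]⁻ in negative mode only; TAGs as the four positive adducts. The ppm
comparison uses the ion m/z for both arguments (the neutral-mass convention
differs by well under 1 ppm; one convention had to be fixed).

**Blank rule.** A peak is kept when its mean intensity across biological
samples is *strictly* greater than twice its blank intensity, i.e.
log2(sample/blank) > 1. The aggregate (mean vs median) and the factor are
configurable; the strict boundary is the one applied throughout.

**Grid filter.** Members of a homologous lipid series fall on a near-planar
surface RT ≈ a + b·carbons + c·double_bonds, and all adducts of one species
co-elute. The filter therefore fits a single robust plane (Huber RLM) per
lipid class and flags matches whose |residual| exceeds k = 3.5 times a
robust residual scale. Two details are load-bearing:

- *Anchors.* The plane is fitted only to matches whose peak has exactly one
  candidate interpretation. The TAG grid contains a genuine cross-adduct
  mass alias — [TAG(c,d)+Na]⁺ and [TAG(c+2,d+3)+H]⁺ differ by ≈2.4 mDa
  (<3 ppm) — so at realistic mass accuracy most sodiated TAGs dual-match
  and would contaminate a naively fitted plane with a parallel cluster. The
  unambiguous ammoniated/potassiated ions (and low-saturation protonated
  species) pin the plane; the aliased interpretations then sit several
  noise SDs off it and are rejected.
- *Scale.* The cut uses Huber's proposal-2 scale floored by the
  normal-consistent MAD and inflated by √(n/(n−3)) for the fitted
  parameters. The raw MAD of ≤9-point robust fits under-estimates badly
  enough to reject a few percent of true peaks.

Classes with fewer than 5 matches, or a degenerate design (a single chain
length), pass through unfiltered with a warning.

**Multi-match resolution.** Among a peak's grid-passing matches the lowest
ppm wins; ties break toward fewer double bonds, then fewer carbons (the
chemically simpler assignment). Peaks with no grid-passing match stay
unannotated.

**Normalization.** Within each sample, species intensities are divided by
the class total and multiplied by 100, so FA and TAG abundances each sum to
100 per sample. Tables measured at different extract dilutions are treated
as separate tables end to end.

## Replication ANOVA

The model is `abundance ~ line + year + line:year`, fixed effects,
sequential (Type I) sums of squares in that order; Type II is available via
an argument. The design this targets is near-balanced (a handful of lines ×
3 years × ~5 replicates, occasionally one lost sample), where the SS-type
choice is immaterial; unbalanced cells are handled by least squares on the
full factorial design matrix, with no imputation.

Reported per term: F, p, the SS fraction of the total, the per-degree-of-
freedom fraction, and a method-of-moments variance-component fraction from
the expected mean squares (σ̂²ₑ = MS_E; σ̂²_gxe = (MS_GxE − MS_E)/k̄;
σ̂²_line = (MS_line − MS_GxE)/(J·k̄), analogously for year; negative
estimates truncated to zero and fractions renormalized). The EMS fractions
are the quantities to compare against planted simulation fractions: raw SS
fractions are biased for small designs (expected line-SS fraction ≈ 0.69
when the planted fraction is 0.8 in a 6×3×5 design), which is a property of
sums of squares, not an estimation error.

Multiple testing across lipids uses Benjamini–Hochberg. The MDS summary is
classical (Torgerson) scaling of D = 1 − Spearman ρ between sample
profiles; SMACOF-style iterative MDS is deliberately not used because the
duplicated-sample and rank-reversal identities (distance 0 and 2) should
hold exactly. Negative eigenvalues (1 − ρ is not Euclidean) are truncated
at zero.

## Genotype QC and population structure

Filtering order matters and is fixed: calls with DP ≤ 4 are masked to
missing first; then SNPs with missing fraction ≥ 0.3 or MAF ≤ the threshold
are dropped. All boundaries are strict (DP > 4, MAF > 0.01 or > 0.03
retained). Re-running the filter is idempotent.

Kinship is the centered-IBS genomic relationship matrix
K = WWᵀ / (2Σⱼ pⱼ(1−pⱼ)) with W the dosage matrix centered at 2pⱼ and
missing dosages mean-imputed (mean imputation preserves allele frequency
and is the standard choice for cross-product estimators). Centering at
sample frequencies makes ΣK = 0 exactly, so the off-diagonal mean for
unrelated panels is −1/n rather than 0 — an identity, not a bias to fix.
PCA runs on the same mean-imputed, centered dosages.

**LD.** r² is the squared Pearson correlation of dosages over jointly
called samples, for intra-chromosomal pairs within 5 Mb, after re-filtering
(MAF > 0.03, DP > 4, called in ≥ 60% of samples). The decay curve is a
lowess smooth of r² against distance (span 0.3, with a delta shortcut at
0.5% of the distance range for speed); the half-decay distance is the
smallest distance where the smoothed curve falls to half its maximum, and
"not reached" (None) when it never does.

**Haplotype blocks.** GBS genotypes are unphased, so D′ per SNP pair is
estimated by two-locus haplotype EM over the 3×3 dosage table (only the
double heterozygote is phase-ambiguous). The 90% interval for |D′| comes
from the normalized likelihood over a 101-point grid with allele
frequencies fixed at their estimates. A pair is in strong LD when the
interval is [≥0.70, ≥0.98], and shows strong recombination when its upper
bound is < 0.90. Any interval of ≥2 SNPs whose informative pairs are ≥95%
strong-LD is a candidate block; candidates are accepted greedily, longest
bp span first, without overlap. Block coordinates are 1-based inclusive and
the printed length in kb is floor(span/1000).

The genome-wide significance threshold is α divided by the number of LD
blocks; the default uses 5000 blocks with α = 0.05, i.e. 10⁻⁵, and a block
count from an actual per-chromosome scan can be substituted.

**Nei distance.** Each line is treated as a one-individual population with
per-locus allele frequencies (x, 1−x), x = dosage/2. D = −ln I with
I = Σ(xy + (1−x)(1−y)) / √(Σ(x²+(1−x)²) · Σ(y²+(1−y)²)) over jointly
called loci. Disjoint profiles (I = 0) are flagged with ∞. 1 − IBS is
available as an alternative.

**Concordance.** Cross-platform agreement per SNP is the fraction of
identical calls over jointly called lines; significance comes from
permuting one platform's line labels, p = (1 + #{permuted ≥ observed}) /
(n_perm + 1), BH-adjusted across SNPs. With ties (few lines, few genotype
classes) the permutation p is conservative, which calibration tests must
account for.

## Mixed-model GWAS

Per trait, samples missing ≥10% of phenotype values are excluded. The model
is y = Xβ + g·b + u + e with u ~ N(0, σ²g K). Variance components are
estimated once under the null (no SNP) by REML, maximizing over
δ = σ²e/σ²g on the eigendecomposition K = USUᵀ (bounded scalar search on
log δ ∈ [−10, 10], with endpoint checks), and then held fixed for every SNP
— the P3D approximation that makes a scan one weighted regression per SNP
in the rotated space. Reported heritability is σ²g·mean(diag K) /
(σ²g·mean(diag K) + σ²e), since this K's diagonal is not normalized to 1.

The SNP test is a two-sided Wald t-test on the dosage coefficient, with the
residual variance re-estimated per SNP. SNPs with missing calls drop those
samples and solve the GLS exactly on the called subset (Cholesky whitening
with the fixed variance components); no genotype imputation is done in
testing. The default fixed effects are 3 genotype PCs plus any collection/
batch factors and weight/internal-standard covariates supplied. Three PCs
is a pragmatic default for a panel drawn from a few collections; the count
is an argument.

Known behavior worth stating: with the causal marker itself (and its LD
neighbors) inside K, part of a planted QTL's signal is absorbed by the
random effect, so observed power is slightly below the naive fixed-effects
prediction — the classic proximal-contamination effect. At the study scale
used in the tests (a QTL explaining 10% of variance, n = 500) detection at
the 10⁻⁵ threshold still succeeds in ≈19/20 simulations.

λ (genomic inflation) is median(χ²_obs)/χ²₀.₅,₁. Under a trait driven
purely by subpopulation, a naive OLS scan inflates to λ > 5 at F_ST = 0.3
while PCs + kinship hold λ within [0.9, 1.1].

Variance explained by a SNP set is the incremental R² of an ordinary
linear model: R²(covariates + SNPs) − R²(covariates), in percent, on
complete cases.

## Enrichment

Genes overlap a block when their 1-based inclusive intervals share ≥1 bp
(a flank argument widens blocks; default 0). The 2×2 table for a pathway
list is a = overlap, b = blocks-only, c = pathway-only, d = remainder; the
odds ratio reported is the sample odds ratio ad/bc and the p-value is the
one-sided (enrichment) hypergeometric tail, matching the directional
question asked of such tables.

## Synthetic data: what it emulates, and what it does not

Defaults mirror the study design this package targets: 543 lines genotyped
at ~15k SNPs on 17 chromosomes from three collections, LD decaying on a
0.7 Mb scale, genotype-dominated lipid variance with a small
line×year interaction (fractions 0.6/0.05/0.05 by default), a replication
experiment of 6 lines × 3 years × 5 replicates with one lost data point,
and peak tables from 27 FA and 42 TAG species with the four major FAs and
the C52/C54 TAGs carrying most intensity.

- **Genotypes.** Subpopulation frequencies follow a Balding–Nichols model
  at F_ST = 0.1; along each chromosome a haplotype copies its previous-SNP
  state with probability exp(−d/L), L = `ld_decay_bp`, else draws fresh
  from its subpopulation frequency. This one-parameter copying process
  gives allele correlation ≈ exp(−d/L) (so r² ≈ exp(−2d/L)) — a tunable
  decay scale that the LD stage must recover, not a coalescent model: no
  recombination hotspots, no allele-frequency spectrum realism, no
  inbreeding (dosages are Hardy–Weinberg). Depth is negative-binomial
  (mean 20, shape 5); missingness is completely at random, so the DP and
  missingness filters are exercised without sequencing being modeled.
- **Phenotypes.** Trait variance is budgeted to 1: planted QTL effects (in
  trait SD per standardized allele) contribute their squared sum, a
  polygenic term with covariance ∝ K fills the genetic fraction up to h²,
  iid noise supplies the rest; realized sample variances are scaled
  exactly. Covariates (collection, batch, seed weight, internal standard)
  carry known effects of configurable size.
- **Replication tables.** Line/year/interaction/residual effects are drawn
  iid normal with variances equal to the configured fractions — exactly
  the additive model the ANOVA assumes, so recovery tests validate the
  estimator, not the biology.
- **Peak tables.** Retention time is linear in carbons and double bonds
  with the double-bond coefficient fixed at −2× the per-carbon coefficient,
  per the reversed-phase equivalent-carbon-number rule (ECN = C − 2·DB);
  RT noise is 1 s. Mass error is multiplicative Gaussian at
  `ppm_noise_sd` (default 3 ppm); adduct intensity yields are fixed
  (NH₄ 1.0, H 0.3, Na 0.2, K 0.1); contaminants sit at uniform random
  m/z and RT; blank intensities pass the 2× rule comfortably except for a
  configured number of deliberate violations. Not emulated: isotope
  patterns, peak shape/width, co-elution artifacts, in-source
  fragmentation, intensity-dependent mass error.

Passing tests on these generators therefore shows the estimators recover
what the models plant under their own assumptions — it does not certify
performance on real chromatograms or real population histories.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale designs chosen so every stochastic
check is comfortably powered: annotation round trips at 195 true peaks × 20
seeds; ANOVA recovery on the 6×3×5 design × 50 seeds; MLM calibration on
n = 500 × 2000 SNPs with 10 phenotype permutations pooled (20,000 tests),
power over 20 simulations, inflation medians over 3; block recovery over 10
seeds; LD half-decay over 5–10 seeds with 100 kb spacing against a 500 kb
decay scale (spacing comparable to the scale so the smoothed curve resolves
both the shoulder and the tail). Stochastic assertions use medians or means
over seeds rather than single draws; calibration checks that are themselves
hypothesis tests (KS uniformity) are judged on the median across a few
seeds because a 1%-level test fails ~1 run in 15 by construction.

Fixed numerical details: REML searches log δ in [−10, 10] with 1e-6
tolerance; eigenvalues of K are clipped at 0; the grid-filter cut adds
1e-8 so noiseless data never flag on rounding error; D′ likelihood grids
use 101 points; lowess uses span 0.3; p-values are floored at the smallest
positive float to keep −log₁₀ finite.

## Known limitations

- The annotation stage starts from peak tables; raw spectra processing
  (peak picking, alignment) is out of scope.
- The net-pattern filter is an automated surrogate for what is, in
  practice, often a manual curation step; its anchor-based plane fit
  assumes each class does form a single RT plane.
- detect_ld_blocks is a reimplementation of the confidence-interval block
  definition on unphased data; boundaries can differ from phased-data tools
  by a SNP at block edges.
- The MLM assumes a single random effect with covariance ∝ K; no
  dominance, no G×E random terms, no multi-trait models.
- Nei distances on one-individual "populations" are a screening statistic,
  not an estimate of divergence time.
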