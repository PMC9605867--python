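# Methods

This note documents the statistical models implemented in `satmap`, the
choices made where the design was genuinely open, and what the synthetic
data generators do and do not emulate.

## Scope and data model

`satmap` operates on summary-level GWAS data only: tables of
conditionally independent genome-wide significant (GWS, P < 5×10⁻⁸)
SNPs with marginal and joint effect estimates (the output format of
conditional-and-joint stepwise selection), gene range lists, paired
discovery/replication summary statistics, binary SNP annotation tables,
and family phenotype/PGS tables. Coordinates are 1-based with closed
intervals everywhere in memory; the BED writer converts to 0-based
half-open at the boundary. Only autosomes (1–22) are handled. Alleles
are stored verbatim and assumed harmonized; `align_effect_pairs` flips
a replication effect onto the discovery effect allele only when the
allele pair matches after swapping.

Study-level SNP QC follows the usual summary-statistic rules:
imputation accuracy r²_INFO ≥ 0.3, Hardy–Weinberg P ≥ 10⁻⁸ (the
stricter 10⁻⁶ reference-panel threshold is a configuration away) and
minor allele count ≥ 5; a rule is skipped for records lacking the
field, and a record can count against several rules in the QC report.

## GWS loci and signal density

A locus is formed by flanking every independent GWS SNP by `flank_bp`
(default 35 kb) and chaining, per chromosome, consecutive signals at
most 2×flank apart. Ties at exactly 2×flank merge (flanked intervals
that touch are one locus). Locus bounds are min(pos)−flank and
max(pos)+flank with no clipping at chromosome ends, so a single-signal
locus is exactly 70 kb at the default; length is defined as end−start
(no +1 — immaterial at kb scale but applied consistently). Genome
coverage divides the cumulative locus length by a fixed genome length,
3,039 Mb by default.

Signal density counts, for each signal, the other same-chromosome
signals within an inclusive window (default 100 kb on either side);
each proximity is counted from both ends, so densities sum to an even
number. Standard errors of density summaries use a
leave-one-chromosome-out jackknife over the k represented chromosomes:

    se = sqrt( (k−1)/k · Σⱼ (θ₋ⱼ − mean θ₋ⱼ)² )

Single-chromosome inputs return the point estimates with the s.e.
reported unavailable (NaN).

No assembly-gap or centromere handling is implemented: a locus whose
flank spans a gap keeps its nominal bounds.

## Gene enrichment near dense signals

Signals are cross-classified by (i) candidate gene within 100 kb —
distance measured to the nearest gene-interval edge, 0 inside the gene
(transcription-start anchoring would be an alternative; edge distance
is the more common convention) — and (ii) signal density above versus
at-or-below a threshold (default: d ≥ 1 vs d = 0). Enrichment is the
odds ratio (a·d)/(b·c) of that 2×2 table, with the Haldane–Anscombe
+0.5 correction applied and flagged when a cell is zero. A dose–response
variant reports OR(k) for thresholds d ≥ k, k = 1..10.

Significance comes from a length-matched resampling null: gene lengths
are binned into 22 classes — <10 kb, nine 10-kb classes covering
[10, 100) kb, nine 100-kb classes covering [100 kb, 1 Mb), [1, 1.5) Mb,
[1.5, 2) Mb and ≥2 Mb — and, per replicate, the candidates in each
class are replaced by an equal number of non-candidate genes sampled
without replacement from the same class. The permutation p-value uses
the add-one estimator p = (1 + #{null OR ≥ observed}) / (1 + R), which
cannot reach zero at finite R. A class containing candidates but too
few non-candidates is a hard error naming the class, not a silent
renormalisation.

## Matched SNP sampling

Two matching strategies are provided. The model-based one fits a
logistic regression of a selection flag on binary functional
annotations (24 in the motivating use), predicts each pool SNP's
selection probability, and samples sets with replacement with
probability proportional to the prediction; balance is diagnosed per
annotation with two-sided Fisher's exact tests between the selected set
and each sample. Constant annotations are dropped from the fit (with
all-constant annotations the sampling degrades gracefully to uniform);
perfect separation is an error suggesting annotation pruning. The
bin-based strategy matches exactly on 28 joint classes — 7 fixed MAF
classes (breaks at 1, 5, 10, 20, 30, 40, 50%) × 4 LD-score quartile
classes computed on the pool — sampling per class without replacement,
which preserves the joint class histogram exactly.

The cross-ancestry LD independence filter keeps a query SNP only when
its maximum r²_LD with the reference signal set stays below 0.8 in
*both* ancestry LD panels; pairs absent from a panel count as r² = 0
and are tallied in the returned info.

## Replication concordance

**Fixed-effect IVW meta-analysis** uses weights 1/se², pooled s.e.
1/√Σw, and Cochran's Q with k−1 degrees of freedom; the I²-style
heterogeneity fraction max(0, (Q−df)/Q) is reported alongside.

**Hudson's F_ST** is computed per SNP as
[(p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1)] / [p₁(1−p₂) + p₂(1−p₁)]
with n the allele counts, and averaged as a ratio of averages
(Σnum/Σden), which is invariant to SNP order and population swap; SNPs
monomorphic in both samples are excluded and counted.

**Winner's-curse correction.** A SNP selected at |β̂/se| ≥ z_α
(α = 5×10⁻⁸ two-sided by default) has an inflated estimate. The
corrector inverts the conditional expectation of a normal estimate
under two-sided truncation,

    E[β̂ | b] = b + se · [φ(z_α − b/se) − φ(−z_α − b/se)]
                      / [Φ(b/se − z_α) + Φ(−b/se − z_α)],

solving E[β̂|b] = β̂ for b by vectorised bisection on [0, |β̂|] (the map
is increasing with g(0)=0 and g(b) ≥ b, so the bracket is guaranteed);
the corrected effect keeps the observed sign and never exceeds the
observed magnitude. *Known limitation:* the inversion map is strongly
concave just above the selection threshold, so averaged over a sample
the corrector is near-unbiased for null and small true effects (the
regime where winner's curse matters), but over-corrects on average for
true effects well above the threshold or for wide effect-size mixtures.
The tests exercise the null and small-effect regimes.

**Effect correlation ρ_b.** For paired discovery/replication estimates
aligned to the same allele,

    ρ̂_b = cov(β̂_d, β̂_r) / sqrt[(var(β̂_d) − med(se_d²)) · (var(β̂_r) − med(se_r²))],

with sample (co)variances and the median squared standard error
deflating each side symmetrically (the raw covariance needs no
correction because the two cohorts' sampling errors are independent).
Estimates are clipped to [−1, 1] with a flag; the s.e. is a
leave-one-SNP-out jackknife, computed in O(M) via streaming moments and
an order-statistics trick for the leave-one-out medians. A nonpositive
deflated variance (noise exceeding signal) is a hard error. Because the
median under-corrects when se² is right-skewed across SNPs (mean >
median), ρ̂_b carries a small deterministic offset under strong MAF
heterogeneity — of order −0.004 at the default simulation design —
which is invisible at interior ρ but dominates the (correctly
calibrated) jackknife s.e. at the ρ = 1 boundary. This is a property of
the median-deflated estimator, kept as specified.

**Closed forms.** Under shared true effects across cohorts, the
expected correlation of *estimated* effects is

    E[ρ_b] = σ_b² / sqrt[(σ_b² + (1 − σ_b² h_d)/(N_d h_d)) · (σ_b² + (1 − σ_b² h_r)/(N_r h_r))],

where h is the mean heterozygosity 2·MAF·(1−MAF) across GWS SNPs and
σ_b² is estimated as var(β̂_d) − med(se_d²). Dimensional analysis (and
exact agreement with simulation) fixes the units: σ_b² is the variance
of true per-allele effects, so that (1 − σ_b²h)/(Nh) is the per-allele
sampling variance and σ_b²·h the mean per-SNP variance explained. The
expected proportion of sign-consistent effects is the Gaussian orthant
probability E[P] = 1/2 + arcsin(ρ)/π evaluated at E[ρ_b]. Observed sign
consistency is tested against 1/2 with the exact binomial upper tail
(this one-sample setting admits no two-sample exact test; the binomial
tail is the faithful reading), zero effects excluded and counted.

## Polygenic and family prediction

A PGS is the weighted sum of effect-allele dosages, with mismatched
dosage columns flipped (dosage → 2 − dosage) and missing weight SNPs
reported while scoring proceeds on the intersection. Prediction
accuracy is incremental R²: R² of phenotype on covariates plus
predictor minus R² on covariates alone, with an individual-level
bootstrap s.e. (1,000 seeded resamples by default; bootstrap rather
than jackknife because the statistic is cheap and the bootstrap handles
its mild skewness better). Phenotypes are assumed standardised to
variance 1 within sex upstream. Within-family accuracy is the plain
squared Pearson correlation of sibling phenotype differences with
sibling PGS differences, which cancels any family-shared term by
construction.

**Combining a PGS with the parental average.** With heritability h²,
spousal phenotypic correlation ρ and PGS accuracy r² (phenotypes
standardised in the parental generation), the best linear predictor of
a child's phenotype from (PGS s, parental average PA) uses the second
moments

    var(PA)    = (1+ρ)/2            cov(y, PA) = h²(1+ρ)/2
    cov(s, PA) = r²(1+ρ)/2          var(s)     = r²(1 + ρr²/2)
    cov(y, s)  = r²(1 + ρh²/2)      var(y)     = 1 + ρh²²/2  (ρh²·h²/2)

with weights w = Σ⁻¹c and combined R² = cᵀΣ⁻¹c / var(y). The ρ-terms
beyond the familiar (1+ρ)/2 factor arise because phenotypic assortment
induces a parental genetic covariance ρh⁴ (regression of g on y has
slope h²), inflating the child's genetic variance to h²(1+ρh²/2); at
ρ = 0 the entries collapse to the textbook random-mating model
(var(s) = cov(y,s) = r², var(y) = 1). These are exactly the moments the
family simulator realises, and the million-trio Monte Carlo oracle is
the certificate: the closed form must sit inside the oracle's 99%
interval across a 3×3×3 grid of (h², ρ, r²). Degenerate cases are
explicit: r² = 0 returns the parental-average-only predictor; a
singular predictor covariance is an error.

## Synthetic data

The generators are seeded (`numpy.random.default_rng`), deterministic
under a fixed seed, and emit the same containers and TSV dialects the
readers consume. Their defaults are the study conditions the analysis
modules are meant to face.

*Signal maps.* 22 equal-length chromosomes totalling 3,039 Mb; 12,111
GWS signals by default, 60% placed in 2,000 hotspots of 200 kb width
(uniform hotspot centers, chromosomes weighted by length), the rest
uniform — chosen to reproduce the scale of the observed clustering (a
mean signal density near 2 and a majority of signals with a ≤100 kb
neighbour). 19,000 genes with lengths drawn from a 22-class weight
vector dominated by the 10–100 kb range, so all length classes are
populated at realistic rates; ~2.5% of genes are candidates (the scale
of curated Mendelian growth-gene lists), selected with odds `gamma`
(default 3, the scale of the observed enrichment) for genes within
100 kb of a hotspot center. Marginal/joint effect columns are filled
with genome-wide significant draws so the tables validate as COJO
output. Not emulated: LD, real chromosome lengths, gene clustering,
assembly gaps — so passing tests certify the statistics' behaviour
under clustered-signal geometry, not their values on real annotation.

*Two-cohort summary statistics.* Per SNP with MAF p (uniform on
[0.01, 0.5] by default, or fixed), true per-allele effects are
bivariate normal across cohorts with correlation ρ_true and variance
σ_b²/(2p(1−p)) (so per-SNP variance explained averages the σ_b²
parameter); observed effects add independent noise with
se = 1/√(2p(1−p)N). Defaults N_d = 5×10⁶, N_r = 5×10⁴, σ_b² = 10⁻³,
M = 5,000 mirror the saturated-discovery / biobank-replication design.

*Family cohorts.* Couple phenotypes are drawn jointly from a bivariate
normal with correlation ρ_spouse — equivalent in law to Gaussian-copula
rank pairing of a mating pool and exact; parental genetic values follow
their conditional law given phenotype (g | y ~ N(h²y, h²(1−h²)));
children receive the mid-parent genetic value plus segregation variance
h²/2, an independent environment of variance 1−h², and a PGS
s = (r²/h²)g + noise with var(s) = cov(y,s) = r² under random mating.
Equilibrium inflation of the *parental* genetic variance under
sustained assortment is deliberately not modelled: the simulator
targets realised covariances and the analytic module matches exactly
those, so the simplification is self-consistent (and stated). Sibling
records use independent segregation, environment and PGS noise.

*Annotation pools.* Binary annotations with configurable prevalence
(default 15%), MAF uniform, gamma-distributed LD scores, and a logistic
selection flag.

## Numerical choices and problem sizes

Bisection tolerance for the winner's-curse inversion is 10⁻¹⁰
relative, 200 iterations maximum, with explicit bracket/convergence
errors. Permutation p-values use add-one estimators. Odds ratios from
tables with zero cells are Haldane-corrected and flagged. The test
suite and the acceptance script run the simulations at reduced sizes
chosen for tight Monte Carlo error at interactive runtimes: 200
two-cohort replicates per ρ for estimator calibration, 200 synthetic
genomes (800 signals, 2,500 genes) at 199 resamples for null
uniformity, five genomes (2,500 signals, 3,000 genes, 240 candidates)
at 999 resamples for planted-enrichment power (~92% per genome at
γ = 3, hence the median-of-five decision rule), 10⁶ bivariate draws per
ρ for the orthant probability, and 10⁶ trios per grid point for the
family oracle.

## Known limitations

- The locus and density statistics ignore assembly gaps and real
  chromosome boundaries.
- The winner's-curse corrector is a point correction, not an
  empirical-Bayes shrinkage; see above for its bias profile.
- ρ̂_b's median deflation leaves a small offset at the |ρ| = 1 boundary
  under strong se² skew.
- The family model has no shared environment, no dominance, and no
  multi-generation assortment equilibrium; its closed forms are exact
  for the stated generative process only.
- Gene–signal proximity uses interval-edge distance; results near the
  100-kb window edge depend on that anchoring choice.
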