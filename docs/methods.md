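# Methods

This note records the statistical models implemented by `admixgwas`,
the design decisions taken where the problem left real choices, the
numerical conventions, and what the synthetic-data experiments do and
do not demonstrate.

## Data model

All lines are fully homozygous inbreds; genotypes are coded 0/1 per
marker (heterozygous input calls are converted to missing and counted).
Each line carries a background label: `D` and `F` for the two pure
groups, `A` for admixed doubled haploids with exactly one `D` and one
`F` parent. Coordinates are 1-based bp; ancestry-track segments are
closed intervals that tile each chromosome without gaps. Line order is
canonicalized (D block, then A, then F, lexicographic within blocks) so
block matrices are reproducible. The missing-call sentinel (−1) is
format-independent and round-trips through every supported format
(genotype matrix TSV + marker map, GT-only VCF, pedigree CSV, BED-like
track TSV, phenotype TSV).

## Polygenic model and ReML

The null model is Y_kl = μ + α_k + G_kl + E_kl with
Cov(G_kl, G_k′l′) = K[kl,k′l′]·σ_Gkk′ and i.i.d. errors. The fixed
part is fit as a cell-means background design (one column per
background present), which spans {μ, α_k} without rank deficiency.

Sigma_G is optimized through its Cholesky factor L (Sigma_G = LL′), so
positive semidefiniteness is structural; the error variance is
optimized on the log scale. The restricted likelihood and its analytic
gradient are evaluated by one Cholesky factorization of V per
iteration; gradients use blockwise sums of P∘K and (Py)(Py)′∘K, where P
is the REML projection matrix. Optimization is L-BFGS-B with parameter
bounds (|L entries| ≤ 20, log σ²_E ∈ [−30, 10]) to prevent overflow,
convergence at relative likelihood change < 1e−8 or 200 iterations, and
three starting points on a heritability grid (0.5, 0.2, 0.8) with
cross-group correlation 0.4. A `warm_start` from a previous fit skips
the grid when it converges; replicated experiments use it. Boundary
estimates (a variance below 1e−6 of the phenotypic scale, or an implied
|correlation| > 0.999) are flagged, not clipped further. The phenotype
is internally standardized to unit variance and results are scaled
back.

Identifiability caveat: when lines are mutually unrelated given their
groups, K ≈ I and σ²_G/σ²_E are separated only by off-diagonal
structure; with K = I exactly, only their sum is identified (the ReML
optimum then recovers the n−1 sample variance as the total). Similarly
the D–F covariance σ_GDF is identified only through the D–F kinship
block, which for independently sampled founder groups carries no
structure (see the recovery experiment below).

## Two-step SNP testing

Variance parameters from the null fit are plugged into G =
Sigma_G[blocks]∘K and R = σ²_E·I. Each SNP is tested by GLS of the
phenotype on an intercept plus one indicator per observed allelic
state. This design is deliberately rank-deficient (indicators sum to
the intercept; background main effects are absorbed by the states);
coefficients use a fixed Moore–Penrose convention (SVD cutoff 1e−10)
and only estimable contrasts are reported — estimability is checked
against the row space of the design itself, not of X′V⁻¹X, so an
ill-conditioned V cannot veto an estimable contrast.

"Keeping the variance ratios fixed" admits two readings; both are
implemented. The default re-estimates one global scale of V per SNP as
the residual quadratic form over its degrees of freedom, which makes
the Wald statistics insensitive to a mis-scaled null fit; the frozen
alternative (`reestimate_scale=False`) and the exact per-SNP ReML
refit (`refit_reml=True`) are available. On simulated null data the
two-step p-values correlate > 0.99 (log scale) with the exact refit.

Wald statistics W = (c′β̂)²/(c′ Var β̂ c) are referred to χ²(1).
Estimates of general/divergent contrasts are exact linear combinations
of the simple ones by construction (same β̂), which the tests assert to
numerical exactness.

## Batteries, filtering, FDR, QTL clustering

The M2 battery is {Δ_D, Δ_F, Δ_D+F, Δ_D−F}; the M3 battery is the 16
rows over (Δ_DD, Δ_DA, Δ_FA, Δ_FF) with coefficients in {−1, 0, +1}:
four simple, five general, seven divergent, of which Δ_DD−DA, Δ_FF−FA,
Δ_(DD+FF)−(DA+FA) and Δ_(DD−DA)−(FF−FA) test SNP × background
interaction.

A SNP is discarded when the least-carried state of the model's full
state space has fewer than 10 carriers — an absent state counts as
zero, so markers fixed within any required ancestry × background
combination are excluded; this is why the M3 marker set is smaller than
M1's on the same panel. Redundant SNPs (identical state vectors over
the analyzed lines) are reduced to the first in map order with an alias
table, so detected loci can be expanded afterwards. Admixed lines whose
local ancestry at a marker is undetermined are dropped marker-wise.

FDR control is Benjamini–Hochberg step-up applied once to the pooled
marker × hypothesis p-values of a strategy (per trait); the adaptive
two-stage variant is available (`method="fdr_tsbh"`). Significant SNPs
of one hypothesis are chained into QTLs by single linkage with a 3-Mbp
physical window; the lead SNP minimizes p with ties broken by smaller
position; overlapping per-hypothesis clusters can be merged for
model-level QTL counts.

## Local-ancestry imputation of admixed DH lines

Per admixed line: (1) at shared markers where the two parents differ,
the transmitting parent is read off directly; an admixed call matching
neither parent (only possible where parents agree) is flagged as a
Mendelian inconsistency and left undetermined. (2) Runs of at most
`max_discordant` determined calls contradicting both flanking runs
(each with at least `min_flank` concordant calls of one common origin)
are reset to undetermined — defaults 1 and 2; the thresholds are
exposed because any smoothing rule is a judgment about genotyping error
rates, and smoothing is disabled (`max_discordant=0`) when the input is
known error-free, otherwise it erases true short double-crossover
blocks. (3) Between consecutive opposite-origin informative markers,
the dense markers strictly inside the interval are split by count: the
first ⌈n/2⌉ keep the left origin (deterministic tie-break), and the
breakpoint is placed midway between the last left and first right
position (midway between the informative markers when n = 0).
Chromosome ends extend the nearest determined origin. (4) Each dense
marker receives the allele of the parent named by its segment.

Imputation is exact outside recombination intervals within the span of
the informative markers; crossovers beyond the terminal informative
marker of a chromosome are invisible in principle. Per-line statistics
(Mendelian inconsistencies, missing counts, fraction of dense markers
inside recombination intervals) are reported.

The selection-bias scan compares the observed admixed allele frequency
with the pedigree expectation (mean over admixed lines of their two
parents' allele average), per marker.

## Kinship, distances, LD diagnostics

Kinship uses background-specific frequencies for the polygenic model
and pooled frequencies for ordination and the epistasis decomposition.
Markers monomorphic in every centering vector are dropped with a logged
count (they contribute nothing and can zero a denominator). PCoA is the
eigendecomposition of the double-centered squared-distance matrix with
negative eigenvalues truncated.

LD is the Pearson correlation r of 0/1 call vectors (for inbreds this
equals the haplotype correlation). Profiles bin marker pairs by
physical distance (default 0–2 Mbp, 1-kb windows, 1-kb step; both
configurable), keeping SNPs with ≥ 10 minor-allele carriers in both
groups, and report per window: mean r² per group, the cross-group
correlation of signed r (phase persistence) and of its sign indicator.
Cross-group sign quantities are meaningful only under one shared
reference-allele coding, which the data model enforces; note that the
per-pair products r_D·r_F are invariant to consistent allele
relabeling but Pearson correlations across pairs are not, since
relabeling moves the means.

## Epistatic variance decomposition

On the joint panel with pooled-frequency kinship: y = 1μ + g + g_e + e,
Cov(g) = K σ²_G, Cov(g_e) = (K∘K) σ²_GxG, Cov(e) = I σ²_E, all fit by
the generic log-variance ReML. The LR statistic 2(llᶠᵘˡˡ − llʳᵉᵈ) is
clipped at 0 and referred to the boundary mixture ½χ²(0) + ½χ²(1)
(plain χ²(1) available). Interpretation requires family structure: for
a panel of unrelated lines K∘K ≈ I and σ²_GxG is confounded with σ²_E
(the LR test stays calibrated, but the component split is arbitrary
along that ridge).

## Synthetic-data generator

Founders follow the Balding–Nichols construction: ancestral frequency
p_m ~ U(0.05, 0.95), group frequencies Beta with mean p_m and variance
F_ST·p_m(1−p_m), one Bernoulli call per inbred line. Admixed DH lines
are one simulated meiosis of a random D × F pair (crossovers
Poisson-distributed with the chromosome's genetic length, uniform
positions, no interference) doubled, with the true ancestry track
recorded. Defaults describe the emulated study conditions: 100 lines
per background, 2,000 markers on 10 chromosomes of 1.6 Morgan /
200 Mbp, F_ST = 0.1, Sigma_G with unit variances and cross-background
correlation 0.7, σ²_E = 1 (heritability 0.5).

Phenotypes add QTL state effects, a polygenic draw from
Sigma_G[blocks]∘K (the realized kinship of the simulated panel), and
white noise. QTL regimes map to allele-1 effect patterns over
(DD, DA, FA, FF): `conserved` (β,β,β,β); `ancestry_divergent`
(β,β,−β,−β); `background_interacting` (β,−β,−β,β), i.e. the effect
reverses between pure and admixed backgrounds — an ancestry-symmetric
interaction chosen so that ancestry-divergence tests stay at their
nominal level under this regime while the interaction tests carry the
signal (an effect merely *scaled* by admixture proportion leaks into
the ancestry-divergent contrasts and is provided separately as
`background_linear`); `admixed_only` (0,β,β,0); and a two-locus
`background_epistatic` variant conditioning the effect on a modifier
locus. In power experiments QTL markers are auto-selected among
markers passing the strictest (M3) carrier filter, so every strategy
tests the same marker.

What the simulations do not emulate: linkage disequilibrium beyond
family structure within the founder groups (founder genotypes are
drawn independently across markers), cross-group founder relatedness,
genotyping error, and selection during DH production. Consequently the
LD profiles of simulated panels are flat, the D–F kinship block is
unstructured (see below), and passing calibration/power tests speaks
to the statistical machinery under the stated generative model, not to
robustness against LD confounding in real panels.

## Experiment designs and sizes

* **Null FDR calibration** (acceptance script and suite): 20 replicate
  null panels at the default study conditions; the realized
  false-discovery proportion of the joint-BH M3 battery at nominal 5%
  is 1 when any test is declared significant, else 0, and its mean
  estimates the delivered FDR. A 60-replicate pilot measured 5.0%.
* **Wald calibration**: one null panel with 2,400 markers (~1,000 pass
  the M3 filter); each contrast's p-values are tested for uniformity
  (KS, α = 0.01).
* **ReML recovery**: 20 replicates at n = 400 (134/133/133), 1,000
  markers, truth Sigma_G = unit variances with correlation 0.7, σ²_E =
  1; means must fall within 2 Monte-Carlo SE of truth. This experiment
  generates and fits with the pooled-frequency kinship: with
  independently sampled founder groups the D–F block of the
  by-background kinship is structureless noise, σ_GDF is then barely
  identified and its constrained (PSD) estimate is visibly shrunk —
  a property of that data design, not of the estimator, so the
  recovery experiment is run where all six (co)variances are
  identified. Real multi-group panels share breeding ancestry and do
  not have this degeneracy.
* **Power ordering**: 50 replicates per regime, 300 lines, 600 markers
  over 5 chromosomes, allele-1 effect 0.6 (chosen a priori by a
  noncentrality calculation to put the M1 within-group tests at
  moderate power so orderings are visible), power read at α = 0.05 at
  the planted marker.
* **Epistasis power**: effect sizes calibrated by a small pilot on the
  family-structured panel (additive sd 1, epistatic sd 2.5, error sd
  0.7) to sit near the 80% rejection target.

Sizes were picked so the whole suite runs in a few minutes on one CPU;
all experiments are seeded and reproducible.

## Known limitations

* Dense V algebra throughout (Cholesky of N×N per ReML iteration):
  comfortable to a few thousand lines, not for biobank scales.
* The two-step approximation shares one V across SNPs; SNPs explaining
  a large variance fraction are better re-fit exactly
  (`refit_reml=True`), mirroring how lead SNPs should be reported.
* Heterozygotes are out of scope by design (inbred panels only), as
  are HMM-based ancestry calling (the pedigree makes origins
  deterministic at informative markers) and population imputation of
  the pure groups, which are assumed complete.
* The BH guarantee applies under positive dependence; the joint
  battery pools highly correlated contrasts, for which BH remains
  conservative in the experiments above.
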