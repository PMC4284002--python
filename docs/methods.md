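# Methods

`grasspred` implements the quantitative-genetics workflow used for diversity
panels of outbred plants genotyped by reduced-representation sequencing:
SNV quality filtering, population-structure inference, trait BLUP
estimation, mixed-linear-model association, perturbation-based power
calibration, and ridge-regression genome-wide prediction.  This note
records the models, the defaults and why, the numerical choices, and what
the synthetic-data generator does and does not emulate.

## Synthetic data generator

The generator (`grasspred.simulate`) emulates a panel like the one the
package was designed around: ~138 outbred individuals from two weakly
differentiated subpopulations (F_ST < 0.06), 10^4–10^5 biallelic SNVs, and
replicated field-trial phenotypes with broad-sense heritabilities of
roughly 0.5–0.9.

**Genotypes.** Subpopulation allele frequencies follow the Balding–Nichols
model: `p_s ~ Beta(p(1-F)/F, (1-p)(1-F)/F)` around an ancestral frequency
`p`.  Under this model Hudson's F_ST estimator recovers `F` in expectation,
which is what the generator tests assert.  Defaults: `n_individuals=138`,
`n_subpops=2`, `fst=0.04` (inside the panel's stated <0.06 range),
ancestral MAF uniform on (0.05, 0.5).

**Linkage disequilibrium.** Loci come in blocks (default 5 loci/block,
mimicking multiple SNVs per sequenced tag).  Three mechanisms couple loci
within a block, all reflecting the shared local genealogy of tightly linked
variants: (1) the ancestral MAF is drawn per block with a ±0.05 per-locus
jitter; (2) the Balding–Nichols drift quantile is shared within a block;
(3) each gamete reuses a shared latent uniform within a block with
probability `ld_strength` (default 0.8).  Together these give a mean
within-block genotypic r² ≈ 0.4–0.6, comparable to the ~0.4 average
reported for SNVs on the same restriction-site tag, while leaving blocks
mutually independent.  This is deliberately simpler than a coalescent
simulation: it provides the LD features the pruning, tagging and
marker-count analyses need and nothing more.

**Relatedness.** By default individuals are exchangeable within
subpopulations.  `family_size > 1` groups consecutive individuals into
half-sib-like families sharing one parental gamete.  Real diversity panels
contain close relatives, and their presence is what makes random
cross-validation easier than across-subpopulation cross-validation; the
across-vs-random prediction contrast is therefore exercised with
`family_size=4`.

**Read support.** Depth is Poisson (truncated at 1) around `mean_depth`;
heterozygous calls split reads Binomial(depth, 1/2); homozygous calls leak
the other allele at `error_rate`.  GQ is the Phred-scaled likelihood ratio
of the best to second-best genotype under the binomial read model.  The
per-locus variant quality is a Gamma(8, 5) draw (mean 40) — a synthetic
annotation whose only purpose is to exercise quality-threshold filters.

**Phenotypes.** A trait is `y_ij = g_i + block_j + e_ij` over `n_blocks`
complete blocks (default 4).  The genotypic value `g` is a sum of `n_qtl`
additive marker effects, rescaled so the clone-mean heritability
`H² = σ²_G/(σ²_G + σ²_E/n_blocks)` equals the requested `h2` exactly in the
per-observation variance budget (σ²_G + σ²_E = 1, so all effect sizes are
in trait-SD units).  `subpop_shift` adds a fixed genetic offset to the
second subpopulation, producing traits confounded with the leading
structure axes.  The generator returns the true genotypic values and QTL
list so recovery tests need no external truth.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: genotyping error correlated with genomic context,
null alleles and allele dropout at restriction sites, genome-scale LD decay
and long-range admixture LD, dominance/epistasis, genotype-by-environment
interaction, and spatial field trends.  Results on synthetic panels
demonstrate that the estimators are implemented correctly and behave as
theory predicts under their assumptions, not that those assumptions hold in
any particular field trial.

## Filtering

`FilterProfile` bundles eight criteria; two built-in profiles mirror common
stringent/liberal practice (stringent: Q ≥ 15, per-call depth ≥ 14, ≤ 10%
missing, |F_IS| ≤ 0.25, het minor-read fraction ≥ 0.05, biallelic; liberal:
per-call depth ≥ 3, mean depth ≥ 6, ≤ 20% missing, ≥ 3 minor-allele copies,
biallelic).  Choices needing a decision:

- `F_IS = 1 − Ho/He` with `He = 2p(1−p)` uncorrected for sample size; the
  statistic is a genotyping-quality screen, not an inbreeding estimate.
- Per-call criteria (minimum depth; heterozygote read balance) set the call
  missing *before* locus statistics are recomputed, mirroring
  VCFtools-style `--minDP` masking; dropping the whole locus on a failed
  het-read check is available via `het_read_drops_locus`.
- The MAF criterion is a minor-allele *copy count* across all genotypes,
  not a frequency, so its meaning is invariant to missingness.
- Mean depth averages over non-missing calls only.

LD is the squared Pearson correlation of dosage vectors over jointly
observed individuals ("genotypic correlation"); monomorphic input yields an
undefined flag (NaN), not an exception.  Pruning is greedy within sliding
windows (defaults 50 loci, step 5, r² > 0.2, per chromosome): the worst
correlated retained pair loses its lower-MAF member (ties drop the larger
index).  The suite verifies the output against an exhaustive pair scan.

## Population structure

The IBS kinship is allele-sharing `(2 − |g_i − g_j|)/2` averaged over
jointly observed loci; the GRM is VanRaden's `ZZ'/(2Σp(1−p))` on
mean-imputed, 2p-centered dosages.  PCA uses the Patterson normalisation
(center 2p, scale √(p(1−p))) so that, absent structure, the leading
eigenvalues follow a Tracy–Widom law.  Per-axis p-values use Patterson's
moment estimator of the effective marker count with successive removal of
leading eigenvalues.  The TW1 distribution itself is evaluated through a
shifted-gamma approximation (Gamma(k=46.446, θ=0.18605) − 9.84801), which
matches published TW1 percentiles to ~1e-3 in probability and avoids
shipping a lookup table.  Outlier removal iterates the smartpca-style rule
(default 6 SD on the top 10 axes, ≤ 5 rounds); gating by axis significance
first is available via `significance_alpha`, since either order is
defensible.  Subpopulation assignment is k-means on the significant axes
with centroid-sorted labels, making the labelling independent of individual
order.

## Trait BLUPs and genetic correlations

The phenotype model is `y = μ + block (fixed) + genotype (random) + e`.
All variance-component fitting in the package goes through one REML core:
the restricted likelihood is profiled over the ratio δ = σ²_e/σ²_g on the
spectrum of the projected covariance S K S, located by a coarse grid over
log δ ∈ [−12, 12] and refined by bounded scalar minimisation (tolerance
1e-10).  BLUPs solve the mixed-model equations at the optimum; H² is
reported on a clone-mean basis with the harmonic-mean replicate count.
Degenerate designs (one block, one replicate) raise an explicit error.

Genetic correlations come in two flavours used interchangeably in practice:
`r_G = r_P/√(H²_x H²_y)` (for traits measured in different years), and a
method-of-moments estimate from clone-mean cross-products minus the
residual cross-covariance over the replicate count (same-design traits).
Estimates outside [−1, 1] are clipped with a warning, never silently;
non-positive genetic variances yield NaN with a message.

## Mixed-model association

The scan is the EMMAX approximation: variance components are fitted once
under the no-marker null, then every marker is tested by GLS with the
covariance held fixed.  After rotating by the eigenvectors of K the
per-marker test is a weighted simple regression, vectorised across markers.
Covariates are an intercept plus (by convention) the first two PC scores.
Test statistics use t/F with `n − q − 1` residual degrees of freedom rather
than the asymptotic χ²: at n ≈ 138 the difference is material in the tails
and the F choice is conservative.  An exact per-marker GLS (full n×n solve)
exists in the test suite as the independent oracle; the two agree to
|Δ log10 p| < 1e-6.  λ_GC is median(χ²)/0.455.  Markers with zero variance
after imputation are flagged untested.  Missing calls are mean-imputed for
testing; observed-call counts and MAF are reported per marker.

Multiple testing: Bonferroni (`α/m`), Benjamini–Hochberg step-up (via
statsmodels), and a Storey-type variant with π₀ estimated on a fixed λ
grid.  The MLMM procedure alternates forward inclusion of the most
significant marker as a fixed cofactor (refitting δ each step, default ≤ 9
steps) with backward elimination, and selects the largest visited model
whose cofactors all pass Bonferroni (the multiple-Bonferroni criterion).
Collinear cofactors are flagged untested, so of a perfectly linked pair
exactly one can enter.

## Perturbation power study

Replicates pick a random segregating SNV, assign genotype effects
(−a, 0, +a), add them to the trait BLUPs, refit δ on the cached spectral
projection and test only that SNV.  The standardized effect is
k = a/SD(BLUPs), with the SD computed once on unperturbed BLUPs.  The
expected proportion of variance explained is

    PVE = 2p(1−p)k² / (1 + 2p(1−p)k²)

— the Hardy–Weinberg additive variance over the total after perturbation —
inverted in closed form to map a PVE grid (default 0.01–0.20 by 0.01) to
effect sizes.  This expression is a reconstruction from its stated
constraints (depends only on p and k; maps the k grid onto PVE 0.01–0.20)
rather than a transcription, and is flagged as such here.  Naive PVE is the
R² of the simple regression of perturbed BLUPs on dosage over observed
calls, recorded only for replicates significant at α (default 1e-5); its
conditional mean exceeds the expected PVE at low power (winner's curse —
the package reproduces ≥ 2× inflation at expected PVE 0.02, and measured
~8× on a 138-individual synthetic panel).

## Genome-wide prediction

Ridge-regression BLUP with a common marker-effect variance: λ = σ²_e/σ²_u
by REML on the spectrum of ZZ' (same core as above), effects
`u = Z'(ZZ' + λI)^{-1}(y − μ)`.  This is the marker-effect dual of GBLUP;
the suite checks prediction equality to 1e-8.  Markers are centered by
training-fold means and test genotypes are centered with the *training*
means; λ is refitted inside every training fold, so no information leaks
from test individuals.  Performance is summarised per repeat by pooled
test-set predictions: predictive ability r, accuracy r/√H², and the
calibration intercept/slope of observed-on-predicted.  Random k-fold
schemes stratify folds by subpopulation when labels are given
(toggleable); across-subpopulation evaluation pairs one deterministic
split with random baselines of identical training/test sizes.  Marker
pre-selection (random, lowest mixed-model p, largest |ridge effect|) is
computed strictly within the training fold.

## Problem sizes in the test suite

Simulation-based checks run at reduced scale chosen so each property is
comfortably identified: panels of 120–300 individuals and 400–20 000 loci,
20 seeds for recovery averages, 50 permutation replicates for type-I
calibration, and 4000 replicates for the winner's-curse point (its hit
probability is ~5e-3, so smaller counts leave the conditional mean
undefined).  The whole suite runs in a few minutes on one CPU.

## Known limitations

- The EMMAX approximation holds the variance ratio fixed across markers;
  for markers of very large effect the exact per-marker REML p-value can
  differ (the package keeps the approximation, as is standard).
- The TW p-values rely on an asymptotic null and a parametric
  approximation; they are accurate for screening axes, not for precise
  tail probabilities beyond ~1e-6.
- Equal-variance ridge shrinkage dilutes strongly oligogenic signals when
  markers greatly outnumber training individuals; marker pre-selection
  partially recovers this, as the marker-selection experiments show.
- The REML profile assumes two variance components; multi-kernel or
  spatial models are out of scope.
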