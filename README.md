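# grasspred

GWAS and genome-wide prediction for structured, outbred plant panels.

`grasspred` is a tested re-implementation of the analysis workflow used to
evaluate marker-based breeding in diversity panels of undomesticated
grasses genotyped by reduced-representation sequencing (RAD-Seq):

1. **SNV filtering** — quality/depth/missingness/Hardy–Weinberg profiles
   (built-in *stringent* and *liberal* presets), per-call heterozygote
   read-balance masking, LD as genotypic correlation, windowed pruning.
2. **Population structure** — IBS kinship and VanRaden GRM, genotype PCA
   with Tracy–Widom axis significance, smartpca-style outlier removal,
   subpopulation assignment.
3. **Trait BLUPs** — REML variance components for replicated
   randomized-complete-block trials, clone-mean broad-sense heritability
   H², phenotypic and genetic correlations.
4. **Mixed-model GWAS** — EMMAX-style single-locus scans with kinship and
   principal-component covariates, naive-regression comparison, genomic
   inflation λ_GC, Bonferroni/FDR control, multi-locus (MLMM)
   forward–backward cofactor selection.
5. **Power calibration** — data-perturbation simulations mapping expected
   per-SNV variance explained, PVE = 2p(1−p)k²/(1+2p(1−p)k²), to empirical
   power and to the winner's-curse inflation of naive PVE estimates.
6. **Genome-wide prediction** — ridge-regression BLUP (the marker-effect
   dual of GBLUP), k-fold/training-size/marker-count cross-validation
   designs, across-subpopulation evaluation, and marker selection by GWAS
   p-value or ridge effect size.  Performance is reported as predictive
   ability r, accuracy Accu = r/√H², and calibration intercept/slope.

No real panel is bundled: a synthetic-data module generates structured
genotypes (Balding–Nichols subpopulations, block-local LD, optional
half-sib families), sequencing read support, and replicated phenotypes
with known truth, at the scale of a ~138-genotype field trial.  See
`docs/methods.md` for the models and their assumptions.

## Worked example

```python
import grasspred as gp

# a synthetic panel at study scale: 138 genotypes, 2 subpopulations,
# 3000 SNVs with read support, replicated phenotypes for 3 traits
paths = gp.make_demo_dataset("demo", seed=7, n_individuals=138,
                             n_loci=3000, n_traits=3)
gt = gp.read_vcf(paths["genotypes"])

gt_f, report = gp.apply_filter_profile(gt, gp.LIBERAL)   # 3000 -> 2991 loci
pca = gp.pca_genotypes(gt_f, max_axes=5)
kin = gp.ibs_kinship(gt_f)

from grasspred.simulate import read_phenotype_tsv
pheno = read_phenotype_tsv(paths["phenotypes"])
blups = gp.estimate_blups(pheno, trait="DOYFS1.9")
print(blups.summary())

scan = gp.emmax_scan(blups, gt_f, kin, n_pcs=2, pca=pca)
print(scan.summary())

cv = gp.cross_validate(blups, gt_f, folds=10, repeats=20, seed=7)
print(cv.summary_text())
```

prints (abridged):

```
Trait BLUP results: DOYFS1.9
  sigma2_G             0.6777
  sigma2_E             0.4243
  H2 (clone-mean)      0.865
GWAS scan (emmax[IBS])
  markers tested  2991 / 2991
  covariates      intercept, PC1, PC2
  lambda_GC       0.981
CV {...}: r = 0.293 (0.038), Accu = 0.315, b0 = -0.006, b1 = 0.864
```

Reading: the trait was simulated at H² = 0.89 and the mixed model recovers
0.865; λ_GC ≈ 1 says the kinship + 2-PC scan is calibrated on this
structured panel (the naive scan is inflated on structure-confounded
traits); 10-fold ridge prediction reaches r = 0.29 for this polygenic
trait at n = 138, and Accu rescales that by 1/√H².  A command-line
interface mirrors the library (`grasspred simulate-demo|filter|pca|
kinship|blup|gwas|predict-cv|run`).

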