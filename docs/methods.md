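# Methods

This note documents the models, parameters, numerical choices and design
decisions behind `clcnet`, and what the synthetic-data experiments do and
do not demonstrate.

## Genotype representation

Genotypes are alt-allele dosages coded 0/1/2; a missing call is the literal
code 3. The network receives these raw codes, including 3 — the missing
state is left as a distinct input value rather than being imputed, so the
model can learn its own handling of missingness. Statistical routines
(r², GRM, GWAS, PCA) instead treat 3 as missing data: r² uses pairwise
deletion, and GRM/GWAS/PCA mean-impute per SNP for that computation only.
Coordinates are 1-based inclusive; SNPs are kept position-sorted within
chromosomes. Multi-allelic VCF records are rejected.

One standard-deviation convention is used everywhere: the sample sd with
n−1 denominator (standardizer, correlations, simulation scaling).

## LD pruning

Windowed greedy pruning over SNP counts, matching the common
`--indep-pairwise 100 10 0.2` idiom: windows of 100 SNPs advancing by 10;
within a window, whenever two retained SNPs have r² > 0.2 the one with the
smaller minor-allele frequency is dropped (ties: the larger index). The
exact tie rule is a package decision — it is documented here because the
classical tools do not publish theirs — and the algorithm is deterministic.
The post-condition is that no retained pair co-occurring in any window
position exceeds the threshold; the test suite verifies this and exact
agreement with an independent quadratic-time re-implementation.

## GRM and heritability

The genomic relationship matrix is VanRaden method 1:
K = (M − 2P)(M − 2P)ᵀ / 2Σpⱼ(1 − pⱼ), with allele frequencies estimated
from non-missing calls and monomorphic SNPs dropped (count recorded). On a
simulated Hardy–Weinberg panel the mean diagonal is ≈1 (tested within
0.05). Heritability is estimated by single-component REML for
y ~ N(μ1, σg²K + σe²I): K is eigendecomposed once, the restricted
likelihood is profiled over the variance ratio, and a bounded 1-D search
over h² ∈ (10⁻⁶, 1−10⁻⁶) maximises it (tolerance 1e-6, max 200
evaluations). Estimates at the lower boundary are reported as h² = 0.
Parameter-recovery behaviour at n = 500, m = 5000 with true h² = 0.6:
estimates fall in [0.45, 0.75] for ≥8/10 simulated traits; null traits
give a median estimate ≈0.01.

## GWAS scan

A deliberately simple marginal scan stands in for mixed-linear-model
association: per-SNP OLS of the phenotype on dosage + intercept + the top
n_pcs (default 5) genotype principal components, with two-sided p from the
t statistic (df = n − n_pcs − 2). The scan exists to support the P < .01
feature-selection baseline and the attribution comparison, not to provide
exact mixed-model parity; its type-I error is calibrated (null fraction of
p < 0.05 within [0.03, 0.07]; KS-uniform under the null).

## Synthetic data

`simulate_genotypes` draws, per chromosome, 2n haplotypes from a copying
process: each SNP starts a new LD block with probability
1/ld_block_mean_snps; within a block, each haplotype copies its previous
allele with probability `copy_prob` (default 0.9), otherwise draws fresh at
the SNP's allele frequency (uniform in `maf_range`, default 0.05–0.5).
Genotype = sum of two haplotypes; missing cells are set to 3 at
`missing_rate` (default 0.02). Positions are uniform-sorted over
`chrom_length_bp` (default 20 Mb, giving a ~25 kb median spacing so that
LD-decay analysis within 100 kb has pairs to bin).

`simulate_trait` draws `n_causal` causal SNPs uniformly, standard-normal
additive effects, and product-interaction effects on
round(`epistatic_pair_fraction`·n_causal/2) disjoint causal pairs.
Environmental noise is orthogonalised against the genetic values and scaled
so that Var(g)/Var(y) equals `h2_target` exactly on the realized sample
(to ~1e-12), which makes heritability-recovery tests sharp.

The standard fixture used throughout the tests is n = 600, m = 4000,
5 chromosomes, 40 causal SNPs, 25% epistatic pairing, h² = 0.7, seed 7.

What the generator does **not** emulate: population structure/admixture,
dominance, genotype-by-environment interaction — and, importantly, any
*chromosome-level concentration* of causal signal: causal SNPs are uniform
across the genome and epistatic partners are paired at random (hence mostly
across chromosomes). Consequences for what passing tests show are discussed
under "Known limitations".

## Chromosome-aware selection

LightGBM regressors score SNPs by total split gain; SNPs with gain > 0 are
kept, per chromosome (local) and genome-wide (global), and the two sets are
merged with duplicates removed (provenance recorded; a SNP kept by both
carries the larger of its two gains). Selection is always fitted on the
internal training rows of the current CV cell only.

Full-scale selector defaults are 200 trees × 31 leaves, learning rate 0.05,
no subsampling, seed 0 per fold. At the marker counts this method targets
(10⁵–10⁶ SNPs) that split budget is a small fraction of m, which is what
makes the positive-gain filter selective. At the desk scale of the test
fixture (m = 4000, 800 per chromosome) the same budget would touch nearly
every SNP several times and the filter degenerates (≈89% kept); desk-scale
experiments therefore use a budget with the same splits-to-markers ratio as
the full-scale setting — 60 trees × 7 leaves ≈ 360 splits, ~0.45·m for a
local fit — exported as `DESK_GBDT_PARAMS` (≈20% of SNPs kept on the
standard fixture). A GBDT fitted to pure noise still spends its split
budget and reports positive gains, so a signal-free chromosome's kept set
is smaller and far lower in total gain than a signal-bearing one, but never
empty.

Baselines with the same fit-on-train/apply-anywhere contract: GWAS
selection keeps scan p < 0.01; PCA keeps the smallest leading set of
components whose cumulative explained variance exceeds 98%, centring
with training-row means.

## Network and training

Architecture (full scale): nonlinear path 4096/2048/1024 with ReLU; linear
path input→1024; outputs summed; trait head 4096/2048/1 (ReLU on the first
two layers); embedding head 4096/2048/1024. No dropout or normalisation
layers. Initialisation is seeded fan-in He-style for rectified layers and
1/√fan_in for linear ones. The width multiplier `scale` applies
ceil(scale·d) to every hidden width (trait output stays 1); scale 0.125
gives 512/256/128, scale 0.03125 gives 128/64/32. Forward and backward
passes are written directly on numpy arrays; the backward pass is verified
against central finite differences to ~1e-7 relative error.

Training: Adam (β₁ 0.9, β₂ 0.999, ε 1e-8); each epoch re-draws a seeded
derangement pairing (every sample appears exactly once as a pair's first
member; no self-pairs); both pair members pass through the shared weights
simultaneously and gradients accumulate. The contrastive reference `diff`
is computed on standardized phenotypes — the same scale as the MSE targets.
λ defaults to 1 (unweighted sum of the three components); λ = 0 yields the
single-task ablations. Epochs are fixed (no early stopping). A non-finite
loss aborts with a diagnostic. Grid search evaluates candidate learning
rates {0.01, 0.001, 0.0001}, batch sizes {16, 32, 64} and epochs
{20, 50, 100} on the first fold's internal train/validation split only,
picking the highest validation PCC (ties: lower learning rate, then smaller
batch; diverged configs rank last).

## Evaluation protocol

`make_cv_plan` builds 10-fold CV repeated with partition seeds 42/84/162
(30 cells); each outer-training set is split 80/20 into internal
train/validation. Standardizer, selection and model are fitted on internal
training rows only; validation rows are monitored; metrics (PCC, MSE,
Spearman with average-rank ties) are computed per test fold on the
standardized scale and averaged over folds (per-fold-then-average, which is
what paired t-tests over cells require). Model comparisons use two-tailed
paired t-tests over identical (repeat, fold) cells with BH-FDR adjustment
and the conventional */**/*** star thresholds; zero-variance differences
report the smallest representable positive p with a warning. Ridge
regression (marker-effect style) and a LightGBM regressor serve as
comparator stand-ins. A `leakage_audit` re-runs any cell with test-fold
phenotypes and genotypes replaced by garbage and asserts bit-identical
standardizer, selection and trained parameters.

The SNP-position experiment applies one global column permutation (values
and snp_ids move; chrom/pos slots stay), preserving each sample's multiset
of codes while scrambling positional identity.

## Attribution

Permutation-sampling Shapley values: per explained row, a fixed set of
(background row, feature permutation) draws — shared across rows so scores
are independent of row order — switches features one at a time from
background to the row's values; prediction increments are credited to the
switched feature and averaged. Per-row attribution sums telescope exactly
to prediction − mean background prediction. Default 16 draws per row,
background of 100 training rows, both seeded. For a linear model the
attribution reduces to wⱼ(xⱼ − mean background) exactly. Per-SNP importance
is the mean absolute attribution over the explained rows; the top 5% of
SNPs are mapped to genes whose ±100 kb window (inclusive at both ends;
distance 0 inside the gene) covers the SNP position, from gene features of
a GFF3 file.

## Desk-scale run sizes

All experiments in the test suite and the acceptance script are sized for a
single CPU: network scale 0.03125 (128/64/32), 15–20 epochs, batch 64,
learning rate 0.001, the desk selector budget above; the ablation runs
1 repeat × 10 folds, the shuffle comparison the full 3 × 10; the leakage
audit uses a subset of cells per strategy at 3 epochs (the property checked
is exact, not statistical). The acceptance script uses 1 repeat × 5 folds
for its CV block. These sizes are the package's stated desk-scale study
conditions; widening them changes precision, not the definitions.

## Known limitations

- **Directional claims that hinge on chromosome-level architecture do not
  transfer to this generator.** Because causal SNPs are placed uniformly
  and epistatic partners are paired at random, the chromosome grouping
  carries no concentrated signal. Measured consequences on the standard
  fixture: per-chromosome (local) selection adds noise-chromosome features
  and the global-only ablation variants score slightly *higher* mean PCC
  than the full model; column-shuffling does not degrade — and can
  improve — test accuracy, because shuffling breaks LD redundancy inside
  local fits. On real crop panels, where trait signal is chromosome- and
  block-structured, the published direction of these effects is the
  opposite; passing or failing these synthetic directional checks therefore
  says little about real data, and the corresponding acceptance assertions
  document the generator's behaviour honestly rather than being calibrated
  to agree.
- The contrastive benefit measured here (held-out embedding-distance/|Δy|
  alignment, and small PCC effects) is at the small-sample end; the
  mechanism is expected to strengthen with larger panels offering richer
  pairwise relationships.
- The GWAS scan is PC-adjusted OLS, not a mixed model; GRM is VanRaden
  method 1 only; REML is single-component.
- Network training is CPU numpy: full-scale widths (scale 1.0) are
  supported but not practical here.
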