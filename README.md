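# clcnet

Contrastive-learning, chromosome-aware genomic prediction for plant
breeding populations.

## The problem

Genomic selection predicts a quantitative trait (or breeding value) of an
individual from genome-wide SNP markers. Typical plant-breeding panels have
far more markers than individuals (10⁵–10⁶ SNPs, 10²–10⁴ samples), so
prediction models overfit, and most of them ignore two structural facts:
markers live on chromosomes (local linkage-disequilibrium structure), and
the quantity that matters to a breeder is how *pairs* of individuals differ,
not just each individual's point prediction.

`clcnet` implements a multi-task neural framework that addresses both:

1. **Chromosome-aware (CA) SNP selection.** A gradient-boosted tree
   regressor scores every SNP by its total split gain ("information gain"),
   once *within each chromosome* (local) and once *genome-wide* (global).
   SNPs with positive gain in either fit are merged, deduplicated and kept.
2. **A dual-pathway network.** A nonlinear pathway of three fully connected
   ReLU layers (widths 4096/2048/1024 at full scale) is summed with a
   parallel single linear layer at the 1024-dimensional level — a residual
   design that preserves additive marker effects while modelling
   interactions. Two heads follow: a trait head (4096/2048/1) emitting the
   phenotype prediction and an embedding head (4096/2048/1024) emitting a
   per-sample representation.
3. **Paired contrastive training.** Each epoch pairs every training sample
   with a distinct random partner; the loss is

   `L = MSE(ŷ₁, y₁) + MSE(ŷ₂, y₂) + λ · mean[(‖e₁ − e₂‖₂ − |y₁ − y₂|)²]`

   so embedding distances are trained to mirror phenotypic differences.

Around this core the package provides the standard population-genetics
toolkit needed to run and evaluate the method end to end: VCF / matrix
genotype I/O (dosage coding 0/1/2, missing = 3), PLINK-style windowed LD
pruning (window 100, step 10, r² 0.2), LD-decay curves, a VanRaden genomic
relationship matrix with single-component REML heritability (GREML), a
PC-adjusted marginal GWAS scan, GWAS-threshold (P < .01) and PCA (98%
variance) selection baselines, leakage-safe 3×10-fold nested
cross-validation with paired t-tests and Benjamini–Hochberg FDR, ablation
variants, a SNP-position shuffle experiment, and permutation-sampling
Shapley SNP attribution with ±100 kb gene-window annotation. A seeded
synthetic-data generator produces multi-chromosome genotypes with block LD
and traits of exactly controlled heritability for all experiments.

## Worked example

```python
import numpy as np
from clcnet import (standard_config, simulate_dataset, make_cv_plan, run_cv,
                    TrainConfig, compute_grm, reml_h2)
from clcnet.select import DESK_GBDT_PARAMS

# canonical synthetic dataset: 600 samples, 4000 SNPs on 5 chromosomes,
# 40 causal SNPs (25% epistatically paired), h² = 0.7
G, y, truth = simulate_dataset(standard_config())
print(truth.realized_h2)                       # 0.7 (exact by construction)

print(reml_h2(compute_grm(G), y).h2)           # 0.7445 — GREML recovers it

plan = make_cv_plan(len(y), seeds=(42,), n_folds=5)
records = run_cv(G, y, plan, model="clcnet", selection="ca", scale=0.03125,
                 train_config=TrainConfig(epochs=15, batch_size=64),
                 gbdt_params=DESK_GBDT_PARAMS)
print(records["pcc"].mean().round(3))          # 0.414 mean test-fold PCC
```

The printed numbers mean: the simulated trait's realized narrow-sense-style
variance ratio is exactly the 0.7 that was requested; restricted maximum
likelihood on the genomic relationship matrix estimates 0.74 from the data
alone; and the CA-selected contrastive network, trained only on each fold's
internal training split, reaches a mean Pearson correlation of ≈0.41
between predicted and observed phenotypes on untouched test folds at the
desk-scale network width (`scale=0.03125`, i.e. hidden widths 128/64/32).

The same pipeline is scriptable from the shell:

```bash
clcnet simulate --preset standard --out data/
clcnet cv --geno data/sim.geno.tsv --pheno data/sim.pheno.tsv \
          --model clcnet --method ca --scale 0.03125 --epochs 15 \
          --folds 5 --seeds 42 --out cv.tsv
```

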