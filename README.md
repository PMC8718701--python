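# gpcal

Genomic prediction for multi-environment plant-breeding trials, built
around one question: **can a cheap output calibration repair the bias of
a deep-learning genomic predictor?** The package implements three
protocols over the same record-level 5-fold cross-validation and
compares them by mean squared error (MSE):

- **GBLUP** — the mixed model

  `Y_ij = mu + Loc_i + g_j + gL_ij + eps_ij`

  with fixed environment effects, random genomic line effects
  `g ~ N(0, sigma2_g G)`, genomic genotype-by-environment deviations
  `gL ~ N(0, sigma2_gL (I ⊗ G))` and residuals `eps ~ N(0, sigma2)`.
  `G` is the VanRaden genomic relationship matrix
  `G = W W' / (2 Σ p_k (1 − p_k))` computed from 0/1/2 allele counts.
  Variance components are estimated by REML; predictions come from the
  mixed-model equations.

- **DL_M1 (conventional deep learning)** — a multilayer perceptron on
  the concatenated predictor `(X_E, X_G[, X_GE])`, where `X_G` is the
  line incidence post-multiplied by the Cholesky factor of `G` and
  `X_GE` is their row-wise product. Hyperparameters come from the fixed
  eight-point grid (hidden width 1.5× or 3× the input count, 1 or 4
  hidden layers, dropout 0.15 or 0.30, learning rate 0.001, 1,000
  epochs), tuned on an 80/20 split of the training fold and refit on the
  full training fold.

- **DL_M2 (calibrated deep learning)** — tunes one level deeper, refits
  on 64% of the data, then fits an ordinary-least-squares line of the
  *observed* validation values on the *predicted* validation values and
  applies that line to the raw test predictions:
  `y_cal = b0 + b1 * y_hat`. The line undoes affine bias (scale
  compression and offset) in the network's outputs at the price of a
  smaller final training set.

A fully seeded synthetic-trial simulator (independent SNPs under
Hardy-Weinberg, additive marker effects, environment main effects,
genomically structured G×E deviations, Gaussian noise, exact realized
variance components) makes every stage testable without external data.

Intended users: breeders and methods researchers who want a desk-scale,
deterministic benchmark of calibration-style protocols before committing
to large trial datasets and long network training runs.

## Worked example

```python
import numpy as np
from gpcal import (SimConfig, simulate_markers, simulate_trial,
                   genomic_relationship, build_design, make_split_plan,
                   run_gblup_cv, run_dl_m1, run_dl_m2, build_report)
from gpcal.learners import AffineBiasedLearner, RidgeLearner
from gpcal.mlp import HyperParams

cfg = SimConfig(n_lines=120, n_markers=200, n_env=3, h2=0.5, ge_ratio=0.3,
                residual_var=1.0, seed=42)
markers = simulate_markers(cfg)
pheno, truth = simulate_trial(markers, cfg)
rel = genomic_relationship(markers)
design = build_design(pheno, rel, include_ge=True)
plan = make_split_plan(pheno, k=5, seed=42, nested=True)

gblup = run_gblup_cv(pheno, design, plan)
# a deliberately mis-scaled base learner standing in for a biased network
biased = AffineBiasedLearner(RidgeLearner(alpha=1.0), slope=0.6, offset=1.0)
grid = [HyperParams(1.5, 1, 0.15, epochs=1)]
m1 = run_dl_m1(pheno, design, plan, seed=42, learner=biased, grid=grid)
m2 = run_dl_m2(pheno, design, plan, seed=42, learner=biased, grid=grid)

report = build_report([gblup, m1, m2])
print(report.summary.query("environment == 'overall'").to_string(index=False))
```

prints

```
  method environment  mean_mse   se_mse  n_folds
gblup_ge     overall  1.877703 0.085911        5
   dl_m1     overall  3.232375 0.332405        5
   dl_m2     overall  2.058548 0.112313        5
```

Read: the phenotypic variance here is 3.86, so an uncalibrated biased
learner (`dl_m1`, MSE 3.23) barely beats the mean predictor, while the
calibrated protocol (`dl_m2`, MSE 2.06) recovers most of the loss — a
36.3% MSE reduction over `dl_m1` — and GBLUP (MSE 1.88) remains best.
The first fold's calibration line, `intercept = -2.169, slope = 1.971`,
is close to the exact inverse of the injected bias
(`y_hat -> 0.6 y_hat + 1`, inverse slope 1/0.6 ≈ 1.67 plus attenuation
from prediction noise). Swapping the biased learner for the real MLP
(`run_dl_m1(pheno, design, plan, seed=42)`) runs the genuine eight-point
grid at 1,000 epochs.

There is also a CLI: `gpcal simulate`, `gpcal kinship`, `gpcal gblup`
and `gpcal benchmark` (see `gpcal --help`); every run writes a manifest
(config, seed, version) into its output.

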