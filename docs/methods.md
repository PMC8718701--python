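# Methods

## The prediction problem

A multi-environment trial phenotypes a panel of genotyped lines in
several environments. The record-level model is

    Y_ij = mu + Loc_i + g_j + gL_ij + eps_ij

with fixed environment effects (mu and Loc_i are absorbed jointly into
per-environment cell means, so no reference level has to be chosen),
random genomic line effects g ~ N(0, sigma2_g G), genomic
genotype-by-environment deviations gL ~ N(0, sigma2_gL (I ⊗ G)) and
i.i.d. residuals. Cross-validation is record-level: a line held out in
one environment usually remains observed in others, which is the
"sparse trial completion" scenario, not new-line or next-generation
prediction.

## Kinship and the shared predictor blocks

G is the VanRaden estimator W W' / (2 Σ p_k (1 − p_k)), with allele
frequencies estimated from the sample (supplying external frequencies is
possible by constructing `MarkerMatrix`/`GenomicRelationship` manually).
Markers whose estimated frequency is exactly 0 or 1 contribute nothing
to numerator or denominator and are dropped with a warning; if all are,
the denominator is zero and the computation errors. A column constant at
genotype 1 is *not* monomorphic in this sense (p = 0.5): it keeps the
denominator positive and simply contributes zero to W.

G from a finite panel is routinely rank-deficient, so its Cholesky
factor — required to build the genotype block — uses an escalating
diagonal jitter: 0, then 1e-8 × 10^k for k = 0..7, stopping at the first
factorization whose reconstruction error is below 1e-8. The jitter used
is recorded on the object.

The three predictor blocks are: XE, full one-hot environment incidence
(rows sum to 1); XG = Z_L L, the line incidence post-multiplied by the
Cholesky factor, so XG XG' = Z (G + jitter I) Z'; and XGE, the row-wise
Khatri-Rao product of XE and XG in environment-major column order, whose
cross-product realizes the Kronecker covariance I ⊗ G. XGE is built from
the Cholesky-transformed XG (not the raw incidence) so that a ridge
penalty on its coefficients induces exactly the genomic G×E covariance.

## GBLUP by REML

The mixed model is fit in its ridge form y = XE b + XG u + XGE w + eps
with u ~ N(0, sigma2_g I) and w ~ N(0, sigma2_gL I), which is exactly
equivalent to the G-covariance formulation because L carries G. REML
profiles out the residual variance: with ratios l1 = sigma2_g/sigma2 and
l2 = sigma2_gL/sigma2,

    H = I + l1 XG XG' + l2 XGE XGE',
    -2 l_R = (n − p) log(y'Py) + log|H| + log|X'H^-1 X| + const,

evaluated through a dense Cholesky of H per objective call. The search
is over log-ratios: Brent (bounded, log-ratio in [log 1e-10, log 1e6],
tolerance 1e-8) for one random term, Nelder-Mead started at ratios of 1
(objective tolerance 1e-8, at most 500 evaluations) for two. Ratios are
floored at 1e-10 so the equations stay solvable in degenerate fits.
BLUPs and GLS fixed effects follow from the mixed-model equations at the
optimum; predictions are XE b + XG u (+ XGE w) on the test rows.

A Bayesian MCMC fit of the same model targets the same estimands; REML
was chosen because it is deterministic and auditable (the optimum is
testable against perturbed ratio points, and fixed-ratio fits against
closed-form ridge/MME solves). Accuracy is assessed by parameter
recovery on simulated data. Heterogeneous per-environment residual
variances and Bayesian-alphabet priors are out of scope.

## The MLP and its grid

The network is a densely connected feed-forward regressor: equal-width
ReLU hidden layers, inverted dropout after each hidden layer (never on
the input), one linear output unit, MSE loss. The tuning grid is the
fixed Cartesian product {1.5, 3.0} × {1, 4} × {0.15, 0.30} (width
multiplier, hidden layers, dropout) at learning rate 0.001 and exactly
1,000 epochs — eight configurations in multiplier-major order with
dropout varying fastest; ties in selection break toward the earliest
entry, so the order is part of the contract. Hidden width is
round-half-up of multiplier × inputs, floored at 1.

Choices the grid leaves open: optimizer is Adam (beta1 0.9, beta2 0.999)
at the stated learning rate; batch size defaults to 32 (configurable);
weights use Glorot-uniform initialization; inputs and the response are
standardized by training statistics (required for stable training at a
fixed learning rate across trait scales) and predictions are returned on
the trait scale. One `numpy` generator per (data, seed) pair drives
initialization, epoch shuffling and dropout masks in a fixed order, so
training is bit-reproducible. The implementation is a compact numpy
network; there is no GPU path, early stopping or schedule.

## Protocols

`make_split_plan` shuffles records by seed, deals them into k (default
5) folds differing in size by at most one, and splits each training set
80/20 into inner-training and validation; nested plans split
inner-training 80/20 again (so for n records: 80% train, 64%/16%, and
51.2%/12.8% at the inner level). Splits are uniform over records;
stratification by environment was considered and skipped because
balanced trials make the two nearly identical. The protocol text
describing tuning is a single 80/20 split, which is what is implemented;
an inner k-fold tuning loop would be a straightforward extension but is
not provided.

DL_M1: grid-search on inner-training scored on validation, refit the
winner on the full training fold, predict the test fold. DL_M2:
grid-search one level deeper, refit on inner-training (64% of records),
predict validation and test, fit the OLS calibration line of observed on
predicted validation values (closed-form normal equations), apply it to
the test predictions. The line is fitted pooled across environments
within a fold; per-environment calibration would need roughly k times
more validation records per line to be stable and is not implemented.
If the validation predictions are constant the slope is undefined and an
identity line is used with a warning. By OLS optimality the calibrated
validation MSE never exceeds the uncalibrated one; on test data the
benefit holds whenever the learner's bias is stable between validation
and test slices.

Master seeds fan out to per-(fold, stage, config) child seeds via
`numpy` `SeedSequence(entropy, spawn_key)`, so runs are reproducible
end-to-end and adding a grid entry does not shift other streams.

Learners are pluggable (`learner(X, y, hp, seed) -> model` with
`model.predict`). `RidgeLearner` and the `AffineBiasedLearner` wrapper
exist for controlled experiments: the wrapper distorts a base learner's
output by a fixed affine map, the precise failure mode the calibration
line can invert. They are diagnostics, not prediction methods.

## Reporting

MSE is averaged fold-then-mean, never pooled across records first; the
"overall" cell pools each fold's test records across environments before
averaging fold values. Standard errors are SD of the k fold MSEs over
sqrt(k). Percent change between a baseline and a method is
100 (MSE_base − MSE_method)/MSE_base, positive when the method improves;
because the formula is asymmetric both directions and both raw MSEs are
always emitted. Only MSE is reported; correlation metrics are out of
scope.

## The simulator

`simulate_markers` draws per-marker allele frequencies uniformly from
`maf_range` and genotypes as Binomial(2, p) per line — Hardy-Weinberg,
no linkage disequilibrium, no dominance or epistasis, no pedigree.
`simulate_trial` builds g = W beta from centered genotypes and rescales
the effects so the *realized* Var(g) equals

    sigma2_g = h2 * residual_var / (1 − h2 (1 + ge_ratio)),

making Var(g)/(Var(g) + Var(gL) + sigma2) = h2 exactly per dataset
(so, e.g., h2 = 0.4, ge_ratio = 0.5, residual 1 gives components
(1, 0.5, 1) exactly). G×E deviations are per-environment genomic values
W beta_i rescaled to ge_ratio × sigma2_g, matching the I ⊗ G covariance
the mixed model assumes. Environment means default to an equally spaced,
unit-step grid centered at 0. With residual_var = 0 the genetic signal
is put on unit scale instead of collapsing to zero.

What passing tests on this generator do *not* show: robustness to
linkage disequilibrium, unbalanced or selected panels, non-Gaussian
residuals, or learner biases that differ between validation and test
slices. The protocol-benefit results quantify the calibration machinery
under a known, stable affine bias; with a real network the size (and
sign) of the benefit depends on how biased its raw outputs are.

## Problem sizes and numerical notes

Default experiment sizes (300 lines × 3 environments, 20 replicates for
the protocol comparison, 10-20 seeds for REML recovery) were chosen so
the full audit runs in minutes on one CPU while keeping Monte-Carlo
error well inside the stated tolerances. Degenerate inputs are handled
explicitly: all-monomorphic panels error, constant predictions fall back
to identity calibration, variance ratios are floored, an environment
with no training records makes the fixed-effects block singular and
errors. The test suite cross-checks every numerical path against an
independent oracle (hand-computed G, dense mixed-model-equation solves,
closed-form ridge, 2×2 normal equations, analytic binomial moments).
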