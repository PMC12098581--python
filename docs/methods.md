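# Methods

## Scope

`cogmix` implements a two-track clustering analysis for a mixed-type
cognitive assessment battery (50 binary items, 3 attention scores in
[0, 1], 1 nonnegative working-memory span), with a synthetic generator
standing in for participant data. This note records the models, the
estimation choices, what the generator does and does not emulate, and the
numerical conventions.

## Synthetic data generator

**Ages.** A three-component truncated-normal mixture on [4, 16] years with
means (6.5, 10.0, 13.5), SDs (1.1, 1.1, 1.3) and weights (0.27, 0.26,
0.47). The weights were calibrated once so that binning at 8 and 12 years
(left-closed intervals; an age of exactly 8.0 falls in the middle bin)
reproduces a 670 : 821 : 1079 composition in a sample of 2570 — the
instrument's reference cohort proportions. The bin index is centered to
{−1, 0, +1} for covariate use.

**Two-class regime** (`simulate_fmm1`). Class membership follows a
multinomial logistic model on the centered bin code with defaults
gamma0 = −0.048, gamma1 = −0.963 (class 1 vs class 2), i.e. each bin step
multiplies the odds of the lower class by exp(−0.963) ≈ 0.382. Item
responses come from a one-factor measurement model with class-invariant
loadings and thresholds and factor point masses at alpha = (−1.451, 0.657).
Six loadings are pinned to published item estimates (logical items 6/11/12
at 0.73/0.72/0.69, phonological 9 at 0.65, phonological 1/4 at −0.41/−0.21);
the remaining loadings are drawn once from U(0.30, 0.70) and the thresholds
from N(0, 0.5²) with a fixed internal seed, then frozen as package
defaults. Binary items use a logistic link (probit is a switch); the [0, 1]
attention items are `logistic(eta + N(0, 0.5²))` and the span score is
`softplus(eta + N(0, 0.5²))`, guaranteeing their ranges. The working-memory
threshold is set to 1.5 so spans fall in a realistic 0–4 range.

**Multi-profile regime** (`simulate_profiles`). G profiles shift per-item
linear predictors by offset vectors; profile prevalence may differ by age
bin. The default ten-profile bank has a dominant near-average profile whose
prevalence rises 0.44 → 0.48 → 0.54 across bins, one declining
(0.27 → 0.08), one rising (0.07 → 0.21), one flat profile, and six small
profiles sharing the remainder — a structure with both developmental trends
and sub-10-member clusters for exercising the reporting filter.

**What the generator does not emulate:** item-level dependence beyond the
single factor (testlets), the adaptive stopping rule of the span task (the
score is generated directly), response times, and missingness. Passing
recovery tests therefore demonstrates estimator correctness under the
assumed measurement model, not robustness to violations of it.

## Factor mixture track

**Likelihood.** Binary items are Bernoulli with a logistic link in the
factor; continuous items are linear-Gaussian with class-invariant residual
variances. FMM-1 evaluates the within-class likelihood at the degenerate
factor value alpha_k. FMM-2 integrates over N(alpha_k, Psi_k) with
Gauss-Hermite quadrature (21 nodes for one factor, 9 per dimension for two
or three, 2000 fixed Monte-Carlo draws beyond); the quadrature rule is part
of the model definition, making the likelihood an exact finite mixture over
class-by-node components — this keeps EM exactly monotone. Psi_k is
diagonal; factor SDs are bounded to [1e-6, 5] on the log scale, so FMM-2
can collapse numerically onto FMM-1.

**EM.** Generalized EM with three M-step blocks per iteration: (1) the
concomitant multinomial logistic coefficients (L-BFGS-B on the aggregated
expected complete-data likelihood, box-capped at ±15 with a warning under
separation), (2) thresholds/loadings/residual variances via vectorized
damped Newton on per-item aggregated sufficient statistics, (3) class
factor means (and log-SDs for FMM-2) via damped Newton with a
positive-semidefinite curvature approximation. Every Newton step backtracks
on the Q-function, so the observed log-likelihood never decreases (tested
at 1e-8 slack). Convergence: relative log-likelihood change below 1e-6,
max 500 iterations, 10 restarts by default (k-means-on-responses
initialization plus random perturbation). Classes are relabeled so the
first-factor means ascend — "class 1" is always the lower-performing
profile — and the covariate coefficients are refit after relabeling.

**Identification.** FMM-1: mixture-weighted mean of the class factor means
fixed to 0 and weighted second moment to 1 per factor; FMM-2: weighted mean
0 with the largest-magnitude loading per factor anchored to 1. Both are
applied as likelihood-invariant reparameterizations each iteration. Because
the latent metric is only identified up to an affine map, recovery tests
align estimates to the generating scale by regressing fitted loadings and
threshold shifts on the true ones (`align_alpha`); only the 50 binary items
enter this regression, since the continuous items are generated through
squashing transforms that the linear-Gaussian measurement part only
approximates.

**Baselines and the ladder.** The LCA baseline is class-conditional
Bernoulli/Gaussian with class-specific means and *pooled* (class-invariant)
continuous variances — the same continuous error model the FMMs use, so the
ladder compares like with like; with class-specific variances the LCA would
absorb the generator's squashing nonlinearity and dominate on data truly
generated from a factor mixture. The FA baseline is one-class
full-information factor analysis (Bock-Aitkin EM over the same quadrature).
Baselines are fitted without the covariate; the FMMs include it. The ladder
fits LCA over the class grid and FA over the factor grid, bounds the FMM
grids by the baseline BIC optima, and the BIC minimizer among converged
fits wins; non-converged cells are flagged and excluded. Parameter counts
subtract the identification constraints described above.

At n = 2570 FMM-2 (K=2, F=1) can edge out FMM-1 by a fraction of a BIC
point: the free within-class variance soaks up a little of the
continuous-item misspecification. The two solutions are substantively
identical (fitted Psi near zero); at n = 1000 the ladder selects FMM-1 in
9/10 seeded replicates.

**Expected response profiles.** For an FMM-1 fit, class k's expected
response on item j is `logistic(tau_j + lambda_j alpha_k)` for binary
items; continuous items report the linear predictor clipped to their range.
The class gap on an item is monotone in its loading, so positive-loading
items favor the upper class and negative-loading items reverse.

## CGMVAE track

**Architecture.** Encoder: `[x, c]` (54 features + 3-bin one-hot) through
two fully connected blocks (linear → ReLU → batch norm) into three heads —
mixture logits (softmax), component means and log-variances of shape
(batch, K, D), log-variances clipped to [−8, 8]. Latent sample: per-
component reparameterization `z_k = mu_k + sigma_k ⊙ eps`, aggregated by
the membership weights. Decoder mirrors the encoder on `[z, c]` with a
sigmoid output head; the span score is max-normalized to [0, 1] in
preprocessing (a linear head is available as an option). Depth (two blocks)
is a package choice; it is configurable.

**Objective.** Reconstruction is mean squared error. The KL between the
mixture posterior and the learnable mixture prior has no closed form; the
standard GMVAE bound is used — the q(y)-weighted component-wise Gaussian KL
plus the categorical KL of q(y) against a uniform component prior. This is
the largest modeling judgment in the package. Free bits floor the
*per-latent-dimension* Gaussian KL (batch-averaged) at `free_bits`; the
categorical term is not clamped. Total = recon + beta · (Σ_d clamped_d +
KL_cat), verified to 1e-6 at every evaluation.

**Training.** Hand-rolled Adam (beta1 0.9, beta2 0.999) with weight decay
added to the gradient, global-norm gradient clipping, reduce-on-plateau
(factor 0.5, patience 5) on validation total loss, 80/20 train/validation
split stratified by age bin, best-validation weights checkpointed.
Gradients come from reverse-mode automatic differentiation (`autograd`) on
the NumPy forward pass; everything is seeded and deterministic on one
device. Divergence (non-finite loss) aborts with diagnostics. Defaults
mirror the selected full-scale configuration (hidden 201, latent 58,
K = 10, beta 0.051, free bits 0.048, lr 9.68e-4, weight decay 4e-5, clip
0.644); desk-scale runs shrink hidden/latent sizes and train for 30–80
epochs, which completes in seconds to a minute on one CPU.

**Hyperparameter search.** Seeded random search over latent_dim ∈ [4, 64],
K ∈ [2, 15], lr log-uniform [1e-4, 1e-2], free_bits ∈ [0.01, 0.2],
minimizing best validation loss; the winning configuration is retrained on
the full dataset.

**Inference.** Memberships are q(y | x, c); hard labels break ties toward
the lowest component index. Latent features are the deterministic
q-weighted posterior means (no sampling), chosen so downstream metrics are
reproducible.

## Cluster quality and profiling

Silhouette, Calinski-Harabasz and Davies-Bouldin are implemented from their
definitions with Euclidean distances and verified against an independent
reference implementation to 1e-9 on randomized instances; singleton-cluster
silhouette is 0 by convention, and degenerate geometry (zero within-cluster
scatter, coincident centroids) yields an infinity sentinel plus a flag
rather than an exception. Xie-Beni uses fuzzifier m = 2 with centroids
computed from the memberships (externally supplied centroids are accepted);
partition entropy uses the natural log, so its maximum is ln K. The FMM
solution is scored in its latent factor space using posterior expected
factor scores; the CGMVAE in its latent embedding with fuzzy indices on the
membership matrix.

Cluster profiles are per-item z-scores of cluster means against the global
mean and sample SD (n−1), computed on raw responses (not embeddings), where
the narrative bands |z| ≥ 0.2 / 0.5 / 1.0 ("slight/moderate/severe") are
presentation only. Zero-variance items get z = 0 with a flag. Clusters with
fewer than 10 members are excluded from interpretation but retained in
counts; the filter is inclusive at exactly 10 and idempotent. Age-bin ×
cluster tables normalize within bins.

## Problem sizes

Recovery and selection studies run at n = 2500 (recovery, 5 restarts),
n = 1000 × 10 replicates (ladder selection, 2 restarts), and n = 2000
(CGMVAE with D = 8, K ∈ {4, 10}, 30–60 epochs, 5 seeds); the analysis
scripts use n = 2570. These sizes give stable estimates for every quantity
reported while keeping a full reproduction run in the minutes range on a
single CPU.

## Known limitations

- FMM variants with class-specific thresholds or loadings (measurement
  non-invariance) are out of scope, as are standard errors and bootstrap
  likelihood-ratio tests.
- FMM-2 uses diagonal within-class factor covariances; correlated-factor
  classes are not representable.
- The CGMVAE mixture-prior KL is an upper bound, not the exact mixture KL.
- Validity indices on model-derived spaces reward the model's own geometry;
  the near-perfect FMM separation in factor space partly reflects that the
  space is built from two point masses.
- The generator's continuous items are intentionally non-Gaussian
  (squashed); estimators treating them as linear-Gaussian carry a small,
  documented bias that the binary-item alignment sidesteps.
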