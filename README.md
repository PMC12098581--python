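# cogmix

Two-track clustering of cognitive profiles from a 54-item game-based
assessment battery: classical **factor mixture modeling** (FMM) with a
binned-age covariate, versus a **conditional Gaussian-mixture variational
autoencoder** (CGMVAE). The package is aimed at psychometricians and
methodologists who want to compare parsimonious latent-class solutions with
deep, fuzzy clustering on the same mixed binary/continuous item data — and
at anyone who needs the individual building blocks: a schema-faithful
synthetic item-response generator, mixed-outcome EM estimation, a GMVAE with
a learnable mixture prior, and the crisp/fuzzy cluster validity index
battery.

## The models

**Track 1 — factor mixture models.** Person *i* in latent class *k* answers
binary item *j* with probability

    P(y_ij = 1 | class k) = logistic(tau_j + lambda_j' eta_i),

with continuous items linear-Gaussian in the same factor. Thresholds
`tau` and loadings `lambda` are class-invariant. In **FMM-1** the
within-class factor covariance is fixed at zero, so classes differ only in
their factor mean `alpha_k`; **FMM-2** frees the within-class factor
variance `Psi_k` (integrated by Gauss-Hermite quadrature). Class membership
depends on the centered age-bin code `c ∈ {-1, 0, +1}` through multinomial
logistic regression `logit P(class 1 vs 2) = gamma_0 + gamma_1 c`, updated
inside the EM M-step. A stepwise ladder (LCA baselines over classes, FA
baselines over factors, then the FMM grids) selects the winner by BIC.

**Track 2 — CGMVAE.** An encoder maps `[x, c]` (responses + one-hot age
bin) to mixture probabilities `q(y = k | x, c)` and per-component Gaussian
parameters; latent samples `z_k = mu_k + sigma_k ⊙ eps` are aggregated as
`z = Σ_k q_k z_k` and decoded together with `c`. The prior is a learnable
Gaussian mixture. Training minimizes

    MSE(x, x̂) + beta · ( Σ_d max(free_bits, KL_d) + KL(q(y) ‖ uniform) ),

with Adam, weight decay, global-norm gradient clipping and a
reduce-on-plateau schedule. Fuzzy memberships are `q(y | x, c)`; hard labels
their argmax.

Both solutions are scored with Silhouette, Calinski-Harabasz and
Davies-Bouldin (crisp) plus Xie-Beni, fuzzy partition coefficient and
partition entropy (fuzzy), and interpreted through per-cluster per-item
z-scores against the global statistics, with an n ≥ 10 reporting filter.

No participant data ships with the package: a synthetic generator emulates
the instrument (six subtests — logical reasoning, visuospatial attention,
motion perception, phonological awareness, verbal comprehension, working
memory — 54 items, trimodal ages on [4, 16] binned at 8 and 12 years), in a
two-class one-factor regime for Track 1 and a ten-profile regime with
age-varying prevalence for Track 2.

## Worked example

```bash
python analysis/01_simulate.py    # writes datasets under scratch/
python analysis/02_fit_fmm.py     # model ladder -> results/fmm_ladder.csv
python analysis/03_fit_cgmvae.py  # CGMVAE training -> results/cgmvae_history.csv
python analysis/04_evaluate.py    # validity indices -> results/cluster_quality.json
python analysis/05_profile.py     # z-score profiles -> results/cluster_zscores.csv
```

At n = 2570 the ladder run prints (abridged):

```
winner: FMM2 K=2 F=1 (BIC=154067.97)
class proportions: [0.4593 0.5407]
age covariate: gamma1=-1.021 -> OR 0.360 (-64.0% odds of class 1 per bin step)
largest class-2 advantage: working_memory_1 (+1.03), logical_12 (+0.35), ...
reversed items (class 1 higher): phonological_1 (-0.19), phonological_4 (-0.10)
```

The generating slope was −0.963 (OR 0.382): each age-bin step roughly
halves the odds of landing in the lower-performing class 1, and items with
negative loadings reverse the class gap. The free-variance FMM-2 edges out
FMM-1 by 0.4 BIC at this n (they tie in substance — the fitted `Psi` is
near zero); at n = 1000 the ladder selects FMM-1 K=2 F=1 in 9/10 replicates.
The evaluation step prints the methodological trade-off in one table:

```
solution         space  K  silhouette  calinski_harabasz  davies_bouldin  xie_beni   fpc  partition_entropy
     FMM    fmm_factor  2       0.996        2003889.053           0.006       NaN   NaN                NaN
  CGMVAE cgmvae_latent 10       0.020             80.641           3.380    44.946 0.103              2.286
```

— the two-class EM solution is essentially perfectly separated in its
factor space, while the ten-component CGMVAE memberships are highly fuzzy
(FPC near 1/K, partition entropy near ln 10), trading crispness for
granularity.

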