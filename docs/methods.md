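# Methods

`survaug` trains a pair of variational autoencoders over two paired tabular
omics modalities, aligns their latent spaces, imputes the scarcer modality
from the richer one, and folds those imputations — filtered by their task
loss and drawn fresh each step — into the training of a discrete-time
neural survival model.  This note records the model, its assumptions, the
parameters that matter, the numerical choices, and what the synthetic
benchmark does and does not demonstrate.

## Model and training procedure

**Modality VAEs.** Each modality (A, the complete one, e.g. DNA
methylation; B, the one with missing rows, e.g. gene expression) gets a
fully connected VAE.  Encoder hidden widths halve from the input dimension
layer by layer, then map to a Gaussian posterior `(mu, log sigma^2)`; the
decoder mirrors the encoder and ends in a sigmoid because all features are
min-max scaled to [0, 1] from training-split statistics.  Losses:

- reconstruction `L_recon = mean((X - X_hat)^2)` over samples and features
  (mean squared error; the magnitude of reported cross-modal losses on
  [0, 1]-scaled data only makes sense under a mean-square convention);
- `L_KL`, the analytic Gaussian KL to the standard-normal prior, averaged
  over samples;
- the cross-modal loss `L_CM = mean((X_B - Dec_B(Enc_A(X_A)))^2)` over
  ID-paired rows, gradient reaching the B decoder only (the A VAE is
  frozen).

**Cyclic KL annealing.** Small tabular datasets trained as VAEs are prone
to posterior collapse.  The KL weight follows a cyclic schedule: with cycle
length `C = ceil(total_epochs / n_cycles)` and phase
`tau = (epoch mod C)/C`, the weight is
`kl_weight * min(1, tau / ramp_fraction)` — a linear ramp over the first
half of each of 4 cycles by default, plateauing at the configured weight
(A: 1e-3, B: 1e-4 by default).

**Training order and stopping.** The A VAE trains first on
`L_recon + beta(epoch) L_KL` and its checkpoint is the epoch with the best
validation reconstruction among epochs whose validation KL exceeds 1e-6
(best reconstruction subject to a non-collapsed posterior).  It is then
frozen — bit-identical through every downstream stage.  The B VAE trains on
`L_recon + beta L_KL + cm_weight L_CM` (cm_weight 0.6, the middle of the
useful 0.4–0.8 range) and its checkpoint minimises validation `L_CM`, since
cross-modal translation quality is what imputation uses.

**Adversarial alignment (optional).** A 4-layer MLP discriminator scores
latent vectors, labels 1 for A and 0 for B, with the least-squares (LSGAN)
objective: `L_Disc = mean((D(z_A)-1)^2) + mean(D(z_B)^2)`, and the
encoder-side `L_adv = mean((D(z_B)-1)^2)` back-propagating only through the
B encoder.  The first 100 of 400 epochs (warm-up) train the B VAE alone;
afterwards each epoch runs, in order, a VAE step, a discriminator step with
the VAE frozen, and an encoder step with the discriminator frozen.
Discriminator latents are posterior means — sampled latents would add
variance to an already delicate game.  Discriminator widths halve from the
latent dimension with a floor of 8; its learning rate is 5e-5 against the
VAE's 1e-4 at full scale.

**Imputation and label carry-over.** For every A sample without a B row,
`X_hat_B = Dec_B(Enc_A(X_A))` using the deterministic posterior mean, so
imputations are reproducible.  The survival outcome (time, event) is copied
verbatim from the A-side sample; continuous labels are never imputed.

**Discrete-time survival predictor.** The prediction head is an MLP from
the B feature space to J = 30 per-interval conditional survival
probabilities (one-year intervals; sigmoid outputs).  An event in interval
k contributes `-(sum_{j<k} log s_j + log(1 - s_k))`; a subject censored in
interval k contributes `-sum_{j<=k} log s_j`.  Probabilities are clamped to
[1e-7, 1-1e-7] before logs.  Events beyond 30 years clamp into the final
interval.  The checkpoint maximises the time-dependent concordance index
(C_td) on validation.

**Oversampling augmentation.** In the oversampling variants every gradient
step pairs the real batch (size `bs`) with a fresh batch of `bsOV` A-train
samples drawn with replacement, imputed, and filtered to rows whose current
per-row task loss is strictly below the threshold `t`; the surviving rows'
loss enters the step with weight `gamma` in [0, 1].  Both `bs` and `bsOV`
are per-step batch sizes; with `gamma = 0` the parameter trajectory is
bit-identical to the unaugmented run (the oversampling draws live on their
own RNG stream).  If a step's entire imputed batch is filtered away, the
step proceeds on real data alone.  Methods without oversampling but with
imputation (the deterministic-translator baseline and the adversarial
variant without OV) instead train on the shuffled union of real and
once-imputed rows.  The plain oversampling baseline resamples real B rows
(a switch to resample from the imputed pool exists, since the source pool
for that baseline is ambiguous in the original description).

**Method grid.** `multisurv` (no augmentation), `ov`, `tdimpute`
(deterministic A→B translator minimising RMSE), `tdimpute_ov`, `cmvae_adv`,
`cmvae_ov`, `cmvae_adv_ov`.

## Evaluation

- **C_td**: over pairs (i, j) with `T_i < T_j` and subject i an event, the
  pair is concordant when subject i's predicted cumulative survival at the
  interval containing `T_i` is below subject j's at the same interval; ties
  in predicted survival earn half credit; tied event times are not
  comparable.  With time-constant risks and no censoring this reduces to
  Harrell's C (used as an independent cross-check in the tests).
- **Cross-modal loss on the test set**, with per-sample values retained for
  signed-rank comparisons.
- **Mean-feature Pearson correlations**: between the test-set B mean
  feature vector and (i) the mean imputed vector, and (ii) the mean of
  decoded standard-normal draws.  The latter probes whether the decoder
  preserves data structure for inputs far from any training sample — the
  advantage of a regularized latent space over a deterministic AE.  The
  number of prior draws defaults to the test-set size so both means average
  comparable counts.
- **Percentile bootstrap** (default 1000 resamples of test subjects at full
  scale; 200 in the desk profile) for C_td intervals; failed replicates
  (e.g. a resample without comparable pairs) are redrawn, at most 10 times.
- **One-sided Wilcoxon signed-rank**: exact null for n <= 25 without ties,
  tie/continuity-corrected normal approximation otherwise; zero differences
  dropped; error when every difference is zero.  Two pairing units are
  used and never mixed: per-sample cross-modal losses on the common test
  set, and bootstrap replicates paired by index (every method is scored on
  the same resampled test sets, which is what makes the signed-rank pairing
  valid).

## Synthetic data generator

The generator emulates a paired bulk-omics extract with survival outcomes:
`z ~ N(0, I_k)` shared factors (k = 4), loadings drawn once per seed with
scale 1.0, features `X = zW + noise` (noise sd 0.1 per modality by
default), exponential event times with rate
`baseline_hazard * exp(z . hazard_coefs)` and independent exponential
censoring.  Defaults `baseline_hazard = 0.06/yr`, `censor_rate = 0.04/yr`,
`hazard_coefs = [0.8, -0.6, 0.4, -0.2]` give roughly 60% events and a
median survival near 12 years — inside the 30-year prediction window, with
realistic censoring.  A categorical stratum (3 levels) stands in for cancer
type: it drives stratified splitting and per-stratum missingness but has no
hazard effect of its own, since no per-stratum hazard parameters are
published for the reference setting.  Modality-B rows are removed
completely at random, per stratum with rounding, within train+val only —
the test split is always complete.  Times are generated in continuous years
and discretized downstream, keeping the generator independent of the
30-interval choice.

What this generator does **not** emulate: non-linear factor structure,
batch effects, heavy-tailed count noise, informative missingness, or the
inter-cancer heterogeneity of real pan-cancer data.  Passing directional
benchmarks on it therefore shows that the pipeline's machinery behaves as
designed (alignment improves imputation; regularization preserves decoder
structure; oversampled imputation adds signal in low-data regimes), not
that the same effect sizes would appear on real omics.

## Desk-scale benchmark conditions

The full-scale profile (400 epochs, learning rates 1e-4 / 5e-5 / 1e-5,
latent 32, dimensions 5000/1000) is preserved as `paper_scale_config`.  The
default desk profile scales every stage to minutes on one CPU while keeping
the protocol:

- n = 1500 samples, d_A = 60, d_B = 30, latent 8, 3 encoder layers for A
  and 2 for B (halving must stay above the latent width);
- 300 VAE epochs at learning rate 1e-3; 150 predictor epochs at 3e-4;
- bs = bsOV = 32, t = 3.0 (a generous bound given per-subject negative
  log-likelihoods of ~0.5 for typical censored rows and ~2–3 for events),
  gamma = 0.5;
- test fraction 0.1; validation 40% of the remainder.  The enlarged
  validation share is deliberate: at 90% missingness a 10% validation split
  of a desk-sized cohort leaves a handful of B rows, and a concordance
  index on so few subjects is too quantized to select checkpoints or
  compare methods.  Real-scale cohorts do not need this (the full-scale
  profile keeps 10%).
- the imputation-recovery benchmark runs larger (n = 2000, d_A = 200,
  d_B = 50, 4% missing) since it trains a single stack.

## Numerical choices and degenerate inputs

- All arithmetic is float64 on a small in-package reverse-mode autodiff
  tape; training is bit-reproducible given a seed, and every stage's seed
  derives from one global seed via `SeedSequence`.
- Optimizer: Adam (beta 0.9/0.999, eps 1e-8) everywhere.
- Min-max scaling maps degenerate (constant) training features to 0;
  values outside the training range are not clipped.
- Variance ties in top-variance feature filtering break by first
  occurrence; column order is preserved.
- The task-loss threshold is a strict `<`: `t = 0` keeps nothing,
  `t = inf` keeps everything.
- Survival probabilities are clamped at 1e-7 from both ends before logs;
  observed times at or beyond the horizon fall into the last interval.
- The LSGAN label assignment follows the operational description
  (discriminator: A→1, B→0; encoder step with labels swapped); the A-side
  term is a constant with respect to the only trainable network in the
  encoder step and is omitted there.

## Known limitations

- Adversarial training at desk scale is stabilised only by warm-up and the
  LSGAN objective; no gradient penalty or spectral normalisation.  The
  discriminator score gap oscillates, and the recorded history shows dips
  rather than monotone shrinkage.
- The oversampling baseline pool ambiguity (real vs imputed B rows) is
  resolved by a flag, defaulting to real rows.
- Checkpoints store raw weight arrays; architectures must match exactly on
  load.
- No competing risks, no Cox objective, no multi-modal prediction inputs:
  prediction always consumes modality B (real or imputed) alone.
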