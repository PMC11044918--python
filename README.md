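# survaug

Cross-modal VAE imputation and oversampling augmentation for survival
prediction on paired tabular omics.

## The problem

Multi-modal biomedical cohorts are rarely complete: a study may hold DNA
methylation for nearly every patient but gene expression for only a
fraction of them.  Discarding incomplete records shrinks an already small
dataset; training on the complete modality alone wastes the paired
structure.  `survaug` is for researchers who want to train a survival
model on the scarcer modality and use the complete one to fill the gaps —
with generated samples that are good enough to *help* the downstream task
rather than pollute it.

## The method

Two modalities A (complete) and B (partially missing) are each modelled by
a fully connected VAE on min-max-scaled features.  The A VAE is trained
first on

```
L_A = ||X_A − X̂_A||² + β(epoch) · KL(q(z|X_A) ‖ N(0, I))
```

with a cyclic KL annealing schedule on β to prevent posterior collapse,
then frozen.  The B VAE adds a cross-modal loss tying its decoder to the
frozen A latent space,

```
L_CM = ||X_B − Dec_B(Enc_A(X_A))||² ,
```

optionally reinforced by an LSGAN discriminator on the two latent
distributions (labels A→1, B→0; the B encoder is trained to fool it).
Missing B rows are imputed as `X̂_B = Dec_B(Enc_A(X_A))` with the survival
label carried over from the A-side sample.

The prediction task is discrete-time survival: an MLP maps B features to
30 per-interval conditional survival probabilities, trained on the
negative log-likelihood.  In the oversampling variants every gradient step
draws `bsOV` A samples with replacement, imputes them, keeps rows whose
current task loss is strictly below a threshold `t`, and adds their loss
with weight `γ`.  Models are selected by the time-dependent concordance
index (C_td) on validation, and compared with percentile-bootstrap
intervals and one-sided Wilcoxon signed-rank tests on shared bootstrap
resamples.

A synthetic generator (shared latent factors, modality-specific noise,
exponential survival with latent-dependent hazard, right censoring,
configurable B-missingness) makes the whole pipeline testable without any
external data.  All networks run on a small in-package float64 autodiff
core, so results are bit-reproducible from a single seed on any CPU.

## Worked example

Ninety percent of modality-B rows removed from train+val; impute from
modality A and compare an unaugmented predictor with oversampled
imputation:

```python
from survaug.pipeline import (desk_scale_config, make_dataset,
                              train_cross_modal, evaluate_imputation,
                              run_method)

cfg = desk_scale_config(seed=0)
ds = make_dataset(cfg, missing_fraction=0.90, seed=0)

models = train_cross_modal(ds, cfg, seed=0)          # VAE A, then VAE B
quality = evaluate_imputation(ds, models["enc_A"], models["dec_B"], seed=0)

baseline  = run_method(ds, "multisurv", None, cfg, seed=0)
augmented = run_method(ds, "cmvae_ov", models, cfg, seed=0)
```

Output:

```
samples: 1500, with modality B: 285
test L_CM: 0.0059  (untrained floor: 0.0625)
PCC(X_B, X_hat_B): 0.890
PCC(X_B, Dec_B(N(0,1))): 0.680
C_td multisurv: 0.730 [0.675, 0.792]
C_td cmvae_ov:  0.756 [0.704, 0.812]
```

Reading: the trained cross-modal pair reconstructs held-out B samples an
order of magnitude better than an untrained pair (`L_CM` 0.0059 vs
0.0625), its imputations track the true mean feature structure
(PCC 0.89), and the decoder still produces structured output from pure
N(0, 1) draws (PCC 0.68) — the payoff of a regularized latent space.
Downstream, oversampled imputation lifts test C_td from 0.730 to 0.756
under 90% missingness (bracketed: 95% bootstrap intervals).

The same workflow is available from the shell:

```
survaug simulate --n 1500 --missing 0.9 --outdir data/
survaug train-vae --data data/ --modality A --outdir models/
survaug train-vae --data data/ --modality B --enc-a models/vae_A --outdir models/
survaug impute --data data/ --enc-a models/vae_A --dec-b models/vae_B --out imputed.tsv
survaug evaluate --data data/ --enc-a models/vae_A --dec-b models/vae_B --out report.json
survaug run-all --seed 0 --outdir results/   # full methods × missingness grid
```

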