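# Methods

## The model

Multichannel EEG is treated as a linear mixture of a small number of latent
source processes: an observed channels-by-time matrix `E` (n × t) is
approximately `M S`, where `M` (n × m) is an unknown mixing matrix and `S`
(m × t) holds m independent latent sources.  Decoding means estimating a
(possibly nonlinear) demixing map from channels to factors.  The package
implements five decoder families that share one contract — fit on pooled
per-time-sample channel vectors, encode a recording into an m × t factor
sequence, reconstruct channels from factors:

* **Autoencoder (AE).**  One hidden layer: `h = f(W₁x + b₁)`,
  `x̂ = g(W₂h + b₂)` with tanh hidden and linear output units (z-scored
  real-valued targets need an unbounded output; the hidden nonlinearity is
  the model's only one).  Encoder and decoder weights are untied.  Trained
  by backprop on mean squared reconstruction error with Adam.
* **Gaussian RBM.**  Gaussian visible units, Bernoulli hidden units, energy
  `E(x,h) = Σᵢ(xᵢ−aᵢ)²/(2σᵢ²) − Σᵢⱼ(xᵢ/σᵢ)Wᵢⱼhⱼ − Σⱼbⱼhⱼ`.  The hidden
  conditional is the logistic `P(hⱼ=1|x) = σ(ΣᵢWᵢⱼxᵢ + bⱼ)` and the visible
  conditional is Gaussian with mean `σᵢΣⱼWᵢⱼhⱼ + aᵢ`; both are verified
  against exhaustive enumeration of the Boltzmann distribution on toy
  models.  Visible scales σᵢ are fixed at 1 because inputs are z-scored.
  Training is contrastive divergence (CD-k, default k = 1) with sampled
  binary hiddens and mean-field visibles, SGD with momentum 0.5.  The
  trained RBM can be unrolled into a sigmoid-hidden autoencoder
  (`W₁ = Wᵀ, b₁ = b, W₂ = W, b₂ = a`) and fine-tuned by backprop; at zero
  fine-tuning epochs the unrolled network reproduces the RBM's mean-field
  reconstruction exactly.
* **VAE.**  Linear Gaussian encoder producing μ and log σ² per latent
  dimension, linear decoder, isotropic standard-normal prior.  The training
  objective is the evidence lower bound with unit observation variance, so
  the likelihood term reduces to `½‖x − x̂‖²` and the KL term has the
  Gaussian closed form `−½Σⱼ(1 + log σⱼ² − μⱼ² − σⱼ²)`.  Latent draws use
  the reparameterization `z = μ + σ⊙ε` with L = 1 Monte-Carlo sample per
  datapoint; both loss terms are logged per epoch.  Encoding at inference
  returns μ — deterministic by construction, which reproducible sequence
  classification requires.
* **ICA / PCA.**  FastICA and PCA (scikit-learn) stored as an
  (unmixing, mixing-back, mean) triple.  ICA keeps 10 independent restarts:
  because ICA orders and scales components arbitrarily, reconstruction is
  scored by the counterpart-matching protocol — each original channel is
  paired with the reconstructed signal of highest Pearson correlation
  (duplicates permitted; ties break to the lowest index; a strict mode
  computes the optimal one-to-one assignment) and matched correlations are
  averaged over the restarts.

The observation unit everywhere is one time sample's channel vector x ∈ ℝⁿ;
temporal context belongs entirely to the sequence classifier.

## Sequence classification

A trial's factor sequence is subsampled at a fixed step (0.25 s default) at
indices `round(k·step·fs)`, giving one ordered sequence of m-vectors per
trial that maps to the trial's single binary label (many-to-one).  The
classifier is an LSTM whose final hidden state feeds a rectified-linear
dense layer and a 2-way softmax, with dropout on the last two layers,
binary cross-entropy loss and RMSprop updates, implemented in NumPy with
exact backpropagation through time (verified against finite differences).
Reference configuration: 200 LSTM units, 100 dense units, batch 50,
dropout 0.5.  Desk-scale synthetic experiments use a proportionally smaller
configuration (8/8 units, batch 10) because the latent dimension is 3 and
each fold holds 30 training sequences.  Two numerical safeguards are config
keys: global gradient-norm clipping (default 5.0) and optional multi-restart
training that keeps the restart with the lowest final training loss —
standard guards against BPTT blow-up and optimization collapse at small
sample counts.  Epochs are capped (default 100; 300 in the desk-scale runs)
with early stopping on a training-loss plateau.  Trials of unequal length
are batched by length, never padded.

Before classification, factor sequences are standardized per factor with
training-fold statistics.  Factors whose pooled training sd is below 1% of
the largest factor sd are dropped first (`min_factor_sd_ratio`): a VAE
routinely prunes excess latent dimensions via the KL term, and rescaling a
collapsed dimension to unit variance would amplify numerical noise into a
subject fingerprint that a small classifier happily overfits — this was
observed directly as isolated fold collapses before the guard existed.

## Evaluation

Reconstruction is scored per channel by Pearson correlation between the
original and the encode→reconstruct signal, averaged over recordings and
subjects; reports carry per-channel values (exportable as heatmap JSON) and
per-subject breakdowns.  Classification is scored by the F1 of the positive
class, `2PR/(P+R)`, preferred over accuracy because trial classes can be
unbalanced; degenerate precision/recall yields 0 with a warning.  Ratings on
a 1–9 scale binarize as >5 positive, <5 negative; exactly 5 is excluded by
default (the alternative — assign negative — is a config option), since a
median rating expresses neither state.

Leave-one-subject-out cross-validation holds each subject out once.  Within
a fold, the decoder is fit on the pooled samples of the training subjects
only, and the sequence standardization and LSTM likewise — the held-out
subject contributes nothing to any training artifact (fold provenance is
recorded and asserted in tests).  Each subject's channels are z-scored with
that subject's own pooled session statistics, so normalization never mixes
subjects.  Folds whose training labels are single-class are skipped with a
warning.  LOSO runs accept multiple seeds and report the mean across seeds.

## Synthetic data

The generator emulates the linear mixing assumption directly: per subject,
`E = M S + ε` with ε i.i.d. Gaussian (sd 0.1 by default).  Sources are AR(2)
processes with a chosen spectral peak (pole radius 0.97), phase-random
sinusoids, or i.i.d. Laplace draws — temporally structured or non-Gaussian
by design, since blind source separation is unidentifiable for i.i.d.
Gaussian sources.  Cross-subject variability: every subject's mixing matrix
is a shared template plus Gaussian perturbations of 0.1× the template scale,
so subjects share structure but differ, making LOSO nontrivial.  Class
structure is an amplitude modulation: positive-class trials multiply one
designated source (the 10 Hz AR(2) by default) by `amplitude_ratio`
(default 2).  Defaults are desk-scale — 4 subjects × 10 balanced trials of
30 s at 128 Hz, 8 channels from 3 sources — so the full pipeline runs in
minutes on one core.

What the generator does **not** emulate: volume conduction from a
biophysical head model, nonstationarity, artifacts (recordings are treated
as pre-cleaned), 1/f background spectra, or rating noise.  Passing tests
therefore show that the pipeline recovers class structure under the linear
mixing model it assumes, not that it attains any particular accuracy on
real recordings.

## Handcrafted feature bank

Per rhythm band (theta 4–8, alpha 8–13, beta 13–30, gamma 30–45 Hz —
conventional boundaries, configurable) and channel: nine time-frequency
features (windowed peak-to-peak mean with 1 s windows, mean square,
variance, the three Hjorth parameters, periodogram peak frequency, peak
density, total power) and nine nonlinear-dynamics features (approximate
entropy with m = 2 and r = 0.2·sd, C0 complexity with a 5× mean-power
spectral threshold, Grassberger–Procaccia correlation dimension, correlation
entropy K2 as the computable stand-in for Kolmogorov entropy, Rosenstein
largest Lyapunov exponent, permutation entropy of order 3, singular-spectrum
entropy with window 20, amplitude-histogram Shannon entropy with 16 bins,
normalized spectral entropy).  All estimator parameters are config keys;
estimators that are undefined on a given series return 0 with a warning so
feature vectors stay finite.  Hemispheric asymmetry uses the 14 homologous
left–right pairs of the standard 32-channel montage and is computed as the
log band-power ratio log(P_L/P_R) — the scale-robust differential-asymmetry
convention; a linear difference is available.  For other montages the
14-pair registry is user-supplied (`registry_for_montage` builds one).
Total dimensionality is 4·n·18 + 56: 2360 for 32 channels, 4520 for 62.

Baselines: an L1-penalized linear SVM (liblinear; squared hinge, the L1
variant liblinear supports) whose zero-weight features are reported as
eliminated, plus random forest (100 trees), k-NN (k = 7), logistic
regression, Gaussian naive Bayes and a 3×100 MLP.

## Numerical and design choices

* Band filtering is a zero-phase forward–backward 4th-order Butterworth;
  phase distortion would corrupt asymmetry and entropy features.
* All neural models are NumPy implementations with hand-derived gradients
  (LSTM gradients validated against finite differences to ~1e-10); every
  fit is bit-reproducible given (data, config, seed).
* AE/VAE training uses per-epoch learning-rate decay (Adam 0.03 ×0.7/epoch;
  RMSprop 5e-3 ×0.85/epoch) so the loss settles onto a plateau within the
  20-epoch, batch-500 budget.
* Pooled-per-fold decoder training is the default (one decoder per LOSO
  fold, fit on all training subjects); per-subject decoders are possible by
  calling the fitters per subject.
* Desk-scale problem sizes throughout the tests and the acceptance script:
  8-channel/3-source datasets, 6 000–20 000 training samples per decoder
  fit, 10 ICA seeds, 3 LSTM pipeline seeds.
* Rating = 5 exclusion, ICA tie-breaking (lowest index), constant-channel
  and constant-series guards, and the collapsed-factor threshold are all
  explicit config surface, logged by the CLI into run manifests.

## Known limitations

* The VAE is linear-Gaussian; it cannot model nonlinearly mixed sources
  (none are generated here).
* The Lyapunov and correlation-dimension estimators use fixed small
  embeddings suited to short windows; they are feature extractors, not
  certified dynamical invariants.
* LOSO F1 on 10-trial subjects is quantized (one flipped trial moves F1 by
  ~0.1), hence the multi-seed averaging in all headline numbers.
* EDF import trusts the file header's sampling rate and channel names; the
  DEAP/SEED-style adapters are import conveniences and deliberately
  untested offline.
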