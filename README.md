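# eegfactors

Latent-factor decoding of multichannel EEG for cross-subject emotion
recognition — and a fully synthetic test bench for it.

Multichannel EEG is modeled as a linear mixture of a few latent brain
sources: an observed channels-by-time matrix **E** (n × t) satisfies
**E ≈ M S**, where **M** (n × m) is an unknown mixing matrix and **S**
(m × t) holds the latent source activations.  The package infers **S** with
five interchangeable unsupervised decoders fit on per-time-sample channel
vectors —

* a one-hidden-layer **autoencoder** (tanh hidden, linear output, Adam),
* a **Gaussian-Bernoulli restricted Boltzmann machine** trained by
  contrastive divergence, optionally unrolled and fine-tuned as an
  autoencoder,
* a **variational autoencoder** maximizing the evidence lower bound
  (closed-form Gaussian KL, reparameterized samples, RMSprop),
* **FastICA** and **PCA** baselines (scikit-learn), with a
  counterpart-matching protocol that resolves ICA's component ordering by
  pairing each original channel with its highest-correlated reconstruction —

and then classifies the decoded factor sequences, subsampled at a fixed
0.25 s step, with a many-to-one **LSTM** (final hidden state → ReLU dense →
softmax, dropout on the last two layers).  Reconstruction is scored by
per-channel Pearson r; classification by the positive-class F1 under
**leave-one-subject-out** cross-validation, where the decoder, sequence
standardization and classifier are fit strictly on the training subjects.
All neural models are NumPy implementations with exact hand-derived
gradients, bit-reproducible given a seed.

Because the affective EEG corpora this methodology targets require
registration, the package ships a synthetic generator that realizes the
mixing model directly: per-subject mixing matrices drawn around a shared
template, AR(2)/sinusoid/Laplace sources, Gaussian sensor noise, and a
class-dependent amplitude modulation of one source so that binary labels
are recoverable in principle.  Every stage of the pipeline is tested
against it offline.  A handcrafted feature bank (per-rhythm time-frequency,
nonlinear-dynamics and hemispheric-asymmetry features; 2360 dimensions for
a 32-channel montage) and the classical baseline roster (L1-SVM, RF, KNN,
LR, NB, MLP) are included for comparison.

Intended users: researchers in EEG decoding / affective computing who want
a transparent, dependency-light reference implementation of this pipeline,
and anyone needing a controlled mixing-model test bench for latent-factor
methods.

## Worked example

```python
import eegfactors as ef

dataset = ef.make_labeled_dataset(ef.SyntheticDatasetConfig(master_seed=1))
config = ef.PipelineConfig(
    decoder="vae", m=3, step_seconds=0.25,
    decoder_params={"epochs": 15, "batch": 500},
    lstm=ef.LSTMConfig(lstm_units=8, dense_units=8, dropout_rate=0.2,
                       batch=10, epochs=300, lr=5e-3, plateau_patience=30,
                       restarts=2),
    seed=1,
)
result = ef.loso_cv(dataset.recordings, dataset.labels, config)
for subject, f1 in result.per_subject_f1.items():
    print(subject, round(f1, 3))
print("mean", round(result.mean_f1, 3))
```

prints (4 synthetic subjects × 10 trials, positive trials doubling one
source's amplitude):

```
s01 0.889
s02 1.0
s03 1.0
s04 1.0
mean 0.972
```

Each row is the F1 achieved on a subject the pipeline never saw during
training; 0.5 is chance.  Values near 1 mean the VAE's latent factors carry
the class-defining amplitude modulation across subjects.  The same run with
permuted training labels lands near 0.5 — the control that the signal is
real.  `examples/` contains this and three more narrated scripts
(decode-and-reconstruct, latent-count sweep, handcrafted features), and the
`eegfactors` CLI exposes the stages (`simulate`, `decode`, `sequences`, `classify`,
`reconstruct-eval`, `features`, `loso`) with run manifests.

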