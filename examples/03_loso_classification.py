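"""Full pipeline: decode latent factors, build sequences, classify with an
LSTM under leave-one-subject-out cross-validation.

Positive-class trials double the amplitude of one latent source; the
pipeline must recover that label from the decoded factor sequences of a
subject it never trained on.  F1 well above the 0.5 chance level means the
latent factors carry subject-transferable class information.
"""

import eegfactors as ef

dataset = ef.make_labeled_dataset(ef.SyntheticDatasetConfig(master_seed=1))
config = ef.PipelineConfig(
    decoder="vae", m=3, step_seconds=0.25,
    decoder_params={"epochs": 15, "batch": 500},
    lstm=ef.LSTMConfig(lstm_units=8, dense_units=8, dropout_rate=0.2, batch=10,
                       epochs=300, lr=5e-3, plateau_patience=30, restarts=2),
    seed=1,
)
result = ef.loso_cv(dataset.recordings, dataset.labels, config)

print("held-out subject F1 (one LOSO fold per subject):")
for subject, f1 in result.per_subject_f1.items():
    print(f"  {subject}: {f1:.3f}")
print(f"mean F1 = {result.mean_f1:.3f}  (0.5 would be chance; the doubled-"
      "amplitude source is recoverable across subjects)")
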