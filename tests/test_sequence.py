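import numpy as np
import pytest

from eegfactors import (
    ConfigError,
    FactorSequence,
    LSTMConfig,
    TrialLabel,
    ValidationError,
    build_sequences,
    predict,
    train_lstm,
)
from eegfactors.sequence import LSTMClassifier, SequenceSample


def _factor_sequence(m=3, t=7680, fs=128.0, seed=0):
    return FactorSequence(
        "s01", "t01", "vae-m3", np.random.default_rng(seed).standard_normal((m, t)), fs
    )


def _label(klass="positive"):
    return TrialLabel("s01", "t01", "predefined", None, klass)


class TestBuildSequences:
    def test_quarter_second_step_on_sixty_second_trial(self):
        seq = _factor_sequence(t=60 * 128)
        sample = build_sequences(seq, _label(), step_seconds=0.25)
        assert sample.n_steps == 240
        assert sample.m == 3

    def test_step_of_one_sample_returns_full_sequence(self):
        seq = _factor_sequence(t=512)
        sample = build_sequences(seq, _label(), step_seconds=1 / 128.0)
        np.testing.assert_array_equal(sample.steps, seq.factors.T)

    def test_label_attaches_to_whole_sequence(self):
        seq = _factor_sequence()
        for klass in ("positive", "negative"):
            assert build_sequences(seq, _label(klass)).label == klass

    def test_step_longer_than_trial_rejected(self):
        seq = _factor_sequence(t=64)
        with pytest.raises(ValidationError, match="exceeds"):
            build_sequences(seq, _label(), step_seconds=1.0)

    def test_excluded_label_rejected(self):
        with pytest.raises(ValidationError, match="excluded"):
            build_sequences(_factor_sequence(), _label("excluded"))

    def test_mismatched_identity_rejected(self):
        bad = TrialLabel("s99", "t01", "predefined", None, "positive")
        with pytest.raises(ValidationError, match="does not match"):
            build_sequences(_factor_sequence(), bad)


class TestLSTMGradients:
    def test_backprop_matches_finite_differences(self):
        cfg = LSTMConfig(lstm_units=5, dense_units=4, dropout_rate=0.0, batch=3,
                         epochs=1, seed=0)
        model = LSTMClassifier(2, cfg)
        rng = np.random.default_rng(1)
        X = rng.standard_normal((3, 7, 2))
        y = np.array([0, 1, 1])
        _, grads = model._loss_and_grads(X, y)
        eps = 1e-6
        for key, P in model.params.items():
            flat = P.ravel()
            probe = np.linspace(0, flat.size - 1, num=min(10, flat.size), dtype=int)
            for idx in probe:
                old = flat[idx]
                flat[idx] = old + eps
                lp, _ = model._loss_and_grads(X, y)
                flat[idx] = old - eps
                lm, _ = model._loss_and_grads(X, y)
                flat[idx] = old
                numeric = (lp - lm) / (2 * eps)
                assert abs(numeric - grads[key].ravel()[idx]) < 1e-7, key


def _separable_samples(n_per_class=12, n_steps=30, m=2, shift=1.5, seed=0):
    rng = np.random.default_rng(seed)
    samples = []
    for k in range(n_per_class * 2):
        klass = "positive" if k % 2 else "negative"
        mu = shift if klass == "positive" else -shift
        samples.append(
            SequenceSample(
                steps=rng.standard_normal((n_steps, m)) * 0.3 + mu,
                label=klass,
                subject_id="s01",
                trial_id=f"t{k:02d}",
            )
        )
    return samples


class TestTrainPredict:
    def test_default_configuration_mirrors_reference_architecture(self):
        cfg = LSTMConfig()
        assert cfg.lstm_units == 200
        assert cfg.dense_units == 100
        assert cfg.batch == 50
        assert cfg.dense_activation == "relu"
        assert cfg.dropout_rate == 0.5

    def test_probabilities_normalize_and_inference_is_deterministic(self):
        samples = _separable_samples()
        cfg = LSTMConfig(lstm_units=6, dense_units=4, dropout_rate=0.3, batch=8,
                         epochs=10, seed=0)
        model = train_lstm(samples, cfg)
        labels1, probs1 = predict(model, samples)
        labels2, probs2 = predict(model, samples)
        np.testing.assert_allclose(probs1.sum(axis=1), 1.0, atol=1e-6)
        assert probs1.shape == (len(samples), 2)
        assert labels1 == labels2
        np.testing.assert_array_equal(probs1, probs2)

    def test_converged_model_memorizes_separable_data(self):
        samples = _separable_samples()
        cfg = LSTMConfig(lstm_units=8, dense_units=6, dropout_rate=0.0, batch=8,
                         epochs=60, lr=5e-3, seed=1)
        model = train_lstm(samples, cfg)
        labels, _ = predict(model, samples)
        from eegfactors import f1_score

        f1, _ = f1_score(labels, [s.label for s in samples])
        assert f1 == 1.0

    def test_training_loss_decreases_on_learnable_data(self):
        samples = _separable_samples()
        cfg = LSTMConfig(lstm_units=8, dense_units=6, dropout_rate=0.0, batch=8,
                         epochs=30, lr=5e-3, seed=2)
        model = train_lstm(samples, cfg)
        assert model.loss_history[-1] <= 0.95 * model.loss_history[0]

    def test_single_class_input_rejected(self):
        samples = [s for s in _separable_samples() if s.label == "positive"]
        with pytest.raises(ValidationError, match="both classes"):
            train_lstm(samples, LSTMConfig(lstm_units=4, dense_units=4, epochs=1))

    def test_dimension_mismatch_rejected(self):
        samples = _separable_samples(m=2)
        cfg = LSTMConfig(lstm_units=4, dense_units=4, epochs=2, batch=8, seed=0)
        model = train_lstm(samples, cfg)
        other = _separable_samples(m=3)
        with pytest.raises(ValidationError, match="dims"):
            predict(model, other)

    def test_training_is_deterministic_given_seed(self):
        samples = _separable_samples()
        cfg = LSTMConfig(lstm_units=4, dense_units=4, dropout_rate=0.4, batch=8,
                         epochs=5, seed=9)
        a = train_lstm(samples, cfg)
        b = train_lstm(samples, cfg)
        np.testing.assert_array_equal(a.params["W"], b.params["W"])
        assert a.loss_history == b.loss_history

    def test_variable_length_sequences_batch_by_length(self):
        samples = _separable_samples(n_steps=20) + _separable_samples(n_steps=35, seed=3)
        cfg = LSTMConfig(lstm_units=4, dense_units=4, batch=8, epochs=3, seed=0)
        model = train_lstm(samples, cfg)
        labels, probs = predict(model, samples)
        assert len(labels) == len(samples)

    def test_invalid_dropout_rejected(self):
        with pytest.raises(ConfigError):
            LSTMConfig(dropout_rate=1.0)


def test_within_subject_classification_of_encoded_factors():
    """Factors encoded from class-modulated synthetic EEG must be learnable:
    a held-out train/test split within subjects reaches F1 >= 0.9."""
    import eegfactors as ef
    from eegfactors.evaluation import drop_dead_factors
    from eegfactors.sequence import sequence_standardizer, standardize_samples

    ds = ef.make_labeled_dataset(ef.SyntheticDatasetConfig(
        n_subjects=2, trials_per_subject=20, trial_seconds=20, master_seed=21))
    normed = ef.zscore_per_subject(ds.recordings)
    X = np.concatenate([r.data.T for r in normed], axis=0)
    vae = ef.fit_vae(X, m=3, epochs=10, batch=500, seed=0)
    index = {(l.subject_id, l.trial_id): l for l in ds.labels}
    samples = [
        build_sequences(ef.encode(vae, r), index[(r.subject_id, r.trial_id)], 0.25)
        for r in normed
    ]
    hold = {"t15", "t16", "t17", "t18", "t19", "t20"}
    train = [s for s in samples if s.trial_id not in hold]
    test = [s for s in samples if s.trial_id in hold]
    train, test = drop_dead_factors(train, test)
    mu, sd = sequence_standardizer(train)
    train, test = standardize_samples(train, mu, sd), standardize_samples(test, mu, sd)
    cfg = LSTMConfig(lstm_units=8, dense_units=8, dropout_rate=0.2, batch=8,
                     epochs=200, lr=5e-3, plateau_patience=25, restarts=3, seed=4)
    model = train_lstm(train, cfg)
    pred, _ = predict(model, test)
    from eegfactors import f1_score

    f1, _ = f1_score(pred, [s.label for s in test])
    assert f1 >= 0.9
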