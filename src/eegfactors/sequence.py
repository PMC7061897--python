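"""Many-to-one LSTM classification of latent factor sequences.

A trial's factor sequence (m x t) is subsampled at a fixed step (0.25 s by
default) into an ordered list of m-vectors; the whole sequence maps to the
trial's single binary label.  The classifier is an LSTM whose final hidden
state feeds a rectified-linear dense layer and a 2-way softmax, with dropout
on the last two layers, binary cross-entropy loss and RMSprop updates —
implemented in NumPy with exact backpropagation through time.  Training is
deterministic given the seed; dropout is disabled at inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import RMSprop, glorot, sigmoid
from .errors import ConfigError, TrainingError, ValidationError
from .io import FactorSequence, TrialLabel

CLASS_TO_INDEX = {"negative": 0, "positive": 1}
INDEX_TO_CLASS = {v: k for k, v in CLASS_TO_INDEX.items()}


@dataclass
class SequenceSample:
    steps: np.ndarray  # (n_steps, m)
    label: str
    subject_id: str
    trial_id: str | None

    def __post_init__(self) -> None:
        self.steps = np.asarray(self.steps, dtype=float)
        if self.steps.ndim != 2 or self.steps.shape[0] < 1:
            raise ValidationError(f"sequence needs >= 1 step, got shape {self.steps.shape}")
        if self.label not in CLASS_TO_INDEX:
            raise ValidationError(f"sequence label must be binary, got {self.label!r}")

    @property
    def n_steps(self) -> int:
        return self.steps.shape[0]

    @property
    def m(self) -> int:
        return self.steps.shape[1]


def build_sequences(
    seq: FactorSequence, label: TrialLabel, step_seconds: float = 0.25
) -> SequenceSample:
    """Sample the factor sequence at equal intervals: indices
    round(k * step_seconds * fs), k = 0, 1, ... strictly inside the trial."""
    if step_seconds <= 0:
        raise ConfigError("step_seconds must be > 0")
    if label.klass not in CLASS_TO_INDEX:
        raise ValidationError(f"cannot build a sequence for label class {label.klass!r}")
    if (label.subject_id, label.trial_id) != (seq.subject_id, seq.trial_id):
        raise ValidationError(
            f"label ({label.subject_id}, {label.trial_id}) does not match "
            f"sequence ({seq.subject_id}, {seq.trial_id})"
        )
    t = seq.n_samples
    if step_seconds * seq.fs >= t:
        raise ValidationError(
            f"step of {step_seconds} s exceeds the trial length {t / seq.fs} s"
        )
    k = np.arange(int(np.ceil(t / (step_seconds * seq.fs))) + 1)
    idx = np.unique(np.round(k * step_seconds * seq.fs).astype(int))
    idx = idx[idx < t]
    return SequenceSample(
        steps=seq.factors[:, idx].T.copy(),
        label=label.klass,
        subject_id=seq.subject_id,
        trial_id=seq.trial_id,
    )


def sequence_standardizer(
    samples: list[SequenceSample],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-factor mean/sd pooled over all steps of the given (training)
    samples; zero sd maps to 1."""
    stacked = np.vstack([s.steps for s in samples])
    mu = stacked.mean(axis=0)
    sd = stacked.std(axis=0)
    return mu, np.where(sd == 0, 1.0, sd)


def standardize_samples(
    samples: list[SequenceSample], mu: np.ndarray, sd: np.ndarray
) -> list[SequenceSample]:
    return [
        SequenceSample(
            steps=(s.steps - mu) / sd,
            label=s.label,
            subject_id=s.subject_id,
            trial_id=s.trial_id,
        )
        for s in samples
    ]


@dataclass
class LSTMConfig:
    lstm_units: int = 200
    dense_units: int = 100
    dense_activation: str = "relu"
    dropout_rate: float = 0.5
    batch: int = 50
    epochs: int = 100
    lr: float = 1e-3
    seed: int = 0
    plateau_tol: float = 1e-3
    plateau_patience: int = 10
    grad_clip: float = 5.0
    restarts: int = 1

    def __post_init__(self) -> None:
        if self.lstm_units < 1 or self.dense_units < 1:
            raise ConfigError("layer sizes must be >= 1")
        if not (0 <= self.dropout_rate < 1):
            raise ConfigError("dropout_rate must be in [0, 1)")
        if self.dense_activation != "relu":
            raise ConfigError("only rectified-linear dense units are supported")


class LSTMClassifier:
    """LSTM(H) -> dense(D, relu) -> softmax(2), many-to-one."""

    def __init__(self, input_dim: int, cfg: LSTMConfig):
        self.cfg = cfg
        self.input_dim = input_dim
        H, D = cfg.lstm_units, cfg.dense_units
        rng = np.random.default_rng(cfg.seed)
        self.params: dict[str, np.ndarray] = {
            "W": glorot(rng, (4 * H, input_dim + H)),
            "b": np.zeros(4 * H),
            "Wd": glorot(rng, (D, H)),
            "bd": np.zeros(D),
            "Wo": glorot(rng, (2, D)),
            "bo": np.zeros(2),
        }
        self.params["b"][H:2 * H] = 1.0  # forget-gate bias
        self.loss_history: list[float] = []

    # -- forward -----------------------------------------------------------

    def _lstm_forward(self, X: np.ndarray, keep_cache: bool):
        B, T, _ = X.shape
        H = self.cfg.lstm_units
        W, b = self.params["W"], self.params["b"]
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        cache = []
        for t in range(T):
            z = np.concatenate([h, X[:, t, :]], axis=1)
            A = z @ W.T + b
            i = sigmoid(A[:, :H])
            f = sigmoid(A[:, H:2 * H])
            g = np.tanh(A[:, 2 * H:3 * H])
            o = sigmoid(A[:, 3 * H:])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            if keep_cache:
                cache.append((z, i, f, g, o, c_prev, tc))
        return h, cache

    def _head_forward(self, hT, masks=None):
        cfg = self.cfg
        h1 = hT if masks is None else hT * masks[0]
        dpre = h1 @ self.params["Wd"].T + self.params["bd"]
        d = np.maximum(dpre, 0.0)
        d1 = d if masks is None else d * masks[1]
        logits = d1 @ self.params["Wo"].T + self.params["bo"]
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        return probs, (h1, dpre, d, d1)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        hT, _ = self._lstm_forward(np.asarray(X, float), keep_cache=False)
        probs, _ = self._head_forward(hT)
        return probs

    # -- backward ----------------------------------------------------------

    def _loss_and_grads(self, X, y_idx, rng=None):
        """Mean binary cross-entropy and exact gradients for one batch of
        equal-length sequences.  ``rng`` enables dropout (training mode)."""
        cfg = self.cfg
        B, T, _ = X.shape
        H = cfg.lstm_units
        hT, cache = self._lstm_forward(X, keep_cache=True)
        masks = None
        if rng is not None and cfg.dropout_rate > 0:
            keep = 1.0 - cfg.dropout_rate
            masks = (
                (rng.random((B, H)) < keep) / keep,
                (rng.random((B, cfg.dense_units)) < keep) / keep,
            )
        probs, (h1, dpre, d, d1) = self._head_forward(hT, masks)
        onehot = np.zeros((B, 2))
        onehot[np.arange(B), y_idx] = 1.0
        loss = float(-np.mean(np.log(probs[np.arange(B), y_idx] + 1e-12)))

        dlogits = (probs - onehot) / B
        grads = {
            "Wo": dlogits.T @ d1,
            "bo": dlogits.sum(axis=0),
        }
        dd1 = dlogits @ self.params["Wo"]
        if masks is not None:
            dd1 = dd1 * masks[1]
        ddpre = dd1 * (dpre > 0)
        grads["Wd"] = ddpre.T @ h1
        grads["bd"] = ddpre.sum(axis=0)
        dh1 = ddpre @ self.params["Wd"]
        dh = dh1 * masks[0] if masks is not None else dh1

        W = self.params["W"]
        dW = np.zeros_like(W)
        db = np.zeros_like(self.params["b"])
        dc = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            z, i, f, g, o, c_prev, tc = cache[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc = dc * f
            dA = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
                axis=1,
            )
            dW += dA.T @ z
            db += dA.sum(axis=0)
            dh = (dA @ W)[:, :H]
        grads["W"] = dW
        grads["b"] = db
        return loss, grads


def _group_by_length(samples: list[SequenceSample]) -> dict[int, list[int]]:
    groups: dict[int, list[int]] = {}
    for k, s in enumerate(samples):
        groups.setdefault(s.n_steps, []).append(k)
    return groups


def train_lstm(samples: list[SequenceSample], cfg: LSTMConfig) -> LSTMClassifier:
    """Train the many-to-one classifier.  Batches group sequences of equal
    length (trials of different lengths never mix in one batch); training
    stops early once the epoch loss plateaus, capped at ``cfg.epochs``.
    With ``cfg.restarts`` > 1 the training is repeated from freshly seeded
    initializations and the model with the lowest final training loss is
    kept — a standard guard against optimization collapse on small sample
    counts.  Deterministic given the config seed."""
    if not samples:
        raise ValidationError("no training sequences given")
    dims = {s.m for s in samples}
    if len(dims) != 1:
        raise ValidationError(f"inconsistent factor dimensions: {sorted(dims)}")
    classes = {s.label for s in samples}
    if len(classes) < 2:
        raise ValidationError(f"training needs both classes, got only {classes}")
    if cfg.restarts > 1:
        candidates = []
        for k in range(cfg.restarts):
            sub = LSTMConfig(**{**vars(cfg), "restarts": 1,
                                "seed": int(np.random.SeedSequence([cfg.seed, k])
                                            .generate_state(1)[0] % (2**31 - 1))})
            candidates.append(train_lstm(samples, sub))
        return min(candidates, key=lambda mdl: mdl.loss_history[-1])
    model = LSTMClassifier(dims.pop(), cfg)
    opt = RMSprop(lr=cfg.lr)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5E9]))
    groups = _group_by_length(samples)
    y_all = np.array([CLASS_TO_INDEX[s.label] for s in samples])
    best = np.inf
    since_best = 0
    for epoch in range(cfg.epochs):
        batches = []
        for _, members in sorted(groups.items()):
            order = rng.permutation(len(members))
            for start in range(0, len(members), cfg.batch):
                batches.append([members[j] for j in order[start:start + cfg.batch]])
        rng.shuffle(batches)
        total, count = 0.0, 0
        for batch_idx in batches:
            X = np.stack([samples[j].steps for j in batch_idx])
            loss, grads = model._loss_and_grads(X, y_all[batch_idx], rng=rng)
            if not np.isfinite(loss):
                raise TrainingError(f"LSTM loss non-finite at epoch {epoch}")
            if cfg.grad_clip > 0:
                norm = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
                if norm > cfg.grad_clip:
                    grads = {k: g * (cfg.grad_clip / norm) for k, g in grads.items()}
            opt.step(model.params, grads)
            total += loss * len(batch_idx)
            count += len(batch_idx)
        epoch_loss = total / count
        model.loss_history.append(epoch_loss)
        if epoch_loss < best * (1.0 - cfg.plateau_tol):
            best = epoch_loss
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.plateau_patience:
                break
    return model


def predict(
    model: LSTMClassifier, samples: list[SequenceSample]
) -> tuple[list[str], np.ndarray]:
    """Deterministic inference: dropout off, argmax of the softmax."""
    if not samples:
        return [], np.zeros((0, 2))
    dims = {s.m for s in samples}
    if dims != {model.input_dim}:
        raise ValidationError(
            f"samples have factor dims {sorted(dims)}, model expects {model.input_dim}"
        )
    probs = np.empty((len(samples), 2))
    for length, members in _group_by_length(samples).items():
        X = np.stack([samples[j].steps for j in members])
        probs[members] = model.predict_proba(X)
    labels = [INDEX_TO_CLASS[int(k)] for k in probs.argmax(axis=1)]
    return labels, probs
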