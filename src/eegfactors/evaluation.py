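"""Reconstruction scoring, classification scoring, and the leave-one-subject-
out (LOSO) cross-validation harness.

Reconstruction quality is the per-channel Pearson correlation between the
original and the encode->reconstruct signal, averaged over recordings and
subjects.  Classification quality is the F1 score of the positive class,
F1 = 2 * precision * recall / (precision + recall), chosen over accuracy
because trial classes can be unbalanced.  LOSO holds each subject out in
turn: the decoder, the per-factor sequence standardization and the LSTM are
fit only on the remaining subjects, and the held-out subject's trials are
scored.  Each subject's channels are z-scored with that subject's own pooled
statistics, so no cross-subject statistics leak into a fold.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import decoders as _dec
from .errors import ConfigError, ValidationError
from .io import Recording, TrialLabel
from .preprocess import apply_zscore, zscore_stats
from .sequence import (
    LSTMConfig,
    SequenceSample,
    build_sequences,
    predict,
    sequence_standardizer,
    standardize_samples,
    train_lstm,
)

# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Centered product-moment correlation; constant input gives 0 with a
    warning rather than NaN."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValidationError("need at least 2 points")
    xc = x - x.mean()
    yc = y - y.mean()
    nx, ny = np.linalg.norm(xc), np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        warnings.warn("constant series in correlation; returning 0", stacklevel=2)
        return 0.0
    return float(np.clip(xc @ yc / (nx * ny), -1.0, 1.0))


def f1_score(
    pred: Sequence[str],
    true: Sequence[str],
    positive_class: str = "positive",
) -> tuple[float, dict[str, int]]:
    """F1 of the positive class plus the confusion counts.  A zero
    denominator (no positive predictions, or no true positives at all)
    yields 0 with a warning."""
    pred = list(pred)
    true = list(true)
    if len(pred) != len(true) or not pred:
        raise ValidationError("prediction/truth length mismatch or empty")
    known = set(pred) | set(true)
    classes = known - {positive_class}
    if len(classes) > 1:
        raise ValidationError(f"more than two label values: {sorted(known)}")
    tp = sum(p == positive_class and t == positive_class for p, t in zip(pred, true))
    fp = sum(p == positive_class and t != positive_class for p, t in zip(pred, true))
    fn = sum(p != positive_class and t == positive_class for p, t in zip(pred, true))
    tn = len(pred) - tp - fp - fn
    counts = {"TP": tp, "FP": fp, "FN": fn, "TN": tn}
    if tp + fp == 0 or tp + fn == 0 or tp == 0:
        if tp + fn > 0 or tp + fp > 0:
            warnings.warn("degenerate precision/recall; F1 set to 0", stacklevel=2)
        return 0.0, counts
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall), counts


def label_binarize(rating, scheme: str = "deap_median5", ties: str = "excluded") -> str:
    """Map a 1-9 rating to {positive, negative, excluded}.

    ``deap_median5``: rating > 5 is positive, < 5 negative; exactly 5 follows
    ``ties`` ("excluded" by default, "negative" optionally).  ``predefined``
    passes an already-binary class string through unchanged.
    """
    if scheme == "predefined":
        if rating not in {"positive", "negative"}:
            raise ValidationError(f"predefined class must be binary, got {rating!r}")
        return rating
    if scheme != "deap_median5":
        raise ConfigError(f"unknown binarization scheme {scheme!r}")
    rating = float(rating)
    if not (1.0 <= rating <= 9.0):
        raise ValidationError(f"rating {rating} outside the 1-9 scale")
    if rating > 5:
        return "positive"
    if rating < 5:
        return "negative"
    if ties not in {"excluded", "negative"}:
        raise ConfigError(f"unknown tie rule {ties!r}")
    return "excluded" if ties == "excluded" else "negative"


# ---------------------------------------------------------------------------
# Reconstruction reports
# ---------------------------------------------------------------------------


@dataclass
class ReconstructionReport:
    model_id: str
    m: int
    per_channel: dict[str, float]
    mean_r: float
    per_subject: dict[str, float]

    def to_heatmap_json(self, path: str | Path) -> Path:
        """Channel label -> mean r, the data behind a topographic heatmap."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(self.per_channel, indent=2))
        return path


def _per_channel_r(model, rec: Recording) -> np.ndarray:
    if isinstance(model, _dec.LinearDecoderModel) and model.kind == "ica" and model.runs:
        return _dec.ica_counterpart_protocol(model, rec)
    recon = _dec.reconstruct(model, _dec.encode(model, rec), rec.channel_labels)
    return np.array(
        [pearson_r(rec.data[i], recon.data[i]) for i in range(rec.n_channels)]
    )


def reconstruction_report(
    model, recordings: Sequence[Recording], heatmap_path: str | Path | None = None
) -> ReconstructionReport:
    """Encode->reconstruct every recording and average per-channel Pearson r
    over recordings, with a per-subject breakdown.  ICA models score through
    the counterpart-matching protocol averaged over their stored restarts."""
    if not recordings:
        raise ValidationError("no recordings to score")
    labels = recordings[0].channel_labels
    acc = np.zeros(len(labels))
    by_subject: dict[str, list[float]] = {}
    for rec in recordings:
        if rec.channel_labels != labels:
            raise ValidationError("recordings have inconsistent channel labels")
        r = _per_channel_r(model, rec)
        acc += r
        by_subject.setdefault(rec.subject_id, []).append(float(r.mean()))
    per_channel = {lab: float(v / len(recordings)) for lab, v in zip(labels, acc)}
    values = np.array(list(per_channel.values()))
    report = ReconstructionReport(
        model_id=model.model_id,
        m=model.m,
        per_channel=per_channel,
        mean_r=float(values.mean()),
        per_subject={s: float(np.mean(v)) for s, v in by_subject.items()},
    )
    if heatmap_path is not None:
        report.to_heatmap_json(heatmap_path)
    return report


# ---------------------------------------------------------------------------
# LOSO cross-validation
# ---------------------------------------------------------------------------

_DECODER_FITTERS = {"ae", "grbm", "vae", "ica", "pca"}


def fit_decoder(kind: str, data: np.ndarray, m: int, seed: int = 0, **params):
    """Uniform entry point over the five decoder families."""
    if kind == "ae":
        return _dec.fit_ae(data, m, seed=seed, **params)
    if kind == "grbm":
        finetune_epochs = params.pop("finetune_epochs", 0)
        model = _dec.fit_grbm(data, m, seed=seed, **params)
        if finetune_epochs:
            return _dec.grbm_unroll_finetune(model, data, epochs=finetune_epochs,
                                             seed=seed)
        return model
    if kind == "vae":
        return _dec.fit_vae(data, m, seed=seed, **params)
    if kind == "ica":
        return _dec.fit_ica(data, m, seed=seed, **params)
    if kind == "pca":
        return _dec.fit_pca(data, m, **params)
    raise ConfigError(f"unknown decoder kind {kind!r}; choose from {_DECODER_FITTERS}")


@dataclass
class PipelineConfig:
    """Everything one LOSO run needs: decoder family and latent count,
    sequence step, LSTM settings, and the master seed."""

    decoder: str = "vae"
    m: int = 3
    step_seconds: float = 0.25
    decoder_params: dict = field(default_factory=dict)
    lstm: LSTMConfig = field(default_factory=LSTMConfig)
    seed: int = 0
    dimension: str = "predefined"
    permute_labels: bool = False
    #: Factors whose pooled training-fold sd falls below this fraction of the
    #: largest factor sd are dropped before standardization.  Collapsed
    #: (KL-pruned) VAE dimensions would otherwise be amplified to unit
    #: variance and act as subject fingerprints rather than signal.
    min_factor_sd_ratio: float = 0.01

    def __post_init__(self) -> None:
        if self.decoder not in _DECODER_FITTERS:
            raise ConfigError(f"unknown decoder {self.decoder!r}")


@dataclass
class FoldResult:
    test_subject: str
    f1: float
    confusion: dict[str, int]
    train_subjects: list[str]
    train_sample_subjects: list[str]
    predictions: list[str]
    truths: list[str]


@dataclass
class CVResult:
    per_subject_f1: dict[str, float]
    mean_f1: float
    folds: list[FoldResult]
    skipped: list[str] = field(default_factory=list)

    def to_table(self) -> "object":
        import pandas as pd

        rows = [{"subject": s, "f1": f} for s, f in self.per_subject_f1.items()]
        rows.append({"subject": "mean", "f1": self.mean_f1})
        return pd.DataFrame(rows)


def drop_dead_factors(
    train_samples: list[SequenceSample],
    test_samples: list[SequenceSample],
    rel_threshold: float = 0.01,
) -> tuple[list[SequenceSample], list[SequenceSample]]:
    """Remove factor dimensions whose pooled training sd is below
    ``rel_threshold`` times the largest factor sd.  Uses training statistics
    only; the same column mask is applied to the test samples."""
    stacked = np.vstack([s.steps for s in train_samples])
    sd = stacked.std(axis=0)
    keep = sd >= rel_threshold * sd.max()
    if keep.all():
        return train_samples, test_samples
    warnings.warn(
        f"dropping {int((~keep).sum())} collapsed factor dimension(s) "
        "before sequence classification", stacklevel=2,
    )

    def _mask(samples):
        return [
            SequenceSample(s.steps[:, keep], s.label, s.subject_id, s.trial_id)
            for s in samples
        ]

    return _mask(train_samples), _mask(test_samples)


def zscore_per_subject(recordings: Sequence[Recording]) -> list[Recording]:
    """Z-score each subject's channels using that subject's statistics pooled
    over all of their trials (each subject normalized independently)."""
    by_subject: dict[str, list[Recording]] = {}
    for rec in recordings:
        by_subject.setdefault(rec.subject_id, []).append(rec)
    out = []
    for recs in by_subject.values():
        pooled = np.concatenate([r.data for r in recs], axis=1)
        mu, sd = zscore_stats(pooled)
        out.extend(apply_zscore(r, mu, sd) for r in recs)
    return out


def _label_index(
    labels: Sequence[TrialLabel], dimension: str
) -> dict[tuple[str, str], TrialLabel]:
    index = {}
    for lab in labels:
        if lab.dimension == dimension and lab.klass != "excluded":
            index[(lab.subject_id, lab.trial_id)] = lab
    return index


def loso_cv(
    recordings: Sequence[Recording],
    labels: Sequence[TrialLabel],
    config: PipelineConfig,
) -> CVResult:
    """One fold per subject; all training artifacts are fit on the remaining
    subjects only.  Folds whose training set is single-class, or whose test
    subject has no labeled trials, are skipped with a warning and recorded."""
    index = _label_index(labels, config.dimension)
    recs = [r for r in recordings if (r.subject_id, r.trial_id) in index]
    subjects = sorted({r.subject_id for r in recs})
    if len(subjects) < 2:
        raise ValidationError("LOSO needs at least 2 subjects with labeled trials")
    normed = zscore_per_subject(recs)
    master = np.random.SeedSequence(config.seed)
    fold_seeds = master.spawn(len(subjects))

    folds: list[FoldResult] = []
    skipped: list[str] = []
    for fold_i, test_subject in enumerate(subjects):
        train_recs = [r for r in normed if r.subject_id != test_subject]
        test_recs = [r for r in normed if r.subject_id == test_subject]
        if not test_recs:
            skipped.append(test_subject)
            continue
        train_classes = {index[(r.subject_id, r.trial_id)].klass for r in train_recs}
        if len(train_classes) < 2:
            warnings.warn(
                f"fold {test_subject}: single-class training data; skipped",
                stacklevel=2,
            )
            skipped.append(test_subject)
            continue
        seeds = fold_seeds[fold_i].generate_state(3) % (2**31 - 1)
        pooled = np.concatenate([r.data.T for r in train_recs], axis=0)
        decoder = fit_decoder(
            config.decoder, pooled, config.m, seed=int(seeds[0]),
            **config.decoder_params,
        )

        def _samples(rec_list, label_lookup):
            out = []
            for rec in rec_list:
                seq = _dec.encode(decoder, rec)
                out.append(
                    build_sequences(seq, label_lookup[(rec.subject_id, rec.trial_id)],
                                    config.step_seconds)
                )
            return out

        label_lookup = dict(index)
        if config.permute_labels:
            rng = np.random.default_rng(int(seeds[2]))
            train_keys = [(r.subject_id, r.trial_id) for r in train_recs]
            klasses = [index[k].klass for k in train_keys]
            perm = rng.permutation(len(klasses))
            for key, j in zip(train_keys, perm):
                orig = index[key]
                label_lookup[key] = TrialLabel(
                    subject_id=orig.subject_id, trial_id=orig.trial_id,
                    dimension=orig.dimension, rating=orig.rating,
                    klass=klasses[j],
                )

        train_samples = _samples(train_recs, label_lookup)
        test_samples = _samples(test_recs, index)
        if config.min_factor_sd_ratio > 0:
            train_samples, test_samples = drop_dead_factors(
                train_samples, test_samples, config.min_factor_sd_ratio
            )
        mu, sd = sequence_standardizer(train_samples)
        train_samples = standardize_samples(train_samples, mu, sd)
        test_samples = standardize_samples(test_samples, mu, sd)

        cfg = LSTMConfig(**{**vars(config.lstm), "seed": int(seeds[1])})
        model = train_lstm(train_samples, cfg)
        pred, _ = predict(model, test_samples)
        truth = [s.label for s in test_samples]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f1, counts = f1_score(pred, truth)
        folds.append(
            FoldResult(
                test_subject=test_subject,
                f1=f1,
                confusion=counts,
                train_subjects=sorted({r.subject_id for r in train_recs}),
                train_sample_subjects=[s.subject_id for s in train_samples],
                predictions=pred,
                truths=truth,
            )
        )
    per_subject = {f.test_subject: f.f1 for f in folds}
    mean = float(np.mean(list(per_subject.values()))) if per_subject else float("nan")
    return CVResult(per_subject_f1=per_subject, mean_f1=mean, folds=folds,
                    skipped=skipped)


def loso_cv_multi(
    recordings: Sequence[Recording],
    labels: Sequence[TrialLabel],
    config: PipelineConfig,
    seeds: Sequence[int],
) -> tuple[float, float, list[CVResult]]:
    """Repeat LOSO over several seeds; returns (mean, sd, results)."""
    results = []
    for s in seeds:
        cfg = PipelineConfig(**{**vars(config), "seed": int(s)})
        results.append(loso_cv(recordings, labels, cfg))
    means = np.array([r.mean_f1 for r in results])
    return float(means.mean()), float(means.std()), results
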