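"""Canonical data model and on-disk formats.

A recording is a channels-by-time real matrix with a JSON sidecar holding the
metadata (channel labels, sampling rate, subject/trial identity).  Latent
factor sequences use the same container.  Trial labels live in a delimited
table.  The array container is a plain ``.npy`` file next to a ``.json``
sidecar with a ``format_version`` field; delimited text is supported for tiny
fixtures, and EDF import (via :mod:`mne`) is an optional adapter.

Time is sample-indexed and 0-based; seconds are always derived via ``fs``.
Readers never reorder channels: the order in the file is the order in memory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

CONTAINER_VERSION = 1

LABEL_DIMENSIONS = ("valence", "arousal", "predefined")
LABEL_CLASSES = ("positive", "negative", "excluded")


def _check_matrix(data: np.ndarray, what: str) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValidationError(f"{what}: expected a 2-D matrix, got shape {data.shape}")
    bad = ~np.isfinite(data)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValidationError(
            f"{what}: non-finite value at row {int(r)}, sample {int(c)}"
        )
    return data


@dataclass
class Recording:
    """One multichannel recording: ``data`` has shape (n_channels, n_samples)."""

    subject_id: str
    trial_id: str | None
    channel_labels: list[str]
    fs: float
    data: np.ndarray

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        self.data = _check_matrix(self.data, "Recording.data")
        labels = list(self.channel_labels)
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValidationError(f"duplicate channel labels: {dupes}")
        if self.data.shape[0] != len(labels):
            raise ValidationError(
                f"{self.data.shape[0]} data rows but {len(labels)} channel labels"
            )
        if not (self.fs > 0):
            raise ValidationError(f"sampling rate must be > 0, got {self.fs}")
        self.channel_labels = labels

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Trial length in seconds."""
        return self.n_samples / self.fs

    def copy_with(self, **changes) -> "Recording":
        return replace(self, **changes)


@dataclass
class TrialLabel:
    subject_id: str
    trial_id: str
    dimension: str
    rating: float | None
    klass: str

    def __post_init__(self) -> None:
        if self.dimension not in LABEL_DIMENSIONS:
            raise ValidationError(f"unknown label dimension {self.dimension!r}")
        if self.klass not in LABEL_CLASSES:
            raise ValidationError(f"unknown label class {self.klass!r}")
        if self.rating is not None and not np.isfinite(self.rating):
            raise ValidationError("rating must be finite or None")


@dataclass
class FactorSequence:
    """Latent factor activations for one recording: ``factors`` is (m, t)."""

    subject_id: str
    trial_id: str | None
    model_id: str
    factors: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.factors = _check_matrix(self.factors, "FactorSequence.factors")
        if self.factors.shape[0] < 1:
            raise ValidationError("factor sequence needs m >= 1")
        if not (self.fs > 0):
            raise ValidationError(f"sampling rate must be > 0, got {self.fs}")

    @property
    def m(self) -> int:
        return self.factors.shape[0]

    @property
    def n_samples(self) -> int:
        return self.factors.shape[1]


# ---------------------------------------------------------------------------
# Array container: <stem>.npy + <stem>.json sidecar
# ---------------------------------------------------------------------------


def _stem(path: str | Path) -> Path:
    path = Path(path)
    if path.suffix in {".npy", ".json", ".tsv"}:
        path = path.with_suffix("")
    return path


def _write_sidecar(stem: Path, meta: dict) -> None:
    meta = {"format_version": CONTAINER_VERSION, **meta}
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def _read_sidecar(stem: Path) -> dict:
    sidecar = stem.with_suffix(".json")
    if not sidecar.exists():
        raise FormatError(f"missing sidecar metadata file {sidecar}")
    meta = json.loads(sidecar.read_text())
    if "format_version" not in meta:
        raise FormatError(f"{sidecar}: sidecar lacks format_version")
    return meta


def write_recording(rec: Recording, path: str | Path, format: str = "array_container") -> Path:
    """Write a recording; returns the container stem path."""
    rec.validate()
    stem = _stem(path)
    stem.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "kind": "recording",
        "subject_id": rec.subject_id,
        "trial_id": rec.trial_id,
        "channel_labels": rec.channel_labels,
        "fs": rec.fs,
    }
    if format == "array_container":
        np.save(stem.with_suffix(".npy"), rec.data)
    elif format == "delimited":
        np.savetxt(stem.with_suffix(".tsv"), rec.data, delimiter="\t", fmt="%.17g")
    else:
        raise FormatError(f"unknown write format {format!r}")
    _write_sidecar(stem, meta)
    return stem


def read_recording(path: str | Path, format: str = "array_container") -> Recording:
    """Read a recording from the array container, delimited text, or EDF."""
    if format == "edf":
        return _read_edf(path)
    stem = _stem(path)
    meta = _read_sidecar(stem)
    if meta.get("kind") != "recording":
        raise FormatError(f"{stem}: sidecar kind is {meta.get('kind')!r}, not 'recording'")
    if format == "array_container":
        data = np.load(stem.with_suffix(".npy"))
    elif format == "delimited":
        data = np.loadtxt(stem.with_suffix(".tsv"), delimiter="\t", ndmin=2)
    else:
        raise FormatError(f"unknown read format {format!r}")
    try:
        return Recording(
            subject_id=meta["subject_id"],
            trial_id=meta.get("trial_id"),
            channel_labels=meta["channel_labels"],
            fs=meta["fs"],
            data=data,
        )
    except KeyError as exc:  # pragma: no cover - malformed sidecar
        raise FormatError(f"{stem}: sidecar missing field {exc}") from exc


def _read_edf(path: str | Path) -> Recording:
    """EDF adapter (optional; requires mne). Sampling rate and labels come
    from the file header, never hard-coded."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF import requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return Recording(
        subject_id=Path(path).stem,
        trial_id=None,
        channel_labels=list(raw.ch_names),
        fs=float(raw.info["sfreq"]),
        data=raw.get_data(),
    )


def write_factors(seq: FactorSequence, path: str | Path) -> Path:
    seq.__post_init__()  # revalidate
    stem = _stem(path)
    stem.parent.mkdir(parents=True, exist_ok=True)
    np.save(stem.with_suffix(".npy"), seq.factors)
    _write_sidecar(
        stem,
        {
            "kind": "factors",
            "subject_id": seq.subject_id,
            "trial_id": seq.trial_id,
            "model_id": seq.model_id,
            "fs": seq.fs,
        },
    )
    return stem


def read_factors(path: str | Path) -> FactorSequence:
    stem = _stem(path)
    meta = _read_sidecar(stem)
    if meta.get("kind") != "factors":
        raise FormatError(f"{stem}: sidecar kind is {meta.get('kind')!r}, not 'factors'")
    factors = np.load(stem.with_suffix(".npy"))
    return FactorSequence(
        subject_id=meta["subject_id"],
        trial_id=meta.get("trial_id"),
        model_id=meta["model_id"],
        factors=factors,
        fs=meta["fs"],
    )


# ---------------------------------------------------------------------------
# Trial label tables (TSV)
# ---------------------------------------------------------------------------

_LABEL_COLUMNS = ["subject_id", "trial_id", "dimension", "rating", "klass"]


def write_labels(labels: Sequence[TrialLabel], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "subject_id": l.subject_id,
            "trial_id": l.trial_id,
            "dimension": l.dimension,
            "rating": "" if l.rating is None else l.rating,
            "klass": l.klass,
        }
        for l in labels
    ]
    pd.DataFrame(rows, columns=_LABEL_COLUMNS).to_csv(path, sep="\t", index=False)
    return path


def read_labels(path: str | Path) -> list[TrialLabel]:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "trial_id": str})
    missing = set(_LABEL_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"label table missing columns: {sorted(missing)}")
    labels = []
    for _, row in df.iterrows():
        rating = None if pd.isna(row["rating"]) else float(row["rating"])
        labels.append(
            TrialLabel(
                subject_id=str(row["subject_id"]),
                trial_id=str(row["trial_id"]),
                dimension=str(row["dimension"]),
                rating=rating,
                klass=str(row["klass"]),
            )
        )
    keys = [(l.subject_id, l.trial_id, l.dimension) for l in labels]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise FormatError(f"duplicate (subject, trial, dimension) keys: {dupes[:3]}")
    return labels
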