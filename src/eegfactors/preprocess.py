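"""Standardization, rhythm band filtering and trial segmentation.

Each subject's channel data are z-scored independently (per-channel mean 0,
sd 1), which both centers the per-sample vectors the decoders consume and
keeps subjects statistically independent of one another.  Band decomposition
uses conventional EEG rhythm boundaries (theta 4-8, alpha 8-13, beta 13-30,
gamma 30-45 Hz) applied with a zero-phase forward-backward 4th-order
Butterworth filter, so downstream asymmetry and entropy features see no
phase distortion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

from .errors import ConfigError, ValidationError
from .io import Recording


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ConfigError(
                f"band {self.name}: need 0 < low ({self.low_hz}) < high ({self.high_hz})"
            )


#: Conventional EEG rhythm boundaries, configurable at call sites.
DEFAULT_BANDS: dict[str, BandDefinition] = {
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 13.0),
    "beta": BandDefinition("beta", 13.0, 30.0),
    "gamma": BandDefinition("gamma", 30.0, 45.0),
}


def zscore_per_channel(rec: Recording) -> Recording:
    """Z-score every channel; constant channels become all-zero with a warning.

    Idempotent up to floating-point tolerance: applying it twice equals once.
    """
    if rec.n_samples < 2:
        raise ValidationError("z-scoring needs at least 2 samples per channel")
    mu = rec.data.mean(axis=1, keepdims=True)
    sd = rec.data.std(axis=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        names = [rec.channel_labels[i] for i in np.flatnonzero(flat)]
        warnings.warn(f"constant channels mapped to zero: {names}", stacklevel=2)
    sd_safe = np.where(sd == 0, 1.0, sd)
    out = (rec.data - mu) / sd_safe
    out[flat, :] = 0.0
    return rec.copy_with(data=out)


def zscore_stats(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel (mean, sd) of an (n, t) matrix; zero sd is mapped to 1."""
    mu = data.mean(axis=1)
    sd = data.std(axis=1)
    return mu, np.where(sd == 0, 1.0, sd)


def apply_zscore(rec: Recording, mu: np.ndarray, sd: np.ndarray) -> Recording:
    """Apply externally fitted per-channel statistics (e.g. a subject's pooled
    session statistics) to one trial."""
    return rec.copy_with(data=(rec.data - mu[:, None]) / sd[:, None])


def bandpass(rec: Recording, band: BandDefinition, order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass; shape-preserving."""
    nyq = rec.fs / 2.0
    if band.high_hz >= nyq:
        raise ConfigError(
            f"band {band.name} high edge {band.high_hz} Hz >= Nyquist {nyq} Hz"
        )
    sos = signal.butter(order, [band.low_hz, band.high_hz], btype="bandpass",
                        fs=rec.fs, output="sos")
    out = signal.sosfiltfilt(sos, rec.data, axis=1)
    return rec.copy_with(data=np.ascontiguousarray(out))


def segment_trials(
    rec: Recording, trial_table: Mapping[str, tuple[int, int]] | Sequence[tuple[str, int, int]]
) -> list[Recording]:
    """Cut (start, stop) sample windows out of a recording, one per trial id."""
    if isinstance(trial_table, Mapping):
        items = [(tid, s, e) for tid, (s, e) in trial_table.items()]
    else:
        items = [tuple(row) for row in trial_table]
    out = []
    for trial_id, start, stop in items:
        if not (0 <= start < stop <= rec.n_samples):
            raise ValidationError(
                f"trial {trial_id!r}: segment [{start}, {stop}) outside "
                f"[0, {rec.n_samples})"
            )
        out.append(
            rec.copy_with(trial_id=str(trial_id), data=rec.data[:, start:stop].copy())
        )
    return out
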