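"""Ground-truth mixing-model EEG synthesis.

The generator realizes the linear generative assumption behind latent-factor
decoding: an observed channels-by-time matrix ``E`` is (approximately) a
mixing matrix ``M`` (n x m) applied to independent latent sources ``S``
(m x t), plus i.i.d. Gaussian sensor noise.  Sources are either second-order
autoregressive processes with a tunable spectral peak (``ar2``), phase-random
sinusoids (``band_sine``), or heavy-tailed i.i.d. draws (``laplace_iid``) —
non-Gaussian or temporally structured by design, since blind source
separation is unidentifiable for i.i.d. Gaussian sources.

Multiple synthetic subjects share a template mixing matrix plus a small
per-subject Gaussian perturbation, emulating cross-subject variability with a
shared underlying structure so that leave-one-subject-out evaluation is
nontrivial but solvable.  Emotion-like class structure enters as an amplitude
modulation of one designated source in positive-class trials, making the
binary labels recoverable from the latent sources in principle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal as _signal

from .errors import ConfigError
from .io import FactorSequence, Recording, TrialLabel, write_labels, write_recording

_AR2_BURN_IN = 500


@dataclass(frozen=True)
class SourceSpec:
    """One latent source: ``kind`` in {ar2, band_sine, laplace_iid}.

    params: ``center_hz`` (ar2/band_sine), ``pole_radius`` (ar2, default 0.97),
    ``scale`` (all kinds; the target standard deviation, default 1).
    """

    kind: str
    center_hz: float | None = None
    pole_radius: float = 0.97
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in {"ar2", "band_sine", "laplace_iid"}:
            raise ConfigError(f"unknown source kind {self.kind!r}")
        if self.kind in {"ar2", "band_sine"} and self.center_hz is None:
            raise ConfigError(f"{self.kind} source needs a center_hz")
        if self.kind == "ar2" and not (0 < self.pole_radius < 1):
            raise ConfigError("ar2 pole_radius must be in (0, 1)")
        if self.scale <= 0:
            raise ConfigError("source scale must be > 0")


@dataclass
class MixingModel:
    """Ground truth for one subject: E = M @ S + noise."""

    M: np.ndarray
    source_specs: list[SourceSpec]
    noise_sd: float
    fs: float

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        n, m = self.M.shape
        if m != len(self.source_specs):
            raise ConfigError(f"M has {m} columns but {len(self.source_specs)} source specs")
        if m > n:
            raise ConfigError(f"more sources ({m}) than channels ({n})")
        if np.linalg.matrix_rank(self.M) < m:
            raise ConfigError("mixing matrix is not full column rank")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")

    @property
    def n(self) -> int:
        return self.M.shape[0]

    @property
    def m(self) -> int:
        return self.M.shape[1]

    def demix(self) -> np.ndarray:
        """Pseudo-inverse of M: maps channels back to source estimates."""
        return np.linalg.pinv(self.M)


def _one_source(spec: SourceSpec, t: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    if spec.kind == "laplace_iid":
        x = rng.laplace(0.0, 1.0, size=t)
    elif spec.kind == "ar2":
        theta = 2 * np.pi * spec.center_hz / fs
        a1 = 2 * spec.pole_radius * np.cos(theta)
        a2 = -spec.pole_radius**2
        e = rng.standard_normal(t + _AR2_BURN_IN)
        x = _signal.lfilter([1.0], [1.0, -a1, -a2], e)[_AR2_BURN_IN:]
    else:  # band_sine
        phase = rng.uniform(0, 2 * np.pi)
        x = np.sin(2 * np.pi * spec.center_hz * np.arange(t) / fs + phase)
    sd = x.std()
    if sd > 0:
        x = x / sd
    return spec.scale * x


def generate_sources(model: MixingModel, t: int, seed: int) -> np.ndarray:
    """Draw the m independent source series (m x t); deterministic given seed."""
    if t < 1:
        raise ConfigError(f"need t >= 1 samples, got {t}")
    rng = np.random.default_rng(seed)
    return np.vstack([_one_source(s, t, model.fs, rng) for s in model.source_specs])


def mix(
    sources: np.ndarray,
    model: MixingModel,
    seed: int,
    subject_id: str = "s01",
    trial_id: str | None = None,
    channel_labels: list[str] | None = None,
) -> Recording:
    """Project sources through M and add Gaussian sensor noise."""
    sources = np.asarray(sources, dtype=float)
    if sources.ndim != 2 or sources.shape[0] != model.m:
        raise ConfigError(
            f"sources have shape {sources.shape}, expected ({model.m}, t)"
        )
    rng = np.random.default_rng(seed)
    data = model.M @ sources
    if model.noise_sd > 0:
        data = data + rng.normal(0.0, model.noise_sd, size=data.shape)
    labels = channel_labels or default_channel_labels(model.n)
    return Recording(
        subject_id=subject_id,
        trial_id=trial_id,
        channel_labels=labels,
        fs=model.fs,
        data=data,
    )


#: 10-20-system names used for small synthetic montages; the first 14 rows of
#: the asymmetry pair registry are reachable once n >= 28.
_TEN_TWENTY = [
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T7", "T8", "P7", "P8", "AF3", "AF4", "FC1", "FC2",
    "FC5", "FC6", "CP1", "CP2", "CP5", "CP6", "PO3", "PO4", "Fz", "Cz",
    "Pz", "Oz", "FT7", "FT8", "TP7", "TP8", "PO7", "PO8", "AFz", "FCz",
]


def default_channel_labels(n: int) -> list[str]:
    if n <= len(_TEN_TWENTY):
        return _TEN_TWENTY[:n]
    return _TEN_TWENTY + [f"X{i:02d}" for i in range(n - len(_TEN_TWENTY))]


def default_source_specs(m: int) -> list[SourceSpec]:
    """Alternating rhythm-peaked AR(2) and heavy-tailed i.i.d. sources."""
    peaks = [10.0, 6.0, 20.0, 35.0]
    specs: list[SourceSpec] = []
    for j in range(m):
        if j % 2 == 0:
            specs.append(SourceSpec("ar2", center_hz=peaks[(j // 2) % len(peaks)]))
        else:
            specs.append(SourceSpec("laplace_iid"))
    return specs


@dataclass
class SyntheticDatasetConfig:
    """Desk-scale defaults: 4 subjects x 10 trials of 30 s, 8 channels mixed
    from 3 sources at 128 Hz, with the 10 Hz AR(2) source doubled in amplitude
    on positive-class trials."""

    n_subjects: int = 4
    trials_per_subject: int = 10
    trial_seconds: float = 30.0
    n: int = 8
    m: int = 3
    fs: float = 128.0
    noise_sd: float = 0.1
    modulated_source_index: int = 0
    amplitude_ratio: float = 2.0
    subject_perturbation_sd: float = 0.1
    master_seed: int = 0
    source_specs: list[SourceSpec] | None = None

    def __post_init__(self) -> None:
        for name in ("n_subjects", "trials_per_subject", "n", "m"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.m > self.n:
            raise ConfigError(f"more sources ({self.m}) than channels ({self.n})")
        if self.amplitude_ratio <= 0:
            raise ConfigError("amplitude_ratio must be > 0")
        if not (0 <= self.modulated_source_index < self.m):
            raise ConfigError("modulated_source_index out of range")
        if self.trial_seconds * self.fs < 1:
            raise ConfigError("trial too short")


@dataclass
class SyntheticDataset:
    recordings: list[Recording]
    labels: list[TrialLabel]
    mixing_models: dict[str, MixingModel]
    config: SyntheticDatasetConfig

    def true_sources(self, rec: Recording) -> FactorSequence:
        """Oracle factor estimate D @ E from the subject's true demixing matrix."""
        model = self.mixing_models[rec.subject_id]
        return FactorSequence(
            subject_id=rec.subject_id,
            trial_id=rec.trial_id,
            model_id="oracle-demix",
            factors=model.demix() @ rec.data,
            fs=rec.fs,
        )

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for rec in self.recordings:
            write_recording(rec, directory / f"{rec.subject_id}_{rec.trial_id}")
        write_labels(self.labels, directory / "labels.tsv")
        manifest = {
            "config": {
                k: v for k, v in vars(self.config).items() if k != "source_specs"
            },
            "source_specs": [vars(s) for s in self.config.source_specs or []],
            "mixing_matrices": {
                sid: mm.M.tolist() for sid, mm in self.mixing_models.items()
            },
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return directory


def make_labeled_dataset(cfg: SyntheticDatasetConfig) -> SyntheticDataset:
    """Generate the full multi-subject labeled dataset; deterministic under
    ``cfg.master_seed``.  Classes are balanced (odd trial counts put the extra
    trial in the negative class)."""
    specs = cfg.source_specs or default_source_specs(cfg.m)
    cfg.source_specs = specs
    ss = np.random.SeedSequence(cfg.master_seed)
    template_rng = np.random.default_rng(ss.spawn(1)[0])
    template = template_rng.standard_normal((cfg.n, cfg.m))

    t = int(round(cfg.trial_seconds * cfg.fs))
    labels_for_trials = ["negative", "positive"] * ((cfg.trials_per_subject + 1) // 2)
    labels_for_trials = labels_for_trials[: cfg.trials_per_subject]

    recordings: list[Recording] = []
    labels: list[TrialLabel] = []
    models: dict[str, MixingModel] = {}
    chan_labels = default_channel_labels(cfg.n)

    subject_seeds = ss.spawn(cfg.n_subjects + 1)[1:]
    for i, sub_ss in enumerate(subject_seeds):
        subject_id = f"s{i + 1:02d}"
        sub_rng = np.random.default_rng(sub_ss)
        M = template + cfg.subject_perturbation_sd * sub_rng.standard_normal(
            (cfg.n, cfg.m)
        )
        model = MixingModel(M=M, source_specs=specs, noise_sd=cfg.noise_sd, fs=cfg.fs)
        models[subject_id] = model
        trial_seeds = sub_rng.integers(0, 2**31 - 1, size=(cfg.trials_per_subject, 2))
        for k in range(cfg.trials_per_subject):
            trial_id = f"t{k + 1:02d}"
            klass = labels_for_trials[k]
            S = generate_sources(model, t, int(trial_seeds[k, 0]))
            if klass == "positive":
                S = S.copy()
                S[cfg.modulated_source_index] *= cfg.amplitude_ratio
            rec = mix(
                S,
                model,
                int(trial_seeds[k, 1]),
                subject_id=subject_id,
                trial_id=trial_id,
                channel_labels=chan_labels,
            )
            recordings.append(rec)
            labels.append(
                TrialLabel(
                    subject_id=subject_id,
                    trial_id=trial_id,
                    dimension="predefined",
                    rating=None,
                    klass=klass,
                )
            )
    return SyntheticDataset(recordings, labels, models, cfg)
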