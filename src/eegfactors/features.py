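"""Handcrafted EEG feature bank for the baseline classifiers.

Per rhythm band (theta/alpha/beta/gamma) and channel, nine time-frequency
features and nine nonlinear-dynamical-system features are extracted, plus
fourteen left-right hemispheric asymmetry features per band, for a total of
4*n*18 + 4*14 dimensions (2360 for a 32-channel montage, 4520 for 62).

Every estimator is deterministic given (signal, params); estimators that are
undefined on degenerate input (constant series, too-short series) return 0
with a warning so the feature vector stays finite.  The asymmetry statistic
is the log band-power ratio log(P_left / P_right) (the standard differential
asymmetry convention); a linear-difference variant is available.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as _sig
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import LinearSVC

from .errors import ConfigError, ValidationError
from .io import Recording
from .preprocess import DEFAULT_BANDS, BandDefinition, bandpass

# ---------------------------------------------------------------------------
# Asymmetry pair registry
# ---------------------------------------------------------------------------

#: The 14 homologous left-right electrode pairs of the standard 32-channel
#: montage, in canonical order (Fp1-Fp2 first).
DEAP_PAIRS: list[tuple[str, str]] = [
    ("Fp1", "Fp2"), ("AF3", "AF4"), ("F3", "F4"), ("F7", "F8"),
    ("FC5", "FC6"), ("FC1", "FC2"), ("C3", "C4"), ("T7", "T8"),
    ("CP5", "CP6"), ("CP1", "CP2"), ("P3", "P4"), ("P7", "P8"),
    ("PO3", "PO4"), ("O1", "O2"),
]

N_PAIRS = 14
TFD_NAMES = [
    "peak_peak_mean", "mean_square", "variance",
    "hjorth_activity", "hjorth_mobility", "hjorth_complexity",
    "max_psd_freq", "max_psd", "power_sum",
]
NDS_NAMES = [
    "approx_entropy", "c0_complexity", "corr_dimension", "kolmogorov_entropy",
    "lyapunov", "perm_entropy", "singular_entropy", "shannon_entropy",
    "spectral_entropy",
]


@dataclass(frozen=True)
class PairRegistry:
    """Ordered list of exactly 14 (left, right) electrode label pairs.  For
    montages other than the standard 32-channel one the registry is
    user-supplied; pairs must be distinct but need not be homologous."""

    pairs: tuple[tuple[str, str], ...] = tuple(DEAP_PAIRS)

    def __post_init__(self) -> None:
        if len(self.pairs) != N_PAIRS:
            raise ConfigError(f"registry needs exactly {N_PAIRS} pairs, got {len(self.pairs)}")
        if len(set(self.pairs)) != N_PAIRS:
            raise ConfigError("registry pairs must be distinct")

    def check_against(self, channel_labels: Sequence[str]) -> None:
        present = set(channel_labels)
        for left, right in self.pairs:
            if left not in present or right not in present:
                raise ValidationError(
                    f"asymmetry pair {left}-{right}: electrode missing from recording"
                )


def registry_for_montage(channel_labels: Sequence[str]) -> PairRegistry:
    """Build a 14-pair registry for an arbitrary montage.  Homologous pairs
    from the standard list are used where present; remaining slots are filled
    with distinct cross-channel pairs so the feature-length contract holds on
    small montages too."""
    present = set(channel_labels)
    pairs: list[tuple[str, str]] = [
        p for p in DEAP_PAIRS if p[0] in present and p[1] in present
    ]
    labels = list(channel_labels)
    offset = 1
    while len(pairs) < N_PAIRS:
        for i, left in enumerate(labels):
            right = labels[(i + offset) % len(labels)]
            if left != right and (left, right) not in pairs:
                pairs.append((left, right))
                if len(pairs) == N_PAIRS:
                    break
        offset += 1
        if offset > len(labels) + 1:
            raise ConfigError(
                f"cannot build {N_PAIRS} distinct pairs from {len(labels)} channels"
            )
    return PairRegistry(tuple(pairs[:N_PAIRS]))


def feature_count(n_channels: int) -> int:
    """4 rhythms x n x (9 TFD + 9 NDS) + 4 rhythms x 14 asymmetry pairs."""
    return 4 * n_channels * 18 + 4 * N_PAIRS


# ---------------------------------------------------------------------------
# Time-frequency-domain features
# ---------------------------------------------------------------------------


def hjorth(x: Sequence[float]) -> tuple[float, float, float]:
    """(activity, mobility, complexity); a constant series gives (0, 0, 0)
    with a warning."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValidationError("Hjorth parameters need length >= 3")
    var0 = float(np.var(x))
    if var0 == 0:
        warnings.warn("constant series: Hjorth parameters set to 0", stacklevel=2)
        return 0.0, 0.0, 0.0
    d1 = np.diff(x)
    var1 = float(np.var(d1))
    mobility = float(np.sqrt(var1 / var0))
    if var1 == 0:
        return var0, 0.0, 0.0
    var2 = float(np.var(np.diff(d1)))
    mobility_d = float(np.sqrt(var2 / var1))
    return var0, mobility, mobility_d / mobility if mobility > 0 else 0.0


def tfd_features(
    x: Sequence[float], fs: float, pp_window_seconds: float = 1.0
) -> dict[str, float]:
    """Nine time-frequency features from one series; the spectral entries use
    a boxcar one-sided periodogram (scipy convention)."""
    x = np.asarray(x, dtype=float)
    if x.size < 16:
        raise ValidationError("time-frequency features need length >= 16")
    w = max(1, int(round(pp_window_seconds * fs)))
    n_win = max(1, x.size // w)
    chunks = [x[k * w:(k + 1) * w] for k in range(n_win)]
    pp_mean = float(np.mean([c.max() - c.min() for c in chunks]))
    act, mob, comp = (
        hjorth(x) if np.var(x) > 0 else (0.0, 0.0, 0.0)
    )
    freqs, psd = _sig.periodogram(x, fs=fs)
    k = int(np.argmax(psd))
    return {
        "peak_peak_mean": pp_mean,
        "mean_square": float(np.mean(x**2)),
        "variance": float(np.var(x)),
        "hjorth_activity": act,
        "hjorth_mobility": mob,
        "hjorth_complexity": comp,
        "max_psd_freq": float(freqs[k]),
        "max_psd": float(psd[k]),
        "power_sum": float(psd.sum()),
    }


# ---------------------------------------------------------------------------
# Nonlinear-dynamical-system features
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NDSParams:
    """Estimator knobs, all logged into run manifests by the pipeline."""

    apen_embed: int = 2
    apen_tolerance_sd: float = 0.2
    c0_threshold_factor: float = 5.0
    gp_embed: int = 3
    gp_delay: int = 1
    gp_n_radii: int = 12
    lyap_embed: int = 5
    lyap_delay: int = 1
    lyap_min_separation: int = 10
    lyap_fit_points: int = 20
    perm_order: int = 3
    perm_delay: int = 1
    singular_window: int = 20
    hist_bins: int = 16
    min_length: int = 256


def _embed(x: np.ndarray, dim: int, delay: int) -> np.ndarray:
    n = x.size - (dim - 1) * delay
    if n < 2:
        return np.empty((0, dim))
    return np.column_stack([x[k * delay:k * delay + n] for k in range(dim)])


def _apen_phi(x: np.ndarray, m: int, r: float) -> float:
    E = _embed(x, m, 1)
    d = np.max(np.abs(E[:, None, :] - E[None, :, :]), axis=2)
    c = np.mean(d <= r, axis=1)  # self-matches included
    return float(np.mean(np.log(c)))


def approx_entropy(x: np.ndarray, m: int = 2, tolerance_sd: float = 0.2) -> float:
    sd = x.std()
    if sd == 0:
        return 0.0
    r = tolerance_sd * sd
    return _apen_phi(x, m, r) - _apen_phi(x, m + 1, r)


def c0_complexity(x: np.ndarray, threshold_factor: float = 5.0) -> float:
    """Fraction of signal power left after removing spectral lines whose
    power exceeds ``threshold_factor`` times the mean spectral power."""
    total = float(np.sum(x.astype(float) ** 2))
    if total == 0:
        return 0.0
    F = np.fft.fft(x)
    P = np.abs(F) ** 2
    keep = P > threshold_factor * P.mean()
    regular = np.fft.ifft(np.where(keep, F, 0)).real
    return float(np.sum((x - regular) ** 2) / total)


def _correlation_sums(x: np.ndarray, dim: int, delay: int, radii: np.ndarray) -> np.ndarray:
    E = _embed(x, dim, delay)
    if E.shape[0] < 3:
        return np.zeros_like(radii)
    d = np.max(np.abs(E[:, None, :] - E[None, :, :]), axis=2)
    iu = np.triu_indices(E.shape[0], k=1)
    dist = d[iu]
    return np.array([np.mean(dist <= r) for r in radii])


def corr_dimension(x: np.ndarray, dim: int = 3, delay: int = 1, n_radii: int = 12) -> float:
    """Grassberger-Procaccia slope of log C(r) vs log r over the scaling
    region where the correlation sum is strictly between 0 and 1."""
    sd = x.std()
    if sd == 0:
        return 0.0
    radii = np.logspace(np.log10(0.1 * sd), np.log10(2.0 * sd), n_radii)
    C = _correlation_sums(x, dim, delay, radii)
    ok = (C > 0) & (C < 1)
    if ok.sum() < 2:
        return 0.0
    slope = np.polyfit(np.log(radii[ok]), np.log(C[ok]), 1)[0]
    return float(slope)


def k2_entropy(x: np.ndarray, dim: int = 3, delay: int = 1,
               tolerance_sd: float = 0.2) -> float:
    """Correlation entropy K2, the standard computable lower bound on the
    Kolmogorov-Sinai entropy: ln( C_m(r) / C_{m+1}(r) )."""
    sd = x.std()
    if sd == 0:
        return 0.0
    r = np.array([tolerance_sd * sd])
    cm = _correlation_sums(x, dim, delay, r)[0]
    cm1 = _correlation_sums(x, dim + 1, delay, r)[0]
    if cm <= 0 or cm1 <= 0:
        return 0.0
    return float(np.log(cm / cm1))


def lyapunov_rosenstein(
    x: np.ndarray, dim: int = 5, delay: int = 1, min_separation: int = 10,
    fit_points: int = 20,
) -> float:
    """Largest Lyapunov exponent: slope (per sample) of the mean log
    divergence of initially nearest trajectories."""
    if x.std() == 0:
        return 0.0
    E = _embed(x, dim, delay)
    n = E.shape[0]
    if n < 2 * (min_separation + fit_points):
        return 0.0
    d = np.sqrt(np.sum((E[:, None, :] - E[None, :, :]) ** 2, axis=2))
    idx = np.arange(n)
    too_close = np.abs(idx[:, None] - idx[None, :]) <= min_separation
    d_masked = np.where(too_close, np.inf, d)
    nn = np.argmin(d_masked, axis=1)
    K = fit_points
    usable = np.flatnonzero((idx + K < n) & (nn + K < n))
    if usable.size < 2:
        return 0.0
    logs = np.full((usable.size, K + 1), np.nan)
    for col in range(K + 1):
        dk = d[usable + col, nn[usable] + col]
        logs[:, col] = np.log(np.maximum(dk, 1e-12))
    y = np.nanmean(logs, axis=0)
    slope = np.polyfit(np.arange(K + 1), y, 1)[0]
    return float(slope)


def perm_entropy(x: np.ndarray, order: int = 3, delay: int = 1) -> float:
    """Normalized permutation entropy; exactly 0 for a strictly monotone
    series (a single ordinal pattern)."""
    E = _embed(x, order, delay)
    if E.shape[0] < 1:
        return 0.0
    patterns = np.apply_along_axis(lambda row: tuple(np.argsort(row, kind="stable")), 1, E)
    _, counts = np.unique(patterns, axis=0, return_counts=True)
    p = counts / counts.sum()
    H = float(-np.sum(p * np.log(p)))
    return H / np.log(float(math.factorial(order))) if order > 1 else 0.0


def singular_entropy(x: np.ndarray, window: int = 20) -> float:
    """Shannon entropy of the normalized squared singular values of the
    delay-embedding trajectory matrix."""
    E = _embed(x, window, 1)
    if E.shape[0] < window:
        return 0.0
    s = np.linalg.svd(E, compute_uv=False)
    energy = s**2
    total = energy.sum()
    if total == 0:
        return 0.0
    p = energy / total
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def shannon_entropy(x: np.ndarray, bins: int = 16) -> float:
    """Entropy of the amplitude histogram."""
    counts, _ = np.histogram(x, bins=bins)
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def spectral_entropy(x: np.ndarray, fs: float) -> float:
    """Normalized entropy of the periodogram power distribution (1 for a
    flat spectrum, near 0 for a single spectral line)."""
    _, psd = _sig.periodogram(x, fs=fs)
    total = psd.sum()
    if total == 0:
        return 0.0
    p = psd / total
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)) / np.log(psd.size))


def nds_features(
    x: Sequence[float], fs: float, params: NDSParams | None = None
) -> dict[str, float]:
    """Nine nonlinear-dynamics features; estimators that cannot run on the
    given series return 0 with a warning so the vector stays finite."""
    params = params or NDSParams()
    x = np.asarray(x, dtype=float)
    if x.size < params.min_length:
        warnings.warn(
            f"series length {x.size} < recommended {params.min_length}; "
            "nonlinear estimators may be unreliable", stacklevel=2,
        )
    out: dict[str, float] = {}

    def _guard(name, fn):
        try:
            v = float(fn())
        except Exception:
            v = float("nan")
        if not np.isfinite(v):
            warnings.warn(f"{name}: estimator degenerate, value set to 0", stacklevel=3)
            v = 0.0
        out[name] = v

    _guard("approx_entropy",
           lambda: approx_entropy(x, params.apen_embed, params.apen_tolerance_sd))
    _guard("c0_complexity", lambda: c0_complexity(x, params.c0_threshold_factor))
    _guard("corr_dimension",
           lambda: corr_dimension(x, params.gp_embed, params.gp_delay, params.gp_n_radii))
    _guard("kolmogorov_entropy",
           lambda: k2_entropy(x, params.gp_embed, params.gp_delay,
                              params.apen_tolerance_sd))
    _guard("lyapunov",
           lambda: lyapunov_rosenstein(x, params.lyap_embed, params.lyap_delay,
                                       params.lyap_min_separation,
                                       params.lyap_fit_points))
    _guard("perm_entropy", lambda: perm_entropy(x, params.perm_order, params.perm_delay))
    _guard("singular_entropy", lambda: singular_entropy(x, params.singular_window))
    _guard("shannon_entropy", lambda: shannon_entropy(x, params.hist_bins))
    _guard("spectral_entropy", lambda: spectral_entropy(x, fs))
    return out


# ---------------------------------------------------------------------------
# Hemispheric asymmetry features
# ---------------------------------------------------------------------------


def bhaa_features(
    trial: Recording, registry: PairRegistry | None = None, mode: str = "log_ratio"
) -> dict[str, float]:
    """Per registry pair, the asymmetry of band power between the left and
    right electrode of a band-filtered trial: log(P_L / P_R) by default, or
    P_L - P_R with ``mode='difference'``."""
    registry = registry or PairRegistry()
    registry.check_against(trial.channel_labels)
    if mode not in {"log_ratio", "difference"}:
        raise ConfigError(f"unknown asymmetry mode {mode!r}")
    index = {lab: i for i, lab in enumerate(trial.channel_labels)}
    out = {}
    for left, right in registry.pairs:
        p_l = float(np.mean(trial.data[index[left]] ** 2))
        p_r = float(np.mean(trial.data[index[right]] ** 2))
        name = f"{left}-{right}"
        if mode == "difference":
            out[name] = p_l - p_r
        elif p_l == 0 or p_r == 0:
            warnings.warn(f"zero band power in pair {name}; asymmetry set to 0",
                          stacklevel=2)
            out[name] = 0.0
        else:
            out[name] = float(np.log(p_l / p_r))
    return out


# ---------------------------------------------------------------------------
# Full feature vector
# ---------------------------------------------------------------------------


@dataclass
class FeatureVector:
    subject_id: str
    trial_id: str | None
    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.size:
            raise ValidationError("feature name/value length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValidationError("feature names are not unique")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("feature vector contains non-finite values")


def feature_vector(
    trial: Recording,
    bands: dict[str, BandDefinition] | None = None,
    registry: PairRegistry | None = None,
    nds_params: NDSParams | None = None,
    filter_order: int = 4,
) -> FeatureVector:
    """Concatenate, in canonical order, per-rhythm per-channel TFD+NDS
    features followed by per-rhythm asymmetry features: 4*n*18 + 56 values."""
    bands = bands or DEFAULT_BANDS
    registry = registry or PairRegistry()
    names: list[str] = []
    values: list[float] = []
    filtered = {name: bandpass(trial, band, order=filter_order)
                for name, band in bands.items()}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for band_name, frec in filtered.items():
            for ci, ch in enumerate(frec.channel_labels):
                x = frec.data[ci]
                tfd = tfd_features(x, frec.fs)
                nds = nds_features(x, frec.fs, nds_params)
                for feat in TFD_NAMES:
                    names.append(f"{band_name}_{ch}_{feat}")
                    values.append(tfd[feat])
                for feat in NDS_NAMES:
                    names.append(f"{band_name}_{ch}_{feat}")
                    values.append(nds[feat])
        for band_name, frec in filtered.items():
            asym = bhaa_features(frec, registry)
            for pair, v in asym.items():
                names.append(f"{band_name}_asym_{pair}")
                values.append(v)
    return FeatureVector(
        subject_id=trial.subject_id,
        trial_id=trial.trial_id,
        names=names,
        values=np.array(values),
    )


# ---------------------------------------------------------------------------
# Baseline classifiers
# ---------------------------------------------------------------------------

BASELINE_ROSTER = ("svm_l1", "rf", "knn", "lr", "nb", "dnn")


@dataclass
class BaselineModel:
    kind: str
    estimator: object
    eliminated_features: np.ndarray | None = None  # svm_l1 only

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(np.asarray(X, float))


def train_baseline(
    features: np.ndarray,
    labels: Sequence[str],
    model_kind: str,
    params: dict | None = None,
) -> BaselineModel:
    """Fit one baseline from the roster.  ``svm_l1`` is a linear SVM with an
    L1 penalty (C trades loss against sparsity); its zero-weight features are
    reported as eliminated.  Others are thin wrappers with the stated
    defaults: rf 100 trees, knn 7 neighbors, dnn three hidden layers of 100."""
    params = dict(params or {})
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or not np.all(np.isfinite(X)):
        raise ValidationError("features must be a finite (N, d) matrix")
    if len(np.unique(y)) < 2:
        raise ValidationError("training needs at least 2 classes")
    seed = int(params.pop("seed", 0))
    if model_kind == "svm_l1":
        est = LinearSVC(
            C=float(params.pop("C", 1.0)), penalty="l1", loss="squared_hinge",
            dual=False, max_iter=int(params.pop("max_iter", 5000)),
        )
        est.fit(X, y)
        eliminated = np.flatnonzero(np.all(est.coef_ == 0, axis=0))
        return BaselineModel("svm_l1", est, eliminated)
    if model_kind == "rf":
        est = RandomForestClassifier(
            n_estimators=int(params.pop("n_estimators", 100)), random_state=seed
        )
    elif model_kind == "knn":
        est = KNeighborsClassifier(n_neighbors=int(params.pop("n_neighbors", 7)))
    elif model_kind == "lr":
        est = LogisticRegression(max_iter=int(params.pop("max_iter", 1000)))
    elif model_kind == "nb":
        est = GaussianNB()
    elif model_kind == "dnn":
        est = MLPClassifier(
            hidden_layer_sizes=tuple(params.pop("hidden_layer_sizes", (100, 100, 100))),
            random_state=seed, max_iter=int(params.pop("max_iter", 500)),
        )
    else:
        raise ConfigError(f"unknown baseline {model_kind!r}; roster is {BASELINE_ROSTER}")
    est.fit(X, y)
    return BaselineModel(model_kind, est)


def svm_l1_nonzero_path(
    features: np.ndarray, labels: Sequence[str], Cs: Sequence[float]
) -> list[int]:
    """Refit the L1 SVM at each C and count nonzero-weight features; the
    count is non-increasing (ties allowed) as C decreases."""
    counts = []
    for C in Cs:
        model = train_baseline(features, labels, "svm_l1", {"C": C})
        coef = model.estimator.coef_
        counts.append(int(np.sum(np.any(coef != 0, axis=0))))
    return counts
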