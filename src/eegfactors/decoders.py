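"""Unsupervised latent-factor decoders for per-time-sample channel vectors.

Five decoder families share one contract: fit on pooled z-scored samples
``X`` of shape (N, n), encode a recording (n, t) into a factor sequence
(m, t), and reconstruct channels from factors.

* **AE** — one-hidden-layer autoencoder, h = f(W1 x + b1),
  x_hat = g(W2 h + b2), trained by backprop on mean squared reconstruction
  error with Adam.  The hidden layer *is* the latent code.
* **GRBM** — Gaussian-visible / Bernoulli-hidden restricted Boltzmann
  machine with the standard energy
  E(x, h) = sum_i (x_i - a_i)^2 / (2 sigma_i^2)
          - sum_ij (x_i / sigma_i) W_ij h_j - sum_j b_j h_j,
  trained by contrastive divergence (CD-k) and optionally unrolled into a
  sigmoid-hidden autoencoder for backprop fine-tuning.  Visible scales
  sigma_i are fixed at 1 because inputs are z-scored.
* **VAE** — linear Gaussian encoder producing mu and log sigma^2, linear
  decoder, trained with RMSprop on the negative evidence lower bound: unit
  observation variance makes the likelihood term 0.5 ||x - x_hat||^2, and the
  KL term has the Gaussian closed form
  -0.5 sum_j (1 + log sigma_j^2 - mu_j^2 - sigma_j^2).
  Latent draws use the reparameterization z = mu + sigma * eps; encoding at
  inference returns mu (deterministic).
* **ICA / PCA** — linear baselines backed by scikit-learn's FastICA and PCA,
  stored as an (unmixing, mixing-back, mean) triple.  ICA keeps ``n_runs``
  independent restarts for the channel-counterpart matching protocol, which
  pairs each original channel with the reconstructed signal of highest
  Pearson correlation (duplicates permitted; a strict mode computes the
  optimal one-to-one assignment instead).

All fits are bit-reproducible given (data, config, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.decomposition import PCA, FastICA

from ._nn import Adam, RMSprop, SGDMomentum, activation_pair, glorot, minibatches, sigmoid
from .errors import ConfigError, TrainingError, ValidationError
from .io import FactorSequence, Recording
from .synthetic import default_channel_labels

# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------


@dataclass
class AEModel:
    W1: np.ndarray  # (m, n) encoder
    b1: np.ndarray  # (m,)
    W2: np.ndarray  # (n, m) decoder
    b2: np.ndarray  # (n,)
    hidden_activation: str = "tanh"
    output_activation: str = "linear"
    loss_history: list[float] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.W1.shape[1]

    @property
    def m(self) -> int:
        return self.W1.shape[0]

    @property
    def model_id(self) -> str:
        return f"ae-m{self.m}"

    def encode_samples(self, X: np.ndarray) -> np.ndarray:
        f, _ = activation_pair(self.hidden_activation)
        return f(X @ self.W1.T + self.b1)

    def reconstruct_samples(self, H: np.ndarray) -> np.ndarray:
        g, _ = activation_pair(self.output_activation)
        return g(H @ self.W2.T + self.b2)


@dataclass
class GRBMModel:
    W: np.ndarray  # (n, m) visible-hidden weights
    a: np.ndarray  # (n,) visible biases
    b: np.ndarray  # (m,) hidden biases
    sigma: np.ndarray  # (n,) visible scales (fixed at 1 for z-scored data)
    recon_errors: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(self.sigma <= 0):
            raise ConfigError("GRBM sigma must be positive")

    @property
    def n(self) -> int:
        return self.W.shape[0]

    @property
    def m(self) -> int:
        return self.W.shape[1]

    @property
    def model_id(self) -> str:
        return f"grbm-m{self.m}"

    def p_hidden(self, X: np.ndarray) -> np.ndarray:
        """P(h_j = 1 | x), the logistic conditional of the Gaussian RBM."""
        return sigmoid((X / self.sigma) @ self.W + self.b)

    def visible_mean(self, H: np.ndarray) -> np.ndarray:
        """E[x | h] = sigma_i * sum_j W_ij h_j + a_i."""
        return self.sigma * (H @ self.W.T) + self.a

    def encode_samples(self, X: np.ndarray) -> np.ndarray:
        return self.p_hidden(X)

    def reconstruct_samples(self, H: np.ndarray) -> np.ndarray:
        return self.visible_mean(H)

    def mean_field_reconstruction(self, X: np.ndarray) -> np.ndarray:
        return self.visible_mean(self.p_hidden(X))

    def energy(self, x: np.ndarray, h: np.ndarray) -> float:
        """Joint energy of one (x, h) configuration."""
        x = np.asarray(x, float)
        h = np.asarray(h, float)
        quad = np.sum((x - self.a) ** 2 / (2 * self.sigma**2))
        inter = (x / self.sigma) @ self.W @ h
        return float(quad - inter - self.b @ h)


@dataclass
class VAEModel:
    We: np.ndarray  # (m, n) -> mu
    be: np.ndarray
    Wv: np.ndarray  # (m, n) -> log sigma^2
    bv: np.ndarray
    Wd: np.ndarray  # (n, m) decoder mean
    bd: np.ndarray
    L: int = 1
    loss_history: list[float] = field(default_factory=list)
    recon_history: list[float] = field(default_factory=list)
    kl_history: list[float] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.We.shape[1]

    @property
    def m(self) -> int:
        return self.We.shape[0]

    @property
    def model_id(self) -> str:
        return f"vae-m{self.m}"

    def encode_mu_logvar(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return X @ self.We.T + self.be, X @ self.Wv.T + self.bv

    def encode_samples(self, X: np.ndarray) -> np.ndarray:
        """Deterministic latent representation: the posterior mean mu."""
        return X @ self.We.T + self.be

    def reconstruct_samples(self, Z: np.ndarray) -> np.ndarray:
        return Z @ self.Wd.T + self.bd


@dataclass
class LinearDecoderModel:
    kind: str  # "ica" or "pca"
    unmix: np.ndarray  # (m, n)
    mix_back: np.ndarray  # (n, m)
    mean: np.ndarray  # (n,)
    component_order: np.ndarray
    explained_variance_ratio: np.ndarray | None = None
    runs: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.unmix.shape[1]

    @property
    def m(self) -> int:
        return self.unmix.shape[0]

    @property
    def model_id(self) -> str:
        return f"{self.kind}-m{self.m}"

    def encode_samples(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) @ self.unmix.T

    def reconstruct_samples(self, H: np.ndarray) -> np.ndarray:
        return H @ self.mix_back.T + self.mean


DecoderModel = AEModel | GRBMModel | VAEModel | LinearDecoderModel


# ---------------------------------------------------------------------------
# Autoencoder
# ---------------------------------------------------------------------------


def _check_training_data(data: np.ndarray, m: int, batch: int) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValidationError(f"training data must be (N, n), got {data.shape}")
    if m < 1:
        raise ConfigError("latent dimension m must be >= 1")
    if data.shape[0] < batch:
        raise ConfigError(
            f"batch size {batch} exceeds the {data.shape[0]} available samples"
        )
    return data


def _ae_epoch_losses(model: AEModel) -> list[float]:
    return model.loss_history


def _train_ae_params(
    params: dict[str, np.ndarray],
    data: np.ndarray,
    hidden: str,
    output: str,
    epochs: int,
    batch: int,
    optimizer,
    rng: np.random.Generator,
    lr_decay: float = 1.0,
) -> list[float]:
    """In-place minibatch backprop on mean squared reconstruction error.

    Returns the per-epoch mean loss (averaged over that epoch's batches).
    ``lr_decay`` multiplies the optimizer's learning rate after each epoch,
    which lets the loss settle onto a plateau within a small epoch budget."""
    f, df = activation_pair(hidden)
    g, dg = activation_pair(output)
    history: list[float] = []
    for epoch in range(epochs):
        if epoch > 0:
            optimizer.lr *= lr_decay
        total, count = 0.0, 0
        for idx in minibatches(data.shape[0], batch, rng):
            X = data[idx]
            B = X.shape[0]
            Hp = X @ params["W1"].T + params["b1"]
            H = f(Hp)
            Op = H @ params["W2"].T + params["b2"]
            Xh = g(Op)
            diff = Xh - X
            loss = float(np.mean(np.sum(diff**2, axis=1)))
            if not np.isfinite(loss):
                raise TrainingError(
                    f"AE loss became non-finite at epoch {epoch}; "
                    f"|W1|max={np.abs(params['W1']).max():.3g}"
                )
            dO = (2.0 / B) * diff * dg(Op, Xh)
            dH = (dO @ params["W2"]) * df(Hp, H)
            grads = {
                "W2": dO.T @ H,
                "b2": dO.sum(axis=0),
                "W1": dH.T @ X,
                "b1": dH.sum(axis=0),
            }
            optimizer.step(params, grads)
            total += loss * B
            count += B
        history.append(total / count)
    return history


def fit_ae(
    data: np.ndarray,
    m: int,
    epochs: int = 20,
    batch: int = 500,
    lr: float = 0.03,
    seed: int = 0,
    hidden_activation: str = "tanh",
    output_activation: str = "linear",
    lr_decay: float = 0.7,
) -> AEModel:
    """Train a one-hidden-layer autoencoder on pooled (N, n) samples."""
    data = _check_training_data(data, m, batch)
    n = data.shape[1]
    if m > n:
        warnings.warn(f"over-complete autoencoder: m={m} > n={n}", stacklevel=2)
    rng = np.random.default_rng(seed)
    params = {
        "W1": glorot(rng, (m, n)),
        "b1": np.zeros(m),
        "W2": glorot(rng, (n, m)),
        "b2": np.zeros(n),
    }
    history = _train_ae_params(
        params, data, hidden_activation, output_activation, epochs, batch,
        Adam(lr=lr), rng, lr_decay=lr_decay,
    )
    return AEModel(
        W1=params["W1"], b1=params["b1"], W2=params["W2"], b2=params["b2"],
        hidden_activation=hidden_activation, output_activation=output_activation,
        loss_history=history,
    )


# ---------------------------------------------------------------------------
# Gaussian RBM
# ---------------------------------------------------------------------------


def fit_grbm(
    data: np.ndarray,
    m: int,
    cd_k: int = 1,
    epochs: int = 10,
    lr: float = 0.02,
    batch: int = 500,
    seed: int = 0,
    momentum: float = 0.5,
    sigma: np.ndarray | None = None,
) -> GRBMModel:
    """Contrastive-divergence training of a Gaussian-visible RBM.

    The positive phase uses the data; the negative phase runs ``cd_k`` Gibbs
    half-steps with sampled binary hiddens and mean-field visibles.  The
    per-epoch mean-field reconstruction error is logged in ``recon_errors``.
    """
    if cd_k < 1:
        raise ConfigError("cd_k must be >= 1")
    data = _check_training_data(data, m, batch)
    n = data.shape[1]
    sig = np.ones(n) if sigma is None else np.asarray(sigma, dtype=float)
    if sig.shape != (n,) or np.any(sig <= 0):
        raise ConfigError("sigma must be positive with one entry per channel")
    rng = np.random.default_rng(seed)
    model = GRBMModel(
        W=0.01 * rng.standard_normal((n, m)),
        a=np.zeros(n),
        b=np.zeros(m),
        sigma=sig,
    )
    params = {"W": model.W, "a": model.a, "b": model.b}
    opt = SGDMomentum(lr=lr, momentum=momentum)
    for epoch in range(epochs):
        for idx in minibatches(data.shape[0], batch, rng):
            v0 = data[idx]
            B = v0.shape[0]
            h0p = model.p_hidden(v0)
            hp, vk = h0p, v0
            for _ in range(cd_k):
                hs = (rng.random(hp.shape) < hp).astype(float)
                vk = model.visible_mean(hs)
                hp = model.p_hidden(vk)
            grads = {
                "W": -((v0 / sig).T @ h0p - (vk / sig).T @ hp) / B,
                "a": -np.mean((v0 - vk) / sig**2, axis=0),
                "b": -np.mean(h0p - hp, axis=0),
            }
            opt.step(params, grads)
        recon = model.mean_field_reconstruction(data)
        err = float(np.mean(np.sum((data - recon) ** 2, axis=1)))
        if not np.isfinite(err):
            raise TrainingError(f"GRBM reconstruction error non-finite at epoch {epoch}")
        model.recon_errors.append(err)
    return model


def grbm_unroll_finetune(
    model: GRBMModel,
    data: np.ndarray,
    epochs: int = 10,
    batch: int = 500,
    lr: float = 1e-3,
    seed: int = 0,
) -> AEModel:
    """Unroll a trained GRBM into a sigmoid-hidden autoencoder and fine-tune.

    At initialization the unrolled network computes exactly the GRBM's
    mean-field reconstruction (encoder W1 = W^T, b1 = b; decoder W2 = W,
    b2 = a).  Fine-tuning then minimizes reconstruction error by backprop;
    if it somehow ends worse than it started, the initial parameters are
    returned with a warning.
    """
    data = _check_training_data(data, model.m, batch if epochs > 0 else 1)
    init = {
        "W1": (model.W / model.sigma[:, None]).T.copy(),
        "b1": model.b.copy(),
        "W2": (model.W * model.sigma[:, None]).copy(),
        "b2": model.a.copy(),
    }
    ae = AEModel(
        W1=init["W1"], b1=init["b1"], W2=init["W2"], b2=init["b2"],
        hidden_activation="sigmoid", output_activation="linear",
    )
    if epochs == 0:
        return ae

    def _mse(p):
        H = sigmoid(data @ p["W1"].T + p["b1"])
        R = H @ p["W2"].T + p["b2"]
        return float(np.mean(np.sum((data - R) ** 2, axis=1)))

    initial_err = _mse(init)
    params = {k: v.copy() for k, v in init.items()}
    rng = np.random.default_rng(seed)
    history = _train_ae_params(
        params, data, "sigmoid", "linear", epochs, batch, Adam(lr=lr), rng
    )
    final_err = _mse(params)
    if final_err > initial_err:
        warnings.warn(
            "fine-tuning did not improve the unrolled reconstruction; "
            "returning the initial parameters", stacklevel=2,
        )
        return ae
    return AEModel(
        W1=params["W1"], b1=params["b1"], W2=params["W2"], b2=params["b2"],
        hidden_activation="sigmoid", output_activation="linear",
        loss_history=[initial_err, *history],
    )


# ---------------------------------------------------------------------------
# Variational autoencoder
# ---------------------------------------------------------------------------


def gaussian_kl(mu: np.ndarray, logvar: np.ndarray) -> float:
    """Closed-form KL( N(mu, diag(sigma^2)) || N(0, I) ) for one datapoint:
    -0.5 * sum_j (1 + log sigma_j^2 - mu_j^2 - sigma_j^2)."""
    mu = np.asarray(mu, float)
    logvar = np.asarray(logvar, float)
    return float(-0.5 * np.sum(1.0 + logvar - mu**2 - np.exp(logvar)))


def reparameterize(
    mu: np.ndarray, sigma: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """z = mu + sigma * eps with eps ~ N(0, I)."""
    return mu + sigma * rng.standard_normal(np.shape(mu))


def fit_vae(
    data: np.ndarray,
    m: int,
    epochs: int = 20,
    batch: int = 500,
    lr: float = 5e-3,
    seed: int = 0,
    L: int = 1,
    lr_decay: float = 0.85,
) -> VAEModel:
    """Train the VAE by stochastic gradient ascent on the evidence lower
    bound (RMSprop on its negation).  ``L`` Monte-Carlo draws estimate the
    likelihood term; the KL term is exact.  Reconstruction and KL parts of
    the loss are logged separately per epoch."""
    if L < 1:
        raise ConfigError("L (Monte-Carlo samples) must be >= 1")
    data = _check_training_data(data, m, batch)
    n = data.shape[1]
    rng = np.random.default_rng(seed)
    params = {
        "We": glorot(rng, (m, n)),
        "be": np.zeros(m),
        "Wv": 0.01 * rng.standard_normal((m, n)),
        "bv": np.zeros(m),
        "Wd": glorot(rng, (n, m)),
        "bd": np.zeros(n),
    }
    opt = RMSprop(lr=lr)
    loss_hist, rec_hist, kl_hist = [], [], []
    for epoch in range(epochs):
        if epoch > 0:
            opt.lr *= lr_decay
        tot_l = tot_r = tot_k = 0.0
        count = 0
        for idx in minibatches(data.shape[0], batch, rng):
            X = data[idx]
            B = X.shape[0]
            mu = X @ params["We"].T + params["be"]
            lv = np.clip(X @ params["Wv"].T + params["bv"], -15.0, 15.0)
            sigma = np.exp(0.5 * lv)
            kl = float(np.mean(-0.5 * np.sum(1 + lv - mu**2 - np.exp(lv), axis=1)))

            dmu = mu / B
            dlv = 0.5 * (np.exp(lv) - 1.0) / B
            dWd = np.zeros_like(params["Wd"])
            dbd = np.zeros_like(params["bd"])
            rec = 0.0
            for _ in range(L):
                eps = rng.standard_normal(mu.shape)
                z = mu + sigma * eps
                Xh = z @ params["Wd"].T + params["bd"]
                diff = Xh - X
                rec += float(np.mean(0.5 * np.sum(diff**2, axis=1))) / L
                dXh = diff / (B * L)
                dWd += dXh.T @ z
                dbd += dXh.sum(axis=0)
                dz = dXh @ params["Wd"]
                dmu += dz
                dlv += dz * eps * 0.5 * sigma
            loss = rec + kl
            if not np.isfinite(loss):
                raise TrainingError(f"VAE loss non-finite at epoch {epoch}")
            grads = {
                "Wd": dWd,
                "bd": dbd,
                "We": dmu.T @ X,
                "be": dmu.sum(axis=0),
                "Wv": dlv.T @ X,
                "bv": dlv.sum(axis=0),
            }
            opt.step(params, grads)
            tot_l += loss * B
            tot_r += rec * B
            tot_k += kl * B
            count += B
        loss_hist.append(tot_l / count)
        rec_hist.append(tot_r / count)
        kl_hist.append(tot_k / count)
    return VAEModel(
        We=params["We"], be=params["be"], Wv=params["Wv"], bv=params["bv"],
        Wd=params["Wd"], bd=params["bd"], L=L,
        loss_history=loss_hist, recon_history=rec_hist, kl_history=kl_hist,
    )


# ---------------------------------------------------------------------------
# Linear baselines
# ---------------------------------------------------------------------------


def fit_pca(data: np.ndarray, m: int) -> LinearDecoderModel:
    data = np.asarray(data, dtype=float)
    if m > data.shape[1]:
        raise ConfigError(f"m={m} exceeds channel count {data.shape[1]}")
    pca = PCA(n_components=m, svd_solver="full")
    pca.fit(data)
    comps = pca.components_
    return LinearDecoderModel(
        kind="pca",
        unmix=comps.copy(),
        mix_back=comps.T.copy(),
        mean=pca.mean_.copy(),
        component_order=np.arange(m),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
    )


def fit_ica(
    data: np.ndarray,
    m: int,
    seed: int = 0,
    n_runs: int = 10,
    max_iter: int = 500,
) -> LinearDecoderModel:
    """FastICA with ``n_runs`` independent restarts retained for the
    counterpart-matching protocol; the first restart is the primary model.
    Non-convergence raises scikit-learn's ConvergenceWarning and keeps the
    best iterate."""
    data = np.asarray(data, dtype=float)
    if m > data.shape[1]:
        raise ConfigError(f"m={m} exceeds channel count {data.shape[1]}")
    seeds = np.random.SeedSequence(seed).spawn(n_runs)
    runs = []
    for s in seeds:
        run_seed = int(s.generate_state(1)[0] % (2**31 - 1))
        ica = FastICA(
            n_components=m, random_state=run_seed, whiten="unit-variance",
            max_iter=max_iter,
        )
        ica.fit(data)
        runs.append((ica.components_.copy(), ica.mixing_.copy(), ica.mean_.copy()))
    unmix, mix_back, mean = runs[0]
    return LinearDecoderModel(
        kind="ica",
        unmix=unmix,
        mix_back=mix_back,
        mean=mean,
        component_order=np.arange(m),
        runs=runs,
    )


@dataclass
class ChannelMatch:
    """Result of the counterpart-matching protocol for one reconstruction."""

    matched_r: np.ndarray  # per original channel
    mapping: np.ndarray  # index of the matched reconstructed signal
    r_matrix: np.ndarray  # full original x reconstructed correlation matrix

    @property
    def mean_r(self) -> float:
        return float(self.matched_r.mean())


def ica_match_channels(
    original: Recording, reconstructed: Recording, strict: bool = False
) -> ChannelMatch:
    """Pair each original channel with the reconstructed signal of highest
    Pearson correlation.  Duplicates are permitted by default; ``strict``
    computes the optimal one-to-one assignment instead.  Ties break toward
    the lowest reconstructed index."""
    if original.data.shape != reconstructed.data.shape:
        raise ValidationError(
            f"shape mismatch: original {original.data.shape} vs "
            f"reconstructed {reconstructed.data.shape}"
        )
    n = original.n_channels
    A = original.data - original.data.mean(axis=1, keepdims=True)
    B = reconstructed.data - reconstructed.data.mean(axis=1, keepdims=True)
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    na = np.where(na == 0, 1.0, na)
    nb = np.where(nb == 0, 1.0, nb)
    R = (A @ B.T) / np.outer(na, nb)
    if strict:
        rows, cols = linear_sum_assignment(-R)
        mapping = np.empty(n, dtype=int)
        mapping[rows] = cols
    else:
        mapping = np.argmax(R, axis=1)  # np.argmax ties -> lowest index
    matched = R[np.arange(n), mapping]
    return ChannelMatch(matched_r=matched, mapping=mapping, r_matrix=R)


def ica_counterpart_protocol(
    model: LinearDecoderModel, rec: Recording, strict: bool = False
) -> np.ndarray:
    """Repeat encode->reconstruct->match over the stored ICA restarts and
    average the per-channel matched correlations."""
    if model.kind != "ica" or not model.runs:
        raise ConfigError("counterpart protocol needs an ICA model with stored runs")
    acc = np.zeros(rec.n_channels)
    for unmix, mix_back, mean in model.runs:
        H = (rec.data.T - mean) @ unmix.T
        recon = rec.copy_with(data=(H @ mix_back.T + mean).T)
        acc += ica_match_channels(rec, recon, strict=strict).matched_r
    return acc / len(model.runs)


# ---------------------------------------------------------------------------
# Shared encode / reconstruct
# ---------------------------------------------------------------------------


def save_model(model: DecoderModel, path) -> None:
    """Serialize any decoder to a .npz checkpoint."""
    import pathlib

    path = pathlib.Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(model, AEModel):
        np.savez(path, kind="ae", W1=model.W1, b1=model.b1, W2=model.W2,
                 b2=model.b2, hidden=model.hidden_activation,
                 output=model.output_activation)
    elif isinstance(model, GRBMModel):
        np.savez(path, kind="grbm", W=model.W, a=model.a, b=model.b,
                 sigma=model.sigma)
    elif isinstance(model, VAEModel):
        np.savez(path, kind="vae", We=model.We, be=model.be, Wv=model.Wv,
                 bv=model.bv, Wd=model.Wd, bd=model.bd, L=model.L)
    elif isinstance(model, LinearDecoderModel):
        np.savez(path, kind=model.kind, unmix=model.unmix,
                 mix_back=model.mix_back, mean=model.mean,
                 order=model.component_order)
    else:  # pragma: no cover
        raise ConfigError(f"cannot serialize {type(model).__name__}")


def load_model(path) -> DecoderModel:
    with np.load(path, allow_pickle=False) as z:
        kind = str(z["kind"])
        if kind == "ae":
            return AEModel(W1=z["W1"], b1=z["b1"], W2=z["W2"], b2=z["b2"],
                           hidden_activation=str(z["hidden"]),
                           output_activation=str(z["output"]))
        if kind == "grbm":
            return GRBMModel(W=z["W"], a=z["a"], b=z["b"], sigma=z["sigma"])
        if kind == "vae":
            return VAEModel(We=z["We"], be=z["be"], Wv=z["Wv"], bv=z["bv"],
                            Wd=z["Wd"], bd=z["bd"], L=int(z["L"]))
        if kind in {"ica", "pca"}:
            return LinearDecoderModel(kind=kind, unmix=z["unmix"],
                                      mix_back=z["mix_back"], mean=z["mean"],
                                      component_order=z["order"])
    raise ConfigError(f"unknown checkpoint kind {kind!r}")


def encode(model: DecoderModel, rec: Recording) -> FactorSequence:
    """Apply the deterministic encoder per time sample (VAE: posterior mean;
    GRBM: hidden conditional probabilities)."""
    if rec.n_channels != model.n:
        raise ValidationError(
            f"recording has {rec.n_channels} channels but model expects {model.n}"
        )
    factors = model.encode_samples(rec.data.T).T
    return FactorSequence(
        subject_id=rec.subject_id,
        trial_id=rec.trial_id,
        model_id=model.model_id,
        factors=factors,
        fs=rec.fs,
    )


def reconstruct(
    model: DecoderModel,
    seq: FactorSequence,
    channel_labels: list[str] | None = None,
) -> Recording:
    """Apply the decoder per time sample, mapping factors back to channels."""
    if seq.m != model.m:
        raise ValidationError(
            f"sequence has m={seq.m} factors but model expects m={model.m}"
        )
    data = model.reconstruct_samples(seq.factors.T).T
    labels = channel_labels or default_channel_labels(model.n)
    return Recording(
        subject_id=seq.subject_id,
        trial_id=seq.trial_id,
        channel_labels=labels,
        fs=seq.fs,
        data=data,
    )
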