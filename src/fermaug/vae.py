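"""Convolutional variational autoencoder for fermentation time series.

The encoder maps one experiment, shaped ``(n_points, 7)`` and min-max
normalized to [0, 1], through five stride-1 convolutional layers (ReLU, with
dropout) to a ``(n_points, 64)`` feature map, flattens it (32,000 values for
the 500-point grid), passes two dense layers of 512 and 64 units, and emits
the mean and log-variance of a 10-dimensional Gaussian posterior q(z|x).
The decoder mirrors the process and ends in a sigmoid, so generated series
stay in the normalized [0, 1] box.  Training minimizes the negative evidence
lower bound (ELBO): a summed-squared-error reconstruction term (Gaussian
log-likelihood up to constants) plus the closed-form KL divergence from
q(z|x) to the standard-normal prior.

The network and its backpropagation are implemented directly in numpy with
an Adam optimizer: the model is small enough (a few dozen megabytes of
weights, a dozen training sequences) that a framework buys nothing, and a
from-scratch implementation keeps every gradient inspectable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import CHANNELS, ExperimentCollection
from .preprocess import Normalizer, SeriesTensor, collection_from_tensor

__all__ = [
    "VAEConfig",
    "EncoderPosterior",
    "LatentSample",
    "LossRecord",
    "VAEModel",
    "encode",
    "reparameterize",
    "kl_divergence",
    "elbo_loss",
    "train_vae",
    "generate_synthetic",
]

_DTYPE = np.float32

#: log-variance values are clipped to +/- this bound for numerical safety
_LOGVAR_LIMIT = 8.0

#: init spread of the posterior-mean head: large enough that experiments map
#: to visibly distinct latent codes before any training (guards against
#: posterior collapse under short training budgets)
_MU_HEAD_INIT_SD = 0.5

#: initial posterior log-variance (head bias): posterior sd ~0.37, so the
#: mean separation between experiments is not swamped by sampling noise
#: before the encoder has learned anything
_LOGVAR_INIT = -2.0

#: the decoder output layer starts at this fraction of its He scale (with
#: its bias at the data-mean logit); small but non-zero so latent gradients
#: flow from the first step
_OUT_W_INIT_SCALE = 0.1


# ---------------------------------------------------------------------------
# configuration and small value types


@dataclass
class VAEConfig:
    """Architecture and training hyperparameters.

    The skeleton is fixed by design — five convolutional layers ending in 64
    filters, dense layers of 512 and 64 units, a 10-dimensional latent space —
    while the free knobs (kernel length, per-layer filters, dropout, optimizer
    settings) are explicit fields.
    """

    n_points: int = 500
    n_channels: int = len(CHANNELS)
    conv_filters: tuple = (32, 32, 48, 64, 64)
    kernel_size: int = 5
    stride: int = 1
    dropout_rate: float = 0.0
    dense_units: tuple = (512, 64)
    latent_dim: int = 10
    epochs: int = 100
    batch_size: int | None = 1
    learning_rate: float = 2e-2
    seed: int = 0
    #: global gradient-norm ceiling; a loose guard that only catches
    #: outright explosions without reshaping ordinary training
    max_grad_norm: float = 5000.0
    #: fraction of training over which the KL weight anneals linearly from
    #: 0 to 1; prevents posterior collapse at short budgets (0 disables,
    #: the final objective is always the plain ELBO)
    kl_anneal_frac: float = 0.5
    #: learning-rate multiplier for the latent bottleneck (posterior heads
    #: and the first decoder layer); accelerates latent engagement, the
    #: slowest-learning pathway at short budgets
    latent_lr_scale: float = 10.0
    #: learning-rate multiplier for the encoder body (convolutions + dense
    #: stack); 0 freezes it as a fixed random projection.  The random
    #: encoder already separates experiments at init, and any appreciable
    #: update rate kills its ReLU units within a few epochs (gradients
    #: through the 32,000-dim flatten are enormous), so the trainable
    #: encoder parameters are the posterior heads
    encoder_lr_scale: float = 0.0
    #: start the posterior heads at exactly (mu, logvar) = (0, 0); the
    #: default random mu head engages the latent space from the first step
    zero_init_heads: bool = False

    def __post_init__(self) -> None:
        if len(self.conv_filters) != 5:
            raise ValueError("the encoder uses exactly five convolutional layers")
        if self.conv_filters[-1] != 64:
            raise ValueError("the final convolutional layer must have 64 filters")
        if tuple(self.dense_units) != (512, 64):
            raise ValueError("dense stack is fixed at (512, 64) units")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.stride != 1:
            raise ValueError("stride 1 is required to keep the n_points x 64 map")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")

    @property
    def flat_dim(self) -> int:
        """Size of the flattened feature map (32,000 on the 500-point grid)."""
        return self.n_points * self.conv_filters[-1]


@dataclass
class EncoderPosterior:
    """Diagonal-Gaussian posterior q(z|x): mean and log-variance vectors."""

    mu: np.ndarray
    logvar: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float).ravel()
        self.logvar = np.asarray(self.logvar, dtype=float).ravel()
        if self.mu.shape != self.logvar.shape:
            raise ValueError("mu and logvar must have the same length")
        if not (np.all(np.isfinite(self.mu)) and np.all(np.isfinite(self.logvar))):
            raise ValueError("posterior parameters must be finite")


@dataclass
class LatentSample:
    """One draw z from q(z|x) (training) or the standard-normal prior."""

    z: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float).ravel()
        if not np.all(np.isfinite(self.z)):
            raise ValueError("latent sample must be finite")


@dataclass
class LossRecord:
    """Per-epoch training losses in the minimized sign convention.

    ``total`` is the negative ELBO: reconstruction loss plus KL divergence.
    """

    epoch: int
    reconstruction: float
    kl: float
    total: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.kl < 0:
            raise ValueError("KL divergence cannot be negative")
        if self.total is None:
            self.total = self.reconstruction + self.kl


# ---------------------------------------------------------------------------
# layers (numpy forward/backward)


class _Param:
    __slots__ = ("value", "grad", "m", "v", "lr_scale")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(_DTYPE)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)
        self.lr_scale = 1.0


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 zero_init=False, init_sd: float | None = None):
        if zero_init:
            w = np.zeros((n_in, n_out))
        else:
            sd = np.sqrt(2.0 / n_in) if init_sd is None else init_sd
            w = rng.normal(0.0, sd, size=(n_in, n_out))
        self.W = _Param(w)
        self.b = _Param(np.zeros(n_out))
        self.params = [self.W, self.b]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout):
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


class _Conv1dSame:
    """Stride-1 'same' 1-D convolution over (N, L, C) arrays via im2col."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        self.k, self.c_in, self.c_out = k, c_in, c_out
        w = rng.normal(0.0, np.sqrt(2.0 / (k * c_in)), size=(k * c_in, c_out))
        self.W = _Param(w)
        self.b = _Param(np.zeros(c_out))
        self.params = [self.W, self.b]

    def _im2col(self, x):
        n, length, c = x.shape
        pad = self.k // 2
        xp = np.zeros((n, length + 2 * pad, c), dtype=_DTYPE)
        xp[:, pad:pad + length] = x
        cols = np.empty((n, length, self.k * c), dtype=_DTYPE)
        for j in range(self.k):
            cols[:, :, j * c:(j + 1) * c] = xp[:, j:j + length, :]
        return cols

    def forward(self, x, training=False):
        n, length, _ = x.shape
        self._cols = self._im2col(x)
        flat = self._cols.reshape(n * length, -1)
        out = flat @ self.W.value + self.b.value
        return out.reshape(n, length, self.c_out)

    def backward(self, dout):
        n, length, _ = dout.shape
        dflat = dout.reshape(n * length, self.c_out)
        self.W.grad += self._cols.reshape(n * length, -1).T @ dflat
        self.b.grad += dflat.sum(axis=0)
        dcols = (dflat @ self.W.value.T).reshape(n, length, self.k * self.c_in)
        pad = self.k // 2
        dxp = np.zeros((n, length + 2 * pad, self.c_in), dtype=_DTYPE)
        for j in range(self.k):
            dxp[:, j:j + length] += dcols[:, :, j * self.c_in:(j + 1) * self.c_in]
        return dxp[:, pad:pad + length]


class _ReLU:
    params: list = []

    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class _Sigmoid:
    """Logistic output scaled to span [-margin, 1 + margin].

    A plain sigmoid reaches 0 and 1 only asymptotically, but min-max
    normalized data places every channel's extremes exactly there; the
    margin keeps those targets at finite logits instead of in the
    vanishing-gradient tails.
    """

    params: list = []
    margin = 0.1

    def forward(self, x, training=False):
        # overflow-safe logistic
        s = np.empty_like(x)
        pos = x >= 0
        s[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        s[~pos] = ex / (1.0 + ex)
        self._s = s
        return -self.margin + (1.0 + 2 * self.margin) * s

    def backward(self, dout):
        return dout * (1.0 + 2 * self.margin) * self._s * (1.0 - self._s)


class _Dropout:
    params: list = []

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask.astype(_DTYPE)

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


def _run(layers, x, training=False):
    for layer in layers:
        x = layer.forward(x, training=training)
    return x


def _backprop(layers, dout):
    for layer in reversed(layers):
        dout = layer.backward(dout)
    return dout


class _Adam:
    def __init__(self, params, lr: float, beta1=0.9, beta2=0.999, eps=1e-8,
                 max_grad_norm: float | None = None, warmup_steps: int = 0,
                 total_steps: int | None = None):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.max_grad_norm = max_grad_norm
        self.warmup_steps = warmup_steps
        self.total_steps = total_steps
        self.t = 0

    @property
    def _lr_t(self):
        # linear warmup guards the ReLU stacks against dying in the first,
        # very-large-gradient epochs; linear decay to 10% settles the
        # oscillations that otherwise dominate the final epochs
        if self.warmup_steps and self.t <= self.warmup_steps:
            return self.lr * self.t / self.warmup_steps
        if self.total_steps and self.total_steps > self.warmup_steps:
            frac = (self.t - self.warmup_steps) / (self.total_steps - self.warmup_steps)
            return self.lr * (1.0 - 0.9 * min(1.0, frac))
        return self.lr

    def step(self):
        if self.max_grad_norm is not None:
            total = np.sqrt(sum(float(np.sum(p.grad.astype(np.float64) ** 2))
                                for p in self.params))
            if total > self.max_grad_norm:
                factor = _DTYPE(self.max_grad_norm / total)
                for p in self.params:
                    p.grad *= factor
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p in self.params:
            p.m = self.b1 * p.m + (1 - self.b1) * p.grad
            p.v = self.b2 * p.v + (1 - self.b2) * p.grad ** 2
            p.value -= (p.lr_scale * self._lr_t) * (p.m / b1t) / (np.sqrt(p.v / b2t) + self.eps)
            p.grad[:] = 0.0


# ---------------------------------------------------------------------------
# the model


class VAEModel:
    """Encoder/decoder pair plus the training-time artefacts needed to sample."""

    def __init__(self, config: VAEConfig):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5AE]))
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 0xD0])
        )
        c = config
        k = c.kernel_size

        # encoder: 5 convs (ReLU), one dropout after the last, flatten,
        # dense 512 -> dense 64 -> zero-initialized (mu, logvar) heads
        chans = (c.n_channels,) + tuple(c.conv_filters)
        self.enc_conv = []
        for i in range(5):
            self.enc_conv += [_Conv1dSame(chans[i], chans[i + 1], k, rng), _ReLU()]
        self.enc_conv.append(_Dropout(c.dropout_rate, self._dropout_rng))
        self.enc_dense = [
            _Dense(c.flat_dim, c.dense_units[0], rng), _ReLU(),
            _Dense(c.dense_units[0], c.dense_units[1], rng), _ReLU(),
        ]
        self.head_mu = _Dense(c.dense_units[1], c.latent_dim, rng,
                              zero_init=c.zero_init_heads, init_sd=_MU_HEAD_INIT_SD)
        # the log-variance head starts at zero weights; its bias starts at
        # _LOGVAR_INIT unless exact-zero heads are requested, so early
        # posterior noise does not swamp the mean separation
        self.head_logvar = _Dense(c.dense_units[1], c.latent_dim, rng, zero_init=True)
        if not c.zero_init_heads:
            self.head_logvar.b.value[:] = _LOGVAR_INIT

        # decoder mirrors the encoder and ends in a sigmoid
        self.dec_dense = [
            _Dense(c.latent_dim, c.dense_units[1], rng), _ReLU(),
            _Dense(c.dense_units[1], c.dense_units[0], rng), _ReLU(),
            _Dense(c.dense_units[0], c.flat_dim, rng), _ReLU(),
        ]
        rev = tuple(reversed(c.conv_filters)) + (c.n_channels,)
        self.dec_conv = []
        for i in range(5):
            self.dec_conv.append(_Conv1dSame(rev[i], rev[i + 1], k, rng))
            self.dec_conv.append(_Sigmoid() if i == 4 else _ReLU())

        self.params = []
        for layer in (self.enc_conv + self.enc_dense + [self.head_mu, self.head_logvar]
                      + self.dec_dense + self.dec_conv):
            self.params += layer.params
        for layer in self.enc_conv + self.enc_dense:
            for p in layer.params:
                p.lr_scale = c.encoder_lr_scale
        for p in (self.head_mu.params + self.head_logvar.params
                  + self.dec_dense[0].params):
            p.lr_scale = c.latent_lr_scale
        self.time_grid: np.ndarray | None = None
        #: (mu, logvar) of the training experiments, set by train_vae
        self.train_posteriors: tuple[np.ndarray, np.ndarray] | None = None

    def save(self, path) -> None:
        """Persist weights + config (numpy archive)."""
        import json

        arrays = {f"p{i}": p.value for i, p in enumerate(self.params)}
        if self.time_grid is not None:
            arrays["time_grid"] = self.time_grid
        if self.train_posteriors is not None:
            arrays["post_mu"], arrays["post_logvar"] = self.train_posteriors
        cfg = dict(self.config.__dict__)
        cfg["conv_filters"] = list(cfg["conv_filters"])
        cfg["dense_units"] = list(cfg["dense_units"])
        np.savez(path, config=json.dumps(cfg), **arrays)

    @classmethod
    def load(cls, path) -> "VAEModel":
        import json

        with np.load(path, allow_pickle=False) as archive:
            cfg = json.loads(str(archive["config"]))
            cfg["conv_filters"] = tuple(cfg["conv_filters"])
            cfg["dense_units"] = tuple(cfg["dense_units"])
            model = cls(VAEConfig(**cfg))
            for i, p in enumerate(model.params):
                p.value = archive[f"p{i}"].astype(_DTYPE)
            if "time_grid" in archive:
                model.time_grid = archive["time_grid"].astype(float)
            if "post_mu" in archive:
                model.train_posteriors = (
                    archive["post_mu"].astype(float),
                    archive["post_logvar"].astype(float),
                )
        return model

    # -- forward passes -----------------------------------------------------

    def encode_batch(self, x: np.ndarray, training=False) -> tuple[np.ndarray, np.ndarray]:
        """(N, n_points, 7) -> per-sample (mu, logvar), each (N, latent_dim)."""
        x = np.asarray(x, dtype=_DTYPE)
        if x.ndim != 3 or x.shape[1:] != (self.config.n_points, self.config.n_channels):
            raise ValueError(
                f"expected (N, {self.config.n_points}, {self.config.n_channels}), "
                f"got {x.shape}"
            )
        h = _run(self.enc_conv, x, training)
        h = h.reshape(x.shape[0], self.config.flat_dim)
        h = _run(self.enc_dense, h, training)
        mu = self.head_mu.forward(h, training)
        logvar_raw = self.head_logvar.forward(h, training)
        # clip log-variance to keep exp() finite; gradient gated in backward
        logvar = np.clip(logvar_raw, -_LOGVAR_LIMIT, _LOGVAR_LIMIT)
        self._logvar_open = np.abs(logvar_raw) < _LOGVAR_LIMIT
        return mu, logvar

    def decode_batch(self, z: np.ndarray, training=False) -> np.ndarray:
        """(N, latent_dim) -> (N, n_points, 7) in [0, 1]."""
        z = np.asarray(z, dtype=_DTYPE)
        h = _run(self.dec_dense, z, training)
        h = h.reshape(z.shape[0], self.config.n_points, self.config.conv_filters[-1])
        return _run(self.dec_conv, h, training)

    # -- backward passes ----------------------------------------------------

    def _backward(self, dx_hat, dmu, dlogvar):
        dh = _backprop(self.dec_conv, dx_hat)
        dh = dh.reshape(dx_hat.shape[0], self.config.flat_dim)
        dz = _backprop(self.dec_dense, dh)
        dmu = dmu + dz                       # z = mu + sd * eps
        dlogvar = (dlogvar + dz * self._dz_dlogvar) * self._logvar_open
        dh64 = self.head_mu.backward(dmu) + self.head_logvar.backward(dlogvar)
        dh = _backprop(self.enc_dense, dh64)
        dh = dh.reshape(dx_hat.shape[0], self.config.n_points, self.config.conv_filters[-1])
        _backprop(self.enc_conv, dh)


# ---------------------------------------------------------------------------
# module operations


def encode(x: np.ndarray, model: VAEModel) -> EncoderPosterior:
    """Posterior q(z|x) for a single normalized experiment of shape
    ``(n_points, 7)``; deterministic given the model state."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.config.n_points, model.config.n_channels):
        raise ValueError(
            f"expected shape ({model.config.n_points}, {model.config.n_channels}), "
            f"got {x.shape}"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("input must be finite")
    mu, logvar = model.encode_batch(x[None], training=False)
    return EncoderPosterior(mu[0], logvar[0])


def reparameterize(post: EncoderPosterior, seed) -> LatentSample:
    """Draw z = mu + exp(logvar/2) * eps with eps ~ N(0, I); seeded."""
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(post.mu.size)
    return LatentSample(post.mu + np.exp(0.5 * post.logvar) * eps)


def kl_divergence(post: EncoderPosterior) -> float:
    """Closed-form KL( q(z|x) || N(0, I) ) in nats; always >= 0."""
    return float(
        0.5 * np.sum(post.mu**2 + np.exp(post.logvar) - post.logvar - 1.0)
    )


def elbo_loss(x: np.ndarray, x_hat: np.ndarray, post: EncoderPosterior) -> LossRecord:
    """Negative ELBO of one sample: summed squared error + KL divergence."""
    x = np.asarray(x, dtype=float)
    x_hat = np.asarray(x_hat, dtype=float)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    recon = float(np.sum((x - x_hat) ** 2))
    return LossRecord(epoch=0, reconstruction=recon, kl=kl_divergence(post))


def train_vae(tensor: SeriesTensor, config: VAEConfig) -> tuple[VAEModel, list[LossRecord]]:
    """Train the VAE on a normalized tensor; returns the model and the
    per-epoch loss curve (batch-mean reconstruction, KL and total, all in
    the minimized sign convention)."""
    data = tensor.data if isinstance(tensor, SeriesTensor) else np.asarray(tensor)
    if data.ndim != 3 or data.shape[0] < 2:
        raise ValueError("need a (n_sets >= 2, n_points, n_channels) tensor")
    if data.min() < -0.1 or data.max() > 1.1:
        warnings.warn(
            "training data outside [0, 1]; did you apply a min-max normalizer?",
            stacklevel=2,
        )
    cfg = VAEConfig(**{**config.__dict__,
                       "n_points": data.shape[1], "n_channels": data.shape[2]})
    model = VAEModel(cfg)
    # start the decoder output at the per-position channel means: the first
    # epochs then refine structure instead of re-learning the mean surface
    margin = _Sigmoid.margin
    mean_map = (np.clip(data.mean(axis=0), 1e-3, 1 - 1e-3) + margin) / (1 + 2 * margin)
    out_layer = model.dec_conv[-2]
    out_layer.W.value *= _DTYPE(_OUT_W_INIT_SCALE)
    out_layer.b.value[:] = np.log(mean_map / (1 - mean_map)).mean(axis=0)
    n = data.shape[0]
    batch = n if cfg.batch_size is None else min(cfg.batch_size, n)
    total_steps = cfg.epochs * int(np.ceil(n / batch))
    opt = _Adam(model.params, lr=cfg.learning_rate, max_grad_norm=cfg.max_grad_norm,
                warmup_steps=max(1, total_steps // 5), total_steps=total_steps)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x7A1]))
    data = np.asarray(data, dtype=_DTYPE)

    anneal_steps = int(cfg.kl_anneal_frac * total_steps)
    step = 0
    history: list[LossRecord] = []
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(n)
        ep_recon = ep_kl = 0.0
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            x = data[idx]
            m = x.shape[0]

            mu, logvar = model.encode_batch(x, training=True)
            eps = rng.standard_normal(mu.shape).astype(_DTYPE)
            sd = np.exp(0.5 * logvar)
            z = mu + sd * eps
            model._dz_dlogvar = 0.5 * sd * eps
            x_hat = model.decode_batch(z, training=True)

            diff = x_hat - x
            recon = float(np.sum(diff.astype(np.float64) ** 2)) / m
            kl = float(0.5 * np.sum(mu.astype(np.float64) ** 2
                                    + np.exp(logvar.astype(np.float64))
                                    - logvar.astype(np.float64) - 1.0)) / m
            if not np.isfinite(recon + kl):
                raise RuntimeError(f"NaN/inf loss at epoch {epoch}")

            step += 1
            beta = min(1.0, step / anneal_steps) if anneal_steps else 1.0
            dx_hat = (2.0 / m) * diff
            dmu = _DTYPE(beta) * mu / m
            dlogvar = _DTYPE(beta) * 0.5 * (np.exp(logvar) - 1.0) / m
            model._backward(dx_hat, dmu, dlogvar)
            opt.step()

            ep_recon += recon * m / n
            ep_kl += kl * m / n
        history.append(LossRecord(epoch=epoch, reconstruction=ep_recon, kl=ep_kl))
    # final per-experiment posteriors (eval mode): the aggregate posterior
    # these define is the default sampling distribution for generation
    mu_all, logvar_all = model.encode_batch(data, training=False)
    model.train_posteriors = (np.asarray(mu_all, float), np.asarray(logvar_all, float))
    return model, history


def generate_synthetic(
    model: VAEModel,
    n: int,
    normalizer: Normalizer,
    seed,
    time: np.ndarray | None = None,
    sampling: str = "aggregate_posterior",
    temperature: float = 0.5,
) -> ExperimentCollection:
    """Sample ``n`` latent vectors, decode them, and inverse-normalize into
    synthetic experiments.

    ``sampling="aggregate_posterior"`` (default) draws z from the uniform
    mixture of the training experiments' posteriors q(z|x_i) — the latent
    region the decoder actually models — so the pool spans the originals'
    spread, blends included.  ``temperature`` scales the posterior spread
    (1 = the exact aggregate posterior; smaller keeps samples nearer the
    learned modes).  ``sampling="prior"`` draws from N(0, I).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if sampling == "prior":
        z = rng.standard_normal((n, model.config.latent_dim))
    elif sampling == "aggregate_posterior":
        if model.train_posteriors is None:
            raise ValueError("model has no stored training posteriors; train first "
                             "or use sampling='prior'")
        mu, logvar = model.train_posteriors
        which = rng.integers(mu.shape[0], size=n)
        eps = rng.standard_normal((n, model.config.latent_dim))
        z = mu[which] + temperature * np.exp(0.5 * logvar[which]) * eps
    else:
        raise ValueError(f"unknown sampling mode {sampling!r}")
    decoded = model.decode_batch(z, training=False).astype(float)
    decoded = np.clip(decoded, 0.0, 1.0)   # decoder margin never leaves the box
    raw = normalizer.inverse_values(decoded)
    if time is None:
        time = model.time_grid
    if time is None:
        time = np.linspace(0.0, 10.0, model.config.n_points)
    return collection_from_tensor(raw, time, provenance="synthetic")
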