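"""CNN–Transformer β-VAE over instance windows.

The encoder applies 1D convolutional blocks to the (L, C) window, adds
sinusoidal positional encoding, runs a Transformer encoder over the L
tokens, pools, and parameterizes a diagonal Gaussian posterior q(z|x) =
N(mu(x), diag(sigma^2(x))).  The decoder projects z back to L tokens,
runs Transformer blocks and a convolutional head to reconstruct the window.

Training minimizes the β-weighted negative ELBO

    L(x) = MSE(x, x_hat) + β · KL(q(z|x) || N(0, I)),

with the reconstruction MSE restricted to valid (unmasked) window positions,
AdamW, a linear β warm-up over the first epochs, and early stopping on an
unmodified validation subset.  At inference the posterior mean (not a
sample) is decoded, so scores are deterministic.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np

from .features import FEATURE_SCHEMA, InstanceWindow
from .nn import (
    AdamW,
    Conv1d,
    LayerNorm,
    Linear,
    Module,
    Tensor,
    TransformerBlock,
    activate,
    sinusoidal_positions,
)

log = logging.getLogger(__name__)


class VaeError(ValueError):
    pass


@dataclass
class VaeConfig:
    L: int = 7
    C: int = 11
    conv_channels: tuple = (64, 64)
    conv_kernel: int = 3
    token_dim: int = 64
    n_encoder_layers: int = 2
    n_decoder_layers: int = 2
    n_heads: int = 4
    latent_dim: int = 16
    ff_mult: int = 2
    activation: str = "relu"  # or "gelu"
    pooling: str = "mean"  # or "attention"
    beta_max: float = 0.01
    warmup_epochs: int = 3
    learning_rate: float = 3e-3
    lr_schedule: str = "cosine"  # or "constant"
    lr_min_factor: float = 0.1
    weight_decay: float = 1e-4
    max_epochs: int = 60
    patience: int = 10
    batch_size: int = 128
    dtype: str = "float32"  # parameter/activation precision
    seed: int = 0

    def __post_init__(self):
        if self.latent_dim > self.token_dim:
            raise VaeError("latent_dim must be <= token_dim")
        if self.pooling not in ("mean", "attention"):
            raise VaeError(f"unknown pooling {self.pooling!r}")
        if self.lr_schedule not in ("cosine", "constant"):
            raise VaeError(f"unknown lr_schedule {self.lr_schedule!r}")
        if min(self.L, self.C, self.token_dim, self.latent_dim) < 1:
            raise VaeError("all dimensions must be positive")
        if self.conv_channels[-1] != self.token_dim:
            raise VaeError("last conv channel count must equal token_dim")


def feature_schema_hash(config: "VaeConfig") -> str:
    key = f"{FEATURE_SCHEMA}|L={config.L}|C={config.C}"
    return hashlib.sha256(key.encode()).hexdigest()[:16]


@dataclass
class LatentPosterior:
    """Diagonal Gaussian posterior parameters, one row per instance."""

    mu: np.ndarray
    logvar: np.ndarray

    def __post_init__(self):
        self.mu = np.atleast_2d(np.asarray(self.mu, dtype=np.float64))
        self.logvar = np.atleast_2d(np.asarray(self.logvar, dtype=np.float64))
        if not (np.isfinite(self.mu).all() and np.isfinite(self.logvar).all()):
            raise VaeError("non-finite posterior parameters")


def beta_at_epoch(epoch: int, beta_max: float, warmup_epochs: int) -> float:
    """Linear β ramp: 0 at epoch 0, beta_max from warmup_epochs onward."""
    if warmup_epochs <= 0 or epoch >= warmup_epochs:
        return beta_max
    return beta_max * epoch / warmup_epochs


def lr_at_epoch(epoch: int, config: "VaeConfig") -> float:
    """Learning rate for an epoch: constant, or half-cosine decay from
    learning_rate down to lr_min_factor * learning_rate at max_epochs."""
    if config.lr_schedule == "constant" or config.max_epochs <= 1:
        return config.learning_rate
    lo = config.lr_min_factor * config.learning_rate
    frac = min(epoch / (config.max_epochs - 1), 1.0)
    return lo + 0.5 * (config.learning_rate - lo) * (1 + np.cos(np.pi * frac))


def elbo_terms(x, xhat, mu, logvar, beta, mask=None):
    """(total, recon_mse, kl) of the β-weighted negative ELBO, on numpy
    arrays; accepts a single window (L, C) or a batch (B, L, C).

    recon_mse averages squared error over valid positions and all channels;
    kl is the closed-form diagonal-Gaussian KL to N(0, I), averaged over the
    batch:  0.5 * sum_h (mu_h^2 + sigma_h^2 - 1 - log sigma_h^2).
    """
    if beta < 0:
        raise VaeError("beta must be >= 0")
    x = np.asarray(x, dtype=np.float64)
    xhat = np.asarray(xhat, dtype=np.float64)
    single = x.ndim == 2
    if single:
        x, xhat = x[None], xhat[None]
    B, L, C = x.shape
    if mask is None:
        mask = np.ones((B, L), dtype=bool)
    else:
        mask = np.atleast_2d(np.asarray(mask, dtype=bool))
    sq = (x - xhat) ** 2 * mask[:, :, None]
    recon = sq.sum() / (mask.sum() * C)
    mu = np.atleast_2d(np.asarray(mu, dtype=np.float64))
    logvar = np.atleast_2d(np.asarray(logvar, dtype=np.float64))
    kl_per = 0.5 * (mu**2 + np.exp(logvar) - 1.0 - logvar).sum(axis=1)
    kl = kl_per.mean()
    return recon + beta * kl, recon, kl


class CnnTransformerVae(Module):
    """The reference-signal model; see module docstring."""

    def __init__(self, config: VaeConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        cfg = config
        chans = [cfg.C, *cfg.conv_channels]
        self.enc_convs = [
            Conv1d(chans[i], chans[i + 1], cfg.conv_kernel, rng)
            for i in range(len(cfg.conv_channels))
        ]
        self.posenc = sinusoidal_positions(cfg.L, cfg.token_dim)
        self.enc_blocks = [
            TransformerBlock(
                cfg.token_dim, cfg.n_heads, cfg.ff_mult, rng,
                activation=cfg.activation,
            )
            for _ in range(cfg.n_encoder_layers)
        ]
        self.enc_ln = LayerNorm(cfg.token_dim)
        if cfg.pooling == "attention":
            self.pool_query = Linear(cfg.token_dim, 1, rng)
        self.to_posterior = Linear(cfg.token_dim, 2 * cfg.latent_dim, rng)

        self.from_latent = Linear(cfg.latent_dim, cfg.L * cfg.token_dim, rng)
        self.dec_blocks = [
            TransformerBlock(
                cfg.token_dim, cfg.n_heads, cfg.ff_mult, rng,
                activation=cfg.activation,
            )
            for _ in range(cfg.n_decoder_layers)
        ]
        self.dec_ln = LayerNorm(cfg.token_dim)
        self.dec_conv = Conv1d(cfg.token_dim, cfg.token_dim, cfg.conv_kernel, rng)
        self.dec_out = Conv1d(cfg.token_dim, cfg.C, cfg.conv_kernel, rng)

        self._np_dtype = np.float32 if cfg.dtype == "float32" else np.float64
        self.astype(self._np_dtype)
        self.posenc = self.posenc.astype(self._np_dtype)

    # -- graph builders (Tensor in, Tensor out) -----------------------------

    def _encode_graph(self, x: Tensor) -> tuple[Tensor, Tensor]:
        h = x
        for conv in self.enc_convs:
            h = activate(conv(h), self.config.activation)
        h = h + Tensor(self.posenc)
        for block in self.enc_blocks:
            h = block(h)
        h = self.enc_ln(h)
        if self.config.pooling == "attention":
            w = self.pool_query(h).transpose(0, 2, 1).softmax()  # (B,1,T)
            pooled = (w @ h).reshape(h.shape[0], self.config.token_dim)
        else:
            pooled = h.mean(axis=1)
        stats = self.to_posterior(pooled)
        H = self.config.latent_dim
        return stats[:, :H], stats[:, H:]

    def _decode_graph(self, z: Tensor) -> Tensor:
        cfg = self.config
        h = self.from_latent(z).reshape(z.shape[0], cfg.L, cfg.token_dim)
        h = h + Tensor(self.posenc)
        for block in self.dec_blocks:
            h = block(h)
        h = self.dec_ln(h)
        h = activate(self.dec_conv(h), self.config.activation)
        return self.dec_out(h)

    def _loss_graph(self, xb, maskb, beta, eps):
        """Training loss on a numpy batch; eps None decodes the mean."""
        x = Tensor(np.asarray(xb, dtype=self._np_dtype))
        if eps is not None:
            eps = np.asarray(eps, dtype=self._np_dtype)
        mu, logvar = self._encode_graph(x)
        if eps is None:
            z = mu
        else:
            z = mu + (logvar * 0.5).exp() * Tensor(eps)
        xhat = self._decode_graph(z)
        w = maskb[:, :, None].astype(self._np_dtype)
        denom = maskb.sum() * xb.shape[2]
        recon = (((xhat - x) ** 2) * Tensor(w)).sum() * (1.0 / denom)
        kl_all = (mu**2 + logvar.exp() - 1.0 - logvar).sum() * (0.5 / xb.shape[0])
        total = recon + beta * kl_all
        return total, recon, kl_all

    # -- numpy-facing API ---------------------------------------------------

    def _check_shape(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        single = x.ndim == 2
        if single:
            x = x[None]
        if x.shape[1:] != (self.config.L, self.config.C):
            raise VaeError(
                f"window shape {x.shape[1:]} does not match config "
                f"({self.config.L}, {self.config.C})"
            )
        if not np.isfinite(x).all():
            raise VaeError("non-finite input window")
        return x

    def encode(self, x: np.ndarray) -> LatentPosterior:
        """Posterior parameters for a window or batch of windows."""
        xb = self._check_shape(x)
        mu, logvar = self._encode_graph(Tensor(xb.astype(self._np_dtype)))
        return LatentPosterior(mu=mu.data, logvar=logvar.data)

    def decode(self, z: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(np.asarray(z, dtype=self._np_dtype))
        if z.shape[1] != self.config.latent_dim:
            raise VaeError(
                f"latent length {z.shape[1]} != latent_dim {self.config.latent_dim}"
            )
        out = self._decode_graph(Tensor(z)).data
        if not np.isfinite(out).all():
            raise VaeError("non-finite reconstruction")
        return out

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        """Deterministic reconstruction: decode the posterior mean."""
        xb = self._check_shape(x)
        return self.decode(self.encode(xb).mu)

    @staticmethod
    def loss(x, xhat, posterior: LatentPosterior, beta: float, validity_mask=None):
        """(total, recon_mse, kl); see :func:`elbo_terms`."""
        return elbo_terms(x, xhat, posterior.mu, posterior.logvar, beta, validity_mask)

    # -- checkpointing ------------------------------------------------------

    def save(self, path) -> None:
        arrays = {f"param_{i}": a for i, a in enumerate(self.state_arrays())}
        meta = {
            "config": asdict(self.config),
            "schema_hash": feature_schema_hash(self.config),
            "feature_schema": FEATURE_SCHEMA,
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "CnnTransformerVae":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            cfg_dict = meta["config"]
            cfg_dict["conv_channels"] = tuple(cfg_dict["conv_channels"])
            config = VaeConfig(**cfg_dict)
            model = cls(config)
            n = len(model.parameters())
            model.load_arrays([data[f"param_{i}"] for i in range(n)])
        if meta["schema_hash"] != feature_schema_hash(config):
            raise VaeError("checkpoint feature schema does not match this build")
        return model

    @property
    def schema_hash(self) -> str:
        return feature_schema_hash(self.config)


def windows_to_arrays(windows: list[InstanceWindow]):
    x = np.stack([w.x for w in windows]).astype(np.float64)
    mask = np.stack([w.mask for w in windows])
    return x, mask


@dataclass
class TrainState:
    """Outcome of a training run: best model plus per-epoch history."""

    model: CnnTransformerVae
    history: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = np.inf

    def history_rows(self):
        return self.history


def _validation_loss(model, x_val, mask_val, beta, chunk=512):
    tot = rec = kl = 0.0
    n = 0
    for i in range(0, len(x_val), chunk):
        xb, mb = x_val[i : i + chunk], mask_val[i : i + chunk]
        post = model.encode(xb)
        xhat = model.decode(post.mu)
        t, r, k = elbo_terms(xb, xhat, post.mu, post.logvar, beta, mb)
        w = len(xb)
        tot += t * w
        rec += r * w
        kl += k * w
        n += w
    return tot / n, rec / n, kl / n


def train(
    train_windows,
    validation_windows,
    config: VaeConfig,
    batches_per_epoch: int | None = None,
) -> TrainState:
    """Train a fresh model on unmodified instance windows.

    ``train_windows`` is either a list of InstanceWindow (shuffled and
    batched internally each epoch) or a callable ``epoch -> iterator of
    window batches`` for streaming corpora.  ``validation_windows`` must be
    drawn from unmodified data only; validation loss is always computed at
    beta_max so epochs are comparable across the warm-up.
    """
    model = CnnTransformerVae(config)
    opt = AdamW(
        model.parameters(),
        lr=config.learning_rate,
        weight_decay=config.weight_decay,
    )
    rng = np.random.default_rng(config.seed)
    if not callable(train_windows):
        windows = list(train_windows)
        if not windows:
            raise VaeError("empty training stream")

        def batch_factory(epoch):
            order = rng.permutation(len(windows))
            for i in range(0, len(windows), config.batch_size):
                yield [windows[j] for j in order[i : i + config.batch_size]]

    else:
        batch_factory = train_windows

    val = list(validation_windows)
    if not val:
        raise VaeError("empty validation set")
    x_val, mask_val = windows_to_arrays(val)

    state = TrainState(model=model)
    best_arrays = None
    bad_epochs = 0
    for epoch in range(config.max_epochs):
        beta = beta_at_epoch(epoch, config.beta_max, config.warmup_epochs)
        opt.lr = lr_at_epoch(epoch, config)
        ep_tot = ep_n = 0.0
        for bidx, batch in enumerate(batch_factory(epoch)):
            if batches_per_epoch is not None and bidx >= batches_per_epoch:
                break
            xb, mb = windows_to_arrays(batch)
            eps = rng.standard_normal((len(xb), config.latent_dim))
            total, recon, kl = model._loss_graph(xb, mb, beta, eps)
            if not np.isfinite(total.data):
                raise VaeError(
                    f"non-finite training loss at epoch {epoch} batch {bidx}"
                )
            opt.zero_grad()
            total.backward()
            opt.step()
            ep_tot += float(total.data) * len(xb)
            ep_n += len(xb)
        if ep_n == 0:
            raise VaeError("empty training stream")
        val_tot, val_rec, val_kl = _validation_loss(
            model, x_val, mask_val, config.beta_max
        )
        state.history.append(
            {
                "epoch": epoch,
                "beta": beta,
                "train_loss": ep_tot / ep_n,
                "val_loss": val_tot,
                "val_recon": val_rec,
                "val_kl": val_kl,
            }
        )
        log.info(
            "epoch %d beta=%.4g train=%.5f val=%.5f (recon %.5f, kl %.5f)",
            epoch, beta, ep_tot / ep_n, val_tot, val_rec, val_kl,
        )
        if val_tot < state.best_val_loss:
            state.best_val_loss = val_tot
            state.best_epoch = epoch
            best_arrays = [a.copy() for a in model.state_arrays()]
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > config.patience:
                log.info("early stopping at epoch %d", epoch)
                break
    if best_arrays is not None:
        model.load_arrays(best_arrays)
    return state


def write_history_tsv(state: TrainState, path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["epoch", "beta", "train_loss", "val_loss", "val_recon", "val_kl"])
        for row in state.history:
            w.writerow(
                [
                    row["epoch"],
                    f"{row['beta']:.6g}",
                    f"{row['train_loss']:.6f}",
                    f"{row['val_loss']:.6f}",
                    f"{row['val_recon']:.6f}",
                    f"{row['val_kl']:.6f}",
                ]
            )
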