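"""Convolutional variational autoencoder with a 2D latent space.

The model condenses 64x64 aortic cross-sections into a two-dimensional
Gaussian posterior (mean, log-variance) and reconstructs them from sampled
latent codes.  Encoder: two strided Conv2D layers, a dense bottleneck, and
linear heads for the posterior mean and log-variance.  Decoder: the mirror
image built from transposed convolutions, emitting pixel logits mapped
through a sigmoid into [0, 1].  Training maximizes the evidence lower bound:
a per-image reconstruction term (Bernoulli cross-entropy by default, squared
error optionally) plus the closed-form KL divergence between the diagonal
Gaussian posterior and the standard-normal prior.

Everything runs on plain numpy (see :mod:`flvae.nn`); training uses float32
arithmetic, the inference API (`encode`, `decode`) float64.  All randomness
flows from the config seed, so identical (data, config) reruns reproduce the
loss history bit for bit on a fixed platform.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Union

import numpy as np

from . import nn
from .types import CrossSection, LatentPoint

IMG = 64  # canonical input size


@dataclass
class VAEConfig:
    latent_dim: int = 2
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    conv_channels: tuple = (16, 32)
    kernel_size: int = 3
    stride: int = 2
    seed: int = 0
    recon_loss: str = "bernoulli"
    hidden_units: int = 16

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1 or self.hidden_units < 1:
            raise ValueError("sizes must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.kernel_size < 1 or self.stride < 1:
            raise ValueError("kernel_size and stride must be positive")
        self.conv_channels = tuple(int(c) for c in self.conv_channels)
        if len(self.conv_channels) != 2 or any(c < 1 for c in self.conv_channels):
            raise ValueError("conv_channels must be two positive integers")
        if self.recon_loss not in ("bernoulli", "gaussian"):
            raise ValueError("recon_loss must be 'bernoulli' or 'gaussian'")
        if self.latent_dim != 2:
            warnings.warn(
                f"latent_dim={self.latent_dim} is non-canonical; the scoring "
                "convention assumes a 2D latent space", stacklevel=2)

    def fingerprint(self) -> str:
        arch = dict(latent_dim=self.latent_dim, conv_channels=list(self.conv_channels),
                    kernel_size=self.kernel_size, stride=self.stride,
                    hidden_units=self.hidden_units)
        return hashlib.sha256(json.dumps(arch, sort_keys=True).encode()).hexdigest()[:12]


def _enc_sizes(cfg: VAEConfig) -> tuple:
    pad = cfg.kernel_size // 2
    h1 = (IMG + 2 * pad - cfg.kernel_size) // cfg.stride + 1
    h2 = (h1 + 2 * pad - cfg.kernel_size) // cfg.stride + 1
    if h2 < 2:
        raise ValueError(
            f"architecture collapses below 2x2 ({IMG}->{h1}->{h2}); "
            "reduce stride or kernel_size")
    return pad, h1, h2


@dataclass
class VAEParams:
    """Trained (or freshly initialized) weight collection plus provenance."""

    weights: dict
    config: VAEConfig
    fingerprint: str
    seed: int
    loss_history: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))

    def loss_history_frame(self):
        import pandas as pd

        return pd.DataFrame(self.loss_history, columns=["total", "recon", "kl"]) \
            .rename_axis("epoch").reset_index()


def init_model(config: VAEConfig) -> VAEParams:
    """Deterministically initialize all weights from ``config.seed``."""
    pad, h1, h2 = _enc_sizes(config)
    c1, c2 = config.conv_channels
    k, hid, ld = config.kernel_size, config.hidden_units, config.latent_dim
    flat = c2 * h2 * h2
    rng = np.random.default_rng(config.seed)

    def he(shape, fan_in):
        return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)

    def lin(shape, fan_in):
        return (rng.standard_normal(shape) * np.sqrt(1.0 / fan_in)).astype(np.float32)

    w = {
        "enc_c1_w": he((c1, 1, k, k), k * k), "enc_c1_b": np.zeros(c1, np.float32),
        "enc_c2_w": he((c2, c1, k, k), c1 * k * k), "enc_c2_b": np.zeros(c2, np.float32),
        "enc_d_w": he((flat, hid), flat), "enc_d_b": np.zeros(hid, np.float32),
        "enc_mu_w": lin((hid, ld), hid), "enc_mu_b": np.zeros(ld, np.float32),
        "enc_lv_w": lin((hid, ld), hid), "enc_lv_b": np.zeros(ld, np.float32),
        "dec_d1_w": he((ld, hid), ld), "dec_d1_b": np.zeros(hid, np.float32),
        "dec_d2_w": he((hid, flat), hid), "dec_d2_b": np.zeros(flat, np.float32),
        "dec_t1_w": he((c2, c1, k, k), c2 * k * k), "dec_t1_b": np.zeros(c1, np.float32),
        "dec_t2_w": lin((c1, 1, k, k), c1 * k * k), "dec_t2_b": np.zeros(1, np.float32),
    }
    return VAEParams(weights=w, config=config, fingerprint=config.fingerprint(),
                     seed=config.seed)


# ---------------------------------------------------------------------------
# forward / backward

def _encode_forward(w, x, cfg, cache=None):
    pad, h1, h2 = _enc_sizes(cfg)
    s = cfg.stride
    a1 = nn.conv2d(x, w["enc_c1_w"], w["enc_c1_b"], s, pad)
    r1 = nn.relu(a1)
    a2 = nn.conv2d(r1, w["enc_c2_w"], w["enc_c2_b"], s, pad)
    r2 = nn.relu(a2)
    f = r2.reshape(x.shape[0], -1)
    a3 = f @ w["enc_d_w"] + w["enc_d_b"]
    r3 = nn.relu(a3)
    mu = r3 @ w["enc_mu_w"] + w["enc_mu_b"]
    lv = r3 @ w["enc_lv_w"] + w["enc_lv_b"]
    if cache is not None:
        cache.update(x=x, a1=a1, r1=r1, a2=a2, r2=r2, f=f, a3=a3, r3=r3)
    return mu, lv


def _decode_forward(w, z, cfg, cache=None):
    pad, h1, h2 = _enc_sizes(cfg)
    c1, c2 = cfg.conv_channels
    s = cfg.stride
    b1 = z @ w["dec_d1_w"] + w["dec_d1_b"]
    q1 = nn.relu(b1)
    b2 = q1 @ w["dec_d2_w"] + w["dec_d2_b"]
    q2 = nn.relu(b2)
    g = q2.reshape(z.shape[0], c2, h2, h2)
    t1 = nn.conv_transpose2d(g, w["dec_t1_w"], w["dec_t1_b"], s, pad, h1)
    u1 = nn.relu(t1)
    logits = nn.conv_transpose2d(u1, w["dec_t2_w"], w["dec_t2_b"], s, pad, IMG)
    if cache is not None:
        cache.update(z=z, b1=b1, q1=q1, b2=b2, q2=q2, g=g, t1=t1, u1=u1, logits=logits)
    return logits


def _loss_and_grads(w, x, eps, cfg):
    """One training step's loss terms and weight gradients for batch x."""
    B = x.shape[0]
    ec, dc = {}, {}
    mu, lv = _encode_forward(w, x, cfg, ec)
    z = mu + np.exp(0.5 * lv) * eps
    logits = _decode_forward(w, z, cfg, dc)

    if cfg.recon_loss == "bernoulli":
        per_px, dlogits = nn.bce_with_logits(logits, x)
        recon = float(per_px.sum()) / B
    else:
        out = nn.sigmoid(logits)
        diff = out - x
        recon = float(np.square(diff).sum()) / B
        dlogits = 2.0 * diff * out * (1.0 - out)
    kl = float(-0.5 * np.sum(1.0 + lv - mu ** 2 - np.exp(lv))) / B
    dlogits = (dlogits / B).astype(x.dtype)

    grads = {}
    pad, h1, h2 = _enc_sizes(cfg)
    s = cfg.stride
    # decoder backward
    du1, grads["dec_t2_w"], grads["dec_t2_b"] = nn.conv_transpose2d_backward(
        dlogits, dc["u1"], w["dec_t2_w"], s, pad)
    dt1 = nn.relu_backward(du1, dc["t1"])
    dg, grads["dec_t1_w"], grads["dec_t1_b"] = nn.conv_transpose2d_backward(
        dt1, dc["g"], w["dec_t1_w"], s, pad)
    dq2 = nn.relu_backward(dg.reshape(B, -1), dc["b2"])
    grads["dec_d2_w"] = dc["q1"].T @ dq2
    grads["dec_d2_b"] = dq2.sum(axis=0)
    dq1 = nn.relu_backward(dq2 @ w["dec_d2_w"].T, dc["b1"])
    grads["dec_d1_w"] = dc["z"].T @ dq1
    grads["dec_d1_b"] = dq1.sum(axis=0)
    dz = dq1 @ w["dec_d1_w"].T

    # through the reparameterization, plus KL gradients
    sig = np.exp(0.5 * lv)
    dmu = dz + mu / B
    dlv = dz * 0.5 * sig * eps + 0.5 * (np.exp(lv) - 1.0) / B

    # encoder backward
    dr3 = dmu @ w["enc_mu_w"].T + dlv @ w["enc_lv_w"].T
    grads["enc_mu_w"] = ec["r3"].T @ dmu
    grads["enc_mu_b"] = dmu.sum(axis=0)
    grads["enc_lv_w"] = ec["r3"].T @ dlv
    grads["enc_lv_b"] = dlv.sum(axis=0)
    da3 = nn.relu_backward(dr3, ec["a3"])
    grads["enc_d_w"] = ec["f"].T @ da3
    grads["enc_d_b"] = da3.sum(axis=0)
    df = da3 @ w["enc_d_w"].T
    dr2 = nn.relu_backward(df.reshape(ec["r2"].shape), ec["a2"])
    dr1, grads["enc_c2_w"], grads["enc_c2_b"] = nn.conv2d_backward(
        dr2, ec["r1"], w["enc_c2_w"], s, pad)
    da1 = nn.relu_backward(dr1, ec["a1"])
    _, grads["enc_c1_w"], grads["enc_c1_b"] = nn.conv2d_backward(
        da1, ec["x"], w["enc_c1_w"], s, pad)
    return recon, kl, grads


# ---------------------------------------------------------------------------
# public API

def _as_batch(images, dtype=np.float64) -> np.ndarray:
    if isinstance(images, CrossSection):
        images = [images]
    if isinstance(images, np.ndarray) and images.ndim == 2:
        images = [images]
    arrs = [im.pixels if isinstance(im, CrossSection) else np.asarray(im) for im in images]
    batch = np.stack(arrs).astype(dtype)
    if batch.ndim != 3 or batch.shape[1:] != (IMG, IMG):
        raise ValueError(f"expected {IMG}x{IMG} images, got batch shape {batch.shape}")
    if batch.min() < -1e-9 or batch.max() > 1 + 1e-9:
        raise ValueError("image intensities must lie in [0, 1]")
    return batch


def _weights64(params: VAEParams) -> dict:
    return {k: v.astype(np.float64) for k, v in params.weights.items()}


def encode(params: VAEParams, image: Union[CrossSection, np.ndarray]) -> LatentPoint:
    """Posterior (mu, logvar) of a single image; deterministic, no sampling."""
    mu, lv = encode_batch(params, _as_batch(image))
    return LatentPoint(mu=mu[0], logvar=lv[0])


def encode_batch(params: VAEParams, images) -> tuple:
    """Posterior means and log-variances for a stack of images, float64."""
    x = _as_batch(images)[:, None, :, :]
    mu, lv = _encode_forward(_weights64(params), x, params.config)
    return mu, lv


def decode(params: VAEParams, z: np.ndarray) -> np.ndarray:
    """Decode one latent vector to a 64x64 image in [0, 1]."""
    z = np.atleast_2d(np.asarray(z, dtype=np.float64))
    if z.shape[1] != params.config.latent_dim:
        raise ValueError(f"z must have length {params.config.latent_dim}")
    logits = _decode_forward(_weights64(params), z, params.config)
    return nn.sigmoid(logits)[0, 0]


def reparameterize(mu, logvar, noise) -> np.ndarray:
    """z = mu + exp(logvar / 2) * noise (elementwise)."""
    mu, logvar, noise = (np.asarray(a, dtype=np.float64) for a in (mu, logvar, noise))
    return mu + np.exp(0.5 * logvar) * noise


def kl_divergence(mu, logvar) -> float:
    """Closed-form KL(q(z|x) || N(0, I)) for a diagonal Gaussian posterior."""
    mu = np.asarray(mu, dtype=np.float64)
    logvar = np.asarray(logvar, dtype=np.float64)
    if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(logvar))):
        raise ValueError("non-finite latent parameters")
    kl = float(-0.5 * np.sum(1.0 + logvar - mu ** 2 - np.exp(logvar)))
    # KL >= 0 analytically; clamp float cancellation residue near the prior
    return max(kl, 0.0) if kl > -1e-9 else kl


def elbo_loss(image, reconstruction, mu, logvar, recon_loss: str = "bernoulli") -> tuple:
    """(total, recon_term, kl_term) for one image/reconstruction pair.

    ``recon_term`` is summed over pixels: Bernoulli cross-entropy for
    ``recon_loss='bernoulli'`` (reconstruction interpreted as probabilities),
    squared error for ``'gaussian'``.
    """
    x = np.asarray(image, dtype=np.float64)
    r = np.asarray(reconstruction, dtype=np.float64)
    if x.shape != r.shape:
        raise ValueError("image and reconstruction shapes differ")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(r))):
        raise ValueError("non-finite inputs to elbo_loss")
    if recon_loss == "bernoulli":
        rc = np.clip(r, 1e-7, 1 - 1e-7)
        recon = float(-(x * np.log(rc) + (1 - x) * np.log(1 - rc)).sum())
    elif recon_loss == "gaussian":
        recon = float(np.square(r - x).sum())
    else:
        raise ValueError("recon_loss must be 'bernoulli' or 'gaussian'")
    kl = kl_divergence(mu, logvar)
    return recon + kl, recon, kl


def train(images: Sequence, config: VAEConfig,
          progress: bool = False) -> VAEParams:
    """Train the VAE on a stack of cross-sections.

    Returns fresh ``VAEParams`` whose ``loss_history`` has one row per epoch
    with per-image (summed-over-pixels) losses averaged over the epoch:
    columns total, reconstruction, KL.
    """
    data = _as_batch(images, dtype=np.float32)
    n = data.shape[0]
    if n == 0:
        raise ValueError("cannot train on an empty dataset")
    params = init_model(config)
    w = params.weights
    opt = nn.Adam(w, lr=config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x7AE]))
    history = np.zeros((config.epochs, 3))
    bs = min(config.batch_size, n)
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        tot = rec = kl = 0.0
        for start in range(0, n, bs):
            idx = perm[start:start + bs]
            x = data[idx][:, None, :, :]
            eps = rng.standard_normal((len(idx), config.latent_dim)).astype(np.float32)
            r, k, grads = _loss_and_grads(w, x, eps, config)
            if not np.isfinite(r + k):
                raise RuntimeError(f"non-finite loss at epoch {epoch}")
            opt.step(w, grads)
            rec += r * len(idx)
            kl += k * len(idx)
        history[epoch] = [(rec + kl) / n, rec / n, kl / n]
        if progress and (epoch % 10 == 0 or epoch == config.epochs - 1):
            print(f"epoch {epoch:3d}  total {history[epoch, 0]:10.2f}  "
                  f"recon {history[epoch, 1]:10.2f}  kl {history[epoch, 2]:7.3f}")
    params.loss_history = history
    return params


def latent_grid_panel(params: VAEParams, lo: float = -3.0, hi: float = 3.0,
                      n: int = 15) -> np.ndarray:
    """Montage of decoded images over a uniform n x n latent grid.

    Tile (i, j) decodes latent (x_j, y_i) with x increasing rightward along
    columns and y increasing downward along rows, both from ``lo`` to ``hi``.
    Returns an ``(n*64, n*64)`` array in [0, 1].
    """
    if not lo < hi:
        raise ValueError("require lo < hi")
    if n < 2:
        raise ValueError("require n >= 2")
    xs = np.linspace(lo, hi, n)
    panel = np.zeros((n * IMG, n * IMG))
    w64 = _weights64(params)
    grid = np.array([[x, y] for y in xs for x in xs])  # row-major: y outer
    imgs = nn.sigmoid(_decode_forward(w64, grid, params.config))[:, 0]
    for i in range(n):
        for j in range(n):
            panel[i * IMG:(i + 1) * IMG, j * IMG:(j + 1) * IMG] = imgs[i * n + j]
    return panel


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(params: VAEParams, path) -> None:
    """Persist weights + config + seed + loss history to one ``.npz`` file."""
    meta = {"config": vars(params.config).copy(), "seed": params.seed,
            "fingerprint": params.fingerprint}
    meta["config"]["conv_channels"] = list(params.config.conv_channels)
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             loss_history=params.loss_history,
             **{f"w_{k}": v for k, v in params.weights.items()})


def load_checkpoint(path) -> VAEParams:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        cfg_d = meta["config"]
        cfg_d["conv_channels"] = tuple(cfg_d["conv_channels"])
        config = VAEConfig(**cfg_d)
        if config.fingerprint() != meta["fingerprint"]:
            raise ValueError("checkpoint fingerprint does not match its config")
        weights = {k[2:]: z[k] for k in z.files if k.startswith("w_")}
        return VAEParams(weights=weights, config=config,
                         fingerprint=meta["fingerprint"], seed=meta["seed"],
                         loss_history=z["loss_history"])
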