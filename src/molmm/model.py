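"""Network definition: shared feature encoder plus task-specific heads.

The architecture mirrors the two-tier training setup: one encoder
``f(d; theta)`` shared by both confidence tiers, and two parameter-disjoint
MLP heads ``g(h; phi_H)`` (refined, high-confidence task) and
``g(h; phi_L)`` (noisy, low-confidence task), each emitting the probability
of the positive class.  Two encoder families are provided: a small CNN over
2D descriptor feature maps and an MLP over flat descriptor vectors.

Parameters are plain dicts of name -> Tensor so the training module can
manipulate them functionally (adapted copies for the inner meta step,
flattening for gradient balancing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["ModelConfig", "ModelParams", "init_params", "encode", "head",
           "forward", "cross_entropy", "predict_proba"]

_ACTS = {"relu": ad.relu, "tanh": ad.tanh}


@dataclass
class ModelConfig:
    """Architecture sizes; defaults are small enough for CPU training."""

    encoder: str = "cnn"                 # "cnn" | "mlp"
    grid_shape: tuple[int, int] = (16, 16)
    in_channels: int = 1
    conv_channels: tuple[int, ...] = (8, 16)
    kernel: int = 3
    pool: int = 1                        # max-pool window after each conv (1 = off)
    mlp_hidden: tuple[int, ...] = (64,)
    latent_dim: int = 32
    head_hidden: int = 8
    activation: str = "tanh"
    seed: int = 0

    @property
    def input_dim(self) -> int:
        return self.in_channels * self.grid_shape[0] * self.grid_shape[1]


@dataclass
class ModelParams:
    """theta (shared encoder) and the two disjoint head parameter sets."""

    theta: dict[str, Tensor]
    phi_H: dict[str, Tensor]
    phi_L: dict[str, Tensor]
    config: ModelConfig = field(repr=False, default=None)

    def copy(self) -> "ModelParams":
        cp = lambda d: {k: Tensor(v.data.copy()) for k, v in d.items()}
        return ModelParams(cp(self.theta), cp(self.phi_H), cp(self.phi_L), self.config)


def _glorot(rng, fan_in, fan_out, shape):
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-lim, lim, size=shape))


def init_params(cfg: ModelConfig) -> ModelParams:
    rng = np.random.default_rng(cfg.seed)
    theta: dict[str, Tensor] = {}
    if cfg.encoder == "cnn":
        cin = cfg.in_channels
        h, w = cfg.grid_shape
        for i, cout in enumerate(cfg.conv_channels):
            k = cfg.kernel
            theta[f"conv{i}_w"] = _glorot(rng, cin * k * k, cout, (cout, cin * k * k))
            theta[f"conv{i}_b"] = Tensor(np.zeros(cout))
            cin = cout
            h, w = h - k + 1, w - k + 1
            if cfg.pool > 1 and h >= cfg.pool and w >= cfg.pool:
                h, w = h // cfg.pool, w // cfg.pool
            if h < 1 or w < 1:
                raise ValueError("grid too small for the configured conv stack")
        flat = cin * h * w
        theta["proj_w"] = _glorot(rng, flat, cfg.latent_dim, (flat, cfg.latent_dim))
        theta["proj_b"] = Tensor(np.zeros(cfg.latent_dim))
    elif cfg.encoder == "mlp":
        din = cfg.input_dim
        for i, hdim in enumerate(cfg.mlp_hidden):
            theta[f"fc{i}_w"] = _glorot(rng, din, hdim, (din, hdim))
            theta[f"fc{i}_b"] = Tensor(np.zeros(hdim))
            din = hdim
        theta["proj_w"] = _glorot(rng, din, cfg.latent_dim, (din, cfg.latent_dim))
        theta["proj_b"] = Tensor(np.zeros(cfg.latent_dim))
    else:
        raise ValueError(f"unknown encoder {cfg.encoder!r}")

    def head_params():
        return {
            "h_w": _glorot(rng, cfg.latent_dim, cfg.head_hidden,
                           (cfg.latent_dim, cfg.head_hidden)),
            "h_b": Tensor(np.zeros(cfg.head_hidden)),
            "out_w": _glorot(rng, cfg.head_hidden, 1, (cfg.head_hidden, 1)),
            "out_b": Tensor(np.zeros(1)),
        }

    return ModelParams(theta, head_params(), head_params(), cfg)


# ---------------------------------------------------------------------
# forward passes
# ---------------------------------------------------------------------

def _conv_indices(batch, cin, h, w, k):
    """Flat gather indices producing im2col patches for a valid conv."""
    ho, wo = h - k + 1, w - k + 1
    b = np.arange(batch)[:, None, None, None, None, None]
    c = np.arange(cin)[None, None, None, :, None, None]
    i = np.arange(ho)[None, :, None, None, None, None]
    j = np.arange(wo)[None, None, :, None, None, None]
    di = np.arange(k)[None, None, None, None, :, None]
    dj = np.arange(k)[None, None, None, None, None, :]
    idx = (b * cin * h * w + c * h * w + (i + di) * w + (j + dj))
    return idx.reshape(batch * ho * wo, cin * k * k), ho, wo


def _maxpool(x: Tensor, p: int) -> Tensor:
    """p x p max pooling via a data-dependent gather (backward: scatter)."""
    b, c, h, w = x.shape
    ho, wo = h // p, w // p
    base = (np.arange(b)[:, None, None, None, None] * c * h * w
            + np.arange(c)[None, :, None, None, None] * h * w)
    ri = (np.arange(ho)[None, None, :, None, None] * p
          + np.arange(p * p)[None, None, None, None, :] // p)
    cj = (np.arange(wo)[None, None, None, :, None] * p
          + np.arange(p * p)[None, None, None, None, :] % p)
    cand = base + ri * w + cj                       # (b, c, ho, wo, p*p)
    vals = x.data.reshape(-1)[cand]
    best = np.take_along_axis(cand, vals.argmax(axis=-1)[..., None], axis=-1)
    return ad.take(x, best[..., 0])


def encode(x: Tensor, theta: dict[str, Tensor], cfg: ModelConfig) -> Tensor:
    """Shared encoder f(d; theta): batch of inputs -> latent batch.

    CNN input: (B, C, H, W) feature-map batch; MLP input: (B, D) flat
    descriptor batch.  Fully deterministic (no dropout, no batch norm).
    """
    act = _ACTS[cfg.activation]
    if cfg.encoder == "cnn":
        if x.data.ndim == 3:
            x = ad.reshape(x, (x.shape[0], 1) + tuple(x.shape[1:]))
        batch, cin, h, w = x.shape
        if (h, w) != tuple(cfg.grid_shape) or cin != cfg.in_channels:
            raise ValueError(f"input shape {x.shape} does not match config")
        cur = x
        for i, cout in enumerate(cfg.conv_channels):
            k = cfg.kernel
            idx, ho, wo = _conv_indices(batch, cin, h, w, k)
            patches = ad.take(cur, idx)                        # (B*ho*wo, cin*k*k)
            conv = patches @ ad.transpose(theta[f"conv{i}_w"]) + theta[f"conv{i}_b"]
            conv = ad.reshape(conv, (batch, ho, wo, cout))
            cur = act(ad.permute(conv, (0, 3, 1, 2)))
            cin, h, w = cout, ho, wo
            if cfg.pool > 1 and h >= cfg.pool and w >= cfg.pool:
                cur = _maxpool(cur, cfg.pool)
                h, w = h // cfg.pool, w // cfg.pool
        flat = ad.reshape(cur, (batch, cin * h * w))
        return act(flat @ theta["proj_w"] + theta["proj_b"])
    else:
        if x.data.ndim != 2:
            x = ad.reshape(x, (x.shape[0], -1))
        if x.shape[1] != cfg.input_dim:
            raise ValueError(f"input dim {x.shape[1]} does not match config "
                             f"({cfg.input_dim})")
        cur = x
        for i in range(len(cfg.mlp_hidden)):
            cur = act(cur @ theta[f"fc{i}_w"] + theta[f"fc{i}_b"])
        return act(cur @ theta["proj_w"] + theta["proj_b"])


def head_logits(h: Tensor, phi: dict[str, Tensor], cfg: ModelConfig) -> Tensor:
    if h.shape[1] != cfg.latent_dim:
        raise ValueError("latent dimension does not match head")
    act = _ACTS[cfg.activation]
    hid = act(h @ phi["h_w"] + phi["h_b"])
    return ad.reshape(hid @ phi["out_w"] + phi["out_b"], (h.shape[0],))


def head(h: Tensor, phi: dict[str, Tensor], cfg: ModelConfig) -> Tensor:
    """Task head g(h; phi): latent batch -> positive-class probability."""
    return ad.sigmoid(head_logits(h, phi, cfg))


def forward(x: Tensor, theta, phi, cfg: ModelConfig) -> Tensor:
    """Logits of the full encoder+head composition."""
    return head_logits(encode(x, theta, cfg), phi, cfg)


def cross_entropy(logits: Tensor, y: np.ndarray) -> Tensor:
    """Mean binary cross-entropy from logits (stable log-sum-exp form)."""
    y = np.asarray(y, dtype=np.float64)
    if y.shape != tuple(logits.shape):
        raise ValueError("labels and scores must have matching length")
    return ad.tmean(ad.softplus(logits) - Tensor(y) * logits)


def predict_proba(params: ModelParams, x: np.ndarray, task: str = "H") -> np.ndarray:
    """Inference-mode probabilities for a numpy batch; deterministic."""
    phi = params.phi_H if task == "H" else params.phi_L
    logits = forward(Tensor(x), params.theta, phi, params.config)
    return ad.sigmoid(logits).data
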