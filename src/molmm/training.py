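"""Two-stage training: meta/multi-task pretraining, then fine-tuning.

Stage I optimizes two tasks that share the encoder parameters theta:

* H task — ordinary supervised cross-entropy on the refined (high
  confidence) half of each batch, through head phi_H;
* L task — a bilevel (meta) objective on the noisy half: the inner loop
  takes one gradient step of size ``meta_alpha`` on the refined-half loss
  for (theta, phi_L) ("meta-training"), and the outer gradient is the
  noisy-half loss evaluated at the adapted parameters ("meta-testing").
  ``meta_order='first_order'`` applies the outer gradient to the original
  parameters directly (FOMAML); ``'full'`` differentiates through the
  inner step exactly (double backward).

The two theta-gradients are combined by the MGDA-UB min-norm rule: solve
min_{gamma in [0,1]} ||gamma*g_H + (1-gamma)*g_L||^2 in closed form and
rescale the min-norm point to the asymmetric form g_H + beta*g_L with
beta = (1-gamma*)/gamma*.  This direction is a first-order Pareto descent
direction for both tasks.  Head gradients are applied to their own heads
without balancing.

Stage II initializes from the pretrained {theta, phi_L} and fine-tunes
with plain supervised cross-entropy on the refined data only, with early
stopping on a held-out validation split.

Batches of size N are drawn half from each tier; per epoch the larger
tier is cycled without replacement and the smaller tier resampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import autodiff as ad
from . import model as M
from .autodiff import Tensor
from .model import ModelConfig, ModelParams

__all__ = ["TrainConfig", "meta_gradient_L", "supervised_gradient_H",
           "min_norm_gamma", "balance_gradients", "stage1_step",
           "train_stage1", "stage2_finetune", "train_molmm"]

BETA_BOUNDS = (1e-3, 1e3)


@dataclass
class TrainConfig:
    meta_alpha: float = 0.05
    lr: float = 0.003
    optimizer: str = "adam"              # "adam" | "sgd"
    batch_size: int = 64                 # split equally between tiers
    stage1_epochs: int = 5
    stage2_epochs: int = 30
    patience: int = 5                    # stage-II early stopping
    val_fraction: float = 0.2
    meta_order: str = "first_order"      # "first_order" | "full"
    mgda_mode: str = "shared_params"     # "shared_params" | "shared_representation"
    seed: int = 0

    def validate(self):
        if self.meta_alpha <= 0:
            raise ValueError("meta_alpha must be positive")
        if self.batch_size % 2:
            raise ValueError("batch_size must be even (equal tier split)")
        if self.meta_order not in ("first_order", "full"):
            raise ValueError("meta_order must be 'first_order' or 'full'")


# ---------------------------------------------------------------------
# gradients
# ---------------------------------------------------------------------

def _named(params: dict[str, Tensor], prefix: str):
    return [(f"{prefix}.{k}", v) for k, v in params.items()]


def supervised_gradient_H(x_ref: np.ndarray, y_ref: np.ndarray,
                          params: ModelParams) -> dict[str, np.ndarray]:
    """Plain gradient of the refined-half cross-entropy w.r.t. (theta, phi_H)."""
    cfg = params.config
    logits = M.forward(Tensor(x_ref), params.theta, params.phi_H, cfg)
    loss = M.cross_entropy(logits, y_ref)
    leaves = _named(params.theta, "theta") + _named(params.phi_H, "phi_H")
    grads = ad.grad(loss, [t for _, t in leaves])
    return {name: g.data for (name, _), g in zip(leaves, grads)}


def meta_gradient_L(x_ref, y_ref, x_noisy, y_noisy, params: ModelParams,
                    cfg: TrainConfig) -> dict[str, np.ndarray]:
    """Bilevel gradient of the L task w.r.t. (theta, phi_L).

    Inner: one step of size ``meta_alpha`` on the refined loss through
    phi_L.  Outer: gradient of the noisy loss at the adapted parameters;
    in 'full' mode the inner step is differentiated through exactly.
    """
    cfg.validate()
    mcfg = params.config
    leaves = _named(params.theta, "theta") + _named(params.phi_L, "phi_L")
    names = [n for n, _ in leaves]
    tensors = [t for _, t in leaves]

    def split(param_list):
        n_theta = len(params.theta)
        theta = dict(zip(params.theta.keys(), param_list[:n_theta]))
        phi = dict(zip(params.phi_L.keys(), param_list[n_theta:]))
        return theta, phi

    inner_logits = M.forward(Tensor(x_ref), params.theta, params.phi_L, mcfg)
    inner_loss = M.cross_entropy(inner_logits, y_ref)
    inner_grads = ad.grad(inner_loss, tensors)

    if cfg.meta_order == "first_order":
        adapted = [Tensor(t.data - cfg.meta_alpha * g.data)
                   for t, g in zip(tensors, inner_grads)]
        theta_a, phi_a = split(adapted)
        outer = M.cross_entropy(
            M.forward(Tensor(x_noisy), theta_a, phi_a, mcfg), y_noisy)
        outer_grads = ad.grad(outer, adapted)
    else:
        adapted = [t - cfg.meta_alpha * g
                   for t, g in zip(tensors, inner_grads)]
        theta_a, phi_a = split(adapted)
        outer = M.cross_entropy(
            M.forward(Tensor(x_noisy), theta_a, phi_a, mcfg), y_noisy)
        outer_grads = ad.grad(outer, tensors)
    return {name: g.data for name, g in zip(names, outer_grads)}


# ---------------------------------------------------------------------
# MGDA-UB min-norm balancing
# ---------------------------------------------------------------------

def min_norm_gamma(g_h: np.ndarray, g_l: np.ndarray) -> float:
    """Closed-form solution of min_{gamma in [0,1]} ||gamma g_H + (1-gamma) g_L||^2."""
    g_h = np.asarray(g_h, dtype=float).ravel()
    g_l = np.asarray(g_l, dtype=float).ravel()
    if g_h.size == 0 or g_h.size != g_l.size:
        raise ValueError("gradients must be nonempty and of equal length")
    diff = g_h - g_l
    denom = diff @ diff
    if denom == 0.0:
        return 0.5
    gamma = ((g_l - g_h) @ g_l) / denom
    return float(np.clip(gamma, 0.0, 1.0))


def balance_gradients(g_h: np.ndarray, g_l: np.ndarray,
                      beta_bounds: tuple[float, float] = BETA_BOUNDS,
                      ) -> tuple[float, np.ndarray]:
    """MGDA-UB combination of two task gradients on the shared parameters.

    Returns ``(beta, g_H + beta * g_L)`` where beta = (1-gamma*)/gamma* is
    derived from the min-norm coefficients and capped at ``beta_bounds``
    for degenerate gamma*.
    """
    g_h = np.asarray(g_h, dtype=float).ravel()
    g_l = np.asarray(g_l, dtype=float).ravel()
    gamma = min_norm_gamma(g_h, g_l)
    lo, hi = beta_bounds
    beta = (1.0 - gamma) / gamma if 0 < gamma < 1 else (hi if gamma == 0 else lo)
    beta = float(np.clip(beta, lo, hi))
    return beta, g_h + beta * g_l


# ---------------------------------------------------------------------
# optimizers (numpy, over flat name->array dicts)
# ---------------------------------------------------------------------

class _Optimizer:
    def __init__(self, cfg: TrainConfig):
        self.lr = cfg.lr
        self.kind = cfg.optimizer
        self.state: dict[str, tuple] = {}
        self.t = 0

    def step(self, params: dict[str, Tensor], grads: dict[str, np.ndarray]):
        self.t += 1
        for name, g in grads.items():
            p = params[name]
            if self.kind == "sgd":
                p.data -= self.lr * g
            elif self.kind == "adam":
                m, v = self.state.get(name, (np.zeros_like(g), np.zeros_like(g)))
                m = 0.9 * m + 0.1 * g
                v = 0.999 * v + 0.001 * g * g
                self.state[name] = (m, v)
                mh = m / (1 - 0.9 ** self.t)
                vh = v / (1 - 0.999 ** self.t)
                p.data -= self.lr * mh / (np.sqrt(vh) + 1e-8)
            else:
                raise ValueError(f"unknown optimizer {self.kind!r}")


def _resolve(params: ModelParams, name: str) -> Tensor:
    group, key = name.split(".", 1)
    return getattr(params, group)[key]


def _flat(grads: dict[str, np.ndarray], prefix: str) -> np.ndarray:
    keys = sorted(k for k in grads if k.startswith(prefix + "."))
    return np.concatenate([grads[k].ravel() for k in keys])


def _representation_beta(x_ref, y_ref, x_noisy, y_noisy,
                         params: ModelParams) -> float:
    """MGDA-UB speed variant: balance on latent-representation gradients.

    Each task's loss is evaluated at the current parameters on its own
    (equal-sized) batch half and differentiated w.r.t. the encoder output
    only, avoiding a second full backward through the encoder.
    """
    mcfg = params.config
    h_ref = M.encode(Tensor(x_ref), params.theta, mcfg)
    loss_h = M.cross_entropy(M.head_logits(h_ref, params.phi_H, mcfg), y_ref)
    (g_h,) = ad.grad(loss_h, [h_ref])
    h_noisy = M.encode(Tensor(x_noisy), params.theta, mcfg)
    loss_l = M.cross_entropy(M.head_logits(h_noisy, params.phi_L, mcfg), y_noisy)
    (g_l,) = ad.grad(loss_l, [h_noisy])
    beta, _ = balance_gradients(g_h.data.ravel(), g_l.data.ravel())
    return beta


# ---------------------------------------------------------------------
# stage I
# ---------------------------------------------------------------------

def stage1_step(x_ref, y_ref, x_noisy, y_noisy, params: ModelParams,
                cfg: TrainConfig, opt: _Optimizer | None = None,
                force_beta: float | None = None,
                with_h_task: bool = True) -> tuple[ModelParams, dict]:
    """One Stage-I update; mutates and returns ``params``.

    theta receives the MGDA-balanced combination of the H and L task
    gradients; phi_H and phi_L receive their own task gradients.
    """
    opt = opt or _Optimizer(cfg)
    g_l = meta_gradient_L(x_ref, y_ref, x_noisy, y_noisy, params, cfg)
    info: dict = {}
    if with_h_task:
        g_h = supervised_gradient_H(x_ref, y_ref, params)
        if force_beta is not None:
            beta = force_beta
        elif cfg.mgda_mode == "shared_representation":
            beta = _representation_beta(x_ref, y_ref, x_noisy, y_noisy, params)
        else:
            beta, _ = balance_gradients(_flat(g_h, "theta"), _flat(g_l, "theta"))
        theta_grads = {k: g_h[k] + beta * g_l[k]
                       for k in g_h if k.startswith("theta.")}
        info["beta"] = beta
    else:
        theta_grads = {k: v for k, v in g_l.items() if k.startswith("theta.")}
        g_h = {}
    updates = dict(theta_grads)
    updates.update({k: v for k, v in g_h.items() if k.startswith("phi_H.")})
    updates.update({k: v for k, v in g_l.items() if k.startswith("phi_L.")})
    opt.step({n: _resolve(params, n) for n in updates}, updates)
    return params, info


def _epoch_batches(n_ref, n_noisy, half, rng):
    """Index pairs covering the larger tier once, resampling the smaller."""
    n_major = max(n_ref, n_noisy)
    steps = max(1, n_major // half)
    perm_ref = rng.permutation(n_ref)
    perm_noisy = rng.permutation(n_noisy)
    for s in range(steps):
        ref_idx = perm_ref[(s * half) % n_ref:(s * half) % n_ref + half]
        if len(ref_idx) < half:
            ref_idx = np.concatenate([ref_idx, rng.choice(n_ref, half - len(ref_idx))])
        noisy_idx = perm_noisy[(s * half) % n_noisy:(s * half) % n_noisy + half]
        if len(noisy_idx) < half:
            noisy_idx = np.concatenate(
                [noisy_idx, rng.choice(n_noisy, half - len(noisy_idx))])
        yield ref_idx, noisy_idx


def train_stage1(x_ref, y_ref, x_noisy, y_noisy, mcfg: ModelConfig,
                 cfg: TrainConfig, with_h_task: bool = True,
                 params: ModelParams | None = None) -> tuple[ModelParams, list]:
    """Stage-I pretraining loop; returns the PTM parameters and a log."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    params = params or M.init_params(replace(mcfg, seed=cfg.seed))
    opt = _Optimizer(cfg)
    half = cfg.batch_size // 2
    log = []
    for epoch in range(cfg.stage1_epochs):
        betas = []
        for ref_idx, noisy_idx in _epoch_batches(len(y_ref), len(y_noisy),
                                                 half, rng):
            _, info = stage1_step(x_ref[ref_idx], y_ref[ref_idx],
                                  x_noisy[noisy_idx], y_noisy[noisy_idx],
                                  params, cfg, opt, with_h_task=with_h_task)
            if "beta" in info:
                betas.append(info["beta"])
        log.append({"epoch": epoch,
                    "beta_mean": float(np.mean(betas)) if betas else None})
    return params, log


# ---------------------------------------------------------------------
# stage II
# ---------------------------------------------------------------------

def _supervised_epochs(x, y, params: ModelParams, head_name: str,
                       cfg: TrainConfig, epochs: int, rng, opt=None,
                       x_val=None, y_val=None, patience=None) -> ModelParams:
    opt = opt or _Optimizer(cfg)
    phi = getattr(params, head_name)
    leaves = _named(params.theta, "theta") + _named(phi, head_name)
    best_loss, best_params, wait = np.inf, params.copy(), 0
    half = max(2, cfg.batch_size // 2)
    for _ in range(epochs):
        perm = rng.permutation(len(y))
        for start in range(0, len(y), half):
            idx = perm[start:start + half]
            if len(idx) < 2:
                continue
            logits = M.forward(Tensor(x[idx]), params.theta, phi, params.config)
            loss = M.cross_entropy(logits, y[idx])
            grads = ad.grad(loss, [t for _, t in leaves])
            opt.step({n: t for n, t in leaves},
                     {n: g.data for (n, _), g in zip(leaves, grads)})
        if x_val is not None and len(y_val):
            vl = M.cross_entropy(
                M.forward(Tensor(x_val), params.theta, phi, params.config),
                y_val).data
            if vl < best_loss - 1e-6:
                best_loss, best_params, wait = vl, params.copy(), 0
            else:
                wait += 1
                if patience is not None and wait >= patience:
                    return best_params
    return best_params if x_val is not None and len(y_val) else params


def stage2_finetune(params: ModelParams, x_ref, y_ref,
                    cfg: TrainConfig) -> ModelParams:
    """Fine-tune the PTM {theta, phi_L} on refined data only.

    A ``val_fraction`` split provides early stopping; the returned model
    predicts through the L head (the pretrained head carried forward).
    """
    cfg.validate()
    params = params.copy()
    if cfg.stage2_epochs == 0:
        return params
    rng = np.random.default_rng(cfg.seed + 1)
    n = len(y_ref)
    perm = rng.permutation(n)
    n_val = int(round(cfg.val_fraction * n))
    val, tr = perm[:n_val], perm[n_val:]
    return _supervised_epochs(x_ref[tr], y_ref[tr], params, "phi_L", cfg,
                              cfg.stage2_epochs, rng,
                              x_val=x_ref[val], y_val=y_ref[val],
                              patience=cfg.patience)


def train_molmm(x_ref, y_ref, x_noisy, y_noisy, mcfg: ModelConfig,
                cfg: TrainConfig, with_h_task: bool = True,
                inverse: bool = False) -> ModelParams:
    """Full two-stage procedure; Stage II always fine-tunes on refined data.

    ``inverse`` swaps the roles of the tiers in Stage I (ablation).
    """
    if inverse:
        ptm, _ = train_stage1(x_noisy, y_noisy, x_ref, y_ref, mcfg, cfg,
                              with_h_task=with_h_task)
    else:
        ptm, _ = train_stage1(x_ref, y_ref, x_noisy, y_noisy, mcfg, cfg,
                              with_h_task=with_h_task)
    return stage2_finetune(ptm, x_ref, y_ref, cfg)


def train_supervised(x, y, mcfg: ModelConfig, cfg: TrainConfig,
                     head_name: str = "phi_L") -> ModelParams:
    """Single-stage supervised baseline (used for the vanilla/Mixed presets)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    params = M.init_params(replace(mcfg, seed=cfg.seed))
    return _supervised_epochs(x, y, params, head_name, cfg,
                              cfg.stage2_epochs, rng)
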