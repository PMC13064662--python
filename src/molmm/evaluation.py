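"""Stratified cross-validated evaluation and the benchmark/ablation harness.

Metrics follow the usual conventions for bioactivity classification:
AUC-ROC as the Mann-Whitney pair statistic (ties counted one half) and
thresholded accuracy, both reported as percentages.  Benchmarks run every
requested model preset on identical stratified folds and seeds and report
mean (sd) over the test folds.

Model presets (the comparison/ablation suite):

==================  =========================================================
MolMM               Stage I (meta L + supervised H, MGDA-balanced) + Stage II
Meta PTM            Stage I with the meta L task only + Stage II
MolMM w/o H         alias of Meta PTM (the supervised branch is dropped)
Multi-task PTM      Stage I with both tasks plain supervised (no inner meta
                    step), MGDA-balanced + Stage II
Vanilla PTM         supervised pretraining on the noisy tier + Stage II
CNN w/o PTM         supervised training on the refined tier only
MLP w/o PTM         same, MLP encoder over flat descriptors
MLP (MolMM)         full two-stage procedure with the MLP encoder
Mixed               one supervised model on refined+noisy pooled labels
MolMM (inverse)     tier roles swapped in Stage I
Noisy only          supervised training on the noisy tier only (no Stage II)
==================  =========================================================
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from . import model as M
from . import training as T
from .model import ModelConfig
from .training import TrainConfig

__all__ = ["CVPlan", "make_folds", "auc_roc", "accuracy", "run_benchmark",
           "MODEL_PRESETS", "fit_preset"]


# ---------------------------------------------------------------------
# folds and metrics
# ---------------------------------------------------------------------

@dataclass
class CVPlan:
    k: int
    seed: int
    assignment: np.ndarray       # fold index per sample

    def folds(self):
        for f in range(self.k):
            yield np.where(self.assignment != f)[0], np.where(self.assignment == f)[0]


def make_folds(labels, k: int = 5, seed: int = 0) -> CVPlan:
    """Stratified k-fold partition; per-fold class counts within 1 of
    proportional.  Deterministic given seed."""
    labels = np.asarray(labels)
    for cls, count in zip(*np.unique(labels, return_counts=True)):
        if count < k:
            raise ValueError(f"class {cls!r} has {count} members, fewer than k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(labels), dtype=int)
    for f, (_, test) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignment[test] = f
    return CVPlan(k, seed, assignment)


def auc_roc(scores, labels) -> float:
    """AUC-ROC in percent: the Mann-Whitney pair statistic, ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return 100.0 * u / (n1 * n0)


def accuracy(scores, labels, threshold: float = 0.5) -> float:
    """Percent of correct thresholded calls (score > threshold -> positive)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.size == 0:
        raise ValueError("empty input")
    return 100.0 * float(np.mean((scores > threshold).astype(int) == labels))


# ---------------------------------------------------------------------
# model presets
# ---------------------------------------------------------------------

def _mlp_cfg(mcfg: ModelConfig) -> ModelConfig:
    return replace(mcfg, encoder="mlp")


def fit_preset(name: str, x_ref, y_ref, x_noisy, y_noisy,
               mcfg: ModelConfig, cfg: TrainConfig):
    """Train one preset; returns (params, task) where ``task`` is the head
    used for prediction."""
    if name == "MolMM":
        return T.train_molmm(x_ref, y_ref, x_noisy, y_noisy, mcfg, cfg), "L"
    if name in ("Meta PTM", "MolMM w/o H"):
        return T.train_molmm(x_ref, y_ref, x_noisy, y_noisy, mcfg, cfg,
                             with_h_task=False), "L"
    if name == "Multi-task PTM":
        # both tasks supervised: vanish the inner meta step
        cfg2 = replace(cfg, meta_alpha=1e-12)
        return T.train_molmm(x_ref, y_ref, x_noisy, y_noisy, mcfg, cfg2), "L"
    if name == "Vanilla PTM":
        ptm = T.train_supervised(x_noisy, y_noisy, mcfg, cfg, head_name="phi_L")
        return T.stage2_finetune(ptm, x_ref, y_ref, cfg), "L"
    if name == "CNN w/o PTM":
        return T.train_supervised(x_ref, y_ref, mcfg, cfg, head_name="phi_L"), "L"
    if name == "MLP w/o PTM":
        return T.train_supervised(x_ref, y_ref, _mlp_cfg(mcfg), cfg,
                                  head_name="phi_L"), "L"
    if name == "MLP (MolMM)":
        return T.train_molmm(x_ref, y_ref, x_noisy, y_noisy, _mlp_cfg(mcfg),
                             cfg), "L"
    if name == "Mixed":
        x = np.concatenate([x_ref, x_noisy])
        y = np.concatenate([y_ref, y_noisy])
        return T.train_supervised(x, y, mcfg, cfg, head_name="phi_L"), "L"
    if name == "MolMM (inverse)":
        return T.train_molmm(x_ref, y_ref, x_noisy, y_noisy, mcfg, cfg,
                             inverse=True), "L"
    if name == "Noisy only":
        return T.train_supervised(x_noisy, y_noisy, mcfg, cfg,
                                  head_name="phi_L"), "L"
    raise ValueError(f"unknown model preset {name!r}")


MODEL_PRESETS = ("MolMM", "Meta PTM", "Multi-task PTM", "Vanilla PTM",
                 "CNN w/o PTM", "MLP w/o PTM", "MLP (MolMM)", "MolMM w/o H",
                 "Mixed", "MolMM (inverse)", "Noisy only")


def run_benchmark(suite, x_ref, y_ref, x_noisy, y_noisy,
                  mcfg: ModelConfig, cfg: TrainConfig,
                  k: int = 5) -> pd.DataFrame:
    """Train/evaluate each preset on identical stratified folds.

    Folds are drawn on the refined set; the noisy set is auxiliary
    training material for every fold.  Returns one row per model with
    mean and sd of AUC-ROC and ACC over the k test folds.
    """
    for name in suite:
        if name not in MODEL_PRESETS:
            raise ValueError(f"unknown model preset {name!r}")
    plan = make_folds(y_ref, k=k, seed=cfg.seed)
    rows = []
    for name in suite:
        aucs, accs = [], []
        for tr, te in plan.folds():
            params, task = fit_preset(name, x_ref[tr], y_ref[tr],
                                      x_noisy, y_noisy, mcfg, cfg)
            scores = M.predict_proba(params, x_ref[te], task=task)
            aucs.append(auc_roc(scores, y_ref[te]))
            accs.append(accuracy(scores, y_ref[te]))
        rows.append({"model": name,
                     "auc_mean": float(np.mean(aucs)),
                     "auc_sd": float(np.std(aucs, ddof=1)) if k > 1 else 0.0,
                     "acc_mean": float(np.mean(accs)),
                     "acc_sd": float(np.std(accs, ddof=1)) if k > 1 else 0.0})
    return pd.DataFrame(rows).set_index("model")
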