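"""Pretrain / fine-tune protocol with the gated position regularizer.

The transfer protocol is leave-one-subject-out: for each target subject the
backbone is pretrained with cross-entropy on the pooled training data of all
other subjects, then fine-tuned on the target's own (scarce) training
trials.  During fine-tuning the composite objective adds the position term
only when the batch cross-entropy has dropped below the gate threshold and
the batch composition supports the silhouette (at least two classes, no
singleton class); ineligible or above-threshold batches optimize CE alone.
Data are reshuffled every epoch, so batch composition — and therefore the
silhouette-optimal targets — varies across iterations, which is the source
of the regularizer's stochasticity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import EpochedDataset, pool_datasets, split_train_test
from .losses import GateConfig, ce_loss_grad, position_loss_grad
from .models import Adam, ReferenceBackbone, clone_model
from .silhouette import FeatureBatch, batch_is_msfs_eligible, opt_pos_sil, rand_pos

__all__ = [
    "TransferPlan",
    "FewShotBudget",
    "STRATEGIES",
    "pretrain",
    "finetune_msfs",
    "train_target_only",
    "loso_transfer",
    "balanced_half_split",
    "stratified_subsample",
    "select_hyperparameters",
    "evaluate_model",
]

logger = logging.getLogger(__name__)

#: fine-tuning strategies: (target function name, gating mode)
STRATEGIES: dict[str, tuple[str, str]] = {
    "tl": ("none", "gated"),
    "tl+msfs": ("opt_pos_sil", "gated"),
    "rand_pos": ("rand_pos", "gated"),
    "nogate": ("opt_pos_sil", "always_on"),
}


@dataclass(frozen=True)
class TransferPlan:
    """Optimization settings of the pretrain + fine-tune pipeline.

    Defaults follow the fixed full-scale settings (Adam, learning rate 0.001,
    weight decay 0.009) with desk-scale epoch counts and batch size; the
    full-scale protocol uses batch 64 and hundreds of epochs.
    """

    pretrain_epochs: int = 30
    finetune_epochs: int = 40
    batch_size: int = 8
    learning_rate: float = 1e-3
    weight_decay: float = 0.009
    n_runs: int = 3

    def __post_init__(self) -> None:
        if self.pretrain_epochs < 0 or self.finetune_epochs < 0:
            raise ValueError("epoch counts must be >= 0")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")


@dataclass(frozen=True)
class FewShotBudget:
    """Fraction of per-class target training trials available for fine-tuning."""

    fraction: float

    def __post_init__(self) -> None:
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")


def _make_optimizer(model, plan: TransferPlan) -> Adam:
    return Adam(model.params, lr=plan.learning_rate,
                weight_decay=plan.weight_decay)


def _train_epochs(model, opt, X: np.ndarray, y: np.ndarray, epochs: int,
                  batch_size: int, shuffle_rng: np.random.Generator,
                  gate: GateConfig | None = None, target_fn: str = "none",
                  gating_mode: str = "gated",
                  randpos_rng: np.random.Generator | None = None,
                  log: list | None = None) -> None:
    """Shared epoch loop; with ``target_fn='none'`` this is plain CE training."""
    if target_fn not in ("none", "opt_pos_sil", "rand_pos"):
        raise ValueError(f"unknown target strategy '{target_fn}'; "
                         "valid: none, opt_pos_sil, rand_pos")
    if gating_mode not in ("gated", "always_on"):
        raise ValueError(f"unknown gating mode '{gating_mode}'")
    n = len(y)
    step = 0
    for _ in range(epochs):
        perm = shuffle_rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = perm[start:start + batch_size]
            logits, feat, cache = model.forward(X[idx])
            ce, dlogits = ce_loss_grad(logits, y[idx])
            lpos, dfeat, gate_open = 0.0, None, False
            wants_pos = (target_fn != "none" and gate is not None
                         and gate.omega > 0
                         and batch_is_msfs_eligible(y[idx]))
            if wants_pos:
                gate_open = (ce < gate.loss_min if gating_mode == "gated"
                             else True)
            if gate_open:
                fb = FeatureBatch(feat, y[idx])
                t = (opt_pos_sil(fb) if target_fn == "opt_pos_sil"
                     else rand_pos(fb, randpos_rng))
                lpos, gpos = position_loss_grad(feat, t)
                dfeat = gate.omega * gpos
            grads = model.backward(cache, dlogits, dfeat)
            opt.step(model.params, grads)
            if log is not None:
                total = ce + (gate.omega * lpos if gate_open else 0.0)
                log.append({"step": step, "ce": ce, "lpos": lpos,
                            "gate_open": gate_open, "total": total})
            step += 1


def pretrain(model, source_data: EpochedDataset, plan: TransferPlan,
             seed: int = 0, log: list | None = None):
    """Cross-entropy pretraining on the pooled source-subject data (in place)."""
    if source_data.n_trials == 0:
        raise ValueError("empty source set")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5153]))
    opt = _make_optimizer(model, plan)
    _train_epochs(model, opt, source_data.X, source_data.y,
                  plan.pretrain_epochs, plan.batch_size, rng, log=log)
    return model


def finetune_msfs(model, target_data: EpochedDataset, plan: TransferPlan,
                  gate: GateConfig, target_fn: str = "opt_pos_sil",
                  gating_mode: str = "gated", seed: int = 0,
                  log: list | None = None):
    """Gated fine-tuning on the target subject's training trials (in place).

    ``target_fn`` selects the target-position strategy (``opt_pos_sil``,
    ``rand_pos``, or ``none`` for CE-only); ``gating_mode`` is ``gated``
    (position term only while CE < ``gate.loss_min``) or ``always_on`` (the
    no-gating ablation).  With ``target_fn='none'``, ``omega = 0`` or an
    unreachable gate, the parameter trajectory is identical to CE-only
    fine-tuning for the same seed.
    """
    ss = np.random.SeedSequence([seed, 0xF17E])
    shuffle_rng, randpos_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    opt = _make_optimizer(model, plan)
    _train_epochs(model, opt, target_data.X, target_data.y,
                  plan.finetune_epochs, plan.batch_size, shuffle_rng,
                  gate=gate, target_fn=target_fn, gating_mode=gating_mode,
                  randpos_rng=randpos_rng, log=log)
    return model


def train_target_only(model, target_data: EpochedDataset, plan: TransferPlan,
                      seed: int = 0):
    """Subject-dependent baseline: CE training on target data alone.

    Gets the same total epoch budget as pretraining plus fine-tuning so the
    comparison against transfer is an initialization comparison, not a
    compute comparison.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x0121]))
    opt = _make_optimizer(model, plan)
    _train_epochs(model, opt, target_data.X, target_data.y,
                  plan.pretrain_epochs + plan.finetune_epochs,
                  plan.batch_size, rng)
    return model


def evaluate_model(model, data: EpochedDataset) -> float:
    """Classification accuracy of the argmax prediction on a dataset."""
    logits, _, _ = model.forward(data.X)
    pred = np.argmax(logits, axis=1) + 1
    return float(np.mean(pred == data.y))


def balanced_half_split(trials: np.ndarray, y: np.ndarray,
                        seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Class-balanced random split into two halves; returns index arrays.

    Used for hyperparameter selection: within each class the trials are
    randomly permuted and split as evenly as possible, the fit half taking
    the extra trial on odd counts.
    """
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    fit_idx, val_idx = [], []
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        if len(idx) < 2:
            raise ValueError(f"class {c} has fewer than 2 trials")
        idx = rng.permutation(idx)
        half = (len(idx) + 1) // 2
        fit_idx.extend(idx[:half])
        val_idx.extend(idx[half:])
    return np.sort(fit_idx), np.sort(val_idx)


def stratified_subsample(trials: np.ndarray, y: np.ndarray,
                         budget: FewShotBudget, seed: int) -> np.ndarray:
    """Per-class uniform subsample at the few-shot budget; returns indices.

    Selects ``floor(fraction * count)`` trials per class (at least 1),
    preserving class proportions.
    """
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    keep = []
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        k = int(np.floor(budget.fraction * len(idx)))
        if k < 1:
            if budget.fraction * len(idx) <= 0:
                raise ValueError(f"budget leaves class {c} empty")
            k = 1
        keep.extend(rng.choice(idx, size=k, replace=False))
    return np.sort(keep)


def _backbone_for(ds: EpochedDataset, feature_dim: int, seed: int,
                  factory=None):
    K = int(np.max(ds.y))
    if factory is not None:
        return factory(ds.n_channels, ds.n_samples, K, seed)
    return ReferenceBackbone(ds.n_channels, ds.n_samples, K,
                             feature_dim=feature_dim, seed=seed)


def loso_transfer(all_subjects: list[EpochedDataset], plan: TransferPlan,
                  gate: GateConfig, strategies=("tl", "tl+msfs"),
                  seeds=(0, 1, 2), n_train_per_class: int = 8,
                  include_original: bool = True, feature_dim: int = 16,
                  budget: FewShotBudget | None = None,
                  backbone_factory=None) -> pd.DataFrame:
    """Leave-one-subject-out transfer over strategies and run seeds.

    For each (seed, target subject): the target is split into training and
    test trials, the remaining subjects' training splits are pooled for a
    single pretraining shared by every fine-tuning strategy, and each
    strategy fine-tunes its own copy of the pretrained model.  ``original``
    (no pretraining) trains a fresh model on the target training trials.
    Returns a tidy table (subject, strategy, seed, split, accuracy).
    """
    if len(all_subjects) < 2:
        raise ValueError("leave-one-subject-out needs >= 2 subjects")
    bad = set(strategies) - set(STRATEGIES)
    if bad:
        raise ValueError(f"unknown strategies {sorted(bad)}; "
                         f"valid: {sorted(STRATEGIES)} (+ 'original')")
    rows = []
    for seed in seeds:
        splits = [split_train_test(ds, n_train_per_class,
                                   int(np.random.SeedSequence(
                                       [seed, t, 0xD1]).generate_state(1)[0]
                                       % 2**31))
                  for t, ds in enumerate(all_subjects)]
        for t, target in enumerate(all_subjects):
            train_t, test_t = splits[t]
            if test_t.n_trials == 0:
                raise ValueError(f"subject {target.subject} has no test split")
            if budget is not None and budget.fraction < 1.0:
                keep = stratified_subsample(
                    train_t.X, train_t.y, budget,
                    seed=int(np.random.SeedSequence(
                        [seed, t, 0xB9]).generate_state(1)[0] % 2**31))
                train_t = train_t.subset(keep)
            source = pool_datasets([splits[s][0]
                                    for s in range(len(all_subjects))
                                    if s != t])
            init_seed = int(np.random.SeedSequence(
                [seed, t, 0xA3]).generate_state(1)[0] % 2**31)
            base = _backbone_for(target, feature_dim, init_seed,
                                 backbone_factory)
            pretrained = pretrain(clone_model(base), source, plan, seed=seed)
            if include_original:
                orig = train_target_only(clone_model(base), train_t, plan,
                                         seed=seed)
                rows.append({"subject": target.subject,
                             "strategy": "original", "seed": seed,
                             "split": "test",
                             "accuracy": evaluate_model(orig, test_t)})
            for name in strategies:
                target_fn, mode = STRATEGIES[name]
                model = finetune_msfs(clone_model(pretrained), train_t, plan,
                                      gate, target_fn=target_fn,
                                      gating_mode=mode, seed=seed)
                rows.append({"subject": target.subject, "strategy": name,
                             "seed": seed, "split": "test",
                             "accuracy": evaluate_model(model, test_t)})
    return pd.DataFrame(rows)


def select_hyperparameters(grid, all_subjects: list[EpochedDataset],
                           plan: TransferPlan, seed: int = 0,
                           n_train_per_class: int = 8,
                           feature_dim: int = 16):
    """Pick (omega, loss_min, ef) maximizing mean validation accuracy.

    For each grid point and target subject, the target training trials are
    half-split per class; the model (pretrained once per target) is
    fine-tuned on the fit half and scored on the validation half.  The grid
    point with the highest subject-mean validation accuracy wins; ties go to
    the earliest grid entry.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty hyperparameter grid")
    pretrained, fits, vals = [], [], []
    for t, target in enumerate(all_subjects):
        train_t, _ = split_train_test(
            target, n_train_per_class,
            int(np.random.SeedSequence([seed, t, 0xD1])
                .generate_state(1)[0] % 2**31))
        fit_idx, val_idx = balanced_half_split(
            train_t.X, train_t.y,
            int(np.random.SeedSequence([seed, t, 0x45])
                .generate_state(1)[0] % 2**31))
        fits.append(train_t.subset(fit_idx))
        vals.append(train_t.subset(val_idx))
        source = pool_datasets([s for u, s in enumerate(all_subjects)
                                if u != t])
        init_seed = int(np.random.SeedSequence([seed, t, 0xA3])
                        .generate_state(1)[0] % 2**31)
        base = _backbone_for(target, feature_dim, init_seed)
        pretrained.append(pretrain(base, source, plan, seed=seed))
    best, best_acc = None, -np.inf
    for omega, loss_min, ef in grid:
        point_plan = replace(plan, finetune_epochs=ef)
        accs = []
        for t in range(len(all_subjects)):
            gate = GateConfig(omega=omega, loss_min=loss_min)
            model = finetune_msfs(clone_model(pretrained[t]), fits[t],
                                  point_plan, gate, seed=seed)
            accs.append(evaluate_model(model, vals[t]))
        mean_acc = float(np.mean(accs))
        logger.info("grid point omega=%g loss_min=%g ef=%d -> val acc %.4f",
                    omega, loss_min, ef, mean_acc)
        if mean_acc > best_acc:  # strict: ties keep the earliest point
            best, best_acc = (omega, loss_min, ef), mean_acc
    return best, best_acc
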