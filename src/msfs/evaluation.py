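"""Metrics, paired significance testing, and experiment orchestration.

Results follow the field's reporting shape: per-subject accuracies averaged
over independent runs, strategy means, and two-sided Wilcoxon signed-rank
p-values on the paired per-subject scores.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .data import SynthSpec, generate_synthetic_subjects, load_epoched
from .losses import GateConfig
from .training import FewShotBudget, TransferPlan, loso_transfer

__all__ = ["evaluate_accuracy", "wilcoxon_paired", "run_experiment",
           "strategy_means", "pairwise_pvalues"]

logger = logging.getLogger(__name__)


def evaluate_accuracy(predictions: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of exact label matches."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.shape != truth.shape or predictions.size == 0:
        raise ValueError("predictions and truth must be equal-length, nonempty")
    return float(np.mean(predictions == truth))


def wilcoxon_paired(scores_a: np.ndarray, scores_b: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired per-subject scores.

    Zero differences are dropped before ranking and the exact null
    distribution is used for n <= 25 (no ties among nonzero ranks assumed
    beyond the standard midrank handling); if every difference is zero the
    test carries no evidence and p = 1 by convention.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("need two equal-length 1-D score vectors")
    diff = a - b
    nz = diff[diff != 0]
    if nz.size == 0:
        return 1.0
    method = "exact" if nz.size <= 25 else "approx"
    res = stats.wilcoxon(nz, alternative="two-sided", method=method)
    return float(res.pvalue)


def strategy_means(table: pd.DataFrame) -> pd.Series:
    """Mean accuracy per strategy (subjects and seeds pooled equally)."""
    return (table.groupby(["strategy", "subject"])["accuracy"].mean()
            .groupby("strategy").mean())


def pairwise_pvalues(table: pd.DataFrame,
                     reference: str = "tl+msfs") -> dict[str, float]:
    """Wilcoxon p-values of every strategy against a reference strategy.

    Per-subject scores are averaged over seeds first, then compared pairwise,
    matching the subject-level testing convention.
    """
    per_subj = (table.groupby(["strategy", "subject"])["accuracy"].mean()
                .unstack("strategy"))
    if reference not in per_subj.columns:
        raise ValueError(f"reference strategy '{reference}' not in table")
    return {s: wilcoxon_paired(per_subj[reference].values,
                               per_subj[s].values)
            for s in per_subj.columns if s != reference}


_VALID_STRATEGIES = ("original", "tl", "tl+msfs", "rand_pos", "nogate")


def run_experiment(config: dict, out_dir=None) -> pd.DataFrame:
    """Run the requested strategies over subjects, seeds, and budgets.

    ``config`` keys: ``synth`` (SynthSpec fields) or ``dataset_paths`` (list
    of epoched-container files), ``strategies``, ``seeds``, ``budgets``
    (few-shot fractions, default ``[1.0]``), ``n_train_per_class``, and the
    plan/gate fields ``ep``, ``ef``, ``batch_size``, ``lr``,
    ``weight_decay``, ``omega``, ``loss_min``, ``feature_dim``.

    Returns the tidy results table and, when ``out_dir`` is given, writes
    ``results.csv``, ``summary.csv``, ``pvalues.json`` and a reproducibility
    manifest.
    """
    strategies = list(config.get("strategies", ("tl", "tl+msfs")))
    bad = set(strategies) - set(_VALID_STRATEGIES)
    if bad:
        raise ValueError(f"invalid strategies {sorted(bad)}; "
                         f"valid names: {_VALID_STRATEGIES}")
    if "dataset_paths" in config:
        subjects = [load_epoched(p) for p in config["dataset_paths"]]
    else:
        subjects = generate_synthetic_subjects(
            SynthSpec(**config.get("synth", {})))
    plan = TransferPlan(
        pretrain_epochs=config.get("ep", 30),
        finetune_epochs=config.get("ef", 40),
        batch_size=config.get("batch_size", 8),
        learning_rate=config.get("lr", 1e-3),
        weight_decay=config.get("weight_decay", 0.009),
    )
    gate = GateConfig(omega=config.get("omega", 1.0),
                      loss_min=config.get("loss_min", 0.2))
    seeds = list(config.get("seeds", range(3)))
    budgets = [float(b) for b in config.get("budgets", [1.0])]
    include_original = "original" in strategies
    ft_strategies = [s for s in strategies if s != "original"]
    tables = []
    for frac in budgets:
        tbl = loso_transfer(
            subjects, plan, gate, strategies=ft_strategies, seeds=seeds,
            n_train_per_class=config.get("n_train_per_class", 8),
            include_original=include_original,
            feature_dim=config.get("feature_dim", 16),
            budget=FewShotBudget(frac))
        tbl.insert(0, "budget", frac)
        tables.append(tbl)
    table = pd.concat(tables, ignore_index=True)
    dup = table.duplicated(["budget", "subject", "strategy", "seed", "split"])
    assert not dup.any(), "duplicate result rows"
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "results.csv", index=False)
        summary = (table.groupby(["budget", "strategy"])["accuracy"]
                   .mean().rename("mean_accuracy").reset_index())
        summary.to_csv(out / "summary.csv", index=False)
        ref = "tl+msfs" if "tl+msfs" in strategies else strategies[0]
        pvals = {f"{frac:g}": pairwise_pvalues(
                     table[table["budget"] == frac], reference=ref)
                 for frac in budgets if len(strategies) > 1}
        (out / "pvalues.json").write_text(json.dumps(pvals, indent=2))
        manifest = {
            "config": config,
            "config_sha256": hashlib.sha256(
                json.dumps(config, sort_keys=True, default=str)
                .encode()).hexdigest(),
            "seeds": seeds,
            "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str))
    return table
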