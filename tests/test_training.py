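"""Transfer protocol: pretraining, gated fine-tuning, splits, LOSO harness."""

import numpy as np
import pytest

from msfs import (FeatureBatch, FewShotBudget, GateConfig, SynthSpec,
                  TransferPlan, balanced_half_split, clone_model,
                  evaluate_model, finetune_msfs, generate_synthetic_subjects,
                  loso_transfer, opt_pos_sil, pool_datasets, pretrain,
                  stratified_subsample)
from msfs.models import ReferenceBackbone


def _tiny_plan(**kw):
    defaults = dict(pretrain_epochs=3, finetune_epochs=4, batch_size=8)
    defaults.update(kw)
    return TransferPlan(**defaults)


def _model_for(ds, seed=0):
    return ReferenceBackbone(ds.n_channels, ds.n_samples, int(ds.y.max()),
                             feature_dim=6, n_filters=4, kernel=33, seed=seed)


def _params_equal(a, b):
    return all(np.array_equal(a.params[k], b.params[k]) for k in a.params)


class TestPretrain:
    def test_zero_epochs_is_a_noop(self, tiny_subjects):
        pool = pool_datasets(tiny_subjects)
        model = _model_for(pool)
        before = clone_model(model)
        pretrain(model, pool, _tiny_plan(pretrain_epochs=0), seed=0)
        assert _params_equal(model, before)

    def test_same_seed_same_trajectory(self, tiny_subjects):
        pool = pool_datasets(tiny_subjects)
        logs = []
        for _ in range(2):
            log = []
            pretrain(_model_for(pool), pool, _tiny_plan(), seed=3, log=log)
            logs.append([r["ce"] for r in log])
        assert logs[0] == logs[1]

    def test_loss_decreases_in_trend(self, tiny_subjects):
        pool = pool_datasets(tiny_subjects)
        log = []
        pretrain(_model_for(pool), pool, _tiny_plan(pretrain_epochs=30),
                 seed=0, log=log)
        ces = [r["ce"] for r in log]
        assert np.mean(ces[-5:]) < np.mean(ces[:5])

    def test_empty_source_rejected(self, tiny_subjects):
        ds = tiny_subjects[0]
        empty = ds.subset(np.array([], dtype=int))
        with pytest.raises(ValueError, match="empty"):
            pretrain(_model_for(ds), empty, _tiny_plan(), seed=0)


class TestGateSemantics:
    """Disabled-gate fine-tuning must be bit-identical to CE-only."""

    @pytest.mark.parametrize("gate,target_fn", [
        (GateConfig(omega=1.0, loss_min=0.0), "opt_pos_sil"),  # gate shut
        (GateConfig(omega=0.0, loss_min=0.2), "opt_pos_sil"),  # zero weight
        (GateConfig(omega=0.0, loss_min=0.2), "rand_pos"),
        (GateConfig(omega=1.0, loss_min=0.2), "none"),
    ])
    def test_bit_identical_to_ce_only(self, tiny_subjects, gate, target_fn):
        ds = tiny_subjects[0]
        base = _model_for(ds)
        ref = finetune_msfs(clone_model(base), ds, _tiny_plan(),
                            GateConfig(omega=0.0, loss_min=0.0),
                            target_fn="none", seed=7)
        out = finetune_msfs(clone_model(base), ds, _tiny_plan(), gate,
                            target_fn=target_fn, seed=7)
        assert _params_equal(ref, out)

    def test_open_gate_changes_parameters(self, tiny_subjects):
        ds = tiny_subjects[0]
        base = _model_for(ds)
        plan = _tiny_plan(finetune_epochs=30)
        ce_only = finetune_msfs(clone_model(base), ds, plan,
                                GateConfig(omega=0.0, loss_min=0.0),
                                target_fn="none", seed=1)
        msfs = finetune_msfs(clone_model(base), ds, plan,
                             GateConfig(omega=1.0, loss_min=10.0),
                             target_fn="opt_pos_sil", seed=1)
        assert not _params_equal(ce_only, msfs)

    def test_always_on_mode_ignores_threshold(self, tiny_subjects):
        ds = tiny_subjects[0]
        base = _model_for(ds)
        log = []
        finetune_msfs(clone_model(base), ds, _tiny_plan(),
                      GateConfig(omega=1.0, loss_min=1e-9),
                      target_fn="opt_pos_sil", gating_mode="always_on",
                      seed=0, log=log)
        assert all(r["gate_open"] for r in log)

    def test_unknown_strategy_rejected(self, tiny_subjects):
        ds = tiny_subjects[0]
        with pytest.raises(ValueError, match="unknown target strategy"):
            finetune_msfs(_model_for(ds), ds, _tiny_plan(), GateConfig(),
                          target_fn="fisher", seed=0)


class TestDegenerateBatches:
    def test_singleton_class_batches_train_without_error(self):
        """Batches with a singleton (or single) class fall back to CE."""
        spec = SynthSpec(n_subjects=1, trials_per_class=3, n_samples=64,
                         cue_sample=16, seed=2)
        ds = generate_synthetic_subjects(spec)[0]  # 6 trials, batch 5 below
        model = _model_for(ds)
        log = []
        finetune_msfs(model, ds, _tiny_plan(batch_size=5, finetune_epochs=6),
                      GateConfig(omega=1.0, loss_min=100.0),
                      target_fn="opt_pos_sil", gating_mode="always_on",
                      seed=0, log=log)
        # the trailing 1-sample batches can never open the gate
        assert any(not r["gate_open"] for r in log)


class TestShuffleStochasticity:
    def test_targets_vary_with_batch_composition(self, rng):
        """Different shuffles give different target sequences on an
        overlapping (non-separable) feature stream."""
        Z = rng.normal(size=(24, 3))
        y = rng.permutation(np.repeat([1, 2], 12))
        seqs = []
        for seed in (0, 1):
            perm = np.random.default_rng(seed).permutation(24)
            seq = [opt_pos_sil(FeatureBatch(Z[perm[i:i + 8]], y[perm[i:i + 8]]))
                   for i in range(0, 24, 8)
                   if len(np.unique(y[perm[i:i + 8]])) == 2]
            seqs.append(np.concatenate([t.ravel() for t in seq]))
        assert not np.array_equal(seqs[0], seqs[1])


class TestSplits:
    def test_half_split_partitions_each_class(self, rng):
        y = np.repeat([1, 2], 10)
        fit, val = balanced_half_split(np.zeros((20, 1)), y, seed=4)
        assert len(fit) == len(val) == 10
        assert not set(fit) & set(val)
        assert sorted(np.concatenate([fit, val])) == list(range(20))
        for c in (1, 2):
            assert (y[fit] == c).sum() == 5

    def test_odd_class_gives_extra_to_fit(self):
        y = np.repeat([1, 2], 7)
        fit, val = balanced_half_split(np.zeros((14, 1)), y, seed=0)
        for c in (1, 2):
            assert (y[fit] == c).sum() == 4
            assert (y[val] == c).sum() == 3

    def test_half_split_seeded(self):
        y = np.repeat([1, 2], 6)
        a = balanced_half_split(np.zeros((12, 1)), y, seed=9)
        b = balanced_half_split(np.zeros((12, 1)), y, seed=9)
        np.testing.assert_array_equal(a[0], b[0])

    def test_single_trial_class_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            balanced_half_split(np.zeros((3, 1)), np.array([1, 1, 2]), seed=0)


class TestFewShotSubsample:
    def test_full_budget_keeps_everything(self):
        y = np.repeat([1, 2], 8)
        idx = stratified_subsample(np.zeros((16, 1)), y,
                                   FewShotBudget(1.0), seed=0)
        assert len(idx) == 16

    @pytest.mark.parametrize("n,frac,expected", [
        (72, 0.25, 18),  # the full-scale per-class budget arithmetic
        (15, 0.1, 1),    # floor with a minimum of one
        (8, 0.5, 4),
    ])
    def test_per_class_counts(self, n, frac, expected):
        y = np.repeat([1, 2], n)
        idx = stratified_subsample(np.zeros((2 * n, 1)), y,
                                   FewShotBudget(frac), seed=1)
        for c in (1, 2):
            assert (y[idx] == c).sum() == expected

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            FewShotBudget(0.0)
        with pytest.raises(ValueError):
            FewShotBudget(1.5)


class TestLosoHarness:
    def test_result_table_shape_and_reproducibility(self, tiny_subjects):
        plan = _tiny_plan()
        kw = dict(strategies=("tl",), seeds=(0,), n_train_per_class=4,
                  include_original=True, feature_dim=6)
        t1 = loso_transfer(tiny_subjects, plan, GateConfig(), **kw)
        t2 = loso_transfer(tiny_subjects, plan, GateConfig(), **kw)
        # 2 subjects x (original + tl) x 1 seed
        assert len(t1) == 4
        assert set(t1["strategy"]) == {"original", "tl"}
        assert t1.equals(t2)
        assert t1["accuracy"].between(0, 1).all()

    def test_identical_subjects_transfer_perfectly(self):
        """Strong signal and no subject shift: transfer accuracy near 1."""
        spec = SynthSpec(n_subjects=2, trials_per_class=24,
                         effect_size=0.8, subject_shift=0.0, seed=3)
        subs = generate_synthetic_subjects(spec)
        plan = TransferPlan(pretrain_epochs=60, finetune_epochs=60,
                            batch_size=16)
        tbl = loso_transfer(subs, plan, GateConfig(), strategies=("tl",),
                            seeds=(0,), n_train_per_class=8,
                            include_original=False)
        assert tbl["accuracy"].mean() > 0.9

    def test_unknown_strategy_listed(self, tiny_subjects):
        with pytest.raises(ValueError, match="valid"):
            loso_transfer(tiny_subjects, _tiny_plan(), GateConfig(),
                          strategies=("msfs_typo",), seeds=(0,))


class TestHyperparameterSelection:
    def test_single_point_grid_returns_it(self, tiny_subjects):
        from msfs import select_hyperparameters
        grid = [(1.0, 0.2, 2)]
        best, acc = select_hyperparameters(
            grid, tiny_subjects, _tiny_plan(pretrain_epochs=2),
            seed=0, n_train_per_class=6, feature_dim=6)
        assert best == grid[0] and 0 <= acc <= 1

    def test_all_tied_grid_prefers_first_point(self, tiny_subjects):
        from msfs import select_hyperparameters
        # omega = 0 makes every point equivalent to CE-only fine-tuning
        grid = [(0.0, 0.1, 2), (0.0, 0.3, 2)]
        best, _ = select_hyperparameters(
            grid, tiny_subjects, _tiny_plan(pretrain_epochs=2),
            seed=0, n_train_per_class=6, feature_dim=6)
        assert best == grid[0]
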