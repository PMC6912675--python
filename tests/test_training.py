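"""Training contract: schedule, loss, folds, checkpoint window, smoke training."""

import numpy as np
import pytest

from spinesva.heatmaps import HeatmapSpec
from spinesva.model import ModelConfig
from spinesva.preprocess import PreprocessSpec
from spinesva.training import (
    HeatmapDataset,
    History,
    TrainConfig,
    hyperparameter_grid,
    learning_rate,
    make_folds,
    mse_heatmap_loss,
    select_checkpoint,
    train_model,
)

TINY_MODEL = ModelConfig(input_height=48, input_width=32, base_filters=4, norm_groups=2)
TINY_PRE = PreprocessSpec.for_canvas(48, 32)


def _tiny_dataset(n=6, seed=0):
    from spinesva.synthetic import SpinePhantomParams, generate_dataset

    images = generate_dataset(n, SpinePhantomParams(height=48, width=32, n_vertebrae=8), seed)
    return HeatmapDataset(images, HeatmapSpec("exponential", 1.57, 1.0), TINY_PRE)


class TestLearningRate:
    def test_reference_schedule_values(self):
        cfg = TrainConfig()
        assert learning_rate(1, cfg) == 0.01
        assert learning_rate(99, cfg) == 0.01
        assert learning_rate(100, cfg) == 0.005
        assert learning_rate(120, cfg) == 0.005

    def test_out_of_range_epoch_rejected(self):
        cfg = TrainConfig()
        for epoch in (0, 121):
            with pytest.raises(ValueError):
                learning_rate(epoch, cfg)


class TestMseLoss:
    def test_identical_stacks_give_zero(self, rng):
        t = rng.random((4, 4, 2))
        assert mse_heatmap_loss(t, t) == 0.0

    def test_constant_offset_gives_offset_squared(self, rng):
        t = rng.random((6, 5, 2))
        assert mse_heatmap_loss(t + 0.3, t) == pytest.approx(0.09)

    def test_matches_elementwise_summation_oracle(self, rng):
        p = rng.random((4, 4, 2))
        t = rng.random((4, 4, 2))
        direct = sum(
            (p[i, j, k] - t[i, j, k]) ** 2
            for i in range(4) for j in range(4) for k in range(2)
        ) / 32
        assert mse_heatmap_loss(p, t) == pytest.approx(direct)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mse_heatmap_loss(np.zeros((2, 2)), np.zeros((3, 2)))


class TestMakeFolds:
    def test_ten_folds_of_99_for_990_images(self):
        plan = make_folds(990, 10, seed=0)
        sizes = [len(plan.fold_indices(f)) for f in range(1, 11)]
        assert sizes == [99] * 10

    def test_partition_is_disjoint_and_exhaustive(self):
        plan = make_folds(103, 7, seed=1)
        seen = np.concatenate([plan.fold_indices(f) for f in range(1, 8)])
        assert sorted(seen) == list(range(103))
        sizes = sorted(len(plan.fold_indices(f)) for f in range(1, 8))
        assert max(sizes) - min(sizes) <= 1
        # train/validation split never overlaps
        for f in range(1, 8):
            assert not set(plan.fold_indices(f)) & set(plan.train_indices(f))

    def test_singleton_folds_when_n_equals_k(self):
        plan = make_folds(5, 5, seed=2)
        assert sorted(len(plan.fold_indices(f)) for f in range(1, 6)) == [1] * 5

    def test_deterministic_given_seed(self):
        assert make_folds(50, 5, seed=9) == make_folds(50, 5, seed=9)

    def test_n_smaller_than_k_rejected(self):
        with pytest.raises(ValueError):
            make_folds(3, 10, seed=0)


class TestSelectCheckpoint:
    def test_monotone_improvement_selects_last_epoch(self):
        hist = History(val_loss=list(np.linspace(1.0, 0.1, 120)))
        assert select_checkpoint(hist, TrainConfig()) == 120

    def test_window_ignores_early_global_minimum(self):
        val = [1.0] * 120
        val[49] = 0.01   # best overall, but before the window opens
        val[94] = 0.05   # best after epoch 80
        hist = History(val_loss=val)
        assert select_checkpoint(hist, TrainConfig()) == 95

    def test_tie_resolves_to_earliest_epoch(self):
        val = [1.0] * 120
        val[89] = val[109] = 0.2
        hist = History(val_loss=val)
        assert select_checkpoint(hist, TrainConfig()) == 90

    def test_insufficient_history_rejected(self):
        with pytest.raises(ValueError):
            select_checkpoint(History(val_loss=[1.0] * 50), TrainConfig())


class TestTrainModel:
    def test_zero_learning_rate_leaves_weights_unchanged(self):
        ds = _tiny_dataset()
        cfg = TrainConfig(epochs=2, checkpoint_min_epoch=0, lr_initial=0.0,
                          l2_strength=0.0, seed=0)
        from spinesva.model import build_model

        reference = build_model(TINY_MODEL, seed=0)
        model, _ = train_model(ds, TINY_MODEL, cfg)
        for p_ref, p in zip(reference.params(), model.params()):
            np.testing.assert_array_equal(p_ref.value, p.value)

    def test_loss_decreases_on_smoke_run(self):
        ds = _tiny_dataset(n=8)
        wins = 0
        for seed in range(5):
            cfg = TrainConfig(epochs=2, checkpoint_min_epoch=0, lr_initial=0.05, seed=seed)
            _, hist = train_model(ds, TINY_MODEL, cfg)
            wins += hist.train_loss[1] < hist.train_loss[0]
        assert wins >= 4

    def test_same_seed_identical_loss_curve(self):
        ds = _tiny_dataset()
        cfg = TrainConfig(epochs=2, checkpoint_min_epoch=0, seed=7)
        _, h1 = train_model(ds, TINY_MODEL, cfg)
        _, h2 = train_model(ds, TINY_MODEL, cfg)
        assert h1.train_loss == h2.train_loss

    def test_gradient_accumulation_matches_single_batch(self):
        """2x2 accumulation and one batch of 4 produce the same first-step update."""
        ds = _tiny_dataset(n=4)
        base = TrainConfig(epochs=1, checkpoint_min_epoch=0, lr_initial=0.01, seed=3)
        accum = TrainConfig(epochs=1, checkpoint_min_epoch=0, lr_initial=0.01, seed=3,
                            per_replica_batch=2, replicas=2)
        single = TrainConfig(epochs=1, checkpoint_min_epoch=0, lr_initial=0.01, seed=3,
                             per_replica_batch=4, replicas=1)
        m_acc, _ = train_model(ds, TINY_MODEL, accum)
        m_one, _ = train_model(ds, TINY_MODEL, single)
        for pa, po in zip(m_acc.params(), m_one.params()):
            np.testing.assert_allclose(pa.value, po.value, atol=1e-6)

    def test_validation_checkpoint_restored(self):
        ds = _tiny_dataset(n=4)
        val = _tiny_dataset(n=2, seed=9)
        cfg = TrainConfig(epochs=3, checkpoint_min_epoch=0, lr_initial=0.05, seed=1)
        model, hist = train_model(ds, TINY_MODEL, cfg, val_dataset=val)
        assert len(hist.val_loss) == 3
        best = select_checkpoint(hist, cfg)
        assert 1 <= best <= 3

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            HeatmapDataset([], HeatmapSpec(), TINY_PRE)


def test_hyperparameter_grid_covers_families_and_widths():
    grid = hyperparameter_grid()
    assert len(grid) == 8
    assert {s.family for s in grid} == {"exponential", "gaussian"}
    assert sorted({s.sigma for s in grid}) == [0.79, 1.57, 3.14, 6.28]
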