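"""Hybrid loss, learning-rate schedules, smoothing, k-fold and train loop."""

import numpy as np
import pytest

from wsf.autodiff import Tensor
from wsf.model import WSFConfig, WSFModel
from wsf.simgen import StomaFieldSpec, generate_sample
from wsf.training import (TrainConfig, TrainHistory, hybrid_loss, kfold_split,
                          lr_at_epoch, smooth_losses, train_loop)

RNG = np.random.default_rng(3)


class TestHybridLoss:
    def test_uniform_logits_cross_entropy_is_ln_k(self):
        logits = Tensor(np.zeros((1, 3, 4, 4), dtype=np.float32))
        mask = RNG.integers(0, 3, (1, 4, 4))
        loss = hybrid_loss(logits, mask, loss_weights=(1.0, 0.0))
        assert float(loss.data) == pytest.approx(np.log(3), rel=1e-5)

    def test_saturated_correct_logits_drive_loss_to_zero(self):
        mask = RNG.integers(0, 3, (1, 8, 8))
        logits = np.full((1, 3, 8, 8), -200.0, dtype=np.float32)
        np.put_along_axis(logits, mask[:, None], 200.0, axis=1)
        loss = hybrid_loss(Tensor(logits), mask)
        assert float(loss.data) < 1e-4

    def test_matches_handrolled_ce_plus_dice(self):
        k = 3
        logits = RNG.standard_normal((1, k, 4, 4)).astype(np.float32)
        mask = RNG.integers(0, k, (1, 4, 4))
        got = float(hybrid_loss(Tensor(logits), mask, loss_weights=(1.0, 1.0)).data)

        # independent formula evaluation
        z = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
        onehot = np.eye(k)[mask].transpose(0, 3, 1, 2)
        ce = -np.mean(np.log(np.take_along_axis(p, mask[:, None], axis=1)))
        dices = []
        for c in range(k):
            inter = (p[:, c] * onehot[:, c]).sum()
            dices.append((2 * inter + 1.0) / (p[:, c].sum() + onehot[:, c].sum() + 1.0))
        expect = ce + (1 - np.mean(dices))
        assert got == pytest.approx(expect, rel=1e-5)

    def test_class_weights_reweight_pixels(self):
        logits = Tensor(RNG.standard_normal((1, 2, 2, 2)).astype(np.float32))
        mask = np.array([[[0, 0], [0, 1]]])
        unweighted = float(hybrid_loss(logits, mask, (1.0, 0.0)).data)
        upweight_fg = float(hybrid_loss(logits, mask, (1.0, 0.0),
                                        class_weights=(1.0, 10.0)).data)
        assert upweight_fg != pytest.approx(unweighted)

    def test_out_of_range_label_rejected(self):
        logits = Tensor(np.zeros((1, 2, 2, 2), dtype=np.float32))
        with pytest.raises(ValueError, match="num_classes"):
            hybrid_loss(logits, np.full((1, 2, 2), 2))


class TestSchedule:
    def test_epoch_decay_initial_values(self):
        cfg = TrainConfig(schedule_mode="epoch_decay")
        assert lr_at_epoch(cfg, 0) == pytest.approx(6e-5)
        assert lr_at_epoch(cfg, 1) == pytest.approx(4.8e-5)

    def test_epoch_decay_exact_ratio_everywhere(self):
        cfg = TrainConfig(schedule_mode="epoch_decay")
        lrs = [lr_at_epoch(cfg, e) for e in range(30)]
        ratios = np.array(lrs[1:]) / np.array(lrs[:-1])
        np.testing.assert_allclose(ratios, 0.8, rtol=1e-12)

    def test_plateau_constant_under_improvement(self):
        cfg = TrainConfig(schedule_mode="plateau", plateau_patience=2)
        hist = TrainHistory(epoch_val_loss=list(np.linspace(1.0, 0.1, 10)))
        for e in range(10):
            assert lr_at_epoch(cfg, e, hist) == pytest.approx(6e-5)

    def test_plateau_decays_after_patience_stall(self):
        cfg = TrainConfig(schedule_mode="plateau", plateau_patience=2)
        hist = TrainHistory(epoch_val_loss=[1.0, 0.9, 0.9, 0.9, 0.85])
        # stalls at epochs 2,3 -> one decay applied from epoch 4 onwards
        assert lr_at_epoch(cfg, 3, hist) == pytest.approx(6e-5)
        assert lr_at_epoch(cfg, 4, hist) == pytest.approx(6e-5 * 0.8)

    def test_negative_epoch_rejected(self):
        with pytest.raises(ValueError):
            lr_at_epoch(TrainConfig(), -1)


class TestSmoothing:
    def test_constant_series_is_fixed_point(self):
        assert smooth_losses([2.5] * 6, 0.3) == [2.5] * 6

    def test_alpha_one_is_identity(self):
        raw = [3.0, 1.0, 2.0]
        assert smooth_losses(raw, 1.0) == raw

    def test_hand_recursion(self):
        assert smooth_losses([1.0, 0.0, 0.0], 0.5) == [1.0, 0.5, 0.25]

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            smooth_losses([], 0.5)


class TestKFold:
    @pytest.mark.parametrize("n,k", [(10, 5), (11, 3), (7, 2)])
    def test_folds_disjoint_exhaustive_balanced(self, n, k):
        folds = kfold_split(n, k, seed=1)
        flat = [i for f in folds for i in f]
        assert sorted(flat) == list(range(n))
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            kfold_split(4, 1)


def _tiny_dataset(n, seed0=100):
    spec = lambda i: StomaFieldSpec(image_height=64, image_width=64, n_stomata=1,
                                    long_axis_range=(28, 36), short_axis_range=(16, 22),
                                    pore_fraction=0.5, background_texture=(6.0, 4.0),
                                    noise_sigma=3.0, seed=seed0 + i)
    return [(s.image, s.mask) for s in (generate_sample(spec(i)) for i in range(n))]


class TestTrainLoop:
    def test_bookkeeping_two_epochs(self):
        pairs = _tiny_dataset(10)
        model = WSFModel(WSFConfig.tiny(), seed=0)
        cfg = TrainConfig(epochs=2, batch_size=4, initial_lr=1e-3, seed=0)
        hist = train_loop(model, pairs[:8], pairs[8:], cfg)
        assert len(hist.epoch_lr) == 2
        assert len(hist.epoch_miou) == len(hist.epoch_precision) == 2
        assert len(hist.train_loss) == 2 * 2          # ceil(8/4) batches/epoch
        assert len(hist.smoothed_train_loss) == len(hist.train_loss)
        assert len(hist.smoothed_val_loss) == len(hist.val_loss)

    def test_identical_seeds_identical_series(self):
        pairs = _tiny_dataset(8)
        cfg = TrainConfig(epochs=2, batch_size=4, initial_lr=1e-3, seed=5)
        h1 = train_loop(WSFModel(WSFConfig.tiny(), seed=1), pairs[:6], pairs[6:], cfg)
        h2 = train_loop(WSFModel(WSFConfig.tiny(), seed=1), pairs[:6], pairs[6:], cfg)
        assert h1.train_loss == h2.train_loss
        assert h1.val_loss == h2.val_loss

    def test_empty_partition_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_loop(WSFModel(WSFConfig.tiny(), seed=0), [], _tiny_dataset(2),
                       TrainConfig(epochs=1))


@pytest.mark.parametrize("bad", [
    dict(initial_lr=0.0),
    dict(lr_decay_factor=1.5),
    dict(batch_size=0),
    dict(loss_weights=(0.0, 0.0)),
    dict(smoothing_alpha=0.0),
    dict(schedule_mode="bogus"),
])
def test_invalid_train_config_rejected(bad):
    with pytest.raises(ValueError):
        TrainConfig(**bad)
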