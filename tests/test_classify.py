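"""Compound scaling, losses, k-fold training, cascade semantics."""

import math

import numpy as np
import pytest

from pneumostage import classify, nn
from pneumostage.classify import (BinaryNet, CascadeModel, CompoundScalingConfig,
                                  TrainConfig, binary_cross_entropy, cascade_predict,
                                  cross_entropy, kfold_indices, scale_channels,
                                  scale_depths)
from pneumostage.staging import StageLabel


class TestCompoundScaling:
    def test_depth_factor_two_doubles_stage_depths(self):
        assert scale_depths((1, 2, 2, 3), 2) == (2, 4, 4, 6)

    def test_width_factor_half_halves_channels(self):
        assert scale_channels((32, 16, 24), 0.5) == (16, 8, 12)

    def test_channels_floored_at_one(self):
        assert scale_channels((1, 2), 0.1) == (1, 1)

    def test_relu(self):
        assert classify.relu(-3) == 0 and classify.relu(2) == 2

    def test_resolution_too_small_rejected(self):
        with pytest.raises(ValueError, match="resolution"):
            classify.build_profusion_net(CompoundScalingConfig(1.0, 1.0, 32),
                                         base_depths=(1, 1, 1, 1, 1))

    def test_forward_softmax_over_classes(self):
        net = classify.build_profusion_net(CompoundScalingConfig(1.0, 0.25, 32), n_classes=4)
        p = classify.predict_proba(net, np.zeros((2, 32, 32), np.float32))
        assert p.shape == (2, 4)
        assert np.allclose(p.sum(axis=1), 1.0)


class TestLosses:
    def test_perfect_prediction_near_zero(self):
        assert cross_entropy((1.0, 0.0, 0.0, 0.0), 0) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_prediction_is_log_four(self):
        assert cross_entropy((0.25,) * 4, 2) == pytest.approx(math.log(4), rel=1e-9)

    def test_direct_evaluation(self):
        assert cross_entropy((0.7, 0.1, 0.1, 0.1), 0) == pytest.approx(-math.log(0.7))

    def test_one_hot_vector_accepted(self):
        assert cross_entropy((0.7, 0.1, 0.1, 0.1), (1, 0, 0, 0)) == pytest.approx(-math.log(0.7))

    @pytest.mark.parametrize("p,y,expected", [
        (0.5, 1, math.log(2)),
        (0.5, 0, math.log(2)),
        (0.9, 1, -math.log(0.9)),
    ])
    def test_binary_cross_entropy(self, p, y, expected):
        assert binary_cross_entropy(p, y) == pytest.approx(expected)

    def test_zero_probability_clamped_not_infinite(self):
        assert np.isfinite(cross_entropy((0.0, 1.0, 0.0, 0.0), 0))
        assert np.isfinite(binary_cross_entropy(0.0, 1))

    def test_losses_nonnegative(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.dirichlet(np.ones(4))
            assert cross_entropy(p, int(rng.integers(4))) >= 0
            assert binary_cross_entropy(float(rng.random()), int(rng.integers(2))) >= 0


class TestKFold:
    def test_cohort_split_sizes(self):
        folds = kfold_indices(398, 5, seed=0)
        assert sorted(len(f) for f in folds) == [79, 79, 80, 80, 80]

    def test_folds_partition_the_data(self):
        folds = kfold_indices(103, 5, seed=1)
        all_idx = np.concatenate(folds)
        assert len(all_idx) == 103
        assert len(np.unique(all_idx)) == 103

    def test_lr_schedule_decays_by_ten(self):
        cfg = TrainConfig()
        assert cfg.lr_at_epoch(0) == pytest.approx(1e-4)
        assert cfg.lr_at_epoch(15) == pytest.approx(1e-5)


class TestTrainClassifier:
    def test_absent_class_rejected_by_name(self):
        x = np.zeros((8, 16, 16), np.float32)
        y = [0, 0, 1, 1, 2, 2, 0, 1]  # class 3 missing
        cfg = TrainConfig(folds=2, epochs=1)
        with pytest.raises(ValueError, match="class 3"):
            classify.train_classifier(
                lambda: classify.build_profusion_net(
                    CompoundScalingConfig(1.0, 0.25, 32), seed=0), x, y, cfg)


def _stub(p):
    net = BinaryNet(trained=True)
    net.predict_prob = lambda img: p
    return net


def _tracking_stub(p):
    net = BinaryNet(trained=True)
    net.calls = 0

    def prob(img):
        net.calls += 1
        return p
    net.predict_prob = prob
    return net


class TestCascade:
    @pytest.mark.parametrize("p1,p2,p3,expected", [
        (0.1, 0.1, 0.1, StageLabel.NORMAL),
        (0.1, 0.1, 0.9, StageLabel.NORMAL),
        (0.1, 0.9, 0.1, StageLabel.NORMAL),
        (0.1, 0.9, 0.9, StageLabel.NORMAL),
        (0.9, 0.9, 0.1, StageLabel.III),
        (0.9, 0.9, 0.9, StageLabel.III),
        (0.9, 0.1, 0.9, StageLabel.II),
        (0.9, 0.1, 0.1, StageLabel.I),
    ])
    def test_all_eight_outcome_paths_map_to_one_stage(self, p1, p2, p3, expected):
        cascade = CascadeModel(_stub(p1), _stub(p2), _stub(p3))
        assert cascade_predict(cascade, np.zeros((8, 8))) is expected

    def test_normal_short_circuits_downstream_nets(self):
        s2, s3 = _tracking_stub(0.9), _tracking_stub(0.9)
        cascade = CascadeModel(_stub(0.01), s2, s3)
        assert cascade_predict(cascade, np.zeros((8, 8))) is StageLabel.NORMAL
        assert s2.calls == 0 and s3.calls == 0

    def test_untrained_component_rejected(self):
        cascade = CascadeModel(_stub(0.9), BinaryNet(trained=False), _stub(0.5))
        with pytest.raises(ValueError, match="stage2"):
            cascade_predict(cascade, np.zeros((8, 8)))

    def test_trained_binary_net_end_to_end_sanity(self):
        # two trivially separable intensity classes
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.random((10, 16, 16)) * 0.2,
                            0.8 + rng.random((10, 16, 16)) * 0.2]).astype(np.float32)
        y = [0] * 10 + [1] * 10
        cfg = TrainConfig(batch_size=4, init_lr=1e-2, epochs=20, max_iterations=10 ** 6)
        bn = classify.train_binary(classify.build_binary_net(16, widths=(4, 8), seed=1), x, y, cfg)
        preds = [bn.predict_prob(im) >= 0.5 for im in x]
        assert np.mean(np.array(preds) == np.array(y)) >= 0.9
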