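"""Loss closed forms, optimization sanity and freeze/broadcast contracts."""

import numpy as np
import pytest

from pdmotion.config import LossConfig, NetworkConfig, TrainConfig
from pdmotion.networks import SSLNetwork, build_model
from pdmotion.train import (finetune, huber_grad, huber_loss, pretrain,
                            ssl_loss, ssl_loss_grad_logits,
                            subject_validation_split)


class TestHuberLoss:
    def test_zero_residual(self):
        assert huber_loss(np.array([3.0]), np.array([3.0])) == 0.0

    def test_quadratic_branch_closed_form(self):
        # r = 0.5, delta = 1 -> 0.5 * 0.25 = 0.125
        assert huber_loss(np.array([0.5]), np.array([0.0])) == pytest.approx(0.125)

    def test_linear_branch_closed_form(self):
        # r = 3, delta = 1 -> 1 * (3 - 0.5) = 2.5
        assert huber_loss(np.array([3.0]), np.array([0.0])) == pytest.approx(2.5)

    def test_continuity_and_smoothness_at_delta(self):
        eps = 1e-6
        below = huber_loss(np.array([1.0 - eps]), np.array([0.0]))
        above = huber_loss(np.array([1.0 + eps]), np.array([0.0]))
        assert above - below == pytest.approx(2 * eps, abs=1e-9)
        g_below = huber_grad(np.array([1.0 - eps]), np.array([0.0]))
        g_above = huber_grad(np.array([1.0 + eps]), np.array([0.0]))
        assert g_above[0] == pytest.approx(g_below[0], abs=1e-5)

    def test_bounded_by_half_squared_error(self, rng):
        r = rng.normal(0, 3, size=200)
        h = np.array([huber_loss(np.array([x]), np.array([0.0])) for x in r])
        assert np.all(h <= 0.5 * r ** 2 + 1e-12)
        quad = np.abs(r) <= 1.0
        np.testing.assert_allclose(h[quad], 0.5 * r[quad] ** 2)

    def test_gradient_matches_finite_difference(self):
        y = np.array([1.0, 5.0, -2.0])
        y_hat = np.array([0.5, 1.0, -1.9])
        g = huber_grad(y, y_hat)
        eps = 1e-6
        for i in range(3):
            yp = y_hat.copy(); yp[i] += eps
            ym = y_hat.copy(); ym[i] -= eps
            num = (huber_loss(y, yp) - huber_loss(y, ym)) / (2 * eps)
            assert g[i] == pytest.approx(num, abs=1e-8)


class TestSSLLoss:
    def test_single_sample_chance_prediction(self):
        # y = 1, P = 0.5 -> -log 0.5 = 0.693147 (unit positive weight)
        cfg = LossConfig(positive_weight=1.0)
        y = np.array([[1.0]]); P = np.array([[0.5]])
        assert ssl_loss(y, P, LossConfig(alphas=(1.0,), positive_weight=1.0)) \
            == pytest.approx(np.log(2), abs=1e-5)

    def test_perfect_prediction_is_zero(self):
        cfg = LossConfig(positive_weight=1.0)
        y = np.array([[1.0, 0.0, 1.0]])
        P = np.where(y > 0.5, 1.0 - cfg.prob_clip_eps, cfg.prob_clip_eps)
        assert ssl_loss(y, P, cfg) < 1e-5

    def test_alpha_linearity(self):
        y = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        P = np.full((2, 3), 0.3)
        base = ssl_loss(y, P, LossConfig(alphas=(1, 1, 1), positive_weight=1))
        doubled = ssl_loss(y, P, LossConfig(alphas=(2, 1, 1), positive_weight=1))
        only_t1 = ssl_loss(y, P, LossConfig(alphas=(1, 0, 0), positive_weight=1))
        assert doubled - base == pytest.approx(only_t1)

    def test_positive_weight_scales_positive_terms_only(self):
        y = np.array([[1.0, 0.0, 0.0]])
        P = np.full((1, 3), 0.5)
        w1 = ssl_loss(y, P, LossConfig(positive_weight=1.0))
        w3 = ssl_loss(y, P, LossConfig(positive_weight=3.0))
        assert w3 - w1 == pytest.approx(2 * np.log(2))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ssl_loss(np.zeros((2, 3)), np.full((3, 2), 0.5))

    def test_logit_gradient_matches_finite_difference(self):
        cfg = LossConfig()
        y = np.array([[1.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
        z = np.array([[0.3, -0.2, 1.0], [-1.0, 0.4, 0.1]])
        _, g = ssl_loss_grad_logits(y, z, cfg)
        from pdmotion.nn import sigmoid
        eps = 1e-6
        for i in range(2):
            for t in range(3):
                zp = z.copy(); zp[i, t] += eps
                zm = z.copy(); zm[i, t] -= eps
                num = (ssl_loss(y, sigmoid(zp), cfg)
                       - ssl_loss(y, sigmoid(zm), cfg)) / (2 * eps)
                assert g[i, t] == pytest.approx(num, abs=1e-7)


class TestValidationSplit:
    def test_holds_out_whole_subjects(self, rng):
        subjects = np.repeat([f"S{i}" for i in range(10)], 20)
        tr, val = subject_validation_split(subjects, 0.2, rng)
        tr_subj = set(subjects[tr]); val_subj = set(subjects[val])
        assert tr_subj.isdisjoint(val_subj)
        assert len(val_subj) == 2

    def test_single_subject_falls_back_to_window_split(self, rng):
        subjects = np.array(["S0"] * 50)
        tr, val = subject_validation_split(subjects, 0.2, rng)
        assert val.sum() == 10 and tr.sum() == 40


def _toy_regression_data(n=96, seed=0):
    """Windows whose 4-6 Hz tone amplitude encodes the target score."""
    rng = np.random.default_rng(seed)
    y = rng.uniform(5, 55, size=n)
    t = np.arange(320) / 64.0
    x_r = 0.3 * rng.standard_normal((n, 320, 6))
    for i in range(n):
        f = rng.uniform(4, 6)
        x_r[i] += (y[i] / 20.0) * np.sin(2 * np.pi * f * t)[:, None]
    from pdmotion.config import StftConfig
    from pdmotion.preprocess import compute_spectrograms
    x_s = (compute_spectrograms(x_r, StftConfig(), fs=64.0) + 80.0) / 80.0
    subjects = np.array([f"S{i % 4}" for i in range(n)])
    return x_r, x_s, y, subjects


@pytest.fixture(scope="module")
def tiny_cfg():
    return NetworkConfig.reduced(scale=16)


class TestFinetune:
    def test_validation_mae_improves_over_untrained(self, tiny_cfg):
        x_r, x_s, y, subjects = _toy_regression_data()
        net = build_model("cnn_multi", tiny_cfg, seed=0)
        tc = TrainConfig(epochs=8, learning_rate=3e-3, seed=0)
        _, hist = finetune(net, x_r, x_s, y, subjects, tc, LossConfig())
        assert hist.val_metric[-1] < hist.val_metric[0]

    def test_deterministic_history_under_seed(self, tiny_cfg):
        x_r, x_s, y, subjects = _toy_regression_data(n=48)
        tc = TrainConfig(epochs=3, learning_rate=1e-3, seed=7)
        hists = []
        for _ in range(2):
            net = build_model("cnn_multi", tiny_cfg, seed=3)
            _, h = finetune(net, x_r, x_s, y, subjects, tc, LossConfig())
            hists.append(h)
        assert hists[0].train_loss == hists[1].train_loss
        assert hists[0].val_loss == hists[1].val_loss

    def test_empty_labels_rejected(self, tiny_cfg):
        net = build_model("cnn_multi", tiny_cfg, seed=0)
        with pytest.raises(ValueError):
            finetune(net, np.empty((0, 320, 6)), np.empty((0, 33, 43, 6)),
                     np.empty(0), np.empty(0, dtype=object))

    def test_round_label_broadcast(self):
        """A 40-window round scored 27 trains against forty 27s."""
        from pdmotion.data import GyroWindow, WindowSet
        wins = [GyroWindow(np.zeros((320, 6)), "S1", 1, "resting", 5.0 * i,
                           updrs_score=27) for i in range(40)]
        ws = WindowSet.from_windows(wins)
        y = ws.meta["updrs"].to_numpy(float)
        assert y.shape == (40,) and np.all(y == 27.0)


class TestPretrain:
    def test_loss_decreases_and_beats_chance(self, reduced_net_cfg):
        """On clearly transformed data the pretext heads become informative."""
        from pdmotion.config import StftConfig, TransformConfig
        from pdmotion.transforms import build_ssl_dataset
        rng = np.random.default_rng(1)
        windows = np.cumsum(rng.standard_normal((50, 320, 6)), axis=1)
        subjects = np.array([f"S{i % 5}" for i in range(50)])
        x_tr, x_ts, y_p, _, subs = build_ssl_dataset(
            windows, TransformConfig(rng_seed=2), StftConfig(),
            subject_ids=subjects)
        x_tr = (x_tr - x_tr.mean()) / (x_tr.std() + 1e-9)
        x_ts = (x_ts + 80.0) / 80.0
        net = SSLNetwork(NetworkConfig.reduced(scale=16), seed=0)
        tc = TrainConfig(epochs=6, learning_rate=1e-3, seed=0)
        _, hist = pretrain(net, x_tr, x_ts, y_p, subs, tc, LossConfig())
        assert hist.train_loss[-1] < hist.train_loss[0]
        assert np.mean(hist.val_metric[-1]) > 0.5

    def test_single_class_task_rejected(self, reduced_net_cfg):
        net = SSLNetwork(NetworkConfig.reduced(scale=16), seed=0)
        y_p = np.zeros((8, 3))
        with pytest.raises(ValueError):
            pretrain(net, np.zeros((8, 320, 6)), np.zeros((8, 33, 43, 6)),
                     y_p, np.array(["a"] * 8))
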