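"""Architecture contracts: shapes, config integrity, variants, transfer."""

import numpy as np
import pytest

from pdmotion.config import NetworkConfig
from pdmotion.networks import (MODEL_VARIANTS, RawBranch, SpecBranch,
                               SSLNetwork, WeightsBundle, build_model,
                               conv_block_keys, count_params,
                               transfer_and_freeze)
from pdmotion.nn import Adam


def test_default_config_matches_published_architecture():
    """The printed layer hyperparameters are the defaults, verbatim."""
    cfg = NetworkConfig()
    assert cfg.conv_r_filters == (64, 128)
    assert cfg.conv_r_kernels == (32, 8)
    assert cfg.conv_r_pool == 16 and cfg.conv_r_pool_stride == 4
    assert cfg.conv_r_dropout == (0.1, 0.2)
    assert cfg.conv_s_filters == (64, 128)
    assert cfg.conv_s_kernels == ((5, 5), (3, 3))
    assert cfg.conv_s_pool == 2 and cfg.conv_s_pool_stride == 2
    assert cfg.conv_s_dropout == (0.1, 0.1)
    assert cfg.task_head_size == 128 and cfg.n_tasks == 3
    assert cfg.lstm_size == 128 and cfg.lstm_dropout == 0.1
    assert cfg.fusion_dense == 256


class TestBranchShapes:
    def test_raw_branch_chain_full_width(self):
        """(B,320,6) -> conv 320x64 -> pool 77x64 -> conv 77x128 -> GAP 128."""
        cfg = NetworkConfig()
        br = RawBranch(cfg, np.random.default_rng(0))
        x = np.random.default_rng(1).standard_normal((3, 320, 6))
        h = br.conv1.forward(x)
        assert h.shape == (3, 320, 64)
        h = br.pool.forward(br.relu1.forward(h))
        assert h.shape == (3, 77, 64)
        h = br.conv2.forward(h)
        assert h.shape == (3, 77, 128)
        assert br.forward(x, pooled=True).shape == (3, 128)
        assert br.forward(x, pooled=False).shape == (3, 77, 128)

    def test_spec_branch_chain_full_width(self):
        """(B,33,43,6) -> 33x43x64 -> pool 16x21x64 -> 16x21x128 -> GMP 128."""
        cfg = NetworkConfig()
        br = SpecBranch(cfg, np.random.default_rng(0))
        x = np.random.default_rng(1).standard_normal((3, 33, 43, 6))
        h = br.conv1.forward(x)
        assert h.shape == (3, 33, 43, 64)
        h = br.pool.forward(br.relu1.forward(h))
        assert h.shape == (3, 16, 21, 64)
        h = br.conv2.forward(h)
        assert h.shape == (3, 16, 21, 128)
        assert br.forward(x, pooled=True).shape == (3, 128)
        assert br.forward(x, pooled=False).shape == (3, 21, 128)

    def test_wrong_input_shape_rejected(self, reduced_net_cfg):
        br = RawBranch(reduced_net_cfg, np.random.default_rng(0))
        with pytest.raises(ValueError):
            br.forward(np.zeros((2, 100, 6)))


class TestSSLNetwork:
    def test_probabilities_strictly_inside_unit_interval(self, reduced_net_cfg):
        net = SSLNetwork(reduced_net_cfg, seed=0)
        P = net.predict_proba(np.random.default_rng(0).standard_normal((4, 320, 6)),
                              np.random.default_rng(1).standard_normal((4, 33, 43, 6)))
        assert P.shape == (4, 3)
        assert np.all((P > 0.0) & (P < 1.0))

    def test_zero_weights_give_chance_probability(self, reduced_net_cfg):
        net = SSLNetwork(reduced_net_cfg, seed=0)
        for p in net.params():
            p.value[...] = 0.0
        P = net.predict_proba(np.zeros((2, 320, 6)), np.zeros((2, 33, 43, 6)))
        np.testing.assert_array_equal(P, 0.5)

    def test_task_head_gradients_are_disjoint(self, reduced_net_cfg):
        """Loss on head t must not touch head u != t weights."""
        net = SSLNetwork(reduced_net_cfg, seed=0)
        xr = np.random.default_rng(2).standard_normal((4, 320, 6))
        xs = np.random.default_rng(3).standard_normal((4, 33, 43, 6))
        net.forward(xr, xs, train=False)
        dlog = np.zeros((4, 3))
        dlog[:, 0] = 1.0  # gradient only through task-0 head
        for p in net.params():
            p.zero_grad()
        net.backward(dlog)
        named = net.named_params()
        assert np.abs(named["task0/dense/W"].grad).max() > 0
        for t in (1, 2):
            assert np.abs(named[f"task{t}/dense/W"].grad).max() == 0.0
            assert np.abs(named[f"task{t}/out/W"].grad).max() == 0.0


class TestVariants:
    @pytest.mark.parametrize("variant", MODEL_VARIANTS)
    def test_all_variants_construct_and_forward(self, variant, reduced_net_cfg):
        net = build_model(variant, reduced_net_cfg, seed=0)
        xr = np.random.default_rng(0).standard_normal((2, 320, 6))
        xs = np.random.default_rng(1).standard_normal((2, 33, 43, 6))
        y = net.forward(xr if net.use_raw else None,
                        xs if net.use_spec else None)
        assert y.shape == (2,) and np.all(np.isfinite(y))

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            build_model("transformer", NetworkConfig.reduced())

    def test_single_input_variant_rejects_other_input(self, reduced_net_cfg):
        net = build_model("cnn1d", reduced_net_cfg, seed=0)
        with pytest.raises(ValueError):
            net.forward(x_r=None, x_s=np.zeros((2, 33, 43, 6)))

    def test_multichannel_params_superset_of_single(self, reduced_net_cfg):
        multi = set(build_model("cnn_multi_lstm", reduced_net_cfg).named_params())
        single = set(build_model("cnn1d_lstm", reduced_net_cfg).named_params())
        raw_keys = {k for k in single if k.startswith("convR")}
        assert raw_keys <= multi

    def test_parameter_count_is_pure_function_of_config(self, reduced_net_cfg):
        a = count_params(build_model("cnn_multi_lstm", reduced_net_cfg, seed=1))
        b = count_params(build_model("cnn_multi_lstm", reduced_net_cfg, seed=99))
        assert a == b

    def test_inference_is_deterministic_with_dropout_off(self, reduced_net_cfg):
        net = build_model("cnn_multi_lstm", reduced_net_cfg, seed=0)
        xr = np.random.default_rng(0).standard_normal((2, 320, 6))
        xs = np.random.default_rng(1).standard_normal((2, 33, 43, 6))
        xr2 = np.concatenate([xr, xr])
        xs2 = np.concatenate([xs, xs])
        y = net.predict(xr2, xs2)
        np.testing.assert_array_equal(y[:2], y[2:])

    def test_zero_weight_network_outputs_bias(self, reduced_net_cfg):
        net = build_model("cnn_multi", reduced_net_cfg, seed=0)
        for p in net.params():
            p.value[...] = 0.0
        y = net.forward(np.random.default_rng(0).standard_normal((2, 320, 6)),
                        np.random.default_rng(1).standard_normal((2, 33, 43, 6)))
        np.testing.assert_array_equal(y, 0.0)


class TestTransferAndFreeze:
    @pytest.fixture
    def bundle_and_net(self, reduced_net_cfg):
        ssl = SSLNetwork(reduced_net_cfg, seed=5)
        bundle = WeightsBundle.from_network(ssl)
        net = build_model("cnn_multi_lstm", reduced_net_cfg, seed=6)
        return bundle, net

    def test_block1_copied_bit_identically_and_frozen(self, bundle_and_net):
        bundle, net = bundle_and_net
        transfer_and_freeze(bundle, net)
        named = net.named_params()
        for key in conv_block_keys(named):
            np.testing.assert_array_equal(named[key].value, bundle.weights[key])
            assert named[key].frozen == ("/block1/" in key)

    def test_trainable_count_excludes_frozen(self, bundle_and_net):
        bundle, net = bundle_and_net
        transfer_and_freeze(bundle, net)
        total = len(net.params())
        frozen = sum(p.frozen for p in net.params())
        assert frozen == 4  # W and b of block1 in each branch
        assert total - frozen == len([p for p in net.params() if not p.frozen])

    def test_one_step_updates_block2_not_block1(self, bundle_and_net):
        bundle, net = bundle_and_net
        transfer_and_freeze(bundle, net)
        xr = np.random.default_rng(7).standard_normal((4, 320, 6))
        xs = np.random.default_rng(8).standard_normal((4, 33, 43, 6))
        opt = Adam(net.params(), lr=1e-2)
        y_hat = net.forward(xr, xs, train=False)
        net.backward(np.ones_like(y_hat))
        opt.step()
        named = net.named_params()
        for key in conv_block_keys(named):
            if "/block1/" in key:
                np.testing.assert_array_equal(named[key].value,
                                              bundle.weights[key])
            elif key.endswith("/W"):
                diff = np.linalg.norm(named[key].value - bundle.weights[key])
                assert diff > 0.0

    def test_missing_keys_reported(self, reduced_net_cfg):
        bundle = WeightsBundle(weights={})
        net = build_model("cnn_multi_lstm", reduced_net_cfg, seed=0)
        with pytest.raises(KeyError, match="convR/block1"):
            transfer_and_freeze(bundle, net)

    def test_bundle_hdf5_roundtrip(self, tmp_path, reduced_net_cfg):
        ssl = SSLNetwork(reduced_net_cfg, seed=1)
        bundle = WeightsBundle.from_network(ssl, metadata={"stage": "pretext"})
        bundle.frozen = {"convR/block1/conv/W"}
        path = tmp_path / "w.h5"
        bundle.save(path)
        loaded = WeightsBundle.load(path)
        assert loaded.frozen == bundle.frozen
        assert loaded.metadata["stage"] == "pretext"
        assert set(loaded.weights) == set(bundle.weights)
        for k in bundle.weights:
            np.testing.assert_array_equal(loaded.weights[k], bundle.weights[k])
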