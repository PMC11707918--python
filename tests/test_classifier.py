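"""Forward-pass oracles, simplex invariants and training behavior for the
two-branch classifier."""

import numpy as np
import pytest

from bcdnet import _nn
from bcdnet.classifier import (
    AHDNAMConfig,
    attention_layer,
    aspp_forward,
    build_branch,
    cnn1d_forward,
    config_from_position,
    dilated_conv1d,
    dtcn_forward,
    hyperparam_search_space,
    phase2_objective,
    predict_ahdnam,
    tcn_residual_block,
    train_branch,
)


def naive_dilated_conv(x, g, dilation, causal):
    """Independent loop oracle for the dilated convolution."""
    x = list(x)
    span = (len(g) - 1) * dilation
    if causal:
        x = [0.0] * span + x
    out = []
    for o in range(len(x) - span):
        out.append(sum(g[e] * x[o + e * dilation] for e in range(len(g))))
    return np.array(out)


class TestDilatedConv:
    def test_printed_toy_case(self):
        out = dilated_conv1d([1, 2, 3, 4, 5], [1, 1], dilation=2)
        assert np.array_equal(out, [4, 6, 8])

    def test_identity_kernel(self):
        x = np.arange(7.0)
        for d in (1, 2, 3):
            assert np.array_equal(dilated_conv1d(x, [1.0], dilation=d), x)

    def test_causal_preserves_length(self):
        x = np.random.default_rng(0).normal(size=11)
        out = dilated_conv1d(x, [0.5, -1.0, 2.0], dilation=4, causal=True)
        assert out.size == x.size

    @pytest.mark.parametrize("dilation", [1, 2, 4, 8])
    def test_matches_loop_oracle(self, dilation):
        rng = np.random.default_rng(dilation)
        for _ in range(25):
            L = int(rng.integers(20, 40))
            k = int(rng.integers(1, 4))
            x = rng.normal(size=L)
            g = rng.normal(size=k)
            for causal in (False, True):
                got = dilated_conv1d(x, g, dilation, causal)
                want = naive_dilated_conv(x, g, dilation, causal)
                assert np.allclose(got, want, atol=1e-12)

    def test_too_short_valid_mode(self):
        with pytest.raises(ValueError):
            dilated_conv1d([1.0, 2.0], [1.0, 1.0, 1.0], dilation=4)


class TestASPP:
    def test_single_rate_identity_path_is_relu(self):
        # identity depthwise kernel, unit pointwise, no norm, unit fuse
        aspp = _nn.ASPPModule(1, rates=(1,), branch_width=1, fuse_width=1,
                              batch_norm=False, rng=np.random.default_rng(0))
        aspp.branches[0].layers[0].w.value[:] = np.array([[0.0], [1.0], [0.0]])
        aspp.branches[0].layers[0].b.value[:] = 0.0
        aspp.branches[0].layers[1].w.value[:] = 1.0
        aspp.branches[0].layers[1].b.value[:] = 0.0
        aspp.fuse.w.value[:] = 1.0
        aspp.fuse.b.value[:] = 0.0
        x = np.array([1.0, -2.0, 3.0, -4.0])
        out = aspp_forward(x, aspp)
        assert np.allclose(out[0, :, 0], np.maximum(x, 0.0))

    def test_output_width_is_fuse_width(self):
        x = np.random.default_rng(1).normal(size=(3, 16, 1))
        for rates in ((1,), (1, 2), (1, 2, 4)):
            aspp = _nn.ASPPModule(1, rates=rates, branch_width=3, fuse_width=5,
                                  rng=np.random.default_rng(0))
            assert aspp_forward(x, aspp).shape == (3, 16, 5)

    def test_matches_manual_per_branch_computation(self):
        rng = np.random.default_rng(2)
        aspp = _nn.ASPPModule(1, rates=(1, 2, 4), branch_width=2, fuse_width=3,
                              batch_norm=False, rng=rng)
        x = rng.normal(size=(2, 12, 1))
        outs = []
        for br in aspp.branches:
            dw, pw = br.layers[0], br.layers[1]
            # depthwise same-padded dilated conv via the loop oracle
            conv = np.stack([
                naive_same_conv(x[n, :, 0], dw.w.value[:, 0], dw.dilation)
                for n in range(2)
            ])[:, :, None] + dw.b.value
            branch = np.maximum(conv @ pw.w.value + pw.b.value, 0.0)
            outs.append(branch)
        manual = np.concatenate(outs, axis=2) @ aspp.fuse.w.value + aspp.fuse.b.value
        assert np.allclose(aspp_forward(x, aspp), manual, atol=1e-12)

    def test_empty_rates_rejected(self):
        with pytest.raises(ValueError):
            _nn.ASPPModule(1, rates=())


def naive_same_conv(x, g, dilation):
    """Same-padded dilated convolution oracle (symmetric zero pad)."""
    span = (len(g) - 1) * dilation
    left = span // 2
    xp = np.r_[np.zeros(left), x, np.zeros(span - left)]
    return np.array([
        sum(g[e] * xp[o + e * dilation] for e in range(len(g)))
        for o in range(len(x))
    ])


class TestTCNResidual:
    def test_zero_transform_is_relu_identity(self):
        block = _nn.TCNResidualBlock(1, 1, kernel=3, dilation=2,
                                     rng=np.random.default_rng(0))
        block.conv1.w.value[:] = 0.0
        block.conv2.w.value[:] = 0.0
        block.conv1.b.value[:] = 0.0
        block.conv2.b.value[:] = 0.0
        x = np.array([1.0, -1.0, 2.0, -2.0])
        out = tcn_residual_block(x, block)
        assert np.allclose(out[0, :, 0], np.maximum(x, 0.0))

    @pytest.mark.parametrize("dilation", [1, 2, 4, 8])
    def test_length_preserved(self, dilation):
        block = _nn.TCNResidualBlock(2, 3, dilation=dilation,
                                     rng=np.random.default_rng(1))
        x = np.random.default_rng(2).normal(size=(2, 16, 2))
        assert tcn_residual_block(x, block).shape == (2, 16, 3)

    def test_hand_computed_tiny_case(self):
        block = _nn.TCNResidualBlock(1, 1, kernel=2, dilation=1,
                                     rng=np.random.default_rng(0))
        block.conv1.w.value[:] = np.array([[[1.0]], [[1.0]]])   # causal sum of pairs
        block.conv2.w.value[:] = np.array([[[0.0]], [[1.0]]])   # identity
        block.conv1.b.value[:] = 0.0
        block.conv2.b.value[:] = 0.0
        x = np.array([1.0, 0.0, -1.0])
        # conv1 (causal, k=2): [1, 1, -1] -> ReLU [1, 1, 0] -> conv2 identity
        # residual: x + [1,1,0] = [2,1,-1] -> ReLU [2,1,0]
        out = tcn_residual_block(x, block)
        assert np.allclose(out[0, :, 0], [2.0, 1.0, 0.0])


class TestAttention:
    def test_identical_positions_uniform_weights(self):
        layer = _nn.AttentionPool(3, rng=np.random.default_rng(0))
        x = np.tile(np.array([1.0, 2.0, 3.0]), (1, 5, 1))
        out, weights = attention_layer(x, layer)
        assert np.allclose(weights, 0.2)
        assert np.allclose(out[0], [1.0, 2.0, 3.0])

    def test_softmax_limit_selects_position(self):
        layer = _nn.AttentionPool(1, rng=np.random.default_rng(0))
        layer.w.value[:] = 1.0
        layer.b.value[:] = 0.0
        x = np.array([[[0.0], [50.0]]])
        out, weights = attention_layer(x, layer)
        assert weights[0, 1] == pytest.approx(1.0, abs=1e-6)
        assert out[0, 0] == pytest.approx(50.0, abs=1e-3)

    def test_weights_match_exp_normalize_oracle(self):
        rng = np.random.default_rng(4)
        layer = _nn.AttentionPool(2, rng=rng)
        x = rng.normal(size=(3, 4, 2))
        _, weights = attention_layer(x, layer)
        scores = x @ layer.w.value + layer.b.value[0]
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        assert np.allclose(weights, e / e.sum(axis=1, keepdims=True), atol=1e-12)

    def test_length_one_sequence_is_identity(self):
        layer = _nn.AttentionPool(2, rng=np.random.default_rng(0))
        x = np.random.default_rng(1).normal(size=(2, 1, 2))
        out, weights = attention_layer(x, layer)
        assert np.allclose(weights, 1.0)
        assert np.allclose(out, x[:, 0, :])

    def test_empty_sequence_rejected(self):
        layer = _nn.AttentionPool(2)
        with pytest.raises(ValueError):
            layer.forward(np.zeros((1, 0, 2)))


class TestBranchForward:
    @pytest.mark.parametrize("branch_id,fwd", [("dtcn", dtcn_forward), ("cnn", cnn1d_forward)])
    def test_rows_on_simplex(self, branch_id, fwd):
        cfg = AHDNAMConfig(seed=3)
        branch = build_branch(branch_id, 3, cfg)
        x = np.random.default_rng(0).normal(size=(6, 64, 1))
        probs = fwd(x, branch)
        assert probs.shape == (6, 3)
        assert np.all(probs >= 0)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_sample_permutation_permutes_rows(self):
        branch = build_branch("dtcn", 3, AHDNAMConfig(seed=1))
        x = np.random.default_rng(1).normal(size=(5, 64, 1))
        perm = np.array([3, 1, 4, 0, 2])
        assert np.allclose(dtcn_forward(x, branch)[perm], dtcn_forward(x[perm], branch))

    def test_constant_sequence_pool_constant(self):
        pool = _nn.MaxPool1D(2)
        x = np.full((1, 8, 3), 1.5)
        assert np.allclose(pool.forward(x), 1.5)

    def test_pool_shorter_than_kernel_rejected(self):
        pool = _nn.MaxPool1D(4)
        with pytest.raises(ValueError):
            pool.forward(np.zeros((1, 2, 1)))


class TestGradients:
    def test_layer_gradients_match_finite_differences(self):
        rng = np.random.default_rng(8)
        net = _nn.Sequential(
            _nn.DilatedConv1D(1, 3, kernel=3, dilation=2, padding="causal", rng=rng),
            _nn.ReLU(),
            _nn.MaxPool1D(2),
            _nn.AttentionPool(3, rng=rng),
            _nn.Dense(3, 4, rng=rng),
            _nn.ReLU(),
            _nn.Dense(4, 2, rng=rng),
        )
        x = rng.normal(size=(4, 10, 1))
        labels = rng.integers(0, 2, 4)
        for p in net.params():
            p.grad[...] = 0.0
        loss, dlogits = _nn.softmax_cross_entropy(net.forward(x, train=True), labels)
        net.backward(dlogits)
        h = 1e-6
        for p in net.params():
            for idx in range(0, p.value.size, max(1, p.value.size // 4)):
                orig = p.value.flat[idx]
                p.value.flat[idx] = orig + h
                l1, _ = _nn.softmax_cross_entropy(net.forward(x, train=True), labels)
                p.value.flat[idx] = orig - h
                l2, _ = _nn.softmax_cross_entropy(net.forward(x, train=True), labels)
                p.value.flat[idx] = orig
                assert (l1 - l2) / (2 * h) == pytest.approx(p.grad.flat[idx], abs=1e-6)


class TestTraining:
    def test_learns_separable_data(self, separable_features):
        values, labels = separable_features
        hits = 0
        for seed in range(5):
            cfg = AHDNAMConfig(seed=seed, dtcn_steps_per_epoch=20, cnn_steps_per_epoch=20)
            dtcn = train_branch(values, labels, "dtcn", cfg)
            probs = dtcn.predict_proba(values)
            hits += np.mean(np.argmax(probs, axis=1) == labels) >= 0.95
        assert hits >= 3  # majority over the recorded seeds

    def test_loss_history_finite(self, separable_features):
        values, labels = separable_features
        for seed in range(5):
            cfg = AHDNAMConfig(seed=seed, train_epochs=2,
                               dtcn_steps_per_epoch=10, cnn_steps_per_epoch=10)
            for branch_id in ("dtcn", "cnn"):
                trained = train_branch(values, labels, branch_id, cfg)
                assert np.all(np.isfinite(trained.loss_history))

    def test_steps_knob_is_live(self, separable_features):
        values, labels = separable_features
        cfg10 = AHDNAMConfig(seed=0, cnn_steps_per_epoch=10, train_epochs=1)
        cfg50 = AHDNAMConfig(seed=0, cnn_steps_per_epoch=50, train_epochs=1)
        t10 = train_branch(values, labels, "cnn", cfg10)
        t50 = train_branch(values, labels, "cnn", cfg50)
        p10 = np.concatenate([p.value.ravel() for p in t10.branch.params()])
        p50 = np.concatenate([p.value.ravel() for p in t50.branch.params()])
        assert not np.array_equal(p10, p50)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_branch(np.zeros((8, 4)), np.zeros(8, dtype=int), "cnn", AHDNAMConfig())

    def test_deterministic_given_seed(self, separable_features):
        values, labels = separable_features
        cfg = AHDNAMConfig(seed=2, train_epochs=1)
        a = train_branch(values, labels, "cnn", cfg)
        b = train_branch(values, labels, "cnn", cfg)
        for pa, pb in zip(a.branch.params(), b.branch.params()):
            assert np.array_equal(pa.value, pb.value)

    def test_checkpoint_round_trip(self, separable_features, tmp_path):
        from bcdnet.classifier import TrainedBranch

        values, labels = separable_features
        cfg = AHDNAMConfig(seed=1, train_epochs=1)
        trained = train_branch(values, labels, "dtcn", cfg)
        trained.save(tmp_path / "ckpt")
        loaded = TrainedBranch.load(tmp_path / "ckpt")
        assert np.allclose(loaded.predict_proba(values), trained.predict_proba(values))


class TestPredictAveraging:
    def _trained_pair(self, separable_features):
        values, labels = separable_features
        cfg = AHDNAMConfig(seed=0, train_epochs=1,
                           dtcn_steps_per_epoch=10, cnn_steps_per_epoch=10)
        return (
            values,
            train_branch(values, labels, "dtcn", cfg),
            train_branch(values, labels, "cnn", cfg),
        )

    def test_average_is_elementwise_mean(self, separable_features):
        values, dtcn, cnn = self._trained_pair(separable_features)
        scores = predict_ahdnam(values, dtcn, cnn)
        assert np.array_equal(scores.averaged, (scores.branch_dtcn + scores.branch_cnn) / 2)
        assert np.allclose(scores.averaged.sum(axis=1), 1.0, atol=1e-6)

    def test_exact_tie_prefers_lowest_class(self):
        # argmax on an exactly tied averaged row must return class 0
        row = np.array([[0.5, 0.5]])
        assert np.argmax(row, axis=1)[0] == 0

    def test_class_count_mismatch_rejected(self, separable_features):
        values, labels = separable_features
        cfg = AHDNAMConfig(seed=0, train_epochs=1)
        two = train_branch(values, labels, "dtcn", cfg)
        three_labels = labels.copy()
        three_labels[:3] = 2
        three = train_branch(values, three_labels, "cnn", cfg)
        with pytest.raises(ValueError):
            predict_ahdnam(values, two, three)


class TestPhase2:
    def test_search_space_matches_printed_ranges(self):
        space = hyperparam_search_space()
        assert np.array_equal(space.lower, [5, 10, 5, 10])
        assert np.array_equal(space.upper, [255, 50, 255, 50])
        assert space.integer_mask.all()

    def test_config_from_position_clips(self):
        cfg = config_from_position(np.array([300.0, 5.0, 0.0, 60.0]), AHDNAMConfig())
        assert cfg.dtcn_hidden == 255 and cfg.dtcn_steps_per_epoch == 10
        assert cfg.cnn_hidden == 5 and cfg.cnn_steps_per_epoch == 50

    def test_out_of_range_config_rejected(self):
        with pytest.raises(ValueError):
            AHDNAMConfig(dtcn_hidden=4)
        with pytest.raises(ValueError):
            AHDNAMConfig(cnn_steps_per_epoch=51)

    def test_objective_finite_on_fixture(self, separable_features):
        values, labels = separable_features
        value = phase2_objective(
            np.array([16.0, 10.0, 16.0, 10.0]), values, labels,
            base_config=AHDNAMConfig(train_epochs=2),
        )
        assert np.isfinite(value)
        assert value >= 2.0
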