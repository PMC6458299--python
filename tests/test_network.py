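import copy

import numpy as np
import pytest

from hebbnet.activations import HingeParams, batch_loss
from hebbnet.network import (
    ConvStage,
    DenseStage,
    LocalStage,
    PRESETS,
    TrainingConfig,
    apply_updates,
    build_network,
    component_rngs,
    evaluate,
    feedback_pass,
    forward_pass,
    parse_architecture,
    train,
    train_step,
)
from hebbnet.synthetic import linearly_separable_dataset


def small_spec(arch="Full 6; Full 4; Output", shape=(8,), C=3, **kw):
    return parse_architecture(arch, shape, C, **kw)


class TestParseArchitecture:
    def test_minimal(self):
        spec = small_spec("Full 10; Output", shape=(4,), C=3)
        kinds = [d.kind for d in spec.descriptors]
        assert kinds == ["full", "output"]
        assert spec.descriptors[0].units == 10

    def test_simpnet_preset(self):
        spec = parse_architecture("simpnet", (3, 32, 32), 10)
        kinds = [d.kind for d in spec.descriptors]
        assert kinds == ["conv", "maxpool", "drop", "full", "drop", "output"]
        d = spec.descriptors
        assert (d[0].channels, d[0].kernel) == (32, 5)
        assert (d[1].window, d[1].stride) == (3, 2)
        assert d[2].rate == pytest.approx(0.8)
        assert d[3].units == 500
        assert d[4].rate == pytest.approx(0.3)

    @pytest.mark.parametrize("name", list(PRESETS))
    def test_all_presets_parse(self, name):
        spec = parse_architecture(name, (3, 32, 32), 10)
        assert spec.descriptors[-1].kind == "output"

    def test_deepnet_s_strides(self):
        spec = parse_architecture("deepnet_s", (3, 32, 32), 10)
        pools = [d for d in spec.descriptors if d.kind == "maxpool"]
        assert [(p.window, p.stride) for p in pools] == [(3, 3), (2, 2), (2, 2)]

    def test_sum_mismatch_rejected(self):
        with pytest.raises(ValueError):
            small_spec("Conv 8 3x3; Conv 4 3x3; SUM; Output", shape=(1, 8, 8))

    def test_sum_matching_ok(self):
        spec = small_spec("Conv 8 3x3; Conv 8 3x3; SUM; Output", shape=(1, 8, 8))
        assert [d.kind for d in spec.descriptors][2] == "sum"

    def test_unknown_descriptor(self):
        with pytest.raises(ValueError):
            small_spec("Frob 7; Output")

    def test_missing_output(self):
        with pytest.raises(ValueError):
            small_spec("Full 10")

    def test_untied_flag_converts_conv(self):
        spec = small_spec(
            "Conv 4 3x3; Output", shape=(1, 8, 8), untied=True
        )
        assert spec.descriptors[0].kind == "local"

    def test_invalid_mode(self):
        with pytest.raises(ValueError):
            small_spec(mode="sgd")


class TestBuildNetwork:
    def test_deterministic(self):
        tc = TrainingConfig(seed=42)
        a = build_network(small_spec(), tc)
        b = build_network(small_spec(), tc)
        for sa, sb in zip(a.trainable_stages, b.trainable_stages):
            np.testing.assert_array_equal(sa.pair.W, sb.pair.W)
            np.testing.assert_array_equal(sa.pair.R, sb.pair.R)

    def test_glorot_bounds(self):
        net = build_network(small_spec("Full 50; Output", shape=(100,), C=10),
                            TrainingConfig(seed=0))
        W = net.trainable_stages[0].pair.W
        b = np.sqrt(6.0 / (100 + 50))
        assert np.abs(W).max() <= b
        assert np.abs(W).max() > 0.8 * b  # actually fills the range

    def test_sparsity_fraction(self):
        spec = small_spec("Full 80; Output", shape=(60,), C=3, sparsity=0.5)
        net = build_network(spec, TrainingConfig(seed=1))
        frac = (net.trainable_stages[0].pair.W == 0).mean()
        assert frac == pytest.approx(0.5, abs=0.05)

    def test_masks_asymmetric(self):
        spec = small_spec("Full 80; Output", shape=(60,), C=3,
                          sparsity=0.5, mode="urfb")
        net = build_network(spec, TrainingConfig(seed=1))
        pair = net.trainable_stages[0].pair
        assert not np.array_equal(pair.mask_W, pair.mask_R.T)

    def test_mirrored_alignment_one(self):
        from hebbnet.diagnostics import network_alignment

        spec = small_spec(mode="urfb", init="mirrored")
        net = build_network(spec, TrainingConfig(seed=0))
        assert all(a == pytest.approx(1.0) for a in network_alignment(net))

    def test_w0_shared_across_modes(self):
        nets = {}
        for mode in ("bp", "urfb", "frfb"):
            rngs = component_rngs(9)
            nets[mode] = build_network(
                small_spec(mode=mode), TrainingConfig(seed=9), rng=rngs["init"]
            )
        w_bp = nets["bp"].trainable_stages[0].pair.W
        for mode in ("urfb", "frfb"):
            np.testing.assert_array_equal(
                nets[mode].trainable_stages[0].pair.W, w_bp
            )
        np.testing.assert_array_equal(
            nets["urfb"].trainable_stages[0].pair.R,
            nets["frfb"].trainable_stages[0].pair.R,
        )


class TestForwardPass:
    def test_zero_weights_zero_scores(self):
        net = build_network(small_spec(), TrainingConfig(seed=0))
        for s in net.trainable_stages:
            s.pair.W[:] = 0.0
        trace = forward_pass(net, np.random.default_rng(0).normal(0, 1, (3, 8)))
        np.testing.assert_array_equal(trace.scores, np.zeros((3, 3)))

    def test_single_identity_layer(self):
        spec = small_spec("Output", shape=(3,), C=3)
        net = build_network(spec, TrainingConfig(seed=0))
        net.trainable_stages[0].pair.W = np.eye(3)
        x = np.array([[0.2, -0.4, 0.1]])
        trace = forward_pass(net, x)
        np.testing.assert_allclose(trace.scores, x)

    def test_hidden_activities_bounded(self, rng):
        net = build_network(small_spec(), TrainingConfig(seed=0))
        trace = forward_pass(net, rng.normal(0, 10, (5, 8)))
        for out, stage in zip(trace.outputs[:-1], net.stages[:-1]):
            assert np.all(np.abs(out) <= 1.0)

    def test_output_layer_unbounded(self, rng):
        spec = small_spec("Output", shape=(3,), C=3)
        net = build_network(spec, TrainingConfig(seed=0))
        net.trainable_stages[0].pair.W = 10 * np.eye(3)
        trace = forward_pass(net, np.ones((1, 3)))
        assert np.abs(trace.scores).max() > 1.0

    def test_dropout_only_in_training(self, toy_small):
        X, _ = toy_small
        spec = parse_architecture(
            "Conv 4 3x3; Drop .8; Full 8; Output", X.shape[1:], 3
        )
        net = build_network(spec, TrainingConfig(seed=0))
        t_eval = forward_pass(net, X[:4], training=False)
        assert t_eval.caches[1]["drop_mask"] is None
        t_train = forward_pass(
            net, X[:4], training=True, rng=np.random.default_rng(0)
        )
        assert t_train.caches[1]["drop_mask"] is not None


class TestFeedbackPass:
    def test_satisfied_loss_gives_zero_deltas(self):
        spec = small_spec("Output", shape=(3,), C=3)
        net = build_network(spec, TrainingConfig(seed=0))
        net.trainable_stages[0].pair.W = 2 * np.eye(3)
        x = np.array([[1.0, -1.0, -1.0]])  # scores (2,-2,-2): all margins met
        trace = forward_pass(net, x)
        fb = feedback_pass(net, trace, np.array([0]))
        np.testing.assert_array_equal(fb.deltas[0], np.zeros((1, 3)))

    def test_single_layer_delta_is_top_error(self):
        from hebbnet.activations import hinge_top_error

        spec = small_spec("Output", shape=(4,), C=3)
        net = build_network(spec, TrainingConfig(seed=0))
        x = np.random.default_rng(1).normal(0, 1, (1, 4))
        trace = forward_pass(net, x)
        fb = feedback_pass(net, trace, np.array([1]))
        np.testing.assert_array_equal(
            fb.deltas[0][0], hinge_top_error(trace.scores[0], 1, net.hinge)
        )

    def test_saturated_hidden_blocks(self):
        net = build_network(small_spec(), TrainingConfig(seed=0))
        # force huge first-layer weights: all hidden units saturate
        net.trainable_stages[0].pair.W[:] = 100.0
        trace = forward_pass(net, np.ones((1, 8)))
        fb = feedback_pass(net, trace, np.array([0]))
        np.testing.assert_array_equal(fb.deltas[0], np.zeros((1, 6)))


class TestApplyUpdates:
    def test_zero_delta_no_change(self):
        spec = small_spec("Output", shape=(3,), C=3)
        net = build_network(spec, TrainingConfig(seed=0))
        net.trainable_stages[0].pair.W = 2 * np.eye(3)
        before = net.trainable_stages[0].pair.W.copy()
        x = np.array([[1.0, -1.0, -1.0]])
        tc = TrainingConfig(seed=0)
        trace = forward_pass(net, x)
        fb = feedback_pass(net, trace, np.array([0]))
        apply_updates(net, trace, fb, tc)
        np.testing.assert_array_equal(net.trainable_stages[0].pair.W, before)

    def test_frfb_keeps_r_fixed(self, rng):
        spec = small_spec(mode="frfb")
        tc = TrainingConfig(seed=0, eta=0.1)
        net = build_network(spec, tc)
        r_before = [s.pair.R.copy() for s in net.trainable_stages]
        w_before = [s.pair.W.copy() for s in net.trainable_stages]
        train_step(net, rng.normal(0, 0.5, (4, 8)), np.array([0, 1, 2, 0]),
                   tc, np.random.default_rng(0))
        for s, r0, w0 in zip(net.trainable_stages, r_before, w_before):
            np.testing.assert_array_equal(s.pair.R, r0)
            assert not np.array_equal(s.pair.W, w0)

    def test_urfb_updates_r_with_w_increment(self, rng):
        spec = small_spec(mode="urfb")
        tc = TrainingConfig(seed=0, eta=0.1)
        net = build_network(spec, tc)
        w0 = [s.pair.W.copy() for s in net.trainable_stages]
        r0 = [s.pair.R.copy() for s in net.trainable_stages]
        train_step(net, rng.normal(0, 0.5, (4, 8)), np.array([0, 1, 2, 0]),
                   tc, np.random.default_rng(0))
        for s, w, r in zip(net.trainable_stages, w0, r0):
            np.testing.assert_allclose(s.pair.R - r, (s.pair.W - w).T, atol=1e-15)

    def test_urfb_frfb_share_first_w_increment(self, rng):
        # identical seeds: same W(0), R(0); first W step identical, runs
        # diverge only through R
        batches = rng.normal(0, 0.5, (4, 8)), np.array([0, 1, 2, 0])
        outs = {}
        for mode in ("urfb", "frfb"):
            rngs = component_rngs(5)
            tc = TrainingConfig(seed=5, eta=0.1)
            net = build_network(small_spec(mode=mode), tc, rng=rngs["init"])
            train_step(net, batches[0], batches[1], tc, rngs["dropout"])
            outs[mode] = [s.pair.W.copy() for s in net.trainable_stages]
        for wa, wb in zip(outs["urfb"], outs["frfb"]):
            np.testing.assert_array_equal(wa, wb)

    def test_mask_invariance_through_training(self):
        spec = small_spec(mode="urfb", sparsity=0.4)
        tc = TrainingConfig(seed=3, eta=0.1, batch_size=16, epochs=2)
        net = build_network(spec, tc)
        x, y = linearly_separable_dataset(8, 3, margin=2.0, n=64, seed=0)
        train(net, (x, y), (x, y), tc, record_alignment=False)
        for s in net.trainable_stages:
            assert np.all(s.pair.W[s.pair.mask_W == 0] == 0.0)
            assert np.all(s.pair.R[s.pair.mask_R == 0] == 0.0)


class TestBPGradientOracle:
    def test_one_step_matches_finite_differences(self):
        rng = np.random.default_rng(7)
        spec = small_spec(mode="bp")
        tc = TrainingConfig(seed=7, eta=0.1)
        net = build_network(spec, tc)
        X = rng.normal(0, 0.3, (4, 8))
        y = np.array([0, 1, 2, 1])
        hp = HingeParams()

        def loss_of(n):
            return batch_loss(forward_pass(n, X).scores, y, "hinge", hp)

        net2 = copy.deepcopy(net)
        trace = forward_pass(net2, X, training=True, rng=np.random.default_rng(0))
        fb = feedback_pass(net2, trace, y)
        apply_updates(net2, trace, fb, tc)
        eps = 1e-6
        for si, stage in enumerate(net.stages):
            W = stage.pair.W
            flat_idx = np.random.default_rng(si).choice(W.size, 6, replace=False)
            for fi in flat_idx:
                i, j = np.unravel_index(fi, W.shape)
                plus = copy.deepcopy(net)
                plus.stages[si].pair.W[i, j] += eps
                minus = copy.deepcopy(net)
                minus.stages[si].pair.W[i, j] -= eps
                grad = (loss_of(plus) - loss_of(minus)) / (2 * eps)
                change = net2.stages[si].pair.W[i, j] - W[i, j]
                assert change == pytest.approx(-tc.eta * grad, abs=1e-7)


class TestMirrorPersistence:
    def test_urfb_mirrored_equals_bp_bitwise(self, toy_small):
        X, y = toy_small
        arch = "Conv 4 3x3; Maxpool 3; Drop .5; Full 16; Output"
        tc = TrainingConfig(eta=0.1, batch_size=30, epochs=1, seed=3)
        results = {}
        for mode, init in (("bp", "independent"), ("urfb", "mirrored")):
            spec = parse_architecture(X.shape[1:] and arch, X.shape[1:], 3,
                                      mode=mode, init=init)
            rngs = component_rngs(3)
            net = build_network(spec, tc, rng=rngs["init"])
            for step in range(100):
                lo = (step * 30) % 150
                train_step(net, X[lo : lo + 30], y[lo : lo + 30], tc,
                           rngs["dropout"])
            results[mode] = net
        for sa, sb in zip(results["bp"].trainable_stages,
                          results["urfb"].trainable_stages):
            if isinstance(sa, DenseStage):
                np.testing.assert_array_equal(sa.pair.W, sb.pair.W)
                np.testing.assert_array_equal(
                    sb.pair.R, np.ascontiguousarray(sb.pair.W.T)
                )
            elif isinstance(sa, ConvStage):
                np.testing.assert_array_equal(sa.F, sb.F)
                np.testing.assert_array_equal(sb.G, sb.F)


class TestEvaluateAndTrain:
    def test_perfect_scores(self):
        spec = small_spec("Output", shape=(3,), C=3)
        net = build_network(spec, TrainingConfig(seed=0))
        net.trainable_stages[0].pair.W = np.eye(3)
        x = np.eye(3)
        assert evaluate(net, x, np.array([0, 1, 2])) == 0.0

    def test_constant_scores_tie_break(self):
        spec = small_spec("Output", shape=(4,), C=4)
        net = build_network(spec, TrainingConfig(seed=0))
        net.trainable_stages[0].pair.W[:] = 0.0
        x = np.zeros((8, 4))
        y = np.array([0, 1, 2, 3] * 2)
        # argmax of all-zero scores -> class 0; balanced 4-class set
        assert evaluate(net, x, y) == 0.75

    def test_empty_dataset(self):
        net = build_network(small_spec(), TrainingConfig(seed=0))
        with pytest.raises(ValueError):
            evaluate(net, np.zeros((0, 8)), np.zeros(0, dtype=int))

    def test_zero_epochs(self):
        tc = TrainingConfig(seed=0, epochs=0)
        net = build_network(small_spec(), tc)
        w0 = net.trainable_stages[0].pair.W.copy()
        x, y = linearly_separable_dataset(8, 3, margin=2.0, n=30, seed=0)
        hist = train(net, (x, y), (x, y), tc)
        assert hist == []
        np.testing.assert_array_equal(net.trainable_stages[0].pair.W, w0)

    def test_seeded_rerun_identical(self):
        x, y = linearly_separable_dataset(8, 3, margin=2.0, n=60, seed=1)
        hists = []
        for _ in range(2):
            tc = TrainingConfig(seed=4, eta=0.1, batch_size=20, epochs=3)
            net = build_network(small_spec(), tc)
            hists.append(train(net, (x, y), (x, y), tc))
        for ra, rb in zip(*hists):
            assert ra.train_error == rb.train_error
            assert ra.val_error == rb.val_error
            assert ra.train_loss == rb.train_loss
            assert ra.alignment == rb.alignment

    def test_separable_data_learned(self):
        x, y = linearly_separable_dataset(8, 3, margin=3.0, n=120, seed=2,
                                          spread=0.05)
        tc = TrainingConfig(seed=0, eta=0.1, batch_size=40, epochs=15)
        net = build_network(small_spec("Full 16; Output", shape=(8,), C=3), tc)
        hist = train(net, (x, y), (x, y), tc, record_alignment=False)
        assert hist[-1].train_error == 0.0

    def test_update_locality_batch_linearity(self, rng):
        # the batch increment is the mean of per-example increments
        spec = small_spec()
        tc = TrainingConfig(seed=0, eta=0.1)
        X = rng.normal(0, 0.5, (3, 8))
        y = np.array([0, 1, 2])
        net = build_network(spec, tc)
        trace = forward_pass(net, X)
        fb = feedback_pass(net, trace, y)
        full = net.stages[0]
        dW_full = fb.deltas[0].T @ trace.x0 / 3
        per = []
        for i in range(3):
            ti = forward_pass(net, X[i : i + 1])
            fi = feedback_pass(net, ti, y[i : i + 1])
            per.append(fi.deltas[0].T @ ti.x0)
        np.testing.assert_allclose(dW_full, np.mean(per, axis=0), atol=1e-12)


class TestResidualNetwork:
    def test_sum_network_trains(self, toy_small):
        X, y = toy_small
        spec = parse_architecture(
            "Conv 4 3x3; Conv 4 3x3; SUM; Maxpool 3; Output",
            X.shape[1:], 3, mode="urfb",
        )
        tc = TrainingConfig(seed=0, eta=0.05, batch_size=30, epochs=2)
        net = build_network(spec, tc)
        hist = train(net, (X, y), (X, y), tc, record_alignment=False)
        assert len(hist) == 2
        assert np.isfinite(hist[-1].train_loss)

    def test_sum_feedback_reaches_skip_branch(self, toy_small):
        X, y = toy_small
        spec = parse_architecture(
            "Conv 4 3x3; Conv 4 3x3; SUM; Output", X.shape[1:], 3, mode="bp"
        )
        net = build_network(spec, TrainingConfig(seed=0))
        trace = forward_pass(net, X[:4])
        fb = feedback_pass(net, trace, y[:4])
        # both conv stages must receive error
        assert 0 in fb.deltas and 1 in fb.deltas
        assert np.abs(fb.deltas[0]).sum() > 0
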