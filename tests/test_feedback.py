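"""Modulatory signals, update rules and their structural guarantees."""

import numpy as np
import pytest

from targetproj import (
    Dense,
    SGD,
    apply_updates,
    error_sign,
    forward,
    init_network,
    loss,
    make_feedback,
    modulatory_signals,
    output_delta,
    target_onehot,
)
from targetproj.feedback import drtp_hidden_delta
from targetproj.network import Conv2D


def _signals(net, algo, x, labels, loss_kind="bce", seed=11):
    """Forward + output delta + modulatory signals in one go."""
    C = net.output_dim
    y_star = target_onehot(labels, C)
    ens = make_feedback(algo, net, seed=seed)
    tr = forward(net, x)
    dz_K = output_delta(loss_kind, tr.ys[-1], y_star, tr.zs[-1], net.layers[-1].activation)
    return tr, y_star, ens, modulatory_signals(net, ens, tr, y_star, dz_K)


class TestTargetsAndSigns:
    def test_onehot_examples(self):
        assert np.array_equal(target_onehot(2, 4), [0, 0, 1, 0])
        assert np.array_equal(target_onehot(0, 1), [1.0])
        with pytest.raises(ValueError):
            target_onehot(4, 4)

    def test_target_is_shifted_error_sign(self, rng):
        # y* = (1 + sign(e))/2 for any valid sigmoid output
        for _ in range(20):
            C = int(rng.integers(2, 8))
            label = int(rng.integers(C))
            y_out = rng.uniform(0.01, 0.99, size=(1, C))
            s = error_sign(y_out, label)
            assert np.array_equal((1 + s) / 2, target_onehot(label, C))

    def test_error_sign_examples(self):
        assert np.array_equal(error_sign(np.array([0.6, 0.3, 0.8]), 2), [-1, -1, 1])
        assert np.array_equal(error_sign(np.array([0.9, 0.9]), 0), [1, -1])

    def test_error_sign_independent_of_magnitudes(self, rng):
        label = 3
        ref = error_sign(rng.uniform(0.01, 0.99, size=(1, 6)), label)
        for _ in range(10):
            assert np.array_equal(error_sign(rng.uniform(0.01, 0.99, size=(1, 6)), label), ref)

    def test_error_sign_rejects_saturated_outputs(self):
        with pytest.raises(ValueError):
            error_sign(np.array([1.0, 0.2]), 0)


class TestOutputDelta:
    def test_zero_at_perfect_prediction(self):
        y = np.array([[0.2, 0.8]])
        assert np.all(output_delta("bce", y, y) == 0.0)

    def test_bce_uniform_half_ten_classes(self):
        y_star = target_onehot(0, 10)[None]
        y = np.full((1, 10), 0.5)
        dz = output_delta("bce", y, y_star)
        expected = np.full(10, -0.05)
        expected[0] = 0.05
        assert np.allclose(dz[0], expected)

    @pytest.mark.parametrize("loss_kind,act", [("bce", "sigmoid"), ("cce", "softmax"), ("mse", "tanh")])
    def test_matches_negative_loss_gradient(self, loss_kind, act, rng):
        # central finite differences of J w.r.t. z_K
        from targetproj.activations import activation

        C = 5
        z = rng.normal(size=(1, C))
        y_star = target_onehot(1, C)[None] if loss_kind != "mse" else rng.uniform(-0.9, 0.9, (1, C))
        dz = output_delta(loss_kind, activation(act, z), y_star, z, act)
        eps = 1e-6
        for c in range(C):
            zp, zm = z.copy(), z.copy()
            zp[0, c] += eps
            zm[0, c] -= eps
            g = (loss(loss_kind, activation(act, zp), y_star)
                 - loss(loss_kind, activation(act, zm), y_star)) / (2 * eps)
            assert dz[0, c] == pytest.approx(-g, rel=1e-5, abs=1e-10)

    def test_invalid_pairing_rejected(self):
        with pytest.raises(ValueError, match="pairs with"):
            output_delta("bce", np.array([[0.5]]), np.array([[1.0]]), act="softmax")


class TestBPOracle:
    """BP's modulatory signals are the true loss gradients (small-net FD oracle)."""

    @pytest.mark.parametrize(
        "loss_kind,hidden_act,out_act",
        [("bce", "tanh", "sigmoid"), ("cce", "tanh", "softmax"), ("mse", "tanh", "tanh")],
    )
    def test_hidden_signals_match_finite_differences(self, loss_kind, hidden_act, out_act, rng):
        from targetproj.activations import activation

        net = init_network([4, Dense(3, hidden_act), Dense(2, out_act)], seed=8)
        x = rng.normal(size=(1, 4))
        if loss_kind == "mse":
            y_star = rng.uniform(-0.9, 0.9, size=(1, 2))
        else:
            y_star = target_onehot(1, 2)[None]
        tr = forward(net, x)
        dz_K = output_delta(loss_kind, tr.ys[-1], y_star, tr.zs[-1], out_act)
        bp = make_feedback("bp", net)
        sig = modulatory_signals(net, bp, tr, y_star, dz_K)

        def loss_from_z1(z1):
            y1 = activation(hidden_act, z1)
            z2 = y1 @ net.layers[1].W.T + net.layers[1].b
            return loss(loss_kind, activation(out_act, z2), y_star)

        z1 = tr.zs[1]
        eps = 1e-6
        fd = np.zeros(3)
        for i in range(3):
            d = np.zeros_like(z1)
            d[0, i] = eps
            fd[i] = (loss_from_z1(z1 + d) - loss_from_z1(z1 - d)) / (2 * eps)
        scale = np.max(np.abs(fd))
        assert np.max(np.abs(sig.dzs[1].ravel() + fd)) / scale < 1e-5

    def test_one_bp_step_is_a_textbook_gradient_step(self, rng):
        # 2-2-1 net: compare the applied update to -lr * dJ/dW by FD
        net = init_network([2, Dense(2, "tanh"), Dense(1, "sigmoid")], seed=2)
        x = rng.normal(size=(1, 2))
        y_star = np.array([[1.0]])
        lr = 0.1

        def total_loss(net_):
            tr = forward(net_, x)
            return loss("bce", tr.ys[-1], y_star)

        grads = []
        eps = 1e-6
        for li, layer in enumerate(net.layers):
            g = np.zeros_like(layer.W)
            for idx in np.ndindex(layer.W.shape):
                saved = layer.W[idx]
                layer.W[idx] = saved + eps
                up = total_loss(net)
                layer.W[idx] = saved - eps
                down = total_loss(net)
                layer.W[idx] = saved
                g[idx] = (up - down) / (2 * eps)
            grads.append(g)

        before = [l.W.copy() for l in net.layers]
        tr = forward(net, x)
        dz_K = output_delta("bce", tr.ys[-1], y_star, tr.zs[-1], "sigmoid")
        sig = modulatory_signals(net, make_feedback("bp", net), tr, y_star, dz_K)
        apply_updates(net, sig, tr, SGD(lr))
        for layer, W0, g in zip(net.layers, before, grads):
            assert np.allclose(layer.W - W0, -lr * g, rtol=1e-5, atol=1e-10)


class TestStructuralGuarantees:
    def test_drtp_delta_is_row_selection(self, tiny_net):
        ens = make_feedback("drtp", tiny_net, seed=5)
        y_star = target_onehot(np.array([0, 1, 1]), 2)
        dy = drtp_hidden_delta(ens, y_star, 1)
        # row lookup of B_1 ...
        assert np.array_equal(dy, ens.Bs[1][[0, 1, 1]])
        # ... identical to the explicit projection B_1^T y*
        assert np.allclose(dy, y_star @ ens.Bs[1])

    def test_drtp_identity_feedback_selects_basis_vector(self):
        # with B_k the identity (C = N_k), the hidden delta for label c* is
        # the c*-th standard basis vector
        net = init_network([3, Dense(2, "tanh"), Dense(2, "sigmoid")], seed=0)
        ens = make_feedback("drtp", net, seed=0)
        ens.Bs[1] = np.eye(2)
        dy = drtp_hidden_delta(ens, target_onehot(1, 2)[None], 1)
        assert np.array_equal(dy[0], [0.0, 1.0])

    def test_drtp_update_locking_free(self, tiny_net, rng):
        # dy_k is computable from (B_k, y*) alone, before any forward pass,
        # and matches bitwise what the full signal computation produces
        labels = np.array([1, 0, 1, 1])
        x = rng.normal(size=(4, 4))
        y_star = target_onehot(labels, 2)
        ens = make_feedback("drtp", tiny_net, seed=3)
        dy_early = drtp_hidden_delta(ens, y_star, 1)  # no forward pass yet
        tr = forward(tiny_net, x)
        dz_K = output_delta("bce", tr.ys[-1], y_star, tr.zs[-1], "sigmoid")
        sig = modulatory_signals(tiny_net, ens, tr, y_star, dz_K)
        assert np.array_equal(dy_early, sig.dys[1])

    @pytest.mark.parametrize("algo", ["fa", "dfa", "sdfa", "drtp"])
    def test_no_weight_transport(self, algo, rng):
        # hidden signals never read deeper forward weights: corrupting W_2
        # after the trace was captured must not change dz_1
        net = init_network([5, Dense(4, "tanh"), Dense(3, "sigmoid")], seed=1)
        x = rng.normal(size=(2, 5))
        tr, y_star, ens, sig = _signals(net, algo, x, np.array([0, 2]))
        net.layers[1].W = rng.normal(size=net.layers[1].W.shape)  # corrupt
        dz_K = output_delta("bce", tr.ys[-1], y_star, tr.zs[-1], "sigmoid")
        sig2 = modulatory_signals(net, ens, tr, y_star, dz_K)
        assert np.array_equal(sig.dzs[1], sig2.dzs[1])

    def test_bp_does_read_deeper_weights(self, rng):
        net = init_network([5, Dense(4, "tanh"), Dense(3, "sigmoid")], seed=1)
        x = rng.normal(size=(2, 5))
        tr, y_star, ens, sig = _signals(net, "bp", x, np.array([0, 2]))
        net.layers[1].W = net.layers[1].W + 1.0
        dz_K = output_delta("bce", tr.ys[-1], y_star, tr.zs[-1], "sigmoid")
        sig2 = modulatory_signals(net, ens, tr, y_star, dz_K)
        assert not np.allclose(sig.dzs[1], sig2.dzs[1])

    def test_sdfa_drtp_shift_identity(self, rng):
        # dy(sdfa) = 2 dy(drtp) - B^T 1, from sign(e) = 2 y* - 1
        net = init_network([6, Dense(5, "tanh"), Dense(3, "sigmoid")], seed=7)
        x = rng.normal(size=(4, 6))
        labels = rng.integers(0, 3, size=4)
        _, y_star, ens_s, sig_s = _signals(net, "sdfa", x, labels, seed=21)
        _, _, ens_d, sig_d = _signals(net, "drtp", x, labels, seed=21)
        assert np.array_equal(ens_s.Bs[1], ens_d.Bs[1])  # same seed, same B
        expected = 2.0 * sig_d.dys[1] - ens_d.Bs[1].sum(axis=0)
        assert np.allclose(sig_s.dys[1], expected, atol=1e-12)

    def test_sdfa_equals_shifted_drtp_when_single_output(self, rng):
        # C = 1: dy(drtp) = B^T (1 + sign(e))/2
        net = init_network([4, Dense(3, "tanh"), Dense(1, "sigmoid")], seed=7)
        x = rng.normal(size=(2, 4))
        labels = np.zeros(2, dtype=int)
        tr, y_star, ens_s, sig_s = _signals(net, "sdfa", x, labels, seed=4)
        _, _, _, sig_d = _signals(net, "drtp", x, labels, seed=4)
        e = y_star - tr.ys[-1]
        assert np.allclose(
            sig_d.dys[1], np.sign(e) @ ens_s.Bs[1] * 0 + ((1 + np.sign(e)) / 2) @ ens_s.Bs[1]
        )
        assert np.allclose(sig_s.dys[1], np.sign(e) @ ens_s.Bs[1])

    def test_shallow_freezes_hidden_layers(self, tiny_net, tiny_batch):
        W1_before = tiny_net.layers[0].W.copy()
        tr, y_star, ens, sig = _signals(tiny_net, "shallow", tiny_batch, np.zeros(6, dtype=int))
        assert sig.dzs[1] is None
        apply_updates(tiny_net, sig, tr, SGD(0.5))
        assert np.array_equal(tiny_net.layers[0].W, W1_before)
        assert not np.array_equal(tiny_net.layers[1].W, tiny_net.layers[1].W * 0)


class TestApplyUpdates:
    def test_zero_learning_rate_is_a_no_op(self, tiny_net, tiny_batch):
        before = [l.W.copy() for l in tiny_net.layers]
        tr, y_star, ens, sig = _signals(tiny_net, "dfa", tiny_batch, np.ones(6, dtype=int))
        apply_updates(tiny_net, sig, tr, SGD(0.0))
        for layer, W0 in zip(tiny_net.layers, before):
            assert np.array_equal(layer.W, W0)

    def test_drtp_first_step_from_zero_is_rank_one(self, rng):
        # zero-init linear hidden layer, single example: W_1 after one step
        # is proportional to (B_1^T y*) x^T
        net = init_network([5, Dense(4, "linear"), Dense(3, "sigmoid")], scheme="zeros")
        x = rng.normal(size=(1, 5))
        tr, y_star, ens, sig = _signals(net, "drtp", x, np.array([2]))
        apply_updates(net, sig, tr, SGD(1e-2))
        W1 = net.layers[0].W
        assert np.linalg.matrix_rank(W1) == 1
        expected = np.outer((y_star @ ens.Bs[1]).ravel(), x.ravel())
        scale = W1[np.unravel_index(np.argmax(np.abs(W1)), W1.shape)] / expected[
            np.unravel_index(np.argmax(np.abs(W1)), W1.shape)
        ]
        assert scale > 0  # positive multiple under the ascent convention
        assert np.allclose(W1, scale * expected, rtol=1e-10)


class TestConvProjection:
    def _conv_net(self, pool=2):
        return init_network(
            [(1, 4, 4), Conv2D(2, 3, pad=1, pool=pool), Dense(3, "sigmoid")], seed=9
        )

    def test_direct_projection_shapes_through_pooling(self, rng):
        net = self._conv_net()
        x = rng.normal(size=(2, 1, 4, 4))
        tr, y_star, ens, sig = _signals(net, "dfa", x, np.array([0, 1]))
        # B_1 projects C=3 onto the flattened pooled map 2*2*2 = 8
        assert ens.Bs[1].shape == (3, 8)
        assert sig.dzs[1].shape == tr.zs[1].shape

    def test_pool_routing_hits_only_argmax_positions(self, rng):
        net = self._conv_net()
        x = rng.normal(size=(1, 1, 4, 4))
        tr, y_star, ens, sig = _signals(net, "drtp", x, np.array([1]))
        dz = sig.dzs[1][0]
        # each 2x2 window contains at most one nonzero delta
        for c in range(2):
            for wy in range(2):
                for wx in range(2):
                    window = dz[c, 2 * wy : 2 * wy + 2, 2 * wx : 2 * wx + 2]
                    assert np.count_nonzero(window) <= 1

    def test_random_kernel_mode_never_updates_conv_weights(self, rng):
        net = self._conv_net()
        W_conv = net.layers[0].W.copy()
        x = rng.normal(size=(2, 1, 4, 4))
        tr, y_star, ens, sig = _signals(net, "dfa", x, np.array([0, 2]))
        apply_updates(net, sig, tr, SGD(0.1), trainable_mask=[False, True])
        assert np.array_equal(net.layers[0].W, W_conv)
        assert not np.array_equal(net.layers[1].W, init_network(
            [(1, 4, 4), Conv2D(2, 3, pad=1, pool=2), Dense(3, "sigmoid")], seed=9
        ).layers[1].W)

    def test_one_by_one_feature_map_reduces_to_dense_rule(self, rng):
        # conv producing a 1x1 map == fully-connected layer on the flat input
        conv_net = init_network(
            [(1, 3, 3), Conv2D(4, 3, pad=0, pool=None), Dense(2, "sigmoid")], seed=13
        )
        dense_net = init_network([9, Dense(4, "tanh"), Dense(2, "sigmoid")], seed=13)
        dense_net.layers[0].W = conv_net.layers[0].W.reshape(4, 9).copy()
        dense_net.layers[1].W = conv_net.layers[1].W.copy()
        x = rng.normal(size=(3, 1, 3, 3))
        labels = np.array([0, 1, 0])
        tr_c, ys, ens_c, sig_c = _signals(conv_net, "dfa", x, labels, seed=17)
        tr_d, _, ens_d, sig_d = _signals(dense_net, "dfa", x.reshape(3, 9), labels, seed=17)
        assert np.allclose(tr_c.ys[-1], tr_d.ys[-1])
        assert np.allclose(sig_c.dzs[1].reshape(3, 4), sig_d.dzs[1])
        apply_updates(conv_net, sig_c, tr_c, SGD(0.05))
        apply_updates(dense_net, sig_d, tr_d, SGD(0.05))
        assert np.allclose(conv_net.layers[0].W.reshape(4, 9), dense_net.layers[0].W)

    def test_bp_through_conv_matches_finite_differences(self, rng):
        # end-to-end conv BP gradient check on a tiny net (<= 50 params in
        # the checked kernel)
        net = init_network(
            [(1, 4, 4), Conv2D(2, 3, pad=0, pool=None), Dense(2, "sigmoid")], seed=4
        )
        x = rng.normal(size=(1, 1, 4, 4))
        y_star = target_onehot(1, 2)[None]

        def total_loss():
            tr = forward(net, x)
            return loss("bce", tr.ys[-1], y_star)

        layer = net.layers[0]
        g = np.zeros_like(layer.W)
        eps = 1e-6
        for idx in np.ndindex(layer.W.shape):
            saved = layer.W[idx]
            layer.W[idx] = saved + eps
            up = total_loss()
            layer.W[idx] = saved - eps
            down = total_loss()
            layer.W[idx] = saved
            g[idx] = (up - down) / (2 * eps)

        tr = forward(net, x)
        dz_K = output_delta("bce", tr.ys[-1], y_star, tr.zs[-1], "sigmoid")
        sig = modulatory_signals(net, make_feedback("bp", net), tr, y_star, dz_K)
        from targetproj.feedback import _raw_update

        dW, _ = _raw_update(layer, sig.dzs[1], tr.ys[0])
        assert np.allclose(dW, -g, rtol=1e-5, atol=1e-9)
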