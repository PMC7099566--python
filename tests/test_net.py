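"""Layer-by-layer and end-to-end checks of the from-scratch CNN.

Every backward pass is validated against central-difference numerical
gradients; forward passes against brute-force oracles.
"""

import numpy as np
import pytest

from dotcad import net
from oracles import (
    batchnorm_twopass,
    conv2d_loops,
    max_relative_error,
    numerical_gradient,
    softmax_exp_normalize,
)


class TestConvForward:
    def test_valid_size_arithmetic(self, rng):
        x = rng.random((3, 1, 32, 32))
        k = rng.random((6, 1, 5, 5))
        assert net.conv2d_forward(x, k, np.zeros(6)).shape == (3, 6, 28, 28)

    def test_zero_kernels_yield_bias(self, rng):
        x = rng.random((2, 3, 8, 8))
        out = net.conv2d_forward(x, np.zeros((4, 3, 5, 5)), np.arange(4.0))
        for f in range(4):
            np.testing.assert_allclose(out[:, f], float(f))

    def test_matches_nested_loop_oracle(self, rng):
        x = rng.standard_normal((2, 3, 8, 8))
        k = rng.standard_normal((2, 3, 5, 5))
        b = rng.standard_normal(2)
        np.testing.assert_allclose(
            net.conv2d_forward(x, k, b), conv2d_loops(x, k, b), atol=1e-10
        )

    def test_channel_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            net.conv2d_forward(rng.random((1, 2, 8, 8)), rng.random((4, 3, 5, 5)), np.zeros(4))


class TestBatchNorm:
    def test_train_mode_standardizes(self, rng):
        x = rng.standard_normal((8, 3, 4, 4)) * 5 + 2
        out, _, _, _ = net.batchnorm_forward(
            x, np.ones(3), np.zeros(3), np.zeros(3), np.ones(3), mode="train"
        )
        np.testing.assert_allclose(out.mean(axis=(0, 2, 3)), 0, atol=1e-10)
        np.testing.assert_allclose(out.var(axis=(0, 2, 3)), 1, atol=1e-3)

    def test_affine_shifts_mean_and_variance(self, rng):
        x = rng.standard_normal((16, 2, 3, 3))
        out, _, _, _ = net.batchnorm_forward(
            x, np.full(2, 2.0), np.full(2, 3.0), np.zeros(2), np.ones(2), mode="train"
        )
        np.testing.assert_allclose(out.mean(axis=(0, 2, 3)), 3.0, atol=1e-10)
        np.testing.assert_allclose(out.var(axis=(0, 2, 3)), 4.0, atol=1e-2)

    def test_matches_two_pass_oracle(self, rng):
        x = rng.standard_normal((6, 4, 5, 5))
        gamma, beta = rng.random(4) + 0.5, rng.standard_normal(4)
        out, _, _, _ = net.batchnorm_forward(
            x, gamma, beta, np.zeros(4), np.ones(4), mode="train"
        )
        np.testing.assert_allclose(out, batchnorm_twopass(x, gamma, beta, net.BN_EPS), atol=1e-10)

    def test_batch_of_one_rejected_in_train(self, rng):
        with pytest.raises(ValueError):
            net.batchnorm_forward(
                rng.random((1, 2, 3, 3)), np.ones(2), np.zeros(2), np.zeros(2), np.ones(2), mode="train"
            )

    def test_infer_uses_running_stats(self, rng):
        x = rng.standard_normal((4, 2, 3, 3))
        rm, rv = np.array([1.0, -1.0]), np.array([4.0, 9.0])
        out, cache, new_rm, new_rv = net.batchnorm_forward(
            x, np.ones(2), np.zeros(2), rm, rv, mode="infer"
        )
        expected = (x - rm[None, :, None, None]) / np.sqrt(rv + net.BN_EPS)[None, :, None, None]
        np.testing.assert_allclose(out, expected)
        assert cache is None
        np.testing.assert_array_equal(new_rm, rm)

    def test_running_stats_ema_update(self, rng):
        x = rng.standard_normal((8, 2, 3, 3))
        rm0, rv0 = np.zeros(2), np.ones(2)
        _, _, rm, rv = net.batchnorm_forward(
            x, np.ones(2), np.zeros(2), rm0, rv0, mode="train"
        )
        np.testing.assert_allclose(rm, 0.1 * x.mean(axis=(0, 2, 3)), atol=1e-12)
        np.testing.assert_allclose(rv, 0.9 + 0.1 * x.var(axis=(0, 2, 3)), atol=1e-12)


class TestActivations:
    def test_sigmoid_values(self):
        assert net.sigmoid(np.array([0.0]))[0] == pytest.approx(0.5)
        x = np.array([1.7, -1.7])
        s = net.sigmoid(x)
        assert s[0] + s[1] == pytest.approx(1.0)

    def test_sigmoid_saturates_without_overflow(self):
        s = net.sigmoid(np.array([500.0, -500.0]))
        assert s[0] == pytest.approx(1.0)
        assert s[1] == pytest.approx(0.0)
        assert np.all(np.isfinite(s))

    def test_sigmoid_derivative_at_zero(self):
        s = net.sigmoid(np.array([0.0]))
        assert net.sigmoid_backward(np.array([1.0]), s)[0] == pytest.approx(0.25)

    def test_avgpool_mean_of_four(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]]).reshape(1, 1, 2, 2)
        assert net.avgpool_forward(x)[0, 0, 0, 0] == pytest.approx(2.5)

    def test_avgpool_constant_and_shape(self):
        x = np.full((2, 3, 28, 28), 1.3)
        out = net.avgpool_forward(x)
        assert out.shape == (2, 3, 14, 14)
        np.testing.assert_allclose(out, 1.3)

    def test_avgpool_odd_dims_rejected(self):
        with pytest.raises(ValueError):
            net.avgpool_forward(np.zeros((1, 1, 5, 4)))

    def test_avgpool_backward_spreads_quarter(self):
        d = np.ones((1, 1, 2, 2))
        np.testing.assert_allclose(net.avgpool_backward(d), 0.25)


class TestClassifier:
    def test_zero_weights_give_uniform(self, rng):
        probs, _ = net.fc_softmax_forward(rng.random((5, 300)), np.zeros((300, 2)), np.zeros(2))
        np.testing.assert_allclose(probs, 0.5)

    def test_softmax_shift_invariance(self, rng):
        f = rng.standard_normal((4, 300))
        w, b = rng.standard_normal((300, 2)), rng.standard_normal(2)
        p1, _ = net.fc_softmax_forward(f, w, b)
        p2, _ = net.fc_softmax_forward(f, w, b + 7.3)  # shift both logits
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_matches_exp_normalize_oracle(self, rng):
        f = rng.standard_normal((6, 300))
        w, b = rng.standard_normal((300, 2)) * 0.1, rng.standard_normal(2)
        probs, logits = net.fc_softmax_forward(f, w, b)
        np.testing.assert_allclose(probs, softmax_exp_normalize(logits), atol=1e-12)

    def test_cross_entropy_closed_forms(self):
        perfect = np.array([[1.0, 0.0]])
        loss, _ = net.cross_entropy_loss(perfect, np.array([[1.0, 0.0]]))
        assert loss == pytest.approx(0.0, abs=1e-10)
        uniform = np.array([[0.5, 0.5], [0.5, 0.5]])
        loss, _ = net.cross_entropy_loss(uniform, np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert loss == pytest.approx(np.log(2))


class TestInit:
    def test_seeded_determinism(self):
        a, b = net.init_params(3), net.init_params(3)
        for k, v in a.as_dict().items():
            np.testing.assert_array_equal(v, b.as_dict()[k])

    def test_identity_batchnorm_and_zero_bias(self):
        p = net.init_params(0)
        np.testing.assert_array_equal(p.bn1_gamma, 1.0)
        np.testing.assert_array_equal(p.bn2_beta, 0.0)
        np.testing.assert_array_equal(p.conv1_bias, 0.0)

    def test_fan_in_bounds(self):
        p = net.init_params(1)
        assert np.all(np.abs(p.conv1_kernels) <= np.sqrt(3 / 25))
        assert np.all(np.abs(p.conv2_kernels) <= np.sqrt(3 / 150))
        assert np.all(np.abs(p.fc_weights) <= np.sqrt(3 / 300))

    def test_shape_chain_enforced(self):
        p = net.init_params(0)
        bad = p.as_dict()
        bad["fc_weights"] = np.zeros((299, 2))
        with pytest.raises(ValueError):
            net.NetworkParams(**bad)


class TestNetworkForward:
    def test_shape_chain_32_to_2(self, rng):
        """32x32x1 -> 28x28x6 -> 14x14x6 -> 10x10x12 -> 5x5x12 -> 300 -> 2."""
        p = net.init_params(0)
        x = rng.random((4, 1, 32, 32))
        c1 = net.conv2d_forward(x, p.conv1_kernels, p.conv1_bias)
        assert c1.shape == (4, 6, 28, 28)
        p1 = net.avgpool_forward(c1)
        assert p1.shape == (4, 6, 14, 14)
        c2 = net.conv2d_forward(p1, p.conv2_kernels, p.conv2_bias)
        assert c2.shape == (4, 12, 10, 10)
        p2 = net.avgpool_forward(c2)
        assert p2.shape == (4, 12, 5, 5)
        assert p2.reshape(4, -1).shape == (4, 300)
        probs, _ = net.forward(p, x, mode="infer")
        assert probs.shape == (4, 2)

    def test_probabilities_normalized(self, rng):
        p = net.init_params(2)
        probs, _ = net.forward(p, rng.random((7, 1, 32, 32)), mode="infer")
        assert np.all(probs > 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_inference_batch_independence(self, rng):
        p = net.init_params(2)
        x = rng.random((5, 1, 32, 32))
        full, _ = net.forward(p, x, mode="infer")
        solo, _ = net.forward(p, x[2:3], mode="infer")
        np.testing.assert_allclose(full[2], solo[0], atol=1e-14)

    def test_wrong_input_shape_rejected(self, rng):
        with pytest.raises(ValueError):
            net.forward(net.init_params(0), rng.random((2, 1, 31, 32)))


class TestGradients:
    """Central-difference verification of every backward pass."""

    def test_conv_backward(self, rng):
        x = rng.standard_normal((2, 2, 8, 8))
        k = rng.standard_normal((3, 2, 5, 5)) * 0.5
        b = rng.standard_normal(3)
        up = rng.standard_normal((2, 3, 4, 4))
        d_x, d_k, d_b = net.conv2d_backward(x, k, up)
        assert max_relative_error(
            d_x, numerical_gradient(lambda: np.sum(net.conv2d_forward(x, k, b) * up), x)
        ) < 1e-6
        assert max_relative_error(
            d_k, numerical_gradient(lambda: np.sum(net.conv2d_forward(x, k, b) * up), k)
        ) < 1e-6
        assert max_relative_error(
            d_b, numerical_gradient(lambda: np.sum(net.conv2d_forward(x, k, b) * up), b)
        ) < 1e-6

    def test_batchnorm_backward(self, rng):
        x = rng.standard_normal((5, 3, 4, 4))
        gamma = rng.random(3) + 0.5
        beta = rng.standard_normal(3)
        up = rng.standard_normal(x.shape)

        def f():
            out, _, _, _ = net.batchnorm_forward(
                x, gamma, beta, np.zeros(3), np.ones(3), mode="train"
            )
            return np.sum(out * up)

        _, cache, _, _ = net.batchnorm_forward(x, gamma, beta, np.zeros(3), np.ones(3), mode="train")
        d_x, d_gamma, d_beta = net.batchnorm_backward(up, cache)
        assert max_relative_error(d_x, numerical_gradient(f, x)) < 1e-5
        assert max_relative_error(d_gamma, numerical_gradient(f, gamma)) < 1e-6
        assert max_relative_error(d_beta, numerical_gradient(f, beta)) < 1e-6

    def test_sigmoid_backward(self, rng):
        x = rng.standard_normal((3, 2, 4, 4))
        up = rng.standard_normal(x.shape)
        d_x = net.sigmoid_backward(up, net.sigmoid(x))
        assert max_relative_error(
            d_x, numerical_gradient(lambda: np.sum(net.sigmoid(x) * up), x)
        ) < 1e-6

    def test_avgpool_backward(self, rng):
        x = rng.standard_normal((2, 2, 6, 6))
        up = rng.standard_normal((2, 2, 3, 3))
        d_x = net.avgpool_backward(up)
        assert max_relative_error(
            d_x, numerical_gradient(lambda: np.sum(net.avgpool_forward(x) * up), x)
        ) < 1e-6

    def test_fc_and_loss_backward(self, rng):
        f = rng.standard_normal((4, 10))
        w = rng.standard_normal((10, 2)) * 0.3
        b = rng.standard_normal(2)
        y = np.zeros((4, 2))
        y[np.arange(4), rng.integers(0, 2, 4)] = 1.0

        def loss_of(features, weights, bias):
            ex = np.exp(features @ weights + bias)
            probs = ex / ex.sum(axis=1, keepdims=True)
            return float(-np.sum(y * np.log(probs)) / 4)

        probs, _ = net.fc_softmax_forward(f, w, b)
        _, d_logits = net.cross_entropy_loss(probs, y)
        d_f, d_w, d_b = net.fc_backward(f, w, d_logits)
        assert max_relative_error(d_f, numerical_gradient(lambda: loss_of(f, w, b), f)) < 1e-6
        assert max_relative_error(d_w, numerical_gradient(lambda: loss_of(f, w, b), w)) < 1e-6
        assert max_relative_error(d_b, numerical_gradient(lambda: loss_of(f, w, b), b)) < 1e-6

    def test_end_to_end_gradient_check(self, rng):
        """Full-network backprop vs numerical gradient on a 4-image batch."""
        params = net.init_params(5)
        x = rng.random((4, 1, 32, 32))
        y = np.zeros((4, 2))
        y[np.arange(4), [0, 1, 0, 1]] = 1.0
        _, grads = net.loss_and_grads(params, x, y)

        worst = 0.0
        for name in net.NetworkParams.LEARNABLE:
            arr = getattr(params, name)

            def f():
                probs, _ = net.forward(params, x, mode="train")
                loss, _ = net.cross_entropy_loss(probs, y)
                return loss

            num = numerical_gradient(f, arr)
            worst = max(worst, max_relative_error(grads[name], num))
        assert worst < 1e-4

    def test_backward_requires_cache(self, rng):
        with pytest.raises(ValueError):
            net.backward(net.init_params(0), None, np.zeros((2, 2)))
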