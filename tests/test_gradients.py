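"""Backpropagation correctness and the first-order update rules."""

import numpy as np
import pytest

from swarmlp import network as net
from swarmlp.gradients import GradientConfig, backprop_gradient, train_gradient


def finite_difference(top, theta, X, Y, h=1e-5):
    fd = np.empty_like(theta)
    for i in range(theta.size):
        tp = theta.copy(); tp[i] += h
        tm = theta.copy(); tm[i] -= h
        fd[i] = (net.mse(net.forward(top, tp, X), Y)
                 - net.mse(net.forward(top, tm, X), Y)) / (2 * h)
    return fd


class TestBackprop:
    def test_hand_computed_scalar_case(self):
        # single sigmoid unit at the origin, one sample x=0 target 1:
        # dMSE/dbias = 2*(0.5-1)*sigma'(0) = -0.25, dMSE/dweight = 0
        g = backprop_gradient(net.Topology(1, (), 1), np.zeros(2),
                              [[0.0]], [[1.0]])
        assert g == pytest.approx([0.0, -0.25])

    def test_zero_at_perfect_fit(self):
        top = net.Topology(2, (), 2)
        theta = np.array([5.0, -5.0, -5.0, 5.0, 0.0, 0.0])
        X = np.array([[10.0, -10.0]])
        Y = net.forward(top, theta, X)  # its own output: exact fit
        g = backprop_gradient(top, theta, X, Y)
        assert np.allclose(g, 0.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_central_differences(self, seed):
        rng = np.random.default_rng(seed)
        top = net.Topology(int(rng.integers(1, 5)),
                           tuple(rng.integers(1, 5, size=rng.integers(1, 4))),
                           int(rng.integers(1, 4)))
        theta = rng.normal(size=net.count_parameters(top))
        X = rng.normal(size=(4, top.n_inputs))
        Y = rng.uniform(size=(4, top.n_outputs))
        g = backprop_gradient(top, theta, X, Y)
        fd = finite_difference(top, theta, X, Y)
        assert np.max(np.abs(g - fd) / (1.0 + np.abs(g))) < 1e-6

    def test_shape_mismatch_rejected(self):
        top = net.Topology(2, (), 2)
        with pytest.raises(ValueError):
            backprop_gradient(top, np.zeros(6), np.zeros((3, 2)), np.zeros((3, 3)))


class TestUpdateRules:
    """Each rule reproduces its textbook recurrence on a hand-computed
    two-step scalar problem: minimise theta^2 type losses are overkill here,
    so we drive the steppers directly with fixed gradients."""

    def _two_steps(self, method, g1, g2, **kw):
        from swarmlp.gradients import _make_stepper
        cfg = GradientConfig(method=method, **kw)
        step = _make_stepper(cfg, 1)
        th = step(np.array([0.0]), np.array([g1]), 1)
        return step(th, np.array([g2]), 2)

    def test_plain_gradient(self):
        # theta = 0 - 0.1*1 - 0.1*(-2) = 0.1
        assert self._two_steps("grad", 1.0, -2.0, learning_rate=0.1)[0] == pytest.approx(0.1)

    def test_rmsprop(self):
        lr, rho, eps = 0.001, 0.9, 1e-8
        E1 = (1 - rho) * 1.0
        t1 = -lr * 1.0 / (np.sqrt(E1) + eps)
        E2 = rho * E1 + (1 - rho) * 4.0
        t2 = t1 - lr * (-2.0) / (np.sqrt(E2) + eps)
        assert self._two_steps("rmsprop", 1.0, -2.0)[0] == pytest.approx(t2)

    def test_adam(self):
        lr, b1, b2, eps = 0.001, 0.9, 0.999, 1e-8
        m1, v1 = (1 - b1) * 1.0, (1 - b2) * 1.0
        t1 = -lr * (m1 / (1 - b1)) / (np.sqrt(v1 / (1 - b2)) + eps)
        m2 = b1 * m1 + (1 - b1) * (-2.0)
        v2 = b2 * v1 + (1 - b2) * 4.0
        t2 = t1 - lr * (m2 / (1 - b1 ** 2)) / (np.sqrt(v2 / (1 - b2 ** 2)) + eps)
        assert self._two_steps("adam", 1.0, -2.0)[0] == pytest.approx(t2)

    def test_adadelta(self):
        rho, eps = 0.95, 1e-6
        Eg1 = (1 - rho) * 1.0
        u1 = -np.sqrt(0.0 + eps) / np.sqrt(Eg1 + eps) * 1.0
        Ed1 = (1 - rho) * u1 * u1
        Eg2 = rho * Eg1 + (1 - rho) * 4.0
        u2 = -np.sqrt(Ed1 + eps) / np.sqrt(Eg2 + eps) * (-2.0)
        assert self._two_steps("adadelta", 1.0, -2.0)[0] == pytest.approx(u1 + u2)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            GradientConfig(method="lbfgs")


class TestTraining:
    def test_zero_learning_rate_is_identity(self, separable_dataset):
        X, _, Y = separable_dataset
        top = net.Topology(2, (2,), 2)
        r = train_gradient(top, X, Y, GradientConfig("grad", learning_rate=0.0,
                                                     iterations=5), seed=0)
        theta0 = np.random.default_rng(0).uniform(-0.5, 0.5,
                                                  net.count_parameters(top))
        assert np.array_equal(r.best_position, theta0)
        assert np.all(r.fitness_trace == r.fitness_trace[0])

    def test_same_seed_identical_trace(self, separable_dataset):
        X, _, Y = separable_dataset
        top = net.Topology(2, (3,), 2)
        cfg = GradientConfig("sgd", iterations=10)
        a = train_gradient(top, X, Y, cfg, seed=4)
        b = train_gradient(top, X, Y, cfg, seed=4)
        assert np.array_equal(a.fitness_trace, b.fitness_trace)

    def test_adam_learns_separable_data(self, separable_dataset):
        X, _, Y = separable_dataset
        r = train_gradient(net.Topology(2, (4,), 2), X, Y,
                           GradientConfig("adam", iterations=2000), seed=0)
        assert r.best_fitness < 0.05

    def test_small_step_descent_monotone_on_near_convex_case(self):
        # single sigmoid unit, two samples: tiny steps shrink the loss
        top = net.Topology(1, (), 1)
        X = np.array([[0.0], [1.0]])
        Y = np.array([[0.2], [0.8]])
        theta = np.array([0.3, -0.2])
        losses = [net.mse(net.forward(top, theta, X), Y)]
        for _ in range(100):
            theta = theta - 0.05 * backprop_gradient(top, theta, X, Y)
            losses.append(net.mse(net.forward(top, theta, X), Y))
        assert all(b <= a + 1e-15 for a, b in zip(losses, losses[1:]))
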