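"""Learning-rule tests: loss gradients, delta rules, the delayed-target
parallel-fibre rule, eligibility traces, e-prop against finite differences
and an unrolled oracle, the optimizer, and session-level invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cerloop.model import Trajectory, VariantConfig, run_trial
from cerloop.plasticity import (
    AdamState,
    LearningConfig,
    adam_step,
    delta_parallel_fibres,
    delta_readout,
    eligibility_update,
    eprop_gradient,
    task_loss,
    train_session,
    trainable_weights,
)
from cerloop.tasks import LineDrawingTask

from conftest import toy_params


class TestTaskLoss:
    def test_perfect_prediction_zero_loss_and_gradient(self, rng):
        z = rng.normal(size=(4, 3, 2))
        loss, g = task_loss(z, z.copy(), np.ones(4, bool), "mse")
        assert loss == 0.0
        assert np.all(g == 0)

    def test_single_step_mse_value_and_gradient(self):
        z = np.zeros((1, 1, 2))
        y = np.array([[[1.0, 0.0]]])
        loss, g = task_loss(z, y, np.ones(1, bool), "mse")
        assert loss == pytest.approx(0.5)  # mean over the 2 output dims
        np.testing.assert_allclose(g[0, 0], [-1.0, 0.0])  # 2(z-y)/n_out

    def test_cross_entropy_uniform_logits(self):
        z = np.zeros((1, 1, 2))
        y = np.array([[[1.0, 0.0]]])
        loss, _ = task_loss(z, y, np.ones(1, bool), "cross_entropy")
        assert loss == pytest.approx(np.log(2))

    def test_cross_entropy_rejects_non_probability_targets(self):
        z = np.zeros((1, 1, 2))
        y = np.array([[[2.0, 1.0]]])
        with pytest.raises(ValueError):
            task_loss(z, y, np.ones(1, bool), "cross_entropy")

    def test_mask_restricts_supervision(self, rng):
        z = rng.normal(size=(3, 2, 2))
        y = np.zeros_like(z)
        mask = np.array([False, True, False])
        _, g = task_loss(z, y, mask, "mse")
        assert np.all(g[0] == 0) and np.all(g[2] == 0) and np.any(g[1] != 0)


def _finite_diff(fun, mat, eps=1e-6):
    grad = np.zeros_like(mat)
    it = np.nditer(mat, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = mat[idx]
        mat[idx] = orig + eps
        fp = fun()
        mat[idx] = orig - eps
        fm = fun()
        mat[idx] = orig
        grad[idx] = (fp - fm) / (2 * eps)
    return grad


class TestDeltaReadout:
    def test_zero_gradient_cases(self, params, rng):
        h = rng.normal(size=(3, 2, params.n_rnn + 0))
        h = np.concatenate([np.zeros((1, 2, params.n_rnn)), h])
        zero_g = np.zeros((3, 2, params.n_out))
        gw, gb = delta_readout(zero_g, h, params)
        assert np.all(gw == 0) and np.all(gb == 0)

    def test_outer_product_accumulation(self, params):
        # 1-D toy: dE_dz = 2 paired with f(h) = (0.5, -0.5, 0)
        h = np.zeros((2, 1, params.n_rnn))
        h[1, 0] = np.arctanh(np.array([0.5, -0.5, 0.0]))
        dE = np.full((1, 1, params.n_out), 0.0)
        dE[0, 0, 0] = 2.0
        gw, gb = delta_readout(dE, h, params)
        np.testing.assert_allclose(gw[0], [1.0, -1.0, 0.0], rtol=1e-12)
        np.testing.assert_allclose(gb, [2.0, 0.0])

    def test_matches_finite_differences(self, params, rng):
        """Analytic dE/dW_rdt equals central differences on a full rollout."""
        x = rng.normal(size=(4, 2, params.n_input))
        y = rng.normal(size=(4, 2, params.n_out))
        mask = np.ones(4, bool)
        vc = VariantConfig("cerebellar_feedback")

        def loss():
            traj = run_trial(params, vc, x)
            return task_loss(traj.z, y, mask, "mse")[0]

        traj = run_trial(params, vc, x)
        _, dE = task_loss(traj.z, y, mask, "mse")
        gw, gb = delta_readout(dE, traj.h, params)
        np.testing.assert_allclose(gw, _finite_diff(loss, params.W_rdt), atol=1e-5)
        np.testing.assert_allclose(gb, _finite_diff(loss, params.b_rdt), atol=1e-5)


class TestDeltaParallelFibres:
    def _traj(self, params, x):
        return run_trial(params, VariantConfig("cerebellar_feedback"), x)

    def test_tau_zero_reduces_to_delta_rule(self, params, rng):
        x = rng.normal(size=(3, 2, params.n_input))
        traj = self._traj(params, x)
        y = rng.normal(size=(3, 2, params.n_out))
        mask = np.ones(3, bool)
        grad = delta_parallel_fibres(traj, y, mask, (0,), "mse", params)
        d = 2.0 * (traj.c - y) / (3 * 2 * params.n_out)
        expected = np.einsum("tbo,tbg->og", d, traj.g)
        np.testing.assert_allclose(grad, expected, rtol=1e-10)

    def test_perfect_predictor_zero_update(self, params, rng):
        x = rng.normal(size=(4, 1, params.n_input))
        traj = self._traj(params, x)
        tau = 1
        y = np.zeros((4, 1, params.n_out))
        y[tau:] = traj.c[:-tau]  # y_t = c_{t-tau} exactly
        mask = np.zeros(4, bool)
        mask[tau:] = True
        grad = delta_parallel_fibres(traj, y, mask, (tau,), "mse", params)
        assert np.allclose(grad, 0.0)

    def test_hand_computed_accumulation(self):
        """T=3, tau=1 scalar toy: explicit sum over t = 2..3."""
        p = toy_params(n_rnn=1, n_input=1, n_out=1, n_granule=1, seed=3)
        c = np.array([0.2, -0.4, 0.5])[:, None, None]
        g = np.array([1.0, 2.0, -1.0])[:, None, None]
        y = np.array([0.0, 0.1, 0.3])[:, None, None]
        traj = Trajectory(h=np.zeros((4, 1, 1)), z=np.zeros((3, 1, 1)),
                          x=np.zeros((3, 1, 1)), c=c, g=g)
        grad = delta_parallel_fibres(traj, y, np.ones(3, bool), (1,), "mse", p)
        # pairs: (c_1, y_2) with g_1 and (c_2, y_3) with g_2; scale 2/(2*1*1)
        expected = (2 * (0.2 - 0.1) * 1.0 + 2 * (-0.4 - 0.3) * 2.0) / 2
        assert grad.shape == (1, 1)
        assert grad[0, 0] == pytest.approx(expected)

    def test_window_exceeding_trial_warns_and_zeroes(self, params, rng):
        x = rng.normal(size=(2, 1, params.n_input))
        traj = self._traj(params, x)
        y = rng.normal(size=(2, 1, params.n_out))
        with pytest.warns(UserWarning):
            grad = delta_parallel_fibres(traj, y, np.ones(2, bool), (5,), "mse", params)
        assert np.all(grad == 0)

    def test_temporal_basis_slices_address_own_windows(self, rng):
        p = toy_params(n_windows=2, seed=9)
        x = rng.normal(size=(5, 2, p.n_input))
        traj = run_trial(p, VariantConfig("cerebellar_feedback"), x)
        y = rng.normal(size=(5, 2, p.n_out))
        grad = delta_parallel_fibres(traj, y, np.ones(5, bool), (0, 2), "mse", p)
        # window 0 rows: plain delta rule on slice 0
        d0 = 2.0 * (traj.c[:, :, :2] - y) / (5 * 2 * p.n_out)
        np.testing.assert_allclose(
            grad[:2], np.einsum("tbo,tbg->og", d0, traj.g), rtol=1e-10
        )
        # window tau=2 rows pair slice 1 at t-2 with y_t
        d1 = 2.0 * (traj.c[:-2, :, 2:] - y[2:]) / (3 * 2 * p.n_out)
        np.testing.assert_allclose(
            grad[2:], np.einsum("tbo,tbg->og", d1, traj.g[:-2]), rtol=1e-10
        )


class TestEligibility:
    def test_explicit_recursion(self):
        eps = np.zeros(1)
        out = []
        for a in (1.0, 0.0, 1.0):
            eps = eligibility_update(eps, np.array([a]), 0.5)
            out.append(eps[0])
        np.testing.assert_allclose(out, [1.0, 0.5, 1.25])

    def test_alpha_zero_is_memoryless(self, rng):
        a = rng.normal(size=4)
        np.testing.assert_array_equal(eligibility_update(rng.normal(size=4), a, 0.0), a)

    @settings(max_examples=50, deadline=None)
    @given(alpha=st.floats(0.0, 0.95), a=st.floats(-2, 2), t=st.integers(1, 60))
    def test_constant_input_geometric_sum(self, alpha, a, t):
        """Closed form: trace after t steps of constant a is a(1-alpha^t)/(1-alpha)."""
        eps = np.zeros(1)
        for _ in range(t):
            eps = eligibility_update(eps, np.array([a]), alpha)
        expected = a * (1 - alpha**t) / (1 - alpha) if alpha < 1 else a * t
        np.testing.assert_allclose(eps[0], expected, rtol=1e-9, atol=1e-12)


class TestEprop:
    def test_fixed_rnn_gives_empty_gradients(self, params, rng):
        x = rng.normal(size=(3, 2, params.n_input))
        traj = run_trial(params, VariantConfig("cerebellar_feedback"), x)
        assert eprop_gradient(traj, np.zeros_like(traj.z), params, "fixed_rnn") == {}

    def test_unknown_regime_raises(self, params, rng):
        x = rng.normal(size=(2, 1, params.n_input))
        traj = run_trial(params, VariantConfig("cerebellar_feedback"), x)
        with pytest.raises(ValueError):
            eprop_gradient(traj, np.zeros_like(traj.z), params, "sometimes_plastic")

    @pytest.mark.parametrize("name", ["W_ih", "W_Ch", "W_hh"])
    def test_single_timestep_matches_finite_differences(self, params, rng, name):
        """For T=1 the e-prop gradient is the exact gradient."""
        x = rng.normal(size=(1, 3, params.n_input))
        y = rng.normal(size=(1, 3, params.n_out))
        mask = np.ones(1, bool)
        vc = VariantConfig("cerebellar_feedback")

        def loss():
            traj = run_trial(params, vc, x)
            return task_loss(traj.z, y, mask, "mse")[0]

        traj = run_trial(params, vc, x)
        _, dE = task_loss(traj.z, y, mask, "mse")
        grads = eprop_gradient(traj, dE, params, "fully_plastic")
        np.testing.assert_allclose(
            grads[name], _finite_diff(loss, getattr(params, name)), atol=1e-5
        )

    def test_linear_network_unrolled_oracle(self, rng):
        """Linear f, T=3: the gradient equals the explicit sum
        sum_t L_t (sum_{s<=t} alpha^{t-s} a_s)^T with geometric weights."""
        p = toy_params(activation="linear", alpha=0.6, seed=21)
        x = rng.normal(size=(3, 2, p.n_input))
        y = rng.normal(size=(3, 2, p.n_out))
        vc = VariantConfig("no_feedback")
        traj = run_trial(p, vc, x)
        _, dE = task_loss(traj.z, y, np.ones(3, bool), "mse")
        grads = eprop_gradient(traj, dE, p, "fully_plastic", "no_feedback")

        expected = np.zeros_like(p.W_ih)
        for t in range(1, 4):
            L = dE[t - 1] @ p.W_rdt  # f' = 1 for linear
            eps = sum(p.alpha ** (t - s) * x[s - 1] for s in range(1, t + 1))
            expected += np.einsum("bj,bi->ji", L, eps)
        np.testing.assert_allclose(grads["W_ih"], expected, rtol=1e-10)


class TestAdam:
    def test_zero_gradient_leaves_parameter_unchanged(self):
        st_ = AdamState()
        st_.begin_step()
        p = np.array([1.0, -2.0])
        adam_step(st_, "w", p, np.zeros(2), eta=0.1)
        np.testing.assert_array_equal(p, [1.0, -2.0])

    def test_first_step_is_signed_learning_rate(self):
        st_ = AdamState()
        st_.begin_step()
        p = np.zeros(2)
        adam_step(st_, "w", p, np.array([3.0, -0.2]), eta=0.01)
        np.testing.assert_allclose(p, [-0.01, 0.01], rtol=1e-6)

    def test_two_step_recursion_oracle(self):
        g1, g2 = np.array([1.0]), np.array([-2.0])
        st_ = AdamState()
        p = np.array([0.5])
        for g in (g1, g2):
            st_.begin_step()
            adam_step(st_, "w", p, g, eta=0.1)
        # hand evaluation
        b1, b2, e = 0.9, 0.999, 1e-8
        m = (1 - b1) * g1
        v = (1 - b2) * g1**2
        q = 0.5 - 0.1 * (m / (1 - b1)) / (np.sqrt(v / (1 - b2)) + e)
        m = b1 * m + (1 - b1) * g2
        v = b2 * v + (1 - b2) * g2**2
        q = q - 0.1 * (m / (1 - b1**2)) / (np.sqrt(v / (1 - b2**2)) + e)
        np.testing.assert_allclose(p, q, rtol=1e-10)


class TestTrainSession:
    def test_zero_learning_rate_leaves_params_unchanged(self, rng):
        task = LineDrawingTask()
        p = toy_params(n_rnn=5, n_input=10, n_out=2, n_granule=8, seed=2)
        before = p.copy()
        cfg = LearningConfig(eta=0.0, n_train_examples=30, batch_size=10)
        errs, _ = train_session(p, VariantConfig("cerebellar_feedback"), task, cfg, rng)
        assert errs.shape == (3,)
        for name in ("W_rdt", "W_PF", "W_ih", "W_hh", "W_Ch"):
            np.testing.assert_array_equal(getattr(p, name), getattr(before, name))

    @pytest.mark.parametrize(
        "regime, frozen",
        [
            ("fixed_rnn", ("W_ih", "W_Ch", "W_hh")),
            ("input_plastic", ("W_hh",)),
            ("fully_plastic", ()),
        ],
    )
    def test_regime_containment(self, rng, regime, frozen):
        """Weights outside the regime's mask are bitwise unchanged; W_MF never learns."""
        task = LineDrawingTask()
        p = toy_params(n_rnn=5, n_input=10, n_out=2, n_granule=8, seed=2)
        before = p.copy()
        cfg = LearningConfig(regime=regime, n_train_examples=50, batch_size=10)
        train_session(p, VariantConfig("cerebellar_feedback"), task, cfg, rng)
        np.testing.assert_array_equal(p.W_MF, before.W_MF)
        for name in frozen:
            np.testing.assert_array_equal(getattr(p, name), getattr(before, name))
        for name in set(("W_rdt", "W_PF")) | (
            {"W_ih", "W_Ch", "W_hh"} - set(frozen)
        ):
            assert not np.array_equal(getattr(p, name), getattr(before, name)), name

    def test_trainable_weights_by_variant(self):
        cfg = LearningConfig(regime="input_plastic")
        assert "W_zh" in trainable_weights(cfg, VariantConfig("readout_feedback"))
        assert "W_Ch" in trainable_weights(cfg, VariantConfig("cerebellar_feedback"))
        names = trainable_weights(LearningConfig(), VariantConfig("cerebellar_readout"))
        assert "W_rdt" not in names and "W_PF" in names
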