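"""Backward pass: loss, direct term, oracle equivalence, SDBP projection."""

import numpy as np
import pytest

from stbp import (
    LIFConfig,
    SurrogateSpec,
    forward_network,
    gradient_check,
    init_uniform,
    loss_mse_rate,
    normalize_weights,
    numerical_gradient_relaxed,
    output_direct_grad,
    parse_architecture,
    relaxed_loss,
    stbp_backward,
)
from stbp.engine import _grad_rel_error
from stbp.lif import LayerTrace
from stbp.surrogate import surrogate_eval


def _trace_from_o(o_steps):
    """Build an output trace with the given (T, S, n) spike tensor."""
    o_steps = np.asarray(o_steps, dtype=float)
    T = o_steps.shape[0]
    o = np.concatenate([np.zeros((1,) + o_steps.shape[1:]), o_steps])
    return LayerTrace(u=np.zeros_like(o), o=o, x=np.zeros_like(o))


class TestLoss:
    def test_perfect_rate_match_is_zero(self):
        tr = _trace_from_o([[[1.0, 0.0]], [[1.0, 0.0]]])
        assert loss_mse_rate(tr, np.array([[1.0, 0.0]]), T=2, S=1) == 0.0

    def test_single_missed_spike(self):
        tr = _trace_from_o([[[0.0]]])
        assert loss_mse_rate(tr, np.array([[1.0]]), T=1, S=1) == pytest.approx(0.5)

    def test_two_sample_silent_network(self):
        tr = _trace_from_o(np.zeros((2, 2, 2)))
        labels = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert loss_mse_rate(tr, labels, T=2, S=2) == pytest.approx(0.5)

    def test_zero_window_rejected(self):
        tr = _trace_from_o(np.zeros((1, 1, 1)))
        with pytest.raises(ValueError):
            loss_mse_rate(tr, np.array([[1.0]]), T=0, S=1)


class TestDirectGrad:
    def test_zero_at_the_minimum(self):
        tr = _trace_from_o([[[1.0]]])
        np.testing.assert_allclose(
            output_direct_grad(tr, np.array([[1.0]]), T=1, S=1), [[0.0]]
        )

    def test_silent_output_pulls_up(self):
        tr = _trace_from_o(np.zeros((2, 1, 1)))
        np.testing.assert_allclose(
            output_direct_grad(tr, np.array([[1.0]]), T=2, S=1), [[-0.5]]
        )

    def test_spurious_rate_pushes_down(self):
        tr = _trace_from_o([[[1.0]]])
        np.testing.assert_allclose(
            output_direct_grad(tr, np.array([[0.0]]), T=1, S=1), [[1.0]]
        )


class TestOracleEquivalence:
    """stbp_backward must be the exact gradient of the relaxed network."""

    @pytest.mark.parametrize("family", ["rectangular", "polynomial", "sigmoid", "gaussian"])
    @pytest.mark.parametrize("T", [1, 3, 7])
    def test_dense_matches_finite_differences(self, family, T):
        chain = parse_architecture("4-6-3")
        cfg = LIFConfig(tau=0.1, v_th=1.5, T=T)
        errs = [
            gradient_check(chain, cfg, SurrogateSpec(family, 1.0), seed=s)
            for s in range(3)
        ]
        assert max(errs) < 1e-5

    @pytest.mark.parametrize("family", ["rectangular", "sigmoid"])
    def test_conv_pool_matches_finite_differences(self, family):
        chain = parse_architecture("6x6x1-2C3-P2-3")
        cfg = LIFConfig(tau=0.1, v_th=1.5, T=3)
        errs = [
            gradient_check(chain, cfg, SurrogateSpec(family, 1.0), seed=s)
            for s in range(3)
        ]
        assert max(errs) < 1e-5

    def test_single_weight_hand_derivation(self):
        # 1 input -> 1 output, T=1, relaxed: L = 0.5*(y - sigma(w*o))^2,
        # dL/dw = -(y - sigma(w*o)) * h(w*o) * o
        chain = parse_architecture("1-1")
        cfg = LIFConfig(tau=0.1, v_th=1.5, T=1, forget_mode="exact")
        spec = SurrogateSpec("sigmoid", 1.0, 1.5)
        p = init_uniform(chain, seed=0)
        p.weights[0][:] = 0.8
        inp = np.ones((1, 1, 1))
        labels = np.array([[1.0]])
        traces = forward_network(p, chain, inp, cfg, spec, relaxed=True)
        g = stbp_backward(traces, p, chain, inp, labels, cfg, spec)
        from stbp.surrogate import smooth_activation

        rate = float(smooth_activation(0.8, spec))
        expected = -(1.0 - rate) * float(surrogate_eval(0.8, spec)) * 1.0
        assert g.dW[0][0, 0] == pytest.approx(expected, rel=1e-12)

    def test_gradient_zero_at_global_minimum(self):
        # saturated network whose rates equal the labels: direct term is 0,
        # so every gradient vanishes
        chain = parse_architecture("2-1")
        cfg = LIFConfig(tau=0.1, v_th=1.5, T=2)
        p = init_uniform(chain, seed=0)
        p.weights[0][:] = 100.0
        inp = np.ones((2, 1, 2))
        labels = np.array([[1.0]])
        traces = forward_network(p, chain, inp, cfg)
        g = stbp_backward(traces, p, chain, inp, labels, cfg, SurrogateSpec("sigmoid", 1.0))
        assert g.max_abs() == 0.0

    def test_epsilon_bounds_enforced(self, dense_chain, small_cfg):
        p = init_uniform(dense_chain, seed=0)
        with pytest.raises(ValueError):
            numerical_gradient_relaxed(
                p, dense_chain, np.zeros((5, 1, 4)), np.eye(3)[:1], small_cfg,
                SurrogateSpec("sigmoid", 1.0), epsilon=1e-2,
            )


def _sdbp_reference(traces, params, chain, inp, labels, cfg, spec):
    """Independent spatial-only backprop: each step treated as its own
    feedforward network, gradients summed over steps."""
    from stbp.engine import GradientSet, _conv_backward, _pool_backward, output_direct_grad

    act = SurrogateSpec(spec.family, spec.a, cfg.v_th)
    S = labels.shape[0]
    direct = output_direct_grad(traces[-1], labels, cfg.T, S)
    dW = [None if w is None else np.zeros_like(w) for w in params.weights]
    db = [None if b is None else np.zeros_like(b) for b in params.biases]
    d_o = [np.zeros_like(tr.u) for tr in traces]
    d_u = [np.zeros_like(tr.u) for tr in traces]
    for t in range(1, cfg.T + 1):
        grad = direct
        for i in range(len(chain) - 1, -1, -1):
            sp, tr = chain[i], traces[i]
            if sp.kind == "avgpool":
                grad = _pool_backward(grad, sp.kernel)
                continue
            delta_o = grad.reshape(tr.o[t].shape)
            delta_u = delta_o * surrogate_eval(tr.u[t], act)
            d_o[i][t], d_u[i][t] = delta_o, delta_u
            below = inp[t - 1] if i == 0 else traces[i - 1].o[t]
            if sp.kind == "dense":
                dW[i] += delta_u.T @ below.reshape(S, -1)
                db[i] += delta_u.sum(axis=0)
                grad = (delta_u @ params.weights[i]).reshape((S,) + sp.in_shape)
            else:
                dWi, grad = _conv_backward(delta_u, below, params.weights[i])
                dW[i] += dWi
                db[i] += delta_u.sum(axis=(0, 2, 3))
    return d_o, d_u, GradientSet(dW=dW, db=db)


class TestSDBP:
    def _setup(self, arch, T, seed=0):
        chain = parse_architecture(arch)
        cfg = LIFConfig(tau=0.2, v_th=0.2, T=T)
        rng = np.random.default_rng(seed)
        p = normalize_weights(init_uniform(chain, rng))
        inp = (rng.random((T, 3) + chain[0].in_shape) < 0.5).astype(float)
        labels = np.eye(chain[-1].n_out)[rng.integers(0, chain[-1].n_out, 3)]
        spec = SurrogateSpec("sigmoid", 1.0)
        traces = forward_network(p, chain, inp, cfg)
        return chain, cfg, p, inp, labels, spec, traces

    def test_identical_to_stbp_for_single_step_window(self):
        chain, cfg, p, inp, labels, spec, traces = self._setup("4-6-3", T=1)
        g_t = stbp_backward(traces, p, chain, inp, labels, cfg, spec, temporal=True)
        g_s = stbp_backward(traces, p, chain, inp, labels, cfg, spec, temporal=False)
        for a, b in zip(g_t.dW + g_t.db, g_s.dW + g_s.db):
            np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("arch,T", [("4-6-3", 5), ("6x6x1-2C3-P2-3", 3)])
    def test_temporal_deletion_term_by_term(self, arch, T):
        # the engine's temporal=False path must equal an independently coded
        # per-step backprop in every delta_o / delta_u entry and gradient
        chain, cfg, p, inp, labels, spec, traces = self._setup(arch, T)
        state, g = stbp_backward(
            traces, p, chain, inp, labels, cfg, spec, temporal=False, return_state=True
        )
        ref_o, ref_u, ref_g = _sdbp_reference(traces, p, chain, inp, labels, cfg, spec)
        for i, sp in enumerate(chain):
            if sp.kind == "avgpool":
                continue
            np.testing.assert_allclose(state.delta_o[i], ref_o[i], atol=1e-14)
            np.testing.assert_allclose(state.delta_u[i], ref_u[i], atol=1e-14)
        for a, b in zip(g.dW + g.db, ref_g.dW + ref_g.db):
            if a is not None:
                np.testing.assert_allclose(a, b, atol=1e-14)


class TestGradientStructure:
    def test_descent_property_on_relaxed_network(self):
        chain = parse_architecture("4-6-3")
        cfg = LIFConfig(tau=0.1, v_th=1.5, T=4, forget_mode="exact")
        spec = SurrogateSpec("sigmoid", 1.0)
        rng = np.random.default_rng(3)
        p = normalize_weights(init_uniform(chain, rng))
        inp = (rng.random((4, 4, 4)) < 0.5).astype(float)
        labels = np.eye(3)[rng.integers(0, 3, 4)]
        traces = forward_network(p, chain, inp, cfg, spec, relaxed=True)
        g = stbp_backward(traces, p, chain, inp, labels, cfg, spec)
        l0 = relaxed_loss(p, chain, inp, labels, cfg, spec)
        q = p.copy()
        lr = 1e-2
        for i in range(len(q.weights)):
            q.weights[i] -= lr * g.dW[i]
            q.biases[i] -= lr * g.db[i]
        l1 = relaxed_loss(q, chain, inp, labels, cfg, spec)
        assert l1 < l0

    def test_batch_gradient_is_mean_of_per_sample_gradients(self):
        chain = parse_architecture("4-6-3")
        cfg = LIFConfig(tau=0.2, v_th=0.2, T=3)
        spec = SurrogateSpec("sigmoid", 1.0)
        rng = np.random.default_rng(11)
        p = normalize_weights(init_uniform(chain, rng))
        inp = (rng.random((3, 4, 4)) < 0.5).astype(float)
        labels = np.eye(3)[rng.integers(0, 3, 4)]
        traces = forward_network(p, chain, inp, cfg)
        g_batch = stbp_backward(traces, p, chain, inp, labels, cfg, spec)
        acc = None
        for s in range(4):
            tr_s = forward_network(p, chain, inp[:, s : s + 1], cfg)
            g_s = stbp_backward(
                tr_s, p, chain, inp[:, s : s + 1], labels[s : s + 1], cfg, spec
            )
            if acc is None:
                acc = g_s
            else:
                for i in range(len(acc.dW)):
                    acc.dW[i] += g_s.dW[i]
                    acc.db[i] += g_s.db[i]
        for a, b in zip(g_batch.dW + g_batch.db, acc.dW + acc.db):
            np.testing.assert_allclose(a, b / 4, atol=1e-12)

    def test_incomplete_trace_rejected(self, dense_chain):
        cfg = LIFConfig(tau=0.2, v_th=0.2, T=4)
        p = init_uniform(dense_chain, seed=0)
        inp = np.zeros((3, 1, 4))
        short_cfg = LIFConfig(tau=0.2, v_th=0.2, T=3)
        traces = forward_network(p, dense_chain, inp, short_cfg)
        with pytest.raises(ValueError, match="trace"):
            stbp_backward(
                traces, p, dense_chain, inp, np.eye(3)[:1], cfg,
                SurrogateSpec("sigmoid", 1.0),
            )
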