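"""The spatio-temporal backward pass and its gradient oracle.

Training minimizes the mean squared error between one-hot labels and mean
output firing rates over the window,

    L = (1/2S) * sum_s || y_s - (1/T) sum_t o_s[t] ||^2 .

Unrolling the network in layers (spatial direction) and time (temporal
direction) makes every dependency explicit, so the chain rule gives a
two-index recursion, iterated from the last step and layer backwards.
Writing d_o = dL/do and d_u = dL/du per layer and step:

    d_o[t,n] = direct[n==N]
             + W[n+1]^T d_u[t,n+1]                (spatial credit)
             + d_u[t+1,n] * u[t,n] * f'(o[t,n])   (temporal, via the gate)
    d_u[t,n] = d_o[t,n] * h(u[t,n])
             + d_u[t+1,n] * f(o[t,n])             (temporal, via the leak)

with h the surrogate derivative standing in for dg/du, and the direct term
-(1/TS) (y - mean rate) applied at the output layer at *every* step,
because the loss depends on all output steps symmetrically through the time
average.  Parameter gradients accumulate over the window:

    dL/dW[n] = sum_t d_u[t,n] (x) o[t,n-1],   dL/db[n] = sum_t d_u[t,n].

Dropping every term that carries a t+1 index yields SDBP, the
spatial-domain-only ablation.

The recursion is the *exact* gradient of the relaxed network (hard
threshold replaced by the surrogate's smooth antiderivative, exact forget
gate), which is what :func:`numerical_gradient_relaxed` exploits: central
finite differences of the relaxed loss are an independent oracle for the
backward pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lif import LIFConfig, LayerTrace, forget_gate
from .models import LayerSpec, NetworkParams, forward_network, init_uniform, normalize_weights
from .surrogate import SurrogateSpec, surrogate_eval

__all__ = [
    "BackwardState",
    "GradientSet",
    "loss_mse_rate",
    "output_direct_grad",
    "stbp_backward",
    "relaxed_loss",
    "numerical_gradient_relaxed",
    "gradient_check",
]


@dataclass
class BackwardState:
    """Per-layer, per-step error signals (time axis length T+1, index 0 unused)."""

    delta_o: list
    delta_u: list


@dataclass
class GradientSet:
    """Per-layer parameter gradients, aligned with the LayerSpec chain."""

    dW: list
    db: list

    def max_abs(self) -> float:
        return max(
            (np.abs(g).max() for g in self.dW + self.db if g is not None and g.size),
            default=0.0,
        )


def loss_mse_rate(output_trace: LayerTrace, labels: np.ndarray, T: int, S: int) -> float:
    """Mean squared error between labels and time-averaged output activity."""
    if T < 1:
        raise ValueError("T must be >= 1")
    rates = output_trace.o[1:].mean(axis=0)
    diff = labels - rates
    return float(0.5 / S * (diff**2).sum())


def output_direct_grad(
    output_trace: LayerTrace, labels: np.ndarray, T: int, S: int
) -> np.ndarray:
    """Direct dependence of the loss on the output spikes at each step.

    The same vector -(1/TS)(y - mean rate) applies at every t, since each
    output step enters the loss only through the time average.
    """
    rates = output_trace.o[1:].mean(axis=0)
    return -(1.0 / (T * S)) * (labels - rates)


def _forget_deriv(o: np.ndarray, cfg: LIFConfig) -> np.ndarray:
    """df/do.  Zero in approximate mode (f is piecewise constant there)."""
    if cfg.forget_mode == "exact":
        return -np.exp(-o / cfg.tau)
    return np.zeros_like(o)


def _pool_backward(grad: np.ndarray, k: int) -> np.ndarray:
    """Distribute incoming error uniformly over each k x k pool window."""
    g = grad / (k * k)
    return np.repeat(np.repeat(g, k, axis=2), k, axis=3)


def _conv_backward(
    delta: np.ndarray, o_in: np.ndarray, W: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of a valid-mode correlation.

    delta: (S, C_out, H_o, W_o); o_in: (S, C_in, H, W); W: (C_out, C_in, k, k).
    Returns (dW, grad wrt o_in) — the transposed correlation.
    """
    k = W.shape[-1]
    Ho, Wo = delta.shape[2], delta.shape[3]
    dW = np.empty_like(W)
    d_in = np.zeros_like(o_in)
    for p in range(k):
        for q in range(k):
            patch = o_in[:, :, p : p + Ho, q : q + Wo]
            dW[:, :, p, q] = np.einsum("soij,scij->oc", delta, patch)
            d_in[:, :, p : p + Ho, q : q + Wo] += np.einsum(
                "soij,oc->scij", delta, W[:, :, p, q]
            )
    return dW, d_in


def stbp_backward(
    traces: list[LayerTrace],
    params: NetworkParams,
    chain: list[LayerSpec],
    input_spikes: np.ndarray,
    labels: np.ndarray,
    cfg: LIFConfig,
    surrogate: SurrogateSpec,
    temporal: bool = True,
    return_state: bool = False,
):
    """Run the full backward recursion; see the module docstring.

    ``temporal=False`` drops every cross-time term (the SDBP ablation).
    Returns a GradientSet, or (BackwardState, GradientSet) with
    ``return_state=True``.
    """
    T, S = cfg.T, labels.shape[0]
    n_layers = len(chain)
    for i, tr in enumerate(traces):
        if tr.T != T:
            raise ValueError(f"trace {i} covers {tr.T} steps, expected {T}")
    act = SurrogateSpec(surrogate.family, surrogate.a, cfg.v_th)
    direct = output_direct_grad(traces[-1], labels, T, S)

    dW = [None if w is None else np.zeros_like(w) for w in params.weights]
    db = [None if b is None else np.zeros_like(b) for b in params.biases]
    delta_u_next = [np.zeros_like(tr.u[0]) for tr in traces]
    state = (
        BackwardState(
            delta_o=[np.zeros_like(tr.u) for tr in traces],
            delta_u=[np.zeros_like(tr.u) for tr in traces],
        )
        if return_state
        else None
    )

    for t in range(T, 0, -1):
        grad_above = direct  # only the top layer sees the loss directly
        new_delta_u = list(delta_u_next)
        for i in range(n_layers - 1, -1, -1):
            spec, tr = chain[i], traces[i]
            if spec.kind == "avgpool":
                grad_above = _pool_backward(grad_above, spec.kernel)
                continue
            delta_o = grad_above.reshape(tr.o[t].shape).copy()
            if temporal and t < T:
                delta_o += delta_u_next[i] * tr.u[t] * _forget_deriv(tr.o[t], cfg)
            delta_u = delta_o * surrogate_eval(tr.u[t], act)
            if temporal and t < T:
                delta_u += delta_u_next[i] * forget_gate(tr.o[t], cfg)
            if not np.isfinite(delta_u).all():
                raise FloatingPointError(f"non-finite gradient in layer {i} at t={t}")
            if state is not None:
                state.delta_o[i][t] = delta_o
                state.delta_u[i][t] = delta_u

            o_below = input_spikes[t - 1] if i == 0 else traces[i - 1].o[t]
            if spec.kind == "dense":
                flat = o_below.reshape(S, -1)
                dW[i] += delta_u.T @ flat
                db[i] += delta_u.sum(axis=0)
                grad_above = (delta_u @ params.weights[i]).reshape((S,) + spec.in_shape)
            else:
                dWi, grad_above = _conv_backward(delta_u, o_below, params.weights[i])
                dW[i] += dWi
                db[i] += delta_u.sum(axis=(0, 2, 3))
            new_delta_u[i] = delta_u
        delta_u_next = new_delta_u

    grads = GradientSet(dW=dW, db=db)
    return (state, grads) if return_state else grads


# ---------------------------------------------------------------------------
# finite-difference oracle on the smooth relaxation


def relaxed_loss(
    params: NetworkParams,
    chain: list[LayerSpec],
    input_spikes: np.ndarray,
    labels: np.ndarray,
    cfg: LIFConfig,
    surrogate: SurrogateSpec,
) -> float:
    """Loss of the fully differentiable relaxed network."""
    traces = forward_network(params, chain, input_spikes, cfg, surrogate, relaxed=True)
    return loss_mse_rate(traces[-1], labels, cfg.T, labels.shape[0])


def numerical_gradient_relaxed(
    params: NetworkParams,
    chain: list[LayerSpec],
    input_spikes: np.ndarray,
    labels: np.ndarray,
    cfg: LIFConfig,
    surrogate: SurrogateSpec,
    epsilon: float = 1e-5,
) -> GradientSet:
    """Central finite differences of the relaxed loss, parameter by parameter."""
    if not (1e-8 <= epsilon <= 1e-4):
        raise ValueError(f"epsilon {epsilon} outside sensible range [1e-8, 1e-4]")

    def fd(arr: np.ndarray) -> np.ndarray:
        g = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = arr[idx]
            arr[idx] = orig + epsilon
            lp = relaxed_loss(params, chain, input_spikes, labels, cfg, surrogate)
            arr[idx] = orig - epsilon
            lm = relaxed_loss(params, chain, input_spikes, labels, cfg, surrogate)
            arr[idx] = orig
            g[idx] = (lp - lm) / (2 * epsilon)
        return g

    dW = [None if w is None else fd(w) for w in params.weights]
    db = [None if b is None else fd(b) for b in params.biases]
    return GradientSet(dW=dW, db=db)


def _grad_rel_error(g1: GradientSet, g2: GradientSet) -> float:
    """Max absolute difference over all parameters, relative to the larger
    of the two gradient magnitudes."""
    num, den = 0.0, 0.0
    for a, b in zip(g1.dW + g1.db, g2.dW + g2.db):
        if a is None:
            continue
        num = max(num, float(np.abs(a - b).max()))
        den = max(den, float(np.abs(a).max()), float(np.abs(b).max()))
    return num / max(den, 1e-12)


def _min_kink_distance(traces, chain, v_th: float, a: float) -> float:
    """Distance of recorded potentials to the rectangular window edges."""
    d = np.inf
    for spec, tr in zip(chain, traces):
        if spec.kind == "avgpool":
            continue
        u = tr.u[1:]
        d = min(d, float(np.abs(np.abs(u - v_th) - a / 2).min()))
    return d


def gradient_check(
    chain: list[LayerSpec],
    cfg: LIFConfig,
    surrogate: SurrogateSpec,
    seed: int,
    batch: int = 2,
    epsilon: float = 1e-5,
    input_rate: float = 0.5,
) -> float:
    """Max relative error between stbp_backward and the finite-difference
    oracle on one randomly drawn relaxed network.

    Runs in exact-forget mode (the relaxation is differentiable there).
    Parameters are drawn wide (weights U[-2, 2], biases U[-0.5, 0.5]) so
    potentials land in every surrogate's responsive region; a draw whose
    gradients are identically zero (network silent or saturated — the check
    would be vacuous) is redrawn.  For the rectangular family the relaxed
    map is only piecewise linear, so draws whose potentials land within
    1e-3 of a window edge are also redrawn — central differences straddling
    a kink measure a subgradient, not the one-sided derivative the backward
    pass computes.
    """
    cfg = LIFConfig(tau=cfg.tau, v_th=cfg.v_th, dt=cfg.dt, T=cfg.T, forget_mode="exact")
    n_classes = chain[-1].n_out
    for attempt in range(50):
        rng = np.random.default_rng([seed, attempt])
        params = init_uniform(chain, rng)
        for i, (w, b) in enumerate(zip(params.weights, params.biases)):
            if w is not None:
                params.weights[i] = 2.0 * w
                params.biases[i] = rng.uniform(-0.5, 0.5, size=b.shape)
        inp = (rng.random((cfg.T, batch) + chain[0].in_shape) < input_rate).astype(float)
        labels = np.eye(n_classes)[rng.integers(0, n_classes, size=batch)]
        traces = forward_network(params, chain, inp, cfg, surrogate, relaxed=True)
        if surrogate.family == "rectangular":
            if _min_kink_distance(traces, chain, cfg.v_th, surrogate.a) < 1e-3:
                continue
        analytic = stbp_backward(
            traces, params, chain, inp, labels, cfg, surrogate, temporal=True
        )
        if analytic.max_abs() < 1e-8:
            continue
        numeric = numerical_gradient_relaxed(
            params, chain, inp, labels, cfg, surrogate, epsilon
        )
        return _grad_rel_error(analytic, numeric)
    raise RuntimeError("could not draw a usable configuration in 50 attempts")
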