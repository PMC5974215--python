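"""Discrete-time leaky integrate-and-fire dynamics.

The neuron model is the iterative map

    u[t] = u[t-1] * f(o[t-1]) + x[t] + b
    o[t] = g(u[t]) = 1{u[t] >= v_th}

where ``f`` is a forget gate implementing both leak and reset: between
spikes the membrane potential decays geometrically by the factor ``tau``;
after a spike the carried-over potential is (almost) annihilated.  Two
forget-gate modes are provided:

* ``exact``        f(o) = tau * exp(-o / tau)
* ``approximate``  f(o) = tau if o == 0 else 0

For the tabulated decay factors (0.1-0.2) the exact post-spike retention
tau*exp(-1/tau) is below 1e-4, which is why the approximate gate is the
default for spiking simulation.  The exact gate is smooth in ``o`` and is
what the differentiable relaxation of the network uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LIFConfig",
    "LayerTrace",
    "SpikeTrain",
    "forget_gate",
    "fire",
    "lif_step",
    "unroll_layer",
]


@dataclass(frozen=True)
class LIFConfig:
    """Neuron constants shared by every LIF unit in a network.

    Parameters
    ----------
    tau
        Dimensionless per-step retention factor in (0, 1).  The fraction of
        membrane potential surviving one step with no spike.
    v_th
        Firing threshold, in membrane-potential units.  Fixed (not learned);
        the learnable per-neuron bias plays the role of an adjustable
        threshold.
    dt
        Simulation step in ms.  Purely descriptive at this layer: the map is
        already discrete.
    T
        Number of time steps in the simulation window.
    forget_mode
        ``"approximate"`` (default) or ``"exact"``; see module docstring.
    """

    tau: float = 0.1
    v_th: float = 1.5
    dt: float = 1.0
    T: int = 30
    forget_mode: str = "approximate"

    def __post_init__(self) -> None:
        if not (0.0 < self.tau < 1.0):
            raise ValueError(f"tau must lie in (0, 1), got {self.tau}")
        if self.v_th <= 0:
            raise ValueError(f"v_th must be positive, got {self.v_th}")
        if self.T < 1:
            raise ValueError(f"T must be >= 1, got {self.T}")
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.forget_mode not in ("approximate", "exact"):
            raise ValueError(f"unknown forget_mode {self.forget_mode!r}")


@dataclass
class LayerTrace:
    """Complete per-layer record of one forward unroll.

    All three tensors have a leading time axis of length ``T + 1``; index 0
    holds the zero initial state, so index ``t`` is simulation step ``t``.

    Attributes
    ----------
    u : membrane potentials.
    o : spike outputs (binary in spiking mode, in [0, 1] for the smooth
        relaxation and for average-pooling layers).
    x : pre-synaptic drive received at each step (x[0] is zero padding).
    """

    u: np.ndarray
    o: np.ndarray
    x: np.ndarray

    @property
    def T(self) -> int:
        return self.u.shape[0] - 1


@dataclass
class SpikeTrain:
    """A binary activity pattern, time-major.

    ``data`` has shape ``(T, n)`` for flat layouts or ``(T, C, H, W)`` for
    image-shaped layouts.
    """

    data: np.ndarray
    layout: str = "flat"  # "flat" or "image"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("spike train entries must be binary")
        expect = 2 if self.layout == "flat" else 4
        if self.data.ndim != expect:
            raise ValueError(
                f"layout {self.layout!r} expects {expect}-d data, got {self.data.ndim}-d"
            )

    @property
    def T(self) -> int:
        return self.data.shape[0]


def forget_gate(o_prev: np.ndarray | float, cfg: LIFConfig) -> np.ndarray | float:
    """Retention factor applied to the carried-over membrane potential.

    Exact mode evaluates tau*exp(-o/tau); approximate mode returns tau where
    the neuron was silent and 0 where it spiked.
    """
    if cfg.forget_mode == "exact":
        return cfg.tau * np.exp(-np.asarray(o_prev, dtype=float) / cfg.tau)
    return cfg.tau * (1.0 - np.asarray(o_prev, dtype=float))


def fire(u: np.ndarray | float, v_th: float) -> np.ndarray:
    """Threshold the membrane potential into a spike: 1 iff u >= v_th.

    The boundary u == v_th fires.  Non-finite potentials are rejected: they
    indicate a diverged simulation, not a modelling choice.
    """
    u = np.asarray(u)
    if not np.isfinite(u).all():
        raise FloatingPointError("non-finite membrane potential")
    return (u >= v_th).astype(float)


def lif_step(
    u_prev: np.ndarray,
    o_prev: np.ndarray,
    x_t: np.ndarray,
    b: np.ndarray | float,
    cfg: LIFConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """One membrane update + threshold: returns (u_t, o_t)."""
    u_prev = np.asarray(u_prev, dtype=float)
    x_t = np.asarray(x_t, dtype=float)
    if u_prev.shape != x_t.shape:
        raise ValueError(f"shape mismatch: u {u_prev.shape} vs x {x_t.shape}")
    u_t = u_prev * forget_gate(o_prev, cfg) + x_t + b
    o_t = fire(u_t, cfg.v_th)
    return u_t, o_t


def unroll_layer(
    input_spikes: np.ndarray,
    weights: np.ndarray,
    bias: np.ndarray,
    cfg: LIFConfig,
    drive_fn=None,
) -> LayerTrace:
    """Run one dense LIF layer over a full T-step window.

    Parameters
    ----------
    input_spikes
        Pre-synaptic activity, shape (T, n_in) or (T, S, n_in).
    weights
        Dense weight matrix, shape (n_out, n_in).  Ignored when ``drive_fn``
        is given.
    bias
        Per-neuron bias, shape (n_out,) (broadcast).
    drive_fn
        Optional callable mapping pre-synaptic spikes at step t to synaptic
        drive (abstracts dense vs. convolutional connectivity).  Defaults to
        ``o @ weights.T``.

    The drive at step t is computed from pre-synaptic spikes at the *same*
    step t: input and membrane update share a time index.
    """
    inp = np.asarray(input_spikes, dtype=float)
    if inp.shape[0] != cfg.T:
        raise ValueError(f"input has {inp.shape[0]} steps, config expects {cfg.T}")
    if drive_fn is None:
        W = np.asarray(weights, dtype=float)

        def drive_fn(o):
            return o @ W.T

    x0 = drive_fn(inp[0]) * 0.0
    out_shape = (cfg.T + 1,) + x0.shape
    u = np.zeros(out_shape)
    o = np.zeros(out_shape)
    x = np.zeros(out_shape)
    for t in range(1, cfg.T + 1):
        x[t] = drive_fn(inp[t - 1])
        u[t], o[t] = lif_step(u[t - 1], o[t - 1], x[t], bias, cfg)
    return LayerTrace(u=u, o=o, x=x)
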