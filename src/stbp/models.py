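"""Composable spiking architectures: dense stacks and conv/pool stacks.

A network is a chain of layers of three kinds:

* ``dense``    fully connected LIF layer,
* ``conv``     2-d convolutional LIF layer ("valid" padding, stride 1),
* ``avgpool``  stateless spatial average (stride = pool size); its
               real-valued output in [0, 1] feeds the next LIF layer as-is.

Architectures can be written as compact strings in the conventional
notation, e.g. ``"784-800-10"`` for an MLP or
``"28x28x1-15C5-P2-40C5-P2-300-10"`` for a spiking CNN, and parsed into a
layer chain with :func:`parse_architecture`.

Weights are initialized U[-1, 1] and then each post-synaptic neuron's
incoming-weight vector is rescaled to unit Euclidean norm, which balances
drive magnitude against the fixed firing threshold so that early activity is
neither silent nor saturated.  Biases start at zero and act as learnable
threshold offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lif import LIFConfig, LayerTrace, fire, forget_gate
from .surrogate import SurrogateSpec, smooth_activation

__all__ = [
    "LayerSpec",
    "NetworkParams",
    "parse_architecture",
    "init_uniform",
    "normalize_weights",
    "forward_network",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class LayerSpec:
    """One layer of the chain.

    ``in_shape``/``out_shape`` are per-sample shapes: ``(n,)`` for flat,
    ``(C, H, W)`` for image-shaped activity.
    """

    kind: str  # "dense" | "conv" | "avgpool"
    in_shape: tuple
    out_shape: tuple
    kernel: int = 0  # conv kernel or pool window size

    @property
    def n_out(self) -> int:
        return int(np.prod(self.out_shape))


@dataclass
class NetworkParams:
    """Per-layer weights and biases, aligned with the LayerSpec chain.

    Pooling layers carry ``None`` entries.  Dense weights have shape
    (n_out, n_in); conv weights (C_out, C_in, k, k); biases (n_out,) or
    (C_out,).
    """

    weights: list
    biases: list

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            weights=[None if w is None else w.copy() for w in self.weights],
            biases=[None if b is None else b.copy() for b in self.biases],
        )


def parse_architecture(arch: str) -> list[LayerSpec]:
    """Parse an architecture string into a LayerSpec chain.

    Tokens are dash-separated.  The first token is the input shape: a bare
    integer (flat) or ``HxWxC``.  Later tokens: ``<n>C<k>`` is a conv layer
    with n output channels and k x k kernel, ``P<k>`` a k x k average pool,
    and a bare integer a dense layer.
    """
    tokens = arch.replace(" ", "").split("-")
    first = tokens[0]
    if "x" in first.lower():
        h, w, c = (int(v) for v in first.lower().split("x"))
        shape: tuple = (c, h, w)
    else:
        shape = (int(first),)
    chain: list[LayerSpec] = []
    for tok in tokens[1:]:
        tl = tok.upper()
        if "C" in tl:
            n_ch, k = (int(v) for v in tl.split("C"))
            if len(shape) != 3:
                raise ValueError(f"conv layer {tok!r} needs image-shaped input, got {shape}")
            c, h, w = shape
            out = (n_ch, h - k + 1, w - k + 1)
            if out[1] < 1 or out[2] < 1:
                raise ValueError(f"kernel {k} too large for input {shape}")
            chain.append(LayerSpec("conv", shape, out, kernel=k))
            shape = out
        elif tl.startswith("P"):
            k = int(tl[1:])
            c, h, w = shape
            if h % k or w % k:
                raise ValueError(f"pool {k} does not tile input {shape}")
            out = (c, h // k, w // k)
            chain.append(LayerSpec("avgpool", shape, out, kernel=k))
            shape = out
        else:
            n = int(tl)
            chain.append(LayerSpec("dense", shape, (n,)))
            shape = (n,)
    if not chain:
        raise ValueError(f"architecture {arch!r} has no layers")
    return chain


def init_uniform(chain: list[LayerSpec], seed) -> NetworkParams:
    """Draw every weight from U[-1, 1]; biases start at zero."""
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for spec in chain:
        if spec.kind == "dense":
            n_in = int(np.prod(spec.in_shape))
            weights.append(rng.uniform(-1.0, 1.0, size=(spec.out_shape[0], n_in)))
            biases.append(np.zeros(spec.out_shape[0]))
        elif spec.kind == "conv":
            c_in = spec.in_shape[0]
            c_out = spec.out_shape[0]
            weights.append(
                rng.uniform(-1.0, 1.0, size=(c_out, c_in, spec.kernel, spec.kernel))
            )
            biases.append(np.zeros(c_out))
        else:
            weights.append(None)
            biases.append(None)
    return NetworkParams(weights=weights, biases=biases)


def normalize_weights(params: NetworkParams, mode: str = "l2") -> NetworkParams:
    """Rescale each neuron's incoming-weight vector.

    ``mode="l2"`` (default) divides by the Euclidean norm so every incoming
    vector has unit length; ``mode="sumsq"`` divides by the sum of squares
    instead, kept as a sensitivity switch for the alternative reading of the
    normalization rule.  Dense layers normalize rows; conv layers normalize
    each output channel over its full receptive field.
    """
    if mode not in ("l2", "sumsq"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    out = params.copy()
    for i, w in enumerate(out.weights):
        if w is None:
            continue
        flat = w.reshape(w.shape[0], -1)
        ss = (flat**2).sum(axis=1)
        if (ss == 0).any():
            raise ValueError("degenerate all-zero incoming-weight vector; resample")
        denom = np.sqrt(ss) if mode == "l2" else ss
        out.weights[i] = (flat / denom[:, None]).reshape(w.shape)
    return out


# ---------------------------------------------------------------------------
# forward pass


def _conv_drive(o: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Valid-mode correlation: o (S, C_in, H, W), W (C_out, C_in, k, k)."""
    k = W.shape[-1]
    win = np.lib.stride_tricks.sliding_window_view(o, (k, k), axis=(2, 3))
    # win: (S, C_in, H_out, W_out, k, k)
    return np.einsum("scijpq,ocpq->soij", win, W)


def _pool(o: np.ndarray, k: int) -> np.ndarray:
    s, c, h, w = o.shape
    return o.reshape(s, c, h // k, k, w // k, k).mean(axis=(3, 5))


def layer_drive(o_in: np.ndarray, spec: LayerSpec, W: np.ndarray) -> np.ndarray:
    """Synaptic drive of one layer from pre-synaptic activity at one step."""
    if spec.kind == "dense":
        return o_in.reshape(o_in.shape[0], -1) @ W.T
    if spec.kind == "conv":
        return _conv_drive(o_in, W)
    raise ValueError(f"{spec.kind} layers have no synaptic drive")


def forward_network(
    params: NetworkParams,
    chain: list[LayerSpec],
    input_spikes: np.ndarray,
    cfg: LIFConfig,
    surrogate: SurrogateSpec | None = None,
    relaxed: bool = False,
) -> list[LayerTrace]:
    """Unroll the whole network over the time window.

    Parameters
    ----------
    input_spikes
        Batched activity, shape (T, S, n) or (T, S, C, H, W).
    relaxed
        When True, the hard threshold is replaced by the smooth activation
        of ``surrogate`` and the exact forget gate is used, making the whole
        map differentiable (the gradient-oracle configuration).

    Returns one LayerTrace per layer; pooling traces store the pooled output
    in ``o`` with ``u`` and ``x`` zero.
    """
    if input_spikes.shape[0] != cfg.T:
        raise ValueError(
            f"input window {input_spikes.shape[0]} != configured T {cfg.T}"
        )
    per_sample = input_spikes.shape[2:]
    if per_sample != chain[0].in_shape:
        raise ValueError(
            f"input layout {per_sample} does not match first layer {chain[0].in_shape}"
        )
    if relaxed:
        if surrogate is None:
            raise ValueError("relaxed forward needs a surrogate spec")
        cfg = LIFConfig(
            tau=cfg.tau, v_th=cfg.v_th, dt=cfg.dt, T=cfg.T, forget_mode="exact"
        )
        act = SurrogateSpec(surrogate.family, surrogate.a, cfg.v_th)

    S = input_spikes.shape[1]
    traces: list[LayerTrace] = []
    below = np.asarray(input_spikes, dtype=float)
    for spec, W, b in zip(chain, params.weights, params.biases):
        shape = (cfg.T + 1, S) + spec.out_shape
        u = np.zeros(shape)
        o = np.zeros(shape)
        x = np.zeros(shape)
        if spec.kind == "avgpool":
            for t in range(1, cfg.T + 1):
                o[t] = _pool(below[t - 1], spec.kernel)
        else:
            bb = b if spec.kind == "dense" else b[:, None, None]
            for t in range(1, cfg.T + 1):
                x[t] = layer_drive(below[t - 1], spec, W)
                u[t] = u[t - 1] * forget_gate(o[t - 1], cfg) + x[t] + bb
                o[t] = smooth_activation(u[t], act) if relaxed else fire(u[t], cfg.v_th)
        traces.append(LayerTrace(u=u, o=o, x=x))
        below = o[1:]
    return traces


def firing_rates(trace: LayerTrace) -> np.ndarray:
    """Mean output activity over the window: shape (S, ...)."""
    return trace.o[1:].mean(axis=0)


def predict(output_trace: LayerTrace, T: int | None = None) -> np.ndarray:
    """Decode class labels as the arg-max of mean output firing rate.

    Ties break toward the lowest class index.
    """
    rates = firing_rates(output_trace)
    return rates.reshape(rates.shape[0], -1).argmax(axis=1)


def save_checkpoint(path, params: NetworkParams, manifest: dict | None = None) -> None:
    """Store parameters as an .npz archive with a JSON-encoded manifest."""
    import json

    arrays = {}
    for i, (w, b) in enumerate(zip(params.weights, params.biases)):
        if w is not None:
            arrays[f"W{i}"] = w
            arrays[f"b{i}"] = b
    arrays["n_layers"] = np.array(len(params.weights))
    arrays["manifest"] = np.frombuffer(
        json.dumps(manifest or {}).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[NetworkParams, dict]:
    import json

    with np.load(path) as z:
        n = int(z["n_layers"])
        weights = [z[f"W{i}"] if f"W{i}" in z else None for i in range(n)]
        biases = [z[f"b{i}"] if f"b{i}" in z else None for i in range(n)]
        manifest = json.loads(bytes(z["manifest"].tobytes()).decode())
    return NetworkParams(weights=weights, biases=biases), manifest
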