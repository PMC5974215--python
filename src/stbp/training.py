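"""Optimization loop, evaluation, and the two ablation harnesses.

Training runs the spiking forward pass (hard threshold, approximate forget
gate by default), the spatio-temporal backward pass with a chosen surrogate
derivative, and an SGD or Adam parameter update, over shuffled mini-batches
for a fixed number of epochs.  When the dataset carries rate images, each
presentation redraws the Bernoulli spike encoding — stochastic rate coding
acts as natural data augmentation; a frozen-train mode exists for exact
regression tests.

The two ablation harnesses mirror the method's analysis experiments:
sweeping the surrogate family and steepness, and deleting the temporal
gradient terms (SDBP) against the full recursion (STBP) on seed-paired
runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .engine import loss_mse_rate, stbp_backward
from .lif import LIFConfig
from .models import (
    LayerSpec,
    NetworkParams,
    firing_rates,
    forward_network,
    init_uniform,
    normalize_weights,
    predict,
)
from .encoding import SpikeDataset
from .surrogate import SurrogateSpec

__all__ = [
    "TrainConfig",
    "TrainLog",
    "AdamState",
    "DivergenceError",
    "sgd_update",
    "adam_update",
    "evaluate",
    "train",
    "ablate_surrogate",
    "ablate_temporal",
]


class DivergenceError(RuntimeError):
    """Raised when the loss or an update becomes non-finite; carries the
    last finite parameter set in ``last_good``."""

    def __init__(self, msg: str, last_good: NetworkParams | None = None):
        super().__init__(msg)
        self.last_good = last_good


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one training run.

    ``lr`` defaults to the tabulated SGD rate 0.5; Adam runs typically use
    a smaller value.  ``temporal=False`` trains with the SDBP ablation.
    ``fresh_encoding`` resamples Bernoulli spike trains at every
    presentation when the dataset provides rate images.
    """

    lr: float = 0.5
    optimizer: str = "sgd"
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    epochs: int = 50
    batch_size: int = 64
    seed: int = 0
    temporal: bool = True
    surrogate: SurrogateSpec = field(default_factory=SurrogateSpec)
    fresh_encoding: bool = True

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if not (0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise ValueError("Adam betas must lie in (0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class TrainLog:
    """Per-epoch bookkeeping of one run."""

    train_loss: list = field(default_factory=list)
    train_acc: list = field(default_factory=list)
    test_acc: list = field(default_factory=list)
    layer_rates: list = field(default_factory=list)  # mean firing rate per layer

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.train_loss) + 1),
                "train_loss": self.train_loss,
                "train_acc": self.train_acc,
                "test_acc": self.test_acc,
            }
        )
        if self.layer_rates:
            for i in range(len(self.layer_rates[0])):
                df[f"rate_layer{i}"] = [r[i] for r in self.layer_rates]
        return df


@dataclass
class AdamState:
    m: list
    v: list
    step: int = 0

    @classmethod
    def zeros_like(cls, params: NetworkParams) -> "AdamState":
        z = lambda a: None if a is None else np.zeros_like(a)
        return cls(
            m=[z(a) for a in params.weights + params.biases],
            v=[z(a) for a in params.weights + params.biases],
        )


def _check_finite(params: NetworkParams, last_good: NetworkParams) -> None:
    for a in params.weights + params.biases:
        if a is not None and not np.isfinite(a).all():
            raise DivergenceError("non-finite parameter update", last_good)


def sgd_update(params: NetworkParams, grads, lr: float) -> NetworkParams:
    """Plain gradient descent: theta <- theta - lr * dL/dtheta."""
    out = params.copy()
    last_good = params
    for arrs, gs in ((out.weights, grads.dW), (out.biases, grads.db)):
        for i, g in enumerate(gs):
            if g is not None:
                arrs[i] -= lr * g
    _check_finite(out, last_good)
    return out


def adam_update(
    params: NetworkParams, grads, moments: AdamState, cfg: TrainConfig
) -> tuple[NetworkParams, AdamState]:
    """One Adam step with bias-corrected first and second moments."""
    out = params.copy()
    t = moments.step + 1
    flat_params = out.weights + out.biases
    flat_grads = grads.dW + grads.db
    m_new, v_new = [], []
    for p, g, m, v in zip(flat_params, flat_grads, moments.m, moments.v):
        if p is None:
            m_new.append(None)
            v_new.append(None)
            continue
        m = cfg.beta1 * m + (1 - cfg.beta1) * g
        v = cfg.beta2 * v + (1 - cfg.beta2) * g * g
        mhat = m / (1 - cfg.beta1**t)
        vhat = v / (1 - cfg.beta2**t)
        p -= cfg.lr * mhat / (np.sqrt(vhat) + cfg.eps)
        m_new.append(m)
        v_new.append(v)
    _check_finite(out, params)
    return out, AdamState(m=m_new, v=v_new, step=t)


def _batch_input(ds: SpikeDataset, idx, fresh: bool, rng) -> np.ndarray:
    """Time-major batched input (T, S, ...) for the given sample indices."""
    if fresh and ds.rates is not None:
        rates = ds.rates[idx]
        T = ds.trains.shape[1]
        draws = rng.random((T,) + rates.shape)
        return (draws < rates[None]).astype(float)
    return np.moveaxis(ds.trains[idx], 1, 0).astype(float)


def evaluate(
    params: NetworkParams,
    chain: list[LayerSpec],
    ds: SpikeDataset,
    lif_cfg: LIFConfig,
    fresh: bool = False,
    rng=None,
) -> float:
    """Classification accuracy via rate decoding (arg-max of mean rate)."""
    rng = rng or np.random.default_rng(0)
    inp = _batch_input(ds, np.arange(len(ds)), fresh, rng)
    traces = forward_network(params, chain, inp, lif_cfg)
    return float((predict(traces[-1]) == ds.labels).mean())


def train(
    chain: list[LayerSpec],
    train_ds: SpikeDataset,
    test_ds: SpikeDataset | None,
    cfg: TrainConfig,
    lif_cfg: LIFConfig,
    init_params: NetworkParams | None = None,
) -> tuple[NetworkParams, TrainLog]:
    """Full training loop; deterministic given ``cfg.seed``.

    Returns the final parameters and the per-epoch log.  A non-finite loss
    aborts with :class:`DivergenceError` carrying the last good checkpoint.
    """
    rng = np.random.default_rng(cfg.seed)
    params = (
        init_params.copy()
        if init_params is not None
        else normalize_weights(init_uniform(chain, rng))
    )
    moments = AdamState.zeros_like(params)
    log = TrainLog()
    n = len(train_ds)
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        rate_sums = None
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            inp = _batch_input(train_ds, idx, cfg.fresh_encoding, rng)
            labels = train_ds.onehot[idx]
            traces = forward_network(params, chain, inp, lif_cfg)
            loss = loss_mse_rate(traces[-1], labels, lif_cfg.T, len(idx))
            if not np.isfinite(loss):
                raise DivergenceError("non-finite training loss", params)
            grads = stbp_backward(
                traces, params, chain, inp, labels, lif_cfg, cfg.surrogate,
                temporal=cfg.temporal,
            )
            if cfg.optimizer == "adam":
                params, moments = adam_update(params, grads, moments, cfg)
            else:
                params = sgd_update(params, grads, cfg.lr)
            losses.append(loss)
            batch_rates = [float(firing_rates(tr).mean()) for tr in traces]
            rate_sums = (
                batch_rates
                if rate_sums is None
                else [a + b for a, b in zip(rate_sums, batch_rates)]
            )
        n_batches = len(losses)
        log.train_loss.append(float(np.mean(losses)))
        log.layer_rates.append([r / n_batches for r in rate_sums])
        log.train_acc.append(
            evaluate(params, chain, train_ds, lif_cfg, cfg.fresh_encoding, rng)
        )
        log.test_acc.append(
            evaluate(params, chain, test_ds, lif_cfg, cfg.fresh_encoding, rng)
            if test_ds is not None
            else np.nan
        )
    return params, log


# ---------------------------------------------------------------------------
# ablation harnesses


def ablate_surrogate(
    task: tuple[SpikeDataset, SpikeDataset],
    chain: list[LayerSpec],
    families,
    a_values,
    seeds,
    base_cfg: TrainConfig,
    lif_cfg: LIFConfig,
) -> pd.DataFrame:
    """Accuracy sweep over surrogate (family, steepness) cells.

    Each cell trains from scratch once per seed; the returned frame has one
    row per (family, a, seed) plus ``mean``/``sd`` summary columns merged
    in, mirroring the shape-and-steepness analysis.
    """
    train_ds, test_ds = task
    rows = []
    for family in families:
        for a in a_values:
            for seed in seeds:
                cfg = replace(
                    base_cfg, seed=seed, surrogate=SurrogateSpec(family, float(a))
                )
                _, log = train(chain, train_ds, test_ds, cfg, lif_cfg)
                rows.append(
                    {
                        "family": family,
                        "a": float(a),
                        "seed": seed,
                        "test_acc": log.test_acc[-1],
                        "train_acc": log.train_acc[-1],
                    }
                )
    df = pd.DataFrame(rows)
    summary = (
        df.groupby(["family", "a"])["test_acc"].agg(["mean", "std"]).reset_index()
    )
    return df.merge(summary, on=["family", "a"])


def ablate_temporal(
    task: tuple[SpikeDataset, SpikeDataset],
    chain: list[LayerSpec],
    seeds,
    base_cfg: TrainConfig,
    lif_cfg: LIFConfig,
) -> pd.DataFrame:
    """Seed-paired comparison of full STBP against the SDBP ablation.

    Each seed trains both variants from the same initialization and data
    order.  Summary rows report mean accuracy per variant and the p-value
    of a paired sign test on per-seed wins.
    """
    train_ds, test_ds = task
    rows = []
    for seed in seeds:
        for temporal in (True, False):
            cfg = replace(base_cfg, seed=seed, temporal=temporal)
            _, log = train(chain, train_ds, test_ds, cfg, lif_cfg)
            rows.append(
                {
                    "method": "STBP" if temporal else "SDBP",
                    "seed": seed,
                    "test_acc": log.test_acc[-1],
                    "train_acc": log.train_acc[-1],
                }
            )
    df = pd.DataFrame(rows)
    wide = df.pivot(index="seed", columns="method", values="test_acc")
    wins = int((wide["STBP"] > wide["SDBP"]).sum())
    ties = int((wide["STBP"] == wide["SDBP"]).sum())
    n_informative = len(wide) - ties
    pval = (
        stats.binomtest(wins, n_informative, 0.5, alternative="greater").pvalue
        if n_informative
        else 1.0
    )
    df.attrs["stbp_mean"] = float(wide["STBP"].mean())
    df.attrs["sdbp_mean"] = float(wide["SDBP"].mean())
    df.attrs["sign_test_p"] = float(pval)
    return df
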