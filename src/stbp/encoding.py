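"""Input pipelines: rate encoding, synthetic tasks, and event-stream IO.

Static images become spike trains by Bernoulli rate coding: each pixel in
[0, 1] is its own firing probability, sampled independently at every time
step.  Event-camera-style data is represented as (timestamp, x, y,
polarity) streams with separate on/off channels and binned into binary
frames.

Two synthetic classification tasks exercise the two credit-assignment
regimes:

* the *rate task* has purely spatial class structure — classes differ in
  which inputs fire at high vs. low rate, so the mean-rate statistic is
  sufficient;
* the *temporal-pattern task* equalizes every per-input mean rate across
  classes and hides the label entirely in spike ordering (which input group
  leads inside each two-step event), so any classifier reading only mean
  rates is at chance and learning requires temporal credit assignment.

Readers/writers for the MNIST IDX container and the 5-byte address-event
(AER) record format are included so real datasets can be dropped in; all
tests run on synthetic fixtures generated by this module.
"""

from __future__ import annotations

import gzip
import struct
from dataclasses import dataclass, field

import numpy as np

from .lif import SpikeTrain

__all__ = [
    "StaticImage",
    "EventStream",
    "TaskSpec",
    "SpikeDataset",
    "bernoulli_encode",
    "make_rate_task",
    "make_temporal_pattern_task",
    "synthesize_event_stream",
    "events_to_spike_train",
    "read_idx_images",
    "read_idx_labels",
    "write_idx_images",
    "write_idx_labels",
    "read_aer",
    "write_aer",
]


@dataclass
class StaticImage:
    """A grayscale image with intensities in [0, 1] plus its class label."""

    pixels: np.ndarray
    label: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("pixel intensities must lie in [0, 1]")


@dataclass
class EventStream:
    """Address events: array of (timestamp_us, x, y, polarity) rows.

    Polarity 1 = on (brighter), 0 = off (darker).  Coordinates are 0-based,
    row-major, origin top-left; ``dims`` = (height, width).
    """

    events: np.ndarray  # (n, 4) int64
    dims: tuple = (34, 34)

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=np.int64).reshape(-1, 4)
        if len(self.events):
            if (np.diff(self.events[:, 0]) < 0).any():
                raise ValueError("event timestamps must be nondecreasing")
            h, w = self.dims
            if (
                self.events[:, 1].min() < 0
                or self.events[:, 1].max() >= w
                or self.events[:, 2].min() < 0
                or self.events[:, 2].max() >= h
            ):
                raise ValueError("event coordinates outside sensor dims")


@dataclass(frozen=True)
class TaskSpec:
    """Parameters of a synthetic classification task.

    rate_hi / rate_lo are the firing probabilities of a class's preferred /
    non-preferred input block in the rate task.  n_events, p_fire and
    jitter control the temporal-pattern task: each sample contains
    ``n_events`` two-step group-ordered events; with ``jitter`` the event
    slots are drawn at random per sample and each unit of the active group
    fires with probability ``p_fire`` (otherwise slots are evenly spaced
    and firing is certain, making all same-class samples identical).
    """

    n_classes: int = 2
    n_inputs: int = 20
    T: int = 10
    n_samples: int = 200
    seed: int = 0
    rate_hi: float = 0.8
    rate_lo: float = 0.1
    n_events: int = 3
    p_fire: float = 0.9
    jitter: bool = True
    test_fraction: float = 0.3

    def __post_init__(self) -> None:
        for r in (self.rate_hi, self.rate_lo, self.p_fire):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must lie in [0, 1]")
        if self.T < 1:
            raise ValueError("T must be >= 1")


@dataclass
class SpikeDataset:
    """Labelled spike trains, optionally with the rate images behind them.

    ``trains``: (S, T, ...) binary; ``labels``: (S,) int class indices.
    When ``rates`` is present (S, ...), training may redraw the Bernoulli
    encoding freshly at each presentation instead of reusing ``trains``.
    """

    trains: np.ndarray
    labels: np.ndarray
    n_classes: int
    rates: np.ndarray | None = None

    def __len__(self) -> int:
        return self.trains.shape[0]

    @property
    def onehot(self) -> np.ndarray:
        return np.eye(self.n_classes)[self.labels]

    def mean_rates(self) -> np.ndarray:
        """Per-sample per-input empirical firing rates (the rate-only view)."""
        return self.trains.mean(axis=1).reshape(len(self), -1)


def bernoulli_encode(image: StaticImage | np.ndarray, T: int, seed) -> SpikeTrain:
    """Rate-code an intensity image: P(spike at each step) = pixel value."""
    pix = image.pixels if isinstance(image, StaticImage) else np.asarray(image, float)
    if pix.min() < 0 or pix.max() > 1:
        raise ValueError("intensities must lie in [0, 1] before encoding")
    rng = np.random.default_rng(seed)
    data = (rng.random((T,) + pix.shape) < pix).astype(float)
    if data.ndim == 3:  # (T, H, W) -> single channel image layout
        return SpikeTrain(data[:, None, :, :], layout="image")
    layout = "flat" if data.ndim == 2 else "image"
    return SpikeTrain(data, layout=layout)


def _split(trains, labels, rates, spec: TaskSpec, rng) -> tuple[SpikeDataset, SpikeDataset]:
    S = len(labels)
    perm = rng.permutation(S)
    n_test = int(round(S * spec.test_fraction))
    te, tr = perm[:n_test], perm[n_test:]

    def take(idx):
        return SpikeDataset(
            trains=trains[idx],
            labels=labels[idx],
            n_classes=spec.n_classes,
            rates=None if rates is None else rates[idx],
        )

    return take(tr), take(te)


def make_rate_task(spec: TaskSpec) -> tuple[SpikeDataset, SpikeDataset]:
    """Spatial-rate classification: class c's input block fires at rate_hi.

    Inputs are divided into ``n_classes`` contiguous blocks; a sample of
    class c drives block c at ``rate_hi`` and all other inputs at
    ``rate_lo``, then Bernoulli-samples a T-step train.  Returns
    (train, test) with labels balanced within one sample.
    """
    if spec.rate_hi == spec.rate_lo:
        raise ValueError("degenerate task: identical rate profiles across classes")
    rng = np.random.default_rng(spec.seed)
    block = spec.n_inputs // spec.n_classes
    profiles = np.full((spec.n_classes, spec.n_inputs), spec.rate_lo)
    for c in range(spec.n_classes):
        profiles[c, c * block : (c + 1) * block] = spec.rate_hi
    labels = np.arange(spec.n_samples) % spec.n_classes
    rng.shuffle(labels)
    rates = profiles[labels]
    trains = (rng.random((spec.n_samples, spec.T, spec.n_inputs)) < rates[:, None, :]).astype(float)
    return _split(trains, labels, rates, spec, rng)


def make_temporal_pattern_task(spec: TaskSpec) -> tuple[SpikeDataset, SpikeDataset]:
    """Order-coded classification with class-identical mean rates.

    Inputs split into two groups A and B.  A sample contains ``n_events``
    non-overlapping two-step events; within an event, class 0 fires group A
    on the first step and group B on the second, class 1 the reverse.  Both
    groups are active for exactly ``n_events`` steps per sample in either
    class, so class-conditional per-input mean rates are identical and only
    the within-event ordering carries the label.
    """
    if spec.T < 2 * spec.n_events:
        raise ValueError("window too short for the requested number of events")
    rng = np.random.default_rng(spec.seed)
    half = spec.n_inputs // 2
    labels = np.arange(spec.n_samples) % 2
    rng.shuffle(labels)
    trains = np.zeros((spec.n_samples, spec.T, spec.n_inputs))
    slots = np.arange(0, spec.T - 1, 2)  # non-overlapping two-step windows
    for s in range(spec.n_samples):
        if spec.jitter:
            starts = rng.choice(slots, size=spec.n_events, replace=False)
        else:
            starts = slots[np.linspace(0, len(slots) - 1, spec.n_events).astype(int)]
        first, second = (slice(0, half), slice(half, None))
        if labels[s] == 1:
            first, second = second, first
        for t0 in starts:
            if spec.jitter:
                fire_a = rng.random(half) < spec.p_fire
                fire_b = rng.random(spec.n_inputs - half) < spec.p_fire
            else:
                fire_a = np.ones(half, bool)
                fire_b = np.ones(spec.n_inputs - half, bool)
            trains[s, t0, first] = fire_a.astype(float)
            trains[s, t0 + 1, second] = fire_b.astype(float)
    ds_tr, ds_te = _split(trains, labels, None, spec, rng)
    return ds_tr, ds_te


# ---------------------------------------------------------------------------
# event synthesis and binning


def synthesize_event_stream(
    image: StaticImage | np.ndarray,
    n_steps: int = 6,
    direction: tuple = (1, 1),
    canvas: tuple = (34, 34),
    contrast_threshold: float = 0.05,
    dt_us: int = 1000,
    background: float = 0.0,
    seed=None,
) -> EventStream:
    """Emulate a sensor saccade over a static image.

    The image is placed on a larger canvas of intensity ``background`` (the
    relative-shift margin) and translated one pixel per step along
    ``direction`` — one leg of the triangular saccade.  Wherever the
    intensity at a canvas pixel rises by more than ``contrast_threshold``
    an on event is emitted, and an off event where it falls; a scene with
    no intensity change (image uniform at the background level) therefore
    emits nothing.
    """
    pix = image.pixels if isinstance(image, StaticImage) else np.asarray(image, float)
    h, w = pix.shape
    H, W = canvas
    if h + abs(direction[0]) * n_steps > H or w + abs(direction[1]) * n_steps > W:
        raise ValueError("image plus motion exceeds the canvas")
    events = []

    def place(k: int) -> np.ndarray:
        frame = np.full(canvas, float(background))
        r0, c0 = k * direction[0], k * direction[1]
        frame[r0 : r0 + h, c0 : c0 + w] = pix
        return frame

    prev = place(0)
    for k in range(1, n_steps + 1):
        cur = place(k)
        diff = cur - prev
        for pol, mask in ((1, diff > contrast_threshold), (0, diff < -contrast_threshold)):
            rr, cc = np.nonzero(mask)
            for r, c in zip(rr, cc):
                events.append((k * dt_us, c, r, pol))
        prev = cur
    ev = np.array(sorted(events), dtype=np.int64).reshape(-1, 4)
    return EventStream(events=ev, dims=canvas)


def events_to_spike_train(
    stream: EventStream, T: int, dt: float = 1.0
) -> SpikeTrain:
    """Bin events into T frames of width dt (ms), two polarity channels.

    A bin with at least one event yields a single spike (binary clipping);
    channel 0 collects on events, channel 1 off events.  Events past the
    window are dropped; an empty stream gives an all-zero train.
    """
    h, w = stream.dims
    data = np.zeros((T, 2, h, w))
    if len(stream.events):
        ts, xs, ys, ps = stream.events.T
        bins = (ts / 1000.0 / dt).astype(int)
        keep = bins < T
        # channel 0 = on (pol 1), channel 1 = off (pol 0)
        data[bins[keep], 1 - ps[keep], ys[keep], xs[keep]] = 1.0
    return SpikeTrain(data, layout="image")


# ---------------------------------------------------------------------------
# file formats

_IDX_IMAGES_MAGIC = 2051
_IDX_LABELS_MAGIC = 2049


def _open(path, mode):
    p = str(path)
    return gzip.open(p, mode) if p.endswith(".gz") else open(p, mode)


def read_idx_images(path) -> list[StaticImage]:
    """Read an IDX image container (optionally gzipped), scaled to [0, 1]."""
    with _open(path, "rb") as fh:
        head = fh.read(16)
        if len(head) < 16:
            raise ValueError(f"truncated IDX header at byte {len(head)}")
        magic, n, rows, cols = struct.unpack(">IIII", head)
        if magic != _IDX_IMAGES_MAGIC:
            raise ValueError(f"bad IDX image magic {magic:#010x} at byte 0")
        raw = fh.read(n * rows * cols)
        if len(raw) != n * rows * cols:
            raise ValueError(f"truncated IDX payload at byte {16 + len(raw)}")
    arr = np.frombuffer(raw, dtype=np.uint8).reshape(n, rows, cols)
    return [StaticImage(pixels=a / 255.0) for a in arr]


def read_idx_labels(path) -> np.ndarray:
    with _open(path, "rb") as fh:
        head = fh.read(8)
        if len(head) < 8:
            raise ValueError(f"truncated IDX header at byte {len(head)}")
        magic, n = struct.unpack(">II", head)
        if magic != _IDX_LABELS_MAGIC:
            raise ValueError(f"bad IDX label magic {magic:#010x} at byte 0")
        raw = fh.read(n)
        if len(raw) != n:
            raise ValueError(f"truncated IDX payload at byte {8 + len(raw)}")
    return np.frombuffer(raw, dtype=np.uint8).copy()


def write_idx_images(images, path) -> None:
    arrs = [
        (np.clip(im.pixels if isinstance(im, StaticImage) else im, 0, 1) * 255)
        .round()
        .astype(np.uint8)
        for im in images
    ]
    rows, cols = arrs[0].shape
    with _open(path, "wb") as fh:
        fh.write(struct.pack(">IIII", _IDX_IMAGES_MAGIC, len(arrs), rows, cols))
        for a in arrs:
            fh.write(a.tobytes())


def write_idx_labels(labels, path) -> None:
    labels = np.asarray(labels, dtype=np.uint8)
    with _open(path, "wb") as fh:
        fh.write(struct.pack(">II", _IDX_LABELS_MAGIC, len(labels)))
        fh.write(labels.tobytes())


def read_aer(path, dims: tuple = (34, 34)) -> EventStream:
    """Read 5-byte AER records: x, y, then polarity bit + 23-bit timestamp."""
    with _open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) % 5:
        raise ValueError(
            f"truncated AER record at byte {len(raw) - len(raw) % 5}"
        )
    b = np.frombuffer(raw, dtype=np.uint8).reshape(-1, 5).astype(np.int64)
    x, y = b[:, 0], b[:, 1]
    pol = b[:, 2] >> 7
    ts = ((b[:, 2] & 0x7F) << 16) | (b[:, 3] << 8) | b[:, 4]
    return EventStream(events=np.stack([ts, x, y, pol], axis=1), dims=dims)


def write_aer(stream: EventStream, path) -> None:
    ev = stream.events
    if len(ev) and ev[:, 0].max() >= 1 << 23:
        raise ValueError("timestamp exceeds the 23-bit AER field")
    out = np.empty((len(ev), 5), dtype=np.uint8)
    out[:, 0] = ev[:, 1]
    out[:, 1] = ev[:, 2]
    out[:, 2] = (ev[:, 3] << 7) | ((ev[:, 0] >> 16) & 0x7F)
    out[:, 3] = (ev[:, 0] >> 8) & 0xFF
    out[:, 4] = ev[:, 0] & 0xFF
    with _open(path, "wb") as fh:
        fh.write(out.tobytes())
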