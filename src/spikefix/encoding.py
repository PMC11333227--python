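"""Image input pipeline: IDX files, nearest-neighbour downscaling, Poisson
rate coding with teacher channels, and synthetic digit fixtures.

Images are presented to the network as Poisson spike trains: during a
350 ms presentation window each pixel's relay neuron spikes independently
per 1 ms step with probability ``(intensity/255)·max_rate·dt``, so a white
pixel fires at ``max_rate_hz`` and a black pixel is silent.  During
training, the teacher channel of the current label fires at a constant
200 Hz over the same window.  A 150 ms silent pause separates
presentations (the network keeps decaying; nothing is skipped).

``max_rate_hz`` for full intensity is a free parameter of the encoding (the
hardware constant is not public); the default of 63.75 Hz follows the
unsupervised digit-classifier lineage this architecture descends from, and
is set in :class:`EncodingConfig`.

The synthetic generator produces 12×12 digit-like grayscale images from ten
fixed stroke prototypes (full-intensity strokes covering 15–30% of the
pixels, pairwise overlap below 40%) plus truncated Gaussian pixel noise —
enough structure to exercise every stage of the pipeline without any
dataset download.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from typing import Optional

import numpy as np

IMAGE_SIZE = 12
N_PIXELS = IMAGE_SIZE * IMAGE_SIZE


@dataclass(frozen=True)
class EncodingConfig:
    """Spike-encoding parameters (durations in ms, rates in Hz)."""

    present_ms: int = 350
    pause_ms: int = 150
    max_rate_hz: float = 63.75
    teacher_rate_hz: float = 200.0
    dt_ms: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be positive")
        for nm in ("present_ms", "pause_ms"):
            v = getattr(self, nm)
            if v <= 0 or v % self.dt_ms != 0:
                raise ValueError(f"{nm} must be a positive multiple of dt")

    @property
    def present_steps(self) -> int:
        return self.present_ms // self.dt_ms

    @property
    def pause_steps(self) -> int:
        return self.pause_ms // self.dt_ms

    @property
    def total_steps(self) -> int:
        return self.present_steps + self.pause_steps


@dataclass
class ImageSample:
    """A 12×12 grayscale image with an optional class label."""

    pixels: np.ndarray        # (12, 12) integers in [0, 255]
    label: Optional[int] = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.shape != (IMAGE_SIZE, IMAGE_SIZE):
            raise ValueError("pixels must be 12x12")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")


@dataclass
class SpikePlan:
    """Per-step boolean spike indicators for the input-layer neurons.

    Columns are ordered pixels first (144), then the teacher channels.
    All rows are false during the pause, and teacher columns are all false
    when no label was supplied (test mode).
    """

    spikes: np.ndarray        # (total_steps, 144 + n_teachers) bool
    n_teachers: int
    present_steps: int

    @property
    def n_inputs(self) -> int:
        return self.spikes.shape[1]

    def to_events(self) -> np.ndarray:
        """(step, neuron_id) event pairs, step-ordered."""
        step, nid = np.nonzero(self.spikes)
        return np.column_stack([step, nid])


# ---------------------------------------------------------------------------
# Resizing
# ---------------------------------------------------------------------------


def resize_nearest(image: np.ndarray, out_size: int = IMAGE_SIZE
                   ) -> np.ndarray:
    """Center-aligned nearest-neighbour downscale of a square image.

    Destination pixel (i, j) samples source pixel
    ``(floor((i+0.5)·n/out), floor((j+0.5)·n/out))``.
    """
    image = np.asarray(image)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("resize_nearest requires a square 2-D image")
    n = image.shape[0]
    idx = np.floor((np.arange(out_size) + 0.5) * n / out_size).astype(int)
    return image[np.ix_(idx, idx)]


# ---------------------------------------------------------------------------
# Poisson encoding
# ---------------------------------------------------------------------------


def poisson_encode(sample: ImageSample, cfg: EncodingConfig,
                   mode: str = "test", n_teachers: int = 10,
                   seed: Optional[int] = None) -> SpikePlan:
    """Encode one image as per-step Bernoulli spike indicators.

    Each pixel spikes with probability ``(intensity/255)·max_rate·dt`` per
    step during the presentation window; in ``train`` mode the labelled
    teacher channel spikes with probability ``teacher_rate·dt``.  The plan
    is fully reproducible from the seed (``cfg.seed`` unless overridden).
    """
    if mode not in ("train", "test"):
        raise ValueError(f"mode must be 'train' or 'test', got {mode!r}")
    if mode == "train" and sample.label is None:
        raise ValueError("teacher encoding requested for an unlabeled sample")
    if mode == "train" and not (0 <= sample.label < n_teachers):
        raise ValueError(f"label {sample.label} out of range")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    dt_s = cfg.dt_ms * 1e-3
    p_pix = (sample.pixels.astype(float).ravel() / 255.0) \
        * cfg.max_rate_hz * dt_s
    spikes = np.zeros((cfg.total_steps, N_PIXELS + n_teachers), dtype=bool)
    pres = cfg.present_steps
    spikes[:pres, :N_PIXELS] = \
        rng.random((pres, N_PIXELS)) < p_pix[None, :]
    if mode == "train":
        p_teach = cfg.teacher_rate_hz * dt_s
        spikes[:pres, N_PIXELS + sample.label] = rng.random(pres) < p_teach
    return SpikePlan(spikes, n_teachers, pres)


def write_events(plan: SpikePlan, path) -> None:
    """Export a spike plan as a two-column '(step neuron_id)' text file."""
    np.savetxt(path, plan.to_events(), fmt="%d", header="step neuron_id")


# ---------------------------------------------------------------------------
# IDX container format
# ---------------------------------------------------------------------------

_IDX_IMAGES_MAGIC = 0x00000803
_IDX_LABELS_MAGIC = 0x00000801


def _read_idx_array(path) -> np.ndarray:
    with open(path, "rb") as fh:
        head = fh.read(4)
        if len(head) < 4:
            raise ValueError(f"{path}: truncated IDX header")
        magic = struct.unpack(">i", head)[0]
        if magic == _IDX_IMAGES_MAGIC:
            ndim = 3
        elif magic == _IDX_LABELS_MAGIC:
            ndim = 1
        else:
            raise ValueError(f"{path}: bad IDX magic 0x{magic:08x}")
        dims = struct.unpack(f">{ndim}i", fh.read(4 * ndim))
        payload = fh.read()
    expected = int(np.prod(dims))
    if len(payload) < expected:
        raise ValueError(f"{path}: truncated IDX payload "
                         f"({len(payload)} < {expected} bytes)")
    return np.frombuffer(payload[:expected],
                         dtype=np.uint8).reshape(dims)


def read_idx(images_path, labels_path) -> tuple[np.ndarray, np.ndarray]:
    """Read an IDX image/label file pair, cross-checking the counts."""
    images = _read_idx_array(images_path)
    labels = _read_idx_array(labels_path)
    if images.ndim != 3:
        raise ValueError(f"{images_path}: not an IDX image file")
    if labels.ndim != 1:
        raise ValueError(f"{labels_path}: not an IDX label file")
    if images.shape[0] != labels.shape[0]:
        raise ValueError(
            f"count mismatch: {images.shape[0]} images vs "
            f"{labels.shape[0]} labels")
    return images, labels


def write_idx(images: np.ndarray, labels: np.ndarray, images_path,
              labels_path) -> None:
    """Write images/labels in the IDX layout (round-trips with read_idx)."""
    images = np.asarray(images, dtype=np.uint8)
    labels = np.asarray(labels, dtype=np.uint8)
    if images.ndim != 3 or labels.ndim != 1 \
            or images.shape[0] != labels.shape[0]:
        raise ValueError("need (n, h, w) images and matching (n,) labels")
    with open(images_path, "wb") as fh:
        fh.write(struct.pack(">4i", _IDX_IMAGES_MAGIC, *images.shape))
        fh.write(images.tobytes())
    with open(labels_path, "wb") as fh:
        fh.write(struct.pack(">2i", _IDX_LABELS_MAGIC, labels.shape[0]))
        fh.write(labels.tobytes())


# ---------------------------------------------------------------------------
# Synthetic digit fixtures
# ---------------------------------------------------------------------------

# Ten fixed stroke prototypes on the 12x12 grid: rings, bars, brackets and
# diagonals anchored at class-specific positions so that every mask covers
# 15-30% of the 144 pixels and every pair of masks shares < 40% of the
# smaller mask's pixels.


def _ring(cy, cx, r0, r1):
    yy, xx = np.mgrid[0:IMAGE_SIZE, 0:IMAGE_SIZE]
    d = np.hypot(yy - cy, xx - cx)
    return (d >= r0) & (d <= r1)


def _bar(r0, r1, c0, c1):
    m = np.zeros((IMAGE_SIZE, IMAGE_SIZE), dtype=bool)
    m[r0:r1 + 1, c0:c1 + 1] = True
    return m


def _diag(r0, c0, n, dr, dc, thick=2):
    m = np.zeros((IMAGE_SIZE, IMAGE_SIZE), dtype=bool)
    for k in range(n):
        r = int(round(r0 + k * dr))
        c = int(round(c0 + k * dc))
        for t in range(thick):
            if 0 <= r < IMAGE_SIZE and 0 <= c + t < IMAGE_SIZE:
                m[r, c + t] = True
    return m


def _prototype_masks() -> dict:
    return {
        0: _ring(6.5, 4.5, 2.2, 3.6),                       # large ring
        1: _bar(0, 11, 5, 6),                               # full-height bar
        2: _bar(4, 5, 1, 6) | _diag(6, 5, 4, 1, -1)         # zigzag
           | _bar(10, 11, 0, 5),
        3: _bar(2, 3, 6, 11) | _bar(6, 7, 7, 11)            # three right bars
           | _bar(10, 11, 6, 11),
        4: _bar(2, 9, 3, 4) | _bar(8, 9, 5, 9),             # post with foot
        5: _bar(3, 4, 0, 4) | _bar(5, 7, 0, 1)              # S-bracket
           | _bar(7, 8, 2, 5),
        6: _ring(4.0, 5.0, 1.8, 3.2),                       # mid ring
        7: _bar(1, 2, 0, 5) | _diag(3, 4, 9, 1, -0.45, 2),  # bar + diagonal
        8: _ring(2.2, 8.8, 1.3, 2.6)                        # stacked rings
           | _ring(7.2, 8.8, 1.3, 2.6),
        9: _ring(2.5, 6.5, 1.5, 2.8) | _bar(4, 10, 8, 9),   # ring with tail
    }


_PROTO_MASKS = _prototype_masks()


def class_prototype(label: int) -> np.ndarray:
    """The fixed 12×12 intensity-255 stroke prototype of one class."""
    if label not in _PROTO_MASKS:
        raise ValueError(f"no prototype for class {label}")
    return _PROTO_MASKS[label].astype(np.uint8) * 255


def synth_digits(n_classes: int, n_per_class: int, noise_sd: float,
                 seed: int) -> list:
    """Generate a balanced synthetic digit set.

    Each sample is its class prototype plus i.i.d. Gaussian pixel noise of
    standard deviation ``noise_sd`` (in intensity units), truncated to
    [0, 255].  Samples are interleaved by class and reproducible from the
    seed.
    """
    if not 1 <= n_classes <= 10:
        raise ValueError("n_classes must be between 1 and 10")
    rng = np.random.default_rng(seed)
    protos = [class_prototype(c).astype(float) for c in range(n_classes)]
    samples = []
    for i in range(n_per_class):
        for c in range(n_classes):
            img = protos[c]
            if noise_sd > 0:
                img = img + rng.normal(0.0, noise_sd, size=img.shape)
            img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
            samples.append(ImageSample(img, label=c))
    return samples
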