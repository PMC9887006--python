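"""Readers/writers for images, weight tables, and the synthetic fixture generator.

Real experiments consume MNIST-style IDX files; every automated test
instead runs on a synthetic digit-like dataset so the whole pipeline is
exercised without any download.  The generator emits three
class-separable templates (a hollow ring for "0", a center vertical bar
for "1", an S-curve for "2") rasterized at a chosen size, with
independent per-pixel flip noise; at zero noise the classes are
linearly separable by a +/-1 weight vector, so a planted model gives an
exact accuracy oracle.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .bnn import BNNModel, ImageSample
from .dualrail import binarize, discretize_3bit

__all__ = [
    "FormatError",
    "Dataset",
    "SynthSpec",
    "read_idx",
    "write_idx",
    "downscale",
    "read_pixel_grid",
    "synth_templates",
    "synth_dataset",
    "planted_model",
    "prepare_dataset",
    "read_weight_table",
    "write_weight_table",
]

_IDX_IMAGES_MAGIC = 2051
_IDX_LABELS_MAGIC = 2049
SUPPORTED_SCALES = (8, 12, 16, 28)


class FormatError(ValueError):
    """Malformed input file; readers never silently coerce."""


@dataclass
class Dataset:
    """A homogeneous collection of image samples.

    ``level_scheme`` is ``"binary"`` (levels +/-1) or ``"3bit"``
    (levels in {-4..-1, 1..4}); ``source`` is a free-form provenance
    tag ("synthetic", a file path, ...).
    """

    samples: list[ImageSample]
    level_scheme: str
    source: str = ""

    def __post_init__(self) -> None:
        if self.level_scheme not in ("binary", "3bit"):
            raise FormatError(f"unknown level scheme {self.level_scheme!r}")
        if self.samples:
            w, h, L = self.samples[0].width, self.samples[0].height, self.samples[0].max_level
            for s in self.samples:
                if (s.width, s.height, s.max_level) != (w, h, L):
                    raise FormatError("dataset samples must share dimensions and level scheme")

    def __len__(self) -> int:
        return len(self.samples)

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Stack to (X, y) for array-based training."""
        X = np.stack([s.levels for s in self.samples])
        y = np.asarray([s.true_label for s in self.samples])
        return X, y


@dataclass
class SynthSpec:
    """Parameters of the synthetic digit-like dataset."""

    n_per_class: int = 100
    size: int = 8
    classes: tuple[int, ...] = (0, 1)
    flip_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise FormatError("n_per_class must be >= 1")
        if self.size < 4:
            raise FormatError("size must be >= 4")
        if not set(self.classes) <= {0, 1, 2}:
            raise FormatError("classes must be a subset of {0, 1, 2}")
        if not (0.0 <= self.flip_prob < 0.5):
            raise FormatError("flip_prob must be in [0, 0.5)")


def _read_idx_header(data: bytes, magic: int, path) -> tuple[tuple[int, ...], int]:
    if len(data) < 4:
        raise FormatError(f"{path}: truncated IDX header")
    got = struct.unpack(">i", data[:4])[0]
    if got != magic:
        raise FormatError(f"{path}: bad IDX magic {got}, expected {magic}")
    ndim = data[3]
    header = 4 + 4 * ndim
    if len(data) < header:
        raise FormatError(f"{path}: truncated IDX dimension block")
    dims = struct.unpack(f">{ndim}i", data[4:header])
    return dims, header


def read_idx(images_path, labels_path) -> tuple[np.ndarray, np.ndarray]:
    """Read an IDX image/label file pair (big-endian, MNIST convention).

    Returns ``(images, labels)`` with intensities 0-255 preserved
    exactly as ``uint8`` arrays of shape (n, h, w) and (n,).
    """
    with open(images_path, "rb") as fh:
        data = fh.read()
    dims, header = _read_idx_header(data, _IDX_IMAGES_MAGIC, images_path)
    if len(dims) != 3:
        raise FormatError(f"{images_path}: image IDX must be 3-D, got {len(dims)}-D")
    n, h, w = dims
    if len(data) != header + n * h * w:
        raise FormatError(f"{images_path}: size mismatch with declared dimensions")
    images = np.frombuffer(data, dtype=np.uint8, offset=header).reshape(n, h, w)

    with open(labels_path, "rb") as fh:
        data = fh.read()
    dims, header = _read_idx_header(data, _IDX_LABELS_MAGIC, labels_path)
    if len(dims) != 1:
        raise FormatError(f"{labels_path}: label IDX must be 1-D")
    if dims[0] != n:
        raise FormatError(
            f"label count {dims[0]} does not match image count {n}"
        )
    if len(data) != header + dims[0]:
        raise FormatError(f"{labels_path}: size mismatch with declared dimensions")
    labels = np.frombuffer(data, dtype=np.uint8, offset=header).copy()
    return images.copy(), labels


def write_idx(images: np.ndarray, labels: np.ndarray, images_path, labels_path) -> None:
    """Write an IDX pair (the inverse of :func:`read_idx`; used for fixtures)."""
    images = np.asarray(images, dtype=np.uint8)
    labels = np.asarray(labels, dtype=np.uint8)
    n, h, w = images.shape
    with open(images_path, "wb") as fh:
        fh.write(struct.pack(">iiii", _IDX_IMAGES_MAGIC, n, h, w))
        fh.write(images.tobytes())
    with open(labels_path, "wb") as fh:
        fh.write(struct.pack(">ii", _IDX_LABELS_MAGIC, n))
        fh.write(labels.tobytes())


def _box_weights(src: int, dst: int) -> np.ndarray:
    """Overlap (dst x src) of output box cells with input cells, in input units."""
    w = np.zeros((dst, src))
    step = src / dst
    for i in range(dst):
        lo, hi = i * step, (i + 1) * step
        for j in range(int(np.floor(lo)), int(np.ceil(hi))):
            w[i, j] = min(hi, j + 1) - max(lo, j)
    return w


def downscale(image: np.ndarray, target: int) -> np.ndarray:
    """Block-average a square grayscale image down to ``target x target``.

    Area-weighted box resampling (exact block averaging when the sizes
    divide), then rounding back to 0-255.  ``target`` equal to the
    input side is the identity.
    """
    image = np.asarray(image)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise FormatError(f"downscale needs a square image, got shape {image.shape}")
    if target not in SUPPORTED_SCALES:
        raise FormatError(f"unsupported target size {target}, expected one of {SUPPORTED_SCALES}")
    side = image.shape[0]
    if target == side:
        return image.astype(np.uint8)
    if target > side:
        raise FormatError(f"cannot upscale {side} -> {target}")
    w = _box_weights(side, target)
    means = (w @ image.astype(np.float64) @ w.T) * (target / side) ** 2
    return np.clip(np.rint(means), 0, 255).astype(np.uint8)


def read_pixel_grid(path) -> np.ndarray:
    """Read a plain-text/CSV pixel grid: one row per line, comma or space separated."""
    rows: list[list[int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            try:
                rows.append([int(p) for p in parts])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer pixel value") from exc
    if not rows:
        raise FormatError(f"{path}: empty pixel grid")
    if len({len(r) for r in rows}) > 1:
        raise FormatError(f"{path}: ragged pixel grid")
    arr = np.asarray(rows, dtype=np.int64)
    if arr.min() < 0 or arr.max() > 255:
        raise FormatError(f"{path}: intensities must be in 0..255")
    return arr.astype(np.uint8)


def synth_templates(size: int) -> dict[int, np.ndarray]:
    """The three class templates as +/-1 grids of shape (size, size).

    0: hollow ring (square annulus inset by one pixel);
    1: center vertical bar two pixels wide;
    2: S-curve (top bar, upper-left side, middle bar, lower-right side,
    bottom bar).
    """
    if size < 4:
        raise FormatError("templates need size >= 4")
    lo, hi = 1, size - 2
    mid = size // 2

    ring = -np.ones((size, size), dtype=np.int64)
    ring[lo, lo : hi + 1] = 1
    ring[hi, lo : hi + 1] = 1
    ring[lo : hi + 1, lo] = 1
    ring[lo : hi + 1, hi] = 1

    bar = -np.ones((size, size), dtype=np.int64)
    bar[:, mid - 1 : mid + 1] = 1

    s_curve = -np.ones((size, size), dtype=np.int64)
    s_curve[lo, lo : hi + 1] = 1
    s_curve[mid, lo : hi + 1] = 1
    s_curve[hi, lo : hi + 1] = 1
    s_curve[lo:mid, lo] = 1
    s_curve[mid : hi + 1, hi] = 1

    return {0: ring, 1: bar, 2: s_curve}


def synth_dataset(spec: SynthSpec, level_scheme: str = "binary") -> Dataset:
    """Generate the synthetic digit-like dataset.

    Each sample starts from its class template mapped to intensities
    (+1 -> 255, -1 -> 0); every pixel is independently inverted with
    probability ``flip_prob``; intensities are then binarized or
    3-bit-discretized into levels.  Fully reproducible per seed.
    """
    templates = synth_templates(spec.size)
    rng = np.random.default_rng(spec.seed)
    to_level = binarize if level_scheme == "binary" else discretize_3bit
    max_level = 1 if level_scheme == "binary" else 4
    samples: list[ImageSample] = []
    for cls in spec.classes:
        intensity = np.where(templates[cls] > 0, 255, 0).astype(np.int64)
        for _ in range(spec.n_per_class):
            flips = rng.random(intensity.shape) < spec.flip_prob
            img = np.where(flips, 255 - intensity, intensity)
            levels = [to_level(int(v)) for v in img.reshape(-1)]
            samples.append(
                ImageSample(
                    np.asarray(levels), spec.size, spec.size, max_level, true_label=cls
                )
            )
    return Dataset(samples, level_scheme, source="synthetic")


def _balanced_sign(u: np.ndarray, t: np.ndarray) -> np.ndarray:
    """sign(u) with ties assigned to keep the tie cells' dot with ``t`` near 0."""
    w = np.where(u > 0, 1, np.where(u < 0, -1, 0)).astype(np.int64)
    c = 0
    for i in np.flatnonzero(w == 0):
        w[i] = -t[i] if c > 0 else t[i]
        c += w[i] * t[i]
    return w


def planted_model(size: int, classes: Sequence[int] = (0, 1)) -> BNNModel:
    """A +/-1 classifier built directly from the template sign differences.

    For two classes the rows are the (balanced) sign of the template
    difference and its negation, so the score pattern is one-hot by
    construction; for three classes each row contrasts one template
    against the sum of the others.  At zero flip noise this model
    classifies the synthetic dataset perfectly.
    """
    templates = synth_templates(size)
    ts = [templates[c].reshape(-1) for c in classes]
    if len(ts) == 2:
        w0 = _balanced_sign(ts[0] - ts[1], ts[0])
        weights = np.stack([w0, -w0])
    elif len(ts) > 2:
        total = np.sum(ts, axis=0)
        rows = [
            _balanced_sign(len(ts) * t - total, t) for t in ts
        ]
        weights = np.stack(rows)
    else:
        raise FormatError("planted_model needs at least 2 classes")
    return BNNModel(weights, tuple(classes))


def prepare_dataset(
    images: np.ndarray,
    labels: np.ndarray,
    level_scheme: str = "binary",
    scale: int | None = None,
    digit_filter: Sequence[int] | None = None,
    use_round_formula: bool = False,
    source: str = "",
) -> Dataset:
    """Turn raw intensity images into a level dataset.

    Optional steps in order: keep only ``digit_filter`` labels,
    block-average ``downscale`` to ``scale``, then binarize or 3-bit
    discretize and flatten row-major.
    """
    images = np.asarray(images)
    labels = np.asarray(labels)
    if digit_filter is not None:
        keep = np.isin(labels, list(digit_filter))
        images, labels = images[keep], labels[keep]
    if len(images) == 0:
        raise FormatError("no images left after filtering")
    max_level = 1 if level_scheme == "binary" else 4
    samples = []
    for img, lab in zip(images, labels):
        if scale is not None:
            img = downscale(img, scale)
        if level_scheme == "binary":
            levels = [binarize(int(v)) for v in np.asarray(img).reshape(-1)]
        else:
            levels = [
                discretize_3bit(int(v), use_round_formula)
                for v in np.asarray(img).reshape(-1)
            ]
        h, w = np.asarray(img).shape
        samples.append(
            ImageSample(np.asarray(levels), w, h, max_level, true_label=int(lab))
        )
    return Dataset(samples, level_scheme, source=source)


def write_weight_table(model: BNNModel, path) -> None:
    """Write weights as a plain-text +/-1 grid, one neuron per row."""
    with open(path, "w") as fh:
        for row in model.weights:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


def read_weight_table(path, class_labels: Sequence | None = None) -> BNNModel:
    """Read a +/-1 weight grid back into a model (lossless round trip)."""
    rows: list[list[int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            values = []
            for p in parts:
                if p not in ("1", "+1", "-1"):
                    raise FormatError(f"{path}:{lineno}: weight entries must be +1/-1, got {p!r}")
                values.append(1 if p in ("1", "+1") else -1)
            rows.append(values)
    if not rows:
        raise FormatError(f"{path}: empty weight table")
    if len({len(r) for r in rows}) > 1:
        raise FormatError(f"{path}: weight rows have unequal lengths")
    return BNNModel(np.asarray(rows), tuple(class_labels) if class_labels else ())
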