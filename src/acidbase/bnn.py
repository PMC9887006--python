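"""Binary neural-network inference, in silico and through the chemistry.

A single-layer network with weights constrained to {+1, -1} classifies a
flattened image by the sign of each neuron's weighted sum.  Chemically,
each pixel is encoded as a dual-rail pair, the weight is applied as a
direct (+1) or rail-swapped (-1) transfer, and the neuron's output pair
is formed by pooling one small aliquot from every pixel's pH rail (and
likewise for the complements).  Neutralization inside the pooled well
computes the weighted sum: the output pair's sign equals
``sign(sum_i w_i x_i)`` exactly in the noise-free model, because the
pooled proton excess is proportional to ``sum_i w_i x_i / L``.

Readout is either a pH indicator (per-neuron sign only; classification
is the unique positive neuron, otherwise UNDECIDED) or an actual pH
measurement (most acidic output wins), mirroring the two ways a plate
can be read.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .chem import Solution
from .dualrail import DualRail, EncodingError, decode, transfer_volumes_nL
from . import chem

__all__ = [
    "BNNModel",
    "ImageSample",
    "ReadoutMode",
    "UNDECIDED",
    "insilico_scores",
    "insilico_label",
    "chemical_neuron",
    "classify_chemical",
    "sample_matches",
    "match_rate",
    "accuracy",
]

DEFAULT_ALIQUOT_NL = 200.0


class _Undecided:
    """Sentinel classification when the indicator readout is not one-hot."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "UNDECIDED"


UNDECIDED = _Undecided()


@dataclass(frozen=True)
class BNNModel:
    """A binary-weight single-layer classifier: one weight row per class neuron."""

    weights: np.ndarray
    class_labels: tuple = ()

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.int64)
        if w.ndim != 2:
            raise ValueError(f"weights must be 2-D (classes x pixels), got {w.ndim}-D")
        if w.shape[0] < 2:
            raise ValueError("a classifier needs at least 2 class neurons")
        if not np.isin(w, (-1, 1)).all():
            raise ValueError("weights must all be +1 or -1")
        object.__setattr__(self, "weights", w)
        labels = tuple(self.class_labels) if len(self.class_labels) else tuple(range(w.shape[0]))
        if len(labels) != w.shape[0]:
            raise ValueError("need one class label per weight row")
        object.__setattr__(self, "class_labels", labels)

    @property
    def n_classes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.weights.shape[1]


@dataclass(frozen=True)
class ImageSample:
    """A flattened image of signed levels plus optional ground truth.

    ``levels`` is row-major (left to right, top to bottom); every level
    is a nonzero integer with ``|level| <= max_level`` (1 for binary
    images, 4 for the 3-bit scheme).
    """

    levels: np.ndarray
    width: int
    height: int
    max_level: int = 1
    true_label: object = None

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels, dtype=np.int64)
        if lv.ndim != 1 or lv.size != self.width * self.height:
            raise ValueError(
                f"levels must be a flat vector of length {self.width * self.height}"
            )
        if (lv == 0).any():
            raise ValueError("levels must be nonzero: 0 has no dual-rail encoding")
        if (np.abs(lv) > self.max_level).any():
            raise ValueError(f"|level| exceeds max_level = {self.max_level}")
        object.__setattr__(self, "levels", lv)

    @property
    def n_pixels(self) -> int:
        return self.levels.size


class ReadoutMode(Enum):
    """How neuron outputs are read: indicator color (sign) or measured pH."""

    INDICATOR = "indicator"
    PH = "ph"


def _check_dims(x: ImageSample, model: BNNModel) -> None:
    if model.n_pixels != x.n_pixels:
        raise ValueError(
            f"model expects {model.n_pixels} pixels but sample has {x.n_pixels}"
        )


def insilico_scores(x: ImageSample, model: BNNModel) -> np.ndarray:
    """Exact integer weighted sums, one per class neuron: s_j = sum_i w_ji x_i."""
    _check_dims(x, model)
    return model.weights @ x.levels


def insilico_label(x: ImageSample, model: BNNModel, return_tie: bool = False):
    """Argmax over neuron scores; ties go to the lowest neuron index.

    With ``return_tie=True`` returns ``(label, tie_flag)`` so callers
    can surface ambiguous classifications.
    """
    s = insilico_scores(x, model)
    idx = int(np.argmax(s))
    label = model.class_labels[idx]
    if return_tie:
        return label, bool((s == s[idx]).sum() > 1)
    return label


def chemical_neuron(
    x: ImageSample,
    weight_row: Sequence[int] | np.ndarray,
    unit_volume_uL: float = 2.4,
    aliquot_nL: float = DEFAULT_ALIQUOT_NL,
    stock_mM: float = 100.0,
    dilution_mode: str = "constant",
    noise=None,
    rng: np.random.Generator | None = None,
) -> DualRail:
    """Compute one neuron's output pair by encoding and pooling every pixel.

    Per pixel: encode the level, apply the binary weight as an optional
    rail swap, then transfer ``aliquot_nL`` from the pixel's pH rail
    into the output pH well and likewise for the complement.  The
    floating-point operations mirror the picklist simulator transfer
    for transfer, so a noise-free simulated run reproduces this result
    bit-for-bit.

    ``noise`` is an optional volume-noise model (see
    :class:`acidbase.robot.NoiseModel`); each physical transfer volume
    (reagent, water, pooling aliquot, per rail) is independently scaled
    by ``1 + eps``.
    """
    w = np.asarray(weight_row, dtype=np.int64)
    if w.ndim != 1 or w.size != x.n_pixels:
        raise ValueError("weight row length must equal the pixel count")
    if not np.isin(w, (-1, 1)).all():
        raise ValueError("weights must be +1 or -1")
    if noise is not None and rng is None:
        rng = noise.rng()

    def eps() -> float:
        return 0.0 if noise is None else noise.sample(rng)

    # Per-rail accumulators for the two pooled output wells.
    ph_vol = ph_acid = ph_base = 0.0
    co_vol = co_acid = co_base = 0.0
    aliquot_uL = aliquot_nL / 1000.0

    levels = x.levels
    L = x.max_level
    for i in range(levels.size):
        sign = 1 if int(levels[i]) * int(w[i]) > 0 else -1
        reagent_nL, water_nL = transfer_volumes_nL(
            int(levels[i]), L, unit_volume_uL, dilution_mode
        )
        # Each rail is an independent well: one reagent transfer plus one
        # water transfer, each with its own volume-noise draw.
        for rail in ("ph", "comp"):
            r_uL = (reagent_nL / 1000.0) * (1.0 + eps()) if noise is not None else reagent_nL / 1000.0
            w_uL = (water_nL / 1000.0) * (1.0 + eps()) if (noise is not None and water_nL > 0.0) else water_nL / 1000.0
            reagent_umol = stock_mM * r_uL / 1000.0
            rail_vol = r_uL + w_uL
            v = aliquot_uL * (1.0 + eps()) if noise is not None else aliquot_uL
            frac = v / rail_vol
            amt = reagent_umol * frac
            # rail is acid when it carries the positive side of the signal
            rail_is_acid = (sign > 0) == (rail == "ph")
            if rail == "ph":
                ph_vol += v
                if rail_is_acid:
                    ph_acid += amt
                else:
                    ph_base += amt
            else:
                co_vol += v
                if rail_is_acid:
                    co_acid += amt
                else:
                    co_base += amt
    return DualRail(
        Solution(ph_vol, ph_acid, ph_base),
        Solution(co_vol, co_acid, co_base),
    )


def _neuron_outputs(x, model, **kw) -> list[DualRail]:
    _check_dims(x, model)
    return [chemical_neuron(x, model.weights[j], **kw) for j in range(model.n_classes)]


def classify_chemical(
    x: ImageSample,
    model: BNNModel,
    mode: ReadoutMode = ReadoutMode.INDICATOR,
    tol_pH: float = 1e-9,
    **neuron_kwargs,
):
    """Classify through the chemistry.

    INDICATOR mode reads only each neuron's sign (the indicator color):
    the answer is the unique neuron whose pair is (acid, base), and
    UNDECIDED when no neuron or several neurons are positive.  PH mode
    measures the output wells and picks the most acidic pH rail, which
    resolves the cases the indicator cannot.
    """
    outs = _neuron_outputs(x, model, **neuron_kwargs)
    if mode is ReadoutMode.PH:
        phs = [chem.ph(d.ph_rail) for d in outs]
        return model.class_labels[int(np.argmin(phs))]
    signs = [decode(d, tol_pH) for d in outs]
    if signs.count(1) == 1:
        return model.class_labels[signs.index(1)]
    return UNDECIDED


def sample_matches(x: ImageSample, model: BNNModel, **neuron_kwargs) -> bool:
    """Does the indicator readout agree with the in-silico classification?

    True iff the noise-free chemical sign pattern is one-hot positive at
    the in-silico argmax neuron.  A sample whose scores all share one
    sign cannot match: the indicator sees no unique positive well even
    though the argmax may be correct.
    """
    _check_dims(x, model)
    idx = int(np.argmax(insilico_scores(x, model)))
    signs = [decode(d) for d in _neuron_outputs(x, model, **neuron_kwargs)]
    return signs[idx] == 1 and signs.count(1) == 1


def match_rate(dataset, model: BNNModel, **neuron_kwargs) -> float:
    """Percentage of samples where chemistry and in-silico network agree."""
    samples = list(getattr(dataset, "samples", dataset))
    if not samples:
        raise ValueError("match_rate needs a non-empty dataset")
    hits = sum(sample_matches(x, model, **neuron_kwargs) for x in samples)
    return 100.0 * hits / len(samples)


def accuracy(dataset, model: BNNModel) -> float:
    """Percentage of samples whose in-silico argmax equals the true label."""
    samples = list(getattr(dataset, "samples", dataset))
    if not samples:
        raise ValueError("accuracy needs a non-empty dataset")
    hits = sum(insilico_label(x, model) == x.true_label for x in samples)
    return 100.0 * hits / len(samples)
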