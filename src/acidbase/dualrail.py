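"""Dual-rail encoding of signed discrete values as (pH rail, complementary rail) pairs.

A logical +1 (TRUE) is the ordered pair (acid, base); -1 (FALSE) is
(base, acid).  Negation is therefore free: swap the rails.  Magnitudes
beyond +/-1 are encoded by diluting both rails so that the rail
concentration is ``stock * |value| / L`` for a maximum encoded value L
(the 3-bit scheme uses L = 4 with the eight levels
{-4,-3,-2,-1,1,2,3,4}; zero is deliberately unencodable because a
neutral pair carries no readable sign).
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .chem import SignState, Solution, dilute, make_stock, sign_state

__all__ = [
    "DualRail",
    "EncodingError",
    "transfer_volumes_nL",
    "encode_level",
    "invert",
    "apply_weight",
    "decode",
    "discretize_3bit",
    "binarize",
    "flatten",
]

DEFAULT_UNIT_VOLUME_UL = 2.4
DEFAULT_STOCK_MM = 100.0


class EncodingError(ValueError):
    """Invalid level, malformed dual-rail pair, or bad raster input."""


@dataclass(frozen=True, slots=True)
class DualRail:
    """Ordered pair of solutions carrying one signed value.

    ``ph_rail`` carries the value's sign directly (acidic = +1);
    ``comp_rail`` carries the complement.  A well-formed encoded value
    has rails of opposite sign (or both neutral for a degenerate 0).
    """

    ph_rail: Solution
    comp_rail: Solution


def _check_level(value: int, max_level: int) -> None:
    if max_level < 1:
        raise EncodingError(f"maximum encoded value must be >= 1, got {max_level}")
    if value == 0:
        raise EncodingError("level 0 cannot be encoded: a neutral pair has no sign")
    if abs(value) > max_level:
        raise EncodingError(f"|level| = {abs(value)} exceeds maximum encoded value {max_level}")


def transfer_volumes_nL(
    value: int,
    max_level: int,
    unit_volume_uL: float = DEFAULT_UNIT_VOLUME_UL,
    dilution_mode: str = "eq5",
) -> tuple[float, float]:
    """Reagent and water volumes (nL) that realize a level on one rail.

    Two dilution modes produce the same rail concentration
    ``stock * |value| / max_level`` and the same solute amount per
    pooled aliquot:

    * ``"eq5"`` — transfer one full unit of reagent and add
      ``unit * (L/|v|) - unit`` of water; total rail volume grows as
      ``unit * L / |v|``.
    * ``"constant"`` — transfer ``unit * |v| / L`` of reagent topped up
      with water to exactly one unit; rail volume is constant, which
      keeps low-magnitude levels inside a low-dead-volume well's
      working range.

    Volumes are returned in nL (converted from the uL unit volume once,
    here) so every consumer derives uL as ``nL / 1000.0`` and all code
    paths agree bit-for-bit.
    """
    _check_level(value, max_level)
    if not (unit_volume_uL > 0.0):
        raise EncodingError(f"unit volume must be > 0, got {unit_volume_uL!r}")
    unit_nL = unit_volume_uL * 1000.0
    v = abs(value)
    if dilution_mode == "eq5":
        reagent_nL = unit_nL
        water_nL = unit_nL * max_level / v - unit_nL
    elif dilution_mode == "constant":
        reagent_nL = unit_nL * v / max_level
        water_nL = unit_nL - reagent_nL
    else:
        raise EncodingError(f"unknown dilution mode {dilution_mode!r}")
    return reagent_nL, water_nL


def encode_level(
    value: int,
    max_level: int = 1,
    unit_volume_uL: float = DEFAULT_UNIT_VOLUME_UL,
    stock_mM: float = DEFAULT_STOCK_MM,
    dilution_mode: str = "eq5",
) -> DualRail:
    """Encode a signed level as a freshly prepared dual-rail pair.

    A positive level puts acid on the pH rail and base on the
    complement; a negative level reverses the rails.  Both rails
    receive the same reagent volume and the same water volume, so the
    pair stays symmetric under rail swap.
    """
    reagent_nL, water_nL = transfer_volumes_nL(value, max_level, unit_volume_uL, dilution_mode)
    reagent_uL = reagent_nL / 1000.0
    water_uL = water_nL / 1000.0
    acid = dilute(make_stock("acid", stock_mM, reagent_uL), water_uL)
    base = dilute(make_stock("base", stock_mM, reagent_uL), water_uL)
    if value > 0:
        return DualRail(acid, base)
    return DualRail(base, acid)


def invert(d: DualRail) -> DualRail:
    """Logical negation: exchange the two rails.  No chemistry happens."""
    return DualRail(d.comp_rail, d.ph_rail)


def apply_weight(d: DualRail, w: int) -> DualRail:
    """Multiply an encoded value by a binary weight: +1 is identity, -1 inverts."""
    if w == 1:
        return d
    if w == -1:
        return invert(d)
    raise EncodingError(f"weight must be +1 or -1, got {w!r}")


def decode(d: DualRail, tol_pH: float = 1e-9) -> int:
    """Read a dual-rail pair back to {+1, -1, 0}.

    +1 when (acid, base), -1 when (base, acid), 0 when both rails are
    neutral.  Rails sharing a non-neutral sign mean the pair was never
    a valid encoding and raise :class:`EncodingError`.
    """
    a = sign_state(d.ph_rail, tol_pH)
    b = sign_state(d.comp_rail, tol_pH)
    if a is SignState.ACID and b is SignState.BASE:
        return 1
    if a is SignState.BASE and b is SignState.ACID:
        return -1
    if a is SignState.NEUTRAL and b is SignState.NEUTRAL:
        return 0
    raise EncodingError(f"malformed dual-rail pair: rails read ({a.name}, {b.name})")


# Upper bounds (inclusive) of the eight 3-bit intensity ranges
# 0:32, 33:64, 65:96, 97:128, 129:160, 161:192, 193:224, 225:255.
_3BIT_UPPER = (32, 64, 96, 128, 160, 192, 224, 255)


def discretize_3bit(intensity: int, use_round_formula: bool = False) -> int:
    """Map an 8-bit intensity to a 3-bit level in {-4..-1, 1..4}.

    The default uses the eight inclusive intensity ranges, which never
    produce 0.  ``use_round_formula=True`` instead applies
    ``round(8 * x / 255) - 4``, kept for comparison; note it can yield
    0 (near mid-scale), which the range table cannot, and it disagrees
    with the table at range boundaries.
    """
    if not (0 <= int(intensity) <= 255):
        raise EncodingError(f"intensity must be in 0..255, got {intensity!r}")
    intensity = int(intensity)
    if use_round_formula:
        return round(8 * intensity / 255.0) - 4
    idx = bisect_left(_3BIT_UPPER, intensity)
    return idx - 4 if idx < 4 else idx - 3


def binarize(intensity: int) -> int:
    """Threshold an 8-bit intensity at 128: below -> -1, at or above -> +1."""
    if not (0 <= int(intensity) <= 255):
        raise EncodingError(f"intensity must be in 0..255, got {intensity!r}")
    return -1 if int(intensity) < 128 else 1


def flatten(image: Sequence[Sequence[int]] | np.ndarray) -> list[int]:
    """Flatten a rectangular grid row-major (left to right, top to bottom)."""
    if not isinstance(image, np.ndarray):
        rows = list(image)
        if len(rows) == 0 or len({len(row) for row in rows}) > 1:
            raise EncodingError("grid must be rectangular with at least one row")
    try:
        arr = np.asarray(image, dtype=np.int64)
    except (ValueError, TypeError) as exc:
        raise EncodingError(f"grid is not a rectangular numeric array: {exc}") from exc
    if arr.ndim != 2 or arr.size == 0:
        raise EncodingError(f"expected a non-empty 2-D grid, got shape {arr.shape}")
    return [int(v) for v in arr.reshape(-1)]
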