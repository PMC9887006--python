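"""Strong-acid / strong-base solution bookkeeping and exact pH arithmetic.

All computation in this package ultimately reduces to mixing fully
dissociated strong acids (HX -> H3O+ + X-) and strong bases
(YOH -> Y+ + OH-) in water.  Because neutralization
(H3O+ + OH- -> 2 H2O) couples the two species, the pH of a mixture is
set by the *excess* of protons over hydroxide together with water
autoionization.  This module keeps exact books on volume and solute
amounts and solves the charge-balance quadratic for [H+].

Units are fixed internally: volumes in microliters (uL) and amounts in
micromoles (umol), so that umol/uL == mol/L and no unit conversion is
ever needed when forming concentrations.

Model assumptions
-----------------
* Ideal solutions: unit activity coefficients.
* Strong electrolytes completely dissociated.
* Water autoionization with Kw = 1e-14 (25 C), so near-neutral mixtures
  have a well-defined pH instead of a divide-by-zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import IntEnum
from typing import Iterable, Sequence

#: Water autoionization constant [H+][OH-] at 25 C (mol^2/L^2).
KW = 1e-14

__all__ = [
    "KW",
    "ChemistryError",
    "NeutralSignalError",
    "Solution",
    "SignState",
    "make_stock",
    "mix",
    "ph",
    "sign_state",
    "dilute",
    "take_aliquot",
]


class ChemistryError(ValueError):
    """Invalid solution state or chemically impossible operation."""


class NeutralSignalError(ChemistryError):
    """A NEUTRAL signal arose where strict mode forbids one."""


@dataclass(frozen=True, slots=True)
class Solution:
    """A volume of water carrying strong-acid protons and strong-base hydroxide.

    Parameters
    ----------
    volume_uL : float
        Total volume in microliters, >= 0.
    acid_umol : float
        Micromoles of strong-acid protons contributed by HX.
    base_umol : float
        Micromoles of strong-base hydroxide contributed by YOH.

    All three fields are additive under mixing; neutralization is
    accounted for only when a pH is requested, so mixing never loses
    information.
    """

    volume_uL: float
    acid_umol: float = 0.0
    base_umol: float = 0.0

    def __post_init__(self) -> None:
        if not (self.volume_uL >= 0.0):  # catches NaN too
            raise ChemistryError(f"volume must be >= 0 uL, got {self.volume_uL!r}")
        if not (self.acid_umol >= 0.0):
            raise ChemistryError(f"acid amount must be >= 0 umol, got {self.acid_umol!r}")
        if not (self.base_umol >= 0.0):
            raise ChemistryError(f"base amount must be >= 0 umol, got {self.base_umol!r}")
        if self.acid_umol + self.base_umol > 0.0 and self.volume_uL == 0.0:
            raise ChemistryError("a solution with solutes must have positive volume")

    def __add__(self, other: "Solution") -> "Solution":
        if not isinstance(other, Solution):
            return NotImplemented
        return Solution(
            self.volume_uL + other.volume_uL,
            self.acid_umol + other.acid_umol,
            self.base_umol + other.base_umol,
        )

    @property
    def net_excess_M(self) -> float:
        """Proton excess (acid - base) concentration in mol/L."""
        if self.volume_uL <= 0.0:
            raise ChemistryError("net excess undefined for zero volume")
        return (self.acid_umol - self.base_umol) / self.volume_uL


class SignState(IntEnum):
    """Ternary sign of a solution: ACID (+1), NEUTRAL (0), BASE (-1)."""

    ACID = 1
    NEUTRAL = 0
    BASE = -1


def make_stock(kind: str, concentration_mM: float, volume_uL: float) -> Solution:
    """Prepare a stock solution of strong acid, strong base, or water.

    Parameters
    ----------
    kind : {"acid", "base", "water"}
    concentration_mM : float
        Stock concentration in millimolar (ignored but required to be 0
        for water).
    volume_uL : float
        Volume in microliters.
    """
    if kind not in ("acid", "base", "water"):
        raise ChemistryError(f"unknown stock kind {kind!r}")
    if not (volume_uL >= 0.0):
        raise ChemistryError(f"stock volume must be >= 0, got {volume_uL!r}")
    if not (concentration_mM >= 0.0):
        raise ChemistryError(f"stock concentration must be >= 0, got {concentration_mM!r}")
    if kind == "water":
        if concentration_mM != 0.0:
            raise ChemistryError("water stock cannot carry solute")
        return Solution(volume_uL, 0.0, 0.0)
    # mM * uL / 1000 = umol  (this exact expression is shared with the
    # picklist simulator so the two paths agree bit-for-bit)
    amount = concentration_mM * volume_uL / 1000.0
    if kind == "acid":
        return Solution(volume_uL, amount, 0.0)
    return Solution(volume_uL, 0.0, amount)


def mix(parts: Sequence[Solution] | Iterable[Solution]) -> Solution:
    """Pool solutions; volume and both solute amounts add exactly.

    Summation is sequential left-to-right so that replaying the same
    transfers through the picklist simulator reproduces the identical
    floating-point result.
    """
    it = iter(parts)
    try:
        total = next(it)
    except StopIteration:
        raise ChemistryError("cannot mix an empty sequence of solutions") from None
    for part in it:
        total = total + part
    return total


def ph(s: Solution) -> float:
    """pH of a strong acid/base mixture, exact to water autoionization.

    With D = ([H+] from acid) - ([OH-] from base) in mol/L, charge
    balance plus Kw gives [H+]^2 - D.[H+] - Kw = 0, whose positive root
    is ``([D + sqrt(D^2 + 4 Kw)] / 2)``.  Strictly decreasing and
    continuous in D; D = 0 gives exactly pH 7.
    """
    if s.volume_uL <= 0.0:
        raise ChemistryError("pH undefined for zero volume")
    d = (s.acid_umol - s.base_umol) / s.volume_uL
    root = math.sqrt(d * d + 4.0 * KW)
    # conjugate form on the basic side avoids catastrophic cancellation
    # between d and the square root when [OH-] dominates
    h = (d + root) / 2.0 if d >= 0.0 else (2.0 * KW) / (root - d)
    return -math.log10(h)


def sign_state(s: Solution, tol_pH: float = 1e-9, strict: bool = False) -> SignState:
    """Classify a solution as ACID, BASE, or NEUTRAL around pH 7.

    ``tol_pH`` is the half-width of the NEUTRAL band in pH units.  With
    ``strict=True`` a NEUTRAL outcome raises :class:`NeutralSignalError`
    instead of being returned, for circuits that must never sit on the
    decision boundary.
    """
    if tol_pH < 0.0:
        raise ChemistryError("tol_pH must be >= 0")
    p = ph(s)
    if p < 7.0 - tol_pH:
        return SignState.ACID
    if p > 7.0 + tol_pH:
        return SignState.BASE
    if strict:
        raise NeutralSignalError(f"solution is NEUTRAL (pH {p:.6f}) in strict mode")
    return SignState.NEUTRAL


def dilute(s: Solution, water_uL: float) -> Solution:
    """Add pure water: volume grows, solute amounts are unchanged."""
    if not (water_uL >= 0.0):
        raise ChemistryError(f"water volume must be >= 0, got {water_uL!r}")
    if water_uL == 0.0:
        return s
    return Solution(s.volume_uL + water_uL, s.acid_umol, s.base_umol)


def take_aliquot(s: Solution, volume_uL: float) -> tuple[Solution, Solution]:
    """Withdraw ``volume_uL`` from ``s``; return ``(aliquot, remainder)``.

    Solute moves in proportion to volume.  The proportional expressions
    are the ones the picklist simulator replays, so a directly computed
    pooling and a simulated pooling agree bit-for-bit.
    """
    if not (volume_uL >= 0.0):
        raise ChemistryError(f"aliquot volume must be >= 0, got {volume_uL!r}")
    if volume_uL > s.volume_uL:
        raise ChemistryError(
            f"cannot withdraw {volume_uL} uL from a {s.volume_uL} uL solution"
        )
    frac = volume_uL / s.volume_uL if s.volume_uL > 0.0 else 0.0
    acid = s.acid_umol * frac
    base = s.base_umol * frac
    aliquot = Solution(volume_uL, acid, base)
    rem_vol = s.volume_uL - volume_uL
    rem_acid = s.acid_umol - acid
    rem_base = s.base_umol - base
    # guard sub-ulp negatives from the subtraction
    remainder = Solution(max(rem_vol, 0.0), max(rem_acid, 0.0), max(rem_base, 0.0))
    return aliquot, remainder
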