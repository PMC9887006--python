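"""Majority/inversion logic over dual-rail acid-base signals.

Mixing an odd number of equal droplets computes the majority function:
neutralization cancels acid against base pairwise and leaves the more
abundant species, so the mixed pair decodes to +1 iff more than half
the inputs were +1.  Majority plus inversion (a free rail swap) is a
functionally complete set; two-input gates are built by adding a
constant bias droplet as a third input (bias -1 gives AND, bias +1
gives OR; NAND/NOR swap the output rails at zero cost).

Circuits are DAGs of gates over named nets, described either in code
or in a minimal line-oriented netlist dialect::

    # comment
    inputs a b
    outputs y0 y1
    n1 = INV(a)
    y0 = AND(n1, b)
    y1 = MAJ(a, b, c)
    c  = CONST(+1)

Cascaded gates attenuate (each mixing stage averages concentrations,
moving every net's pH toward 7), so evaluation supports the signal
restoration the chemistry would need in practice: replacing each gate
output with a fresh full-strength pair of the same sign before fan-out.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .chem import NeutralSignalError, mix, ph
from .dualrail import (
    DEFAULT_STOCK_MM,
    DEFAULT_UNIT_VOLUME_UL,
    DualRail,
    EncodingError,
    decode,
    encode_level,
    invert,
)

__all__ = [
    "CircuitError",
    "Gate",
    "Circuit",
    "TraceEntry",
    "majority",
    "gate_eval",
    "restore",
    "evaluate_circuit",
    "build_decoder_2to4",
    "parse_netlist",
    "format_netlist",
]

GATE_KINDS = ("MAJ", "INV", "AND", "OR", "NAND", "NOR", "CONST")
_BINARY = ("AND", "OR", "NAND", "NOR")


class CircuitError(ValueError):
    """Malformed gate, netlist, or circuit graph."""


@dataclass(frozen=True, slots=True)
class Gate:
    """One logic gate: ``output = kind(inputs)``."""

    kind: str
    inputs: tuple[str, ...]
    output: str
    const_value: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in GATE_KINDS:
            raise CircuitError(f"unknown gate kind {self.kind!r}")
        n = len(self.inputs)
        if self.kind == "MAJ":
            if n < 3 or n % 2 == 0:
                raise CircuitError(
                    f"MAJ needs an odd number >= 3 of inputs, got {n} "
                    "(an even mix can neutralize)"
                )
        elif self.kind == "INV":
            if n != 1:
                raise CircuitError(f"INV takes exactly 1 input, got {n}")
        elif self.kind in _BINARY:
            if n != 2:
                raise CircuitError(f"{self.kind} takes exactly 2 inputs, got {n}")
        else:  # CONST
            if n != 0:
                raise CircuitError("CONST takes no inputs")
            if self.const_value not in (1, -1):
                raise CircuitError("CONST needs const_value of +1 or -1")


class Circuit:
    """A DAG of gates over named nets.

    Every net must have exactly one driver: a primary input, or one
    gate output.  The topological evaluation order is computed once,
    deterministically, with ties broken by gate declaration order.
    """

    def __init__(
        self,
        gates: Sequence[Gate],
        primary_inputs: Sequence[str],
        primary_outputs: Sequence[str],
    ) -> None:
        self.gates = tuple(gates)
        self.primary_inputs = tuple(primary_inputs)
        self.primary_outputs = tuple(primary_outputs)
        self._validate()
        self.order = self._topological_order()

    def _validate(self) -> None:
        drivers: dict[str, str] = {}
        for name in self.primary_inputs:
            if name in drivers:
                raise CircuitError(f"duplicate primary input {name!r}")
            drivers[name] = "input"
        for g in self.gates:
            if g.output in drivers:
                raise CircuitError(f"net {g.output!r} has more than one driver")
            drivers[g.output] = "gate"
        for g in self.gates:
            for net in g.inputs:
                if net not in drivers:
                    raise CircuitError(f"gate input net {net!r} is undriven")
        for net in self.primary_outputs:
            if net not in drivers:
                raise CircuitError(f"primary output {net!r} is undriven")
        self.nets = tuple(drivers)

    def _topological_order(self) -> tuple[Gate, ...]:
        # Kahn's algorithm; the ready queue is kept in declaration order
        # so traces are reproducible.
        produced = set(self.primary_inputs)
        pending = list(self.gates)
        order: list[Gate] = []
        while pending:
            ready = [g for g in pending if all(i in produced for i in g.inputs)]
            if not ready:
                cyclic = sorted(g.output for g in pending)
                raise CircuitError(f"netlist contains a cycle through nets {cyclic}")
            for g in ready:
                order.append(g)
                produced.add(g.output)
            pending = [g for g in pending if g not in order]
        return tuple(order)

    def gate_depth(self) -> dict[str, int]:
        """Depth of each net: 0 for primary inputs/CONST, else 1 + max input depth."""
        depth = {n: 0 for n in self.primary_inputs}
        for g in self.order:
            depth[g.output] = 0 if g.kind == "CONST" else 1 + max(
                depth[i] for i in g.inputs
            )
        return depth


def majority(inputs: Sequence[DualRail]) -> DualRail:
    """Mix an odd number of dual-rail pairs rail-wise; the majority sign survives.

    The output pH rail pools every input pH rail and likewise for the
    complements, so ``decode(out) = +1`` iff more than half the inputs
    decode to +1 (for equal volumes and concentrations).
    """
    n = len(inputs)
    if n == 0 or n % 2 == 0:
        raise CircuitError(
            f"majority requires an odd number of inputs, got {n}: "
            "an even split would neutralize"
        )
    return DualRail(
        mix([d.ph_rail for d in inputs]),
        mix([d.comp_rail for d in inputs]),
    )


def gate_eval(
    kind: str,
    a: DualRail,
    b: DualRail | None = None,
    unit_volume_uL: float = DEFAULT_UNIT_VOLUME_UL,
    stock_mM: float = DEFAULT_STOCK_MM,
) -> DualRail:
    """Evaluate one primitive gate chemically.

    AND/OR add a fresh bias droplet (-1 / +1) as the third majority
    input; NAND/NOR additionally swap the output rails (the crossed
    output lines of the schematic); INV is a pure rail swap.
    """
    if kind == "INV":
        if b is not None:
            raise CircuitError("INV takes a single operand")
        return invert(a)
    if kind not in _BINARY:
        raise CircuitError(f"gate_eval does not handle kind {kind!r}")
    if b is None:
        raise CircuitError(f"{kind} needs two operands")
    bias_sign = -1 if kind in ("AND", "NAND") else 1
    bias = encode_level(bias_sign, 1, unit_volume_uL, stock_mM)
    out = majority([a, b, bias])
    if kind in ("NAND", "NOR"):
        out = invert(out)
    return out


def restore(
    d: DualRail,
    unit_volume_uL: float = DEFAULT_UNIT_VOLUME_UL,
    stock_mM: float = DEFAULT_STOCK_MM,
    tol_pH: float = 1e-9,
) -> DualRail:
    """Replace an attenuated signal with fresh full-strength stock of its sign."""
    sign = decode(d, tol_pH)
    if sign == 0:
        raise NeutralSignalError("cannot restore a NEUTRAL signal: its sign is lost")
    return encode_level(sign, 1, unit_volume_uL, stock_mM)


@dataclass(frozen=True, slots=True)
class TraceEntry:
    """pH-rail observation of one net during evaluation."""

    net: str
    depth: int
    pH: float
    sign: int


def evaluate_circuit(
    circuit: Circuit,
    inputs: Mapping[str, int],
    restoration: str = "after-every-gate",
    unit_volume_uL: float = DEFAULT_UNIT_VOLUME_UL,
    stock_mM: float = DEFAULT_STOCK_MM,
    strict: bool = False,
    tol_pH: float = 1e-9,
) -> tuple[dict[str, int], list[TraceEntry]]:
    """Run a circuit through the chemistry, gate by gate in topological order.

    Parameters
    ----------
    inputs : mapping net -> {+1, -1}
        Value for every primary input.
    restoration : {"after-every-gate", "none"}
        With restoration each gate output is replaced by a fresh
        full-concentration pair of the same sign before fan-out, which
        makes arbitrarily deep circuits exact; without it signals
        attenuate toward pH 7 with depth.
    strict : bool
        Raise :class:`NeutralSignalError` if any net decodes to 0.

    Returns
    -------
    (outputs, trace)
        Decoded sign for every primary output, and a per-net trace of
        (net, depth, pH-rail pH, sign) in evaluation order.
    """
    if restoration not in ("after-every-gate", "none"):
        raise CircuitError(f"unknown restoration policy {restoration!r}")
    missing = [n for n in circuit.primary_inputs if n not in inputs]
    if missing:
        raise CircuitError(f"unassigned primary inputs: {missing}")
    depth = circuit.gate_depth()

    signals: dict[str, DualRail] = {}
    trace: list[TraceEntry] = []

    def observe(net: str, d: DualRail) -> None:
        sign = decode(d, tol_pH)
        if strict and sign == 0:
            raise NeutralSignalError(f"net {net!r} is NEUTRAL in strict mode")
        trace.append(TraceEntry(net, depth[net], ph(d.ph_rail), sign))

    for net in circuit.primary_inputs:
        v = inputs[net]
        if v not in (1, -1):
            raise CircuitError(f"primary input {net!r} must be +1 or -1, got {v!r}")
        signals[net] = encode_level(v, 1, unit_volume_uL, stock_mM)
        observe(net, signals[net])

    for g in circuit.order:
        if g.kind == "CONST":
            out = encode_level(g.const_value, 1, unit_volume_uL, stock_mM)
        elif g.kind == "MAJ":
            out = majority([signals[i] for i in g.inputs])
        elif g.kind == "INV":
            out = gate_eval("INV", signals[g.inputs[0]])
        else:
            out = gate_eval(
                g.kind, signals[g.inputs[0]], signals[g.inputs[1]], unit_volume_uL, stock_mM
            )
        observe(g.output, out)
        if restoration == "after-every-gate" and g.kind not in ("CONST",):
            sign = decode(out, tol_pH)
            if sign != 0:
                out = encode_level(sign, 1, unit_volume_uL, stock_mM)
        signals[g.output] = out

    outputs = {net: decode(signals[net], tol_pH) for net in circuit.primary_outputs}
    return outputs, trace


def build_decoder_2to4() -> Circuit:
    """The 2-bit decoder: output k is +1 exactly for input code k.

    Input ``a`` is the high bit, ``b`` the low bit (+1 reads as bit 1),
    so code = 2*[a=+1] + [b=+1].  Built from INV and biased AND blocks.
    """
    gates = [
        Gate("INV", ("a",), "na"),
        Gate("INV", ("b",), "nb"),
        Gate("AND", ("na", "nb"), "y0"),
        Gate("AND", ("na", "b"), "y1"),
        Gate("AND", ("a", "nb"), "y2"),
        Gate("AND", ("a", "b"), "y3"),
    ]
    return Circuit(gates, ["a", "b"], ["y0", "y1", "y2", "y3"])


def parse_netlist(text: str) -> Circuit:
    """Parse the line-oriented netlist dialect (see module docstring)."""
    primary_inputs: list[str] = []
    primary_outputs: list[str] = []
    gates: list[Gate] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        lowered = line.lower()
        if lowered.startswith("inputs"):
            primary_inputs.extend(line.split()[1:])
            continue
        if lowered.startswith("outputs"):
            primary_outputs.extend(line.split()[1:])
            continue
        if "=" not in line:
            raise CircuitError(f"line {lineno}: expected 'net = KIND(args)': {raw!r}")
        out, expr = (part.strip() for part in line.split("=", 1))
        if "(" not in expr or not expr.endswith(")"):
            raise CircuitError(f"line {lineno}: malformed gate expression {expr!r}")
        kind, argstr = expr.split("(", 1)
        kind = kind.strip().upper()
        args = [a.strip() for a in argstr[:-1].split(",") if a.strip()]
        if kind == "CONST":
            if len(args) != 1 or args[0] not in ("+1", "1", "-1"):
                raise CircuitError(f"line {lineno}: CONST takes +1 or -1")
            gates.append(Gate("CONST", (), out, 1 if args[0] in ("+1", "1") else -1))
        else:
            gates.append(Gate(kind, tuple(args), out))
    if not primary_inputs and not gates:
        raise CircuitError("empty netlist")
    return Circuit(gates, primary_inputs, primary_outputs)


def format_netlist(circuit: Circuit) -> str:
    """Serialize a circuit back to the netlist dialect (round-trips with parse)."""
    lines = [
        "inputs " + " ".join(circuit.primary_inputs),
        "outputs " + " ".join(circuit.primary_outputs),
    ]
    for g in circuit.gates:
        if g.kind == "CONST":
            lines.append(f"{g.output} = CONST({'+1' if g.const_value == 1 else '-1'})")
        else:
            lines.append(f"{g.output} = {g.kind}({', '.join(g.inputs)})")
    return "\n".join(lines) + "\n"
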