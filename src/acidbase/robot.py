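"""Liquid-handler picklist compilation, simulation, and validation.

The wet protocol encodes an image into a 1536-well low-dead-volume
plate (two wells per pixel per neuron, order of the acid/base pair set
by ``sign(pixel) * weight``), pools a small aliquot from every pixel
well into per-neuron output wells on the 384-well stock plate, and
reads the outputs.  This module compiles those steps into an ordered
transfer list (an Echo-style picklist), replays picklists through the
exact chemistry of :mod:`acidbase.chem`, and validates them against
plate working volumes and droplet granularity.

A transfer from a *stock* well moves solute at the well's declared
concentration (withdrawing liquid from a uniform stock never changes
its concentration), so a noise-free simulated run reproduces the
directly computed :func:`acidbase.bnn.chemical_neuron` output
bit-for-bit.  Volume noise scales each transferred volume by
``1 + eps`` with eps drawn from a bounded distribution, emulating the
instrument's stated maximum deviation from target volume.
"""

from __future__ import annotations

import copy
import csv
from dataclasses import dataclass, field

import numpy as np

from .bnn import BNNModel, ImageSample
from .chem import Solution, make_stock
from .dualrail import transfer_volumes_nL

__all__ = [
    "PlateSpec",
    "PLATE_384PP",
    "PLATE_1536LDV",
    "RobotError",
    "CapacityError",
    "TransferError",
    "Plate",
    "Transfer",
    "Picklist",
    "NoiseModel",
    "Violation",
    "well_name",
    "parse_well",
    "layout_stock_plate",
    "PicklistCompiler",
    "simulate_picklist",
    "validate_picklist",
    "write_picklist_csv",
    "read_picklist_csv",
    "write_plate_csv",
]

DEFAULT_GRANULARITY_NL = 25.0


class RobotError(ValueError):
    """Invalid plate layout, transfer, or picklist."""


class CapacityError(RobotError):
    """A well would exceed its plate's working volume."""


class TransferError(RobotError):
    """A transfer reads an empty/undefined well or underflows its source."""


@dataclass(frozen=True, slots=True)
class PlateSpec:
    """Geometry and working volume of a well plate type."""

    name: str
    rows: int
    cols: int
    min_fill_uL: float
    max_fill_uL: float

    def __post_init__(self) -> None:
        if not (0 <= self.min_fill_uL < self.max_fill_uL):
            raise RobotError("need 0 <= min_fill < max_fill")

    @property
    def n_wells(self) -> int:
        return self.rows * self.cols


#: 384-well polypropylene source plate: 10-60 uL working volume.
PLATE_384PP = PlateSpec("384PP", 16, 24, 10.0, 60.0)
#: 1536-well low-dead-volume plate: 1-4 uL working volume.
PLATE_1536LDV = PlateSpec("1536LDV", 32, 48, 1.0, 4.0)


def well_name(row: int, col: int) -> str:
    """0-based (row, col) -> plate convention name, e.g. (0, 0) -> 'A1'."""
    if row < 0 or col < 0:
        raise RobotError("row/col must be >= 0")
    letters = chr(ord("A") + row) if row < 26 else "A" + chr(ord("A") + row - 26)
    return f"{letters}{col + 1}"


def parse_well(name: str, spec: PlateSpec) -> tuple[int, int]:
    """Well name -> 0-based (row, col), validated against the plate spec."""
    i = 0
    while i < len(name) and name[i].isalpha():
        i += 1
    if i == 0 or i > 2 or not name[i:].isdigit():
        raise RobotError(f"malformed well name {name!r}")
    letters = name[:i].upper()
    row = (ord(letters[0]) - ord("A")) if i == 1 else 26 + ord(letters[1]) - ord("A")
    col = int(name[i:]) - 1
    if not (0 <= row < spec.rows and 0 <= col < spec.cols):
        raise RobotError(f"well {name!r} outside {spec.name} ({spec.rows}x{spec.cols})")
    return row, col


@dataclass
class Plate:
    """Named plate instance: spec, well contents, and stock annotations.

    ``stock`` maps wells that hold a uniform prepared reagent to their
    ``(kind, concentration_mM)``; the simulator moves solute out of
    those wells at the declared concentration.
    """

    name: str
    spec: PlateSpec
    wells: dict[str, Solution] = field(default_factory=dict)
    stock: dict[str, tuple[str, float]] = field(default_factory=dict)

    def fill(self, well: str, solution: Solution) -> None:
        parse_well(well, self.spec)
        if solution.volume_uL > self.spec.max_fill_uL:
            raise CapacityError(
                f"{solution.volume_uL} uL exceeds {self.spec.name} max fill "
                f"{self.spec.max_fill_uL} uL in {self.name}:{well}"
            )
        self.wells[well] = solution

    def total_volume_uL(self) -> float:
        return float(sum(s.volume_uL for s in self.wells.values()))


@dataclass(frozen=True, slots=True)
class Transfer:
    """One liquid movement: src plate/well -> dst plate/well, volume in nL."""

    src_plate: str
    src_well: str
    dst_plate: str
    dst_well: str
    volume_nL: float

    def __post_init__(self) -> None:
        if not (self.volume_nL > 0.0):
            raise RobotError(f"transfer volume must be > 0 nL, got {self.volume_nL!r}")


@dataclass
class Picklist:
    """An ordered, replayable sequence of transfers."""

    transfers: list[Transfer] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.transfers)

    def __iter__(self):
        return iter(self.transfers)

    def __add__(self, other: "Picklist") -> "Picklist":
        return Picklist(self.transfers + other.transfers)


@dataclass
class NoiseModel:
    """Bounded volume noise: each transfer volume is scaled by 1 + eps.

    ``uniform`` draws eps ~ U[-max_fraction, +max_fraction] (the
    instrument spec states only a maximum deviation); the
    ``truncated-gaussian`` mode draws from N(0, (max/2)^2) clipped to
    the same bounds.
    """

    max_fraction: float = 0.10
    seed: int = 0
    distribution: str = "uniform"

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_fraction < 1.0):
            raise RobotError("max_fraction must be in [0, 1)")
        if self.distribution not in ("uniform", "truncated-gaussian"):
            raise RobotError(f"unknown noise distribution {self.distribution!r}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def sample(self, rng: np.random.Generator) -> float:
        if self.max_fraction == 0.0:
            return 0.0
        if self.distribution == "uniform":
            return float(rng.uniform(-self.max_fraction, self.max_fraction))
        eps = float(rng.normal(0.0, self.max_fraction / 2.0))
        return float(np.clip(eps, -self.max_fraction, self.max_fraction))


def layout_stock_plate(
    acid_rows: int = 4,
    base_rows: int = 4,
    water_rows: int = 2,
    fill_uL: float = 50.0,
    concentration_mM: float = 100.0,
    spec: PlateSpec = PLATE_384PP,
    name: str = "stock",
) -> Plate:
    """Prepare the source plate: rows of acid, then base, then water.

    Every listed well is filled with ``fill_uL`` of its reagent and
    annotated as a uniform stock at the given concentration.
    """
    n_rows = acid_rows + base_rows + water_rows
    if n_rows > spec.rows:
        raise CapacityError(f"{n_rows} stock rows exceed the {spec.rows} rows of {spec.name}")
    plate = Plate(name, spec)
    kinds = ["acid"] * acid_rows + ["base"] * base_rows + ["water"] * water_rows
    for row, kind in enumerate(kinds):
        conc = concentration_mM if kind in ("acid", "base") else 0.0
        for col in range(spec.cols):
            well = well_name(row, col)
            plate.fill(well, make_stock(kind, conc, fill_uL))
            plate.stock[well] = (kind, conc)
    return plate


class _StockCursor:
    """Deterministic rotation over a reagent's stock wells.

    Each well yields at most ``fill - min_fill`` of usable volume; the
    cursor advances to the next well of the same kind when the current
    one cannot supply a requested transfer.
    """

    def __init__(self, plate: Plate, kind: str) -> None:
        self.plate = plate
        self.wells = [w for w, (k, _) in plate.stock.items() if k == kind]
        if not self.wells:
            raise RobotError(f"stock plate has no {kind!r} wells")
        self.idx = 0
        budget = lambda w: plate.wells[w].volume_uL - plate.spec.min_fill_uL
        self.remaining = [budget(w) for w in self.wells]

    def draw(self, volume_nL: float) -> str:
        v_uL = volume_nL / 1000.0
        while self.idx < len(self.wells) and self.remaining[self.idx] < v_uL - 1e-9:
            self.idx += 1
        if self.idx >= len(self.wells):
            raise TransferError(
                f"stock exhausted: no well can supply {v_uL} uL without "
                "dropping below the plate's minimum fill"
            )
        self.remaining[self.idx] -= v_uL
        return self.wells[self.idx]


class PicklistCompiler:
    """Compile an image + model into encoding and pooling picklists.

    The compiler owns the well bookkeeping: which encoding well belongs
    to which (neuron, pixel, rail), where each neuron's output pair
    lives on the source plate, and which stock well serves each
    transfer.  ``compile_encoding`` must run before ``compile_pooling``.
    """

    def __init__(
        self,
        stock_plate: Plate | None = None,
        enc_plate_name: str = "enc",
        enc_spec: PlateSpec = PLATE_1536LDV,
        unit_volume_uL: float = 2.4,
        dilution_mode: str = "constant",
        granularity_nL: float = DEFAULT_GRANULARITY_NL,
    ) -> None:
        self.stock_plate = stock_plate if stock_plate is not None else layout_stock_plate()
        self.enc_plate_name = enc_plate_name
        self.enc_spec = enc_spec
        self.unit_volume_uL = unit_volume_uL
        self.dilution_mode = dilution_mode
        self.granularity_nL = granularity_nL
        self._cursors = {
            kind: _StockCursor(self.stock_plate, kind) for kind in ("acid", "base", "water")
        }
        self._enc_wells: list[str] | None = None  # flat (neuron-major) rail wells
        self._sample: ImageSample | None = None
        self._model: BNNModel | None = None
        self.neuron_output_wells: list[tuple[str, str]] = []

    def initial_plates(self) -> dict[str, Plate]:
        """Fresh copies of the plates a simulation of these picklists starts from."""
        return {
            self.stock_plate.name: copy.deepcopy(self.stock_plate),
            self.enc_plate_name: Plate(self.enc_plate_name, self.enc_spec),
        }

    def compile_encoding(
        self, x: ImageSample, model: BNNModel, check_capacity: bool = True
    ) -> Picklist:
        """Encode every pixel for every neuron into consecutive rail wells.

        For each neuron, for each pixel in flatten order, two reagent
        transfers land in consecutive wells: acid first when
        ``sign(pixel) * weight`` is positive, base first otherwise.
        Water transfers for sub-maximal levels are appended after the
        reagent phase, mirroring the two-phase wet protocol.
        """
        if model.n_pixels != x.n_pixels:
            raise RobotError("model pixel count must equal the sample's")
        n_wells = model.n_classes * x.n_pixels * 2
        if n_wells > self.enc_spec.n_wells:
            raise CapacityError(
                f"need {n_wells} encoding wells but {self.enc_spec.name} has "
                f"{self.enc_spec.n_wells}"
            )
        enc_wells = [
            well_name(i // self.enc_spec.cols, i % self.enc_spec.cols)
            for i in range(n_wells)
        ]
        reagent_transfers: list[Transfer] = []
        water_transfers: list[Transfer] = []
        well_fill_nL: dict[str, float] = {}
        for j in range(model.n_classes):
            for i in range(x.n_pixels):
                level = int(x.levels[i])
                w = int(model.weights[j, i])
                sign = 1 if level * w > 0 else -1
                reagent_nL, water_nL = transfer_volumes_nL(
                    level, x.max_level, self.unit_volume_uL, self.dilution_mode
                )
                base_idx = 2 * (j * x.n_pixels + i)
                first, second = enc_wells[base_idx], enc_wells[base_idx + 1]
                first_kind, second_kind = ("acid", "base") if sign > 0 else ("base", "acid")
                for well, kind in ((first, first_kind), (second, second_kind)):
                    src = self._cursors[kind].draw(reagent_nL)
                    reagent_transfers.append(
                        Transfer(self.stock_plate.name, src, self.enc_plate_name, well, reagent_nL)
                    )
                    well_fill_nL[well] = well_fill_nL.get(well, 0.0) + reagent_nL
                if water_nL > 0.0:
                    for well in (first, second):
                        src = self._cursors["water"].draw(water_nL)
                        water_transfers.append(
                            Transfer(self.stock_plate.name, src, self.enc_plate_name, well, water_nL)
                        )
                        well_fill_nL[well] = well_fill_nL.get(well, 0.0) + water_nL
        if check_capacity:
            limit_nL = self.enc_spec.max_fill_uL * 1000.0
            over = [w for w, v in well_fill_nL.items() if v > limit_nL + 1e-6]
            if over:
                raise CapacityError(
                    f"encoding overfills {self.enc_spec.name} wells {over[:8]}"
                    f"{'...' if len(over) > 8 else ''}: "
                    f"up to {max(well_fill_nL.values()) / 1000.0} uL vs max "
                    f"{self.enc_spec.max_fill_uL} uL (try dilution_mode='constant')"
                )
        self._enc_wells = enc_wells
        self._sample = x
        self._model = model
        return Picklist(reagent_transfers + water_transfers)

    def compile_pooling(self, aliquot_nL: float = 200.0) -> Picklist:
        """Pool each neuron's rails into an output pair on the source plate.

        Scans the neuron's well block from the first well to the end,
        skipping every second well (the pH rails sit at even offsets,
        the complements at odd offsets).
        """
        if self._enc_wells is None:
            raise RobotError("compile_encoding must run before compile_pooling")
        if aliquot_nL < self.granularity_nL:
            raise RobotError(
                f"aliquot {aliquot_nL} nL is below the {self.granularity_nL} nL "
                "droplet granularity"
            )
        x, model = self._sample, self._model
        spec = self.stock_plate.spec
        out_row = max(
            (parse_well(w, spec)[0] for w in self.stock_plate.wells), default=-1
        ) + 1
        transfers: list[Transfer] = []
        self.neuron_output_wells = []
        for j in range(model.n_classes):
            if out_row >= spec.rows:
                raise CapacityError("no free row left on the source plate for outputs")
            ph_out = well_name(out_row, 2 * j)
            co_out = well_name(out_row, 2 * j + 1)
            self.neuron_output_wells.append((ph_out, co_out))
            block = self._enc_wells[2 * j * x.n_pixels : 2 * (j + 1) * x.n_pixels]
            for offset, dst in ((0, ph_out), (1, co_out)):
                for src in block[offset::2]:
                    transfers.append(
                        Transfer(self.enc_plate_name, src, self.stock_plate.name, dst, aliquot_nL)
                    )
        return Picklist(transfers)


def simulate_picklist(
    picklist: Picklist,
    plates: dict[str, Plate],
    noise: NoiseModel | None = None,
) -> dict[str, Plate]:
    """Replay a picklist through the exact mixing chemistry.

    Returns deep-copied final plates; sources are decremented, and
    every destination well is the running mixture of what was
    transferred into it.  With a noise model, each transferred volume
    is scaled by ``1 + eps``, seed-reproducibly, in picklist order.
    """
    plates = {name: copy.deepcopy(p) for name, p in plates.items()}
    rng = noise.rng() if noise is not None else None
    for t in picklist:
        if t.src_plate not in plates:
            raise TransferError(f"unknown source plate {t.src_plate!r}")
        if t.dst_plate not in plates:
            raise TransferError(f"unknown destination plate {t.dst_plate!r}")
        src_plate = plates[t.src_plate]
        dst_plate = plates[t.dst_plate]
        src = src_plate.wells.get(t.src_well)
        if src is None:
            raise TransferError(
                f"transfer from empty/undefined well {t.src_plate}:{t.src_well}"
            )
        v_uL = t.volume_nL / 1000.0
        if noise is not None:
            v_uL = v_uL * (1.0 + noise.sample(rng))
        if v_uL > src.volume_uL + 1e-12:
            raise TransferError(
                f"source underflow at {t.src_plate}:{t.src_well}: "
                f"{v_uL} uL requested, {src.volume_uL} uL present"
            )
        stock = src_plate.stock.get(t.src_well)
        if stock is not None:
            # a uniform stock delivers solute at its declared concentration
            moved = make_stock(stock[0], stock[1], v_uL)
        else:
            frac = v_uL / src.volume_uL
            moved = Solution(v_uL, src.acid_umol * frac, src.base_umol * frac)
        src_plate.wells[t.src_well] = Solution(
            max(src.volume_uL - moved.volume_uL, 0.0),
            max(src.acid_umol - moved.acid_umol, 0.0),
            max(src.base_umol - moved.base_umol, 0.0),
        )
        dst = dst_plate.wells.get(t.dst_well, Solution(0.0, 0.0, 0.0))
        dst_plate.wells[t.dst_well] = dst + moved
    return plates


@dataclass(frozen=True, slots=True)
class Violation:
    """One picklist problem found by validation (violations are data, not errors)."""

    kind: str  # capacity | min-fill | granularity | use-before-fill
    plate: str
    well: str
    transfer_index: int
    message: str


def validate_picklist(
    picklist: Picklist,
    plates: dict[str, Plate],
    granularity_nL: float = DEFAULT_GRANULARITY_NL,
) -> list[Violation]:
    """Dry-run checks: capacity, min-fill, droplet granularity, ordering."""
    violations: list[Violation] = []
    volumes: dict[tuple[str, str], float] = {}
    for name, plate in plates.items():
        for well, sol in plate.wells.items():
            volumes[(name, well)] = sol.volume_uL
    for idx, t in enumerate(picklist):
        if granularity_nL > 0:
            droplets = t.volume_nL / granularity_nL
            if abs(droplets - round(droplets)) > 1e-6:
                violations.append(
                    Violation(
                        "granularity", t.src_plate, t.src_well, idx,
                        f"{t.volume_nL} nL is not a multiple of {granularity_nL} nL",
                    )
                )
        v_uL = t.volume_nL / 1000.0
        key = (t.src_plate, t.src_well)
        if key not in volumes:
            violations.append(
                Violation(
                    "use-before-fill", t.src_plate, t.src_well, idx,
                    "transfer reads a well before anything was put in it",
                )
            )
        else:
            volumes[key] -= v_uL
            spec = plates[t.src_plate].spec
            if volumes[key] < spec.min_fill_uL - 1e-9:
                violations.append(
                    Violation(
                        "min-fill", t.src_plate, t.src_well, idx,
                        f"source drops to {volumes[key]:.3f} uL, below the "
                        f"{spec.min_fill_uL} uL minimum of {spec.name}",
                    )
                )
        dkey = (t.dst_plate, t.dst_well)
        volumes[dkey] = volumes.get(dkey, 0.0) + v_uL
        dspec = plates[t.dst_plate].spec
        if volumes[dkey] > dspec.max_fill_uL + 1e-9:
            violations.append(
                Violation(
                    "capacity", t.dst_plate, t.dst_well, idx,
                    f"destination reaches {volumes[dkey]:.3f} uL, above the "
                    f"{dspec.max_fill_uL} uL maximum of {dspec.name}",
                )
            )
    return violations


_CSV_HEADER = [
    "Source Plate Name",
    "Source Well",
    "Destination Plate Name",
    "Destination Well",
    "Transfer Volume",
]


def write_picklist_csv(picklist: Picklist, path) -> None:
    """Write the Echo-style CSV dialect; volumes in nL, repr-exact floats."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_HEADER)
        for t in picklist:
            writer.writerow([t.src_plate, t.src_well, t.dst_plate, t.dst_well, repr(t.volume_nL)])


def read_picklist_csv(path) -> Picklist:
    """Read the CSV dialect back; bit-exact round trip with the writer."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != _CSV_HEADER:
            raise RobotError(f"unexpected picklist CSV header: {header!r}")
        transfers = []
        for row in reader:
            if len(row) != 5:
                raise RobotError(f"malformed picklist row: {row!r}")
            transfers.append(Transfer(row[0], row[1], row[2], row[3], float(row[4])))
    return Picklist(transfers)


def write_plate_csv(plate: Plate, path) -> None:
    """Export a plate's state: well, volume, solute amounts, and pH."""
    from .chem import ph

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["well", "volume_uL", "acid_umol", "base_umol", "pH"])
        for well in sorted(plate.wells, key=lambda w: parse_well(w, plate.spec)):
            s = plate.wells[well]
            p = f"{ph(s):.6f}" if s.volume_uL > 0 else ""
            writer.writerow([well, repr(s.volume_uL), repr(s.acid_umol), repr(s.base_umol), p])
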