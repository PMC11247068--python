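"""Radionuclide decay data: half-lives and per-decay emission lines.

The five nuclides handled here are the PET candidates scandium-43,
scandium-44, scandium-44m and gallium-68 plus the therapeutic reference
lutetium-177.  Each nuclide is described at the level of ICRP-107-style
summary data: one line per radiation class carrying the intensity per decay
(yield, dimensionless) and the mean energy of that class in MeV.  Beta
spectra are represented by their mean energy only; no spectrum sampling is
done downstream (charged particles deposit locally in the transport model).

A curated fixture table is bundled under ``scandose/data/decay_table.csv``.
Cells that were damaged in the printed source are corrected there with a
line-by-line provenance note; the loader itself never rewrites values.
"""

from __future__ import annotations

import csv
import enum
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "RadiationClass",
    "EmissionLine",
    "RadionuclideDecayData",
    "DecayTableError",
    "load_decay_table",
    "write_decay_table",
    "load_bundled_decay_table",
    "mean_energy_per_decay",
    "HALF_LIVES_HOURS",
    "MEV_TO_J",
    "DECAYS_PER_MBQ_HOUR",
    "PHOTON_CLASSES",
    "CHARGED_CLASSES",
]

#: Joule per MeV (CODATA exact).
MEV_TO_J = 1.602176634e-13

#: Number of decays represented by 1 MBq·h of time-integrated activity.
DECAYS_PER_MBQ_HOUR = 3.6e9

#: Physical half-lives in hours.  Values for day/minute-quoted nuclides are
#: converted here, once: Lu-177 6.64 d, Ga-68 68 min.
HALF_LIVES_HOURS: dict[str, float] = {
    "scandium-43": 3.89,
    "scandium-44": 4.04,
    "scandium-44m": 58.7,
    "gallium-68": 68.0 / 60.0,
    "lutetium-177": 6.64 * 24.0,
}

_HALF_LIFE_UNIT_TO_HOURS = {"h": 1.0, "min": 1.0 / 60.0, "d": 24.0}

#: Curated mean annihilation-photon energy (keV-level constant, in MeV).
ANNIHILATION_ENERGY_MEV = 0.511


class RadiationClass(str, enum.Enum):
    """Emission classes; the class decides the transport treatment."""

    GAMMA = "gamma"
    XRAY = "xray"
    ANNIHILATION_PHOTON = "annihilation_photon"
    BETA_PLUS = "beta_plus"
    BETA_MINUS = "beta_minus"
    INTERNAL_CONVERSION_ELECTRON = "internal_conversion_electron"
    AUGER_ELECTRON = "auger_electron"


#: Classes transported as photons through the voxel grid.
PHOTON_CLASSES = frozenset(
    {RadiationClass.GAMMA, RadiationClass.XRAY, RadiationClass.ANNIHILATION_PHOTON}
)

#: Classes deposited locally at the decay site (charged particles).
CHARGED_CLASSES = frozenset(
    {
        RadiationClass.BETA_PLUS,
        RadiationClass.BETA_MINUS,
        RadiationClass.INTERNAL_CONVERSION_ELECTRON,
        RadiationClass.AUGER_ELECTRON,
    }
)


class DecayTableError(ValueError):
    """Schema violation in a decay table file, naming row and field."""


@dataclass(frozen=True)
class EmissionLine:
    """One radiation class of a nuclide: yield per decay and mean energy."""

    radiation_class: RadiationClass
    yield_per_decay: float
    mean_energy_mev: float
    provenance_note: str = ""

    def __post_init__(self) -> None:
        if self.yield_per_decay < 0:
            raise DecayTableError(
                f"{self.radiation_class.value}: yield_per_decay must be >= 0, "
                f"got {self.yield_per_decay}"
            )
        if self.mean_energy_mev <= 0:
            raise DecayTableError(
                f"{self.radiation_class.value}: mean_energy_mev must be > 0, "
                f"got {self.mean_energy_mev}"
            )

    @property
    def energy_per_decay_mev(self) -> float:
        return self.yield_per_decay * self.mean_energy_mev


@dataclass(frozen=True)
class RadionuclideDecayData:
    """Half-life plus the emission-line set of one radionuclide."""

    name: str
    half_life_hours: float
    emissions: tuple[EmissionLine, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.half_life_hours <= 0:
            raise DecayTableError(f"{self.name}: half_life must be > 0")
        if not self.emissions:
            raise DecayTableError(f"{self.name}: at least one emission line required")
        object.__setattr__(self, "emissions", tuple(self.emissions))
        for line in self.emissions:
            if line.radiation_class is RadiationClass.ANNIHILATION_PHOTON:
                # table rounding: printed as 5.1E-01 MeV
                if abs(line.mean_energy_mev - ANNIHILATION_ENERGY_MEV) > 0.005:
                    raise DecayTableError(
                        f"{self.name}: annihilation photon energy "
                        f"{line.mean_energy_mev} MeV inconsistent with 511 keV"
                    )

    @property
    def decay_constant_per_hour(self) -> float:
        import math

        return math.log(2.0) / self.half_life_hours

    def lines(self, classes: Iterable[RadiationClass] | None = None) -> tuple[EmissionLine, ...]:
        if classes is None:
            return self.emissions
        wanted = {RadiationClass(c) for c in classes}
        return tuple(l for l in self.emissions if l.radiation_class in wanted)


def mean_energy_per_decay(
    nuclide: RadionuclideDecayData,
    classes: Iterable[RadiationClass] | None = None,
) -> float:
    """Total mean energy emitted per decay, Σ_i Y_i·E_i, in MeV.

    Restricted to ``classes`` when given; an empty subset yields 0.  The sum
    is linear in yields and additive over disjoint class subsets, which the
    dose engine relies on for per-class bookkeeping.
    """
    return sum(l.energy_per_decay_mev for l in nuclide.lines(classes))


# ---------------------------------------------------------------------------
# loaders / writers

_CSV_FIELDS = [
    "nuclide",
    "half_life_value",
    "half_life_unit",
    "radiation_class",
    "yield_per_decay",
    "mean_energy_MeV",
    "provenance_note",
]


def _parse_rows(rows: Sequence[dict], origin: str) -> list[RadionuclideDecayData]:
    by_nuclide: dict[str, dict] = {}
    for i, row in enumerate(rows, start=1):
        where = f"{origin} row {i}"
        try:
            name = row["nuclide"].strip()
            hl_raw = row["half_life_value"]
            unit = row["half_life_unit"].strip()
            rclass_raw = row["radiation_class"].strip()
            y_raw = row["yield_per_decay"]
            e_raw = row["mean_energy_MeV"]
        except KeyError as exc:  # pragma: no cover - malformed header
            raise DecayTableError(f"{where}: missing column {exc}") from exc
        if not name:
            raise DecayTableError(f"{where}: empty nuclide name")
        if hl_raw in ("", None):
            raise DecayTableError(f"{where}: missing half-life for {name}")
        if unit not in _HALF_LIFE_UNIT_TO_HOURS:
            raise DecayTableError(f"{where}: unknown half_life_unit {unit!r}")
        try:
            rclass = RadiationClass(rclass_raw)
        except ValueError:
            raise DecayTableError(
                f"{where}: unknown radiation_class {rclass_raw!r}"
            ) from None
        try:
            half_life_h = float(hl_raw) * _HALF_LIFE_UNIT_TO_HOURS[unit]
            y = float(y_raw)
            e = float(e_raw)
        except (TypeError, ValueError) as exc:
            raise DecayTableError(f"{where}: non-numeric field ({exc})") from None
        try:
            line = EmissionLine(rclass, y, e, str(row.get("provenance_note", "") or ""))
        except DecayTableError as exc:
            raise DecayTableError(f"{where}: {exc}") from None
        rec = by_nuclide.setdefault(name, {"half_life": half_life_h, "lines": []})
        if abs(rec["half_life"] - half_life_h) > 1e-9 * half_life_h:
            raise DecayTableError(
                f"{where}: conflicting half-life for {name}: "
                f"{rec['half_life']} h vs {half_life_h} h"
            )
        rec["lines"].append(line)
    out = []
    for name, rec in by_nuclide.items():
        try:
            out.append(RadionuclideDecayData(name, rec["half_life"], tuple(rec["lines"])))
        except DecayTableError as exc:
            raise DecayTableError(f"{origin}: nuclide {name}: {exc}") from None
    return out


def load_decay_table(path: str | Path) -> list[RadionuclideDecayData]:
    """Load a decay table from CSV (or its JSON mirror with the same fields).

    One record is returned per nuclide, in file order of first appearance.
    Any invariant violation raises :class:`DecayTableError` naming the row
    and field.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
        if not isinstance(rows, list):
            raise DecayTableError(f"{path}: JSON decay table must be a list of rows")
        return _parse_rows(rows, str(path))
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        return _parse_rows(list(reader), str(path))


def write_decay_table(nuclides: Sequence[RadionuclideDecayData], path: str | Path) -> None:
    """Write nuclide records in the CSV schema; round-trips losslessly."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = []
        for n in nuclides:
            for l in n.emissions:
                rows.append(
                    {
                        "nuclide": n.name,
                        "half_life_value": n.half_life_hours,
                        "half_life_unit": "h",
                        "radiation_class": l.radiation_class.value,
                        "yield_per_decay": l.yield_per_decay,
                        "mean_energy_MeV": l.mean_energy_mev,
                        "provenance_note": l.provenance_note,
                    }
                )
        path.write_text(json.dumps(rows, indent=1))
        return
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_FIELDS)
        for n in nuclides:
            for l in n.emissions:
                writer.writerow(
                    [
                        n.name,
                        repr(n.half_life_hours),
                        "h",
                        l.radiation_class.value,
                        repr(l.yield_per_decay),
                        repr(l.mean_energy_mev),
                        l.provenance_note,
                    ]
                )


def load_bundled_decay_table() -> list[RadionuclideDecayData]:
    """Load the curated five-nuclide table shipped with the package."""
    ref = resources.files("scandose").joinpath("data/decay_table.csv")
    with resources.as_file(ref) as path:
        return load_decay_table(path)


def get_nuclide(name: str, table: Sequence[RadionuclideDecayData] | None = None) -> RadionuclideDecayData:
    """Look up one nuclide by name, defaulting to the bundled table."""
    table = table if table is not None else load_bundled_decay_table()
    for n in table:
        if n.name == name:
            return n
    raise KeyError(f"nuclide {name!r} not in table ({[n.name for n in table]})")
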