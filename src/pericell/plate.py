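"""Multiwell-plate geometry: from (plate format, medium volume) to the
medium-column depth that the oxygen transport model needs.

The depth of medium over an adherent monolayer is set by the fill volume
divided by the well growth area, minus a meniscus correction: surface
tension pulls medium up the well wall, so the column is thinnest at the
well centre where the cells sit under the least medium.  The correction
is a single scalar calibrated against a measured minimum depth of
~2.4 mm for 1 mL in a 12-well plate, not a capillary-physics model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import yaml

from .errors import DegenerateGeometryError, InvalidInputError

__all__ = [
    "PlateFormat",
    "MediumSpec",
    "PLATE_CATALOGUE",
    "DEFAULT_MENISCUS_DEPRESSION_MM",
    "nominal_depth",
    "minimum_depth",
    "load_plate_catalogue",
]

#: Depth reduction at the well centre relative to a flat fill, mm.
#: Calibrated so 1 mL in a 12-well plate gives a 2.40 mm minimum depth.
DEFAULT_MENISCUS_DEPRESSION_MM = 0.23


@dataclass(frozen=True)
class PlateFormat:
    """A named multiwell format.

    Parameters
    ----------
    name : str
        Vendor-style label, e.g. ``"12-well"``.
    growth_area_mm2 : float
        Growth area per well, mm².
    well_diameter_mm : float
        Inner well diameter, mm.  Must be consistent with the growth
        area within 20% under a circular-well assumption.
    """

    name: str
    growth_area_mm2: float
    well_diameter_mm: float

    def __post_init__(self) -> None:
        if self.growth_area_mm2 <= 0 or self.well_diameter_mm <= 0:
            raise InvalidInputError(
                f"plate {self.name!r}: growth area and diameter must be positive"
            )
        circular = math.pi * (self.well_diameter_mm / 2.0) ** 2
        if not (0.8 <= self.growth_area_mm2 / circular <= 1.2):
            raise InvalidInputError(
                f"plate {self.name!r}: growth area {self.growth_area_mm2} mm² "
                f"inconsistent with diameter {self.well_diameter_mm} mm "
                f"(circular area {circular:.1f} mm²)"
            )


#: Standard vendor growth areas; vendors differ, so this is overridable
#: via :func:`load_plate_catalogue`.
PLATE_CATALOGUE: dict[str, PlateFormat] = {
    "96-well": PlateFormat("96-well", 32.0, 6.4),
    "24-well": PlateFormat("24-well", 190.0, 15.6),
    "12-well": PlateFormat("12-well", 380.0, 22.1),
    "6-well": PlateFormat("6-well", 960.0, 34.8),
}


@dataclass(frozen=True)
class MediumSpec:
    """A fill condition: volume of medium in a given plate format."""

    volume_ul: float
    plate: PlateFormat
    meniscus_depression_mm: float = DEFAULT_MENISCUS_DEPRESSION_MM

    def __post_init__(self) -> None:
        if self.volume_ul <= 0:
            raise InvalidInputError("medium volume must be positive")
        if self.meniscus_depression_mm < 0:
            raise InvalidInputError("meniscus depression cannot be negative")


def nominal_depth(spec: MediumSpec) -> float:
    """Flat-fill depth of the medium column, mm.

    ``depth = volume / growth_area`` with 1 µL = 1 mm³; ignores the
    meniscus entirely.
    """
    return spec.volume_ul / spec.plate.growth_area_mm2


def minimum_depth(spec: MediumSpec) -> float:
    """Minimum (well-centre) depth of the medium column, mm.

    Nominal depth minus the meniscus depression.  Raises
    :class:`DegenerateGeometryError` when the depression consumes the
    whole column (too little medium to form a continuous layer).
    """
    nominal = nominal_depth(spec)
    if spec.meniscus_depression_mm >= nominal:
        raise DegenerateGeometryError(
            f"meniscus depression {spec.meniscus_depression_mm} mm "
            f">= nominal depth {nominal:.3f} mm: no continuous medium column"
        )
    return nominal - spec.meniscus_depression_mm


def load_plate_catalogue(path: str) -> dict[str, PlateFormat]:
    """Read a plate catalogue from YAML.

    Schema: ``{name: {growth_area_mm2: float, well_diameter_mm: float}}``.
    Entries are validated like the built-in catalogue.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise InvalidInputError(f"plate catalogue {path!r}: expected a mapping")
    out: dict[str, PlateFormat] = {}
    for name, entry in raw.items():
        out[name] = PlateFormat(
            name=name,
            growth_area_mm2=float(entry["growth_area_mm2"]),
            well_diameter_mm=float(entry["well_diameter_mm"]),
        )
    return out
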