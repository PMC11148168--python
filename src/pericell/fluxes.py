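"""Extracellular glucose-uptake and lactate-production arithmetic.

Endpoint medium assays give start/end glucose and lactate
concentrations; combined with the fill volume, culture duration and
well growth area they yield per-area fluxes (nmol/mm²/h) directly
comparable across plate formats.

The lactate/glucose summary is expressed as the fraction of consumed
glucose *carbon* exported as lactate — lactate/(2·glucose) on a molar
basis, since one glucose can yield two lactate.  The raw molar ratio
is also reported; the carbon-fraction convention is this package's and
is stated rather than assumed universal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError
from .plate import PlateFormat

__all__ = ["MediumAssay", "FluxRecord", "compute_fluxes"]


@dataclass(frozen=True)
class MediumAssay:
    """Paired start/end medium measurements for one well.

    Concentrations in mM, volume in µL, duration in hours.  The start
    values are those of naïve (unconditioned) medium.
    """

    start_glucose_mm: float
    end_glucose_mm: float
    start_lactate_mm: float
    end_lactate_mm: float
    volume_ul: float
    duration_h: float
    plate: PlateFormat

    def __post_init__(self) -> None:
        for name in (
            "start_glucose_mm",
            "end_glucose_mm",
            "start_lactate_mm",
            "end_lactate_mm",
        ):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} cannot be negative")
        if self.volume_ul <= 0 or self.duration_h <= 0:
            raise InvalidInputError("volume and duration must be positive")


@dataclass(frozen=True)
class FluxRecord:
    """Per-area fluxes and the lactate/glucose summary.

    ``lactate_glucose_fraction`` is lactate production over twice the
    glucose uptake (fraction of glucose carbon exported as lactate);
    ``lactate_glucose_molar_ratio`` is the unscaled molar ratio.  Both
    are NaN, with a flag, when glucose uptake is zero.  Negative fluxes
    (concentrations moving the "wrong" way) are preserved and flagged.
    """

    glucose_uptake: float
    lactate_production: float
    lactate_glucose_fraction: float
    lactate_glucose_molar_ratio: float
    flags: tuple[str, ...] = ()


def compute_fluxes(assay: MediumAssay) -> FluxRecord:
    """Area- and time-normalised glucose and lactate fluxes, nmol/mm²/h.

    ``uptake = ΔG·V/(A·t)`` and ``production = ΔL·V/(A·t)`` with
    Δ concentrations in mM and volume in µL (mM·µL = nmol).
    """
    area = assay.plate.growth_area_mm2
    scale = assay.volume_ul / (area * assay.duration_h)
    uptake = (assay.start_glucose_mm - assay.end_glucose_mm) * scale
    production = (assay.end_lactate_mm - assay.start_lactate_mm) * scale

    flags: list[str] = []
    if uptake < 0:
        flags.append("glucose_released")
    if production < 0:
        flags.append("lactate_consumed")
    if uptake == 0:
        flags.append("zero_glucose_uptake")
        fraction = float("nan")
        ratio = float("nan")
    else:
        ratio = production / uptake
        fraction = ratio / 2.0
    return FluxRecord(
        glucose_uptake=uptake,
        lactate_production=production,
        lactate_glucose_fraction=fraction,
        lactate_glucose_molar_ratio=ratio,
        flags=tuple(flags),
    )
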