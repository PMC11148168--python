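"""Steady-state diffusion–consumption model of oxygen in a medium column.

An adherent monolayer at the bottom of a well consumes oxygen that can
only arrive by diffusion from the air–medium interface at the top of a
stagnant column of depth ``x``.  At steady state with consumption
confined to the (infinitesimally thin) monolayer, the flux ``J`` is
constant through the column and the concentration profile is linear
(Fick's first law):

    J = D * (c_interface - c_pericellular) / x

with ``D`` the diffusion coefficient of O₂ in medium.  Delivery is
maximal when pericellular O₂ falls to the critical concentration below
which respiration cannot be sustained; demand beyond that capacity is
unmet and the monolayer is oxygen-limited.

Consumption is modelled as zero-order (oxygen-independent) demand with a
hard critical-O₂ cutoff, matching the observed near-step dependence of
respiration on O₂ down to ~4 µM.  Units follow :mod:`pericell.units`:
µM, mm, fmol/mm²/s, with 1 µM = 1000 fmol/mm³.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError
from .units import (
    ALPHA_UM_PER_MMHG,
    C_INTERFACE_UM,
    CRITICAL_O2_UM,
    D_O2_MM2_S,
    UM_TO_FMOL_PER_MM3,
)

__all__ = [
    "MediumColumn",
    "MonolayerDemand",
    "OxygenSolution",
    "HenryCoefficient",
    "max_ocr",
    "max_depth",
    "solve_pericellular",
    "profile_at_height",
    "mmhg_to_um",
    "um_to_mmhg",
]


@dataclass(frozen=True)
class MediumColumn:
    """Stagnant medium column between air interface and monolayer.

    Parameters
    ----------
    depth_mm : float
        Diffusion length from interface to monolayer, mm.
    diffusion_mm2_s : float
        O₂ diffusion coefficient in medium, mm²/s.
    c_interface_um : float
        Dissolved O₂ at the air–medium interface, µM.
    """

    depth_mm: float
    diffusion_mm2_s: float = D_O2_MM2_S
    c_interface_um: float = C_INTERFACE_UM

    def __post_init__(self) -> None:
        if self.depth_mm <= 0:
            raise InvalidInputError("column depth must be positive")
        if self.diffusion_mm2_s <= 0 or self.c_interface_um <= 0:
            raise InvalidInputError(
                "diffusion coefficient and interface O₂ must be positive"
            )


@dataclass(frozen=True)
class MonolayerDemand:
    """Zero-order O₂ demand of the monolayer with a critical cutoff."""

    ocr_demand: float
    critical_o2_um: float = CRITICAL_O2_UM

    def __post_init__(self) -> None:
        if self.ocr_demand < 0 or self.critical_o2_um < 0:
            raise InvalidInputError("OCR demand and critical O₂ must be >= 0")


@dataclass(frozen=True)
class OxygenSolution:
    """Steady-state outcome for one column/demand pair."""

    realised_ocr: float
    c_pericellular_um: float
    limited: bool


@dataclass(frozen=True)
class HenryCoefficient:
    """Solubility coefficient linking dissolved µM to partial-pressure mmHg."""

    alpha_um_per_mmhg: float = ALPHA_UM_PER_MMHG

    def __post_init__(self) -> None:
        if self.alpha_um_per_mmhg <= 0:
            raise InvalidInputError("Henry coefficient must be positive")


def max_ocr(col: MediumColumn) -> float:
    """Maximum flux the column can deliver, fmol/mm²/s.

    The Fick flux when pericellular O₂ is drawn down to zero:
    ``D * c_interface / depth`` with µM converted to fmol/mm³.
    """
    return (
        col.diffusion_mm2_s
        * col.c_interface_um
        * UM_TO_FMOL_PER_MM3
        / col.depth_mm
    )


def max_depth(
    ocr: float,
    diffusion_mm2_s: float = D_O2_MM2_S,
    c_interface_um: float = C_INTERFACE_UM,
) -> float:
    """Deepest column that can still deliver ``ocr``, mm.

    Inverse of :func:`max_ocr`; raises for non-positive demand, where
    the admissible depth is unbounded.
    """
    if ocr <= 0:
        raise InvalidInputError("OCR must be positive (depth unbounded at 0)")
    return diffusion_mm2_s * c_interface_um * UM_TO_FMOL_PER_MM3 / ocr


def solve_pericellular(col: MediumColumn, demand: MonolayerDemand) -> OxygenSolution:
    """Steady-state pericellular O₂ and realised OCR.

    If demand does not exceed the column capacity
    ``D * (c_interface - critical_o2) / depth``, the monolayer respires
    at its demand and pericellular O₂ sits wherever the linear gradient
    puts it.  Otherwise delivery caps respiration: pericellular O₂ is
    pinned at the critical concentration and realised OCR equals
    capacity.  An interface already at or below critical O₂ yields the
    no-respiration solution rather than an exception.
    """
    if col.c_interface_um <= demand.critical_o2_um:
        return OxygenSolution(
            realised_ocr=0.0,
            c_pericellular_um=col.c_interface_um,
            limited=True,
        )
    capacity = (
        col.diffusion_mm2_s
        * (col.c_interface_um - demand.critical_o2_um)
        * UM_TO_FMOL_PER_MM3
        / col.depth_mm
    )
    if demand.ocr_demand <= capacity:
        c_peri = col.c_interface_um - demand.ocr_demand * col.depth_mm / (
            col.diffusion_mm2_s * UM_TO_FMOL_PER_MM3
        )
        return OxygenSolution(
            realised_ocr=demand.ocr_demand,
            c_pericellular_um=c_peri,
            limited=False,
        )
    return OxygenSolution(
        realised_ocr=capacity,
        c_pericellular_um=demand.critical_o2_um,
        limited=True,
    )


def profile_at_height(
    sol: OxygenSolution, col: MediumColumn, height_mm: float | np.ndarray
) -> float | np.ndarray:
    """O₂ concentration at ``height_mm`` above the monolayer, µM.

    Consumption confined to the monolayer means constant flux through
    the column, hence a linear profile:
    ``c(h) = c_pericellular + J * h / D``.  Accepts scalar or array
    heights; heights outside ``[0, depth]`` raise.
    """
    h = np.asarray(height_mm, dtype=float)
    if np.any(h < 0) or np.any(h > col.depth_mm + 1e-12):
        raise InvalidInputError(
            f"height must lie within [0, {col.depth_mm}] mm above the monolayer"
        )
    c = sol.c_pericellular_um + sol.realised_ocr * h / (
        col.diffusion_mm2_s * UM_TO_FMOL_PER_MM3
    )
    return float(c) if np.isscalar(height_mm) else c


def mmhg_to_um(p_mmhg: float, alpha: HenryCoefficient | None = None) -> float:
    """Convert an O₂ partial pressure (mmHg) to dissolved µM."""
    if p_mmhg < 0:
        raise InvalidInputError("partial pressure cannot be negative")
    alpha = alpha or HenryCoefficient()
    return alpha.alpha_um_per_mmhg * p_mmhg


def um_to_mmhg(
    c_um: float, alpha: HenryCoefficient | None = None, rounded: bool = True
) -> float:
    """Convert dissolved O₂ (µM) to partial pressure (mmHg).

    With ``rounded=True`` (default) the result is rounded half away
    from zero to an integer, the convention used when reporting
    tensions alongside concentrations.
    """
    if c_um < 0:
        raise InvalidInputError("concentration cannot be negative")
    alpha = alpha or HenryCoefficient()
    p = c_um / alpha.alpha_um_per_mmhg
    if not rounded:
        return p
    return float(math.floor(p + 0.5) if p >= 0 else math.ceil(p - 0.5))
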