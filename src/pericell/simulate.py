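"""Synthetic-data generators mirroring each measurement the pipeline reads.

Each generator is the corresponding forward model plus a noise model:

* GC-MS isotopologue intensities — the MIDA mixture envelope scaled to
  instrument counts, with multiplicative lognormal noise per ion (the
  standard behaviour of GC-MS peak areas);
* optical oxygen-sensor traces — the analytic linear concentration
  profile sampled at probe heights, with additive Gaussian noise;
* endpoint medium assays — concentrations moved by the stated fluxes,
  with multiplicative noise on each measured concentration.

All generators are pure functions of (spec, seed): the seed is a
mandatory field of each spec, and reruns are byte-identical.  Noise-free
generation composed with the matching estimator recovers the true
parameters exactly — the package's central self-consistency property.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .fluxes import MediumAssay
from .isotopes import DEFAULT_WINDOW, MolecularFormula, natural_pattern
from .mida import predict_observed
from .oxygen import MediumColumn, MonolayerDemand, profile_at_height, solve_pericellular
from .plate import PlateFormat, MediumSpec, minimum_depth
from .units import (
    ALPHA_UM_PER_MMHG,
    ATM_MMHG,
    D_O2_MM2_S,
    INCUBATOR_O2_PCT,
    WATER_VAPOUR_MMHG,
)

__all__ = [
    "MidaSimSpec",
    "OxygenSimSpec",
    "MediumSimSpec",
    "gen_mida_dataset",
    "gen_oxygen_trace",
    "gen_medium_assay",
]

#: Default probe heights above the monolayer, mm: the scan window of
#: optical micro-probe lids (0.55–0.95 mm, five points).
DEFAULT_PROBE_HEIGHTS_MM = (0.55, 0.65, 0.75, 0.85, 0.95)


@dataclass(frozen=True)
class MidaSimSpec:
    """Ground truth for a simulated ²H₂O fatty-acid labelling experiment.

    Defaults are the study conditions: 8% deuterated water, palmitate
    methyl ester (C17H34O2) with N = 14 exchangeable sites, and ~1%
    multiplicative measurement noise on ion intensities.
    """

    seed: int
    f: float = 0.25
    p: float = 0.08
    n_sites: int = 14
    formula: str = "C17H34O2"
    fatty_acid: str = "palmitate"
    noise_cv: float = 0.01
    n_replicates: int = 6
    amount_nmol: float = 40.0
    intensity_scale: float = 1e6
    window: int = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        if not (0 <= self.f <= 1) or not (0 <= self.p < 1):
            raise InvalidInputError("f must be in [0,1] and p in [0,1)")
        if self.noise_cv < 0 or self.n_replicates < 1:
            raise InvalidInputError("noise_cv >= 0 and n_replicates >= 1 required")


@dataclass(frozen=True)
class OxygenSimSpec:
    """Ground truth for a simulated oxygen-sensor scan.

    Defaults emulate a respiring adipocyte monolayer under 100 µL in a
    96-well plate: demand 200 fmol/mm²/s, 18.6% incubator O₂.
    """

    seed: int
    ocr_demand: float = 200.0
    plate: PlateFormat = field(
        default_factory=lambda: PlateFormat("96-well", 32.0, 6.4)
    )
    volume_ul: float = 100.0
    incubator_o2_pct: float = INCUBATOR_O2_PCT
    probe_heights_mm: tuple[float, ...] = DEFAULT_PROBE_HEIGHTS_MM
    noise_sd_um: float = 0.5
    critical_o2_um: float = 4.0
    diffusion_mm2_s: float = D_O2_MM2_S

    def __post_init__(self) -> None:
        if self.noise_sd_um < 0:
            raise InvalidInputError("noise_sd_um cannot be negative")


@dataclass(frozen=True)
class MediumSimSpec:
    """Ground truth for a simulated endpoint glucose/lactate assay.

    Defaults emulate adipocytes under 1 mL in a 12-well plate for 16 h
    with glucose uptake ~2 and lactate export ~2.6 nmol/mm²/h (most
    glucose carbon leaving as lactate under standard, high-medium
    conditions).
    """

    seed: int
    glucose_uptake: float = 2.0
    lactate_production: float = 2.6
    start_glucose_mm: float = 25.0
    start_lactate_mm: float = 0.0
    volume_ul: float = 1000.0
    duration_h: float = 16.0
    plate: PlateFormat = field(
        default_factory=lambda: PlateFormat("12-well", 380.0, 22.1)
    )
    noise_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise InvalidInputError("noise_cv cannot be negative")


def _lognormal_factors(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Multiplicative noise factors with unit mean and the given CV."""
    if cv == 0:
        return np.ones(shape)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=shape)


def gen_mida_dataset(spec: MidaSimSpec) -> pd.DataFrame:
    """Simulated raw GC-MS intensity table, one row per replicate.

    Columns match the analysis input contract: ``sample, fatty_acid,
    formula, m0..m{window-1}, amount_nmol``.  Intensities are emitted
    raw (noise applied per ion before any normalisation — normalising
    is the analysis pipeline's job).
    """
    formula = MolecularFormula.parse(spec.formula)
    natural = natural_pattern(formula, spec.window)
    truth = predict_observed(spec.f, spec.p, spec.n_sites, natural).as_array()
    rng = np.random.default_rng(spec.seed)
    rows = []
    for i in range(spec.n_replicates):
        factors = _lognormal_factors(rng, spec.noise_cv, spec.window)
        intensities = truth * factors * spec.intensity_scale
        row = {
            "sample": f"sim_{i:03d}",
            "fatty_acid": spec.fatty_acid,
            "formula": spec.formula,
        }
        row.update({f"m{j}": intensities[j] for j in range(spec.window)})
        row["amount_nmol"] = spec.amount_nmol
        rows.append(row)
    return pd.DataFrame(rows)


def interface_o2_um(
    incubator_o2_pct: float, alpha_um_per_mmhg: float = ALPHA_UM_PER_MMHG
) -> float:
    """Dissolved O₂ at the interface from the incubator headspace %.

    Headspace is water-saturated at 37 °C, so the O₂ partial pressure
    is pct/100 × (760 − 47) mmHg, converted to µM by the solubility
    coefficient.
    """
    if incubator_o2_pct < 0:
        raise InvalidInputError("incubator O₂ % cannot be negative")
    return alpha_um_per_mmhg * incubator_o2_pct / 100.0 * (ATM_MMHG - WATER_VAPOUR_MMHG)


def gen_oxygen_trace(spec: OxygenSimSpec) -> pd.DataFrame:
    """Simulated oxygen-probe scan: concentration at each probe height.

    Columns: ``height_mm, o2_um, o2_true_um``.  Heights must lie within
    the medium column implied by the plate and fill volume.
    """
    depth = minimum_depth(MediumSpec(spec.volume_ul, spec.plate))
    heights = np.asarray(spec.probe_heights_mm, dtype=float)
    if np.any(heights > depth):
        raise InvalidInputError(
            f"probe heights {heights.max()} mm exceed column depth {depth:.3f} mm"
        )
    col = MediumColumn(
        depth_mm=depth,
        diffusion_mm2_s=spec.diffusion_mm2_s,
        c_interface_um=interface_o2_um(spec.incubator_o2_pct),
    )
    sol = solve_pericellular(
        col, MonolayerDemand(spec.ocr_demand, spec.critical_o2_um)
    )
    truth = profile_at_height(sol, col, heights)
    rng = np.random.default_rng(spec.seed)
    noisy = truth + rng.normal(0.0, spec.noise_sd_um, size=heights.shape)
    return pd.DataFrame(
        {"height_mm": heights, "o2_um": noisy, "o2_true_um": truth}
    )


def gen_medium_assay(spec: MediumSimSpec) -> MediumAssay:
    """Simulated endpoint medium assay consistent with the stated fluxes.

    End concentrations are the start values moved by flux × area ×
    duration / volume, then perturbed multiplicatively at ``noise_cv``
    (start values are naïve-medium measurements and get the same noise).
    With ``noise_cv = 0``, :func:`pericell.fluxes.compute_fluxes`
    recovers the true fluxes exactly.
    """
    area = spec.plate.growth_area_mm2
    delta_scale = area * spec.duration_h / spec.volume_ul  # nmol/mm²/h → mM
    end_glucose = spec.start_glucose_mm - spec.glucose_uptake * delta_scale
    end_lactate = spec.start_lactate_mm + spec.lactate_production * delta_scale
    if end_glucose < 0:
        raise InvalidInputError(
            "stated glucose uptake exhausts the medium before the endpoint"
        )
    rng = np.random.default_rng(spec.seed)
    factors = _lognormal_factors(rng, spec.noise_cv, 4)
    return MediumAssay(
        start_glucose_mm=spec.start_glucose_mm * factors[0],
        end_glucose_mm=end_glucose * factors[1],
        start_lactate_mm=spec.start_lactate_mm * factors[2],
        end_lactate_mm=end_lactate * factors[3],
        volume_ul=spec.volume_ul,
        duration_h=spec.duration_h,
        plate=spec.plate,
    )
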