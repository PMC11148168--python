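"""Package-wide unit conventions and physical constants.

Convention (fixed across every module):

* length        mm
* time          s (oxygen transport) / h (medium assays)
* concentration µM, with 1 µM = 1000 fmol/mm³
* flux          fmol/mm²/s per unit monolayer area
* volume        µL (= mm³)

The oxygen diffusion coefficient and the Henry-type solubility
coefficient are calibration constants of the steady-state column model;
both are configurable wherever they are consumed.
"""

#: fmol of solute per mm³ of medium for a 1 µM solution.
UM_TO_FMOL_PER_MM3 = 1000.0

#: Diffusion coefficient of O₂ in aqueous culture medium at 37 °C,
#: mm²/s (= 2.69e-5 cm²/s).  Within the literature range for dilute
#: aqueous solutions; calibrated so that a 2.43 mm column under 181 µM
#: interface O₂ delivers 200 fmol/mm²/s.
D_O2_MM2_S = 2.69e-3

#: Dissolved O₂ at the air–medium interface of a standard incubator
#: (18.6% O₂ headspace after water-vapour and CO₂ displacement), µM.
C_INTERFACE_UM = 181.0

#: Henry-type solubility coefficient, µM per mmHg, calibrated from the
#: 181 µM ↔ 140 mmHg incubator pair at 37 °C.
ALPHA_UM_PER_MMHG = 181.0 / 140.0

#: O₂ concentration below which a monolayer can no longer respire
#: maximally (closed-system respirometry of 3T3-L1 adipocytes), µM.
CRITICAL_O2_UM = 4.0

#: Standard atmosphere, mmHg.
ATM_MMHG = 760.0

#: Water vapour pressure at 37 °C, mmHg.
WATER_VAPOUR_MMHG = 47.0

#: Incubator headspace O₂ fraction (%) consistent with the 140 mmHg /
#: 181 µM interface calibration in a water-saturated incubator.
INCUBATOR_O2_PCT = 100.0 * 140.0 / (ATM_MMHG - WATER_VAPOUR_MMHG)
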