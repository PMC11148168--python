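# Methods

This note documents the models implemented in `pericell`, their
assumptions, the defaults that matter, and the limits of what the test
suite demonstrates.

## Medium-column geometry

A well is reduced to a one-dimensional column: depth = fill volume /
growth area (1 µL = 1 mm³). The built-in catalogue uses standard vendor
growth areas (96-well 32 mm², 24-well 190 mm², 12-well 380 mm², 6-well
960 mm²); vendors differ, so a YAML catalogue can be supplied. Surface
tension raises medium at the wall and thins it over the well centre
where the cells are scored; this is handled as a single scalar
*meniscus depression*, default **0.23 mm**, calibrated so that 1 mL in
a 12-well plate yields a 2.40 mm minimum depth — a measured value, not
a capillary model. Both the meniscus-corrected minimum and the
flat-fill nominal depth are reported wherever depth matters, because a
real monolayer spans the range between them. Evaporation, sensor-lid
displacement and 2-D meniscus profiles are out of scope.

## Steady-state oxygen transport

Assumptions: stagnant medium (no convection), steady state, oxygen
consumed only at the (infinitesimally thin) monolayer, zero-order
demand with a hard critical floor. Under these, flux is constant in
depth and the profile is linear, so the whole model is closed-form:

* capacity of a column: `J_max = D·c_interface/x` (µM → fmol/mm³ by
  ×1000);
* depth ceiling for a demand J: `x_max = D·c_interface/J`;
* pericellular O₂ when unlimited: `c_interface − J·x/D`;
* when demand exceeds `D·(c_interface − c_crit)/x`, realised OCR is
  capped at that value and pericellular O₂ pinned at `c_crit`.

Defaults, all configurable:

| parameter | default | unit | rationale |
|---|---|---|---|
| D | 2.69e-3 | mm²/s | within the 37 °C aqueous literature range; calibrated so a 2.43 mm column at 181 µM delivers 200 fmol/mm²/s |
| c_interface | 181 | µM | standard incubator headspace (140 mmHg) |
| α (Henry) | 181/140 ≈ 1.2929 | µM/mmHg | calibrated from the same 181 µM / 140 mmHg pair |
| critical O₂ | 4 | µM | closed-system respirometry shows maximal respiration down to ~4 µM, supporting the near-step (zero-order + cutoff) demand model rather than Michaelis–Menten kinetics |

mmHg outputs are rounded half away from zero to integers, matching the
convention of reporting tensions alongside concentrations. The
incubator headspace default is expressed as 19.64% O₂ of a
water-saturated atmosphere (760 − 47 mmHg), the percentage consistent
with the 140 mmHg calibration.

A caveat the model does not hide: an idealised flat 3.125 mm column
(100 µL, 96-well) caps OCR near 156 fmol/mm²/s, yet monolayers in that
condition are observed respiring at ~200. Meniscus thinning and
sensor-lid volume displacement plausibly close the gap; the package
reports both depth variants and leaves measured-vs-predicted
discrepancies visible.

## Isotope patterns

Natural-abundance envelopes are computed by exact polynomial expansion
of per-element isotope generating functions (¹³C 1.07%, ²H 0.0115%,
¹⁷O 0.038%, ¹⁸O 0.205%, plus N and S), truncated to the ion window
(default five ions, M0–M4). Abundances are pinned constants for
reproducibility. Deuterium incorporation is binomial over N
exchangeable sites at enrichment p; the envelope of a newly synthesised
molecule is the convolution of the two.

A deliberate asymmetry in normalisation: model patterns are kept
*unnormalised* after truncation (tail mass beyond M4 is real and must
not be redistributed), while observed instrument data are fractional
over the window by construction and are renormalised on ingestion.
Model predictions are window-normalised only at the point where they
are compared to observations. The alternative — comparing unnormalised
model vectors — is available behind `MidaConfig(normalise_model=False)`
for sensitivity analysis.

A measured unlabelled-control envelope may be supplied per fatty acid
in place of the theoretical one (pass the control pattern as `natural`
to the fitting layer); theory is the default.

## MIDA estimation

For fixed N, (f, p) are estimated by minimising the sum of squared
residuals between the observed fractional envelope and the mixture
model over [0,1]×[0,1), using trust-region bounded least squares
polished from a fixed 4×4 multistart grid (f ∈ {0.05, 0.3, 0.6, 0.9},
p ∈ {0.02, 0.05, 0.1, 0.2}). The multistart exists because the
objective has a ridge at low label (small f with large p trades off
against large f with small p); the procedure is fully deterministic.
Convergence tolerances: 1e-12 (xtol), 1e-14 (ftol). The fitted optimum
is regression-tested against a 101×101 brute-force grid.

N is determined by exhaustive scan (default 8–24): the water
enrichment is set by the experimenter, so the N whose freely fitted p̂
lands closest to the known target (default 0.08) is selected, ties
breaking to the smaller N. An alternative mode (`fit_mode="fixed_p"`)
pins p at the target, fits f alone and selects N by minimum residual;
it is provided for comparison, not default, because the free-p fit is
what makes the p-matching selection rule meaningful.

Identifiability: when the observed envelope differs from natural
abundance by less than `identifiability_threshold` (default 3e-3,
roughly 3× a typical fractional-intensity noise floor) in every ion,
any (f, p) on the ridge fits equally well; the estimator then reports
f = 0 at the nominal enrichment with an `unidentifiable` flag rather
than an arbitrary ridge point. In that case the N-scan is
uninformative and returns the smallest N by the tie rule, flagged.

Absolute de novo lipogenesis is f × pool size (nmol per well);
degenerate inputs (missing pool size, negative amounts, malformed
formulas) raise or are recorded per-row by the batch driver, which
never aborts a table on a single bad row.

## Glucose/lactate fluxes

Endpoint assays (start = naïve medium) are converted to per-area rates:
`flux = Δc · V / (A · t)` in nmol/mm²/h. The lactate/glucose summary is
reported two ways: the raw molar ratio, and lactate/(2·glucose) — the
fraction of consumed glucose carbon exported as lactate, which is the
convention under which "about half" (standard culture) and in-vivo
"15–30%" figures are mutually coherent. The convention is this
package's stated choice; no evaporation correction is applied.

## Synthetic data

Generators are pure functions of (spec, seed); seeds are mandatory.

* **GC-MS envelopes**: forward-model mixture × multiplicative lognormal
  noise per ion (unit mean, configurable CV, default 1% — typical of
  well-behaved GC-MS peak areas), emitted as raw intensities at an
  arbitrary instrument scale. Defaults are the study conditions: 8%
  ²H₂O, palmitate FAME (C17H34O2), N = 14.
* **Oxygen traces**: analytic profile sampled at the optical-probe
  window (0.55–0.95 mm above the cells, five points) plus additive
  Gaussian noise (default SD 0.5 µM).
* **Medium assays**: endpoint concentrations moved by the stated true
  fluxes, multiplicative noise on each measured concentration.

What these emulate is the *statistical structure the estimators
assume* — independent per-ion multiplicative noise, a linear O₂
gradient, nominal volumes. Real data add effects deliberately not
simulated: chromatographic drift and correlated ion noise, convective
stirring and evaporation, meniscus curvature across the probe field.
Passing round-trip tests therefore demonstrates correctness of the
inference given the model, not robustness to model violation.

## Problem sizes and determinism

The shipped test suite and acceptance script run at desk scale: single
fits take ~0.1 s, an N-scan ~2 s, and the largest simulation is 200
replicate fits at 1% noise (median |f̂ − f| < 0.02, fixed seed). All
randomness flows through explicit integer seeds; property tests run
derandomised.
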