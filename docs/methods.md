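# Methods

## Model and assumptions

The package simulates scar formation in the infarcted left ventricle as a
seven-state ODE system (README for the equations). The biological
assumptions are those of the underlying modeling framework:

1. all monocytes arriving at the infarct differentiate into macrophages,
   and macrophages do not proliferate locally — they enter by chemotaxis
   (the biphasic curve `M(T_beta)`) and leave by lymphatic emigration at
   `d_Mphi` = 0.6/day;
2. fibroblasts arise by proliferation of resident cells only (logistic
   growth gated by the crowding limiter), not by recruitment;
3. TGF-β1 secreted at the injury site is predominantly active, so an
   expression-profile-shaped pulse `u_T(t)` can serve as the activation
   input;
4. ECM in the infarct is produced by local cells (fibroblast secretion is
   the only collagen source).

Collagen proteolysis follows mass-action enzyme–substrate kinetics:
MMP-9 binds free collagen (`k_on`), the complex dissociates (`k_off`) or
turns over catalytically (`k_onc`) into degraded peptides (`CID`).
TIMP-1 is not a state variable; its TGF-β1-driven induction is folded into
the inhibition factor `h(T) = 1/(1 + T_beta/6.0)` applied, by default, to
macrophage MMP-9 secretion (a config switch moves it to the association
flux instead, since the biology admits both readings).

**Crowding.** Total occupancy
`kappa = k_mem(t) + M_phi/2500 + F/1250 + C/3300` throttles macrophage
influx, fibroblast proliferation and collagen secretion through
`(1 - kappa)`. The structural term `k_mem(t) = 0.17 + 0.56 exp(-0.05 t)`
encodes myocyte death in the infarct over a persistent vascular fraction.
For proliferation and secretion the limiter may go negative — over-packed
tissue actively suppresses growth — while macrophage influx uses
`max(1 - kappa, 0)` because immigration cannot run backwards. Note that
densities per mm³ and concentrations per μL share one volume basis
(1 mm³ = 1 μL).

**Domain of validity.** Within states whose total occupancy does not
exceed 1, every positive flux is gated by the limiter, occupancy cannot
cross 1, and all components provably stay non-negative. Starting
over-packed with near-zero collagen, the negative limiter would push the
collagen secretion flux below zero at `C = 0` and drive `C` negative; such
states are outside the model's domain and `simulate` raises rather than
integrating through them. (The standard initial state has occupancy
1.0024 — negligibly above 1, with collagen far from zero, so this never
triggers in practice.)

## Structural choices where the record is ambiguous

* **Complex loss.** The published normal-LV equilibrium
  (`C = 839.5`, `M9A = 7.1`, `CM9 = 447.6`) is consistent with complex
  decay governed by `k_onc` alone (`3e-4 * 839.5 * 7.1 / 0.004 = 447.0`,
  0.13% off) and not with `k_off + k_onc` (406). The `konc` balance is the
  default; the other variant sits behind `ModelOptions(complex_loss=...)`.
* **Kinetic time units.** The enzyme-kinetic constants are tabulated in
  s⁻¹-based units while every other rate is per day; only reading their
  numerals as per-day values reproduces the published equilibrium, so
  `kinetic_time_unit = "per-day-as-printed"` is the default and
  `"per-second"` (x 86400) is available for sensitivity work.
* **Baseline TGF-β1.** With no baseline activation the TGF-β1 balance at
  the healthy cell densities supports only 0.029 pg/μL, not the published
  0.21. Scenarios use the published state verbatim (`u_T0 = 0`);
  `calibrate_baseline_activation` exposes the inconsistency by solving for
  the activation (2.72 pg/μL/day) that makes 0.21 a fixed point.
* **Balanced baseline mode.** More broadly, the published healthy state is
  not a fixed point of the bare equations at all: baseline occupancy
  slightly exceeds 1 while fibroblast stationarity needs a limiter of
  `d_F/k_F ≈ 0.13`, macrophage emigration has no balancing influx, and
  catalytic turnover keeps producing peptides. For steady-state studies,
  `baseline_mode="balanced"` freezes `k_mem` at its day-0 value (healthy
  tissue: no myocyte death) and adds the constant homeostatic source/sink
  offsets (`homeostatic_offsets`) that make the reference state an exact
  fixed point of the zero-stimulus system — the same closure applied to
  the TGF-β1 equation by `calibrate_baseline_activation`, extended to the
  six physical components. `CID` is excluded: with `d_CID = 0` it is a
  pure accumulator of turnover and has no stationary value. Infarction
  scenarios never use this mode.
* **Peptide clearance.** No removal term for degraded peptides is on
  record; `d_CID` defaults to 0 (pure accumulation) and is exposed as a
  parameter.
* **Intervention semantics.** "Elevation of MMP-9 to level X from time t"
  is a clamp: from `start_day` the free-MMP-9 coordinate is held at
  `level` (derivative zeroed) while binding fluxes are computed from the
  clamped value. The onset is an integration breakpoint. The early
  (reperfusion-mimicking) intervention starts at 8 h = 1/3 day.

## Interaction curves and their calibration

The four response curves are anchored tables interpolated with
shape-preserving monotone cubics (PCHIP); a global polynomial interpolant
is selectable but not default, because polynomials oscillate over
concentration ranges spanning decades. Outside the anchor range curves
clamp to their end values; `M(T_beta)` anchors at (0, 0), so zero
chemoattractant means zero influx.

Anchor values are not on public record; they are generated from parametric
families and frozen as CSV package data (`lvremodel/data/curves`):

* `M(T_beta)`: generalized Ricker
  `m_max * ((T/theta) e^{1-T/theta})^p` — biphasic, as monocyte chemotaxis
  assays show. The magnitude and optimum are pinned by published
  *simulation outputs*: MMP-9 peaks of 80 and 220 pg/μL for the
  amplitude-15 and -60 stimuli, and macrophage/MMP-9 peak days of 3 and 4
  under the amplitude-30 stimulus. One calibration
  (`scripts/calibrate_default_curves.py`) fixed `m_max = 2845`
  cells/mm³/day, `theta = 2.239` pg/μL, `p = 4`, frozen thereafter;
  `lvremodel.calibration.calibrate_curve_magnitudes` re-derives
  near-identity scales from the shipped tables. The steep rise (`p = 4`)
  is structural, not cosmetic: with a flatter low-concentration tail the
  macrophage–TGF-β1 positive feedback loop, fed by the post-pulse
  endogenous TGF-β1 of ~0.1–0.3 pg/μL, dominates the stimulus and pushes
  the macrophage peak past day 10.
* `Fg(T_beta)`, `Fc(T_beta)`: saturating Michaelis forms normalised to 1
  at the healthy TGF-β1 concentration (0.21 pg/μL). `Fc(T_beta)` is
  anchored to the measured ~2-fold induction of collagen-I expression in
  cardiac fibroblasts at 10 ng/mL TGF-β1 (ratio 1.985 at 10 pg/μL in the
  model's working units).
* `Fc(C)`: decreasing Hill, 1 at the healthy collagen density
  (839.5 μg/μL), 0.10 at the packing maximum 3300 — consistent with the
  reported ~80% suppression of collagen synthesis under saturating
  feedback.

Curve concentration axes use the model's working unit (pg/μL for TGF-β1).
The in-vitro assays behind these relationships report pg/mL–ng/mL doses;
as the model's own operating range (baseline 0.21, pulse-driven excursions
to ~4 pg/μL) is what the curves must cover, anchors span 0–20 pg/μL.

**Activation pulse.** A log-normal pulse
`A exp(-(ln(t/t_peak))^2 / (2 w^2))` reaching amplitude `A` exactly at
`t_peak` = 2 days. The width `w = 0.33` log-days belongs to the same
one-time calibration (wider pulses delay the macrophage/MMP-9 peaks beyond
day 3.5/4.5); it leaves the activation below 0.1% of peak by day 7,
consistent with the TGF-β1 expression profile returning to normal after
day 7. A gamma-shaped alternative is selectable.

## Numerics

* Integration: `scipy.integrate.solve_ivp` with LSODA (stiff-capable),
  `rtol = 1e-8`, per-component `atol = 1e-10 x` component scale, dense
  output sampled on a uniform 0.01-day grid over days 0–30. Halving the
  tolerances moves peak metrics by < 0.1% (tested). Fitting loops use a
  faster profile (`rtol 1e-6`, 0.05-day grid).
* Tiny solver undershoots below zero are clipped inside the right-hand
  side; excursions beyond `1e-9 x` scale raise `SimulationError` with the
  failing time and state.
* Peak metrics: grid argmax refined by a local quadratic through the three
  surrounding samples — but only at strict interior maxima; on plateaus or
  at jump discontinuities (a clamp onset) the raw grid value is returned,
  since a parabola fitted across a discontinuity overshoots. Ties break
  toward the earliest time.
* Fitting: bounded `scipy.optimize.least_squares` (TRF) on fold-change
  residuals weighted by 1/SD (unit weight where SD = 0), with a seeded
  log-uniform multistart (default 8 starts; the first start is the
  geometric midpoint of the bounds). Simulation failures inside the loss
  are penalised, not fatal.

## Synthetic observations

`lvremodel.synthetic` emulates the structure of post-MI validation data:
fold changes of macrophage density, fibroblast density and MMP-9
concentration at harvest days {0, 1, 3, 5, 7, 14, 21, 28}, reported as
mean ± SD over `n = 5` replicates. Noise is multiplicative log-normal with
CV 10% by default (fold-change data are positive and right-skewed; the
log-scale shift makes draws mean-unbiased), fully seeded, with a
normal-additive alternative. What passing recovery tests show is that the
estimation machinery is self-consistent under the model's own noise
structure — not that the model fits real animals, whose replicate
variation includes strain differences, between-lab assay effects and
sampling of distinct cohorts per time point.

## Known limitations

* Under the median stimulus, collagen is still rising at day 30
  (deposition decelerating: 28 vs a peak 45 μg/μL/day) rather than flat
  after day 20, and the fibroblast fold change stays modest (~1.2x);
  the framework's own account notes its predicted fibroblast density at
  days 14–30 ran below measurements. Neither quantity is pinned by a
  published number.
* Early (pre-day-4) MMP-9 dynamics omit neutrophils, an early MMP-9
  source; interleukin signalling and spatial structure are likewise out of
  scope.
* The healthy-state closure (balanced baseline) is a modeling device to
  make steady-state analysis well-posed; the offsets are not measured
  homeostatic fluxes.
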