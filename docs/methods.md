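# Model and methods

## What is being modelled

A bench mechanical breathing model of a sleeping infant: a pair of
compliant bellows "lungs" (compliance 0.7 mL/mbar) driven between 30 and
65 mL (tidal volume 35 mL) at 44 breaths/min, breathing through an
exchangeable airway — an open-ended tube 300 mm long and 5 mm in bore,
optionally behind a sharp-edged orifice — with, in some conditions, a
porous polyfill gas-storage medium around the airway opening.  CO2 is
metered into the lung gas and O2 removed to emulate metabolism; the
lung CO2/O2 concentrations relax to an equilibrium that is measured,
together with the work of breathing (WOB) computed from the
pressure-volume loop.

The simulator reproduces the apparatus's defining property: the tidal
volume and rate are *prescribed*, so mechanics and gas transport
decouple.  Airway resistance changes the pressure needed to move the
fixed tidal volume (hence WOB) but not the gas exchanged; bedding gas
storage changes what is re-inhaled (hence equilibrium CO2/O2) but adds
almost no resistance.  These are the two distinct suffocation
mechanisms — airflow resistance and CO2 rebreathing — that the model
separates and then combines.

## Mechanics

The volume driver is sinusoidal by default,
`V(t) = v_min + (V_T/2)(1 - cos ωt)`, with an optional trapezoid
(constant-flow ramps with end-of-stroke holds, `rise_fraction` of each
half-period spent moving) to emulate valve-switched suction.  Flow is
the analytic derivative; circuit pressure is `p = -ΔP_airway(Q)` —
negative during inhalation, positive during exhalation.

Pressure-drop laws:

* tube — laminar Poiseuille, `ΔP = R Q`, `R = 8 μ L / (π r⁴)`;
  the default tube gives `R = 3.54e-3 mbar·s/mL` (0.285 mbar at the
  80.6 mL/s peak flow);
* orifice — sharp-edged quadratic, `ΔP = ρ Q|Q| / (2 C_d² A²)` with
  discharge coefficient `C_d = 0.6` (configurable) and room-air density
  1.2 kg/m³;
* series chain — drops add; the law is odd and strictly increasing in Q.

Air is treated as incompressible with fixed room-temperature
properties.  This is a documented limitation for the 1.07 mm orifice,
where the suction peak (~134 mbar ≈ 13% of atmospheric) is large enough
that compressibility and possibly choking would matter in reality; the
quadratic incompressible law is retained as the standard lumped
idealization.

A pressure-driven mode (`simulate_pressure_driven`) is exposed in which
an applied pleural-side pressure moves the lung through its compliance
against the airway resistance (quasi-static force balance, per-step
root solve for the flow).  The replication harness does not use it: the
bench model drives volume.

## Work of breathing

WOB is the area on the negative-pressure side of the p-v loop:
`W = ∫ (-p) dV` over samples with `p < 0` on the inspiratory limb
(`dV > 0`), by the trapezoidal rule, with `1 mbar·mL = 1e-4 J` exactly.
Work done against positive pressure during exhalation is computed
separately and reported but excluded from the headline number, which by
definition counts only the negative side.  Work per cycle times the
breathing rate gives J/min.

Breath cycles are delimited by local minima of the moving-average
smoothed volume channel (end-expiration convention; prominence-gated
peak finding so trapezoid volume holds and sensor-style ripple do not
split cycles); partial leading/trailing cycles are discarded.  For the
sinusoid through a linear resistance the closed form
`W = π R ω V_T² / 8 × 1e-4 J` holds, and for a quadratic law
`W = k Q_peak³ · 4/(3ω) × 1e-4 J`; the fixture generator attaches these
(and the half-ellipse `π a b / 2 × 1e-4 J`) as expected values, and the
trapezoidal computation agrees with them within 1% at ≥ 200
samples/breath (0.5% between 250 and 1000 samples/cycle in the
resampling test).

## Gas transport

The lung is a single well-mixed compartment tracked as CO2 and O2
volumes; the balance gas absorbs the (small) net volume difference of
metabolic exchange.  Ambient air is 0.04 vol% CO2 / 21 vol% O2.

The metabolic source defaults to
`injection = 0.044 × V_T × rate ≈ 67.8 mL CO2/min`, calibrated so the
no-storage mean exhaled CO2 fraction is exactly
`ambient + injection_per_breath / V_T = 4.44 vol%`, matching the
4.4 vol% exhaled-breath benchmark; O2 uptake is `injection / RQ` with
RQ = 0.8.  The bench study does not print its metering rate, so this
calibration (not a measurement) defines the default.  O2 uptake is
limited to the O2 present, so the sink can never drive the lung O2
fraction below zero.  Injection is continuous in time by default;
`injection_mode="per_breath"` applies the whole per-breath bolus at
end-inhalation, the timing assumed by the analytic recurrence (the two
modes differ in where within the breath the enrichment lands, which
shifts the end-exhalation lung fraction by ~1 vol% at the defaults but
not the exhaled-gas mass balance).

### Storage compartment

The bedding is a single compartment of capacity `V_s` holding a stored
gas amount and composition.  Within a breath:

* **inhalation** — a fraction β (entrainment) of the inhaled flow is
  drawn from the stored gas, capped by the amount available; the rest is
  fresh ambient air.  Drawing gas removes volume at the stored
  composition (no mixing on the way out).
* **exhalation** — exhaled gas first refills the freed space
  (volume-weighted mixing, nothing vented), then the remainder passes
  through the full, well-mixed compartment and the mixed excess vents to
  ambient (a continuously-stirred overflow, an exponential relaxation of
  the stored composition toward the exhaled gas).
* **breath boundary** — the stored composition's excess over ambient is
  multiplied by the washout retention `a ∈ [0,1]`, emulating inter-breath
  dissipation through the material (the parameter subsumes diffusive and
  convective transport, which the bench study does not separate).

This ordering is the one consistent with both limiting behaviours: with
β = 0 none of the stored gas is re-inhaled and the lung sits exactly at
the fresh-air limit, and with β = 1, a = 1 and `V_s ≥ V_T` the exhaled
breath exactly refills what inhalation removed, no CO2 is ever vented,
and lung CO2 grows without bound (reported as non-converged rather than
as an error).

### Polyfill calibration

The bench study quantifies *layers* of polyfill, not storage volume, so
layers map linearly onto the compartment parameters with free
calibration constants:

| parameter | value | rationale |
|---|---|---|
| storage volume | 12 mL/layer | a layer pocketed around a 5 mm opening holds on the order of 10 mL of air; linear in layers |
| entrainment β | min(1, 0.12 × layers) | the wrapped condition approaches full rebreathing (β → 1 at 8 layers) |
| washout retention a | 0.6 | roughly half the stored excess dissipates between breaths through a porous, open medium; keeps the wrapped condition convergent |
| intrinsic resistance | 5e-5 mbar·s/mL per layer | "soft, low-resistance" material: ~1% of the open tube's resistance per layer |

The grid's "wrapped in polyfill" condition is the 8-layer-equivalent
preset (the study's results text describes the third-series storage
ladder as two, four and eight layers).  These constants were chosen once
as physically plausible values and are configuration, not physics; only
the *trends* across conditions — not absolute CO2 levels — are
meaningful, and that is all the replication harness asserts.

## Equilibrium and the analytic recurrence

Equilibrium is declared when the end-exhalation lung CO2 fraction
changes by less than 1e-4 per breath for 5 consecutive breaths
(both configurable); runs continue a configurable number of breaths past
equilibrium so steady-state fluxes can be audited, and cap at
`max_breaths` (default 1000) with an explicit non-converged flag.

Because every within-breath operation is linear in the compositions, one
breath is an affine map of the state (lung CO2 fraction at start of
inhalation, storage CO2 fraction): inhalation mixes `b = min(βV_T, V_s)`
of stored gas into the lung; the bolus adds `q/v_max`; exhalation
refills the compartment and relaxes it toward the exhaled composition by
`exp(-(V_T - b)/V_s)`; washout contracts toward ambient by `a`.
`breath_recurrence_steady_state` builds the 2×2 map and solves
`(I - A) x = d` directly, raising when the spectral radius reaches 1
(the β = 1, a = 1 map is row-stochastic: nothing leaves).  The
time-stepping engine, run with the matching per-breath bolus, agrees
with this fixed point to better than 0.001 vol% at the polyfill presets
(tolerance asserted: 0.05 vol%), and the β = 0 limit
`L* = ambient + q/V_T` is exact by construction in both.

Steady-state CO2 conservation (injected = net vented over 50
post-equilibrium breaths) holds to ~0.006% in the worst grid cell
(asserted: 0.5%); the residual is the geometric tail of the relaxation
plus first-order transport discretization.

## Numerical choices

* 256 steps/breath by default (minimum enforced: 200 for loop-area and
  transport accuracy); species advection is explicit first-order within
  a breath, exact for the mixing steps whose inputs are constant over a
  step.
* The pressure/flow profile of a breath is identical every breath (the
  driver is prescribed), so it is computed once and tiled; WOB is
  evaluated on a single cycle.
* All computation is deterministic; there is no randomness anywhere in
  the package.
* Degenerate inputs are errors, not silent defaults: empty airway
  chains, zero-volume mixes, non-monotonic time channels, constant
  volume records, tidal-volume/lung-excursion mismatches, and any
  NaN/out-of-range fraction during a run (reported with the breath and
  step at which it occurred).

## Replication harness and its thresholds

Series 1 (resistance ladder, no storage), series 2 (layer ladder
{0, 1, 2, 4, 8} over the open tube), and series 3 (the 3×3 grid of
{open, 3.25 mm, 1.93 mm} × {2 layers, 4 layers, wrapped}) all run
through one code path; series 1 and 2 are slices of the grid logic.
The qualitative findings are encoded as numeric assertions with
configurable thresholds chosen as operationalizations of "significant"
vs "slight": CO2 spread ≤ 0.1 vol% across resistances; series-2 WOB span
≤ 20% of the series-1 WOB range; series-3 WOB additivity within 10%.
In this simulator the dissociation is exact (the CO2 spread across
resistances is 0 and WOB additivity holds to round-off) because the
volume driver decouples the two mechanisms perfectly; the thresholds
exist so the same assertions remain meaningful for configurations that
couple them (e.g. a pressure-driven mode).

## What the synthetic fixtures do and do not show

The fixture generator emits p-v loops with closed-form areas (ellipse,
linear-resistance sinusoid, quadratic-orifice sinusoid, flat-pressure)
— deterministic, seedless, noise-free.  They validate the area
computation, segmentation and unit chain, not the physics of any real
record: real transducer data carries noise, baseline drift, and cycle
jitter that these fixtures deliberately lack (segmentation's smoothing
and prominence gate are the only concessions to that).  Likewise the
engine's equilibria validate the stated mass balance, not infant
physiology: there is no anatomical dead space, no chemoreflex adjustment
of rate or tidal volume, no fatigue, and no temperature/humidity
dynamics, so absolute CO2 levels and WOB values are properties of the
model configuration, not predictions for a live infant.

## Known limitations

* Absolute WOB is purely resistive; the bench circuit pressure may
  include an elastic bellows component, so only trends are comparable.
* The storage compartment is a single well-mixed volume with per-breath
  washout; continuous inter-breath washout and porous-media flow are not
  modelled.
* Incompressible orifice flow (see above).
* Exhaled-breath benchmark rows (116 mm Hg / 16.4 vol% O2,
  35 mm Hg / 4.4 vol% CO2) are mutually inconsistent under any single
  total-pressure convention (dry gives 124.6 / 33.4 mm Hg, BTPS
  116.9 / 31.4 mm Hg from the stated fractions); the package exposes
  both conventions and reports concentrations as fractions, converting
  only at the reporting boundary.
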