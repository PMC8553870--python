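# Methods

## Model structure

`ednacolumn` integrates two coupled advection–diffusion–reaction equations
for large (LP) and small (SP) eDNA particles on a uniform vertical grid
(default 0–1500 m, dz 0.5 m, dt 10 s, 90-day seasonal runs; depth positive
downward internally, with the sign conventions pinned by tests: settling
moves LP mass toward greater depth, upward advection toward the surface).
The source is a migrating cohort treated as a continuous line source of
thickness 20 m: 500 m residence by day, 50 m by night, 3-hour constant-speed
ramps starting 2 h before (season-mean) sunset and 1 h before sunrise. A
fraction `pm` of individuals migrates; the remainder resides at the daytime
depth permanently. Shedding is specified per unit time (default 360 mass
units/h, equivalent to 1 unit per 10 s step) so results are invariant to
the time step, and is split between LP and SP by `f_lp`.

Assumptions: one horizontal dimension is ignored entirely; the cohort is a
single species with fixed behaviour; shedding is constant in time; forcing
(diffusivity, temperature, vertical velocity) is static within a run; decay
is first order with a depth-dependent but time-constant rate; breakdown
converts LP to SP conserving mass; only LP settles.

## Numerical schemes

Operator splitting per step, in the order: source deposit → decay →
breakdown → settling → advection → diffusion.

* Decay and breakdown use exact exponential factors (`exp(−k dt)`,
  `exp(−δ dt)`): unconditionally stable and exact for those terms, so the
  decay-only solution matches the closed form to round-off.
* Settling (LP only) is first-order upwind in flux form: monotone, no
  spurious negatives, conservative, with the flux through the bottom edge
  logged as exported mass.
* Advection is first-order upwind in **advective** form, exactly as the
  governing equation is written. With the prescribed divergent triangular
  velocity profile the advective term alone does not conserve mass; the
  per-step mass change is accumulated and reported in the budget as
  `advective_residual` rather than hidden. The budget closure check
  includes it.
* Diffusion is implicit backward Euler solved with a banded Cholesky
  factorization (computed once per run), allowing mixed-layer diffusivities
  up to 10⁻² m² s⁻¹ at dt 10 s. No-flux boundaries at surface and bottom;
  the matrix is an M-matrix, so positivity is preserved.
* Boundary conditions: no flux through the surface for diffusion and
  settling; zero-gradient open bottom (mass may leave by settling and is
  logged). CFL violations for the explicit settling/advection terms raise
  a `StabilityError` naming the offending term.
* Mass budget: shed = decayed + exported + resident (+ logged advective
  residual and any clipped negatives), enforced to 0.1% of shed mass and
  in practice closing to round-off. Negative concentrations (round-off
  only, given the monotone schemes) are clipped and logged.

Rationale: positivity and robustness were preferred over formal order of
accuracy; a time-step halving test keeps the 30-day bin proportions within
0.5 percentage points.

## Forcing profiles

The study's conclusions are insensitive to the detailed shapes of the
physical profiles, so the package prescribes analytic families:

* diffusivity: `κ = κ_ml` (10⁻³ m² s⁻¹) above the mixed layer depth,
  relaxing exponentially (10 m e-folding) to a background 10⁻⁵ m² s⁻¹;
* temperature: exponential thermocline `T(z) = t_deep + (t_surf −
  t_deep)·exp(−z/150 m)` with `t_deep = 4 °C`;
* vertical velocity: triangular, 0 at surface → ±10⁻⁴ m s⁻¹ at 200 m → 0
  at 400 m and below, representing submesoscale vertical motion;
* decay: constant 0.01 or 0.1 h⁻¹, or `k(T) = 0.05 + 0.0014·T` h⁻¹.

Seasonal defaults (mld, t_surf): JFM 150 m/13 °C, AMJ 30 m/16 °C, JAS
15 m/24 °C, OND 80 m/18 °C. The summer pairing is calibrated so the
0–550 m volume-mean temperature-dependent decay rate is ≈0.06 h⁻¹ (it
evaluates to 0.063 h⁻¹), the representative summer average used in the
scale analysis. User-supplied profiles (two-column CSV `depth_m,value`)
override any of these.

The solar clock uses the standard NOAA closed-form equations (fractional
year, equation of time, declination, hour angle at zenith 90.833°) at
42.35° N, 71.05° W for 2019; clock times are fixed UTC−5 standard time with
no daylight saving, since only durations and relative timing matter and a
fixed offset keeps runs reproducible. Migration times are frozen per season
at the mean of the daily sunrise/sunset times.

Note on the scale analysis: with the representative summer inputs the
advective length evaluates to `L_advect = 13.8 m` while the commonly quoted
rounded trio is 12 / 13 / 16 m; the function returns the computed value and
leaves rounding to the caller (13 is consistent with rounding T90 to 38 h
before multiplying).

## Metrics and the box-model oracle

Depth bins are surface 0–100 m, mid 100–450 m, deep 450–550 m. Proportions
are normalized over the **three bins**: mass settled below 550 m is
excluded from the denominator and reported separately, which is how the
binned totals close to 100%. Bin statistics (min/mean/max/population sd)
are computed over the full run including the few-day spin-up; an optional
exclusion flag is deliberately absent because the spin-up is short. The
surface/deep ratio `Cs/Cd` compares time-mean bin-average concentrations
(`mode="mean"`, the default) or time-means of per-snapshot bin maxima
(`mode="max"`).

`occupancy_box_model` is a semi-analytic cross-check on the PDE solver: at
equilibrium each bin's mass is proportional to (source occupancy time per
day)/(local decay rate), with transit occupancy allocated by time in bin
and the non-migrating fraction fixed at the day depth. It ignores transport
entirely — justified because the transport length scales (≈10–20 m) are
small compared with the bin sizes — and agrees with the full solver to
within ~1 percentage point per bin across the summer Pm sweep (the test
tolerance is 5 points).

## Experiments, presets and inversion

The factorial sweep driver enumerates configurations in deterministic
lexicographic order; the default sensitivity design is 4 seasons × 3
advection modes × 3 settling rates (0/25/50 m day⁻¹) × 3 decay scenarios ×
3 percent-migrating levels (0/50/100%) × 3 LP:SP splits = 972 runs, and the
percent-migrating study is 4 seasons × 11 Pm levels = 44 runs. Two readings
of the LP:SP three-level factor circulate (ratios 1:1/1:2/2:1, i.e.
f_lp ∈ {1/2, 1/3, 2/3}, versus all-small/half/all-large); both are provided
as named presets (`FLP_PRESETS`), with the ratio triplet as the default.

Resolution presets: `full` (dz 0.5 m, dt 10 s, 90 d) are the full study
conditions; `desk` (dz 2 m, dt 60 s, 30 d) is the package's scaled-down
default for interactive work, the test suite and the acceptance script —
chosen because the bin proportions equilibrate within days, so 30-day time
means track the full runs to within about a percentage point (verified by
the dt-halving convergence test). A coarse `smoke` preset (dz 10 m, dt
600 s, 3 d) exists for qualitative end-to-end checks only.

The Pm calibration runs the 11-point grid for one season, verifies the
ratio curve is strictly increasing (anything else signals a broken
configuration and raises), and stores a monotone piecewise-linear
interpolant — linear rather than spline to preclude overshoot between
knots. Inversion clamps ratios above the 100% knot to 100% with a warning.
Measured profiles are read as two-column CSVs and bin-averaged by
trapezoidal integration over the sampled depths (a single sample stands for
its whole bin); parameter-recovery tests show off-knot Pm values are
recovered within ±5 percentage points at desk scale.

## What the defaults do and do not emulate

The built-in forcing emulates climatological seasonal stratification and
mixing at a Northwest Atlantic slope-sea site; it does not emulate storm
events, diurnal mixed-layer cycling, prognostic temperature evolution (so
no diurnal modulation of the decay rate), salinity effects, horizontal
transport, resuspension, or predation-mediated eDNA redistribution.
Passing tests therefore demonstrate internal consistency of the mechanism
— migration geometry plus first-order kinetics dominating over physical
transport — under idealized forcing, not a validated hindcast of any real
water column. Shedding and settling rates for real eDNA remain highly
uncertain; all kinetic parameters are configurable.
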