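# Methods

## Model

The athlete, the sit-ski bucket and the skis are treated as a single
rigid body whose COM moves in the plane of a uniform incline of angle α.
Coordinates are slope-frame: x downslope (positive downhill), y
cross-slope (positive rightward facing downhill). The state is
(x, y, v, ψ, Φ₁): speed v, heading ψ measured from the fall line, and
lean angle Φ₁ (degrees at every interface, radians internally).

Forces on the COM:

* downslope gravity component G′ = m g sin α,
* aerodynamic drag f_a = ½ C_d ρ_a s v²,
* sliding friction f_s = µ m g cos α (unloaded normal force; a
  `loaded_friction` flag instead uses µ m √((g cos α)² + (v²/R_c)²) for
  the turn-loaded normal — off by default to stay consistent with the
  planar force equations),
* centripetal force F_c = m v²/R_c,
* "equivalent gravity" F_g-eff = √(G′² + F_c²), the vector-sum magnitude
  of the downslope and centripetal loads carried by the ski edge. The
  term is named but nowhere formulated in the source literature of such
  models; the vector-sum reading is this package's definition.

During a carving turn the ground reaction passes through the inner ski
edge and the COM, which ties lean to turn radius:

    tan Φ₁ = v² / (g R_c cos α) − tan α · cos β          (carving constraint)

β is the trunk inclination relative to the slope normal; callers that do
not track the trunk separately pass β = 0. The inverse,
R_c = v² / (g cos α (tan Φ₁ + tan α cos β)), has no finite solution when
tan Φ₁ + tan α cos β ≤ 0 (leaning "uphill" of the slope normal); that is
reported as infinite radius and treated as straight running.

Edging regimes compare the ski edge angle Ψ₁ with the lean Φ₁:
Ψ₁ < Φ₁ is under-edged (side-slip, no carve), Ψ₁ ≈ Φ₁ is the ideal
loss-free carve, Ψ₁ > Φ₁ over-edged (carves but scrubs speed). Ψ₁ has
no constitutive equation here — it is an input, and the regime tolerance
defaults to 0.5°.

## Dynamics and integration

    dv/dt = g sin α cos ψ − (f_a + f_s)/m        (clamped so v ≥ 0)
    dψ/dt = sign(Φ₁) · v / R_c(v, |Φ₁|)          (0 when R_c is infinite)
    dx/dt = v cos ψ,   dy/dt = v sin ψ

The quasi-steady within-turn speed assumption of the underlying turning
model is *not* imposed: dv/dt integrates continuously, otherwise turn
entry and exit could not be simulated. The sign convention makes a
rightward lean a rightward turn, and the turn rate is odd in the lean,
so mirrored courses with mirrored schedules give mirrored runs (tested).
Note the turn rate is discontinuous at Φ₁ = 0 on a slope (the carving
curvature does not vanish as |Φ₁| → 0⁺ because of the tan α term); a
zero lean is interpreted as riding flat, i.e. straight running.

Numerics: fixed-step RK4, default dt = 5 ms, time cap 60 s. The lean is
held constant across each step at the schedule value. The final sample
is interpolated onto the finish line so run time is not quantized to dt.
The turn rate v/R_c ∝ 1/v diverges at low speed; rates above 6 rad/s are
clamped and the step is logged as `side_slip` (physically a skidded
pivot the carving model cannot follow). Halving dt moves run time and
path length by ≲ 0.02% on the reference course, and the kinetic-energy
budget closes against the gravity/drag/friction work integral to ~1e-6
relative (the lateral constraint force does no work); both are asserted
in the test suite.

Gate passage: the COM polyline must come within the gate's
`capture_radius` (default 1.5 m, motivated by the ~1.3 m mean minimum
COM–gate distance of elite gate turns) *and* cross the gate's downslope
level on the prescribed side ("left" = smaller y than the gate, facing
downhill). Passing is nowhere formally defined for COM tracks in the
field literature; this operational definition is the package's.

## Time-minimal control search

The control is a piecewise-linear lean schedule over equally spaced time
knots (default 12), with the first and last knot pinned to zero lean —
the turn-phase boundary convention (turn phases begin and end at lean
zero-crossings). The knot span is 1.15× the fastest seed run.

The search minimizes run time plus a gate-miss penalty that is exactly
zero when every gate is passed and grows linearly (20 s/m) in the miss
distance; inside the objective the capture radii are tightened by 0.1 m
so the returned schedule clears the true radii with margin. Structure:

1. **Seeding.** Pure-pursuit tracking runs along cubic-spline racing
   lines threaded `waypoint_margin` ∈ {0.3, 0.6, 0.9} m inside each gate,
   with lookahead ∈ {0.45, 0.6} s: the closed-loop lean traces are
   near-feasible by construction and become the initial population.
2. **Global stage.** Differential evolution over the interior knots
   (bounds ±lean_max), population seeded with the tracking traces, their
   seeded Gaussian jitters and the zero schedule; 60 generations.
3. **Polish.** Powell's direction-set method from the best point, then a
   hard feasibility check at the true capture radii. Remaining
   violations raise an infeasibility report naming the gates.

Every random draw derives from the caller's integer seed, so repeated
same-seed runs are bit-identical. A plain multi-start local search
(Powell from heuristic alternating-lean schedules) was tried first and
repeatedly stalled 10–30 cm short of feasibility on three-gate courses —
the penalty landscape couples all downstream knots — which is why the
global evolutionary stage exists. On gateless courses the search reduces
to the polish stage and recovers the straight-run optimum to < 0.1%.

A caveat for property testing: the solver is a budgeted heuristic, so
monotonicity of the optimal time in, e.g., capture radius holds only up
to search noise (the suite allows 1%).

## Trajectory analysis

* **Segmentation.** Lean zero-crossings (sign changes, linearly
  interpolated in time) partition a run; each gate is assigned the
  segment containing the interpolated instant its downslope level is
  first crossed. Gates whose level is never reached are logged and
  skipped.
* **Per-gate metrics.** L_s is the polyline length over the segment
  (with endpoints interpolated onto the boundary times), t_s the segment
  duration. d_min is the *continuous* minimum COM–gate distance
  (point-to-segment over the polyline), which is stable under
  resampling, unlike a sample-only minimum. d_lev is the lateral
  distance at the gate-level instant (linear interpolation between the
  bracketing samples — the "moment of reaching the gate" is not
  formalized in the field literature; this is the package's definition).
  The closest-approach pattern compares t(d_min) with t(gate level):
  `after`/`before`/`at`, with tolerance eps_t defaulting to half the
  median sampling interval.
* **Curvature.** Cumulative chord length parameterizes the path; within
  each centred window (default 3 points, any odd size ≥ 3 for denser
  data) x(s) and y(s) are least-squares quadratics and
  κ = |x′y″ − y′x″|/(x′² + y′²)^{3/2} at the centre, R = 1/|κ|.
  Endpoints reuse the nearest full window; |κ| < 1e-6 m⁻¹ is reported as
  infinite radius (straight running); consecutive duplicate points are
  dropped with a warning. Accuracy scales with the point spacing h: on
  a radius-5 circle the 3-point fit is within 1e-3 m of R at h ≈ 0.08 m
  but only ~5e-3 at h ≈ 0.3 m; conversely, under positional noise σ the
  second difference amplifies error as σ/h², so noisy tracks want
  *coarser* spacing or wider windows (both tested).

## Statistics

Reported SDs default to the population convention (÷ n), which is what
measurement-accuracy tables in this field print; the sample convention
is a flag. Confidence intervals always use the sample-SD estimator with
the Student t quantile: mean ± t(0.975, n−1)·sd/√n. Pearson is used for
continuous variables, Spearman for ordinal ones (closest-approach
patterns are coded before = −1, at = 0, after = +1). The agreement ICC
is the two-way, absolute-agreement, single-measure form ICC(A,1),
computed directly from the two-way ANOVA mean squares (robust to the
degenerate all-equal case, where it returns 1); pingouin's
implementation serves as an independent cross-check in the tests, not as
the implementation. One-sample t against a constant signals an infinite
statistic on zero-variance input off the reference. Shapiro–Wilk
normality is exposed as an advisory check, not a precondition. All
p-values are two-sided.

Air density from site conditions uses the ISA troposphere barometric
pressure (sea level 101325 Pa, lapse 6.5 K/km) with the ideal gas law at
the local temperature. At 1800 m and −10 °C this gives 1.079 kg/m³,
within 3% of the 1.0525 kg/m³ conventionally quoted for such sites; the
discrepancy is inherent to the unstated pressure formula behind that
figure, so the package asserts only the 3% band.

## Synthetic data

The generator emulates a giant-slalom-like study section: by default 3
gates spaced 69.7/3 ≈ 23.2 m downslope (last gate at 69.7 m, finish 1 m
beyond) with alternating ±4 m lateral offsets on a 24° slope, entry
speed 12 m/s; COM tracks are resampled at 60 Hz (drone-video rate) and
corrupted with i.i.d. Gaussian position noise of SD 0.03 m (the spatial
error scale of calibrated drone video). Noise is white by design — only
static deviations are quantified for such systems, not a noise spectrum
— so the generator does not reproduce the autocorrelated drift of real
IMU/video tracks, and passing tests say nothing about drift robustness.
Metric datasets draw (t_s, L_s, d_min, d_lev) from a single-factor
Gaussian model (each variable correlates with t_s at the requested ρ,
cross-correlations ρ²), scaled to field-like moments
(0.88 ± 0.19 s, 13.61 ± 2.87 m, 1.31 ± 0.47 m, 1.34 ± 0.49 m) and
truncated at zero by redrawing. All generators are bit-reproducible per
seed.

What synthetic passing tests do show: the pipeline's internal
consistency (simulator → metrics → statistics round-trips, parameter
recovery within sampling error). What they cannot show: agreement with
field-measured gate turns, which requires real athlete trajectories and
gate surveys.

## Default parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| mass_total | 85 | kg | athlete (~55–65) + bucket + skis |
| drag_area C_d·s | 0.30 | m² | seated posture wind-tunnel scale |
| lean_max | 55 | deg | sit-ski frames limit edging below standing range |
| µ | 0.2 | – | hard-packed snow, literature value |
| g | 9.8 | m/s² | convention of the source model |
| ρ_a | 1.0525 | kg/m³ | ~1800 m, −10 °C race site |
| slope α | 24 | deg | study section gradient |
| dt | 0.005 | s | convergence < 0.1% vs dt/2 |
| capture_radius | 1.5 | m | ~mean d_min + margin |
| regime tol | 0.5 | deg | sensor-scale angular tolerance |

## Known limitations

Planar rigid-body model: no ski/chassis flex, no suspension, no aerial
phases, no skidded-turn dynamics, no 3-D terrain or variable snow. The
optimizer is a budgeted heuristic — it returns feasible, locally
near-optimal schedules, not certified global optima. The carving-rate
discontinuity at zero lean is physical to the model but means lean
dithering near zero (as the tracking seeder produces) creates many short
"turn segments"; segmentation on such runs assigns gates correctly but
the inter-gate boundaries are only as clean as the lean trace.
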