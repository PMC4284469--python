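# Methods

## The speed law and its parameters

Gliding speed after a reversal is modelled as an offset exponential,

    v(t) = v_term + (v_max − v_term) · exp(−t/τ),   t ≥ 0,

the minimal law consistent with a burst of propulsion that relaxes to a
steady terminal value, as expected if mucilage secretion is maximal when
a freshly refilled nozzle row fires and then declines. A power-law
alternative was considered out of scope. The time constant is reported
in the literature with an inverse-seconds symbol, but a time constant is
dimensionally a time; it is treated as seconds throughout.

Anchored condition parameters:

| agar (% w/v) | v_term (µm/s) | τ (s) | pooled mean (µm/s) | v_max (µm/s, derived) |
|---|---|---|---|---|
| 1.5 | 0.169 | 99 | 0.216 | 0.3849 |
| 2.0 | 0.148 | 108 | 0.162 | 0.2073 |

`v_max` is not directly observable from pooled statistics and is fixed by
inverting the cycle-average identity at the reference cycle duration
T = 450 s (midpoint of the observed 5–10 min reversal interval). The
cycle average is affine in `v_max`, so the inversion is closed-form; a
bisection oracle cross-checks it in the tests. Reversal-to-reversal
intervals are drawn independently per cycle from U(300 s, 600 s); the
5–10 min figure is read as the reversal-to-reversal interval (not a full
back-and-forth period), consistent with the decay approaching terminal
speed (τ ≈ 99 s ≪ 300 s) before the next reversal. Intermediate agar
concentrations interpolate `v_term`, `τ` and the mean linearly between
the two anchors; below 1.1% agar the substrate is flagged submerged.

## Synthetic data generator

The generator stands in for undeposited time-lapse recordings and
emulates their statistical structure, not their imagery.

* **Tracks** integrate the speed law exactly within each scheduled cycle
  (the displacement integral is closed-form), alternate direction at
  reversals, follow a path of constant curvature (default 0: straight),
  and add i.i.d. Gaussian position noise per frame. Defaults: 1 s frame
  interval, 0.05 µm noise SD — a tracking error well below the
  0.15–0.39 µm per-frame displacements. Identical seeds give identical
  tracks, and ground-truth reversal times are returned alongside.
* **Pooled speeds** emulate fixed-rate video pooled "over all time
  points": cycle durations are drawn duration-biased (a cycle contributes
  observations in proportion to its length), observation times uniformly
  within the cycle. A mean-one multiplicative log-normal observation
  noise (CV 0.2 by default) reproduces the log-normal-like spread of
  measured pooled distributions without shifting the condition mean; the
  noiseless sampler is checked against the closed-form pooled CDF
  (KS < 0.02 at n = 10⁵).

What the generator does *not* emulate: segmentation artefacts, uneven
frame intervals, track fragmentation, filament-length heterogeneity, and
any dependence of noise on speed. Passing recovery tests therefore show
the pipeline is unbiased under the stated model, not that it is robust to
every artefact of real video.

## Measurement pipeline

1. **1D coordinate.** Positions are smoothed with a centred moving
   average (default window 3; symmetric shrinking windows at the ends so
   linear motion is unbiased everywhere). The signed coordinate threads
   the path: each displacement increment is signed by its projection on a
   running tangent, so back-and-forth motion along a curved sheath maps
   to a 1D oscillation. Without smoothing, single-frame tracking glitches
   flip the apparent step direction and masquerade as reversals.
2. **Velocity** by `np.gradient` (central differences interior, one-sided
   at the ends), then the same smoothing.
3. **Reversals** at sign changes of the smoothed velocity exceeding a
   hysteresis of 0.02 µm/s on both sides; reversal times are linear
   interpolations of the zero crossing. The hysteresis suppresses jitter
   around zero; it is far below the ≥ 0.148 µm/s speeds away from
   reversals.
4. **Cycles** span consecutive reversals; partial head/tail intervals are
   dropped (no reversal anchor → biased phase). Displacement is the
   trapezoid integral of v with zero pinned at the interpolated reversal
   endpoints.
5. **Decay fits** are bounded nonlinear least squares in
   (v_term, amplitude, τ), pooled over cycles by default. Samples within
   two frame intervals of a reversal are dropped: finite differencing
   across the sign change smears speeds low there. Initialisation:
   v_term = min speed, amplitude = range, τ = duration/3; bounds
   v_term ≥ 0, amplitude ≥ 0, τ ∈ (0, 10·max duration]. Non-convergence
   — including flat data, where amplitude ≈ 0 leaves τ unidentifiable,
   and τ at its bounds — sets a flag rather than raising.
6. **Distributions** pool |v| over all time points; zero speeds are
   excluded from log statistics with their count reported; histograms on
   linear and log₁₀ scales (base 10 is presentation only).
7. **Condition comparison** defaults to Welch's t on log₁₀ speeds (the
   pooled distributions are log-normal-like and the sample sizes are
   unequal); a Mann–Whitney option is available. Its type-I error is
   calibrated in the tests (5% ± 2% under the same-model null).
8. **Saturating length–velocity relation** is fit as
   v = a(1 − e^(−L/λ)) — the minimal two-parameter saturating form; the
   fit is flagged degenerate when saturation completes before the
   shortest sampled length.

## Plate simulator

Filaments are polyline agents on a 2D plane (right-handed, angles
counterclockwise-positive). Per step: speed from the decay law at the
current phase; the leading tip either follows its own sheath trail
(nearest stored trail point *ahead* of the tip dictates the tangent, with
a pull toward the trail that locks retraced paths within one deposit
radius) or, on virgin substrate, turns at curvature κ and deposits new
trail. Scheduled reversals flip the leading end and reset the phase. The
body follows the head: the tip advances, and the trailing end is trimmed
by the same arc length, so `step` conserves length to 10⁻⁶ (growth is the
only length change). A stability condition requires v_max·dt below the
trail deposit radius.

Design choices:

* **Chirality is body-framed.** Filaments curve counterclockwise on the
  plate whichever end leads (forward and backward tracks retrace; spirals
  are counterclockwise). The lateral-slide side is therefore fixed in the
  filament's body frame — the axial rotation sense flips with travel
  direction — so the motion-frame turn sign flips with the leading end.
  A motion-framed sign would produce S-shapes instead of spirals.
* **Axial rotation and precession are not represented**; their net effect
  is the single curvature parameter κ (default 0.002 rad/µm, a model
  parameter exposed in config). Curvature applies only on virgin
  substrate; trail guidance overrides it entirely.
* **Encounters**: when the proposed step segment passes within half a
  filament width of another filament's body (or a foreign trail, in the
  default blocking mode), the heading rotates counterclockwise — a left
  turn — in 5° increments up to 170°; if no direction clears, the
  filament stalls for the step. Increment, cap and clearance are model
  parameters. Foreign trails can instead be ignored via a flag.
* **Growth** multiplies length by 2^(dt/doubling time), appended equally
  at both ends; each extension follows an existing trail when one lies
  ahead, else continues with curvature κ — the same rules as motion, so
  growth into virgin substrate contributes the same counterclockwise
  winding that motion does.
* **Per-filament motion is synchronous** along the whole polyline; the
  observed non-uniform intra-filament motion is outside the default
  model.
* **Submerged substrates** (< 1.1% agar) simulate normally but spiral
  classification is disabled (filaments leave the surface; the model does
  not represent 3D intrusion).
* All stochastic draws flow from one seeded generator recorded in run
  manifests; identical seeds replay identical plates.

**Spiral classification**: total signed turning along the polyline
(counterclockwise positive) with |winding| ≥ 2π·min_turns (default 2
turns) and minimum-bounding-circle diameter below half the arc length.
The compactness gate separates a spiral from a long meandering arc.

**Rasters** mark pixels whose centres lie within width/2 of any filament
polyline (row-major, row 0 at maximum y, pixel centres at half-integer
offsets). The radial spread statistic is the mean and population SD of
foreground-pixel distances from the inoculation point.

## Problem sizes and desk scale

Analyses run at sizes chosen to keep every experiment seconds-to-minutes
on a single core while leaving comfortable statistical margins:

* kinetics recovery: 30 tracks × 1 h at 1 fps ≈ 190 pooled cycles per
  condition (tolerances 5% on v_term, 10% on τ are several standard
  errors wide at this size);
* pooled means: 2×10⁴ samples; comparison at the measured n = 8882/1397;
* type-I calibration: 1000 null replicates at n = 200 per arm.

Plate runs use a desk-scale reduction of the two-week plug experiment:
spatial scale ≈ ×0.1 (so κ rises from 0.002 to 0.02 rad/µm under length
rescaling) and growth compressed to a 1 h doubling time, with kinetic
parameters left at the anchored values. A 5 h desk run grows a 60 µm
filament to ≈ 1.9 mm and winds it into a ≈ 5-turn spiral; the submerged
control produces none. Spread-vs-agar comparisons pair replicates: the
same plug layout is rerun under both conditions so the comparison
isolates the kinetic difference.

## Known limitations

* The simulator is 2D and mechanically rigid (no bending elasticity, no
  mucilage hydrodynamics, no nutrient or light fields); bundling of many
  filaments into thick ropes is not modelled beyond trail
  blocking/ignoring.
* Spiral *initiation* is an emergent outcome of the stated rules, not a
  validated mechanism; the simulator reports what the rules produce.
* The agar interpolation is linear between two anchors and extrapolated
  with clipping outside them; below 1.1% it extrapolates to faster
  kinetics while real filaments submerge and slow — submerged runs are
  used only for the classification contract, not for kinetic claims.
* Cycle fits assume the decay restarts cleanly at each reversal; real
  filaments may show history effects the model omits.
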