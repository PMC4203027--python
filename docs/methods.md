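# Methods

## Measurement model and frames

A rigid model is mounted on a sting at its center of mass (COM), oriented
by roll φ, pitch θ and yaw ψ, in a uniform flow of speed U and density ρ.
A six-axis load cell reads force **F** and torque **M** in its own frame.
The tunnel frame has x downstream, y starboard, z completing a right-handed
triad; moments are ordered (roll, pitch, yaw) about (x, y, z) with nose-up
pitch, right-wing-down roll and nose-right yaw positive, so a negative
∂C/∂(angle) is restoring.

The Euler sequence is fixed as **R** = R_z(ψ)·R_y(θ)·R_x(φ) on column
vectors (the standard aerospace intrinsic z–y′–x″ order). Since the raw
data only state "combined roll, pitch, and yaw angles", the order is a
convention of this package; the synthetic generator uses the same one, so
the chain is self-consistent, and the tests verify the matrix against an
independent quaternion composition.

Reduction of one recording:

    F_tunnel = R F_sensor
    M_com    = R M_sensor + (R r) × F_tunnel

with r the COM-to-sensor offset in body coordinates (default
(−0.05, 0, 0) m: a sting exiting downwind). The sensor is assumed zeroed
immediately before each recording, so model deadweight never appears in
the readings; the generator honors this contract. Angles are degrees at
every I/O boundary and radians in every derivative.

Coefficients: C = M / (½ρU²λS) per axis, with λ the snout–vent length
(default 0.08 m) and S the planform area (default 0.02 m²). λ doubles as
the length scale of Re = Uλ/ν; defaults ρ = 1.204 kg m⁻³ and
ν = 1.5×10⁻⁵ m² s⁻¹ (air near 20 °C; ν is configurable since it is an
assumption, not a measurement) give Re ≈ 32,000 at U = 6 m s⁻¹. The
generator is quasi-static — coefficients do not depend on U — so reducing
runs generated at Re 30,000 and 70,000 returns identical coefficients to
1e-12; this mirrors the scale-independence check done with physical models
and is asserted as an invariance property, not a fluid-dynamics claim.

## The virtual wind tunnel

Each virtual taxon is an `AeroTruth`: analytic coefficient curves plus
noise parameters. The pitching curve C_m(α) is a piecewise cubic Hermite
spline through (angle, value, slope) knots, so its value *and* derivative
at each knot are exact by construction. Roll and yaw baselines are linear
in their own perturbation angle, with separate slopes for the low (15°)
and high (75°) angle-of-attack regimes (the regime boundary is 45°).
Appendage control enters as an additive linear offset δ·(∂C/∂δ) on the
baseline — a linearized control model matching the way effectiveness is
defined and estimated.

Where a slope is meant to be recovered by the windowed fit, the segment
spanning that window is linear, making the noise-free pipeline identity
exact: the finite-difference/regression error of a windowed OLS fit on a
curved (cubic) segment is c₃·Σxᵢ⁴/Σxᵢ² for centred window offsets xᵢ, so
only curvature-free windows admit the ≤1e-9 end-to-end identity the tests
assert; elsewhere the estimate is a window-average slope, which is what
the discretization consumes anyway.

Noise is i.i.d. Gaussian per raw sample on each force and torque channel
in the sensor frame (defaults 0.05 N and 0.012 N·m per sample). One
recording is the average of n_samples = 600 samples, standing in for a
one-minute averaged recording at reduced rate; the generator draws the
recording mean directly from N(0, sd²/n), which is distributionally
identical and keeps 200-taxon simulations cheap. The torque default makes
the per-recording coefficient noise ≈0.014 at the reference dynamic
pressure — large enough that marginal bands are visible, small relative to
the archetype slope magnitudes (0.25–0.9 rad⁻¹). Mean aerodynamic forces
(lift/drag) are not modeled: force channels carry noise only, which still
exercises the (R r)×F moment-transfer path under averaging.

The default test design enumerates 221 positions: a 0–90° pitch sweep in
5° steps for the baseline and each pitch movement state, and roll/yaw
sweeps of ±15° in 5° steps at both angle-of-attack regimes for their
movement states, each with 5 replicates. Published per-series position
totals for the physical experiment do not reconcile exactly, so the design
here is fully explicit in configuration rather than matching any total.
Movement extents: symmetric wing protraction ±45°, tail dorsiflexion ±15°,
tail lateral flexion ±30°, asymmetric pronation/supination ±15°; tucking
of one wing is one-sided and has no conventional angular extent, so 45° is
used as its nominal deflection when converting the coefficient change to a
per-radian effectiveness.

### Reference fixtures

* **sphere** — all curves identically zero: every stability slope truly 0
  (marginal), nothing controllable. Since the whole curve is an
  equilibrium, 45° is declared its representative trim point.
* **weathervane** — restoring slope −0.9 rad⁻¹ in pitch and yaw, marginal
  in roll, no control; the 0.09 rad⁻¹ effectiveness threshold is one tenth
  of this reference restoring slope.
* **long_tailed** — stable trim at 17.5° (inside the 10–25° band typical of
  long-tailed gliders), slopes −0.6 rad⁻¹ at low α and −0.25 at 75°,
  highly effective tail (0.40 rad⁻¹) and moderately effective wings.
* **short_tailed** — "humped" pitching curve: unstable trim at 4°, slope
  +0.5 rad⁻¹ at low α, stable at high α, tail nearly ineffective
  (0.03 rad⁻¹) but wings effective (0.30 rad⁻¹).

`random_truth` draws the 20 ground-truth states uniformly and builds a
curve realizing them, with fixed magnitudes (±0.4 rad⁻¹ stability; 0.30
effective / 0.02 ineffective control, random sign) and the trim point at
45°. One deliberate coupling: the pitch 0° and 15° characters share one
low-α slope, because on a 5° grid their ±10° fit windows overlap (both
contain the 5° and 10° points) and independent slopes at both points
cannot be exactly recoverable by the same windowed estimator. Marginal
trim points (zero slope at the crossing) produce a flat zero segment whose
crossing location under noise is diffuse; mislocalized crossings whose
windows straddle adjacent curved segments are the main residual error mode
of the end-to-end recovery, consistent with marginal/stable confusion
dominating.

### What the generator does and does not emulate

It emulates the test design, the frame geometry, sensor noise after
averaging, and exact linearized control. It does not emulate unsteady or
flapping aerodynamics, added-mass/damping, sensor drift or correlated
noise, Reynolds-number dependence, interference from the sting, or
geometry-derived planform/COM. Passing tests therefore demonstrate that
the *reduction and inference chain* is correct and calibrated, not that
any particular organism has particular aerodynamics.

## Derivative estimation

Stability: ordinary least squares of coefficient on angle (radians) over
all replicate points within ±10° of the evaluation point (up to 5 grid
angles × 5 replicates). The two-sided interval is slope ± t(0.875, n−2)·se,
default level 0.75. With fewer than 3 points (or a single distinct angle)
the estimate is reported missing and the character coded `?`. Noise-free
data yield zero-width intervals; a constant series (true marginal body,
zero noise) is treated as a perfect zero-slope fit.

Trim points: sign changes of the replicate-averaged pitching series,
located by linear interpolation (a run of exact zeros counts once, at its
midpoint). The equilibrium character uses the lowest-α crossing with a
locally negative slope if one exists, else the lowest-α crossing; all
crossings are reported. The slope at the trim point is the same windowed
OLS centred on the interpolated crossing.

Control: series are paired on (grid angle, replicate); the estimate is the
mean of (C₊ − C₋)/(2δ) over window points (one-sided (C₊ − C₀)/δ when only
one deflection sign exists, e.g. the wing tuck), with a t-interval over
the paired differences. Swapping the + and − series negates the estimate
exactly. Effectiveness coding uses |slope| because sign encodes direction
of the produced moment, not the capacity to produce it.

The estimator choice (pooled OLS with a Student-t interval) is the
simplest one consistent with the replicate structure; the 75% level is the
convention of this analysis. An exactly calibrated 75% interval straddles
a true zero slope in exactly 75% of runs — by construction, independent of
noise scale and sample size — so a truly marginal body is coded marginal
~75% of the time per character, not more. This is the honest operating
characteristic of CI-based marginal coding and is measured, not assumed,
by the acceptance script (`sphere_marginal_character_pct`,
`sphere_all_marginal_run_pct` ≈ 0.75⁸ ≈ 10%).

## Character coding and formats

Twenty characters in a fixed order: stability at pitch 0°/15°/75°/trim,
roll 15°/75°, yaw 15°/75°; then control for (pitch: tail dorsiflexion,
symmetric protraction; roll: wing tuck, asymmetric pronation; yaw: tail
lateral, asymmetric pronation) × (15°, 75°). The per-axis assignment of
movements follows which axis each movement predominantly drives;
asymmetric pronation/supination contributes to both roll and yaw. States:
0 stable / 1 marginal / 2 unstable, 0 ineffective / 1 effective, `?`
missing. NEXUS output is a STANDARD matrix with SYMBOLS="012", MISSING=?,
and CHARSTATELABELS, readable by Mesquite; a continuous matrix of raw
slopes is exported alongside but not used by parsimony. Coding is
scale-free (jointly rescaling moments and dynamic pressure changes no
state) and monotone (growing |slope| at fixed CI width never flips
effective → ineffective).

## Parsimony

Unordered parsimony is implemented as Sankoff dynamic programming with
uniform unit cost between distinct states, which equals Fitch on binary
trees and is well-defined on polytomies (hard multifurcations — the
consensus trees this is used on contain unresolved nodes). `?` tips cost
zero in every state. MPR sets come from combining the down-pass cost with
a rerooted "rest-of-tree" cost: a state is in a node's set iff some
minimum-change assignment uses it; no ACCTRAN/DELTRAN resolution is
imposed and `?` tips report the full symbol set. Scores are invariant to
rerooting and MPR sets to tip-order permutation (nodes are keyed by their
descendant-tip sets). A brute-force enumerator over all internal (and
missing-tip) assignments serves as the independent oracle on trees of ≤7
tips; agreement is 100% over 1000 random instances.

## Pipeline and reproducibility

`run_pipeline(RunConfig)` persists every intermediate table and a manifest
(seed, SHA-256 of the scientific configuration — output path excluded —
and package version); identical configuration and seed reproduce every
output byte-for-byte. All constants (0.09 threshold, 0.75 CI level, 5°
grids, 15°/75° regimes, movement extents, window, air properties) are
named configuration keys. Validation (e.g. CI level in (0,1)) happens
before any stage runs.

Problem sizes in the test suite and acceptance script — 200 random taxa
for end-to-end recovery, 10,000 simulations for interval calibration,
1,000 random trees for the parsimony oracle, 100 seeded sphere runs — were
chosen so each estimate's Monte-Carlo error is small against the margin it
is compared to (e.g. 4,000 matrix cells put the standard error of the
agreement fraction near 0.3%).

## Known limitations

* Quasi-static, rigid, linearized control: very dynamic maneuvers
  (flapping, added-mass effects) are outside the model.
* The estimator is a window-average slope; on curved segments it is biased
  relative to the point derivative by design (documented above), and
  marginal trim points are intrinsically hard to localize.
* No likelihood/Bayesian ancestral states, no branch lengths, no tree
  search: trees are inputs.
* Planform area, COM and sensor offset are inputs, never derived from
  geometry.
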