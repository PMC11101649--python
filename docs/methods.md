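# Methods

This note documents the models behind `imcluster`: what is computed, the
assumptions, the parameters that matter, what the synthetic data do and
do not emulate, and the design choices made where the design was open.

## Rigid-body estimator

The cluster treats the instrumented body segment as rigid. The
acceleration of a fixed point at r from a reference point obeys
`a = a₀ + α×r + ω×(ω×r)`; inverting this over three linearly independent
relative vectors with the dual (contravariant) basis yields the angular
acceleration α per sample without time differentiation
(`geometry.alpha_from_configuration`). The general covariant machinery is
always used — no orthogonality shortcut — so mispositioned (hence
non-orthogonal) true geometries are handled by the very same code path.
Degeneracy is declared when the scalar triple product of a root's
relative vectors falls below 1e-12 m³ (coplanar packages); rotations must
be orthonormal to 1e-10.

Eight estimates per sample arise as 4 root choices × 2 projection
orderings of each coordinate's index pair — the only enumeration that
yields exactly eight. The fused angular velocity (4-way, β = 0.6) feeds
every configuration's centripetal term; the eight α estimates are fused
per coordinate (β = 0.8). The fusion is a convex combination of the inner
mean (weight β) and the mean of the two sorted extremes (weight 1−β); it
is bounded by the input min/max, and ties are broken by stable sort
order.

**A property worth knowing.** For any angular velocity shared by the two
orderings of a pair, the centripetal projections cancel in the pair mean
(`(ω×(ω×g_i))·g_j` is symmetric in i, j), and the remaining antisymmetric
accelerometer combination is identical for every root. The eight values
are therefore pairwise symmetric about a common value, and the sorted
weighted mean returns exactly that value for any β: on the acceleration
side the cluster estimator coincides, in exact arithmetic, with the
nine-axis accelerometer-only (NAP) formula. The cluster's genuine
advantages are elsewhere: a four-fold redundant, sign-unambiguous angular
velocity (NAP must solve sign-ambiguous quadratics from noisy
accelerations), outlier robustness when a channel misbehaves, and the
avoidance of differentiation altogether. A corollary of the pair
symmetry: the fused α variance undercuts at least six of the eight
configuration estimates on every axis and all eight on the transverse
axis, but not the single best long-arm estimate on that arm's own axis —
the equal-weight pair average cannot beat an optimally short lever arm.

## Baseline estimators

Built by disabling sensors of the same recording: `numdiff` is the
backward difference of package 0's gyroscope, `α[k] = (ω[k]−ω[k−1])·f`,
with `α[0] = α[1]` and no filtering (comparisons are on raw outputs);
`nap` uses the nine accelerometer axes in symmetric arm differences where
the centripetal products cancel exactly, and recovers ω up to sign from
the diagonal relations, resolving signs by temporal continuity with a
low-confidence mask where magnitudes or cross products vanish; `ars` uses
package 0's gyroscope and the accelerometers of packages 0–2, averaging
the two redundant arm evaluations of the z coordinate with equal weight
(the x and y coordinates each have a single available combination). NAP
arm lengths reuse the cluster's nominal norms. On noiseless, perfectly
mounted data all direct estimators agree with ground truth to better
than 1e-9 rad/s².

## Sensor error model

Per-axis white noise with σ = ν√f (defaults: ν_g = 5.236e-4 rad/s/√Hz,
ν_a = 6.116e-5 m/s²/√Hz, f = 200 Hz) and true-but-unknown mounting
errors: the simulator evaluates readings at the true (offset) package
positions in the true (misaligned) package frames, while the estimator
only ever sees nominal geometry. The reference scenario carries the
metrology values Δr₁₀ = (0.01, −0.008, 0.002) m,
Δr₂₀ = (−0.005, 0.003, −0.003) m, Δr₃₀ = (0.008, 0.002, 0.005) m and
single-axis misalignments Δφ₁₀ₓ = 0.017, Δφ₂₀ᵧ = −0.035,
Δφ₃₀𝓏 = −0.026 rad. Accelerometer readings include the specific-force
gravity term; it cancels exactly in every inter-package difference, so it
never biases α, and its quasi-static projection through the misalignments
is removed by static calibration (≈30 s standing record; the
per-coordinate means of the fused outputs are subtracted from all
subsequent outputs). Segment non-rigidity (soft tissue) is not modelled.

Error budget under the reference scenario on the synthetic ten-step walk
(α_y RMSE, single-source runs): sensor noise alone ≈ 0.008 rad/s²,
misalignment alone (after calibration) ≈ 0.011, mispositioning alone
≈ 0.25. Unknown ~1 cm position offsets on 0.10–0.17 m arms leak about 6%
of the angular-acceleration signal into the estimate — a geometric
mismatch no fusion can remove — so the absolute RMSE scales with the
trajectory's α_y RMS (4.0 rad/s² here). The differentiated single-IMU
error is flat at √2·σ_g·f ≈ 2.09 rad/s² regardless; the cluster's error
stays an order of magnitude below it throughout.

## Synthetic walking and perturbations

The generator emulates sagittal-plane trunk kinematics of steady walking:
one touchdown-induced α_y maximum per step (twice the stride frequency,
default 0.9 Hz), peak amplitudes drawn uniformly per pulse — 8–15 rad/s²
in the simulated-walker regime, 20–40 rad/s² in the human regime — over a
small stride-frequency background (0.8 rad/s²). Touchdown pulses are
biphasic: a raised-cosine spike (width 0.10 s) followed by a shallower
rebound trough of equal impulse (depth 0.6× the spike, width 0.1/0.6 s),
which reproduces the negative α_y lobes of real trunk data and makes
every pulse integrate to zero, so the closed-form angular velocity is a
bounded train of positive bumps with one maximum per step — exactly
consistent with α at machine precision (oracle tests run at 1e-9).
Off-sagittal axes carry small sinusoids (0.2 rad/s); the reference-point
specific force combines gravity with step- and stride-frequency bobbing.
The trapezoid integral of the sampled α_y matches ω_y to the trapezoid
rule's own second-order discretization error (~1e-3 at 200 Hz, falling
16-fold at 4× rate); the consistency is exact, the comparison is limited
by quadrature, not by the generator.

Trip-like episodes are injected as a fast-attack / plateau / final-third
decay train of the same biphasic pulse family at three times the
touchdown rate (spike width 0.65× baseline, rebound 0.45), added to α_y
with its exact integral added to ω_y. The scale is chosen so that, among
the four baseline envelope sides (α_y and ω_y global max and min), the
side reached most easily attains exactly `multiplier` times its
pre-injection extremum and no side exceeds that multiple. Episodes at
multiplier ≤ 1.1 therefore remain inside the detection algorithm's
anomaly bandwidth by construction and are flagged sub-threshold; at
multiplier 2.0 the α-max side binds while ω_y still reaches ≈1.8–2.0× its
own maximum. Because every episode pulse carries zero net impulse, the
series returns to the baseline exactly at the episode end.

What the generator does **not** emulate: left/right gait asymmetry,
stride-time variability, soft-tissue wobble, multi-axis perturbation
coupling, or the specific waveforms of any individual. Passing tests
therefore demonstrate the estimator and detection algebra under
controlled, known-truth conditions, not population-level performance on
real recordings.

## Detection

Personalized thresholds come from an unperturbed baseline of the same
sensor and placement: global max/min of ω_y and α_y, plus the averaged
touchdown-induced local maximum isolated iteratively — detect one
extremum per zero-crossing-bounded lobe (zero crossings linearly
interpolated; the largest-magnitude sample represents the lobe),
histogram the maxima (bin width 5% of the global max), drop the
lowest-magnitude bin and re-detect until the retained event rate matches
the touchdown rate within ±15% (at most 20 rounds). The touchdown rate is
the first prominent autocorrelation peak of α_y that also carries real
positive correlation (height ≥ 0.1 after normalization) — the height
requirement stops low sidelobes of sharp biphasic waveforms from
masquerading as the period. Minima receive a single low-magnitude filter
(drop below 25% of |global min|). In the human regime these averaged
local maxima fall in the participant ranges 0.499–1.343 rad/s (ω) and
28.6–70.7 rad/s² (α).

Observation windows: a candidate opens when an ω_y lobe extremum exceeds
1.1× the baseline global threshold (either side) and an α_y extremum
inside the same lobe span is likewise anomalous; the window starts at the
zero crossing preceding that first anomalous α extremum. Candidates
without α corroboration are rejected — the joint criterion is what
separates reactive trips from voluntary trunk motion. Scanning at most
six steps (6 × stride period/2, from the baseline cadence), the window
closes at the first α zero crossing after the last irregular extremum of
either signal, accepted once touchdown-scale α maxima (≥ half the
averaged local maximum) recur at the touchdown rate ±15% over the next
two strides; otherwise it closes at the six-step bound flagged
`unrecovered`. Thresholds are all relative, so scaling both baseline and
trial signals leaves detections unchanged, and thresholds extracted from
differentiated single-IMU signals come out systematically higher than the
cluster's — directly degrading detection resolution.

## Recovery metrics

The trunk is a homogeneous solid elliptical slab: semi-axes depth/2
(sagittal) and width/2 (medio-lateral), height = trunk length, referenced
to the pelvic midpoint q through the parallel-axis shift L/2, giving
Θ_yy^(q) = m(a²/4 + L²/3) with a = depth/2. The slab convention is
isolated in one function (`recovery.trunk_inertia`) and the formula is
logged with the output so alternative conventions can be swapped. Trunk
mass defaults to 0.497 × body mass when not measured. Over a window,
aTAM = Θ ∫|ω_y| dt and aRCTAM = Θ ∫|α_y| dt by the trapezoid rule on the
piecewise-linear interpolant of the rectified signal with interpolated
endpoints — exactly additive under any partition of the window. Negative
lobes count positively: they indicate recovery effort just as positive
ones do. Trials 1–2, 4–5, 7–8 pool into early/mid/late adaptation phases
(washout-adjacent trials 3 and 6 are ignored); missing trials are allowed
and empty phases flagged.

## Numerical choices and degenerate inputs

Degeneracy tolerance 1e-12 m³; rotation orthonormality 1e-10; uniform
time grids to 1e-6 s; relative-deviation mask ε = 1e-6 in signal units
(the ratio is undefined at reference zero crossings; masked counts are
reported); extremum pairing window = half the median inter-extremum
interval, unpaired extrema counted; constant or sign-definite signals
yield empty extrema lists with a warning rather than an error; a
nominally static calibration shorter than 10 s warns. NAP angular
velocity components with near-zero magnitudes (<1e-3 rad/s) or cross
products (<1e-6) are returned with a low-confidence mask, not an
exception, and the very first sample's dominant-component sign is a
configuration flag.

## Problem sizes

The default verification runs use ten-step walks (≈5.6 s at 200 Hz) for
accuracy comparisons, 25–30 s recordings for threshold extraction and
detection trials (20 seeded trials per condition), and 1e5-sample static
series for the noise-calibration, lever-arm and differentiation
closed-form checks — sizes at which the Monte-Carlo standard errors are
comfortably below the tolerances being asserted.

## Known limitations

Rigid-mount assumption (no soft-tissue artefact model); no orientation
estimation (by design — the method needs none); the NAP sign-resolution
scheme is our continuity-based choice, flagged in output metadata; the
elliptical-slab inertia is one of several published trunk conventions;
detection tunables (bin width, ±15% rate tolerance, 25% minima filter,
iteration cap) are only qualitatively constrained by the framework and
are exposed in `DetectionConfig`.
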