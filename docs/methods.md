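# Methods

This note records the models implemented in `stemmap`, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and
the numerical decisions a maintainer would want spelled out.

## Conventions

Camera frame: x right, y down, z forward; image coordinates (u, v) are
column/row, 0-based, pixel centers at integer coordinates. Twists are
ordered rotation-first `(ωx, ωy, ωz, tx, ty, tz)`. All lengths are meters
(a centimeter baseline in a calibration file is converted on ingest). The
planar map frame is a top-down view with counter-clockwise positive heading;
a planar body frame has x along the heading and y to the left.

Two sign conventions deserve emphasis because they are easy to get wrong:

- **Jacobian of the warp.** The rotation block of `d(T(ξ)x)/dξ` at ξ = 0 is
  `−[x]×` for the standard exponential `T(ξ) = exp(ξ̂)`. Every analytic
  linearization in the package (the IC rows, the graph blocks A/B/C/D, the
  refinement blocks E/F) is validated against central finite differences in
  the test suite rather than trusted from a printed formula.
- **Planar heading from a camera twist.** With y pointing down, a positive
  rotation about the camera's y-axis is a clockwise turn seen from above,
  so `se3_to_se2_motion` returns θ = atan2(−R₀₂, R₂₂). This is the unique
  sign for which chaining the planar motion triples reproduces the
  plan-view projection of the chained 3-D motions — without it a real
  trajectory would be mirrored and could never be rigidly aligned to a GPS
  track. The property is tested explicitly.

The twist returned by `estimate_egomotion` is the *warp* twist (reference →
input coordinates); the camera's pose increment used to build the odometry
chain is its inverse. `run_vo_sequence` performs that inversion.

## Direct visual odometry

- **Pixel selection.** Zero-disparity pixels are discarded first (they
  back-project to infinity), the rest are ranked by gradient magnitude with
  raster-order tie-breaking, and the first `floor(N·p/100)` are kept, where
  N is the *total* pixel count — so a fixed percentage gives a
  fixed-size system (the 240×320 defaults give exactly 19,200 px at 25%).
- **IC iteration.** With residual `r = I′(W(p; ξ)) − I(p)`, the weighted GN
  step is `Δξ = (JᵀWJ)⁻¹ JᵀW r` followed by the inverse-compositional
  update `ξ ← log(exp(ξ)exp(−Δξ̂))`. J and H = JᵀJ are computed once per
  reference frame; that is the entire point of the IC formulation.
- **Robust weights.** `w_i = ρ(r_i/ŝ)` with ρ the Tukey biweight
  (c = 4.6851 for 95% normal efficiency) and `ŝ = 1.4826·median|r|`. No
  median subtraction: photometric residuals are assumed zero-centered. Note
  the biweight *weight* function `(1 − (u/c)²)²` equals ψ(u)/u for Tukey's
  ψ, so the "weight vs ψ/r" ambiguity is vacuous here — both forms
  coincide.
- **Interpolation and gradients.** Bilinear interpolation for warped
  lookups; central-difference gradients with replicated borders. Pixels
  warping out of the image or behind the camera get weight 0; more than 50%
  invalid raises a low-overlap warning.
- **Convergence.** Stop when ‖Δξ‖ < 1e-6 or the relative cost change is
  below 1e-8, with a 100-iteration default cap. Because J is frozen at the
  reference frame, convergence is linear far from the optimum; for warps of
  tens of pixels (large lateral motion) 100–250 iterations can be needed,
  so the simulation studies pass `max_iters=300`. There is no image
  pyramid: the method is intended for small inter-frame motion at video
  rate, and the synthetic scenes are band-limited accordingly (below).
- **Degenerate inputs.** A frame with no valid-disparity, nonzero-gradient
  pixel raises a degenerate-frame error; a singular weighted Hessian
  (textureless selection) raises a degenerate-texture error.

## Global alignment

- **State and residuals.** `s = (ϕ, v₁ … v_n)`. The motion residual is
  defined through the transform product `T(ξij)⁻¹T(vi)⁻¹T(vj)` so that it
  vanishes exactly on a chain built by composing the edges; the angle
  component is wrapped to (−π, π] before weighting. The GPS residual is
  `R(ϕ)t_i − g_k` with the track anchored at the first fix (stored and
  restored on recovery). At least two fixes are required for ϕ to be
  observable. Note (ϕ, poses) carry a one-dimensional gauge freedom —
  rotating all poses while decrementing ϕ leaves every residual unchanged —
  which is harmless: the damped system stays positive definite and the
  recovered (UTM) track is gauge-invariant.
- **Assembly and solving.** The normal equations are assembled analytically
  per edge/fix into a sparse symmetric matrix (phi row/column first). Below
  200 state entries a dense solve is used; above, a sparse LU
  factorization. Hessian blocks and gradients are verified against dense
  numerically-differentiated stacked Jacobians in the tests.
- **LM schedule.** Steps that increase the objective are rejected and the
  damping λ is doubled; accepted steps halve it; termination when the
  accepted ‖Δs‖ < 1e-3 (configurable). The damping is additive (H + λI).
  λ is initialized to `1e-8·max(diag H)`: the trace of H is dominated by
  the stiff heading-information entries and, used directly as λ, makes the
  first damped step smaller than the termination threshold — the solver
  would stop before moving. Initializing at a tiny fraction of the peak
  curvature starts the solver essentially at Gauss–Newton and lets step
  rejection grow λ only when needed. The raw trace rule remains available
  via `LMConfig.lambda_init_rule`.
- **ϕ initialization.** ϕ = 0 works for moderate frame misalignment but can
  start near the antipodal saddle when the odometry frame is ~π away from
  UTM. By default ϕ is initialized by a coarse 16-angle scan minimizing the
  *median* squared GPS misfit of the rigidly rotated chain (median, so
  outlier fixes cannot steer it). This changes only the starting point,
  never the model.
- **Robust GPS weighting.** Per-fix Tukey weights on MAD-standardized
  residual *norms*, multiplying Q_k; recomputed at each linearization and
  frozen within the iteration so that step acceptance compares a fixed
  objective.
- **Information defaults.** For user data: odometry
  `diag(1/0.1², 1/0.1², 1/0.005²)` (σt = 0.1 m, σθ = 0.005 rad — heading
  substantially stiffer than translation) and GPS `I/σ²` with σ = 5 m,
  optionally scaled per fix by PDOP (off by default; receivers report it
  but its calibration is receiver-specific). All are configurable; the
  right values are whatever matches the actual sensor noise, which is
  exactly how the simulation studies set them (below).

## Local refinement

Observations are transformed with the aligned poses, clustered once by
DBSCAN (Euclidean, radius 1 m, min 10 points, label 0 = outlier; backed by
scikit-learn and verified against a brute-force density-clustering oracle),
and cluster means initialize the stem centers. The augmented system drops
ϕ (consumed during recovery), so the GPS block is `(I₂, 0)`. Outlier
observations take no part in the optimization. The same LM driver is used;
internally the problem is translated to a local frame near the origin so
UTM-scale coordinates never enter the normal equations. Per-cluster
empirical covariances are reported before and after refinement; their mean
trace shrinking is the signature of the track and map improving jointly.

Observation information is `I/σ(d)²` with `σ(d) = 0.1 + 0.05·d` (d = range,
m): a 2 m stem is trusted to ~0.2 m, a 10 m stem to ~0.6 m. This encodes
the triangulation geometry (error grows with range) at the scale of a
stereo detector at VGA resolution; the synthetic detection generator draws
its noise from the same σ(d), so the information is consistent by
construction.

## Synthetic world and study conditions

The generators emulate a hand-held stereo survey of a ponderosa-pine-like
stand: a ~1115 m smooth walking path (bounded curvature ≤ 0.03 rad/m,
random initial heading) sampled at 10 poses/s at 1 m/s (~10 poses/m),
~140 stems with ≥ 2.5 m spacing in a 15 m corridor around the path, a
90° horizontal detection fov with a 12 m range, GPS noise σ = 5 m per axis,
a 5% uniform [0, 200] m radial outlier variant, and an intermittent variant
keeping the first fix, the last fix, and one random fix per 100 m interval
(12 fixes on the default path). All generators are pure functions of
(spec, seed) with split sub-streams; repeated calls are bit-identical.

Study-specific choices, made once:

- **Degraded/outlier GPS studies** use exact odometry edges with stiff
  information (σt = 0.5 mm, σθ = 2 µrad, heading stiffest). The edges are
  noise-free, so stiff information is consistent with the data and puts the
  estimator in the near-rigid regime these studies describe. In that regime
  the achievable RMSE against truth is the information floor of fitting a
  rigid shape to n noisy fixes, ≈ σ√(3/n) ≈ 0.08 m at n ≈ 11,000 — which
  is why the measured ~0.08 m sits where it does and why it cannot be
  driven arbitrarily low.
- **The intermittent study** adds drift to the edges: i.i.d. noise
  (σt = 2 mm, σθ = 0.5 mrad per edge, information matched) plus a constant
  heading-rate bias of 1e-5 rad per edge (0.1 mrad/m) with random sign —
  the systematic component that makes real uncorrected visual odometry
  curve away coherently. Against it we report two baselines: the raw chain
  after its *most favorable* rigid placement (an oracle baseline, placed
  using the truth), and piecewise-linear interpolation of the fixes.
- **The stem-map study** uses drifting odometry (σt = 2 cm, σθ = 2 mrad per
  edge) so the aligned track wobbles at the decimeter scale and the
  repeated stem sightings carry real information for the joint refinement.
  Its dead-mapping baseline re-places the *same* clustered observations
  using raw GPS positions with true headings — isolating the value of the
  fused track while keeping the association fixed.

What the generators do **not** emulate: real image noise, exposure changes
and motion blur (the renderer is noise-free and band-limited); canopy-
dependent, temporally correlated GPS error (noise is i.i.d.); detector
false positives and misses (every stem in the frustum is detected every
frame); terrain (the world is planar). Passing tests therefore demonstrate
the estimators' correctness and their behavior under the stated noise
models, not field performance.

**Rendered stereo pairs.** The test scene is a set of vertical stripes,
each a fronto-parallel plane at an exact integer disparity (depths 1–10.5 m
with f = 350 px, b = 0.12 m), textured with a smooth sinusoid mixture whose
frequencies are scaled by 1/z so the pixel-scale wavelength (~40–400 px) is
depth-independent: coarse enough that single-scale alignment has a wide
convergence basin, fine enough to constrain all six twist parameters. The
second view is evaluated analytically by ray/plane intersection — the exact
limit of warping the first image with perfect resampling — and disocclusion
bands are filled with a flat value (the robust weights discount them).

## Problem sizes

The simulation studies run at full scale: ~11,150 poses (33k–34k state
entries), ~11,150 GPS fixes, and 5–20k stem observations per run; each
alignment-plus-refinement takes a few seconds on one CPU, and the headline
numbers average 8 seeds. Unit and property tests use 60–300 m worlds.

## Known limitations

- Heading is observable only through odometry plus the GPS-constrained
  track shape; with very sparse fixes the heading drifts between them
  (a magnetometer term would fix this and would drop into the GPS-style
  residual structure directly).
- Clustering runs once on the aligned state; a grossly misaligned input
  track will produce merged or split clusters that refinement cannot undo.
- The VO front end is single-scale by design and will not converge for
  inter-frame displacements much beyond the texture wavelength.
- A single UTM zone is assumed; zone crossings are rejected at ingest.
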