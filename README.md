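# stemmap

Stereo visual odometry, GNSS fusion, and individual tree-stem mapping for
terrestrial forest inventory.

Consumer-grade GPS under a forest canopy is good to roughly 4–12 m — too
coarse to map individual trees or to hold a machine inside a virtual
boundary. A stereo camera, on the other hand, tracks its own motion with
centimeter-level *local* accuracy but drifts without bound. `stemmap`
combines the two: direct visual odometry provides locally rigid motion
estimates, a pose-graph optimizer conforms the odometry track to the GPS
track, and repeated camera-frame detections of tree stems are clustered into
landmarks and refined jointly with the trajectory, producing a georeferenced
stem map substantially more accurate than the GPS fixes it was built from.

## The model

**Direct visual odometry.** Frame-to-frame camera motion is a twist
ξ ∈ se(3) estimated by minimizing the photometric error

    min_ξ  Σ_{p∈Φ} [ I(p) − I′(W(p̃; ξ)) ]²,

where the warp `W(p̃; ξ) = π(T(ξ) π⁻¹(p̃, z))` back-projects a pixel with
its stereo depth `z = f·b/D` (integer disparity `D`, left/right consistency
checked with threshold δ = 1), applies the rigid transform `T(ξ) = exp(ξ̂)`,
and re-projects. Φ is the top fraction of pixels ranked by gradient
magnitude (a fixed percentage of the image, so the normal equations have a
fixed size). The solver is inverse-compositional Gauss–Newton: the Jacobian
and Hessian are built once on the reference frame, each step solves
`(JᵀWJ) Δξ = JᵀWr` and composes inversely, `ξ ← log(exp(ξ) exp(−Δξ̂))`.
The weights W are Tukey biweights (c = 4.6851) on MAD-standardized
residuals (k = 1.4826), which suppresses occlusions, exposure changes, and
bad disparities.

**Global alignment.** Planar poses v_i = (x, y, θ) form a chain with motion
edges ξ_ij and information matrices Q_ij; GPS fixes g_k (UTM meters,
anchored by subtracting the first fix) constrain poses through a global
orientation parameter ϕ:

    ε(s) = Σ r_ijᵀ Q_ij r_ij + Σ r_ikᵀ Q_k r_ik,
    r_ij = motion residual of (v_i, v_j),   r_ik = R(ϕ) t_i − g_k,

minimized over s = (ϕ, v_1 … v_n) by Levenberg–Marquardt with analytically
assembled sparse normal equations. GPS outliers are handled by the same
Tukey/MAD weighting applied per fix to Q_k.

**Local refinement.** Camera-frame stem detections are mapped to the world
with the aligned poses, associated by DBSCAN (1 m radius, ≥ 10 points), and
initialized at cluster means m_ℓ. The augmented state (v_1…v_n, m_1…m_L)
is then optimized over the combined objective with stem residuals
`r_iℓ = R(θ_i)ᵀ(m_ℓ − t_i) − z_iq`, tightening both the track and the map.

A synthetic-world module generates every input — smooth kilometer-scale
trajectories with exact odometry edges, degraded/intermittent GPS,
range-dependent stem detections, and rendered stereo pairs with exact
disparity — so the full stack is testable without field data.

## Worked example

```
$ stemmap simulate --seed 3 --out survey --path-length 300 --gps-sigma 5
wrote synthetic survey: 2501 poses, 2501 GPS fixes, 3624 detections, 140 stems

$ cat > config.yaml <<EOF
odometry: survey/odometry.csv
gps: survey/gps.csv
detections: survey/detections.csv
output_dir: out
odom_sigma_t: 0.001
odom_sigma_theta: 0.0001
EOF
$ stemmap run --config config.yaml
{
 "stages": {
  "odometry": {"n_poses": 2501},
  "align": {"iterations": 14, "phi": 1.1931421595778238,
            "final_objective": 4343.162757027982},
  "refine": {"iterations": 10, "n_stems": 66, "n_observations": 3624,
             "n_outlier_observations": 81}
 },
 "elapsed_s": 2.58
}

$ stemmap evaluate --stems out/stem_map.csv --truth-stems survey/truth_stems.csv \
    --trajectory out/trajectory_refined.csv --truth-trajectory survey/truth_trajectory.csv
{
 "stem_rmse_m": 0.21286123143817917,
 "matched": 66,
 "duplicates": 0,
 "false_positives": 0,
 "trajectory_rmse_m": 0.058000894408422585
}
```

Reading: from GPS fixes with 5 m noise, the fused track is recovered to
~0.06 m RMSE, and the 66 stems that were sighted at least 10 times are
mapped to ~0.21 m RMSE — over twenty times better than the raw GPS — with
no spurious or duplicated stems. (Exact numbers vary with the seed;
`stemmap simulate --help` lists the scenario knobs, including intermittent
GPS and outlier contamination.)

The library API mirrors the pipeline: `estimate_egomotion`, `build_graph` /
`lm_optimize` / `recover_global`, `refine_map`, and the generators in
`stemmap.synthetic`. See `docs/methods.md` for the modeling details and
parameter choices.

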