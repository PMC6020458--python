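# Methods

## Model

`slsm3d` segments a single bright, approximately spherical target in a
3D scalar volume with a two-region level-set evolution. The implicit
field φ is positive inside the target, zero on its surface, negative
outside. One explicit Euler step is

    Δφ = δ_ε(φ) [ μ·κ − ν − λ₁(μ₀ − c₁)² + λ₂(μ₀ − c₂)² ] + τ·φ_s,
    φ ← φ + dt·Δφ,

with κ = div(∇φ/|∇φ|) the mean curvature of the level sets, c₁ and c₂
the mean intensities over {φ > 0} and {φ ≤ 0} (recomputed every step),
and δ_ε the Cauchy-shaped Dirac weight (1/π)·ε/(ε² + φ²). The region
terms drive each voxel toward the side whose mean it resembles; λ₂ > λ₁
biases capture of targets brighter than their surroundings.

The shape term is refitted every iteration: the current region is
summarized by the sphere of equal voxel volume (center = centroid of
{φ > 0}, radius from V = (4/3)πr³) and expanded to the signed radial
field φ_s = r − ‖p − c‖. Because τ·φ_s is *not* damped by δ_ε, it acts
everywhere: distant false-positive fragments sit deep in φ_s < 0 and
are steadily drained, while voxels near the fitted surface feel almost
nothing. With τ = 0 the prior is disabled and the method is a plain 3D
two-region level set.

Assumptions: one connected, roughly convex target brighter than the
background (λ defaults), approximately spherical (the prior's family is
spheres only), and an initial seed sphere overlapping the target.

## Parameters

| name | default | units / meaning |
|---|---|---|
| λ₁, λ₂ | 1, 2 | inside/outside region weights; λ₂ > λ₁ favors bright targets |
| μ | 0.2 | curvature smoothing weight |
| ν | 0 | constant height adjustment; > 0 shrinks the region |
| ε | 3.0 | Dirac width, voxels of φ |
| dt | 5.0 | Euler step (matched to [0, 1]-normalized intensities) |
| τ | 0.02 | shape-prior weight; 0 disables |
| max_iters, tol | 300, 1e-3 | stop at mean |Δφ| < tol or the iteration cap |
| init radius | min(shape)/8 | seed sphere at the volume center |

Intensities are min-max rescaled to [0, 1] before evolution (the
`normalize` flag). This is numerical conditioning: it fixes the scale
of the region terms so one set of (dt, τ, μ) defaults behaves the same
across images, and it makes the output invariant to affine intensity
changes. With dt = 5 the interface moves on the order of one voxel per
iteration; much smaller steps leave the surface essentially frozen
within the iteration cap, much larger ones overshoot so far that φ
becomes jagged and the Dirac weight freezes misclassified voxels.

The width ε = 3 matters for the prior: the barrier a noise voxel puts
up at the surface scales with δ_ε(0) = 1/(πε), so a wider Dirac band
lets τ·φ_s override isolated bright voxels that are pointwise
indistinguishable from tumor.

The seed sphere should start *inside* the target. The refitted
equal-volume sphere makes any solid ball a self-consistent state (a
ball reproduces its own fit), so a seed much larger than the target can
lock the evolution near the oversized sphere; grown from inside, the
fit tracks the region and the prior only ever cleans up around it.

## Numerics

Derivatives are central differences with replicate (edge-clamped)
boundaries; second and mixed derivatives likewise. The curvature
denominator (|∇φ|²)^{3/2} is regularized by adding η² = 1e-8 inside the
power, and the result is clipped to ±3: the mean curvature resolvable
on a unit lattice is bounded, while the closed-form estimator diverges
where |∇φ| ≈ 0 with nonzero second derivatives, and those spikes are
purely numerical. No signed-distance reinitialization is performed by
default (`reinit_every` enables it); φ is not a distance function after
the first step and none of the terms require it.

Two literal-mode flags reproduce historically printed variants of the
update — `paper_literal_signs` negates both region terms (which cannot
drive a surface toward a bright target and is kept only for
comparison), and `paper_literal_curvature` uses an asymmetric curvature
cross-term set (−2fx·fy·fyz − 2fx·fy·fxy − 2fx·fz·fxz) instead of the
symmetric divergence identity. Defaults use the consistent forms.
Similarly, the prior field defaults to the Euclidean signed distance
r − ‖p − c‖; a `squared` flag exposes the radical-free literal variant
r − ‖p − c‖², which grows quadratically and overwhelms the evolution at
realistic τ.

Ties and degenerate cases: voxels with φ = 0 exactly belong to the
outside region for c₂, and the output mask is the strict {φ > 0}. An
evolution that empties either region raises a degenerate-region error
carrying the iteration index. A constant field has no isosurface and
yields an empty mesh rather than an error.

## Phantom generator

`make_phantom` emulates the benchmark images used for quantitative
evaluation: a sphere or ellipsoid of one intensity (default 200) on a
darker background (default 50) in a 64³ grid, blurred per z-slice by a
k×k uniform mean filter (edge replication) and then corrupted by
salt-and-pepper impulse noise that replaces each voxel with probability
`noise_density` by the volume minimum or maximum (equal odds). Blur
precedes noise so the speckle stays sharp, matching the benchmark's
visual description; a flag reverses the order. The study conditions are
densities of 10–50% and masks 3×3 to 7×7; the ground-truth mask is the
analytic region (voxel centers inside the ellipsoid) and is independent
of corruption and seed.

What the phantom does *not* emulate: MRI bias fields, Rician noise,
partial-volume gradients at tissue interfaces, anatomical clutter, or
inter-observer truth uncertainty. Passing phantom benchmarks therefore
demonstrates the mechanics of the method — noise suppression by the
prior, recovery of a known shape — not clinical performance.

## Evaluation conventions

Confusion counts are computed over the full (ROI-cropped) lattice; the
ROI is an axis-aligned box, half-open in every coordinate, delineated
on one slice and extended across a slice range. Standard (ground-truth)
contours from several expert delineations are combined by voxelwise
intersection. CCR, SP and FAR are kept at full precision internally and
rounded half-up to 2 decimals for report tables. The bundled clinical
reference counts contain one externally reported row whose tallies are
inconsistent with its own Nₚ/Nₙ columns; counts are therefore validated
advisorily (`is_consistent()`), while counts the package computes
itself always satisfy the identities. Dice is available as an extra
metric and is used by the phantom benchmark alongside the triple.

Benchmark problem sizes: phantoms are 64³ with a radius-10 tumor, and
the grid comparison uses five replicate seeds per cell; these sizes
give stable means (Dice spread across seeds ≲ 0.01) while keeping a
full benchmark run in minutes on a single core.

## Surface extraction

Meshes come from marching cubes (scikit-image's lookup-table
implementation) with linearly interpolated vertices. Binary masks are
padded with one background layer before extraction so surfaces close
even when the mask touches the volume boundary (a warning notes that
the closure there is an artifact), and vertex coordinates are shifted
back to unpadded space. Mesh volume is the signed-tetrahedron sum, area
the triangle-area sum. Known limitation: masks with diagonally touching
voxels (checkerboard configurations) produce non-manifold edges — an
inherent marching-cubes ambiguity that does not arise at the smooth
φ = 0 isosurface.

## Design choices

- The estimator follows scikit-learn clusterer semantics
  (`fit`/`fit_predict`, fitted attributes `mask_`, `phi_`, `n_iter_`,
  `c1_`, `c2_`, `converged_`) so it composes with sklearn tooling;
  `run_segmentation` is a functional wrapper.
- The per-iteration sphere refit uses unweighted voxel positions, not
  intensity weighting.
- τ is a scalar broadcast uniformly; a spatially varying weight field
  can be supplied by calling `lsm_step` directly with a custom prior.
- Anisotropic voxel spacing is carried as metadata but the lattice is
  treated as unit cubes during evolution; spacing-aware gradients were
  left out because every supported workflow resamples or accepts the
  approximation at 2 mm slice spacing.

## Known limitations

- Single target, two regions; no multiphase extension.
- The sphere prior penalizes genuinely non-spherical tumors; τ must be
  lowered or zeroed for irregular shapes.
- Whole-volume dense updates (no narrow band); 300 iterations on a 64³
  volume take a few seconds, but cost grows linearly with voxel count.
- Explicit Euler with a fixed step; stability relies on the curvature
  clip and normalization rather than an adaptive step.
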