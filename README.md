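# slsm3d

Three-dimensional shape-weighted level-set segmentation of volumetric
tumor images, with a synthetic-phantom benchmark, the CCR/SP/FAR
evaluation triple, and marching-cubes surface extraction.

## The problem

Measuring a tumor's size and shape from MRI requires segmenting it in
3D. Stacking independent 2D segmentations ignores the coupling between
adjacent slices; a true 3D method evolves a single surface through the
whole volume. Breast DCE-MRI adds two difficulties: heavy noise and
indistinct margins where tumor infiltrates surrounding tissue, so a
purely intensity-driven surface picks up scattered background fragments.
`slsm3d` is written for researchers in medical image analysis who need a
tested, reproducible implementation of a region-based 3D level set with
a spherical shape prior, plus the infrastructure to benchmark it.

## The model

The surface is carried implicitly by a scalar field φ(x, y, z): φ > 0
inside, φ = 0 on the surface, φ < 0 outside. Each iteration applies

    Δφ = δ_ε(φ) [ μ·div(∇φ/|∇φ|) − ν − λ₁(μ₀ − c₁)² + λ₂(μ₀ − c₂)² ] + τ·φ_s
    φ ← φ + dt·Δφ

where μ₀ is the image, c₁/c₂ are the mean intensities inside/outside the
current surface (the two-region Chan–Vese energy), δ_ε(φ) =
(1/π)·ε/(ε² + φ²) concentrates updates near the surface, and
div(∇φ/|∇φ|) is the mean curvature, which smooths the surface.

The shape term τ·φ_s is the distinctive ingredient: at every iteration
the inside region {φ > 0} is summarized by the **equal-volume sphere** —
center at the region's centroid, radius r from V = (4/3)πr³ with V the
voxel count — and expanded into the signed radial field
φ_s = r − ‖p − c‖. Added with weight τ, it pulls the evolving surface
toward the fitted sphere: voxels far outside it are drained (suppressing
background noise and disconnected fragments) while the surface region is
barely perturbed. With τ = 0 the method reduces to a plain 3D level set.

Accuracy against a ground-truth mask is reported as
CCR = (TPN+TNN)/N, SP = TNN/(TNN+FPN), FAR = FPN/Nₙ (all in %), the
standard triple for medical detection systems.

## Worked example

Segment a simulated tumor (radius-10 sphere of intensity 200 on
background 50 in a 64³ grid, degraded by 5×5 mean-filter blur and 30%
salt-and-pepper noise), with and without the shape prior:

```python
from slsm3d import (BinaryMask, PhantomSpec, ShapeWeightedLevelSet3D,
                    confusion, dice, make_phantom, metrics)

vol, truth = make_phantom(PhantomSpec(noise_density=0.3, blur_mask=5, seed=0))
for tau, label in ((0.0, "3D-LSM "), (0.02, "3D-SLSM")):
    est = ShapeWeightedLevelSet3D(tau=tau)
    mask = BinaryMask(est.fit_predict(vol))
    m = metrics(confusion(mask, truth)).rounded()
    print(f"{label}  CCR={m.ccr:6.2f}%  SP={m.sp:6.2f}%  FAR={m.far:5.2f}%  "
          f"Dice={dice(mask, truth):.3f}  iters={est.n_iter_}")
```

prints

```
3D-LSM   CCR= 97.01%  SP= 97.22%  FAR= 2.78%  Dice=0.471  iters=300
3D-SLSM  CCR= 99.81%  SP= 99.84%  FAR= 0.16%  Dice=0.943  iters=300
```

Without the prior, bright noise voxels near the growing surface are
captured as false positives (FAR 2.78%, Dice 0.471); the sphere prior
drains them and the result closely matches the analytic ground truth.
The segmented mask converts to a closed triangle mesh for viewing:

```python
from slsm3d import render_mask
mesh = render_mask(mask)
print(f"{len(mesh.triangles)} triangles, closed={mesh.is_closed()}, "
      f"volume={mesh.enclosed_volume():.0f} vox^3")
```

On the clean phantom this prints
`3800 triangles, closed=True, volume=4148 vox^3` (analytic sphere:
4189).

The same pipeline is available from the shell:

```sh
slsm3d phantom --shape 64,64,64 --radius 10 --density 0.3 --mask 5 \
               --seed 0 --out vol.nii.gz --truth truth.nii.gz
slsm3d segment --in vol.nii.gz --out mask.nii.gz --tau 0.02
slsm3d evaluate --pred mask.nii.gz --truth truth.nii.gz
slsm3d render  --in mask.nii.gz --out tumor.stl
slsm3d bench   --densities 0.1,0.3,0.5 --masks 3,5,7 --replicates 3 --seed 1
```

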