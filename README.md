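# mrvolumetry

Tumour volumetry from small-animal MR images: a batch, reproducible
implementation of semi-automatic threshold segmentation with manual
exclusion polygons and interior hole filling, the sphere-on-grid
simulation that bounds the partial-volume-effect (PVE) error of any such
segmentation, caliper (gauge-block) mass estimation, and the agreement
statistics used to compare the methods. A synthetic phantom generator
with analytic ground-truth volume makes every stage testable without
animal data.

It is aimed at preclinical imaging groups who measure subcutaneous
xenograft tumours (here in the 0.01–2.28 g range) on T2-weighted images,
where the tumour appears hyperintense on a darker background, and who
need to know how much of their volume error is attributable to voxels
straddling the tumour rim.

## The methods in brief

**Segmentation.** The mean signal of a hand-drawn region containing
roughly equal amounts of tumour and background sets a global threshold;
voxels at or above it are tumour. The threshold can be replaced per
slice, polygons can exclude regions of failed segmentation, and enclosed
low-signal interior regions (necrosis) are converted back to tumour by
hole filling or seeded region growing. The tumour voxel count times the
voxel volume, at an assumed density of 1.0 g/cm³, gives the mass:
*m* = *N*·*v*·ρ.

**PVE error bounds.** A sphere of diameter *d* is superimposed on a grid
of cubic elements of edge *a* with coinciding origins. Elements fully
inside the sphere are tumour, elements crossed by the rim are PVE
elements. Counting the PVE elements entirely as tumour or entirely as
background gives the two extreme segmentations Ṽ₊ and Ṽ₋, reported as
relative errors 100·(Ṽ−V)/V against V = (π/6)·d³. The single governing
parameter is the voxels-per-diameter ratio *d/a*; at ratio 12 the worst
error is ≈ 40 %.

**Caliper comparison.** Three perpendicular diameters give an ellipsoid
mass m_GB = ρ·(π/6)·l·w·h. Agreement is quantified by the coefficient
of variation of repeated segmentations, signed relative deviation from a
reference mean, and ordinary least-squares regression with Pearson r².

## Worked example

```python
from mrvolumetry import (PhantomSpec, PlanarROI, render_phantom,
                         segment_tumour, simulate_pve, SphereGridSpec,
                         sphere_diameter_for_mass)

# PVE bounds for a 3 mm tumour imaged at 250 µm isotropic voxels
res = simulate_pve(SphereGridSpec(diameter_um=3000, voxel_edge_um=250))
print(f"ratio {res.ratio:.0f}: over {res.over_error_pct:+.1f} %, "
      f"under {res.under_error_pct:+.1f} %")

# a 0.10 g spherical phantom at 160 µm voxels, mild noise
radius = sphere_diameter_for_mass(0.10) / 2
spec = PhantomSpec(semi_axes_um=(radius,) * 3, spacing_um=(160.0,) * 3,
                   noise_sigma=4.0, seed=1)
image, truth, analytic_mm3 = render_phantom(spec)

# reference region straddling the rim on the central slice
zc, rc = image.shape[0] // 2, image.shape[1] // 2
edge = image.shape[2] / 2 + radius / 160.0
roi = PlanarROI(zc, [(rc - 5, edge - 5), (rc - 5, edge + 5),
                     (rc + 5, edge + 5), (rc + 5, edge - 5)])
mask, est = segment_tumour(image, roi)
print(f"mass {est.mass_g:.4f} g, volume {est.volume_mm3:.2f} mm³ "
      f"({est.method_tag})")
```

prints

```
ratio 12: over +38.8 %, under -31.0 %
mass 0.0976 g, volume 97.60 mm³ (seg3D)
```

The phantom's analytic volume is 100.0 mm³, so the recovered mass is
2.4 % low — comfortably inside the ±~40 % worst-case PVE band for a
ratio-12 geometry, and typical for a threshold that lands near the
half-occupancy level.

The same pipelines are scriptable from the shell; every command writes
its results plus a provenance JSON (inputs, parameters, seed, version)
so runs replay bit-identically:

```sh
mrvolumetry simulate-pve --diameter-um 3000 --voxel-um 250
mrvolumetry sweep-pve               # CSV + text table over 3–9 mm × 100–250 µm
mrvolumetry phantom --mass-g 0.1 --voxel-um 160,160,160 --seed 1
mrvolumetry segment --image phantoms/….nii.gz --roi roi.json
mrvolumetry agree --masses-csv masses.csv
```

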