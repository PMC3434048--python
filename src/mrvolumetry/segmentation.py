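"""Semi-automatic tumour delineation pipeline.

The pipeline mirrors an interactive workflow made batch-reproducible:

1. a planar reference region straddling the tumour border, containing
   roughly equal amounts of tumour and background tissue, sets the global
   segmentation threshold (its mean intensity);
2. the threshold is applied to every slice, with optional per-slice
   replacement values where the global value fails;
3. exclusion polygons remove regions of failed segmentation;
4. enclosed low-signal interior regions (e.g. necrosis), wrongly assigned
   to background, are converted back to tumour by hole filling (automatic)
   or seeded region growing;
5. the voxel count is converted to a mass.

Tumours are hyperintense (T2-weighted appearance), so a voxel is labelled
tumour when its intensity is greater than or equal to the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import Polygon

from .core import ImageVolume, MassEstimate, SegMask, mask_to_mass

__all__ = [
    "PlanarROI",
    "ThresholdPlan",
    "estimate_threshold",
    "apply_threshold",
    "exclude_polygons",
    "fill_interior",
    "segment_tumour",
]


@dataclass(frozen=True)
class PlanarROI:
    """A closed polygon on one slice, in (row, column) voxel coordinates.

    Voxel centers sit at integer coordinates; fractional vertices are
    allowed.  Used both for the threshold reference region and for
    exclusion polygons.
    """

    slice_index: int
    vertices: tuple[tuple[float, float], ...]

    def __init__(self, slice_index: int, vertices: Iterable[Sequence[float]]):
        object.__setattr__(self, "slice_index", int(slice_index))
        verts = tuple((float(r), float(c)) for r, c in vertices)
        object.__setattr__(self, "vertices", verts)
        if len(verts) < 3:
            raise ValueError(f"polygon needs >=3 vertices, got {len(verts)}")
        if not self.polygon().is_valid:
            raise ValueError("polygon is self-intersecting or degenerate")

    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @classmethod
    def from_dict(cls, d: dict) -> "PlanarROI":
        return cls(d["slice"], d["vertices"])

    def to_dict(self) -> dict:
        return {"slice": self.slice_index, "vertices": [list(v) for v in self.vertices]}


@dataclass(frozen=True)
class ThresholdPlan:
    """A global threshold with optional per-slice replacement values."""

    global_value: float
    per_slice_overrides: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.global_value):
            raise ValueError("global threshold must be finite")
        for k, v in self.per_slice_overrides.items():
            if not np.isfinite(v):
                raise ValueError(f"override for slice {k} must be finite")

    def effective(self, slice_index: int) -> float:
        return self.per_slice_overrides.get(slice_index, self.global_value)


def _check_slice(index: int, n_slices: int) -> None:
    if not (0 <= index < n_slices):
        raise IndexError(f"slice index {index} out of range [0, {n_slices})")


def _covered_centers(roi: PlanarROI, shape_rc: tuple[int, int],
                     include_boundary: bool = True) -> np.ndarray:
    """Boolean (rows, cols) raster of voxel centers selected by the polygon.

    Center-inside membership; ``include_boundary`` decides whether centers
    lying exactly on the polygon edge count as selected.
    """
    poly = roi.polygon()
    rmin, cmin, rmax, cmax = poly.bounds
    r0 = max(0, int(np.floor(rmin)))
    r1 = min(shape_rc[0] - 1, int(np.ceil(rmax)))
    c0 = max(0, int(np.floor(cmin)))
    c1 = min(shape_rc[1] - 1, int(np.ceil(cmax)))
    out = np.zeros(shape_rc, dtype=bool)
    if r1 < r0 or c1 < c0:
        return out
    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    if include_boundary:
        hit = shapely.intersects_xy(poly, rr.ravel(), cc.ravel())
    else:
        hit = shapely.contains_xy(poly, rr.ravel(), cc.ravel())
    out[r0:r1 + 1, c0:c1 + 1] = hit.reshape(rr.shape)
    return out


def estimate_threshold(image: ImageVolume, roi: PlanarROI) -> float:
    """Mean intensity over the voxel centers inside the reference region.

    With a region containing approximately equal amounts of tumour and
    background, the mean lands midway between the two class intensities.
    """
    _check_slice(roi.slice_index, image.n_slices)
    sel = _covered_centers(roi, image.shape[1:])
    if not sel.any():
        raise ValueError("ROI rasterizes to zero voxel centers")
    return float(image.data[roi.slice_index][sel].mean())


def apply_threshold(image: ImageVolume, plan: ThresholdPlan | float) -> SegMask:
    """Label every voxel with intensity >= its slice's effective threshold."""
    if not isinstance(plan, ThresholdPlan):
        plan = ThresholdPlan(float(plan))
    for idx in plan.per_slice_overrides:
        _check_slice(idx, image.n_slices)
    thresholds = np.array([plan.effective(i) for i in range(image.n_slices)])
    labels = image.data >= thresholds[:, None, None]
    step = {
        "op": "apply_threshold",
        "global_value": plan.global_value,
        "per_slice_overrides": {int(k): float(v) for k, v in plan.per_slice_overrides.items()},
    }
    return SegMask(labels, image.spacing, [step])


def exclude_polygons(
    mask: SegMask,
    polygons: Sequence[PlanarROI],
    boundary_policy: str = "background",
) -> SegMask:
    """Set the voxels selected by each polygon to background on its slice.

    Selection is by voxel-center test.  Voxels whose centers lie exactly on
    the polygon edge follow ``boundary_policy``: ``"background"`` (default)
    excludes them, ``"tumour"`` keeps them — the assignment of
    border-intersected voxels is consequential for small tumours, so it is
    an explicit choice rather than an accident of the rasterizer.
    """
    if boundary_policy not in ("background", "tumour"):
        raise ValueError(f"boundary_policy must be 'background' or 'tumour', got {boundary_policy!r}")
    labels = mask.labels.copy()
    for roi in polygons:
        _check_slice(roi.slice_index, labels.shape[0])
        sel = _covered_centers(roi, labels.shape[1:],
                               include_boundary=(boundary_policy == "background"))
        labels[roi.slice_index][sel] = False
    step = {
        "op": "exclude_polygons",
        "n_polygons": len(polygons),
        "boundary_policy": boundary_policy,
        "polygons": [p.to_dict() for p in polygons],
    }
    return mask.with_labels(labels, step)


def _fill_structure(mask: SegMask, connectivity: str) -> tuple[np.ndarray, bool]:
    """Binary structure for background connectivity, and whether to work
    slice-by-slice."""
    if connectivity == "auto":
        # single-slice volumes must be filled in-plane: a 3D fill would see
        # any in-slice hole as connected to the array's z-border
        slicewise = _is_2d_stack(mask) or mask.labels.shape[0] == 1
    elif connectivity == "slice":
        slicewise = True
    elif connectivity == "volume":
        slicewise = False
    else:
        raise ValueError(f"connectivity must be 'auto', 'slice' or 'volume', got {connectivity!r}")
    if slicewise:
        return ndimage.generate_binary_structure(2, 1), True  # 4-neighbourhood
    return ndimage.generate_binary_structure(3, 1), False  # 6-neighbourhood


def _is_2d_stack(mask: SegMask) -> bool:
    from .core import is_thick_slice_stack

    return is_thick_slice_stack(mask.spacing)


def fill_interior(
    mask: SegMask,
    seeds: Sequence[tuple[int, int, int]] | None = None,
    connectivity: str = "auto",
) -> SegMask:
    """Convert enclosed background regions to tumour.

    Automatic mode (no seeds) fills every background component not connected
    to the image border — hole filling, the non-interactive equivalent of a
    growing-seed conversion of enclosed low-signal interior regions.  Seeded
    mode converts only the background components containing a seed.

    Connectivity is 6-neighbourhood in 3D for isotropic volumes and
    4-neighbourhood per slice for thick-slice 2D stacks (``auto``), fewer
    diagonal bridges than the alternatives; override with ``'slice'`` or
    ``'volume'``.
    """
    structure, slicewise = _fill_structure(mask, connectivity)
    labels = mask.labels
    if seeds is None:
        if slicewise:
            filled = np.stack([ndimage.binary_fill_holes(sl, structure=structure)
                               for sl in labels])
        else:
            filled = ndimage.binary_fill_holes(labels, structure=structure)
        step = {"op": "fill_interior", "mode": "automatic",
                "connectivity": "slice" if slicewise else "volume"}
        return mask.with_labels(filled, step)

    filled = labels.copy()
    background = ~labels
    if slicewise:
        comp = np.zeros(labels.shape, dtype=np.int64)
        offset = 0
        for z in range(labels.shape[0]):
            lab, n = ndimage.label(background[z], structure=structure)
            lab = np.where(lab > 0, lab + offset, 0)
            comp[z] = lab
            offset += n
    else:
        comp, _ = ndimage.label(background, structure=structure)
    convert: set[int] = set()
    for seed in seeds:
        seed = tuple(int(x) for x in seed)
        if any(not (0 <= seed[a] < labels.shape[a]) for a in range(3)):
            raise IndexError(f"seed {seed} out of bounds for shape {labels.shape}")
        if labels[seed]:
            warnings.warn(f"seed {seed} lies inside the tumour region; ignored",
                          stacklevel=2)
            continue
        convert.add(int(comp[seed]))
    convert.discard(0)
    if convert:
        filled |= np.isin(comp, sorted(convert))
    step = {"op": "fill_interior", "mode": "seeded",
            "seeds": [list(map(int, s)) for s in seeds],
            "connectivity": "slice" if slicewise else "volume"}
    return mask.with_labels(filled, step)


def segment_tumour(
    image: ImageVolume,
    roi: PlanarROI,
    overrides: dict[int, float] | None = None,
    polygons: Sequence[PlanarROI] = (),
    seeds: Sequence[tuple[int, int, int]] | None = None,
    boundary_policy: str = "background",
    connectivity: str = "auto",
    density_g_cm3: float = 1.0,
) -> tuple[SegMask, MassEstimate]:
    """Full pipeline: threshold estimate → threshold → exclusion → fill → mass.

    ``seeds=None`` uses automatic hole filling; pass ``seeds=[]`` to skip
    interior conversion entirely.
    """
    thr = estimate_threshold(image, roi)
    plan = ThresholdPlan(thr, dict(overrides or {}))
    mask = apply_threshold(image, plan)
    mask = exclude_polygons(mask, polygons, boundary_policy=boundary_policy)
    if seeds is None or len(seeds) > 0:
        mask = fill_interior(mask, seeds=seeds, connectivity=connectivity)
    estimate = mask_to_mass(mask, density_g_cm3=density_g_cm3)
    return mask, estimate
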