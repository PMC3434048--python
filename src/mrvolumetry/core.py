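"""Shared domain types and physical-unit bookkeeping.

All physical quantities use a fixed internal convention: voxel spacing in
micrometres (µm), volumes in cubic millimetres (mm³), masses in grams (g)
and densities in g/cm³.  Every unit conversion in the package happens here.

Image axes are ordered (slice, row, column); spacing triples are stored in
the same order.  Anisotropic multi-slice 2D stacks (thick slices, e.g.
700 µm slices over ~150–200 µm in-plane pixels) and isotropic 3D volumes
share the same representation — the spacing ratio alone distinguishes them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

__all__ = [
    "ImageVolume",
    "SegMask",
    "MassEstimate",
    "voxel_volume",
    "mask_to_mass",
    "is_thick_slice_stack",
]

#: spacing anisotropy (slice / max in-plane) above which a volume is
#: treated as a multi-slice 2D stack rather than an isotropic 3D volume
THICK_SLICE_ANISOTROPY = 2.0

UM3_PER_MM3 = 1e9
MM3_PER_CM3 = 1e3


def _validate_spacing(spacing: Sequence[float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise ValueError(f"spacing must have 3 entries, got {len(spacing)}")
    if not all(np.isfinite(spacing)) or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be strictly positive and finite, got {spacing}")
    return spacing


@dataclass
class ImageVolume:
    """A 3D scalar intensity grid with physical voxel spacing.

    Parameters
    ----------
    data
        3D array of nonnegative, finite intensities, axis order
        (slice, row, column).
    spacing
        Voxel edge lengths in µm, ordered like the axes.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"image data must be 3D, got ndim={self.data.ndim}")
        if self.data.size == 0:
            raise ValueError("image data must have at least one element per axis")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image intensities must be finite")
        if np.any(self.data < 0):
            raise ValueError("image intensities must be nonnegative")
        self.spacing = _validate_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    def is_thick_slice_stack(self) -> bool:
        return is_thick_slice_stack(self.spacing)


def is_thick_slice_stack(spacing: Sequence[float]) -> bool:
    """True when the slice spacing dwarfs the in-plane spacing (2D protocol)."""
    s = _validate_spacing(spacing)
    return s[0] > THICK_SLICE_ANISOTROPY * max(s[1], s[2])


@dataclass
class SegMask:
    """A binary tumour/background labelling aligned to an :class:`ImageVolume`.

    ``provenance`` records the ordered list of operations that produced the
    mask (thresholds applied, polygons excluded, holes filled), so a run can
    be audited and replayed.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    provenance: list[dict[str, Any]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=bool)
        if self.labels.ndim != 3:
            raise ValueError(f"mask labels must be 3D, got ndim={self.labels.ndim}")
        self.spacing = _validate_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.labels))

    def with_labels(self, labels: np.ndarray, step: dict[str, Any]) -> "SegMask":
        """Derived mask with one provenance step appended."""
        return SegMask(labels, self.spacing, self.provenance + [step])


@dataclass(frozen=True)
class MassEstimate:
    """A tumour mass in grams, with its volume, density assumption and origin.

    ``method_tag`` distinguishes the estimation route: ``seg2D`` (thick-slice
    stack segmentation), ``seg3D`` (isotropic volume segmentation),
    ``gauge_block`` (caliper triple via the ellipsoid formula) and
    ``reference`` (e.g. resection weight).
    """

    mass_g: float
    volume_mm3: float
    density_g_cm3: float
    method_tag: str

    _TAGS = ("seg2D", "seg3D", "gauge_block", "reference")

    def __post_init__(self) -> None:
        if self.method_tag not in self._TAGS:
            raise ValueError(f"method_tag must be one of {self._TAGS}, got {self.method_tag!r}")
        if self.density_g_cm3 <= 0:
            raise ValueError("density must be positive")
        if self.mass_g < 0:
            raise ValueError("mass must be nonnegative")
        expected = self.volume_mm3 / MM3_PER_CM3 * self.density_g_cm3
        if not np.isclose(self.mass_g, expected, rtol=1e-9, atol=1e-15):
            raise ValueError(
                f"inconsistent MassEstimate: mass {self.mass_g} g != "
                f"volume {self.volume_mm3} mm³ × density {self.density_g_cm3} g/cm³"
            )


def voxel_volume(spacing: Sequence[float]) -> float:
    """Volume of one voxel in mm³ from its per-axis edge lengths in µm."""
    s = _validate_spacing(spacing)
    return s[0] * s[1] * s[2] / UM3_PER_MM3


def mask_to_mass(
    mask: SegMask,
    spacing: Sequence[float] | None = None,
    density_g_cm3: float = 1.0,
    method_tag: str | None = None,
) -> MassEstimate:
    """Convert a segmentation mask to a tumour mass.

    The number of tumour voxels times the voxel volume gives the tumour
    volume, converted to mass under an assumed uniform tumour density
    (default 1.0 g/cm³).

    Parameters
    ----------
    mask
        The segmentation; its own spacing is used unless ``spacing`` is given.
    spacing
        Optional override of the voxel edge lengths (µm).
    density_g_cm3
        Assumed tumour density, must be positive.
    method_tag
        Override for the provenance tag; by default inferred from the
        spacing anisotropy (``seg2D`` for thick-slice stacks, else ``seg3D``).
    """
    if density_g_cm3 <= 0:
        raise ValueError(f"density must be positive, got {density_g_cm3}")
    s = _validate_spacing(spacing if spacing is not None else mask.spacing)
    vol_mm3 = mask.voxel_count() * voxel_volume(s)
    if method_tag is None:
        method_tag = "seg2D" if is_thick_slice_stack(s) else "seg3D"
    mass_g = vol_mm3 / MM3_PER_CM3 * density_g_cm3
    return MassEstimate(mass_g=mass_g, volume_mm3=vol_mm3,
                        density_g_cm3=density_g_cm3, method_tag=method_tag)
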