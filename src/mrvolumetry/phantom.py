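"""Synthetic MR-like tumour phantoms with analytic ground truth.

The generator emulates the appearance that the segmentation pipeline is
built for: a hyperintense ellipsoidal subcutaneous tumour on a darker
background (T2-weighted contrast), with partial-volume edge voxels,
optional enclosed low-signal (necrotic) spheres, optional Gaussian blur
standing in for the point-spread function, and additive noise (Gaussian by
default, Rician optionally, since magnitude MR noise is Rician).

Each voxel's tumour occupancy fraction is computed by supersampling, so
edge voxels carry realistic intermediate intensities and the rendered
volume conserves the analytic ellipsoid volume V = (4π/3)·a·b·c to within
the supersampling tolerance.  Necrotic cores change intensities only: the
tumour includes its necrotic interior, so neither the analytic volume nor
the ground-truth mask is affected.

Geometries mirror the two acquisition protocols the pipeline targets:
isotropic 3D voxels (160³/200³/240³ µm³) and thick-slice 2D stacks
(~150×200 µm in-plane, 700 µm slices).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .core import ImageVolume, SegMask

__all__ = [
    "PhantomSpec",
    "NecroticCore",
    "render_phantom",
    "phantom_suite",
    "sphere_diameter_for_mass",
]

UM3_PER_MM3 = 1e9

#: default acquisition geometries: isotropic 3D at three resolutions and
#: the thick-slice 2D protocol, spacing in µm (slice, row, column)
DEFAULT_GEOMETRIES: tuple[tuple[float, float, float], ...] = (
    (160.0, 160.0, 160.0),
    (200.0, 200.0, 200.0),
    (240.0, 240.0, 240.0),
    (700.0, 150.0, 200.0),
)

#: default phantom cohort masses (g): spans the 0.01–2.28 g study range and
#: includes the three observer-study sizes 0.01, 0.10 and 0.87 g
DEFAULT_MASSES_G: tuple[float, ...] = (0.01, 0.02, 0.05, 0.10, 0.22, 0.47, 0.87, 1.50, 2.28)


@dataclass(frozen=True)
class NecroticCore:
    """An enclosed low-signal sphere inside the tumour: (center µm, radius µm,
    intensity)."""

    center_um: tuple[float, float, float]
    radius_um: float
    intensity: float

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("core radius must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    """Generative description of a synthetic tumour image.

    Parameters
    ----------
    semi_axes_um
        Ellipsoid semi-axes (a, b, c) along (slice, row, column), µm.
    spacing_um
        Voxel edge lengths, µm, same axis order.
    tumour_intensity, background_intensity
        Class intensities in arbitrary units; tumour must be brighter.
    noise_sigma
        Standard deviation of the additive noise, intensity units.
    noise_model
        ``"gaussian"`` (default) or ``"rician"``.
    psf_sigma_um
        Gaussian blur sigma in µm (0 disables).
    necrotic_cores
        Low-signal spheres rendered inside the tumour.
    margin_voxels
        Background margin around the ellipsoid on every side.
    supersampling_factor
        Subsamples per voxel edge for occupancy; raised automatically when
        the tumour is only a few voxels across.
    seed
        RNG seed for the noise; identical specs render bit-identically.
    """

    semi_axes_um: tuple[float, float, float]
    spacing_um: tuple[float, float, float] = (160.0, 160.0, 160.0)
    tumour_intensity: float = 100.0
    background_intensity: float = 20.0
    noise_sigma: float = 0.0
    noise_model: Literal["gaussian", "rician"] = "gaussian"
    psf_sigma_um: float = 0.0
    necrotic_cores: tuple[NecroticCore, ...] = ()
    margin_voxels: int = 2
    supersampling_factor: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.semi_axes_um):
            raise ValueError("semi-axes must be positive")
        if any(s <= 0 for s in self.spacing_um):
            raise ValueError("spacing must be positive")
        if self.tumour_intensity <= self.background_intensity:
            raise ValueError("tumour intensity must exceed background intensity")
        if self.background_intensity < 0:
            raise ValueError("background intensity must be nonnegative")
        if self.noise_sigma < 0 or self.psf_sigma_um < 0:
            raise ValueError("noise and PSF sigmas must be nonnegative")
        if self.supersampling_factor < 1:
            raise ValueError("supersampling_factor must be >= 1")
        if self.margin_voxels < 1:
            raise ValueError("margin_voxels must be >= 1")
        for core in self.necrotic_cores:
            u = sum(((c / ax) ** 2) for c, ax in zip(core.center_um, self.semi_axes_um))
            # core must fit strictly inside the ellipsoid (conservative bound:
            # center-offset fraction plus radius over the smallest semi-axis)
            if np.sqrt(u) + core.radius_um / min(self.semi_axes_um) > 1.0:
                raise ValueError("necrotic core does not fit inside the tumour")

    @property
    def analytic_volume_mm3(self) -> float:
        a, b, c = self.semi_axes_um
        return 4.0 / 3.0 * np.pi * a * b * c / UM3_PER_MM3

    @property
    def analytic_mass_g(self) -> float:
        """Mass at unit density (1.0 g/cm³)."""
        return self.analytic_volume_mm3 / 1e3

    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(
            2 * (int(np.ceil(ax / sp)) + self.margin_voxels)
            for ax, sp in zip(self.semi_axes_um, self.spacing_um)
        )  # type: ignore[return-value]

    def effective_supersampling(self) -> int:
        """Raise the supersampling for tumours only a few voxels across."""
        min_ratio = min(2 * ax / sp for ax, sp in zip(self.semi_axes_um, self.spacing_um))
        if min_ratio < 8:
            return max(self.supersampling_factor, 8)
        return self.supersampling_factor


def sphere_diameter_for_mass(mass_g: float, density_g_cm3: float = 1.0) -> float:
    """Diameter (µm) of the sphere with the given mass at the given density."""
    if mass_g <= 0 or density_g_cm3 <= 0:
        raise ValueError("mass and density must be positive")
    volume_cm3 = mass_g / density_g_cm3
    return 2.0 * (3.0 * volume_cm3 / (4.0 * np.pi)) ** (1.0 / 3.0) * 1e4


def _occupancy(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    center_um: tuple[float, float, float],
    semi_axes_um: tuple[float, float, float],
    s: int,
) -> np.ndarray:
    """Per-voxel occupancy fraction of an axis-aligned ellipsoid, by
    supersampling s³ points per voxel, processed slab-wise to bound memory."""
    subs = []
    for n, sp, c, ax in zip(shape, spacing, center_um, semi_axes_um):
        # subsample centers within each voxel; voxel i spans [i*sp, (i+1)*sp)
        fine = (np.arange(n * s) + 0.5) / s * sp
        subs.append(((fine - c) / ax) ** 2)
    uz, uy, ux = subs
    ny, nx = shape[1], shape[2]
    occ = np.empty(shape, dtype=np.float64)
    plane = uy[:, None] + ux[None, :]  # (ny*s, nx*s)
    for iz in range(shape[0]):
        block = plane[None, :, :] + uz[iz * s:(iz + 1) * s, None, None] <= 1.0
        occ[iz] = (
            block.reshape(s, ny, s, nx, s)
            .mean(axis=(0, 2, 4), dtype=np.float64)
        )
    return occ


def render_phantom(spec: PhantomSpec) -> tuple[ImageVolume, SegMask, float]:
    """Render a phantom: (image, ground-truth mask, analytic volume mm³).

    The ground-truth mask is occupancy ≥ 0.5 (unbiased for symmetric
    bodies); the analytic ellipsoid volume is the primary truth.
    """
    shape = spec.grid_shape()
    s = spec.effective_supersampling()
    center = tuple(n * sp / 2.0 for n, sp in zip(shape, spec.spacing_um))
    occ = _occupancy(shape, spec.spacing_um, center, spec.semi_axes_um, s)
    data = spec.background_intensity + occ * (spec.tumour_intensity - spec.background_intensity)
    for core in spec.necrotic_cores:
        c_abs = tuple(cc + off for cc, off in zip(core.center_um, center))
        occ_core = _occupancy(shape, spec.spacing_um, c_abs,
                              (core.radius_um,) * 3, s)
        data += occ_core * (core.intensity - spec.tumour_intensity)
    if spec.psf_sigma_um > 0:
        sigma_vox = [spec.psf_sigma_um / sp for sp in spec.spacing_um]
        data = ndimage.gaussian_filter(data, sigma=sigma_vox)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        if spec.noise_model == "gaussian":
            data = data + rng.normal(0.0, spec.noise_sigma, size=shape)
        elif spec.noise_model == "rician":
            n1 = rng.normal(0.0, spec.noise_sigma, size=shape)
            n2 = rng.normal(0.0, spec.noise_sigma, size=shape)
            data = np.sqrt((data + n1) ** 2 + n2**2)
        else:  # pragma: no cover - guarded by dataclass Literal
            raise ValueError(f"unknown noise model {spec.noise_model!r}")
    data = np.clip(data, 0.0, None)
    image = ImageVolume(data, spec.spacing_um)
    truth = SegMask(occ >= 0.5, spec.spacing_um,
                    provenance=[{"op": "phantom_ground_truth", "rule": "occupancy>=0.5"}])
    return image, truth, spec.analytic_volume_mm3


@dataclass(frozen=True)
class PhantomCase:
    """One rendered cohort member with its analytic truth."""

    case_id: str
    spec: PhantomSpec
    image: ImageVolume
    ground_truth: SegMask
    analytic_volume_mm3: float
    analytic_mass_g: float


def phantom_suite(
    masses_g: Sequence[float] = DEFAULT_MASSES_G,
    geometries_um: Sequence[tuple[float, float, float]] = DEFAULT_GEOMETRIES,
    seed: int = 0,
    noise_sigma: float = 0.0,
    **spec_overrides,
) -> list[PhantomCase]:
    """Render a cohort of spherical phantoms: every mass at every geometry.

    Masses convert to sphere diameters at density 1.0 g/cm³.  The per-case
    seed is derived from ``seed`` and the case index so cases are
    independent yet the whole suite is reproducible.
    """
    if any(m <= 0 for m in masses_g):
        raise ValueError("masses must be positive")
    cases: list[PhantomCase] = []
    idx = 0
    for m in masses_g:
        radius = sphere_diameter_for_mass(m) / 2.0
        for geom in geometries_um:
            spec = PhantomSpec(
                semi_axes_um=(radius, radius, radius),
                spacing_um=tuple(float(g) for g in geom),
                noise_sigma=noise_sigma,
                seed=(seed * 10007 + idx) % (2**31),
                **spec_overrides,
            )
            image, truth, vol = render_phantom(spec)
            cases.append(PhantomCase(
                case_id=f"m{m:g}_vox{'x'.join(f'{g:g}' for g in geom)}",
                spec=spec,
                image=image,
                ground_truth=truth,
                analytic_volume_mm3=vol,
                analytic_mass_g=spec.analytic_mass_g,
            ))
            idx += 1
    return cases


def suite_manifest(cases: Sequence[PhantomCase]) -> list[dict]:
    """JSON-serializable manifest of a rendered suite."""
    out = []
    for c in cases:
        out.append({
            "case_id": c.case_id,
            "analytic_mass_g": c.analytic_mass_g,
            "analytic_volume_mm3": c.analytic_volume_mm3,
            "spacing_um": list(c.spec.spacing_um),
            "semi_axes_um": list(c.spec.semi_axes_um),
            "noise_sigma": c.spec.noise_sigma,
            "seed": c.spec.seed,
        })
    return out
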