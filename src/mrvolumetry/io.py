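"""File-format glue: NIfTI volumes, multi-page TIFF import, ROI JSON,
provenance sidecars.

NIfTI spacing is taken from the header ``pixdim`` (mm) and converted to µm
on load; TIFF carries no reliable physical spacing, so it must be supplied
by the caller.  Image axes are reordered to the package convention
(slice, row, column) — for NIfTI, the last data axis is treated as the
slice axis.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Sequence

import nibabel as nib
import numpy as np
import tifffile

from .core import ImageVolume, SegMask
from .segmentation import PlanarROI

__all__ = [
    "read_nifti",
    "write_nifti",
    "write_mask",
    "read_tiff_stack",
    "read_rois",
    "write_rois",
    "write_provenance",
]


def read_nifti(path: str | Path) -> ImageVolume:
    """Load a NIfTI-1 volume; spacing from pixdim, mm → µm."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI volume, got ndim={data.ndim}")
    zooms = img.header.get_zooms()[:3]
    # NIfTI is (x, y, z); package convention is (slice, row, column) = (z, y, x)
    data = np.transpose(data, (2, 1, 0))
    spacing_um = (zooms[2] * 1000.0, zooms[1] * 1000.0, zooms[0] * 1000.0)
    return ImageVolume(data, spacing_um)


def _to_nifti(data: np.ndarray, spacing_um: Sequence[float]) -> nib.Nifti1Image:
    xyz = np.transpose(np.asarray(data), (2, 1, 0))
    affine = np.diag([spacing_um[2] / 1000.0, spacing_um[1] / 1000.0,
                      spacing_um[0] / 1000.0, 1.0])
    img = nib.Nifti1Image(xyz.astype(np.float32), affine)
    img.header.set_zooms(tuple(s / 1000.0 for s in spacing_um[::-1]))
    return img


def write_nifti(image: ImageVolume, path: str | Path) -> None:
    nib.save(_to_nifti(image.data, image.spacing), str(path))


def write_mask(mask: SegMask, path: str | Path) -> None:
    """Write a segmentation as a 0/1 NIfTI plus a provenance JSON sidecar."""
    nib.save(_to_nifti(mask.labels.astype(np.uint8), mask.spacing), str(path))
    sidecar = Path(str(path)).with_suffix("").with_suffix("")  # strip .nii.gz/.nii
    write_provenance({"spacing_um": list(mask.spacing), "operations": mask.provenance},
                     Path(f"{sidecar}_provenance.json"))


def read_tiff_stack(path: str | Path, spacing_um: Sequence[float]) -> ImageVolume:
    """Load a multi-page TIFF as (slice, row, column); spacing must be given."""
    data = tifffile.imread(str(path))
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"expected a 2D/3D TIFF stack, got ndim={data.ndim}")
    return ImageVolume(data, tuple(float(s) for s in spacing_um))


def read_rois(path: str | Path) -> list[PlanarROI]:
    """Read ROI/polygon definitions from JSON.

    Schema: a list (or single object) of ``{"slice": int,
    "vertices": [[row, col], ...]}`` in 0-based voxel coordinates, where an
    integer coordinate is a voxel center.
    """
    with open(path) as fh:
        payload = json.load(fh)
    if isinstance(payload, dict):
        payload = [payload]
    return [PlanarROI.from_dict(d) for d in payload]


def write_rois(rois: Sequence[PlanarROI], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([r.to_dict() for r in rois], fh, indent=2)


def write_provenance(record: dict[str, Any], path: str | Path) -> None:
    """Write a provenance record; every artifact-producing run gets one."""
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
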