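"""Volume and table I/O.

MetaImage (.mha / .mhd+raw) and NIfTI (.nii / .nii.gz) scalar volumes are
read and written through SimpleITK.  SimpleITK arrays are ordered
``(z, y, x)``; everything inside this package uses ``(x, y, z)`` with z the
axial axis, so arrays are transposed on the way in and out.  Only isotropic
spacing is supported because the FE mesh and the advection scheme assume
cubic voxels.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .images import BinaryMask, DensityImage

__all__ = ["read_image", "write_image", "read_mask", "write_mask", "write_json", "read_json"]

_SPACING_RTOL = 1e-4


def _check_isotropic(spacing: tuple[float, ...]) -> float:
    s = np.asarray(spacing, dtype=float)
    if not np.allclose(s, s[0], rtol=_SPACING_RTOL):
        raise ValueError(f"only isotropic spacing is supported, got {tuple(s)}")
    return float(s[0])


def read_image(path: str | Path) -> DensityImage:
    """Read a scalar volume; spacing (mm) is taken from the header."""
    img = sitk.ReadImage(str(path))
    spacing = _check_isotropic(img.GetSpacing())
    values = sitk.GetArrayFromImage(img).astype(np.float64).transpose(2, 1, 0)
    return DensityImage(values, spacing, tuple(img.GetOrigin()))


def write_image(image: DensityImage, path: str | Path) -> None:
    """Write a density volume as MetaImage or NIfTI (by file extension)."""
    img = sitk.GetImageFromArray(np.ascontiguousarray(image.values.transpose(2, 1, 0)))
    img.SetSpacing((image.spacing,) * 3)
    img.SetOrigin(tuple(image.origin))
    sitk.WriteImage(img, str(path))


def read_mask(path: str | Path, threshold: float = 0.5) -> BinaryMask:
    """Read a binary mask stored as an 8-bit (or any scalar) volume."""
    img = read_image(path)
    return BinaryMask(img.values >= threshold, img.spacing, img.origin)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as an 8-bit volume (bone = 1, background = 0)."""
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(mask.values.transpose(2, 1, 0).astype(np.uint8))
    )
    img.SetSpacing((mask.spacing,) * 3)
    img.SetOrigin(tuple(mask.origin))
    sitk.WriteImage(img, str(path))


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
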