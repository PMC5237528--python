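"""Image and mask I/O with physical pixel spacing.

Supported formats: PNG (8/16-bit grayscale; spacing defaults to 1 mm
and can be overridden), NIfTI (``.nii``/``.nii.gz``) and MetaImage
(``.mha``/``.mhd``), whose headers carry the spacing.  3D volumes are
exposed slice-wise along the transverse axis.  Intensities are returned
as real values without rescaling.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

_PNG_EXT = {".png"}
_NIFTI_EXT = {".nii", ".nii.gz"}
_META_EXT = {".mha", ".mhd"}


def _ext(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return ".nii.gz"
    return path.suffix.lower()


def read_image(path, spacing: tuple[float, float] | None = None):
    """Read a 2D grayscale image (or one slice-able volume).

    Returns ``(array, spacing)`` where ``array`` is 2D float (or 3D for
    volumes, transverse slices along axis 0) and ``spacing`` is the
    per-axis pixel size in mm of the in-plane axes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    ext = _ext(path)
    if ext in _PNG_EXT:
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(path)).astype(float)
        if arr.ndim == 3:  # collapse an RGB(A) png written by other tools
            arr = arr[..., 0]
        return arr, spacing or (1.0, 1.0)
    if ext in _NIFTI_EXT:
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(float)
        zooms = img.header.get_zooms()
        if data.ndim == 3:
            # transverse slices: axis 2 in NIfTI convention -> slice axis first
            data = np.moveaxis(data, 2, 0)
            sp = (float(zooms[0]), float(zooms[1]))
        else:
            sp = (float(zooms[0]), float(zooms[1]))
        return data, spacing or sp
    if ext in _META_EXT:
        import SimpleITK as sitk

        try:
            img = sitk.ReadImage(str(path))
        except RuntimeError as e:
            raise ValueError(f"cannot read MetaImage {path}: {e}") from e
        data = sitk.GetArrayFromImage(img).astype(float)  # (z, y, x) or (y, x)
        sp_all = img.GetSpacing()  # (x, y[, z])
        sp = (float(sp_all[1]), float(sp_all[0]))
        return data, spacing or sp
    raise ValueError(f"unknown image extension {ext!r} for {path}")


def write_image(path, array: np.ndarray, spacing: tuple[float, float] = (1.0, 1.0)) -> None:
    """Write a real-valued 2D image.

    PNG output is scaled to the full 16-bit range (probability maps and
    normalized images survive a round trip to ~1.5e-5); NIfTI and
    MetaImage keep float values and carry the spacing.
    """
    path = Path(path)
    ext = _ext(path)
    array = np.asarray(array, dtype=float)
    if ext in _PNG_EXT:
        import imageio.v3 as iio

        lo, hi = array.min(), array.max()
        scaled = np.zeros_like(array) if hi == lo else (array - lo) / (hi - lo)
        iio.imwrite(path, (scaled * 65535).round().astype(np.uint16))
        return
    if ext in _NIFTI_EXT:
        import nibabel as nib

        affine = np.diag([spacing[0], spacing[1], 1.0, 1.0])
        nib.save(nib.Nifti1Image(array.astype(np.float32), affine), str(path))
        return
    if ext in _META_EXT:
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(array.astype(np.float32))
        img.SetSpacing((spacing[1], spacing[0]))
        sitk.WriteImage(img, str(path))
        return
    raise ValueError(f"unknown image extension {ext!r} for {path}")


def read_mask(path):
    """Read a binary mask; any nonzero value is foreground.

    Returns ``(mask uint8, spacing)``.
    """
    arr, sp = read_image(path)
    return (arr > 0).astype(np.uint8), sp


def write_mask(path, mask: np.ndarray, spacing: tuple[float, float] = (1.0, 1.0)) -> None:
    """Write a binary mask (8-bit PNG with 0/255, or labeled volume)."""
    path = Path(path)
    ext = _ext(path)
    mask = (np.asarray(mask) > 0).astype(np.uint8)
    if ext in _PNG_EXT:
        import imageio.v3 as iio

        iio.imwrite(path, mask * np.uint8(255))
        return
    write_image(path, mask.astype(float), spacing)
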