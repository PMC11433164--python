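"""3D scalar volumes: the I/O boundary of the toolkit.

A :class:`Volume` couples a 3D intensity grid with voxel spacing (mm per
axis) and the NIfTI affine, which is carried through untouched — all
computation in the toolkit happens in voxel index space, and no
reorientation is ever performed.  Intensities are rescaled to [0, 1]
per volume before any model sees them.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Optional

import nibabel as nib
import numpy as np

from voxsr.errors import FormatError, ParameterError

CONTRAST_TAGS = ("T1", "T2", "PD", "synthetic")


@dataclass
class Volume:
    """A 3D scalar grid with voxel spacing and orientation metadata.

    Parameters
    ----------
    data : ndarray, shape (D, H, W)
        Finite scalar intensities, stored as float32 or float64.
    spacing : tuple of 3 floats
        Voxel edge length in mm per axis; strictly positive.
    affine : ndarray (4, 4), optional
        Voxel-to-world affine, carried opaquely.  When absent, a diagonal
        affine built from ``spacing`` is used on write.
    contrast_tag : str, optional
        One of ``T1``, ``T2``, ``PD``, ``synthetic``.
    """

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    affine: Optional[np.ndarray] = None
    contrast_tag: Optional[str] = None
    ident: str = field(default="", compare=False)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(
                f"expected a 3D volume, got rank {self.data.ndim}"
            )
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(np.float32)
        if not np.all(np.isfinite(self.data)):
            raise ParameterError("volume contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ParameterError(f"spacing must be 3 positive floats, got {self.spacing}")
        if self.contrast_tag is not None and self.contrast_tag not in CONTRAST_TAGS:
            raise ParameterError(
                f"contrast_tag must be one of {CONTRAST_TAGS}, got {self.contrast_tag!r}"
            )

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "Volume":
        """Copy of this volume with new intensities on the same grid."""
        return replace(self, data=data)


def read_volume(path) -> Volume:
    """Read a 3D NIfTI file.

    Intensities are returned untouched (no rescaling).  4D or higher-rank
    payloads are rejected; degenerate trailing singleton dimensions are not
    squeezed silently.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        img = nib.load(path)
        shape = img.shape
    except Exception as exc:  # malformed header / not NIfTI
        raise FormatError(f"not a readable NIfTI file: {path}: {exc}") from exc
    if len(shape) != 3:
        raise FormatError(
            f"{path}: expected a 3D payload, got rank {len(shape)} with shape {shape}"
        )
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(data=data, spacing=spacing, affine=np.asarray(img.affine))


def write_volume(v: Volume, path) -> str:
    """Write ``v`` to ``path`` as NIfTI-1 (.nii or .nii.gz), returning the path."""
    path = os.fspath(path)
    if v.affine is not None:
        affine = np.asarray(v.affine, dtype=np.float64)
    else:
        affine = np.diag(list(v.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(v.data, dtype=np.float32), affine)
    img.header.set_zooms(v.spacing)
    nib.save(img, path)
    return path


def rescale_intensity(v: Volume) -> Volume:
    """Linearly rescale intensities to [0, 1].

    The map is ``(x - min) / (max - min)``.  A constant volume has no
    intensity range and maps to all zeros, which keeps the output inside
    [0, 1] for every finite input.
    """
    data = np.asarray(v.data, dtype=np.float32)
    lo = float(data.min())
    hi = float(data.max())
    if hi == lo:
        return v.with_data(np.zeros_like(data))
    return v.with_data((data - lo) / (hi - lo))
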