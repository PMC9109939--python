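"""NIfTI + FSL-style gradient-table I/O for diffusion-weighted MRI.

The unit of I/O is :class:`DWIVolume`: a 4D image (x, y, z, volume) with its
voxel spacing, affine, gradient table and an optional binary brain mask.
Axial slices are (x, y) planes and the through-plane (slice) axis is the
third spatial axis; no reorientation is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Optional

import nibabel as nib
import numpy as np

#: b-values below this (s/mm^2) are treated as b=0. Scanners commonly report
#: small nonzero b-values for "b0" volumes.
B0_THRESHOLD = 50.0


class FormatError(ValueError):
    """Inconsistent or malformed on-disk DWI data."""


@dataclass
class GradientTable:
    """Per-volume b-values (s/mm^2) and unit gradient directions."""

    bvals: np.ndarray  # (n,)
    bvecs: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=np.float64).reshape(-1)
        self.bvecs = np.asarray(self.bvecs, dtype=np.float64)
        if self.bvecs.ndim != 2 or self.bvecs.shape[1] != 3:
            raise FormatError(f"bvecs must be (n, 3), got {self.bvecs.shape}")
        if len(self.bvals) != len(self.bvecs):
            raise FormatError(
                f"{len(self.bvals)} b-values but {len(self.bvecs)} b-vectors"
            )
        norms = np.linalg.norm(self.bvecs, axis=1)
        weighted = self.bvals > B0_THRESHOLD
        bad = weighted & (np.abs(norms - 1.0) > 1e-3)
        if np.any(bad):
            raise FormatError(
                f"non-unit gradient directions at volumes {np.where(bad)[0].tolist()}"
            )

    def __len__(self) -> int:
        return len(self.bvals)

    @property
    def is_b0(self) -> np.ndarray:
        return self.bvals <= B0_THRESHOLD

    def subset(self, idx: np.ndarray) -> "GradientTable":
        return GradientTable(self.bvals[idx], self.bvecs[idx])


@dataclass
class DWIVolume:
    """4D diffusion MRI volume with geometry, gradients and optional mask."""

    data: np.ndarray  # (x, y, z, n) float32, nonnegative
    affine: np.ndarray  # (4, 4)
    gradients: GradientTable
    mask: Optional[np.ndarray] = None  # (x, y, z) bool

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 4:
            raise FormatError(f"expected a 4D image, got shape {self.data.shape}")
        if self.data.shape[3] != len(self.gradients):
            raise FormatError(
                f"image has {self.data.shape[3]} volumes but gradient table has "
                f"{len(self.gradients)} entries"
            )
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise FormatError(f"affine must be 4x4, got {self.affine.shape}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask).astype(bool)
            if self.mask.shape != self.data.shape[:3]:
                raise FormatError(
                    f"mask shape {self.mask.shape} != spatial shape "
                    f"{self.data.shape[:3]}"
                )

    @property
    def spacing(self) -> np.ndarray:
        """Voxel spacing (mm) extracted from the affine."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self):
        return self.data.shape

    @property
    def n_slices(self) -> int:
        return self.data.shape[2]

    def with_data(self, data: np.ndarray, **kw) -> "DWIVolume":
        return replace(self, data=data, **kw)


@dataclass
class MaskedRegionLabels:
    """Integer label map with region names; label 0 is background."""

    labels: np.ndarray
    names: Dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels).astype(np.int32)
        if 0 in self.names:
            raise ValueError("label 0 is reserved for background")


def _parse_bvecs(path) -> np.ndarray:
    """Read an FSL bvec file, accepting both 3-row and N-row x 3-col layouts."""
    arr = np.atleast_2d(np.loadtxt(path, dtype=np.float64))
    if arr.shape[0] == 3 and arr.shape[1] != 3:
        arr = arr.T
    elif arr.shape[1] == 3:
        pass  # column layout (also covers the ambiguous 3x3 case)
    elif arr.shape[0] == 3:
        arr = arr.T
    else:
        raise FormatError(f"bvec file {path} has shape {arr.shape}, expected 3xN or Nx3")
    return arr


def read_gradient_table(bval_path, bvec_path) -> GradientTable:
    bvals = np.atleast_1d(np.loadtxt(bval_path, dtype=np.float64)).reshape(-1)
    bvecs = _parse_bvecs(bvec_path)
    if len(bvals) != len(bvecs):
        raise FormatError(
            f"{bval_path} has {len(bvals)} b-values but {bvec_path} has "
            f"{len(bvecs)} directions"
        )
    return GradientTable(bvals, bvecs)


def read_dwi(image_path, bval_path, bvec_path, mask_path=None) -> DWIVolume:
    """Read a 4D NIfTI plus FSL-style bval/bvec (and optionally a mask)."""
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim != 4:
        raise FormatError(
            f"{image_path}: expected a 4D image, got {data.ndim}D {data.shape}"
        )
    grads = read_gradient_table(bval_path, bvec_path)
    if data.shape[3] != len(grads):
        raise FormatError(
            f"{image_path} has {data.shape[3]} volumes but the gradient table "
            f"has {len(grads)} entries"
        )
    mask = None
    if mask_path is not None:
        mimg = nib.load(str(mask_path))
        mask = np.asarray(mimg.dataobj) > 0.5
    return DWIVolume(data, np.asarray(img.affine), grads, mask=mask)


def write_dwi(vol: DWIVolume, image_path, bval_path, bvec_path,
              mask_path=None) -> None:
    """Write a DWIVolume so that :func:`read_dwi` reproduces it exactly.

    bvecs are emitted in the FSL 3-row layout. If ``mask_path`` is given and
    the volume carries a mask, a sibling mask NIfTI is written as well.
    """
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), vol.affine)
    nib.save(img, str(image_path))
    np.savetxt(str(bval_path), vol.gradients.bvals[None, :], fmt="%.6g")
    np.savetxt(str(bvec_path), vol.gradients.bvecs.T, fmt="%.17g")
    if mask_path is not None:
        if vol.mask is None:
            raise ValueError("mask output requested but volume has no mask")
        nib.save(nib.Nifti1Image(vol.mask.astype(np.uint8), vol.affine),
                 str(mask_path))


def select_shell(vol: DWIVolume, b_target: float, tol: float = 50.0) -> DWIVolume:
    """Restrict a 4D volume to one b-value shell, preserving volume order.

    ``b_target == 0`` selects all volumes under the b0 threshold regardless
    of ``tol``.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    bvals = vol.gradients.bvals
    if b_target == 0:
        keep = bvals <= B0_THRESHOLD
    else:
        keep = np.abs(bvals - b_target) <= tol
    if not np.any(keep):
        raise FormatError(
            f"no volumes with b-value within {tol} of {b_target} "
            f"(available: {sorted(set(bvals.tolist()))})"
        )
    return vol.with_data(vol.data[..., keep], gradients=vol.gradients.subset(keep))
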