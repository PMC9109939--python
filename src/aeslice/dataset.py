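"""Normalized 2D slice sets and the alternating slice-removal protocol.

Training operates on normalized axial slices; evaluation removes N
intermediate slices (N = 1 or 2) from a stack in alternating order and asks
each method to predict them from the kept neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .formats_io import DWIVolume


@dataclass
class NormalizedVolume:
    """A DWIVolume rescaled per 3D volume to [0, 1].

    ``scale[i]`` is the intensity that was mapped to 1 in volume i; the
    inverse transform is ``data[..., i] * scale[i]``.
    """

    data: np.ndarray            # (x, y, z, n) in [0, 1], float32
    scale: np.ndarray           # (n,)
    affine: np.ndarray
    mask: Optional[np.ndarray] = None

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def n_slices(self) -> int:
        return self.data.shape[2]

    def with_data(self, data, **kw) -> "NormalizedVolume":
        return replace(self, data=data, **kw)


def normalize_volume(vol: DWIVolume) -> NormalizedVolume:
    """Divide each 3D volume by its own maximum in-mask intensity.

    Per-volume (not per-slice) normalization preserves inter-slice intensity
    relations, which latent interpolation and histogram matching rely on.
    An all-zero volume maps to itself with scale 1.
    """
    data = np.asarray(vol.data, dtype=np.float32)
    if np.any(data < 0):
        raise ValueError("negative intensities cannot be normalized")
    n = data.shape[3]
    scale = np.empty(n, dtype=np.float64)
    out = np.empty_like(data)
    for i in range(n):
        v = data[..., i]
        m = float(v[vol.mask].max()) if vol.mask is not None else float(v.max())
        if m <= 0:
            scale[i] = 1.0
            out[..., i] = v
        else:
            scale[i] = m
            out[..., i] = np.clip(v / m, 0.0, 1.0)
    return NormalizedVolume(out, scale, np.asarray(vol.affine, dtype=np.float64),
                            mask=vol.mask)


def denormalize(nv: NormalizedVolume) -> np.ndarray:
    """Invert :func:`normalize_volume` (up to float32 rounding)."""
    return (nv.data * nv.scale[None, None, None, :]).astype(np.float32)


def pad_or_crop_slice(sl: np.ndarray, target: Tuple[int, int]) -> np.ndarray:
    """Symmetrically zero-pad or centrally crop a 2D slice to ``target``."""
    out = sl
    for ax in (0, 1):
        d = target[ax] - out.shape[ax]
        if d > 0:
            before, after = d // 2, d - d // 2
            pads = [(0, 0), (0, 0)]
            pads[ax] = (before, after)
            out = np.pad(out, pads)
        elif d < 0:
            start = (-d) // 2
            sel = [slice(None), slice(None)]
            sel[ax] = slice(start, start + target[ax])
            out = out[tuple(sel)]
    return out


def make_slice_set(vols: Sequence[NormalizedVolume], shell: str = "b0",
                   bvals: Optional[Sequence[np.ndarray]] = None,
                   input_size: Optional[Tuple[int, int]] = None) -> np.ndarray:
    """Collect all axial slices of the selected shell across volumes.

    ``shell`` is "b0" or "dwi"; ``bvals`` gives, per NormalizedVolume, the
    b-value of each 3D volume (if omitted, every 3D volume is used).
    Ordering is deterministic: (volume object, 3D volume index, slice index).
    Returns an (n_slices, H, W) float32 array.
    """
    from .formats_io import B0_THRESHOLD

    slices: List[np.ndarray] = []
    for vi, nv in enumerate(vols):
        n = nv.data.shape[3]
        if bvals is not None:
            bv = np.asarray(bvals[vi])
            keep = bv <= B0_THRESHOLD if shell == "b0" else bv > B0_THRESHOLD
            vol_idx = np.where(keep)[0]
        else:
            vol_idx = np.arange(n)
        for i in vol_idx:
            for k in range(nv.n_slices):
                sl = nv.data[:, :, k, i]
                if input_size is not None:
                    sl = pad_or_crop_slice(sl, input_size)
                slices.append(np.asarray(sl, dtype=np.float32))
    if not slices:
        raise ValueError("empty slice set")
    shapes = {s.shape for s in slices}
    if len(shapes) > 1:
        raise ValueError(
            f"mixed in-plane shapes {sorted(shapes)}; pass input_size to pad/crop"
        )
    return np.stack(slices)


def slice_set_accounting(n_subjects: int, vols_per_subject: int,
                         slices_per_volume: int,
                         in_plane: Tuple[int, int]) -> Tuple[int, int]:
    """(slice count, voxel count) of a slice set, from the geometry alone."""
    n_slices = n_subjects * vols_per_subject * slices_per_volume
    return n_slices, n_slices * in_plane[0] * in_plane[1]


@dataclass(frozen=True)
class SliceRemovalPlan:
    """Alternating removal of N slices per gap.

    ``positions[i]`` is the fractional position of ``removed_indices[i]``
    between its bracketing kept slices: 1/2 for N=1; 1/3 or 2/3 for N=2.
    Trailing slices not bracketed by two kept slices are excluded from
    evaluation altogether.
    """

    N: int
    Z: int
    kept_indices: Tuple[int, ...]
    removed_indices: Tuple[int, ...]
    excluded_indices: Tuple[int, ...]
    positions: Tuple[float, ...]


def plan_slice_removal(Z: int, N: int) -> SliceRemovalPlan:
    """Plan the removal of N in (1, 2) intermediate slices in alternating order."""
    if N not in (1, 2):
        raise ValueError("N must be 1 or 2")
    if Z < 2 * N + 1:
        raise ValueError(f"need at least {2 * N + 1} slices for N={N}, got {Z}")
    kept = tuple(range(0, Z, N + 1))
    last_kept = kept[-1]
    removed, positions = [], []
    for k in range(Z):
        if k in kept:
            continue
        if k < last_kept:
            removed.append(k)
            lo = (k // (N + 1)) * (N + 1)
            positions.append((k - lo) / (N + 1))
    excluded = tuple(k for k in range(Z) if k not in kept and k not in removed)
    return SliceRemovalPlan(N=N, Z=Z, kept_indices=kept,
                            removed_indices=tuple(removed),
                            excluded_indices=excluded,
                            positions=tuple(positions))


def split_subjects(n_subjects: int, val_fraction: float = 0.15) -> Tuple[np.ndarray, np.ndarray]:
    """Deterministic subject-level train/validation split (last fraction = val)."""
    n_val = max(1, int(round(val_fraction * n_subjects))) if n_subjects > 1 else 0
    idx = np.arange(n_subjects)
    return idx[: n_subjects - n_val], idx[n_subjects - n_val:]
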