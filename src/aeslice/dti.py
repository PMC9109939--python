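"""Diffusion tensor fitting and scalar maps (FA, MD, AD, RD, colored FA).

The single-tensor model ln S = ln S0 - b g^T D g is fitted per voxel by
weighted log-linear least squares (weights S^2, the standard variance
stabilization for log-transformed Rician-corrupted magnitudes), using the
b=0 volumes plus one diffusion shell. Negative eigenvalues are clipped to
zero for map computation and flagged; no positive-definiteness constraint
is imposed, keeping the fit closed-form.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .formats_io import DWIVolume, MaskedRegionLabels

_LOW_SIGNAL_FRAC = 1e-8  # voxels with any S <= frac * S0 are excluded


def design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """(n, 7) design: [1, -b gx^2, -b gy^2, -b gz^2, -2b gxgy, -2b gxgz, -2b gygz].

    Solves ln S = X beta with beta = [ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz].
    """
    b = np.asarray(bvals, dtype=np.float64)
    g = np.asarray(bvecs, dtype=np.float64)
    X = np.column_stack([
        np.ones_like(b),
        -b * g[:, 0] ** 2, -b * g[:, 1] ** 2, -b * g[:, 2] ** 2,
        -2 * b * g[:, 0] * g[:, 1],
        -2 * b * g[:, 0] * g[:, 2],
        -2 * b * g[:, 1] * g[:, 2],
    ])
    return X


@dataclass
class TensorFit:
    """Per-voxel tensor fit with cached eigen-decomposition."""

    tensors: np.ndarray        # (x, y, z, 6): Dxx, Dyy, Dzz, Dxy, Dxz, Dyz
    S0: np.ndarray             # (x, y, z)
    fit_mask: np.ndarray       # voxels actually fitted
    eigvals: np.ndarray        # (x, y, z, 3) descending
    eigvecs: np.ndarray        # (x, y, z, 3, 3), column i = eigenvector i
    negative_flags: np.ndarray # voxels where eigenvalues were clipped

    @property
    def principal_direction(self) -> np.ndarray:
        """Unit principal eigenvector e1, (x, y, z, 3)."""
        return self.eigvecs[..., :, 0]

    def tensor_3x3(self) -> np.ndarray:
        """(x, y, z, 3, 3) full symmetric tensors."""
        t = self.tensors
        out = np.zeros(t.shape[:3] + (3, 3), dtype=t.dtype)
        out[..., 0, 0] = t[..., 0]
        out[..., 1, 1] = t[..., 1]
        out[..., 2, 2] = t[..., 2]
        out[..., 0, 1] = out[..., 1, 0] = t[..., 3]
        out[..., 0, 2] = out[..., 2, 0] = t[..., 4]
        out[..., 1, 2] = out[..., 2, 1] = t[..., 5]
        return out


@dataclass
class ScalarMaps:
    FA: np.ndarray
    MD: np.ndarray
    AD: np.ndarray
    RD: np.ndarray
    colored_FA: np.ndarray  # (x, y, z, 3) = FA * |e1|


def fit_tensor(vol: DWIVolume, mask: Optional[np.ndarray] = None,
               wls_iterations: int = 1) -> TensorFit:
    """Weighted log-linear least-squares tensor fit.

    ``wls_iterations = 0`` gives the plain OLS fit on log-signals; each WLS
    iteration reweights by the squared model-predicted signal. Voxels with
    any non-positive or near-zero signal are excluded from the fit and
    zero-filled.
    """
    bvals = vol.gradients.bvals
    bvecs = vol.gradients.bvecs
    if np.sum(vol.gradients.is_b0) < 1:
        raise ValueError("tensor fit needs at least one b=0 volume")
    X = design_matrix(bvals, bvecs)
    rank = np.linalg.matrix_rank(X)
    if rank < 7:
        raise ValueError(
            f"rank-deficient design matrix (rank {rank} < 7): directions "
            f"{np.round(bvecs, 3).tolist()} do not span 6 unique tensor "
            "components"
        )
    mask = vol.mask if mask is None else np.asarray(mask, dtype=bool)
    if mask is None:
        mask = np.ones(vol.data.shape[:3], dtype=bool)

    S = vol.data[mask].astype(np.float64)          # (nvox, nvol)
    s0_proxy = S[:, vol.gradients.is_b0].mean(axis=1)
    good = np.all(S > np.maximum(_LOW_SIGNAL_FRAC * s0_proxy[:, None], 0), axis=1) \
        & (s0_proxy > 0)
    Y = np.log(np.where(good[:, None], S, 1.0))

    pinv = np.linalg.pinv(X)
    beta = Y @ pinv.T                               # OLS start, (nvox, 7)
    for _ in range(wls_iterations):
        W = np.exp(2.0 * (beta @ X.T))             # predicted S^2 weights
        A = np.einsum("vn,nk,nl->vkl", W, X, X)
        rhs = np.einsum("vn,nk->vk", W * Y, X)
        beta = np.linalg.solve(A, rhs[..., None])[..., 0]

    nx, ny, nz = vol.data.shape[:3]
    tensors = np.zeros((nx, ny, nz, 6))
    S0 = np.zeros((nx, ny, nz))
    fit_mask = np.zeros((nx, ny, nz), dtype=bool)
    beta[~good] = 0.0
    tensors[mask] = beta[:, 1:]
    S0[mask] = np.where(good, np.exp(beta[:, 0]), 0.0)
    fit_mask[mask] = good

    D = TensorFit(tensors, S0, fit_mask, None, None, None)  # type: ignore
    full = D.tensor_3x3()
    w, V = np.linalg.eigh(full[fit_mask])
    w = w[:, ::-1]
    V = V[:, :, ::-1]
    eigvals = np.zeros((nx, ny, nz, 3))
    eigvecs = np.zeros((nx, ny, nz, 3, 3))
    eigvals[fit_mask] = w
    eigvecs[fit_mask] = V
    D.eigvals = eigvals
    D.eigvecs = eigvecs
    D.negative_flags = fit_mask & np.any(eigvals < 0, axis=-1)
    return D


def scalar_maps(fit: TensorFit) -> ScalarMaps:
    """FA, MD, AD, RD and colored-FA from the cached eigenvalues.

    FA = sqrt(3/2) * ||lambda - mean(lambda)|| / ||lambda||, clipped to
    [0, 1]; negative eigenvalues are clipped to zero first.
    """
    lam = np.clip(fit.eigvals, 0.0, None)
    md = lam.mean(axis=-1)
    ad = lam[..., 0]
    rd = 0.5 * (lam[..., 1] + lam[..., 2])
    dev = lam - md[..., None]
    norm = np.linalg.norm(lam, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.linalg.norm(dev, axis=-1) / norm
    fa = np.clip(np.nan_to_num(fa), 0.0, 1.0)
    fa[~fit.fit_mask] = 0.0
    colored = fa[..., None] * np.abs(fit.principal_direction)
    return ScalarMaps(FA=fa, MD=md, AD=ad, RD=rd, colored_FA=colored)


def region_stats(scalar_map: np.ndarray, labels: MaskedRegionLabels,
                 mask: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Per-region mean/SD/voxel-count table of a scalar map.

    Background (label 0) is excluded; regions named in ``labels.names`` but
    absent from the label image get a zero-count row.
    """
    if scalar_map.shape != labels.labels.shape:
        raise ValueError("map and label shapes differ")
    sel = labels.labels > 0
    if mask is not None:
        sel &= mask
    present = sorted(set(np.unique(labels.labels[sel]).tolist())
                     | set(labels.names))
    rows = []
    for lab in present:
        if lab == 0:
            continue
        vals = scalar_map[sel & (labels.labels == lab)]
        rows.append({
            "label": lab,
            "region": labels.names.get(lab, f"label{lab}"),
            "mean": float(vals.mean()) if vals.size else np.nan,
            "sd": float(vals.std()) if vals.size else np.nan,
            "n_voxels": int(vals.size),
        })
    return pd.DataFrame(rows)
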