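"""Quantitative evaluation: MSE/PSNR, latent-space similarity, Wilcoxon
tests, interpolation-weight grid search and the slice-removal experiment.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .autoencoder import ConvAutoencoder
from .dataset import NormalizedVolume, plan_slice_removal
from .formats_io import DWIVolume
from .superres import (ae_synthesize_removed, baseline_interp,
                       synthesize_middle, weights_for)


def mse(a: np.ndarray, b: np.ndarray,
        mask: Optional[np.ndarray] = None) -> float:
    """Mean squared error, optionally restricted to a boolean mask."""
    a, b = np.asarray(a, dtype=np.float64), np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    d = (a - b) ** 2
    if mask is not None:
        d = d[mask]
    return float(d.mean())


def psnr(a: np.ndarray, b: np.ndarray, peak: float = 1.0,
         mask: Optional[np.ndarray] = None) -> float:
    """Peak signal-to-noise ratio in dB; +inf when the images are equal."""
    if peak <= 0:
        raise ValueError("peak must be positive")
    m = mse(a, b, mask=mask)
    if m == 0:
        return math.inf
    return 10.0 * math.log10(peak * peak / m)


def volume_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Mean over axial slices of the Euclidean distance between the
    flattened slices: d(u, v) = ||u - v||_2 per slice, averaged over z."""
    u, v = np.asarray(u, dtype=np.float64), np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError(f"shape mismatch {u.shape} vs {v.shape}")
    diff = (u - v).reshape(-1, u.shape[2]) if u.ndim == 3 else (u - v)[..., None]
    per_slice = np.sqrt(np.sum(diff ** 2, axis=0))
    return float(per_slice.mean())


def gradient_angle(g1: np.ndarray, g2: np.ndarray) -> float:
    """Angle between two gradient directions in degrees, in [0, 180]."""
    g1, g2 = np.asarray(g1, dtype=np.float64), np.asarray(g2, dtype=np.float64)
    n1, n2 = np.linalg.norm(g1), np.linalg.norm(g2)
    if n1 == 0 or n2 == 0:
        raise ValueError("gradient directions must be nonzero")
    c = np.clip(np.dot(g1, g2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


@dataclass
class SimilarityRow:
    pair: Tuple[int, int]
    angle_deg: float
    input_distance: float
    latent_distance: float


def similarity_analysis(model: ConvAutoencoder,
                        shell_vol: DWIVolume) -> List[SimilarityRow]:
    """Pairwise input- and latent-space distances vs gradient angle.

    For every unordered pair of shell volumes: the angle between their
    gradient directions, the input-space slice-averaged Euclidean distance,
    and the same distance computed between the per-slice latent codes
    (flattened feature maps).
    """
    data = shell_vol.data
    K = data.shape[3]
    if K < 2:
        raise ValueError("need at least 2 shell volumes")
    Z = data.shape[2]
    codes = []
    for i in range(K):
        sl = np.moveaxis(data[:, :, :, i], 2, 0)  # (Z, X, Y)
        z = model.encode_batch(sl.astype(np.float32))
        codes.append(z.reshape(Z, -1).T)           # (features, Z)
    rows = []
    for i, j in itertools.combinations(range(K), 2):
        ang = gradient_angle(shell_vol.gradients.bvecs[i],
                             shell_vol.gradients.bvecs[j])
        d_in = volume_distance(data[:, :, :, i], data[:, :, :, j])
        d_lat = volume_distance(codes[i], codes[j])
        rows.append(SimilarityRow((i, j), ang, d_in, d_lat))
    return rows


def similarity_frame(rows: Sequence[SimilarityRow]) -> pd.DataFrame:
    return pd.DataFrame([{
        "i": r.pair[0], "j": r.pair[1], "angle_deg": r.angle_deg,
        "abs_cos_angle": abs(math.cos(math.radians(r.angle_deg))),
        "input_distance": r.input_distance,
        "latent_distance": r.latent_distance,
    } for r in rows])


def paired_wilcoxon(x: Sequence[float], y: Sequence[float],
                    alternative: str = "two-sided") -> Dict:
    """Paired Wilcoxon signed-rank test on x - y.

    Exact null enumeration for n <= 25 without ties; normal approximation
    with tie/zero correction otherwise. All-zero differences return p = 1
    with a warning flag rather than an error.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    if np.all(d == 0):
        return {"statistic": 0.0, "pvalue": 1.0, "zero_differences": True,
                "method": "degenerate"}
    nz = d[d != 0]
    ties = len(np.unique(np.abs(nz))) < len(nz)
    method = "exact" if (len(nz) <= 25 and not ties) else "approx"
    res = stats.wilcoxon(x, y, alternative=alternative, method=method,
                         zero_method="wilcox", correction=(method == "approx"))
    return {"statistic": float(res.statistic), "pvalue": float(res.pvalue),
            "zero_differences": False, "method": method}


def weight_grid_search(model: ConvAutoencoder,
                       triples: Sequence[Tuple[np.ndarray, np.ndarray, np.ndarray]],
                       grid: Optional[Sequence[float]] = None) -> Dict:
    """Mean synthesis MSE per interpolation weight over (a, b, gt) triples.

    The grid spans 0.1–0.9 with a step of 0.1 (nine weights). Returns the
    per-weight mean-MSE table and the argmin weight.
    """
    if len(triples) == 0:
        raise ValueError("need at least one (slice_a, slice_b, gt) triple")
    if grid is None:
        grid = np.round(np.arange(0.1, 0.95, 0.1), 10)
    table = {}
    for w in grid:
        errs = []
        for a, b, gt in triples:
            s, = synthesize_middle(model, a, b, N=1, weights=(w,))
            errs.append(mse(s, gt))
        table[float(w)] = float(np.mean(errs))
    best = min(table, key=table.get)
    return {"best_weight": best, "mse_by_weight": table}


@dataclass
class EvalRecord:
    """One (volume, method, N) measurement of the removal experiment."""

    volume: int
    method: str
    N: int
    target: str
    mse: float
    psnr: float


def run_removal_experiment(model: ConvAutoencoder, vol: NormalizedVolume,
                           N: int,
                           methods: Sequence[str] = ("ae", "linear", "cubic",
                                                     "spline5"),
                           target: str = "signal") -> List[EvalRecord]:
    """Remove N slices per gap from each 3D volume, resynthesize, and score.

    MSE/PSNR are computed at the removed slice positions only, within the
    brain mask when the volume carries one. PSNR peak is 1 (normalized
    intensities).
    """
    plan = plan_slice_removal(vol.n_slices, N)
    ridx = list(plan.removed_indices)
    mask = vol.mask[:, :, ridx] if vol.mask is not None else None
    records = []
    for v in range(vol.data.shape[3]):
        v3d = vol.data[:, :, :, v]
        gt = v3d[:, :, ridx]
        for method in methods:
            if method == "ae":
                pred = ae_synthesize_removed(model, v3d, plan)
            elif method == "gt":
                pred = gt
            else:
                pred = baseline_interp(v3d, plan, method)
            records.append(EvalRecord(
                volume=v, method=method, N=N, target=target,
                mse=mse(pred, gt, mask=mask),
                psnr=psnr(pred, gt, peak=1.0, mask=mask)))
    return records


def records_frame(records: Sequence[EvalRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])
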