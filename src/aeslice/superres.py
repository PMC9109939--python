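"""Slice synthesis by weighted latent interpolation, plus baselines.

Two neighbouring slices are encoded, their latent codes combined as
``w * z_a + (1 - w) * z_b`` and decoded. For N = 1 synthesized slice the
weighting is equal (w = 1/2); for N = 2 the weights are inverse-distance:
the synthesized slice nearer slice_a uses w = 2/3 on z_a. Because decoder
outputs are normalized to (0, 1), each synthesized slice is histogram-
normalized to the corresponding weighted average of the input slices.

Baselines synthesize the same slices by 1D through-plane interpolation of
the kept slices (linear, cubic, and 5th-order B-spline).
"""

from __future__ import annotations

from typing import List, Sequence

import numpy as np
from scipy.interpolate import make_interp_spline

from .autoencoder import ConvAutoencoder
from .dataset import NormalizedVolume, SliceRemovalPlan


def weights_for(N: int) -> tuple:
    """Latent weights on the slice_a side, ordered from slice_a to slice_b."""
    if N == 1:
        return (0.5,)
    if N == 2:
        return (2.0 / 3.0, 1.0 / 3.0)
    raise ValueError("N must be 1 or 2")


def interpolate_latent(z_a: np.ndarray, z_b: np.ndarray, w: float) -> np.ndarray:
    """Elementwise convex combination w * z_a + (1 - w) * z_b."""
    if z_a.shape != z_b.shape:
        raise ValueError(f"latent shapes differ: {z_a.shape} vs {z_b.shape}")
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"weight {w} outside [0, 1]")
    return w * z_a + (1.0 - w) * z_b


def histogram_normalize(img: np.ndarray, reference: np.ndarray,
                        n_quantiles: int = 256) -> np.ndarray:
    """Monotone remapping of ``img`` onto ``reference``'s intensity histogram.

    The empirical quantile function of the output matches the reference's at
    ``n_quantiles`` uniformly spaced quantiles; rank order is preserved
    (ties allowed).
    """
    if img.shape != reference.shape:
        raise ValueError("image and reference shapes differ")
    q = np.linspace(0.0, 1.0, n_quantiles)
    iq = np.quantile(img, q)
    rq = np.quantile(reference, q)
    out = np.interp(img.ravel(), iq, rq).reshape(img.shape)
    return out.astype(np.float32)


def synthesize_middle(model: ConvAutoencoder, slice_a: np.ndarray,
                      slice_b: np.ndarray, N: int = 1,
                      weights: Sequence[float] | None = None) -> List[np.ndarray]:
    """Predict the N slices between slice_a and slice_b.

    Returns slices ordered from the slice_a side to the slice_b side, each
    histogram-normalized to the weighted average ``w*a + (1-w)*b`` of the
    inputs.
    """
    if weights is None:
        weights = weights_for(N)
    z_a = model.encode(np.asarray(slice_a, dtype=np.float32))
    z_b = model.encode(np.asarray(slice_b, dtype=np.float32))
    zs = np.stack([interpolate_latent(z_a, z_b, w) for w in weights])
    decoded = model.decode_batch(zs)
    out = []
    for w, d in zip(weights, decoded):
        ref = w * slice_a + (1.0 - w) * slice_b
        out.append(histogram_normalize(d, ref))
    return out


def enhance_volume(model: ConvAutoencoder, vol: NormalizedVolume,
                   N: int = 1) -> NormalizedVolume:
    """Insert N synthesized slices between each adjacent pair of slices.

    The output has Z + (Z-1)*N slices, original slices unmodified at
    indices k*(N+1), and through-plane spacing divided by (N+1). Applied
    independently to each 3D volume of the 4D stack.
    """
    Z = vol.n_slices
    if Z < 2:
        raise ValueError("need at least 2 slices to enhance")
    X, Y, _, V = vol.data.shape
    Znew = Z + (Z - 1) * N
    out = np.zeros((X, Y, Znew, V), dtype=np.float32)
    for v in range(V):
        for k in range(Z):
            out[:, :, k * (N + 1), v] = vol.data[:, :, k, v]
        for k in range(Z - 1):
            synth = synthesize_middle(model, vol.data[:, :, k, v],
                                      vol.data[:, :, k + 1, v], N=N)
            for j, s in enumerate(synth):
                out[:, :, k * (N + 1) + 1 + j, v] = s
    affine = vol.affine.copy()
    affine[:3, 2] /= (N + 1)
    return NormalizedVolume(out, vol.scale.copy(), affine, mask=None)


def replace_slice(model: ConvAutoencoder, vol: NormalizedVolume,
                  k: int) -> NormalizedVolume:
    """Replace (outlier) slice k with the synthesis from its two neighbours.

    Slice k must be interior; all other slices are returned bit-identical.
    """
    Z = vol.n_slices
    if not 0 < k < Z - 1:
        raise ValueError(f"slice {k} has no two neighbours in a {Z}-slice stack")
    out = vol.data.copy()
    for v in range(vol.data.shape[3]):
        synth, = synthesize_middle(model, vol.data[:, :, k - 1, v],
                                   vol.data[:, :, k + 1, v], N=1)
        out[:, :, k, v] = synth
    return vol.with_data(out)


_BASELINE_ORDER = {"linear": 1, "cubic": 3, "spline5": 5}


def baseline_interp(vol3d: np.ndarray, plan: SliceRemovalPlan,
                    method: str) -> np.ndarray:
    """Through-plane 1D interpolation of the kept slices at removed positions.

    ``vol3d`` is an (X, Y, Z) stack; returns an (X, Y, n_removed) array at
    the plan's removed indices. The spline order is 1 (linear), 3 (cubic)
    or 5 (quintic B-spline); orders above the kept-slice count fall back to
    the largest feasible odd order.
    """
    if method not in _BASELINE_ORDER:
        raise ValueError(f"unknown method {method!r}; "
                         f"choose from {sorted(_BASELINE_ORDER)}")
    kept = np.asarray(plan.kept_indices, dtype=np.float64)
    removed = np.asarray(plan.removed_indices, dtype=np.float64)
    k = _BASELINE_ORDER[method]
    k = min(k, len(kept) - 1 if (len(kept) - 1) % 2 else len(kept) - 2)
    y = vol3d[:, :, list(plan.kept_indices)]
    # interpolate along the slice axis for all in-plane voxels at once
    spl = make_interp_spline(kept, np.moveaxis(y, 2, 0), k=k)
    vals = spl(removed)  # (n_removed, X, Y)
    return np.moveaxis(np.asarray(vals), 0, 2).astype(vol3d.dtype)


def ae_synthesize_removed(model: ConvAutoencoder, vol3d: np.ndarray,
                          plan: SliceRemovalPlan) -> np.ndarray:
    """Autoencoder prediction of the removed slices of one 3D stack.

    Equivalent to calling :func:`synthesize_middle` gap by gap, but encodes
    every kept slice once and decodes all interpolated codes in one batch.
    """
    kept = list(plan.kept_indices)
    slices = np.moveaxis(vol3d[:, :, kept], 2, 0).astype(np.float32)
    codes = model.encode_batch(slices)
    ws = weights_for(plan.N)
    zs, refs = [], []
    for gi in range(len(kept) - 1):
        z_a, z_b = codes[gi], codes[gi + 1]
        a, b = slices[gi], slices[gi + 1]
        for w in ws:
            zs.append(interpolate_latent(z_a, z_b, w))
            refs.append(w * a + (1.0 - w) * b)
    decoded = model.decode_batch(np.stack(zs))
    out = np.zeros(vol3d.shape[:2] + (len(plan.removed_indices),),
                   dtype=np.float32)
    col = {r: i for i, r in enumerate(plan.removed_indices)}
    idx = 0
    for gi, lo in enumerate(kept[:-1]):
        for j in range(plan.N):
            out[:, :, col[lo + 1 + j]] = histogram_normalize(decoded[idx],
                                                             refs[idx])
            idx += 1
    return out
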