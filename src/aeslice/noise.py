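"""Rician noise injection at a controlled output SNR.

Magnitude MR images corrupted by complex Gaussian noise follow a Rician
distribution: for a clean intensity S_clean,

    S_noisy = sqrt((S_clean + GN1)^2 + GN2^2),

with GN1, GN2 iid Normal(0, SD) and SD = S_clean(b=0) / SNR_out, where
SNR_out is the desired simulated SNR. The b=0 reference is taken as the
mean in-mask b=0 intensity of the volume (a per-voxel mode is available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .formats_io import DWIVolume


@dataclass
class NoiseSpec:
    """Desired output SNR, the b=0 reference intensity, and a seed."""

    snr_out: float
    s0_ref: float
    seed: int = 0

    def __post_init__(self):
        if not self.snr_out > 0:
            raise ValueError("snr_out must be positive")
        if not self.s0_ref > 0:
            raise ValueError("s0_ref must be positive")

    @property
    def sd(self) -> float:
        return 0.0 if np.isinf(self.snr_out) else self.s0_ref / self.snr_out


def add_rician(clean: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    """Apply Rician noise to a nonnegative array (any shape), seeded.

    An infinite ``snr_out`` is the noise-free sentinel: the input is
    returned unchanged (both Gaussians degenerate at zero).
    """
    clean = np.asarray(clean)
    if np.any(clean < 0):
        raise ValueError("input intensities must be nonnegative")
    sd = spec.sd
    if sd == 0.0:
        return clean.copy()
    rng = np.random.default_rng(spec.seed)
    gn1 = rng.normal(0.0, sd, size=clean.shape)
    gn2 = rng.normal(0.0, sd, size=clean.shape)
    return np.hypot(clean + gn1, gn2).astype(clean.dtype)


def s0_reference(vol: DWIVolume) -> float:
    """Volume-level b=0 reference: mean in-mask intensity of the b0 volumes."""
    b0 = vol.data[..., vol.gradients.is_b0]
    if b0.shape[-1] == 0:
        raise ValueError("volume has no b=0 images")
    if vol.mask is not None:
        vals = b0[vol.mask]
    else:
        vals = b0.reshape(-1, b0.shape[-1])
    ref = float(vals.mean())
    if ref <= 0:
        raise ValueError("non-positive b=0 reference intensity")
    return ref


def add_rician_volume(vol: DWIVolume, snr_out: float, seed: int = 0) -> DWIVolume:
    """Rician-corrupt a whole 4D volume at the given output SNR."""
    spec = NoiseSpec(snr_out=snr_out, s0_ref=s0_reference(vol), seed=seed)
    return vol.with_data(add_rician(vol.data, spec))
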