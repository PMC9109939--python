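"""Desk-scale experiment protocol: phantom suites and scaled training runs.

These helpers assemble the study conditions used by the evaluation suite:
a set of seeded diffusion-tensor phantoms with a 15-direction b=700-style
shell plus b=0 volumes, a training corpus of normalized b0 axial slices
(with mild Rician acquisition noise, so the repeated b0 volumes of a
phantom differ the way real repeats do), and a scaled-down autoencoder
configuration that keeps the reference topology — four double-convolution
blocks, two tail convolutions, spatial latent at 1/16 resolution with an
8x compression ratio — at widths a CPU can train in minutes.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np

from .autoencoder import AEConfig, ConvAutoencoder, TrainingHistory
from .dataset import NormalizedVolume, normalize_volume
from .formats_io import DWIVolume
from .noise import NoiseSpec, add_rician, s0_reference
from .phantom import (PhantomSpec, make_gradient_scheme, make_phantom,
                      simulate_dwi)

#: SNR of the mild acquisition noise carried by the emulated scans (the
#: emulated data are denoised scanner images, i.e. cleaner than the
#: robustness-experiment SNR levels of 27-23 for b0). The same level is
#: used for the training b0 slices and for the "acquired" evaluation
#: volumes.
TRAINING_B0_SNR = 30.0
ACQUISITION_SNR = 30.0


def make_phantom_suite(n_phantoms: int, seed: int,
                       shape=(64, 64, 17), n_directions: int = 15,
                       b: float = 700.0, n_b0: int = 3
                       ) -> Tuple[List[DWIVolume], List]:
    """Simulate ``n_phantoms`` seeded phantoms; returns (volumes, fields)."""
    vols, fields = [], []
    for i in range(n_phantoms):
        s = seed * 1000 + i
        field = make_phantom(PhantomSpec(shape=shape, n_directions=n_directions,
                                         b=b, n_b0=n_b0, seed=s))
        grads = make_gradient_scheme(n_directions, b, n_b0=n_b0, seed=s)
        vols.append(simulate_dwi(field, grads))
        fields.append(field)
    return vols, fields


def training_b0_slices(vols: Sequence[DWIVolume], seed: int,
                       snr: float = TRAINING_B0_SNR,
                       repeats_per_volume: Optional[int] = None) -> np.ndarray:
    """Normalized axial b0 slices of the given volumes, with mild Rician
    acquisition noise (a different realization per b0 repeat).

    ``repeats_per_volume`` limits how many b0 repeats of each phantom are
    used (None = all); favouring more phantoms over more repeats gives the
    corpus more anatomical variety at the same slice budget.
    """
    out = []
    for vi, vol in enumerate(vols):
        ref = s0_reference(vol)
        b0_idx = np.where(vol.gradients.is_b0)[0]
        if repeats_per_volume is not None:
            b0_idx = b0_idx[:repeats_per_volume]
        for j, idx in enumerate(b0_idx):
            clean = vol.data[:, :, :, idx]
            noisy = add_rician(clean, NoiseSpec(snr, ref,
                                                seed=seed + 7919 * vi + j))
            m = float(noisy[vol.mask].max()) if vol.mask is not None \
                else float(noisy.max())
            sl = np.clip(noisy / m, 0.0, 1.0)
            out.append(np.moveaxis(sl, 2, 0))
    return np.concatenate(out).astype(np.float32)


def acquire(vols: Sequence[DWIVolume], seed: int,
            snr: float = ACQUISITION_SNR) -> List[DWIVolume]:
    """Emulated acquisitions: the noiseless simulations plus Rician noise.

    Slice-removal experiments run on acquired volumes, so the ground truth
    a method is compared against is the acquired (noisy) removed slice —
    as it is when the experiment is run on real scans.
    """
    from .noise import add_rician_volume

    return [add_rician_volume(v, snr, seed=seed + 101 + i)
            for i, v in enumerate(vols)]


def scaled_config(seed: int, epochs: int = 50) -> AEConfig:
    """Scaled-down configuration for 64x64 phantom slices."""
    return AEConfig(input_size=(64, 64), block_channels=(8, 16, 32, 64),
                    tail_channels=(64, 64), latent_channels=32,
                    learning_rate=5e-4, batch_size=8, epochs=epochs,
                    lr_decay_at=(int(0.6 * epochs), int(0.85 * epochs)),
                    augment_flips=True, seed=seed)


def train_scaled_model(train_slices: np.ndarray, seed: int,
                       epochs: int = 50
                       ) -> Tuple[ConvAutoencoder, TrainingHistory]:
    model = ConvAutoencoder(scaled_config(seed, epochs=epochs))
    hist = model.train(train_slices)
    return model, hist
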