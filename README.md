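# aeslice

Through-plane super-resolution of diffusion-weighted MRI (DW-MRI) with a
convolutional autoencoder.

Fetal and neonatal DW-MRI is acquired as stacks of 2D axial slices whose
through-plane spacing (3–5 mm) is far coarser than the in-plane
resolution. `aeslice` synthesizes the missing intermediate slices — and
recovers motion-corrupted outlier slices — by interpolating in the latent
space of an autoencoder trained, unsupervised, on normalized b = 0 slices:
two neighbouring slices are encoded, their latent codes are combined as

    z(w) = w · z_a + (1 − w) · z_b,          w = 1/2            (N = 1)
                                             w ∈ {2/3, 1/3}     (N = 2)

and decoded; the decoded slice is histogram-normalized to the weighted
average w·a + (1−w)·b of its neighbours. A stack of Z slices becomes
Z + (Z−1)·N slices with the slice spacing divided by N + 1 — and because
interpolation happens at inference, N is chosen after training.

The package is aimed at researchers in perinatal diffusion imaging and
ships the full evaluation protocol around the method:

* `formats_io` — NIfTI + FSL bval/bvec I/O, shell selection
* `phantom` — diffusion-tensor phantoms (ground-truth 4D DWI) with
  neonatal-like anatomy, for fully controlled experiments
* `dataset` — per-volume normalization, slice sets, alternating
  slice-removal plans
* `nn`, `autoencoder` — the network (numpy engine, seeded and
  CPU-reproducible) with training, checkpointing and history
* `superres` — latent interpolation, histogram normalization, volume
  enhancement, outlier-slice replacement, and linear/cubic/quintic-spline
  interpolation baselines
* `noise` — Rician noise at controlled output SNR
* `dti` — weighted log-linear tensor fit; FA/MD/AD/RD and colored-FA maps,
  region statistics
* `evaluate` — MSE/PSNR, latent-space similarity vs gradient angle, paired
  Wilcoxon tests, interpolation-weight grid search, the slice-removal
  experiment
* `cli` — the `aeslice` command (`phantom`, `train`, `enhance`,
  `fix-slice`, `noise`, `dti`, `eval`)

See `docs/methods.md` for the model, the phantom and all numerical
choices.

## Worked example

Generate a phantom, train a small model on its b0 slices, and double the
through-plane resolution:

```sh
aeslice phantom --shape 64 64 17 --ndirs 15 --bval 700 --nb0 3 --seed 7 --out work/p
aeslice train --in work/p_dwi.nii.gz --bval work/p.bval --bvec work/p.bvec \
              --mask work/p_mask.nii.gz --channels 8,16,32,64 --latent 32 \
              --epochs 50 --lr 5e-4 --batch 8 --seed 7 --out work/model
aeslice enhance --in work/p_dwi.nii.gz --bval work/p.bval --bvec work/p.bvec \
                --model work/model --n 1 --out work/p_enhanced.nii.gz
```

which reports

```
phantom written to work/p_*
checkpoint saved to work/model (selected epoch 45)
enhanced volume (17 -> 33 slices) written to work/p_enhanced.nii.gz
```

The phantom has 17 slices at 1.5 mm spacing; the enhanced volume has 33
slices at 0.75 mm. `work/model.history.json` holds the per-epoch training
and validation losses ("selected epoch 45" = the checkpoint with minimal
validation loss), and `work/p_FA.nii.gz` / `work/p_MD.nii.gz` are the
ground-truth scalar maps for downstream comparison. The same checkpoint
drives outlier recovery:

```sh
aeslice fix-slice --in work/p_dwi.nii.gz --bval work/p.bval --bvec work/p.bvec \
                  --model work/model --index 8 --out work/p_fixed.nii.gz
```

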