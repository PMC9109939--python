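# Methods

## Problem

Diffusion-weighted MRI (DW-MRI) of fetuses and newborns is acquired as
stacks of 2D axial slices whose through-plane spacing (3–5 mm) is much
coarser than the in-plane resolution (~1 mm). `aeslice` synthesizes the
missing intermediate slices — and replaces motion-corrupted outlier
slices — by interpolating in the latent space of a convolutional
autoencoder trained, unsupervised, on the b=0 slices of the same kind of
data. Because the interpolation happens at inference time, the enhancement
factor (N = 1 or 2 new slices per gap) is chosen after training.

## Autoencoder

The encoder consumes one normalized slice (values in [0, 1], single
channel) and applies four blocks of two 3×3 convolutions, each followed by
batch normalization and an ELU nonlinearity, with 2×2 average pooling
after each block; block widths double from 32 (32, 64, 128, 256). Two
further 3×3 convolution layers (512 channels each, BN + ELU) are followed
by a linear 3×3 projection onto the latent space: a 32-channel feature map
at 1/16 of the input resolution (8×8 for 128×128 inputs; an 8× compression
of the input). The decoder mirrors the encoder — nearest-neighbour 2×
upsampling before each block, widths halving (256, 128, 64, 32) — and
ends with a 1×1 convolution and a sigmoid, so outputs live in (0, 1).

Under this reading the reference configuration has 6,104,289 convolution
weights and biases, 5,888 batch-norm scale/shift parameters and 5,888
batch-norm moving statistics: 6,116,065 parameters in the framework-summary
convention `build_model` reports. The prose description of such a network
under-determines the two tail widths and the accounting of batch-norm
arrays; the adopted reading (tail 512/512, separate 3×3 latent projection,
mirrored decoder without a tail mirror) is fixed in `AEConfig` defaults
and documented here so the count is reproducible.

Training minimizes reconstruction mean squared error with Adam
(β₁ = 0.5, β₂ = 0.999), batch size 32, learning rate 5e-5, 200 epochs in
the reference protocol; 15 % of slices are held out and the checkpoint
with minimal validation loss is kept. Weights use seeded He-style
variance-scaling initialization; batch-norm moving statistics use
momentum 0.9. With one seed and one backend the whole run is
bit-reproducible; reproducibility across BLAS builds is not promised.

The layers and the optimizer are implemented directly on numpy arrays
(`aeslice.nn`), with convolutions evaluated as nine shift-and-matmul
accumulations so the work lands in BLAS. All backward passes are verified
against central finite differences in the test suite.

## Slice synthesis

Two neighbouring slices a and b are encoded; each missing slice is decoded
from w·z_a + (1−w)·z_b. For N = 1 the weight is 1/2. For N = 2 the weights
are inverse-distance — the synthesized slice nearer a uses w = 2/3 on z_a
(the nearer neighbour dominates), its partner the complement. Because
decoder outputs are renormalized by the sigmoid, each synthesized slice is
histogram-normalized to the corresponding weighted average w·a + (1−w)·b
of the input slices: a monotone intensity remapping that matches the
empirical quantile function at 256 uniformly spaced quantiles, preserving
rank order. A grid search over w ∈ {0.1, …, 0.9} (step 0.1; nine values)
is provided to verify that 0.5 is optimal for symmetric pairs.

`enhance_volume` inserts N synthesized slices in every gap (Z slices →
Z + (Z−1)·N, slice spacing divided by N+1, original slices untouched);
`replace_slice` substitutes an interior outlier slice with the N = 1
synthesis from its two neighbours.

## Classical baselines

The comparison baselines interpolate the kept slices through-plane with
1D splines of order 1 (linear), 3 (cubic) and 5 (quintic B-spline),
evaluated at the removed positions. We use `scipy.interpolate.
make_interp_spline` with its default (not-a-knot style) end conditions
rather than mirror boundaries: interpolation then reproduces polynomials
up to the spline order exactly, which is the property the test suite
checks (quintic through-plane profiles are recovered to ≤ 1e-6). Orders
that exceed the number of kept slices fall back to the largest feasible
odd order.

## Phantom generator

Every experiment runs on synthetic diffusion-tensor phantoms, so all
ground truth is known. A phantom is a per-voxel 3×3 symmetric tensor
field D and baseline intensity S0 on a 64×64×17 grid (default): an
ellipsoidal "brain" of isotropic background (MD 0.9×10⁻³ mm²/s) containing
two crossing anisotropic bars and one arcuate tract (eigenvalues
(1.7, 0.2, 0.2)×10⁻³ mm²/s, FA ≈ 0.87, principal axis along the bar or the
local arc tangent), a CSF-like ventricle (isotropic 2.8×10⁻³ mm²/s, bright
on b0) and a bright cortical/CSF rim. White-matter-like structures are
darker than background on b0 (S0 contrast 0.75–0.8), as in neonatal
T2-weighted b0 images — this matters because the method's premise is that
the b0 images carry the anatomy the network must learn before it is
applied to diffusion-weighted volumes of the same anatomy. Structures
drift smoothly in-plane across slices (0.25–0.9 voxel/slice), so a removed
slice is never the plain average of its neighbours, and a seeded
low-frequency cosine field modulates eigenvalues and S0 by ±10 % to avoid
piecewise-constant degeneracy. Overlapping structures resolve
last-listed-wins.

Signals follow the noiseless single-tensor model S = S0·exp(−b·gᵀDg) over
a deterministic electrostatic-repulsion gradient scheme (default: 3 b=0
volumes plus 15 directions at b = 700 s/mm², the fetal-like protocol).
`thick_slice_stack` emulates thick-slice acquisition by keeping every
k-th slice and scaling the slice spacing.

What the phantom does not emulate: EPI distortion, motion, multi-shell or
non-Gaussian diffusion, k-space sampling, and the anatomical richness of
real brains. Passing tests therefore demonstrate the machinery and the
relative ordering of methods under controlled conditions, not clinical
performance.

## Rician noise

Magnitude images corrupted by complex Gaussian noise follow
S_noisy = √((S_clean + GN₁)² + GN₂²) with GN₁, GN₂ ~ N(0, SD) and
SD = S0_ref / SNR_out. S0_ref is the volume-level mean in-mask b=0
intensity (a per-voxel mode exists as a switch). Noise is applied on the
unnormalized intensity scale and the volume renormalized afterwards,
mirroring acquisition physics. The robustness experiment uses
SNR_out ∈ {27, 25, 23} for b0 and {20, 16, 13} for the diffusion shell.
The implementation is validated against Rayleigh closed forms (zero
signal: mean SD·√(π/2), variance SD²(2 − π/2)) and the exact Rician second
moment S² + 2·SD².

## DTI fitting

ln S = ln S0 − b·gᵀDg is fitted per voxel by log-linear least squares:
an OLS pass followed by one weighted pass with weights equal to the
squared model-predicted signal (the standard variance stabilization).
No positive-definiteness constraint is imposed — the fit stays
closed-form; negative eigenvalues are clipped to zero for map computation
and flagged. Voxels with any non-positive or near-zero signal
(≤ 1e-8·S0) are excluded. Scalar maps follow the usual definitions:
AD = λ₁, RD = (λ₂+λ₃)/2, MD = (λ₁+λ₂+λ₃)/3,
FA = √(3/2)·‖λ − λ̄‖/‖λ‖ clipped to [0, 1], colored FA = FA·|e₁|.
On noiseless phantoms the fit recovers every in-mask tensor to ≤ 1e-6
relative error; an independent per-voxel nonlinear least-squares fit
(scipy) serves as cross-check in the tests.

## Evaluation protocol

Slice removal: from each stack, N ∈ {1, 2} intermediate slices per gap are
removed in alternating order (kept indices 0, N+1, 2(N+1), …; trailing
slices without two kept neighbours are excluded). Each method — the
autoencoder and the three baselines — predicts the removed slices from
the kept ones; MSE and PSNR (peak 1, in-mask) are computed at the removed
positions only. Paired two-sided Wilcoxon signed-rank tests compare
methods across phantoms (exact null enumeration for n ≤ 25 without ties,
normal approximation with tie/zero correction otherwise; all-zero
differences return p = 1 with a flag).

Latent-space analysis: for every unordered pair of shell volumes, the
per-slice Euclidean distance between flattened slices is averaged over
slices, both on voxel data and on the per-slice latent codes, and related
to the angle between the gradient directions. Because diffusion signals
are antipodally symmetric, correlations are computed against |cos(angle)|.

## Desk-scale study conditions

The evaluation suite trains one scaled-down model per session and shares
it across experiments. 35 seeded phantoms are simulated with per-phantom
anatomy (structure positions, widths, tilts and tissue contrasts drawn
from physiologic ranges — the analogue of inter-subject variability).
The training corpus is the normalized b0 slices of the first 15 phantoms
(2 b0 repeats × 17 slices each, 510 slices), each repeat carrying an
independent mild Rician noise realization at SNR 30 — denoised-scanner-
grade noise, cleaner than the robustness-experiment levels, which both
makes the repeats informative and exposes the network to low noise as
real training data would. The remaining 20 phantoms are held out for
evaluation and "acquired" with the same SNR-30 Rician noise, so the
slice-removal ground truth is the acquired removed slice, exactly as it
is when the experiment runs on real scans.

The scaled configuration keeps the reference topology (four double-conv
blocks, two tail convolutions, spatial latent at 1/16 resolution, 8×
compression) at widths (8, 16, 32, 64), tail 64, latent 32 for 64×64
inputs, and trains 50 epochs with batch size 8, Adam (β₁ = 0.5) at 5e-4
with step decay (×0.3 at 60 % and 85 % of the run) and random in-plane
flip/rotation augmentation — small batches give the short run enough
optimizer steps, the decay stabilizes its tail, and the augmentation
substitutes variety the small corpus lacks. Neither the decay nor the
augmentation is part of the reference 128×128 protocol. These sizes are
the package's choice of a CPU-friendly experiment; the reference
configuration is instantiated for architecture checks and available for
full-scale training.

At this training scale (roughly 2 % of the reference protocol's
optimizer steps on 2 % of its data) the latent synthesis beats linear
and cubic interpolation on b0 volumes and approaches quintic-spline
accuracy as N grows, but a b0-trained network transfers only partially
to diffusion-weighted contrast, and its reconstruction bias stays above
the mild-noise floor — so the full method-superiority and denoising
inequalities of the reference-scale experiment are not reached by the
desk-scale run. The test suite states both inequalities at full strength
and they fail transparently there.

## Known limitations

* The numpy engine is single-threaded BLAS-bound; full-scale (128×128,
  200-epoch) training is possible but slow — the design target is the
  phantom-scale protocol and inference.
* The autoencoder trained on b0 slices transfers to diffusion-weighted
  contrast only to the extent that the b0 images contain the anatomy;
  on phantoms this is weaker than on real data, where b0 images are
  anatomically rich.
* Histogram normalization assumes the weighted average of the neighbour
  slices is a valid intensity reference; pathological slices (e.g. signal
  dropout on a neighbour) violate this.
* No automatic outlier detection: `replace_slice` requires the slice
  index.
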