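"""Synthetic diffusion-tensor phantoms.

A phantom is a per-voxel field of symmetric positive semi-definite diffusion
tensors inside an ellipsoidal "brain", with anisotropic structures (bars and
an arc) embedded in an isotropic background, plus a smooth seeded eigenvalue
modulation so that no region is piecewise constant. Diffusion-weighted
signals follow the single-tensor model

    S(b, g) = S0 * exp(-b * g^T D g)

which makes every downstream stage (training, slice synthesis, DTI fitting,
noise robustness) testable against known ground truth without any download.

Geometry emulates neonatal/fetal protocols: 2D axial slices with coarse
through-plane spacing, one set of b=0 volumes plus a single diffusion shell
over many unit directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .formats_io import DWIVolume, GradientTable, MaskedRegionLabels

MM2_PER_S = 1e-3  # convenience scale for typical brain diffusivities


@dataclass
class Structure:
    """A geometric primitive carrying its own tensor and b0 intensity.

    kind: "bar" (a tilted rectangular prism), "arc" (an annular segment),
    "blob" (an ellipsoid, e.g. a CSF-filled ventricle) or "shell" (an
    ellipsoidal rim just inside the brain boundary, emulating the bright
    cortical/CSF band of neonatal b0 images).
    eigvals: tensor eigenvalues (mm^2/s), principal first; equal values
    give an isotropic tensor.
    axis: principal diffusion axis for bars; arcs use the local tangent.
    s0_contrast: baseline-intensity multiplier — white-matter-like
    structures are darker than background on b0, CSF-like ones brighter.
    """

    kind: str
    center: Tuple[float, float, float]
    size: Tuple[float, float, float]
    eigvals: Tuple[float, float, float] = (1.7e-3, 0.2e-3, 0.2e-3)
    axis: Tuple[float, float, float] = (1.0, 0.0, 0.0)
    tilt_per_slice: Tuple[float, float] = (0.0, 0.0)  # in-plane drift (vox/slice)
    s0_contrast: float = 0.85  # S0 multiplier inside the structure
    label: int = 0


@dataclass
class PhantomSpec:
    """Reproducible description of one phantom acquisition."""

    shape: Tuple[int, int, int] = (64, 64, 17)
    n_directions: int = 15
    b: float = 700.0
    n_b0: int = 3
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.5)
    background_md: float = 0.9e-3  # isotropic background diffusivity (mm^2/s)
    s0: float = 500.0
    modulation_amplitude: float = 0.10
    structures: Optional[List[Structure]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_directions < 6:
            raise ValueError("need >= 6 gradient directions for a tensor fit")
        if self.shape[2] < 5:
            raise ValueError("need >= 5 slices for slice-removal experiments")
        if self.structures is None:
            # independent stream so geometry sampling does not interact
            # with the modulation field draw
            rng = np.random.default_rng(1_000_003 + self.seed)
            self.structures = default_structures(self.shape, rng)


def default_structures(shape, rng=None) -> List[Structure]:
    """Neonatal-like anatomy: two crossing white-matter bars, one arcuate
    tract, a CSF-filled ventricle and a bright cortical/CSF rim.

    Geometry, tilt and baseline contrast are drawn from physiologic ranges
    per phantom (inter-subject anatomical variability); pass ``rng=None``
    for the fixed mid-range anatomy. The through-plane tilt makes adjacent
    slices related by a smooth in-plane drift, so that a removed slice is
    not the plain average of its neighbours. White-matter-like structures
    are darker than background on b0 (s0_contrast < 1); CSF-like ones are
    brighter and nearly isotropic with high diffusivity, giving the b0
    images genuine tissue contrast in the same locations where the
    diffusion-weighted contrast lives.
    """
    nx, ny, nz = shape

    def u(lo, hi):
        if rng is None:
            return 0.5 * (lo + hi)
        return float(rng.uniform(lo, hi))

    return [
        Structure("bar",
                  center=(0.50 * nx, u(0.30, 0.46) * ny, 0.5 * nz),
                  size=(u(0.55, 0.68) * nx, u(0.06, 0.11) * ny, nz),
                  axis=(1, 0, 0), tilt_per_slice=(0.0, u(0.5, 1.2)),
                  s0_contrast=u(0.65, 0.85), label=1),
        Structure("bar",
                  center=(u(0.54, 0.70) * nx, 0.52 * ny, 0.5 * nz),
                  size=(u(0.06, 0.11) * nx, u(0.55, 0.68) * ny, nz),
                  axis=(0, 1, 0), tilt_per_slice=(u(0.5, 1.1), 0.0),
                  s0_contrast=u(0.68, 0.88), label=2),
        Structure("arc",
                  center=(u(0.36, 0.48) * nx, u(0.56, 0.68) * ny, 0.5 * nz),
                  size=(u(0.24, 0.34) * nx, u(0.04, 0.07) * nx, 0.8 * nz),
                  tilt_per_slice=(u(0.15, 0.35), 0.0),
                  s0_contrast=u(0.70, 0.90), label=3),
        Structure("blob",
                  center=(u(0.42, 0.50) * nx, u(0.48, 0.56) * ny, 0.5 * nz),
                  size=(u(0.09, 0.14) * nx, u(0.06, 0.10) * ny, 0.75 * nz),
                  eigvals=(2.8e-3, 2.8e-3, 2.8e-3),
                  tilt_per_slice=(u(0.2, 0.4), u(0.15, 0.35)),
                  s0_contrast=u(1.4, 1.8), label=4),
        Structure("shell", center=(0.0, 0.0, 0.0),
                  size=(u(0.84, 0.88), 1.0, 0.0),
                  eigvals=(1.5e-3, 1.5e-3, 1.5e-3),
                  s0_contrast=u(1.25, 1.45), label=5),
    ]


@dataclass
class TensorField:
    """Ground-truth per-voxel diffusion tensor field."""

    D: np.ndarray          # (x, y, z, 3, 3) symmetric PSD tensors, mm^2/s
    S0: np.ndarray         # (x, y, z) nonnegative baseline intensity
    mask: np.ndarray       # (x, y, z) bool
    labels: Optional[MaskedRegionLabels] = None
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.5)

    def eigenvalues(self) -> np.ndarray:
        """Sorted (descending) eigenvalues, (x, y, z, 3)."""
        w = np.linalg.eigvalsh(self.D)
        return w[..., ::-1]


def _axis_tensor(eigvals, axis) -> np.ndarray:
    """Tensor with principal eigenvector `axis` and cylindrical symmetry."""
    e1 = np.asarray(axis, dtype=np.float64)
    e1 = e1 / np.linalg.norm(e1)
    l1, l2, l3 = eigvals
    lperp = 0.5 * (l2 + l3)
    return lperp * np.eye(3) + (l1 - lperp) * np.outer(e1, e1)


def _smooth_modulation(shape, rng, amplitude) -> np.ndarray:
    """Seeded low-frequency multiplicative field in [1-a, 1+a].

    A sum of separable cosines with random phases; smooth in all three axes
    so that interpolation is non-trivial but well-posed.
    """
    nx, ny, nz = shape
    x = np.arange(nx)[:, None, None]
    y = np.arange(ny)[None, :, None]
    z = np.arange(nz)[None, None, :]
    f = np.zeros(shape, dtype=np.float64)
    for _ in range(3):
        kx, ky, kz = rng.uniform(0.5, 2.0, size=3)
        px, py, pz = rng.uniform(0, 2 * np.pi, size=3)
        f += (np.cos(2 * np.pi * kx * x / nx + px)
              * np.cos(2 * np.pi * ky * y / ny + py)
              * np.cos(2 * np.pi * kz * z / nz + pz))
    f /= np.max(np.abs(f))
    return 1.0 + amplitude * f


def make_phantom(spec: PhantomSpec) -> TensorField:
    """Build the ground-truth tensor field for a :class:`PhantomSpec`.

    Background voxels inside the ellipsoidal brain mask get isotropic tensors
    at ``background_md``; voxels inside a structure get its anisotropic
    tensor (later-listed structures win on overlap). All eigenvalues are
    scaled by a seeded smooth modulation.
    """
    nx, ny, nz = spec.shape
    rng = np.random.default_rng(spec.seed)

    xi, yi, zi = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    ax, ay, az = 0.46 * nx, 0.44 * ny, 0.52 * nz
    r_ell2 = (((xi - cx) / ax) ** 2 + ((yi - cy) / ay) ** 2
              + ((zi - cz) / az) ** 2)
    mask = r_ell2 <= 1.0
    if not np.any(mask):
        raise ValueError("empty brain mask")

    D = np.zeros((nx, ny, nz, 3, 3), dtype=np.float64)
    D[mask] = spec.background_md * np.eye(3)
    labels = np.zeros((nx, ny, nz), dtype=np.int32)
    names = {}

    for s in spec.structures:
        inside = np.zeros((nx, ny, nz), dtype=bool)
        if s.kind == "shell":
            inside = (r_ell2 >= s.size[0] ** 2) & mask
        else:
            for k in range(nz):
                dzc = k - s.center[2]
                cxk = s.center[0] + s.tilt_per_slice[0] * dzc
                cyk = s.center[1] + s.tilt_per_slice[1] * dzc
                if abs(dzc) > s.size[2] / 2:
                    continue
                if s.kind == "bar":
                    inside[..., k] = ((np.abs(xi[..., k] - cxk) <= s.size[0] / 2)
                                      & (np.abs(yi[..., k] - cyk) <= s.size[1] / 2))
                elif s.kind == "blob":
                    inside[..., k] = (((xi[..., k] - cxk) / s.size[0]) ** 2
                                      + ((yi[..., k] - cyk) / s.size[1]) ** 2
                                      <= 1.0)
                elif s.kind == "arc":
                    r = np.hypot(xi[..., k] - cxk, yi[..., k] - cyk)
                    half_sweep = 0.75 * np.pi / 2
                    theta = np.arctan2(yi[..., k] - cyk, xi[..., k] - cxk)
                    inside[..., k] = ((np.abs(r - s.size[0]) <= s.size[1])
                                      & (np.abs(theta) <= half_sweep))
                else:
                    raise ValueError(f"unknown structure kind {s.kind!r}")
            inside &= mask
        if s.kind != "arc":
            D[inside] = _axis_tensor(s.eigvals, s.axis)
        else:
            # tangent direction of the annulus at each voxel
            idx = np.argwhere(inside)
            for i, j, k in idx:
                dzc = k - s.center[2]
                tx = -(j - (s.center[1] + s.tilt_per_slice[1] * dzc))
                ty = (i - (s.center[0] + s.tilt_per_slice[0] * dzc))
                n = np.hypot(tx, ty)
                tangent = (tx / n, ty / n, 0.0) if n > 0 else (1.0, 0.0, 0.0)
                D[i, j, k] = _axis_tensor(s.eigvals, tangent)
        labels[inside] = s.label
        if s.label:
            names[s.label] = f"{s.kind}{s.label}"

    mod = _smooth_modulation(spec.shape, rng, spec.modulation_amplitude)
    D *= mod[..., None, None]

    S0 = np.zeros((nx, ny, nz), dtype=np.float64)
    S0[mask] = spec.s0
    for s in spec.structures:
        S0[labels == s.label] *= s.s0_contrast if s.label else 1.0
    S0 *= mod

    return TensorField(D=D, S0=S0, mask=mask,
                       labels=MaskedRegionLabels(labels, names),
                       spacing=spec.spacing)


def make_gradient_scheme(n_directions: int, b: float, n_b0: int = 1,
                         seed: int = 0, n_iter: int = 200) -> GradientTable:
    """Deterministic electrostatic-repulsion-style point set on the sphere.

    Points are initialised from a seeded uniform draw and relaxed by gradient
    descent on the antipodally-symmetric Coulomb energy, then ``n_b0`` zero
    rows are prepended for the b=0 volumes.
    """
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n_directions, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    step = 0.05
    for _ in range(n_iter):
        force = np.zeros_like(v)
        for sgn in (1.0, -1.0):  # antipodal symmetry: repel from +/- of others
            diff = v[:, None, :] - sgn * v[None, :, :]
            dist2 = np.sum(diff ** 2, axis=-1)
            np.fill_diagonal(dist2, np.inf)
            if sgn < 0:
                dist2[dist2 < 1e-12] = np.inf  # own antipode at same spot
            force += np.sum(diff / (dist2 ** 1.5)[..., None], axis=1)
        v += step * force
        v /= np.linalg.norm(v, axis=1, keepdims=True)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, float(b))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), v])
    return GradientTable(bvals, bvecs)


def simulate_dwi(field: TensorField, gradients: GradientTable,
                 affine: Optional[np.ndarray] = None) -> DWIVolume:
    """Noiseless single-tensor DWI signal: S = S0 exp(-b g^T D g).

    b=0 volumes return S0 exactly.
    """
    if affine is None:
        affine = np.diag(list(field.spacing) + [1.0])
    n = len(gradients)
    out = np.empty(field.S0.shape + (n,), dtype=np.float32)
    for i in range(n):
        b, g = gradients.bvals[i], gradients.bvecs[i]
        if b <= 0:
            out[..., i] = field.S0
        else:
            adc = np.einsum("i,...ij,j->...", g, field.D, g)
            out[..., i] = field.S0 * np.exp(-b * adc)
    return DWIVolume(out, affine, gradients, mask=field.mask)


def thick_slice_stack(vol: DWIVolume, keep_every: int) -> DWIVolume:
    """Downsample through-plane by keeping slices {0, k, 2k, ...}.

    The slice spacing in the affine is multiplied by ``keep_every``,
    emulating a thick-slice (low through-plane resolution) acquisition.
    """
    if keep_every < 2:
        raise ValueError("keep_every must be >= 2")
    idx = np.arange(0, vol.n_slices, keep_every)
    if len(idx) < 2:
        raise ValueError(
            f"only {len(idx)} slice(s) would remain of {vol.n_slices}"
        )
    affine = vol.affine.copy()
    affine[:3, 2] *= keep_every
    mask = vol.mask[:, :, idx] if vol.mask is not None else None
    return vol.with_data(vol.data[:, :, idx, :], affine=affine, mask=mask)
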