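"""2D data synthesis: forward projection, slice extraction, k-space, noise.

The projector is a parallel-beam line-integral model: the volume is rotated
about the SI axis and summed along the AP ray direction, giving a detector
with SI rows and (rotated) LR columns.  This is the geometry-agnostic
analogue of a digitally reconstructed radiograph; the geometry is tagged so
a cone-beam projector can be substituted behind the same contract.

Test-time image degradation uses a parametric model: Poisson photon noise
applied through an attenuation-style transform at a configurable count
scale (dose proxy), plus an additive low-frequency scatter term built from
a Gaussian-blurred copy of the projection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, rotate

from .fields import Grid3, Volume3D

__all__ = [
    "Projection2D",
    "SlicePair",
    "KSpacePair",
    "NoiseModel",
    "forward_project",
    "extract_slices",
    "central_lattice",
    "to_kspace",
    "from_kspace",
    "slices_to_kspace",
    "add_noise",
    "downsample_volume",
    "downsample_projection",
]


@dataclass
class Projection2D:
    """2D projection: rows = SI, columns = rotated LR, at gantry angle alpha."""

    pixels: np.ndarray
    angle_deg: float
    pixel_spacing: tuple[float, float]  # (row/SI, col/LR) mm
    geometry: str = "parallel"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("projection contains non-finite pixels")
        if not (0.0 <= self.angle_deg < 360.0):
            raise ValueError("gantry angle must be in [0, 360)")


@dataclass
class SlicePair:
    """Coronal and sagittal slices (rows = SI) with their plane indices."""

    coronal: np.ndarray
    coronal_idx: int
    sagittal: np.ndarray
    sagittal_idx: int
    pixel_spacing: tuple[float, float]


@dataclass
class KSpacePair:
    """Centred 2D spectra (orthonormal DFT) of a coronal/sagittal slice pair."""

    coronal_real: np.ndarray
    coronal_imag: np.ndarray
    sagittal_real: np.ndarray
    sagittal_imag: np.ndarray


@dataclass
class NoiseModel:
    """Parametric projection degradation model.

    ``count_scale`` is the incident photon count per pixel (dose proxy);
    ``scatter_fraction`` in [0, 1) scales the additive blurred scatter term
    with blur width ``scatter_blur_mm``.
    """

    count_scale: float = 1e4
    scatter_fraction: float = 0.1
    scatter_blur_mm: float = 20.0
    attenuation: float = 4.0  # max optical depth across the normalised projection
    seed: int = 0

    def __post_init__(self) -> None:
        if self.count_scale <= 0:
            raise ValueError("count_scale must be positive")
        if not (0.0 <= self.scatter_fraction < 1.0):
            raise ValueError("scatter_fraction must be in [0, 1)")


def forward_project(V: Volume3D, angle_deg: float) -> Projection2D:
    """Parallel-beam projection of a volume at gantry angle ``angle_deg``.

    The volume is rotated by ``-angle`` about the SI axis (trilinear
    resampling in the LR-AP plane) and summed along AP.  At exactly 0 the
    projection equals the plain AP-axis sum.
    """
    if not (0.0 <= angle_deg < 360.0):
        raise ValueError("gantry angle must be in [0, 360)")
    vals = V.values
    if angle_deg != 0.0:
        vals = rotate(vals, -angle_deg, axes=(0, 1), reshape=False, order=1, mode="constant", cval=0.0)
    proj = vals.sum(axis=1)  # (LR, SI)
    return Projection2D(
        pixels=proj.T,  # rows = SI, cols = LR
        angle_deg=float(angle_deg),
        pixel_spacing=(V.grid.spacing[2], V.grid.spacing[0]),
    )


def extract_slices(V: Volume3D, coronal_idx: int, sagittal_idx: int) -> SlicePair:
    """Axis-aligned coronal (fixed AP index) and sagittal (fixed LR index)
    planes, both returned with SI rows."""
    n_lr, n_ap, n_si = V.grid.shape
    if not (0 <= coronal_idx < n_ap):
        raise IndexError(f"coronal index {coronal_idx} outside [0, {n_ap})")
    if not (0 <= sagittal_idx < n_lr):
        raise IndexError(f"sagittal index {sagittal_idx} outside [0, {n_lr})")
    coronal = V.values[:, coronal_idx, :].T  # (SI, LR)
    sagittal = V.values[sagittal_idx, :, :].T  # (SI, AP)
    return SlicePair(
        coronal=coronal,
        coronal_idx=int(coronal_idx),
        sagittal=sagittal,
        sagittal_idx=int(sagittal_idx),
        pixel_spacing=(V.grid.spacing[2], V.grid.spacing[0]),
    )


def central_lattice(grid: Grid3, k: int = 16) -> list[tuple[int, int]]:
    """The central k x k lattice of (coronal, sagittal) slice-index pairs
    used to enumerate training slice pairs."""
    n_lr, n_ap, _ = grid.shape
    if k > n_ap or k > n_lr:
        raise ValueError(f"lattice k={k} does not fit grid {grid.shape}")
    c0 = (n_ap - k) // 2
    s0 = (n_lr - k) // 2
    return [(c0 + i, s0 + j) for i in range(k) for j in range(k)]


def to_kspace(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centred orthonormal 2D DFT split into real and imaginary parts."""
    img = np.asarray(img, dtype=np.float64)
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    spec = np.fft.fftshift(np.fft.fft2(img, norm="ortho"))
    return spec.real.copy(), spec.imag.copy()


def from_kspace(real: np.ndarray, imag: np.ndarray) -> np.ndarray:
    """Inverse of :func:`to_kspace`; round-trips to ~1e-12."""
    spec = np.fft.ifftshift(np.asarray(real) + 1j * np.asarray(imag))
    return np.fft.ifft2(spec, norm="ortho").real


def slices_to_kspace(pair: SlicePair) -> KSpacePair:
    cr, ci = to_kspace(pair.coronal)
    sr, si = to_kspace(pair.sagittal)
    return KSpacePair(coronal_real=cr, coronal_imag=ci, sagittal_real=sr, sagittal_imag=si)


def add_noise(p: Projection2D, model: NoiseModel) -> Projection2D:
    """Apply Poisson photon noise and additive scatter to a projection.

    The projection is normalised to optical depth, attenuated
    (``I = N0 * exp(-mu)``), Poisson-sampled at ``count_scale``, and
    log-recovered; a Gaussian-blurred copy scaled by ``scatter_fraction``
    is added.  Deterministic under the model seed.
    """
    pix = p.pixels
    if pix.min() < 0:
        raise ValueError("projection pixels must be non-negative for the noise model")
    rng = np.random.default_rng(model.seed)
    peak = pix.max()
    if peak <= 0:
        return Projection2D(pix.copy(), p.angle_deg, p.pixel_spacing, p.geometry)
    depth = model.attenuation * pix / peak
    expected = model.count_scale * np.exp(-depth)
    counts = np.maximum(rng.poisson(expected).astype(np.float64), 1.0)
    recovered = -np.log(counts / model.count_scale) / model.attenuation * peak
    if model.scatter_fraction > 0:
        sigma = model.scatter_blur_mm / np.asarray(p.pixel_spacing)
        scatter = gaussian_filter(pix, sigma=sigma)
        recovered = recovered + model.scatter_fraction * scatter
    return Projection2D(recovered, p.angle_deg, p.pixel_spacing, p.geometry)


def _box_reduce(arr: np.ndarray, target: tuple[int, ...]) -> np.ndarray:
    if len(target) != arr.ndim:
        raise ValueError("target rank mismatch")
    factors = []
    for n, t in zip(arr.shape, target):
        if t > n:
            raise ValueError(f"upsampling {n} -> {t} is out of scope; use a resize instead")
        if n % t:
            raise ValueError(f"downsampling requires integer factors, got {n} -> {t}")
        factors.append(n // t)
    shape = []
    for t, f in zip(target, factors):
        shape.extend([t, f])
    out = arr.reshape(shape)
    for axis in range(arr.ndim - 1, -1, -1):
        out = out.mean(axis=2 * axis + 1)
    return out


def downsample_volume(V: Volume3D, target_shape: tuple[int, int, int]) -> Volume3D:
    """Box-average a volume to ``target_shape``; spacing is rescaled so the
    physical extent is preserved (e.g. 512x256x512 at 1 mm -> 128^3 gives
    4 x 2 x 4 mm voxels)."""
    vals = _box_reduce(V.values, tuple(target_shape))
    factors = [n // t for n, t in zip(V.grid.shape, target_shape)]
    spacing = tuple(s * f for s, f in zip(V.grid.spacing, factors))
    return Volume3D(Grid3(tuple(target_shape), spacing, V.grid.origin), vals)


def downsample_projection(p: Projection2D, target_shape: tuple[int, int]) -> Projection2D:
    pix = _box_reduce(p.pixels, tuple(target_shape))
    factors = [n // t for n, t in zip(p.pixels.shape, target_shape)]
    spacing = tuple(s * f for s, f in zip(p.pixel_spacing, factors))
    return Projection2D(pix, p.angle_deg, spacing, p.geometry)
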