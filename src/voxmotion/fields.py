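"""Core geometry: grids, velocity/displacement fields, diffeomorphic
integration, warping, and Jacobian diagnostics.

All volumetric data live on a :class:`Grid3` with a fixed axis convention
``(LR, AP, SI)`` (left-right, anterior-posterior, superior-inferior) and
0-based voxel indexing.  Displacements and velocities are stored in
millimetres and converted to voxel units per axis only at interpolation
time.

Deformations are parameterised by stationary velocity fields: integrating
the flow ODE ``dphi/dt = u(phi)`` over ``t in [0, 1]`` yields a
diffeomorphic (smooth, invertible, topology-preserving) mapping.  The
integration is performed by scaling and squaring: ``u`` is scaled by
``2**-T`` and the resulting small displacement is composed with itself
``T`` times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "Grid3",
    "Volume3D",
    "Mask3D",
    "VelocityField",
    "DisplacementField",
    "integrate_velocity",
    "compose",
    "invert",
    "warp_volume",
    "warp_mask",
    "jacobian_determinant",
    "negative_jacobian_fraction",
    "read_volume",
    "write_volume",
    "read_displacement_field",
    "write_displacement_field",
]


@dataclass(frozen=True)
class Grid3:
    """Regular 3D voxel grid on a physical (mm) coordinate frame.

    Parameters
    ----------
    shape
        Number of voxels along (LR, AP, SI).  Each entry must be >= 2.
    spacing
        Voxel size in mm along each axis; all entries > 0.
    origin
        Physical position (mm) of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 2 for n in self.shape):
            raise ValueError(f"grid shape must be 3 entries >= 2, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"grid spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical size of the field of view along each axis."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def voxel_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Dense voxel-index coordinate arrays (one per axis)."""
        return np.meshgrid(*(np.arange(n, dtype=np.float64) for n in self.shape), indexing="ij")


def _check_values(grid: Grid3, values: np.ndarray, name: str, ncomp: int | None = None) -> np.ndarray:
    values = np.asarray(values)
    expected = grid.shape if ncomp is None else (ncomp,) + grid.shape
    if values.shape != expected:
        raise ValueError(f"{name} shape {values.shape} does not match grid {expected}")
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{name} contains non-finite values")
    return values


@dataclass
class Volume3D:
    """Scalar 3D image on a grid (arbitrary intensity units)."""

    grid: Grid3
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = _check_values(self.grid, self.values, "volume").astype(np.float64, copy=False)


@dataclass
class Mask3D:
    """Binary structure mask on a grid."""

    grid: Grid3
    values: np.ndarray

    def __post_init__(self) -> None:
        v = _check_values(self.grid, self.values, "mask")
        if not np.isin(v, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        self.values = v.astype(np.uint8, copy=False)

    def volume_mm3(self) -> float:
        return float(self.values.sum()) * float(np.prod(self.grid.spacing))

    def centroid_mm(self) -> np.ndarray:
        """Unweighted centroid of mask voxels in mm (grid frame)."""
        if not self.values.any():
            raise ValueError("centroid of an empty mask is undefined")
        idx = np.argwhere(self.values > 0).mean(axis=0)
        return idx * np.asarray(self.grid.spacing)


@dataclass
class VelocityField:
    """Stationary velocity field u, 3-vector per voxel in mm."""

    grid: Grid3
    components: np.ndarray

    def __post_init__(self) -> None:
        self.components = _check_values(self.grid, self.components, "velocity", 3).astype(
            np.float64, copy=False
        )


@dataclass
class DisplacementField:
    """Deformation vector field phi, 3-vector displacement per voxel in mm.

    ``provenance`` records how the field was produced: ``integrated(u,T)``
    for scaling-and-squaring output, ``ground_truth`` for phantom labels, or
    ``predicted`` for network output.
    """

    grid: Grid3
    components: np.ndarray
    provenance: str = "ground_truth"

    def __post_init__(self) -> None:
        self.components = _check_values(self.grid, self.components, "displacement", 3).astype(
            np.float64, copy=False
        )

    @classmethod
    def identity(cls, grid: Grid3, provenance: str = "ground_truth") -> "DisplacementField":
        return cls(grid, np.zeros((3,) + grid.shape), provenance=provenance)

    def max_magnitude_mm(self) -> float:
        return float(np.sqrt((self.components**2).sum(axis=0)).max())


# ---------------------------------------------------------------------------
# interpolation helpers

def _sample_components(components: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Trilinearly sample each component of a vector field at voxel coords.

    ``coords`` has shape (3,) + spatial; out-of-bounds samples are edge
    clamped (``mode='nearest'``).
    """
    return np.stack(
        [map_coordinates(c, coords, order=1, mode="nearest") for c in components]
    )


def _displaced_coords(grid: Grid3, disp_mm: np.ndarray) -> np.ndarray:
    """Voxel coordinates v + phi(v) with mm->voxel conversion per axis."""
    coords = np.stack(grid.voxel_coords())
    spacing = np.asarray(grid.spacing).reshape(3, 1, 1, 1)
    return coords + disp_mm / spacing


def _compose_disp(grid: Grid3, outer_mm: np.ndarray, inner_mm: np.ndarray) -> np.ndarray:
    """Displacement of (outer after inner): inner + outer sampled at v+inner."""
    coords = _displaced_coords(grid, inner_mm)
    return inner_mm + _sample_components(outer_mm, coords)


# ---------------------------------------------------------------------------
# operations

def integrate_velocity(u: VelocityField, T: int = 10) -> DisplacementField:
    """Integrate a stationary velocity field by scaling and squaring.

    The flow ODE ``dphi/dt = u(phi)`` with ``phi(0) = id`` is solved over
    ``t in [0, 1]``.  The group property ``phi(1) = phi(1/2) o phi(1/2)``
    allows ``u`` to be scaled by ``2**-T`` (so the small-deformation
    approximation ``phi(2**-T) ~ id + u * 2**-T`` holds) and the result to be
    squared ``T`` times.

    Parameters
    ----------
    u
        Stationary velocity field in mm.
    T
        Number of squaring steps (>= 1).  ``T=10`` is the working default.
    """
    if T < 1:
        raise ValueError("integration requires T >= 1")
    disp = u.components * (2.0 ** -T)
    for _ in range(T):
        disp = _compose_disp(u.grid, disp, disp)
    return DisplacementField(u.grid, disp, provenance=f"integrated(u,T={T})")


def compose(outer: DisplacementField, inner: DisplacementField) -> DisplacementField:
    """Displacement of the mapping (outer applied after inner).

    The outer displacement is sampled at the inner-displaced positions by
    trilinear interpolation and added to the inner displacement.
    """
    if outer.grid != inner.grid:
        raise ValueError("compose requires displacement fields on the same grid")
    disp = _compose_disp(outer.grid, outer.components, inner.components)
    return DisplacementField(outer.grid, disp, provenance="ground_truth")


def invert(phi: DisplacementField, iterations: int = 20) -> DisplacementField:
    """Numerical inverse of a diffeomorphic displacement field.

    Fixed-point iteration ``psi <- -phi(v + psi(v))`` which converges for
    smooth fields with positive Jacobian determinant.  A non-diffeomorphic
    input produces a warning and a best-effort result.
    """
    detj = jacobian_determinant(phi)
    if (detj.values <= 0).any():
        warnings.warn(
            "invert() called on a non-diffeomorphic field (detJ <= 0 somewhere); "
            "result is best-effort",
            RuntimeWarning,
            stacklevel=2,
        )
    psi = -phi.components
    for _ in range(iterations):
        coords = _displaced_coords(phi.grid, psi)
        psi = -_sample_components(phi.components, coords)
    return DisplacementField(phi.grid, psi, provenance="ground_truth")


def warp_volume(X: Volume3D, phi: DisplacementField) -> Volume3D:
    """Backward-warp a volume: output(v) = X(v + phi(v)).

    This realises the convention that warping the reference image X by the
    DVF phi produces the acquired image Y.  Sampling is trilinear with edge
    clamping; displacements are converted mm -> voxels per axis.
    """
    if X.grid != phi.grid:
        raise ValueError("warp_volume requires volume and field on the same grid")
    coords = _displaced_coords(X.grid, phi.components)
    out = map_coordinates(X.values, coords, order=1, mode="nearest")
    return Volume3D(X.grid, out)


def warp_mask(M: Mask3D, phi: DisplacementField) -> Mask3D:
    """Warp a binary mask as a real-valued field, then threshold at 0.5."""
    if M.grid != phi.grid:
        raise ValueError("warp_mask requires mask and field on the same grid")
    coords = _displaced_coords(M.grid, phi.components)
    out = map_coordinates(M.values.astype(np.float64), coords, order=1, mode="nearest")
    return Mask3D(M.grid, (out >= 0.5).astype(np.uint8))


def jacobian_determinant(phi: DisplacementField) -> Volume3D:
    """Jacobian determinant of the mapping v -> v + phi(v), per voxel.

    Derivatives are taken in voxel units (central differences on the
    interior, one-sided at the boundaries).  detJ > 0 everywhere is the
    discrete check that the mapping preserves topology and is invertible.
    """
    grid = phi.grid
    if any(n < 3 for n in grid.shape):
        raise ValueError("jacobian requires at least 3 voxels per axis")
    spacing = np.asarray(grid.spacing)
    # mapping in voxel units: v + phi(v)/spacing
    J = np.empty((3, 3) + grid.shape)
    for comp in range(3):
        disp_vox = phi.components[comp] / spacing[comp]
        grads = np.gradient(disp_vox)  # d(disp)/d(axis) per axis, voxel units
        for axis in range(3):
            J[comp, axis] = grads[axis] + (1.0 if comp == axis else 0.0)
    det = (
        J[0, 0] * (J[1, 1] * J[2, 2] - J[1, 2] * J[2, 1])
        - J[0, 1] * (J[1, 0] * J[2, 2] - J[1, 2] * J[2, 0])
        + J[0, 2] * (J[1, 0] * J[2, 1] - J[1, 1] * J[2, 0])
    )
    return Volume3D(grid, det)


def negative_jacobian_fraction(detJ: Volume3D) -> float:
    """Fraction of voxels with detJ <= 0 (in [0, 1])."""
    return float((detJ.values <= 0).mean())


# ---------------------------------------------------------------------------
# I/O: NIfTI (.nii/.nii.gz) and MetaImage (.mha)

def _nifti_affine(grid: Grid3) -> np.ndarray:
    aff = np.diag(list(grid.spacing) + [1.0])
    aff[:3, 3] = grid.origin
    return aff


def write_volume(path: str, vol: Volume3D | Mask3D) -> None:
    """Write a scalar volume or mask as NIfTI or MetaImage by extension."""
    path = str(path)
    if path.endswith(".mha") or path.endswith(".mhd"):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.asarray(vol.values, dtype=np.float32).transpose(2, 1, 0))
        img.SetSpacing(vol.grid.spacing)
        img.SetOrigin(vol.grid.origin)
        sitk.WriteImage(img, path)
    else:
        import nibabel as nib

        nib.save(nib.Nifti1Image(np.asarray(vol.values, dtype=np.float32), _nifti_affine(vol.grid)), path)


def read_volume(path: str) -> Volume3D:
    path = str(path)
    if path.endswith(".mha") or path.endswith(".mhd"):
        import SimpleITK as sitk

        img = sitk.ReadImage(path)
        values = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        grid = Grid3(values.shape, tuple(img.GetSpacing()), tuple(img.GetOrigin()))
    else:
        import nibabel as nib

        img = nib.load(path)
        values = np.asarray(img.dataobj, dtype=np.float64)
        zooms = img.header.get_zooms()[:3]
        origin = tuple(np.asarray(img.affine[:3, 3], dtype=float))
        grid = Grid3(values.shape, tuple(float(z) for z in zooms), origin)
    return Volume3D(grid, values)


def write_displacement_field(path: str, phi: DisplacementField) -> None:
    """Write a DVF as a 3-component vector image (mm units in the header)."""
    path = str(path)
    comps = np.asarray(phi.components, dtype=np.float32)
    if path.endswith(".mha") or path.endswith(".mhd"):
        import SimpleITK as sitk

        arr = comps.transpose(3, 2, 1, 0)  # (SI, AP, LR, 3) for sitk vector image
        img = sitk.GetImageFromArray(arr, isVector=True)
        img.SetSpacing(phi.grid.spacing)
        img.SetOrigin(phi.grid.origin)
        sitk.WriteImage(img, path)
    else:
        import nibabel as nib

        img = nib.Nifti1Image(comps.transpose(1, 2, 3, 0), _nifti_affine(phi.grid))
        img.header.set_xyzt_units(xyz="mm")
        nib.save(img, path)


def read_displacement_field(path: str, provenance: str = "ground_truth") -> DisplacementField:
    path = str(path)
    if path.endswith(".mha") or path.endswith(".mhd"):
        import SimpleITK as sitk

        img = sitk.ReadImage(path)
        comps = sitk.GetArrayFromImage(img).transpose(3, 2, 1, 0)
        grid = Grid3(comps.shape[1:], tuple(img.GetSpacing()), tuple(img.GetOrigin()))
    else:
        import nibabel as nib

        img = nib.load(path)
        arr = np.asarray(img.dataobj, dtype=np.float64)
        comps = arr.transpose(3, 0, 1, 2)
        zooms = img.header.get_zooms()[:3]
        origin = tuple(np.asarray(img.affine[:3, 3], dtype=float))
        grid = Grid3(comps.shape[1:], tuple(float(z) for z in zooms), origin)
    return DisplacementField(grid, comps, provenance=provenance)
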