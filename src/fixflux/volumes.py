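"""Volume containers and NIfTI I/O.

Every quantitative map in this package (concentration, T2, B1, masks,
diffusion tensors) lives on a common voxel grid.  :class:`VolumeGrid` holds
the geometry (shape, spacing in mm, voxel-to-world affine); the containers
below pair a grid with per-voxel data.  All stencil computations operate in
voxel space using the physical spacing from the header; the affine is carried
through I/O but never used for resampling — inputs are assumed pre-aligned.

Internal computation is double precision; files are written as 32-bit float
(uint8 for masks).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeGrid",
    "ScalarVolume",
    "Mask",
    "TensorVolume",
    "VolumeFormatError",
    "GridIncompatibilityError",
    "read_scalar_volume",
    "write_scalar_volume",
    "read_mask",
    "write_mask",
    "read_tensor_volume",
    "write_tensor_volume",
    "check_grid_compatibility",
]

#: tolerance (mm / dimensionless) for declaring two grids identical
GRID_TOL = 1e-6


class VolumeFormatError(ValueError):
    """A file or array does not satisfy the expected volume format."""


class GridIncompatibilityError(ValueError):
    """Two volumes do not share the same grid (shape, spacing or affine)."""


@dataclass(frozen=True)
class VolumeGrid:
    """Geometry shared by all volumes of one run.

    Parameters
    ----------
    shape
        Matrix size ``(nx, ny, nz)`` in voxels.
    spacing
        Voxel size ``(hx, hy, hz)`` in mm, strictly positive.
    affine
        4x4 voxel-to-world map.  Defaults to ``diag(spacing, 1)``.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    affine: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(h) for h in self.spacing)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise VolumeFormatError(f"shape must be 3 positive integers, got {shape}")
        if len(spacing) != 3 or not all(np.isfinite(spacing)) or any(h <= 0 for h in spacing):
            raise VolumeFormatError(f"spacing must be 3 positive lengths (mm), got {spacing}")
        affine = self.affine
        if affine is None:
            affine = np.diag([*spacing, 1.0])
        affine = np.asarray(affine, dtype=float)
        if affine.shape != (4, 4) or not np.isfinite(affine).all():
            raise VolumeFormatError("affine must be a finite 4x4 matrix")
        if abs(np.linalg.det(affine)) < 1e-12:
            raise VolumeFormatError("affine must be invertible")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "affine", affine)

    def isclose(self, other: "VolumeGrid", tol: float = GRID_TOL) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, rtol=0.0, atol=tol)
            and np.allclose(self.affine, other.affine, rtol=0.0, atol=tol)
        )

    def __eq__(self, other: object) -> bool:  # value equality incl. affine
        if not isinstance(other, VolumeGrid):
            return NotImplemented
        return (
            self.shape == other.shape
            and self.spacing == other.spacing
            and np.array_equal(self.affine, other.affine)
        )

    def __hash__(self) -> int:
        return hash((self.shape, self.spacing))


def _check_values(grid: VolumeGrid, values: np.ndarray, name: str) -> np.ndarray:
    values = np.asarray(values)
    if values.shape != grid.shape:
        raise GridIncompatibilityError(
            f"{name} values shape {values.shape} does not match grid shape {grid.shape}"
        )
    return values


@dataclass
class ScalarVolume:
    """One real value per voxel with a units tag (``ms``, ``mm``,
    ``mm^2/s`` or ``unitless``)."""

    grid: VolumeGrid
    values: np.ndarray
    units: str = "unitless"

    def __post_init__(self) -> None:
        self.values = _check_values(self.grid, self.values, "scalar").astype(float)


@dataclass
class Mask:
    """Boolean voxel mask.

    ``label`` names the compartment: ``tissue``, ``white``, ``grey`` or
    ``medium``.  The tissue/medium partition drives the Dirichlet boundary of
    the diffusion simulation: every non-tissue voxel is medium.
    """

    grid: VolumeGrid
    values: np.ndarray
    label: str = "tissue"

    def __post_init__(self) -> None:
        self.values = _check_values(self.grid, self.values, "mask").astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    def complement(self, label: str = "medium") -> "Mask":
        return Mask(self.grid, ~self.values, label=label)


# canonical in-memory component order (row-major upper triangle)
TENSOR_COMPONENTS = ("Dxx", "Dxy", "Dxz", "Dyy", "Dyz", "Dzz")

# file-order dialects -> permutation taking file order to canonical order.
# "lower" is the common DTI lower-triangular row-major convention
# (Dxx, Dxy, Dyy, Dxz, Dyz, Dzz); "upper" is the canonical order itself.
_COMPONENT_ORDERS = {
    "upper": (0, 1, 2, 3, 4, 5),
    "lower": (0, 1, 3, 2, 4, 5),
}


@dataclass
class TensorVolume:
    """Per-voxel symmetric 3x3 diffusion tensor in mm^2/s.

    Components are stored as a trailing axis of length 6 in the order
    ``(Dxx, Dxy, Dxz, Dyy, Dyz, Dzz)``; symmetry therefore holds by
    construction.
    """

    grid: VolumeGrid
    components: np.ndarray  # (*shape, 6)

    def __post_init__(self) -> None:
        comps = np.asarray(self.components, dtype=float)
        if comps.shape != (*self.grid.shape, 6):
            raise GridIncompatibilityError(
                f"tensor components shape {comps.shape} != {(*self.grid.shape, 6)}"
            )
        self.components = comps

    def component(self, name: str) -> np.ndarray:
        return self.components[..., TENSOR_COMPONENTS.index(name)]

    def full_matrix(self) -> np.ndarray:
        """Expand to an explicit (*shape, 3, 3) symmetric matrix field."""
        c = self.components
        m = np.empty((*c.shape[:-1], 3, 3))
        m[..., 0, 0] = c[..., 0]
        m[..., 0, 1] = m[..., 1, 0] = c[..., 1]
        m[..., 0, 2] = m[..., 2, 0] = c[..., 2]
        m[..., 1, 1] = c[..., 3]
        m[..., 1, 2] = m[..., 2, 1] = c[..., 4]
        m[..., 2, 2] = c[..., 5]
        return m

    @property
    def mean_diffusivity(self) -> np.ndarray:
        c = self.components
        return (c[..., 0] + c[..., 3] + c[..., 5]) / 3.0

    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues per voxel, descending (L1 >= L2 >= L3)."""
        w = np.linalg.eigvalsh(self.full_matrix())
        return w[..., ::-1]

    def eigensystem(self) -> tuple[np.ndarray, np.ndarray]:
        """(eigenvalues descending, eigenvectors as columns V1..V3)."""
        w, v = np.linalg.eigh(self.full_matrix())
        return w[..., ::-1], v[..., :, ::-1]

    def fractional_anisotropy(self) -> np.ndarray:
        w = self.eigenvalues()
        md = w.mean(axis=-1, keepdims=True)
        num = np.sum((w - md) ** 2, axis=-1)
        den = np.sum(w**2, axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            fa = np.sqrt(1.5 * num / den)
        return np.where(den > 0, fa, 0.0)

    @classmethod
    def from_matrix(cls, grid: VolumeGrid, m: np.ndarray) -> "TensorVolume":
        """Build from a (*shape, 3, 3) field; the matrix is symmetrised."""
        m = np.asarray(m, dtype=float)
        c = np.stack(
            [
                m[..., 0, 0],
                0.5 * (m[..., 0, 1] + m[..., 1, 0]),
                0.5 * (m[..., 0, 2] + m[..., 2, 0]),
                m[..., 1, 1],
                0.5 * (m[..., 1, 2] + m[..., 2, 1]),
                m[..., 2, 2],
            ],
            axis=-1,
        )
        return cls(grid, c)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------


def _load(path) -> nib.Nifti1Image:
    try:
        img = nib.load(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # nibabel raises a zoo of error types
        raise VolumeFormatError(f"could not read {path!s} as NIfTI: {exc}") from exc
    return img


def _grid_from_image(img: nib.Nifti1Image) -> VolumeGrid:
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise VolumeFormatError(f"non-positive or NaN voxel spacing in header: {zooms}")
    return VolumeGrid(shape=img.shape[:3], spacing=zooms, affine=img.affine)


def read_scalar_volume(path, units: str = "unitless") -> ScalarVolume:
    """Read a 3-D NIfTI file into a :class:`ScalarVolume`.

    Raises :class:`VolumeFormatError` for non-3-D images or invalid spacing.
    """
    img = _load(path)
    if img.ndim != 3:
        raise VolumeFormatError(f"{path!s}: expected a 3-D image, got shape {img.shape}")
    grid = _grid_from_image(img)
    return ScalarVolume(grid, np.asarray(img.get_fdata(), dtype=float), units=units)


def write_scalar_volume(vol: ScalarVolume, path) -> None:
    img = nib.Nifti1Image(vol.values.astype(np.float32), vol.grid.affine)
    img.header.set_zooms(vol.grid.spacing)
    nib.save(img, str(path))


def read_mask(path, label: str = "tissue") -> Mask:
    img = _load(path)
    if img.ndim != 3:
        raise VolumeFormatError(f"{path!s}: expected a 3-D mask, got shape {img.shape}")
    grid = _grid_from_image(img)
    return Mask(grid, np.asarray(img.get_fdata()) > 0.5, label=label)


def write_mask(mask: Mask, path) -> None:
    img = nib.Nifti1Image(mask.values.astype(np.uint8), mask.grid.affine)
    img.header.set_zooms(mask.grid.spacing)
    nib.save(img, str(path))


def read_tensor_volume(path, component_order: str = "lower") -> TensorVolume:
    """Read a 4-D NIfTI with 6 tensor components per voxel.

    ``component_order`` names the file dialect: ``"lower"`` (default,
    Dxx Dxy Dyy Dxz Dyz Dzz) or ``"upper"`` (Dxx Dxy Dxz Dyy Dyz Dzz).
    """
    if component_order not in _COMPONENT_ORDERS:
        raise VolumeFormatError(
            f"unknown component order {component_order!r}; expected one of "
            f"{sorted(_COMPONENT_ORDERS)}"
        )
    img = _load(path)
    if img.ndim != 4 or img.shape[3] != 6:
        raise VolumeFormatError(
            f"{path!s}: expected a 4-D image with 6 components, got shape {img.shape}"
        )
    grid = _grid_from_image(img)
    data = np.asarray(img.get_fdata(), dtype=float)
    perm = _COMPONENT_ORDERS[component_order]
    canonical = np.empty_like(data)
    for canon_idx, file_idx in enumerate(perm):
        canonical[..., canon_idx] = data[..., file_idx]
    return TensorVolume(grid, canonical)


def write_tensor_volume(field: TensorVolume, path, component_order: str = "lower") -> None:
    if component_order not in _COMPONENT_ORDERS:
        raise VolumeFormatError(f"unknown component order {component_order!r}")
    perm = _COMPONENT_ORDERS[component_order]
    out = np.empty_like(field.components, dtype=np.float32)
    for canon_idx, file_idx in enumerate(perm):
        out[..., file_idx] = field.components[..., canon_idx]
    img = nib.Nifti1Image(out, field.grid.affine)
    img.header.set_zooms((*field.grid.spacing, 1.0))
    nib.save(img, str(path))


def check_grid_compatibility(volumes, tol: float = GRID_TOL) -> None:
    """Verify that every grid-bearing object shares one grid.

    Shapes must match exactly; spacings and affines to within ``tol``.
    Raises :class:`GridIncompatibilityError` naming the first offending pair.
    """
    volumes = list(volumes)
    if len(volumes) < 2:
        raise ValueError("need at least two volumes to compare")
    ref = volumes[0].grid
    for i, vol in enumerate(volumes[1:], start=1):
        g = vol.grid
        if g.shape != ref.shape:
            raise GridIncompatibilityError(
                f"volume 0 and volume {i} differ in shape: {ref.shape} vs {g.shape}"
            )
        if not np.allclose(g.spacing, ref.spacing, rtol=0.0, atol=tol):
            raise GridIncompatibilityError(
                f"volume 0 and volume {i} differ in spacing: {ref.spacing} vs {g.spacing}"
            )
        if not np.allclose(g.affine, ref.affine, rtol=0.0, atol=tol):
            raise GridIncompatibilityError(f"volume 0 and volume {i} differ in affine")
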