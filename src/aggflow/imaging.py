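"""Voxelized geometry processing for microscopy z-stacks.

Per-slice binary outlines of a wall-attached platelet aggregate are turned
into a smooth volumetric occupancy field, and fluorescence-intensity stacks
are co-registered with the uniform flow grid.  All geometry is handled as a
level set (signed distance to the aggregate surface) on a voxel lattice:
slice in-fill, surface smoothing and resampling are interpolation and
filtering operations on that representation, so no surface or tetrahedral
meshing is ever required.

Conventions: x is lateral, y is streamwise (flow along +y), z is vertical
with z = 0 at the collagen-coated bottom wall.  Scalars live at voxel/cell
centers, physical positions are ``origin + (i + 1/2) * h`` for flow-grid
cells and ``origin + i * spacing`` for image voxels (microscope slices are
point samples).  All lengths are in mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile
from scipy import ndimage

__all__ = [
    "ImageStack",
    "VoxelGrid",
    "stack_and_interpolate",
    "smooth_geometry",
    "resample_to_grid",
    "occupied_volume",
    "read_stack",
    "write_stack",
]

#: occupancy at or above this value classifies a cell as intrathrombus
OCCUPANCY_THRESHOLD = 0.5

_KINDS = ("intensity", "mask", "occupancy")


@dataclass(frozen=True)
class ImageStack:
    """A 3D scalar lattice with physical voxel spacing.

    ``data`` is indexed ``[ix, iy, iz]``; slice ``iz`` of a microscopy stack
    is the plane at height ``origin[2] + iz * spacing[2]``.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
    spacing : (dx, dy, dz) in mm, all positive.
    origin : physical position of voxel (0, 0, 0), mm.
    kind : ``"intensity"`` (arbitrary units), ``"mask"`` (binary {0,1}) or
        ``"occupancy"`` (soft indicator in [0, 1]).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    kind: str = "intensity"

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3 or min(data.shape) < 1:
            raise ValueError("stack must be 3D with at least one voxel per axis")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be three positive lengths")
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}")
        if self.kind == "mask":
            vals = np.unique(data)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError("mask stacks may contain only {0, 1}")
        if self.kind == "occupancy":
            if data.min() < 0 or data.max() > 1:
                raise ValueError("occupancy must lie in [0, 1]")
        object.__setattr__(self, "data", data)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical span covered by voxel centers along each axis (mm)."""
        return tuple((n - 1) * s for n, s in zip(self.data.shape, self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        n = self.data.shape[axis]
        return self.origin[axis] + np.arange(n) * self.spacing[axis]


@dataclass(frozen=True)
class VoxelGrid:
    """Uniform cell-centered grid of the flow domain.

    Cells are cubes of side ``h``; cell ``(i, j, k)`` is centered at
    ``origin + (i + 1/2, j + 1/2, k + 1/2) * h``.  ``shape = (nx, ny, nz)``
    with x lateral, y streamwise, z vertical; ``nz * h`` is the channel
    height.
    """

    shape: tuple[int, int, int]
    h: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ValueError("grid needs at least one cell per axis")
        if self.h <= 0:
            raise ValueError("cell size must be positive")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))

    @property
    def extents(self) -> tuple[float, float, float]:
        return tuple(n * self.h for n in self.shape)

    @property
    def cell_volume(self) -> float:
        return self.h ** 3

    def cell_centers(self, axis: int) -> np.ndarray:
        return self.origin[axis] + (np.arange(self.shape[axis]) + 0.5) * self.h

    @classmethod
    def for_channel(cls, height: float, nz: int, lx: float, ly: float) -> "VoxelGrid":
        """Grid whose cube size is set by the channel height resolution."""
        h = height / nz
        nx = int(round(lx / h))
        ny = int(round(ly / h))
        return cls((nx, ny, nz), h)


# ---------------------------------------------------------------------------
# level-set primitives


def _signed_distance_2d(mask: np.ndarray, dx: float, dy: float, cap: float) -> np.ndarray:
    """Signed distance of one slice: negative inside, boundary between pixels."""
    half = 0.5 * min(dx, dy)
    if not mask.any():
        return np.full(mask.shape, cap)
    if mask.all():
        return np.full(mask.shape, -cap)
    d_in = ndimage.distance_transform_edt(mask, sampling=(dx, dy))
    d_out = ndimage.distance_transform_edt(~mask, sampling=(dx, dy))
    sd = np.where(mask, -(d_in - half), d_out - half)
    return np.clip(sd, -cap, cap)


def _signed_distance_3d(mask: np.ndarray, spacing, cap: float) -> np.ndarray:
    half = 0.5 * min(spacing)
    if not mask.any():
        return np.full(mask.shape, cap)
    if mask.all():
        return np.full(mask.shape, -cap)
    d_in = ndimage.distance_transform_edt(mask, sampling=spacing)
    d_out = ndimage.distance_transform_edt(~mask, sampling=spacing)
    sd = np.where(mask, -(d_in - half), d_out - half)
    return np.clip(sd, -cap, cap)


def _occupancy_from_sd(sd: np.ndarray, href: float) -> np.ndarray:
    """Soft Heaviside: 1 deep inside, 0 outside, 1/2 on the surface."""
    return np.clip(0.5 - sd / href, 0.0, 1.0)


# ---------------------------------------------------------------------------
# operations


def stack_and_interpolate(masks: ImageStack, target_dz: float) -> ImageStack:
    """Shape-based in-fill between mask slices.

    Each slice is converted to a 2D signed-distance field; the fields are
    linearly interpolated along z at spacing ``target_dz`` and converted back
    to a soft occupancy (0.5 on the reconstructed surface).  Interpolating
    distances rather than raw binaries fills the gap between slices with the
    geometric blend of the neighbouring outlines.  A single slice is returned
    extruded unchanged; a stack with no foreground anywhere yields an
    all-zero occupancy.
    """
    if masks.kind != "mask":
        raise ValueError("stack_and_interpolate expects a binary mask stack")
    if target_dz <= 0:
        raise ValueError("target z-resolution must be positive")
    dx, dy, dz = masks.spacing
    nx, ny, nz = masks.shape
    fg = masks.data.astype(bool)
    cap = 2.0 * max(nx * dx, ny * dy, nz * dz)
    href = min(dx, dy, target_dz)

    sd = np.empty((nx, ny, nz))
    for k in range(nz):
        sd[:, :, k] = _signed_distance_2d(fg[:, :, k], dx, dy, cap)

    if nz == 1:
        occ = _occupancy_from_sd(sd, href)
        return ImageStack(occ, (dx, dy, target_dz), masks.origin, kind="occupancy")

    z_src = np.arange(nz) * dz
    span = z_src[-1]
    n_out = int(np.floor(span / target_dz + 1e-9)) + 1
    z_out = np.arange(n_out) * target_dz
    idx = np.clip(np.searchsorted(z_src, z_out, side="right") - 1, 0, nz - 2)
    t = (z_out - z_src[idx]) / dz
    sd_out = sd[:, :, idx] * (1.0 - t) + sd[:, :, idx + 1] * t
    occ = _occupancy_from_sd(sd_out, href)
    return ImageStack(occ, (dx, dy, target_dz), masks.origin, kind="occupancy")


def smooth_geometry(occupancy: ImageStack, length: float) -> ImageStack:
    """Gaussian smoothing of the aggregate surface at a physical length scale.

    The occupancy is re-expressed as a signed distance, filtered with an
    (anisotropy-aware) Gaussian of standard deviation ``length`` and
    converted back.  ``length = 0`` is the identity.  Features much smaller
    than ``length`` (e.g. single-voxel specks) vanish because their filtered
    distance field never re-crosses zero.
    """
    if length < 0:
        raise ValueError("smoothing length must be non-negative")
    if length == 0:
        return replace(occupancy, data=occupancy.data.copy())
    spacing = occupancy.spacing
    mask = occupancy.data >= OCCUPANCY_THRESHOLD
    cap = 2.0 * max(n * s for n, s in zip(occupancy.shape, spacing))
    sd = _signed_distance_3d(mask, spacing, cap)
    sigma = [length / s for s in spacing]
    sd = ndimage.gaussian_filter(sd, sigma=sigma, mode="nearest")
    occ = _occupancy_from_sd(sd, min(spacing))
    return ImageStack(occ, spacing, occupancy.origin, kind="occupancy")


def resample_to_grid(stack: ImageStack, grid: VoxelGrid) -> np.ndarray:
    """Trilinear interpolation of a stack at flow-grid cell centers.

    Positions outside the stack's physical extent evaluate to 0 (with a
    warning if there is no overlap at all).  Trilinear interpolation
    reproduces constants and affine fields exactly and never widens the
    value range.
    """
    coords = []
    overlap = True
    for axis in range(3):
        x = grid.cell_centers(axis)
        i = (x - stack.origin[axis]) / stack.spacing[axis]
        n = stack.shape[axis]
        if (i < -0.5).all() or (i > n - 0.5).all():
            overlap = False
        coords.append(i)
    if not overlap:
        warnings.warn("stack extent does not overlap the target grid; returning zeros")
        return np.zeros(grid.shape)
    ii, jj, kk = np.meshgrid(*coords, indexing="ij")
    return ndimage.map_coordinates(
        stack.data.astype(float), [ii, jj, kk], order=1, mode="constant", cval=0.0
    )


def occupied_volume(occupancy: ImageStack | np.ndarray, spacing=None, soft: bool = True) -> float:
    """Aggregate volume in mm³, from the soft occupancy sum (default) or the
    thresholded voxel count."""
    if isinstance(occupancy, ImageStack):
        data, spacing = occupancy.data, occupancy.spacing
    else:
        data = np.asarray(occupancy)
        if spacing is None:
            raise ValueError("spacing required for a bare array")
    voxel = float(np.prod(spacing))
    if soft:
        return float(data.sum()) * voxel
    return float((data >= OCCUPANCY_THRESHOLD).sum()) * voxel


# ---------------------------------------------------------------------------
# TIFF I/O (multi-page, one page per z-slice, z ascending)


def write_stack(stack: ImageStack, path) -> None:
    # pages are (row=y, col=x); stored z-major for microscope convention
    pages = np.transpose(stack.data, (2, 1, 0))
    if stack.kind == "mask":
        pages = pages.astype(np.uint8)
    else:
        pages = pages.astype(np.float32)
    tifffile.imwrite(path, pages, photometric="minisblack")


def read_stack(path, spacing, origin=(0.0, 0.0, 0.0), kind="intensity") -> ImageStack:
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    data = np.transpose(pages, (2, 1, 0))
    if kind == "mask":
        data = (data > 0).astype(np.uint8)
    return ImageStack(data, tuple(spacing), tuple(origin), kind=kind)
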