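"""3D map and mask handling: MRC I/O, soft masks, centres-of-mass, and the
ordered non-overlap decomposition of body masks.

Maps are cubic real-space grids with an even side length D; the box centre is
the voxel at index D/2 on every axis, and all rotations, centre-of-mass
coordinates and Fourier phase origins refer to that centre.  File I/O goes
through gemmi's CCP4/MRC reader and writer (mode 2, 32-bit float).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy import ndimage

__all__ = [
    "Volume",
    "SoftMask",
    "MaskDecomposition",
    "read_map",
    "write_map",
    "read_stack",
    "write_stack",
    "make_soft_mask",
    "centre_of_mass",
    "decompose_overlaps",
]


class MapFormatError(ValueError):
    """Raised for maps that are not cubic, even-sided, float-valued volumes."""


@dataclass
class Volume:
    """A cubic 3D scalar field with its voxel size in Angstrom/pixel."""

    data: np.ndarray
    voxel_size: float = 1.0

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or len(set(self.data.shape)) != 1:
            raise MapFormatError(f"expected a cubic 3D volume, got shape {self.data.shape}")
        if self.data.shape[0] % 2:
            raise MapFormatError("volume side length must be even")
        if not np.all(np.isfinite(self.data)):
            raise MapFormatError("volume contains non-finite values")

    @property
    def box_size(self) -> int:
        return self.data.shape[0]


@dataclass
class SoftMask:
    """A real-space weight map with values in [0, 1] and a smooth edge."""

    data: np.ndarray
    voxel_size: float = 1.0
    soft_edge_width: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.min() < -1e-6 or self.data.max() > 1 + 1e-6:
            raise ValueError("mask values must lie in [0, 1]")
        if self.data.max() <= 0:
            raise ValueError("mask has empty support")
        self.data = np.clip(self.data, 0.0, 1.0)


def _grid_to_array(m: gemmi.Ccp4Map) -> np.ndarray:
    return np.array(m.grid, copy=True)


def read_map(path) -> Volume:
    """Read a cubic MRC/CCP4 mode-2 map; voxel size from the header cell."""
    m = gemmi.read_ccp4_map(str(path))
    data = _grid_to_array(m)
    if data.ndim != 3 or len(set(data.shape)) != 1 or min(data.shape) < 2:
        raise MapFormatError(f"{path}: expected a cubic 3D map, got shape {data.shape}")
    voxel = float(m.grid.spacing[0])
    return Volume(data=data.astype(np.float64), voxel_size=voxel)


def _write_mrc(data: np.ndarray, voxel_size: float, path) -> None:
    data = np.ascontiguousarray(data, dtype=np.float32)
    grid = gemmi.FloatGrid(data)
    cell = [n * voxel_size for n in data.shape]
    grid.set_unit_cell(gemmi.UnitCell(*cell, 90.0, 90.0, 90.0))
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def write_map(volume: Volume | SoftMask, path) -> None:
    """Write a volume or mask as an MRC mode-2 map."""
    _write_mrc(volume.data, volume.voxel_size, path)


def read_stack(path) -> tuple[np.ndarray, float]:
    """Read a particle image stack (MRCS); returns (N, D, D) array + voxel size."""
    m = gemmi.read_ccp4_map(str(path))
    data = _grid_to_array(m)
    if data.ndim != 3 or data.shape[1] != data.shape[2]:
        raise MapFormatError(f"{path}: expected an (N, D, D) image stack, got {data.shape}")
    return data.astype(np.float64), float(m.grid.spacing[1])


def write_stack(images: np.ndarray, voxel_size: float, path) -> None:
    images = np.asarray(images)
    if images.ndim != 3:
        raise MapFormatError("image stack must be a 3D (N, D, D) array")
    _write_mrc(images, voxel_size, path)


def make_soft_mask(binary_mask: np.ndarray, extend_px: float, soft_edge_px: float,
                   voxel_size: float = 1.0) -> SoftMask:
    """Dilate a binary mask and add a raised-cosine soft edge.

    The support is extended by ``extend_px`` (Euclidean distance), after
    which values fall from 1 to 0 over ``soft_edge_px`` following
    ``0.5 * (1 + cos(pi * t))`` of the normalised distance t beyond the
    extended support.
    """
    binary = np.asarray(binary_mask) > 0.5
    if not binary.any():
        raise ValueError("cannot soften an empty mask")
    if extend_px < 0 or soft_edge_px < 0:
        raise ValueError("extend and soft-edge widths must be >= 0")
    if extend_px == 0 and soft_edge_px == 0:
        return SoftMask(binary.astype(float), voxel_size=voxel_size, soft_edge_width=0.0)
    dist = ndimage.distance_transform_edt(~binary)
    out = np.zeros(binary.shape, dtype=float)
    out[dist <= extend_px] = 1.0
    if soft_edge_px > 0:
        edge = (dist > extend_px) & (dist <= extend_px + soft_edge_px)
        t = (dist[edge] - extend_px) / soft_edge_px
        out[edge] = 0.5 * (1.0 + np.cos(np.pi * t))
    return SoftMask(out, voxel_size=voxel_size, soft_edge_width=float(soft_edge_px))


def centre_of_mass(mask: np.ndarray | SoftMask) -> np.ndarray:
    """Intensity-weighted mean coordinate, in voxels relative to the box centre."""
    data = mask.data if isinstance(mask, SoftMask) else np.asarray(mask, dtype=float)
    total = data.sum()
    if total <= 0:
        raise ValueError("mask has no positive weight")
    com = np.array(ndimage.center_of_mass(data))
    centre = np.array(data.shape) // 2
    return com - centre


@dataclass
class MaskDecomposition:
    """Ordered non-overlap decomposition of body masks.

    ``partials[b][b']`` is the part of mask b' to be subtracted when body b is
    the refinement target: mask b' multiplied by the complement of every mask
    of higher subtraction precedence (bodies earlier in file order, plus the
    target itself).  For binary masks, the target mask together with its
    partial masks tiles the union of all masks without double counting.
    """

    masks: list[np.ndarray]
    partials: dict[int, dict[int, np.ndarray]] = field(default_factory=dict)

    @property
    def n_bodies(self) -> int:
        return len(self.masks)

    def n_stored_transforms(self) -> int:
        """Number of distinct 3D transforms kept in memory (full + partials).

        A partial identical to its source mask needs no extra storage, so
        fully disjoint bodies cost B transforms and fully mutually
        overlapping bodies cost B^2.
        """
        count = self.n_bodies
        for b, parts in self.partials.items():
            for bp, pm in parts.items():
                if not np.allclose(pm, self.masks[bp]):
                    count += 1
        return count


def decompose_overlaps(ordered_masks: list[np.ndarray | SoftMask]) -> MaskDecomposition:
    """Compute the partial masks used for per-body partial signal subtraction.

    Bodies earlier in the list take subtraction precedence: when subtracting
    for target body b, body b' contributes only the part of its mask that
    does not overlap the target or any body listed before b'.  The rule is
    multiplicative in the mask values, which reduces to strict set
    subtraction for binary masks and extends smoothly to soft masks.
    """
    arrs = [m.data if isinstance(m, SoftMask) else np.asarray(m, dtype=float)
            for m in ordered_masks]
    if not arrs:
        raise ValueError("need at least one mask")
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValueError("all masks must share the same grid")
    decomp = MaskDecomposition(masks=arrs)
    B = len(arrs)
    for b in range(B):
        parts: dict[int, np.ndarray] = {}
        for bp in range(B):
            if bp == b:
                continue
            partial = arrs[bp].copy()
            partial *= 1.0 - arrs[b]
            for k in range(bp):
                if k != b:
                    partial *= 1.0 - arrs[k]
            parts[bp] = partial
        decomp.partials[b] = parts
    return decomp
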