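"""Reading, writing and reshaping density maps.

The grid convention used everywhere in the package is defined here:

* ``values[i, j, k]`` is the density at the **center** of voxel ``(i, j, k)``,
  with the first array axis being x (canonical axis order).
* the physical position (Å) of that center is ``origin + (i, j, k) * voxel_size``.
* trimming and resampling preserve physical coordinates; nothing downstream
  ever reasons about raw indices.

Only orthorhombic cells are supported — maps with non-90° cell angles are
rejected on read.  Negative densities are meaningful (they mark hydrophobic
regions by convention) and are preserved through every operation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import gemmi
import numpy as np
from scipy.interpolate import RegularGridInterpolator

__all__ = ["DensityMap", "read_map", "write_map", "trim_map", "resample_map"]


@dataclass
class DensityMap:
    """A 3-D scalar density field on a regular orthorhombic grid.

    Attributes
    ----------
    values : ndarray, shape (nx, ny, nz)
        Density values; arbitrary units, may be negative.
    voxel_size : ndarray, shape (3,)
        Grid spacing per axis in Å (anisotropic spacing allowed).
    origin : ndarray, shape (3,)
        Physical coordinate (Å) of the center of voxel (0, 0, 0).
    label : str
        Free-text role tag ("experimental", "simulated", "half1", ...).
    """

    values: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=np.float64), (3,)
        ).copy()
        self.origin = np.broadcast_to(
            np.asarray(self.origin, dtype=np.float64), (3,)
        ).copy()
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3-D, got shape {self.values.shape}")
        if any(d < 2 for d in self.values.shape):
            raise ValueError(f"all dims must be >= 2, got {self.values.shape}")
        if not np.all(self.voxel_size > 0):
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("map contains non-finite voxel values")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis physical coordinates (Å) of voxel centers."""
        return tuple(
            self.origin[a] + np.arange(self.dims[a]) * self.voxel_size[a]
            for a in range(3)
        )

    def empty_like(self, label: str = "") -> "DensityMap":
        """A zero-valued map sharing this map's grid spec."""
        return DensityMap(
            np.zeros(self.dims), self.voxel_size.copy(), self.origin.copy(), label
        )

    def same_grid(self, other: "DensityMap", tol: float = 1e-6) -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.voxel_size, other.voxel_size, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def copy(self) -> "DensityMap":
        return replace(self, values=self.values.copy())


def require_same_grid(a: DensityMap, b: DensityMap) -> None:
    if not a.same_grid(b):
        raise ValueError(
            "grid mismatch: "
            f"dims {a.dims} vs {b.dims}, voxel {a.voxel_size} vs {b.voxel_size}, "
            f"origin {a.origin} vs {b.origin}"
        )


def read_map(path, label: str = "") -> DensityMap:
    """Read an MRC/CCP4 volume into canonical (x-fastest) axis order.

    The file's MAPC/MAPR/MAPS axis permutation is undone on read, so the
    returned array always has axis 0 = x.  Spacing comes from the cell and
    sampling header fields; the origin from the ORIGIN words if set, else
    from NCSTART/NRSTART/NSSTART.
    """
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot read {path} as an MRC/CCP4 volume: {exc}") from exc

    mode = ccp4.header_i32(4)
    if mode not in (0, 1, 2, 6, 12):
        raise ValueError(f"unsupported MODE={mode} in header (expected a volume mode)")

    cell = ccp4.grid.unit_cell
    if not (
        abs(cell.alpha - 90) < 1e-3
        and abs(cell.beta - 90) < 1e-3
        and abs(cell.gamma - 90) < 1e-3
    ):
        raise ValueError(
            "non-orthorhombic cell rejected: "
            f"CELLB angles ({cell.alpha}, {cell.beta}, {cell.gamma}) != 90"
        )

    # Canonicalize axis order in memory; header fields are updated by gemmi.
    ccp4.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    values = np.array(ccp4.grid, copy=True, dtype=np.float64)
    if not np.all(np.isfinite(values)):
        raise ValueError("map data contains NaN/Inf voxels (corrupt DATA block)")

    mx, my, mz = (ccp4.header_i32(w) for w in (8, 9, 10))
    if mx <= 0 or my <= 0 or mz <= 0:
        raise ValueError(f"invalid sampling MX/MY/MZ = ({mx}, {my}, {mz}) in header")
    voxel = np.array([cell.a / mx, cell.b / my, cell.c / mz])

    origin_words = np.array([ccp4.header_float(w) for w in (50, 51, 52)])
    if np.any(origin_words != 0.0):
        origin = origin_words
    else:
        nstart = np.array([ccp4.header_i32(w) for w in (5, 6, 7)], dtype=float)
        origin = nstart * voxel
    return DensityMap(values, voxel, origin, label=label)


def write_map(dmap: DensityMap, path) -> None:
    """Write a map as a mode-2 (32-bit float) MRC/CCP4 file, canonical order."""
    nx, ny, nz = dmap.dims
    grid = gemmi.FloatGrid(nx, ny, nz)
    np.asarray(grid)[...] = dmap.values.astype(np.float32)
    grid.unit_cell = gemmi.UnitCell(
        nx * dmap.voxel_size[0], ny * dmap.voxel_size[1], nz * dmap.voxel_size[2],
        90.0, 90.0, 90.0,
    )
    grid.spacegroup = gemmi.SpaceGroup("P1")
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    for w, v in zip((50, 51, 52), dmap.origin):
        ccp4.set_header_float(w, float(v))
    ccp4.write_ccp4_map(str(path))


def trim_map(dmap: DensityMap, lo, hi) -> DensityMap:
    """Extract the half-open voxel box [lo, hi) preserving physical coordinates."""
    lo = np.asarray(lo, dtype=int)
    hi = np.asarray(hi, dtype=int)
    dims = np.array(dmap.dims)
    if np.any(lo < 0) or np.any(hi > dims):
        raise ValueError(f"trim box [{lo}, {hi}) outside map dims {tuple(dims)}")
    if np.any(hi - lo < 2):
        raise ValueError(f"trim box [{lo}, {hi}) too small (need >= 2 voxels per axis)")
    values = dmap.values[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]].copy()
    origin = dmap.origin + lo * dmap.voxel_size
    return DensityMap(values, dmap.voxel_size.copy(), origin, label=dmap.label)


def resample_map(dmap: DensityMap, new_dims) -> DensityMap:
    """Trilinear resampling onto ``new_dims`` voxels spanning the same physical box.

    The physical extent (dims·voxel_size per axis) is preserved exactly; the
    new voxel centers are placed symmetrically inside it.  Values are clamped
    to the old voxel-center range at the edges, so a constant map stays
    constant.
    """
    new_dims = tuple(int(d) for d in np.broadcast_to(np.asarray(new_dims), (3,)))
    if any(d < 2 for d in new_dims):
        raise ValueError(f"new_dims must be >= 2 per axis, got {new_dims}")
    if new_dims == dmap.dims:
        return dmap.copy()
    old_dims = np.array(dmap.dims, dtype=float)
    extent = old_dims * dmap.voxel_size
    new_voxel = extent / np.array(new_dims, dtype=float)
    box_min = dmap.origin - 0.5 * dmap.voxel_size
    new_origin = box_min + 0.5 * new_voxel

    old_axes = dmap.axes()
    interp = RegularGridInterpolator(
        old_axes, dmap.values, method="linear", bounds_error=False, fill_value=None
    )
    new_axes = [
        np.clip(
            new_origin[a] + np.arange(new_dims[a]) * new_voxel[a],
            old_axes[a][0],
            old_axes[a][-1],
        )
        for a in range(3)
    ]
    pts = np.stack(np.meshgrid(*new_axes, indexing="ij"), axis=-1)
    values = interp(pts)
    return DensityMap(values, new_voxel, new_origin, label=dmap.label)
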