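"""Volumetric data model: grids, statistic maps, binary masks, NIfTI I/O.

Everything downstream (hypothesis spaces, fROI growth, whole-brain
clustering) works on these three containers.  Voxel indices are 0-based;
world coordinates are mm in the affine's frame (MNI by convention).
Distances are always center-to-center Euclidean mm, never voxel counts,
so anisotropic voxels are handled correctly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "VolumeGrid",
    "ScalarVolume",
    "BinaryMask",
    "connected_components",
    "connectivity_structure",
    "read_volume",
    "write_volume",
]

#: allowed 3-D neighbourhoods: faces / faces+edges / faces+edges+corners
CONNECTIVITIES = (6, 18, 26)


@dataclass(frozen=True)
class VolumeGrid:
    """A 3-D sampling grid: voxel dimensions plus a voxel->world affine."""

    dims: tuple[int, int, int]
    affine: np.ndarray  # 4x4, voxel index -> world mm

    def __post_init__(self):
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        dims = tuple(int(d) for d in self.dims)
        if len(dims) != 3 or any(d < 1 for d in dims):
            raise ValueError(f"dims must be three integers >= 1, got {self.dims}")
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "affine", affine)

    @property
    def voxel_size(self) -> np.ndarray:
        """Edge lengths in mm (column norms of the linear part)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, ijk) -> np.ndarray:
        """Map voxel indices (..., 3) to world mm coordinates."""
        return nib.affines.apply_affine(self.affine, np.asarray(ijk, dtype=float))

    def world_to_voxel(self, xyz) -> np.ndarray:
        """Map world mm coordinates to (rounded) integer voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        if not np.all(np.isfinite(xyz)):
            raise ValueError("world coordinates must be finite")
        inv = np.linalg.inv(self.affine)
        return np.rint(nib.affines.apply_affine(inv, xyz)).astype(int)

    def world_to_voxel_continuous(self, xyz) -> np.ndarray:
        inv = np.linalg.inv(self.affine)
        return nib.affines.apply_affine(inv, np.asarray(xyz, dtype=float))

    def contains(self, ijk) -> bool:
        ijk = np.asarray(ijk)
        return bool(np.all(ijk >= 0) and np.all(ijk < np.asarray(self.dims)))

    def all_world_coords(self) -> np.ndarray:
        """World coordinates of every voxel center, shape dims + (3,)."""
        idx = np.indices(self.dims).reshape(3, -1).T
        return self.voxel_to_world(idx).reshape(self.dims + (3,))

    def matches(self, other: "VolumeGrid", atol: float = 1e-6) -> bool:
        return self.dims == other.dims and np.allclose(
            self.affine, other.affine, atol=atol
        )


def mni_grid(dims=(40, 48, 40), voxel_mm=4.0) -> VolumeGrid:
    """Default desk-scale grid: 4 mm isotropic spanning roughly MNI
    +/-80 / +/-96 / +/-80, large enough to hold all seven region centers."""
    dims = tuple(int(d) for d in dims)
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    # anchor voxel d//2 exactly at 0 mm so the origin (and, on 1/2/4 mm
    # grids, the integer-mm region centers) fall on voxel centers
    affine[:3, 3] = [-voxel_mm * (d // 2) for d in dims]
    return VolumeGrid(dims, affine)


@dataclass
class ScalarVolume:
    """A per-voxel statistic map (e.g. a contrast T-map) on a grid.

    ``df`` carries the degrees of freedom of the statistic so that
    p-value thresholds can be converted to statistic cutoffs.
    """

    grid: VolumeGrid
    values: np.ndarray
    df: int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.dims:
            raise ValueError(
                f"values shape {self.values.shape} != grid dims {self.grid.dims}"
            )
        if self.df is not None and self.df < 1:
            raise ValueError("df must be >= 1 when present")


@dataclass
class BinaryMask:
    """A set of voxels on a grid, stored as a boolean array."""

    grid: VolumeGrid
    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.shape != self.grid.dims:
            raise ValueError(
                f"mask shape {self.data.shape} != grid dims {self.grid.dims}"
            )

    @classmethod
    def from_indices(cls, grid: VolumeGrid, indices) -> "BinaryMask":
        data = np.zeros(grid.dims, dtype=bool)
        indices = np.asarray(list(indices), dtype=int)
        if indices.size:
            if np.any(indices < 0) or np.any(indices >= np.asarray(grid.dims)):
                raise ValueError("mask member index outside grid dims")
            data[tuple(indices.T)] = True
        return cls(grid, data)

    @property
    def members(self) -> np.ndarray:
        """Member voxel indices as an (n, 3) integer array."""
        return np.argwhere(self.data)

    @property
    def size(self) -> int:
        return int(self.data.sum())


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3x3x3 binary structuring element for 6/18/26-neighbourhoods."""
    if connectivity not in CONNECTIVITIES:
        raise ValueError(f"connectivity must be one of {CONNECTIVITIES}")
    order = {6: 1, 18: 2, 26: 3}[connectivity]
    return ndimage.generate_binary_structure(3, order)


def connected_components(mask: BinaryMask, connectivity: int = 26) -> list[np.ndarray]:
    """Partition mask members into maximal connected components.

    Returns a list of (n_i, 3) index arrays, one per component, sorted by
    descending size then by first linear index for determinism.  An empty
    mask yields an empty list.
    """
    structure = connectivity_structure(connectivity)
    labels, n = ndimage.label(mask.data, structure=structure)
    comps = []
    for lab in range(1, n + 1):
        comps.append(np.argwhere(labels == lab))
    linear = [np.ravel_multi_index(tuple(c.T), mask.grid.dims).min() for c in comps]
    comps.sort(key=lambda c: (-len(c),
                              np.ravel_multi_index(tuple(c.T), mask.grid.dims).min()))
    return comps


def label_components(data: np.ndarray, connectivity: int = 26):
    """scipy-style labeling of a boolean array; returns (labels, n)."""
    return ndimage.label(np.asarray(data, dtype=bool),
                         structure=connectivity_structure(connectivity))


def read_volume(path, as_mask: bool = False, df: int | None = None):
    """Read a NIfTI-1/2 file as a ScalarVolume (default) or BinaryMask."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"volume file not found: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise IOError(f"could not read NIfTI file {path}: {exc}") from exc
    data = np.asarray(img.get_fdata())
    grid = VolumeGrid(data.shape, img.affine)
    if as_mask:
        return BinaryMask(grid, data > 0.5)
    if df is None:
        df_hdr = img.header.get("descrip")
        df = _df_from_descrip(df_hdr)
    return ScalarVolume(grid, data, df=df)


def write_volume(volume, path) -> None:
    """Write a ScalarVolume (float32) or BinaryMask (uint8 0/1) as NIfTI."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(volume, BinaryMask):
        img = nib.Nifti1Image(volume.data.astype(np.uint8), volume.grid.affine)
    elif isinstance(volume, ScalarVolume):
        dtype = np.float64 if volume.values.dtype == np.float64 else np.float32
        img = nib.Nifti1Image(volume.values.astype(dtype), volume.grid.affine)
        if volume.df is not None:
            img.header["descrip"] = f"df={int(volume.df)}".encode()
    else:
        raise TypeError(f"cannot write object of type {type(volume)}")
    nib.save(img, str(path))


def _df_from_descrip(descrip) -> int | None:
    try:
        text = bytes(descrip).decode(errors="ignore")
    except Exception:
        return None
    if text.startswith("df="):
        try:
            return int(text.split("=", 1)[1].split()[0].rstrip("\x00"))
        except ValueError:
            return None
    return None
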