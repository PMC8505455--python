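"""Voxel grid geometry with anatomical lobe labels.

The analysis operates on a regular 3-D voxel grid in which every voxel
carries exactly one lobe label from the four large territories used for
the per-lobe factor analyses: frontal, parietal, temporal-fusiform and
occipital. Voxels are enumerated in C order of their (i, j, k) grid index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LOBES: tuple[str, ...] = ("frontal", "parietal", "temporal-fusiform", "occipital")


@dataclass(frozen=True)
class BrainGeometry:
    """A regular voxel grid with physical voxel size and lobe labels.

    Parameters
    ----------
    grid_shape
        Number of voxels along each axis (nx, ny, nz).
    voxel_size_mm
        Physical edge lengths of one voxel in millimetres.
    lobe_codes
        Flat array (length ``n_voxels``) of indices into :data:`LOBES`.
    origin_mm
        Physical coordinate of the centre of voxel (0, 0, 0).
    """

    grid_shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    lobe_codes: np.ndarray
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    lobe_names: tuple[str, ...] = LOBES

    def __post_init__(self) -> None:
        codes = np.asarray(self.lobe_codes, dtype=np.int8)
        object.__setattr__(self, "lobe_codes", codes)
        if codes.shape != (self.n_voxels,):
            raise ValueError(
                f"lobe_codes must have one entry per voxel "
                f"({self.n_voxels}), got shape {codes.shape}"
            )
        if codes.min() < 0 or codes.max() >= len(self.lobe_names):
            raise ValueError("lobe_codes reference unknown lobes")

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.grid_shape
        return int(nx) * int(ny) * int(nz)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    @property
    def affine(self) -> np.ndarray:
        """4x4 index->mm mapping (scaling plus the stated origin)."""
        a = np.eye(4)
        a[:3, :3] = np.diag(self.voxel_size_mm)
        a[:3, 3] = self.origin_mm
        return a

    def index_to_grid(self, voxel: np.ndarray | int) -> np.ndarray:
        """Flat voxel index -> (i, j, k) grid coordinates."""
        ijk = np.unravel_index(np.asarray(voxel), self.grid_shape)
        return np.stack(ijk, axis=-1)

    def grid_to_index(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.asarray(ijk)
        return np.ravel_multi_index(tuple(ijk.T), self.grid_shape)

    def voxel_mm(self, voxel: np.ndarray | int) -> np.ndarray:
        """Physical (mm) centre coordinate of a voxel."""
        ijk = self.index_to_grid(voxel).astype(float)
        return ijk * np.asarray(self.voxel_size_mm) + np.asarray(self.origin_mm)

    def nearest_voxel(self, mm: np.ndarray) -> int:
        """Flat index of the grid voxel whose centre is nearest to ``mm``."""
        ijk = (np.asarray(mm, float) - np.asarray(self.origin_mm)) / np.asarray(
            self.voxel_size_mm
        )
        ijk = np.clip(
            np.round(ijk).astype(int), 0, np.asarray(self.grid_shape) - 1
        )
        return int(self.grid_to_index(ijk))

    def lobe_mask(self, lobe: str) -> np.ndarray:
        """Boolean mask over flat voxel indices for one lobe."""
        try:
            code = self.lobe_names.index(lobe)
        except ValueError as exc:
            raise ValueError(f"unknown lobe {lobe!r}") from exc
        return self.lobe_codes == code

    def lobe_of(self, voxel: int) -> str:
        return self.lobe_names[int(self.lobe_codes[voxel])]


def make_geometry(
    grid_shape: tuple[int, int, int],
    voxel_size_mm: tuple[float, float, float] = (3.125, 3.125, 6.0),
    lobe_partition_plan: str | np.ndarray = "octant",
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> BrainGeometry:
    """Build a labelled voxel grid.

    The default ``"octant"`` plan splits the grid at the midpoint of each
    axis; the four x-y quadrants (each spanning the full z extent, i.e. two
    octants) become the four lobes. An explicit per-voxel label array (of
    lobe names or codes) may be passed instead.

    Raises
    ------
    ValueError
        If any lobe of the partition is empty (the offending lobe is named).
    """
    grid_shape = tuple(int(n) for n in grid_shape)
    if any(n <= 0 for n in grid_shape):
        raise ValueError(f"grid_shape must be positive, got {grid_shape}")
    nx, ny, nz = grid_shape
    if isinstance(lobe_partition_plan, str):
        if lobe_partition_plan != "octant":
            raise ValueError(f"unknown partition plan {lobe_partition_plan!r}")
        ii, jj, _ = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        quadrant = (ii >= nx // 2) * 2 + (jj >= ny // 2)
        codes = quadrant.ravel().astype(np.int8)
    else:
        plan = np.asarray(lobe_partition_plan).ravel()
        if plan.dtype.kind in "US O":
            codes = np.array([LOBES.index(str(x)) for x in plan], dtype=np.int8)
        else:
            codes = plan.astype(np.int8)
    geom = BrainGeometry(grid_shape, tuple(map(float, voxel_size_mm)), codes, origin_mm)
    for lobe in geom.lobe_names:
        if not geom.lobe_mask(lobe).any():
            raise ValueError(f"lobe {lobe!r} is empty under the given partition")
    return geom


def face_neighbors(geom: BrainGeometry, voxel: int) -> list[int]:
    """Flat indices of the (up to six) face-adjacent neighbours of a voxel."""
    ijk = geom.index_to_grid(voxel)
    out = []
    for axis in range(3):
        for step in (-1, 1):
            n = ijk.copy()
            n[axis] += step
            if 0 <= n[axis] < geom.grid_shape[axis]:
                out.append(int(geom.grid_to_index(n)))
    return out
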