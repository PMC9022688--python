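"""Shared in-memory image containers and mask helpers.

Volumes are plain numpy arrays indexed ``[x, y, z]`` (plus time for 4D),
with a NIfTI affine mapping 0-based voxel indices to world millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


def default_affine(voxel_size: float = 1.0) -> np.ndarray:
    """Diagonal affine ``diag(voxel_size, voxel_size, voxel_size, 1)``."""
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = float(voxel_size)
    return aff


@dataclass
class Image4D:
    """A single subject's functional series.

    Parameters
    ----------
    data : ndarray, shape (X, Y, Z, T)
        BOLD-like signal.
    affine : ndarray, shape (4, 4)
        Voxel-to-world transform.
    tr : float
        Repetition time in seconds.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=default_affine)
    tr: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"Image4D requires 4D data, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]


def ellipsoid_mask(grid_shape: tuple[int, int, int], extent: float = 0.9) -> np.ndarray:
    """Centered ellipsoidal brain mask covering ``extent`` of each axis.

    The semi-axes are ``extent/2`` of the grid extent, so the default
    ellipsoid spans 90% of the volume in every direction.
    """
    shape = tuple(int(s) for s in grid_shape)
    center = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    semi = np.asarray(shape, dtype=float) * extent / 2.0
    coords = np.indices(shape, dtype=float)
    dist2 = sum(((coords[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    return dist2 <= 1.0


def mask_edge_shell(mask: np.ndarray) -> np.ndarray:
    """Outermost one-voxel shell of a binary mask."""
    eroded = ndimage.binary_erosion(mask)
    return mask & ~eroded
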