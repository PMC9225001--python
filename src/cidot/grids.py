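"""Regular voxel grids for image-space data.

All image-space arrays in this package are stored flattened in C order over a
:class:`Grid`; ``Grid.coords()`` gives the voxel centers in mm so masks and
ROIs can be built geometrically.  The convention throughout is that the optode
plane is ``z = 0`` with tissue at ``z < 0``, ``x`` increasing to the subject's
right (so ``x < 0`` is the left hemisphere) and ``y`` increasing anteriorly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Grid:
    """Regular isotropic voxel grid.

    Parameters
    ----------
    origin : tuple of float
        Center of voxel (0, 0, 0) in mm.
    spacing : float
        Isotropic voxel edge length in mm (default pipelines use 3 mm).
    shape : tuple of int
        Number of voxels along (x, y, z).
    """

    origin: tuple[float, float, float]
    spacing: float
    shape: tuple[int, int, int]

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def coords(self) -> np.ndarray:
        """(n_voxels, 3) array of voxel-center coordinates in mm, C order."""
        ax = [self.origin[i] + self.spacing * np.arange(self.shape[i]) for i in range(3)]
        xx, yy, zz = np.meshgrid(*ax, indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])

    def mask_sphere(self, center, radius: float) -> np.ndarray:
        """Boolean mask (flattened) of voxels within ``radius`` mm of ``center``."""
        d = self.coords() - np.asarray(center, float)
        return (d * d).sum(axis=1) <= radius * radius

    def mask_box(self, lo, hi) -> np.ndarray:
        """Boolean mask of voxels with lo <= coord <= hi componentwise."""
        c = self.coords()
        lo = np.asarray(lo, float)
        hi = np.asarray(hi, float)
        return np.all((c >= lo) & (c <= hi), axis=1)

    def mask_hemisphere(self, side: str) -> np.ndarray:
        """Voxels strictly on one side of the midline plane x = 0."""
        x = self.coords()[:, 0]
        if side == "left":
            return x < 0
        if side == "right":
            return x > 0
        raise ValueError(f"unknown hemisphere {side!r}")

    def to_volume(self, flat: np.ndarray) -> np.ndarray:
        """Reshape a flattened voxel array (possibly with trailing axes) to 3-D."""
        return np.asarray(flat).reshape(self.shape + np.asarray(flat).shape[1:])

    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> mm affine (for NIfTI export)."""
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.spacing
        aff[:3, 3] = self.origin
        return aff
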