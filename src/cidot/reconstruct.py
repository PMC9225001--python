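"""Tomographic image reconstruction.

Inverts the sensitivity model with Tikhonov regularization plus spatially
variant (depth-compensating) preconditioning, converts the two-wavelength
absorption images to hemoglobin concentration changes by solving the 2x2
extinction-coefficient system, and resamples images between grids.

The inverse operator for a retained-measurement submatrix ``A`` is::

    L   = 1 / sqrt(diag(A^T A) + lambda2 * max(diag(A^T A)))
    A~  = A diag(L)
    W   = diag(L) A~^T (A~ A~^T + lambda1 * eigmax(A~ A~^T) I)^-1

so voxel columns are first rescaled by their total sensitivity (reducing the
superficial bias of unweighted minimum-norm solutions) and the ridge level is
a fraction of the largest spectral value of the preconditioned system.
Operators are cached per retained-channel set, so rerunning with different
channel-dropout patterns only pays the factorization cost once per pattern.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import Grid
from .preprocess import ODSeries
from .synthetic_data import OpticsConstants, SensitivityModel


class ReconstructionError(ValueError):
    pass


@dataclass
class MuaSeries:
    """Absorption-change images (voxels x time, mm^-1) per wavelength."""

    dmua: tuple[np.ndarray, np.ndarray]
    grid: Grid
    rate_hz: float


@dataclass
class HbImageSeries:
    """Hemoglobin concentration-change images (voxels x time, uM)."""

    hbo: np.ndarray
    hbr: np.ndarray
    grid: Grid
    rate_hz: float

    @property
    def hbt(self) -> np.ndarray:
        return self.hbo + self.hbr

    def chromophore(self, name: str) -> np.ndarray:
        return {"hbo": self.hbo, "hbr": self.hbr, "hbt": self.hbt}[name]


def invert_sensitivity(A: np.ndarray, lambda1: float, lambda2: float) -> np.ndarray:
    """Regularized pseudo-inverse (voxels x measurements) of one sensitivity
    submatrix; ``lambda1``/``lambda2`` are fractions of the respective
    spectral maxima and must be non-negative (zero disables each term)."""
    A = np.asarray(A, float)
    if A.ndim != 2 or A.shape[0] < 1:
        raise ReconstructionError("sensitivity matrix needs at least one measurement row")
    if lambda1 < 0 or lambda2 < 0:
        raise ReconstructionError("regularization parameters must be non-negative")
    c = (A * A).sum(axis=0)
    cmax = c.max()
    if cmax <= 0:
        raise ReconstructionError("sensitivity matrix is identically zero")
    denom = c + lambda2 * cmax
    L = np.where(denom > 0, 1.0 / np.sqrt(np.where(denom > 0, denom, 1.0)), 0.0)
    At = A * L[None, :]
    M = At @ At.T
    if lambda1 > 0:
        M = M + lambda1 * np.linalg.eigvalsh(M)[-1] * np.eye(M.shape[0])
    W = np.linalg.solve(M, At).T * L[:, None]
    return W


class TikhonovInverter:
    """Caches inverse operators per (wavelength, retained-row set)."""

    def __init__(self, sens: SensitivityModel, lambda1: float, lambda2: float,
                 cache_size: int = 8):
        self.sens = sens
        self.lambda1 = float(lambda1)
        self.lambda2 = float(lambda2)
        self._cache: OrderedDict = OrderedDict()
        self.cache_size = cache_size

    def operator(self, rows: np.ndarray, collapse: np.ndarray | None = None) -> np.ndarray:
        """Inverse operator for measurement ``rows`` of the full matrix.

        ``collapse`` (n_voxels weight vector, e.g. an ROI mean) returns the
        exact voxel-collapsed operator ``collapse @ W`` instead, which is what
        the permutation dropout study uses.
        """
        rows = np.asarray(rows, int)
        key = (rows.tobytes(),
               None if collapse is None else collapse.tobytes())
        if key in self._cache:
            self._cache.move_to_end(key)
            return self._cache[key]
        W = invert_sensitivity(self.sens.A[rows], self.lambda1, self.lambda2)
        out = W if collapse is None else collapse @ W
        self._cache[key] = out
        if len(self._cache) > self.cache_size:
            self._cache.popitem(last=False)
        return out


def reconstruct_mua(od: ODSeries, sens: SensitivityModel,
                    inverter: TikhonovInverter | None = None,
                    lambda1: float = 0.01, lambda2: float = 0.1) -> MuaSeries:
    """Per wavelength, apply the inverse operator to the retained OD rows."""
    if od.data.shape[0] != sens.A.shape[0]:
        raise ReconstructionError("OD rows do not align with sensitivity measurements")
    if inverter is None:
        inverter = TikhonovInverter(sens, lambda1, lambda2)
    layout = sens.layout
    images = []
    for wl in range(2):
        rows = layout.wl_rows(wl)
        rows = rows[od.retained[rows]]
        if len(rows) == 0:
            raise ReconstructionError(f"no retained measurement at wavelength index {wl}")
        W = inverter.operator(rows)
        images.append(W @ od.data[rows])
    return MuaSeries((images[0], images[1]), sens.grid, od.rate_hz)


def spectroscopy(mua: MuaSeries, optics: OpticsConstants) -> HbImageSeries:
    """Solve E (dHbO, dHbR)^T = (dmua_750, dmua_850)^T per voxel and time."""
    E = optics.extinction_uM
    if abs(np.linalg.det(E)) < 1e-300:
        raise ReconstructionError("singular extinction matrix")
    Einv = np.linalg.inv(E)
    hbo = Einv[0, 0] * mua.dmua[0] + Einv[0, 1] * mua.dmua[1]
    hbr = Einv[1, 0] * mua.dmua[0] + Einv[1, 1] * mua.dmua[1]
    return HbImageSeries(hbo, hbr, mua.grid, mua.rate_hz)


def resample_to_atlas(img: HbImageSeries, affine: np.ndarray,
                      target_grid: Grid | None = None) -> HbImageSeries:
    """Trilinear resampling of the image series under a 3x4 (or 4x4) affine
    mapping target-grid mm coordinates to source-grid mm coordinates.

    The identity affine (with the same target grid) returns the input
    unchanged.  Non-invertible affines are rejected.
    """
    aff = np.asarray(affine, float)
    if aff.shape == (3, 4):
        aff = np.vstack([aff, [0, 0, 0, 1]])
    if aff.shape != (4, 4):
        raise ReconstructionError("affine must be 3x4 or 4x4")
    if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
        raise ReconstructionError("non-invertible affine")
    if target_grid is None:
        target_grid = img.grid
    if target_grid == img.grid and np.allclose(aff, np.eye(4)):
        return img

    src = img.grid
    # target voxel index -> target mm -> (affine) source mm -> source index
    tgt_mm = np.eye(4)
    tgt_mm[:3, :3] *= target_grid.spacing
    tgt_mm[:3, 3] = target_grid.origin
    src_mm_inv = np.eye(4)
    src_mm_inv[:3, :3] /= src.spacing
    src_mm_inv[:3, 3] = -np.asarray(src.origin) / src.spacing
    full = src_mm_inv @ aff @ tgt_mm

    def _resample(flat):
        vols = flat.reshape(src.shape + (-1,))
        n_t = vols.shape[-1]
        out = np.empty(target_grid.shape + (n_t,))
        for t in range(n_t):
            out[..., t] = ndimage.affine_transform(
                vols[..., t], full[:3, :3], full[:3, 3],
                output_shape=target_grid.shape, order=1, mode="nearest")
        return out.reshape(target_grid.n_voxels, n_t)

    return HbImageSeries(_resample(img.hbo), _resample(img.hbr),
                         target_grid, img.rate_hz)
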