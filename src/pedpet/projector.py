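"""Parallel-beam system model: scanner geometry, Siddon projector, TOF weights.

The scanner is modelled as a 2-D parallel-beam tomograph: lines of response
(LORs) are indexed by (angle, radial bin).  The projector computes exact
ray/pixel intersection lengths (Siddon tracing) and is materialized as a
sparse matrix, so the back projector is its exact transpose — adjointness
holds to machine precision by construction.

Time-of-flight is modelled by a Gaussian kernel along each LOR whose spatial
FWHM is c*dt/2 for a coincidence timing resolution dt; the kernel is
integrated over discrete TOF bins.  The TOF system matrix carries one row
per (LOR, TOF bin).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import sparse
from scipy.special import erf

__all__ = [
    "SPEED_OF_LIGHT_MM_PER_PS",
    "FWHM_TO_SIGMA",
    "ScannerGeometry",
    "default_geometry",
    "SystemMatrix",
    "get_system_matrix",
    "tof_spatial_fwhm",
]

#: Speed of light in mm per picosecond.
SPEED_OF_LIGHT_MM_PER_PS = 0.299792458

#: FWHM = FWHM_TO_SIGMA * sigma for a Gaussian.
FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


def tof_spatial_fwhm(tof_resolution_ps: float) -> float:
    """Spatial localisation FWHM (mm) along the LOR: c * dt / 2."""
    return SPEED_OF_LIGHT_MM_PER_PS * tof_resolution_ps / 2.0


@dataclass(frozen=True)
class ScannerGeometry:
    """Parallel-beam LOR binning plus TOF timing parameters.

    Parameters
    ----------
    n_angles : number of projection angles over 180 degrees.
    n_radial_bins : radial bins per angle.
    radial_bin_size : radial bin width, mm.
    tof_resolution : coincidence timing resolution FWHM, ps (555 ps default,
        matching a modern clinical TOF PET/CT system).
    tof_bin_size : TOF bin width, ps; must not exceed half the resolution.
    """

    n_angles: int = 56
    n_radial_bins: int = 100
    radial_bin_size: float = 4.073
    tof_resolution: float = 555.0
    tof_bin_size: float = 200.0

    def __post_init__(self) -> None:
        if self.n_angles < 1 or self.n_radial_bins < 1:
            raise ValueError("n_angles and n_radial_bins must be positive")
        if self.tof_bin_size > self.tof_resolution / 2.0 + 1e-9:
            raise ValueError("tof_bin_size must be <= tof_resolution / 2")

    @property
    def fov_diameter(self) -> float:
        """Transaxial field of view spanned by the radial bins, mm."""
        return self.n_radial_bins * self.radial_bin_size

    @property
    def tof_sigma_mm(self) -> float:
        return tof_spatial_fwhm(self.tof_resolution) / FWHM_TO_SIGMA

    @property
    def tof_bin_mm(self) -> float:
        """Spatial extent of one TOF bin along the LOR, mm."""
        return SPEED_OF_LIGHT_MM_PER_PS * self.tof_bin_size / 2.0

    @property
    def tof_half_bins(self) -> int:
        """Signed TOF bin indices run in [-tof_half_bins, +tof_half_bins]."""
        reach = self.fov_diameter / 2.0 + 3.0 * self.tof_sigma_mm
        return int(math.ceil(reach / self.tof_bin_mm))

    @property
    def n_tof_bins(self) -> int:
        return 2 * self.tof_half_bins + 1

    @property
    def n_lors(self) -> int:
        return self.n_angles * self.n_radial_bins

    def angles(self) -> np.ndarray:
        return np.arange(self.n_angles) * math.pi / self.n_angles

    def radial_offsets(self) -> np.ndarray:
        return (np.arange(self.n_radial_bins)
                - (self.n_radial_bins - 1) / 2.0) * self.radial_bin_size

    def to_dict(self) -> dict:
        return {
            "n_angles": self.n_angles,
            "n_radial_bins": self.n_radial_bins,
            "radial_bin_size": self.radial_bin_size,
            "tof_resolution": self.tof_resolution,
            "tof_bin_size": self.tof_bin_size,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScannerGeometry":
        return cls(**d)


def default_geometry(**overrides) -> ScannerGeometry:
    """The package's standard desk-scale geometry (56 angles x 100 radial)."""
    return ScannerGeometry(**overrides)


@njit(cache=True)
def _siddon_trace(angles, offsets, n_image, voxel, max_t):  # pragma: no cover
    """Exact intersection lengths of all rays with the pixel grid.

    Returns flat COO arrays: row (lor), col (pixel), length (mm) and the
    signed midpoint position of each intersection segment along the ray
    (mm, measured from the perpendicular foot of the LOR).
    """
    n_ang = angles.shape[0]
    n_rad = offsets.shape[0]
    half = n_image * voxel / 2.0
    # generous upper bound on entries: each ray crosses <= 2*n pixels
    cap = n_ang * n_rad * (2 * n_image + 4)
    rows = np.empty(cap, dtype=np.int64)
    cols = np.empty(cap, dtype=np.int64)
    vals = np.empty(cap, dtype=np.float64)
    smid = np.empty(cap, dtype=np.float64)
    k = 0
    for ia in range(n_ang):
        ux = math.cos(angles[ia])
        uy = math.sin(angles[ia])
        vx = -uy
        vy = ux
        for ir in range(n_rad):
            s = offsets[ir]
            px = s * vx
            py = s * vy
            # ray p(t) = (px,py) + t*(ux,uy); clip to grid box [-half, half]^2
            tmin = -max_t
            tmax = max_t
            if abs(ux) > 1e-12:
                t1 = (-half - px) / ux
                t2 = (half - px) / ux
                if t1 > t2:
                    t1, t2 = t2, t1
                if t1 > tmin:
                    tmin = t1
                if t2 < tmax:
                    tmax = t2
            elif px <= -half or px >= half:
                continue
            if abs(uy) > 1e-12:
                t1 = (-half - py) / uy
                t2 = (half - py) / uy
                if t1 > t2:
                    t1, t2 = t2, t1
                if t1 > tmin:
                    tmin = t1
                if t2 < tmax:
                    tmax = t2
            elif py <= -half or py >= half:
                continue
            if tmax - tmin < 1e-12:
                continue
            lor = ia * n_rad + ir
            t = tmin + 1e-9
            x = px + t * ux
            y = py + t * uy
            ix = int(math.floor((x + half) / voxel))
            iy = int(math.floor((y + half) / voxel))
            if ix < 0:
                ix = 0
            if ix > n_image - 1:
                ix = n_image - 1
            if iy < 0:
                iy = 0
            if iy > n_image - 1:
                iy = n_image - 1
            # parametric distances to the next x / y pixel boundary
            if ux > 1e-12:
                tx = ((ix + 1) * voxel - half - px) / ux
                dtx = voxel / ux
                step_x = 1
            elif ux < -1e-12:
                tx = (ix * voxel - half - px) / ux
                dtx = -voxel / ux
                step_x = -1
            else:
                tx = 1e30
                dtx = 1e30
                step_x = 0
            if uy > 1e-12:
                ty = ((iy + 1) * voxel - half - py) / uy
                dty = voxel / uy
                step_y = 1
            elif uy < -1e-12:
                ty = (iy * voxel - half - py) / uy
                dty = -voxel / uy
                step_y = -1
            else:
                ty = 1e30
                dty = 1e30
                step_y = 0
            tcur = tmin
            while tcur < tmax - 1e-12:
                if tx < ty:
                    tnext = tx
                else:
                    tnext = ty
                if tnext > tmax:
                    tnext = tmax
                seg = tnext - tcur
                if seg > 1e-12 and 0 <= ix < n_image and 0 <= iy < n_image:
                    rows[k] = lor
                    cols[k] = iy * n_image + ix
                    vals[k] = seg
                    smid[k] = 0.5 * (tcur + tnext)
                    k += 1
                tcur = tnext
                if tx < ty:
                    ix += step_x
                    tx += dtx
                else:
                    iy += step_y
                    ty += dty
                if ix < 0 or ix >= n_image or iy < 0 or iy >= n_image:
                    break
    return rows[:k], cols[:k], vals[:k], smid[:k]


class SystemMatrix:
    """Sparse Siddon system matrix for one (geometry, image grid) pair.

    Attributes
    ----------
    A : csr_matrix, shape (n_lors, n_pixels)
        Intersection lengths in mm; ``A @ x`` is the line integral sinogram.
    s_along : ndarray aligned with ``A.data``
        Signed position (mm) of each intersection midpoint along its LOR,
        used as the true emission position for TOF.
    """

    def __init__(self, geometry: ScannerGeometry, n_image: int, voxel_size: float):
        self.geometry = geometry
        self.n_image = int(n_image)
        self.voxel_size = float(voxel_size)
        max_t = (geometry.fov_diameter + n_image * voxel_size) * 2.0
        rows, cols, vals, smid = _siddon_trace(
            geometry.angles(), geometry.radial_offsets(),
            self.n_image, self.voxel_size, max_t,
        )
        n_pix = self.n_image * self.n_image
        coo = sparse.coo_matrix(
            (vals, (rows, cols)), shape=(geometry.n_lors, n_pix)
        )
        order = np.lexsort((cols, rows))
        self.A = sparse.csr_matrix(
            (vals[order], (rows[order], cols[order])),
            shape=(geometry.n_lors, n_pix),
        )
        # csr with pre-sorted unique (row, col) keeps data order = lexsort order
        self.s_along = smid[order]
        self._A_tof: sparse.csr_matrix | None = None

    # -- TOF ---------------------------------------------------------------
    @property
    def A_tof(self) -> sparse.csr_matrix:
        """TOF system matrix, shape (n_lors * n_tof_bins, n_pixels).

        Row index = lor * n_tof + (tof_bin + tof_half_bins).  Each Siddon
        entry is spread over the TOF bins it can populate, weighted by the
        Gaussian TOF kernel integrated over each bin.
        """
        if self._A_tof is None:
            g = self.geometry
            sigma = g.tof_sigma_mm
            bin_mm = g.tof_bin_mm
            half = g.tof_half_bins
            n_tof = g.n_tof_bins
            reach = int(math.ceil(3.0 * sigma / bin_mm)) + 1
            coo = self.A.tocoo()
            s = self.s_along
            t0 = np.rint(s / bin_mm).astype(np.int64)
            rows_all = []
            cols_all = []
            vals_all = []
            inv = 1.0 / (sigma * math.sqrt(2.0))
            for dt in range(-reach, reach + 1):
                t = t0 + dt
                keep = np.abs(t) <= half
                if not np.any(keep):
                    continue
                tc = t[keep] * bin_mm
                sk = s[keep]
                w = 0.5 * (erf((tc + bin_mm / 2.0 - sk) * inv)
                           - erf((tc - bin_mm / 2.0 - sk) * inv))
                good = w > 1e-6
                if not np.any(good):
                    continue
                idx = np.flatnonzero(keep)[good]
                rows_all.append(coo.row[idx] * n_tof + (t[keep][good] + half))
                cols_all.append(coo.col[idx])
                vals_all.append(coo.data[idx] * w[good])
            At = sparse.coo_matrix(
                (np.concatenate(vals_all),
                 (np.concatenate(rows_all), np.concatenate(cols_all))),
                shape=(g.n_lors * n_tof, self.A.shape[1]),
            )
            self._A_tof = At.tocsr()
        return self._A_tof

    def attenuation_factors(self, mu_map: np.ndarray) -> np.ndarray:
        """Per-LOR survival probability exp(-integral of mu) for mu in 1/cm."""
        mu_per_mm = np.asarray(mu_map, dtype=float).ravel() * 0.1
        return np.exp(-(self.A @ mu_per_mm))


_MATRIX_CACHE: dict[tuple, SystemMatrix] = {}


def get_system_matrix(geometry: ScannerGeometry, n_image: int,
                      voxel_size: float) -> SystemMatrix:
    """Build (or fetch from cache) the system matrix for a geometry/grid pair."""
    key = (geometry, int(n_image), round(float(voxel_size), 6))
    if key not in _MATRIX_CACHE:
        _MATRIX_CACHE[key] = SystemMatrix(geometry, n_image, voxel_size)
    return _MATRIX_CACHE[key]
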