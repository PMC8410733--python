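"""Image-quality figures of merit evaluated on circular VOIs.

Conventions: the background VOI is a fixed 20-mm disc placed in the liver
region; lesion VOIs are sized to the lesion.  All standard deviations are
sample SDs (ddof=1).  Contrast, noise, SNR and the TOF gains are
dimensionless and invariant to global image scaling; SUV carries the
kBq/ml-vs-MBq/kg convention (tissue density 1 g/ml, so MBq/kg == kBq/ml).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .recon import ReconResult

__all__ = [
    "Voi", "FomRecord", "GainRecord", "RegressionResult",
    "contrast", "suv_mean", "noise", "snr", "cnr",
    "snr_gain", "cnr_gain", "compute_foms",
    "gain_vs_size_regression", "BACKGROUND_VOI_DIAMETER",
]

#: Fixed diameter of the liver background VOI, mm.
BACKGROUND_VOI_DIAMETER = 20.0

_GAIN_PAIRING = {"TOF": "OSEM", "PSF_TOF": "PSF"}


@dataclass(frozen=True)
class Voi:
    """A circular region of interest in physical image coordinates."""

    kind: str  # 'lesion' | 'background'
    center: tuple[float, float]  # mm, origin at image centre
    diameter: float  # mm

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("VOI diameter must be positive")

    def mask(self, shape: tuple[int, int], voxel_size: float) -> np.ndarray:
        """Voxel membership by the centre-inside rule.

        Raises if the diameter is below one voxel (a silent single-voxel
        VOI would make the SD meaningless) or if the VOI leaves the image.
        """
        if self.diameter < voxel_size:
            raise ValueError(
                f"VOI diameter {self.diameter} mm is below one voxel "
                f"({voxel_size} mm)"
            )
        ny, nx = shape
        cx, cy = self.center
        r = self.diameter / 2.0
        if abs(cx) + r > nx * voxel_size / 2 or abs(cy) + r > ny * voxel_size / 2:
            raise ValueError("VOI extends outside the image")
        x = (np.arange(nx) - (nx - 1) / 2.0) * voxel_size
        y = (np.arange(ny) - (ny - 1) / 2.0) * voxel_size
        xx, yy = np.meshgrid(x, y)
        m = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
        if not m.any():
            raise ValueError("empty VOI")
        return m

    def values(self, image: np.ndarray, voxel_size: float) -> np.ndarray:
        return np.asarray(image)[self.mask(np.asarray(image).shape, voxel_size)]


def _mean_sd(image, voi: Voi, voxel_size: float) -> tuple[float, float]:
    v = voi.values(image, voxel_size)
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return float(np.mean(v)), sd


def contrast(image, lesion_voi: Voi, background_voi: Voi, voxel_size: float) -> float:
    """Lesion-to-background mean ratio: Mean_lesion / Mean_background."""
    m_les, _ = _mean_sd(image, lesion_voi, voxel_size)
    m_bg, _ = _mean_sd(image, background_voi, voxel_size)
    if m_bg == 0:
        raise ZeroDivisionError("background mean is zero")
    return m_les / m_bg


def suv_mean(image, voi: Voi, injected: float, weight: float,
             voxel_size: float) -> float:
    """Mean standardized uptake value in the VOI.

    SUV = Activity_VOI / (Activity_injected / Bodyweight) with the image in
    kBq/ml, injected activity in MBq and weight in kg; with a 1 g/ml tissue
    density, MBq/kg equals kBq/ml, so no unit factor appears.
    """
    if injected <= 0 or weight <= 0:
        raise ValueError("injected activity and body weight must be positive")
    m, _ = _mean_sd(image, voi, voxel_size)
    return m / (injected / weight)


def noise(image, background_voi: Voi, voxel_size: float) -> float:
    """Coefficient of variation in the background VOI: SD / mean."""
    v = background_voi.values(image, voxel_size)
    if v.size < 2:
        raise ValueError("background VOI needs at least 2 voxels")
    m = float(np.mean(v))
    if m == 0:
        raise ZeroDivisionError("background mean is zero")
    return float(np.std(v, ddof=1)) / m


def snr(image, voi: Voi, voxel_size: float) -> float:
    """Signal-to-noise ratio in the VOI: Mean_VOI / SD_VOI."""
    m, sd = _mean_sd(image, voi, voxel_size)
    if sd == 0:
        raise ZeroDivisionError("VOI standard deviation is zero (infinite SNR)")
    return m / sd


def cnr(image, lesion_voi: Voi, background_voi: Voi, voxel_size: float) -> float:
    """Contrast-to-noise ratio: (Mean_lesion - Mean_background) / SD_background."""
    m_les, _ = _mean_sd(image, lesion_voi, voxel_size)
    m_bg, sd_bg = _mean_sd(image, background_voi, voxel_size)
    if sd_bg == 0:
        raise ZeroDivisionError("background standard deviation is zero")
    return (m_les - m_bg) / sd_bg


def _check_pair(tof_rec: ReconResult, nontof_rec: ReconResult) -> None:
    tv, nv = tof_rec.params.variant, nontof_rec.params.variant
    if _GAIN_PAIRING.get(tv) != nv:
        raise ValueError(
            f"gain pairing must be TOF-vs-OSEM or PSF_TOF-vs-PSF, got {tv} vs {nv}"
        )
    if not np.isclose(tof_rec.count_level, nontof_rec.count_level):
        raise ValueError("gain pair must share the same count level")
    if tof_rec.voxel_size != nontof_rec.voxel_size:
        raise ValueError("gain pair must share the same image grid")


def snr_gain(tof_rec: ReconResult, nontof_rec: ReconResult, voi: Voi) -> float:
    """TOF gain: SNR_TOF / SNR_non-TOF on a matched reconstruction pair."""
    _check_pair(tof_rec, nontof_rec)
    vs = tof_rec.voxel_size
    return snr(tof_rec.image, voi, vs) / snr(nontof_rec.image, voi, vs)


def cnr_gain(tof_rec: ReconResult, nontof_rec: ReconResult,
             lesion_voi: Voi, background_voi: Voi) -> float:
    """CNR_TOF / CNR_non-TOF on a matched reconstruction pair."""
    _check_pair(tof_rec, nontof_rec)
    vs = tof_rec.voxel_size
    return (cnr(tof_rec.image, lesion_voi, background_voi, vs)
            / cnr(nontof_rec.image, lesion_voi, background_voi, vs))


@dataclass(frozen=True)
class FomRecord:
    """All figures of merit for one (image, VOI pair) evaluation."""

    variant: str
    count_level: float
    contrast: float
    noise: float
    snr_lesion: float
    snr_background: float
    cnr: float
    suv_mean: float | None = None


@dataclass(frozen=True)
class GainRecord:
    """Matched-pair TOF gain with its body-size covariate."""

    pairing: str  # 'OSEM_vs_TOF' | 'PSF_vs_PSF_TOF'
    count_level: float
    snr_gain: float
    cnr_gain: float | None
    bmi: float | None = None
    diameter: float | None = None  # mm, body-size proxy


def compute_foms(
    rec: ReconResult,
    lesion_voi: Voi | None,
    background_voi: Voi,
    injected: float | None = None,
    weight: float | None = None,
) -> FomRecord:
    """Evaluate all figures of merit on one reconstruction."""
    vs = rec.voxel_size
    img = rec.image
    kw: dict = {}
    if lesion_voi is not None:
        kw["contrast"] = contrast(img, lesion_voi, background_voi, vs)
        kw["cnr"] = cnr(img, lesion_voi, background_voi, vs)
        kw["snr_lesion"] = snr(img, lesion_voi, vs)
        if injected and weight:
            kw["suv_mean"] = suv_mean(img, lesion_voi, injected, weight, vs)
    else:
        kw["contrast"] = float("nan")
        kw["cnr"] = float("nan")
        kw["snr_lesion"] = float("nan")
    return FomRecord(
        variant=rec.params.variant,
        count_level=rec.count_level,
        noise=noise(img, background_voi, vs),
        snr_background=snr(img, background_voi, vs),
        **kw,
    )


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r: float
    p: float
    stderr: float

    def slope_ci(self, alpha: float = 0.05, n: int | None = None) -> tuple[float, float]:
        """Two-sided confidence interval for the slope (normal approx if n unset)."""
        if n is None:
            z = stats.norm.ppf(1 - alpha / 2)
        else:
            z = stats.t.ppf(1 - alpha / 2, df=n - 2)
        return self.slope - z * self.stderr, self.slope + z * self.stderr


def gain_vs_size_regression(
    gains: list[GainRecord], x: str = "bmi", metric: str = "snr_gain"
) -> RegressionResult:
    """OLS trend of a TOF gain on a body-size covariate (BMI or diameter)."""
    if len(gains) < 3:
        raise ValueError("need at least 3 gain records")
    xs = np.array([getattr(g, x) for g in gains], dtype=float)
    ys = np.array([getattr(g, metric) for g in gains], dtype=float)
    if np.any(np.isnan(xs)) or np.any(np.isnan(ys)):
        raise ValueError("gain records with missing values")
    if np.allclose(xs, xs[0]):
        raise ValueError("degenerate (constant) size covariate")
    res = stats.linregress(xs, ys)
    return RegressionResult(
        slope=float(res.slope), intercept=float(res.intercept),
        r=float(res.rvalue), p=float(res.pvalue), stderr=float(res.stderr),
    )
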