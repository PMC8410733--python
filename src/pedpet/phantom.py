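"""Digital paediatric phantoms.

Single-slice (2-D) emission/attenuation phantoms that stand in for
whole-body FDG-PET images of paediatric oncology patients: an elliptical
body of uniform background uptake, a liver-like sub-region used as the
background VOI, and focal disc lesions with configurable
lesion-to-background uptake ratios.  Body size is parameterized by an
effective diameter derived from BMI, so a cohort of phantoms can span the
same body-size range as a clinical paediatric cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "PatientMeta",
    "LesionSpec",
    "PhantomSpec",
    "PhantomImage",
    "make_phantom",
    "bmi_to_diameter",
    "cohort_fixture",
    "cohort_dataframe",
    "DEFAULT_MATRIX",
    "DEFAULT_VOXEL_MM",
    "MU_WATER_511",
]

#: Default reconstruction matrix (in-plane) and voxel size in mm.
DEFAULT_MATRIX = 200
DEFAULT_VOXEL_MM = 4.073

#: Linear attenuation coefficient of water at 511 keV, 1/cm.
MU_WATER_511 = 0.096

#: Effective-diameter scale: D = _BMI_DIAMETER_K * sqrt(BMI), chosen so that
#: BMI 19 kg/m^2 (a typical paediatric cohort mean) maps to a 220 mm body.
_BMI_DIAMETER_K = 220.0 / math.sqrt(19.0)


def bmi_to_diameter(bmi: float) -> float:
    """Map BMI (kg/m^2) to an effective body diameter in mm.

    Strictly monotone increasing; BMI 19 -> 220 mm by construction.
    """
    if bmi <= 0:
        raise ValueError(f"BMI must be positive, got {bmi}")
    return _BMI_DIAMETER_K * math.sqrt(bmi)


@dataclass(frozen=True)
class PatientMeta:
    """Demographics and injection data for one patient."""

    patient_id: str
    weight: float  # kg
    height: float | None = None  # m
    bmi: float | None = None  # kg/m^2
    injected_activity: float | None = None  # MBq
    age: float | None = None  # years
    sex: str | None = None  # 'M' / 'F'
    n_lesions: int = 0

    def __post_init__(self) -> None:
        if self.injected_activity is not None and self.injected_activity <= 0:
            raise ValueError("injected_activity must be > 0")

    @property
    def activity_per_kg(self) -> float | None:
        """Injected activity normalised to body weight, MBq/kg."""
        if self.injected_activity is None:
            return None
        return self.injected_activity / self.weight

    @property
    def effective_diameter(self) -> float | None:
        """Body-size proxy in mm derived from BMI."""
        if self.bmi is None:
            return None
        return bmi_to_diameter(self.bmi)


@dataclass(frozen=True)
class LesionSpec:
    center: tuple[float, float]  # mm, image coordinates (0,0) = image centre
    diameter: float  # mm
    uptake_ratio: float  # lesion / background


@dataclass(frozen=True)
class PhantomSpec:
    body_diameter: float  # mm (major axis; minor = aspect * major)
    lesions: Sequence[LesionSpec] = ()
    background_uptake: float = 5.0  # kBq/ml
    liver_fraction: float = 0.25  # liver diameter / body diameter
    mu_body: float = MU_WATER_511  # 1/cm
    body_aspect: float = 0.8  # minor/major axis ratio of the body ellipse
    meta: PatientMeta | None = None


@dataclass
class PhantomImage:
    """Voxelized activity and attenuation maps with labelled regions."""

    activity_map: np.ndarray  # kBq/ml
    mu_map: np.ndarray  # 1/cm
    voxel_size: tuple[float, float]  # mm
    masks: dict[str, np.ndarray]
    meta: PatientMeta | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.activity_map.shape

    def grid_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (x, y) voxel-centre coordinates in mm, origin at centre."""
        ny, nx = self.activity_map.shape
        dy, dx = self.voxel_size
        x = (np.arange(nx) - (nx - 1) / 2.0) * dx
        y = (np.arange(ny) - (ny - 1) / 2.0) * dy
        return np.meshgrid(x, y)


def _disc_mask(xx: np.ndarray, yy: np.ndarray, center: tuple[float, float],
               diameter: float) -> np.ndarray:
    cx, cy = center
    r = diameter / 2.0
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r


def make_phantom(
    spec: PhantomSpec,
    n_image: int = DEFAULT_MATRIX,
    voxel_size: float = DEFAULT_VOXEL_MM,
) -> PhantomImage:
    """Build a deterministic 2-D phantom from a structural specification.

    The body is an ellipse (major axis ``body_diameter``) of uniform
    ``background_uptake``; a liver disc in the upper-left body quadrant holds
    the background VOI; each lesion is a disc at
    ``uptake_ratio * background_uptake``.  A voxel belongs to a region iff
    its centre lies inside the analytic shape.

    Raises
    ------
    ValueError
        If the body does not fit the field of view, a lesion extends outside
        the body, or two lesions overlap.
    """
    if spec.body_diameter <= 0:
        raise ValueError("body_diameter must be positive")
    fov = n_image * voxel_size
    if spec.body_diameter > fov:
        raise ValueError(
            f"body diameter {spec.body_diameter} mm exceeds field of view {fov} mm"
        )
    if spec.background_uptake <= 0:
        raise ValueError("background_uptake must be positive")

    x = (np.arange(n_image) - (n_image - 1) / 2.0) * voxel_size
    xx, yy = np.meshgrid(x, x)

    a = spec.body_diameter / 2.0
    b = a * spec.body_aspect
    body = (xx / a) ** 2 + (yy / b) ** 2 <= 1.0

    # Liver: a disc offset toward the upper-left quadrant of the body.
    liver_d = spec.liver_fraction * spec.body_diameter
    liver_center = (-0.35 * a, -0.3 * b)
    liver = _disc_mask(xx, yy, liver_center, liver_d) & body

    activity = np.where(body, spec.background_uptake, 0.0)
    masks: dict[str, np.ndarray] = {"body": body, "liver": liver}

    lesion_union = np.zeros_like(body)
    for i, les in enumerate(spec.lesions):
        if les.uptake_ratio <= 0:
            raise ValueError("lesion uptake_ratio must be > 0")
        if les.diameter < voxel_size:
            raise ValueError(
                f"lesion diameter {les.diameter} mm below one voxel ({voxel_size} mm)"
            )
        cx, cy = les.center
        r = les.diameter / 2.0
        # analytic containment check against the body ellipse
        if ((abs(cx) + r) / a) ** 2 + ((abs(cy) + r) / b) ** 2 > 1.0:
            raise ValueError(f"lesion {i} extends outside the body")
        m = _disc_mask(xx, yy, les.center, les.diameter)
        if np.any(m & lesion_union):
            raise ValueError(f"lesion {i} overlaps a previous lesion")
        lesion_union |= m
        activity[m] = les.uptake_ratio * spec.background_uptake
        masks[f"lesion_{i}"] = m

    mu = np.where(body, spec.mu_body, 0.0)
    return PhantomImage(
        activity_map=activity,
        mu_map=mu,
        voxel_size=(voxel_size, voxel_size),
        masks=masks,
        meta=spec.meta,
    )


# ---------------------------------------------------------------------------
# Embedded 29-patient cohort (demographics of a retrospective paediatric
# whole-body FDG-PET cohort): patient id, age [y], sex, weight [kg],
# height [m], BMI [kg/m^2], injected activity [MBq], number of analysed
# lesions.  The per-kg activity column of the source table is recomputed as
# injected/weight (MBq/kg).
# ---------------------------------------------------------------------------
_COHORT_ROWS: list[tuple[str, float, str, float, float, float, float, int]] = [
    ("P1", 8, "M", 29.0, 1.3, 16.2, 136.0, 2),
    ("P2", 8, "M", 26.7, 1.3, 16.6, 124.0, 1),
    ("P3", 15, "F", 48.9, 1.6, 19.6, 188.0, 1),
    ("P4", 17, "F", 70.2, 1.7, 24.0, 210.0, 2),
    ("P5", 6, "F", 21.4, 1.1, 17.1, 102.0, 2),
    ("P6", 17, "M", 77.4, 1.9, 21.4, 205.0, 0),
    ("P7", 15, "M", 57.6, 1.7, 21.2, 185.0, 3),
    ("P8", 15, "M", 49.4, 1.7, 18.1, 172.0, 2),
    ("P9", 15, "F", 46.4, 1.5, 19.6, 179.0, 2),
    ("P10", 14, "F", 70.5, 1.7, 25.9, 201.0, 3),
    ("P11", 18, "M", 44.7, 1.7, 14.9, 159.0, 0),
    ("P12", 10, "M", 29.7, 1.4, 15.8, 121.0, 1),
    ("P13", 14, "M", 69.0, 1.7, 22.8, 195.0, 1),
    ("P14", 15, "F", 60.1, 1.6, 24.7, 208.0, 2),
    ("P15", 13, "F", 73.8, 1.7, 25.2, 216.0, 3),
    ("P16", 12, "M", 44.1, 1.3, 28.2, 148.0, 1),
    ("P17", 6, "F", 23.7, 1.2, 17.3, 93.0, 0),
    ("P18", 15, "M", 50.1, 1.8, 15.6, 177.0, 0),
    ("P19", 15, "M", 65.6, 1.8, 19.4, 211.0, 0),
    ("P20", 13, "M", 43.3, 1.6, 17.3, 160.0, 0),
    ("P21", 16, "F", 69.6, 1.7, 25.6, 197.0, 0),
    ("P22", 12, "M", 46.8, 1.7, 17.2, 184.0, 2),
    ("P23", 7, "F", 21.0, 1.3, 12.6, 106.0, 0),
    ("P24", 7, "M", 26.6, 1.3, 14.8, 110.0, 1),
    ("P25", 12, "F", 32.0, 1.4, 16.8, 118.0, 1),
    ("P26", 4, "M", 21.0, 1.1, 19.0, 106.0, 0),
    ("P27", 2, "F", 10.0, 0.8, 16.0, 58.0, 2),
    ("P28", 3, "M", 16.9, 1.0, 15.9, 87.0, 0),
    ("P29", 17, "M", 51.9, 1.8, 16.8, 173.0, 3),
]


def cohort_fixture() -> list[PatientMeta]:
    """Return the embedded 29-patient cohort as :class:`PatientMeta` rows."""
    return [
        PatientMeta(
            patient_id=pid, age=age, sex=sex, weight=w, height=h,
            bmi=bmi, injected_activity=act, n_lesions=nles,
        )
        for pid, age, sex, w, h, bmi, act, nles in _COHORT_ROWS
    ]


def cohort_dataframe():
    """Cohort as a tidy pandas DataFrame (one row per patient)."""
    import pandas as pd

    rows = cohort_fixture()
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in rows],
            "age": [r.age for r in rows],
            "sex": [r.sex for r in rows],
            "weight": [r.weight for r in rows],
            "height": [r.height for r in rows],
            "bmi": [r.bmi for r in rows],
            "injected_activity": [r.injected_activity for r in rows],
            "activity_per_kg": [r.activity_per_kg for r in rows],
            "n_lesions": [r.n_lesions for r in rows],
        }
    )


def cohort_phantom_specs(
    background_uptake: float = 5.0,
    lesion_uptake_ratio: float = 4.0,
    lesion_diameter: float = 20.0,
) -> list[PhantomSpec]:
    """Phantom specs emulating the embedded cohort's body-size range.

    Each patient becomes an elliptical body whose major axis is the
    BMI-derived effective diameter; patients with analysed lesions get one
    representative focal lesion.
    """
    specs = []
    for meta in cohort_fixture():
        d = bmi_to_diameter(meta.bmi)
        lesions = []
        if meta.n_lesions > 0:
            lesions.append(
                LesionSpec(center=(0.18 * d, 0.0), diameter=lesion_diameter,
                           uptake_ratio=lesion_uptake_ratio)
            )
        specs.append(
            PhantomSpec(body_diameter=d, lesions=tuple(lesions),
                        background_uptake=background_uptake, meta=meta)
        )
    return specs
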