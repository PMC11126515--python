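"""Synthetic inputs: a digital lung phantom and a feature-level cohort simulator.

Two generators at two scales:

* :func:`build_phantom` constructs a 3D iodine-density volume with ground
  truth — two ellipsoidal half-lungs carrying a linear ventro-dorsal perfusion
  gradient (pulmonary blood volume rises toward the dorsal lung in the supine
  position), sharply bounded wedge-shaped hypoperfusion defects, blood-pool
  reference regions for the main pulmonary artery (MPA) and left atrium (LA),
  and optional additive Gaussian noise.  In chronic thromboembolic disease,
  systemic (bronchopulmonary) collaterals partially re-perfuse embolized lung;
  the phantom models this as an additive fractional term
  (``collateral_fraction``) on top of the residual defect perfusion.

* :func:`sample_feature_cohort` draws per-patient feature tables from
  per-group normal distributions, so that diagnostic-performance statistics
  can be exercised at the published cohort scale without voxel data.

Both are deterministic given their seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .io import (
    GROUPS,
    CohortTable,
    ConfigurationError,
    IodineVolume,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "WedgeDefect",
    "PhantomParams",
    "PhantomCase",
    "MorphologicalFeatures",
    "CohortSimParams",
    "build_phantom",
    "sample_feature_cohort",
    "group_phantom_params",
    "default_cohort_params",
    "DEFAULT_FEATURE_PARAMS",
    "POSITIVE_FEATURES",
]


# ---------------------------------------------------------------------------
# Parameter types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WedgeDefect:
    """A cone-shaped perfusion defect with its apex pointing from the hilum
    toward the pleura, mimicking the segmental wedge shape of embolic defects.

    ``axis`` is the cone axis direction in (z, y, x) order (any length, mm
    frame); ``opening_angle_deg`` is the full apex opening angle.
    """

    apex_voxel: tuple[int, int, int]
    axis: tuple[float, float, float]
    opening_angle_deg: float
    length_mm: float


@dataclass(frozen=True)
class MorphologicalFeatures:
    """Morphological CT readings (manual in clinical practice, simulated here)."""

    mpa_dia: float
    mpa_aorta_ratio: float
    rv_lv_ratio: float
    bronchial_dia: float | None = None

    def __post_init__(self) -> None:
        for name in ("mpa_dia", "mpa_aorta_ratio", "rv_lv_ratio"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValidationError(f"{name} must be positive, got {v}")
        if self.bronchial_dia is not None and self.bronchial_dia <= 0:
            raise ValidationError(f"bronchial_dia must be positive, got {self.bronchial_dia}")

    @property
    def aorta_dia(self) -> float:
        return self.mpa_dia / self.mpa_aorta_ratio


def _default_defects() -> list[WedgeDefect]:
    # one wedge per lung, apex near the hilum pointing laterally toward the pleura
    return [
        WedgeDefect(apex_voxel=(16, 22, 18), axis=(0.0, 0.4, -1.0), opening_angle_deg=40.0, length_mm=80.0),
        WedgeDefect(apex_voxel=(14, 20, 22), axis=(0.2, 0.5, 1.0), opening_angle_deg=35.0, length_mm=75.0),
    ]


@dataclass(frozen=True)
class PhantomParams:
    """Full parameterization of the voxel-level phantom.

    Axis order is (z craniocaudal, y ventral-to-dorsal, x left-to-right).
    ``gradient_slope`` is the fractional iodine increase per cm along +y,
    measured from the ventral-most lung voxel, so every lung voxel carries at
    least ``baseline_id``.  ``defect_multiplier`` is the fractional residual
    perfusion inside a defect relative to the local baseline;
    ``collateral_fraction`` adds systemic-collateral perfusion on top.
    """

    grid_shape: tuple[int, int, int] = (32, 40, 40)
    spacing_mm: tuple[float, float, float] = (6.0, 6.0, 6.0)
    # (center_mm, radii_mm) per half-lung, both in (z, y, x) order
    lung_geometry: tuple[tuple[tuple[float, float, float], tuple[float, float, float]], ...] = (
        ((96.0, 120.0, 65.0), (80.0, 90.0, 40.0)),
        ((96.0, 120.0, 175.0), (80.0, 90.0, 40.0)),
    )
    gradient_slope: float = 0.02
    baseline_id: float = 1.6
    id_mpa_true: float = 12.6
    id_la_true: float = 10.1
    mpa_center_mm: tuple[float, float, float] = (110.0, 100.0, 120.0)
    la_center_mm: tuple[float, float, float] = (85.0, 145.0, 120.0)
    roi_radius_mm: float = 12.0
    defect_spec: tuple[WedgeDefect, ...] = field(default_factory=lambda: tuple(_default_defects()))
    defect_multiplier: float = 0.10
    collateral_fraction: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0
    group: str = "CONTROL"
    require_detectable: bool = True

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.grid_shape) or any(s <= 0 for s in self.spacing_mm):
            raise ValidationError("grid_shape and spacing_mm must be positive")
        for v, name in [(self.baseline_id, "baseline_id"), (self.id_mpa_true, "id_mpa_true"), (self.id_la_true, "id_la_true")]:
            if v <= 0:
                raise ValidationError(f"{name} must be > 0, got {v}")
        if not (0 <= self.defect_multiplier < 1):
            raise ValidationError(f"defect_multiplier must be in [0, 1), got {self.defect_multiplier}")
        if self.collateral_fraction < 0:
            raise ValidationError(f"collateral_fraction must be >= 0, got {self.collateral_fraction}")
        if self.noise_sd < 0:
            raise ValidationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}, got {self.group!r}")


@dataclass
class PhantomCase:
    """One synthetic patient: the volume, its masks and the ground truth."""

    volume: IodineVolume
    lung_mask: np.ndarray
    mpa_roi: np.ndarray
    la_roi: np.ndarray
    truth_defect_mask: np.ndarray
    truth_defect_fraction: float  # % of lung voxels
    group: str
    morphology: MorphologicalFeatures
    params: PhantomParams

    def __post_init__(self) -> None:
        if (self.mpa_roi & self.lung_mask).any() or (self.la_roi & self.lung_mask).any():
            raise ValidationError("reference ROIs must be disjoint from the lung mask")
        if (self.truth_defect_mask & ~self.lung_mask).any():
            raise ValidationError("truth defect mask extends outside the lung mask")
        recomputed = 100.0 * self.truth_defect_mask.sum() / max(self.lung_mask.sum(), 1)
        if not math.isclose(recomputed, self.truth_defect_fraction, abs_tol=1e-9):
            raise ValidationError("truth_defect_fraction inconsistent with truth_defect_mask")


# ---------------------------------------------------------------------------
# Voxel-level phantom construction
# ---------------------------------------------------------------------------

def _coordinate_grids(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")  # zz, yy, xx in mm


def _ellipsoid_mask(grids, center, radii):
    zz, yy, xx = grids
    return (
        ((zz - center[0]) / radii[0]) ** 2
        + ((yy - center[1]) / radii[1]) ** 2
        + ((xx - center[2]) / radii[2]) ** 2
    ) <= 1.0


def _sphere_mask(grids, center, radius):
    zz, yy, xx = grids
    return ((zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2) <= radius**2


def _wedge_mask(grids, spacing, defect: WedgeDefect) -> np.ndarray:
    zz, yy, xx = grids
    apex = np.array([defect.apex_voxel[i] * spacing[i] for i in range(3)])
    axis = np.asarray(defect.axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValidationError("wedge defect axis must be a nonzero vector")
    axis = axis / norm
    dz, dy, dx = zz - apex[0], yy - apex[1], xx - apex[2]
    proj = dz * axis[0] + dy * axis[1] + dx * axis[2]
    dist = np.sqrt(dz**2 + dy**2 + dx**2)
    half = math.radians(defect.opening_angle_deg) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_angle = np.where(dist > 0, proj / np.maximum(dist, 1e-12), 1.0)
    return (proj >= 0) & (proj <= defect.length_mm) & (cos_angle >= math.cos(half))


def build_phantom(params: PhantomParams) -> PhantomCase:
    """Construct a phantom case from its parameters.

    Before noise, every lung voxel outside a defect carries
    ``baseline_id * (1 + gradient_slope * y_cm)`` with y measured from the
    ventral-most lung voxel; defect voxels carry
    ``local_baseline * (defect_multiplier + collateral_fraction)``; MPA/LA ROI
    voxels carry their true blood-pool densities; everything else is 0.
    Defects extending outside the lung are clipped to the lung.
    """
    grids = _coordinate_grids(params.grid_shape, params.spacing_mm)

    lung = np.zeros(params.grid_shape, dtype=bool)
    for center, radii in params.lung_geometry:
        lung |= _ellipsoid_mask(grids, center, radii)
    if not lung.any():
        raise ValidationError("degenerate lung geometry: empty lung mask")

    mpa_roi = _sphere_mask(grids, params.mpa_center_mm, params.roi_radius_mm)
    la_roi = _sphere_mask(grids, params.la_center_mm, params.roi_radius_mm)
    if not mpa_roi.any() or not la_roi.any():
        raise ValidationError("reference ROI falls outside the grid")
    if (mpa_roi & la_roi).any():
        raise ValidationError("MPA and LA reference ROIs overlap")
    mpa_roi &= ~lung
    la_roi &= ~lung

    yy = grids[1]
    y_min = yy[lung].min()
    local_baseline = params.baseline_id * (1.0 + params.gradient_slope * np.maximum(yy - y_min, 0.0) / 10.0)

    defect = np.zeros(params.grid_shape, dtype=bool)
    for wedge in params.defect_spec:
        defect |= _wedge_mask(grids, params.spacing_mm, wedge)
    defect &= lung  # clip to the lung, by design

    values = np.zeros(params.grid_shape, dtype=np.float64)
    values[lung] = local_baseline[lung]
    residual = params.defect_multiplier + params.collateral_fraction
    values[defect] = local_baseline[defect] * residual
    values[mpa_roi] = params.id_mpa_true
    values[la_roi] = params.id_la_true

    threshold = 0.05 * params.id_mpa_true
    if params.require_detectable and defect.any():
        worst = values[defect].max()
        if worst >= threshold:
            raise ValidationError(
                f"defect not detectable: max in-defect density {worst:.3f} mg/mL "
                f"is not below 5% of MPA ({threshold:.3f} mg/mL); lower "
                "defect_multiplier/collateral_fraction or set require_detectable=False"
            )

    rng = np.random.default_rng(params.seed)
    if params.noise_sd > 0:
        interior = lung | mpa_roi | la_roi
        noise = rng.normal(0.0, params.noise_sd, size=int(interior.sum()))
        values[interior] = np.maximum(values[interior] + noise, 0.0)

    morphology = _sample_morphology(params.group, rng)

    frac = 100.0 * defect.sum() / lung.sum()
    return PhantomCase(
        volume=IodineVolume(values=values, spacing_mm=params.spacing_mm),
        lung_mask=lung,
        mpa_roi=mpa_roi,
        la_roi=la_roi,
        truth_defect_mask=defect,
        truth_defect_fraction=float(frac),
        group=params.group,
        morphology=morphology,
        params=params,
    )


def group_phantom_params(group: str, seed: int = 0, noise_sd: float = 0.0) -> PhantomParams:
    """Preset phantom parameters per study group.

    Controls carry no wedge defects (the ventro-dorsal gradient alone).  The
    acute-embolism preset has low residual defect perfusion and no collateral
    supply; the chronic preset adds a collateral fraction, kept low enough
    that defects stay below the 5%-of-MPA detection threshold even at the
    dorsal end of the gradient.
    """
    base = PhantomParams(group=group, seed=seed, noise_sd=noise_sd)
    if group == "CONTROL":
        return replace(base, defect_spec=(), defect_multiplier=0.0, collateral_fraction=0.0)
    if group == "APE":
        return replace(base, defect_multiplier=0.10, collateral_fraction=0.0)
    if group == "CTEPH":
        return replace(base, defect_multiplier=0.10, collateral_fraction=0.15)
    raise ValidationError(f"unknown group {group!r}")


# ---------------------------------------------------------------------------
# Feature-level cohort simulation
# ---------------------------------------------------------------------------

#: Per-feature per-group (mean, sd); group order (APE, CTEPH, CONTROL).
DEFAULT_FEATURE_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "id_mpa": {"APE": (12.6, 5.2), "CTEPH": (14.3, 3.9), "CONTROL": (15.3, 3.8)},
    "id_la": {"APE": (10.1, 2.8), "CTEPH": (9.0, 2.3), "CONTROL": (10.4, 2.9)},
    "mpa_dia": {"APE": (28.8, 4.5), "CTEPH": (34.0, 5.5), "CONTROL": (26.7, 2.6)},
    "mpa_aorta_ratio": {"APE": (0.85, 0.14), "CTEPH": (1.05, 0.22), "CONTROL": (0.83, 0.10)},
    "rv_lv_ratio": {"APE": (1.09, 0.36), "CTEPH": (1.26, 0.43), "CONTROL": (0.93, 0.13)},
    "bronchial_dia": {"APE": (1.6, 0.31), "CTEPH": (2.4, 0.74), "CONTROL": (1.5, 0.16)},
    "normal_fraction_pct": {"APE": (68.6, 17.9), "CTEPH": (53.6, 20.0), "CONTROL": (73.1, 18.2)},
    "malp_fraction_pct": {"APE": (28.3, 18.4), "CTEPH": (44.1, 20.2), "CONTROL": (23.9, 18.5)},
    "normal_id_mean_mpa": {"APE": (0.13, 0.04), "CTEPH": (0.10, 0.02), "CONTROL": (0.11, 0.03)},
    "normal_id_mean_la": {"APE": (0.15, 0.03), "CTEPH": (0.16, 0.04), "CONTROL": (0.16, 0.05)},
    "normal_id_max_mpa": {"APE": (0.44, 0.16), "CTEPH": (0.33, 0.13), "CONTROL": (0.35, 0.09)},
    "normal_id_max_la": {"APE": (0.4993, 0.0035), "CTEPH": (0.4998, 0.0003), "CONTROL": (0.4990, 0.0042)},
    "normal_id_kurtosis": {"APE": (5.4, 3.5), "CTEPH": (5.3, 3.6), "CONTROL": (6.3, 3.9)},
    "normal_id_skewness": {"APE": (2.0, 0.7), "CTEPH": (2.0, 0.7), "CONTROL": (2.1, 0.8)},
    "malp_id_mean_mpa": {"APE": (0.022, 0.005), "CTEPH": (0.023, 0.004), "CONTROL": (0.028, 0.005)},
    "malp_id_mean_la": {"APE": (0.028, 0.012), "CTEPH": (0.040, 0.016), "CONTROL": (0.046, 0.022)},
    "malp_id_max_mpa": {"APE": (0.0497, 0.0003), "CTEPH": (0.0498, 0.0002), "CONTROL": (0.0499, 0.0001)},
    "malp_id_max_la": {"APE": (0.06, 0.02), "CTEPH": (0.09, 0.03), "CONTROL": (0.08, 0.04)},
    "malp_id_kurtosis": {"APE": (-1.1, 0.3), "CTEPH": (-1.1, 0.2), "CONTROL": (-0.7, 0.8)},
    "malp_id_skewness": {"APE": (0.03, 0.48), "CTEPH": (-0.06, 0.38), "CONTROL": (-0.57, 0.45)},
}

#: Features with strictly positive physical support: non-positive draws are redrawn.
POSITIVE_FEATURES = frozenset(
    {
        "id_mpa",
        "id_la",
        "mpa_dia",
        "mpa_aorta_ratio",
        "rv_lv_ratio",
        "bronchial_dia",
        "normal_fraction_pct",
        "malp_fraction_pct",
        "normal_id_mean_mpa",
        "normal_id_mean_la",
        "normal_id_max_mpa",
        "normal_id_max_la",
        "malp_id_mean_mpa",
        "malp_id_mean_la",
        "malp_id_max_mpa",
        "malp_id_max_la",
    }
)

#: Fraction of patients in whom the bronchial arteries are measurable
#: (detectable in 31/57 acute, 46/52 chronic, 5/22 control patients).
DEFAULT_DETECT_RATES: dict[str, dict[str, float]] = {
    "bronchial_dia": {"APE": 31 / 57, "CTEPH": 46 / 52, "CONTROL": 5 / 22},
}


@dataclass(frozen=True)
class CohortSimParams:
    """Parameterization of the feature-level cohort simulator.

    ``correlation`` optionally names one feature pair drawn jointly within
    each group with the given Pearson correlation; all other features are
    independent.  ``cteph_central_fraction`` sets the share of chronic
    patients labelled with central (vs peripheral) thrombus level.
    """

    group_sizes: dict[str, int] = field(default_factory=lambda: {"APE": 57, "CTEPH": 52, "CONTROL": 22})
    feature_params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_FEATURE_PARAMS.items()}
    )
    detect_rates: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_DETECT_RATES.items()}
    )
    correlation: tuple[str, str, float] | None = None
    cteph_central_fraction: float = 14 / 52
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ValidationError(f"unknown group {g!r} in group_sizes")
            if n < 0:
                raise ValidationError(f"group size must be >= 0, got {n} for {g}")
        for feat, per_group in self.feature_params.items():
            for g, (_, sd) in per_group.items():
                if sd < 0:
                    raise ValidationError(f"SD must be >= 0 for {feat}/{g}, got {sd}")
        if self.correlation is not None:
            a, b, rho = self.correlation
            if not -1.0 <= rho <= 1.0:
                raise ValidationError(f"correlation must be in [-1, 1], got {rho}")
            for name in (a, b):
                if name not in self.feature_params:
                    raise ConfigurationError(f"correlated feature {name!r} has no configured parameters")


def _draw_positive(rng: np.random.Generator, mean: float, sd: float, n: int, feature: str) -> np.ndarray:
    """Normal draws with rejection of non-positive values (redraw, logged)."""
    values = rng.normal(mean, sd, size=n)
    redraws = 0
    while True:
        bad = values <= 0
        if not bad.any():
            break
        redraws += int(bad.sum())
        values[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    if redraws:
        logger.info("feature %s: redrew %d non-positive draw(s)", feature, redraws)
    return values


def sample_feature_cohort(params: CohortSimParams, features: list[str] | None = None) -> CohortTable:
    """Draw a per-patient cohort table from the configured group distributions.

    Rows are ordered APE, CTEPH, CONTROL; patient ids are ``P0001``…  With a
    seed the draw is fully reproducible.
    """
    import pandas as pd

    if features is None:
        features = list(params.feature_params)
    for f in features:
        if f not in params.feature_params:
            raise ConfigurationError(f"feature {f!r} requested without configured parameters")

    rng = np.random.default_rng(params.seed)
    group_order = [g for g in ("APE", "CTEPH", "CONTROL") if params.group_sizes.get(g, 0) > 0]

    corr_pair = params.correlation
    rows: dict[str, list] = {"patient_id": [], "group": [], "subtype": []}
    for f in features:
        rows[f] = []

    pid = 0
    for group in group_order:
        n = params.group_sizes[group]
        block: dict[str, np.ndarray] = {}
        if corr_pair is not None and corr_pair[0] in features and corr_pair[1] in features:
            a, b, rho = corr_pair
            ma, sa = params.feature_params[a][group]
            mb, sb = params.feature_params[b][group]
            cov = np.array([[sa**2, rho * sa * sb], [rho * sa * sb, sb**2]])
            draws = rng.multivariate_normal([ma, mb], cov, size=n)
            va, vb = draws[:, 0], draws[:, 1]
            if a in POSITIVE_FEATURES or b in POSITIVE_FEATURES:
                bad = (va <= 0) | (vb <= 0)
                redraws = 0
                while bad.any():
                    redraws += int(bad.sum())
                    rd = rng.multivariate_normal([ma, mb], cov, size=int(bad.sum()))
                    va[bad], vb[bad] = rd[:, 0], rd[:, 1]
                    bad = (va <= 0) | (vb <= 0)
                if redraws:
                    logger.info("pair (%s, %s): redrew %d non-positive draw(s)", a, b, redraws)
            block[a], block[b] = va, vb
        for f in features:
            if f in block:
                continue
            if group not in params.feature_params[f]:
                raise ConfigurationError(f"feature {f!r} has no parameters for group {group}")
            mean, sd = params.feature_params[f][group]
            if f in POSITIVE_FEATURES and sd > 0:
                block[f] = _draw_positive(rng, mean, sd, n, f)
            else:
                block[f] = rng.normal(mean, sd, size=n) if sd > 0 else np.full(n, mean)
        # missingness for features not measurable in every patient
        for f in features:
            rates = params.detect_rates.get(f)
            if rates is not None:
                detected = rng.random(n) < rates.get(group, 1.0)
                block[f] = np.where(detected, block[f], np.nan)
        if group == "CTEPH":
            central = rng.random(n) < params.cteph_central_fraction
            subtypes = np.where(central, "cCTEPH", "pCTEPH")
        else:
            subtypes = np.full(n, None, dtype=object)
        for i in range(n):
            pid += 1
            rows["patient_id"].append(f"P{pid:04d}")
            rows["group"].append(group)
            rows["subtype"].append(subtypes[i])
            for f in features:
                rows[f].append(float(block[f][i]))

    df = pd.DataFrame(rows)
    return CohortTable(df)


def default_cohort_params(seed: int = 0, **overrides) -> CohortSimParams:
    """The published cohort's default simulation parameters (n = 57/52/22)."""
    return CohortSimParams(seed=seed, **overrides)


def _sample_morphology(group: str, rng: np.random.Generator) -> MorphologicalFeatures:
    """Sample one patient's morphological features from the group distributions."""
    vals = {}
    for f in ("mpa_dia", "mpa_aorta_ratio", "rv_lv_ratio", "bronchial_dia"):
        mean, sd = DEFAULT_FEATURE_PARAMS[f][group]
        vals[f] = float(_draw_positive(rng, mean, sd, 1, f)[0])
    if rng.random() >= DEFAULT_DETECT_RATES["bronchial_dia"][group]:
        vals["bronchial_dia"] = None
    return MorphologicalFeatures(**vals)
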