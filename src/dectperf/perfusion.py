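"""Iodine-density perfusion analysis: reference measurement, three-compartment
threshold segmentation, compartment fractions, first-order histogram features,
and normalization to the blood-pool references.

The segmentation rule partitions the lung by iodine density (ID) against two
blood-pool readings: *malperfused* lung has ID below 5% of the mean MPA
density, the *vessel* compartment has ID at or above 50% of the mean LA
density, and *normally perfused* lung lies in between.  Boundary voxels at
exactly 5% of the MPA go to NORMAL and at exactly 50% of the LA go to VESSEL,
so the three intervals are a strict partition.

Histogram features use the population moment estimators: skewness
g1 = m3 / m2^(3/2) and excess kurtosis g2 = m4 / m2^2 - 3 (normal
distribution = 0).  Normalized features divide the raw mean/max by the mean
MPA or LA density:

    ID_mean,MPA = ID_mean / ID_MPA      ID_max,MPA = ID_max / ID_MPA
    ID_mean,LA  = ID_mean / ID_LA       ID_max,LA  = ID_max / ID_LA

A direct consequence of the thresholds: malperfused ID_max,MPA < 0.05 and
normal ID_max,LA < 0.5 on every input.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .io import (
    LABEL_MALPERFUSED,
    LABEL_NORMAL,
    LABEL_OUTSIDE,
    LABEL_VESSEL,
    IodineVolume,
    ValidationError,
)
from .phantom import MorphologicalFeatures, PhantomCase

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceDensities",
    "CompartmentMap",
    "CompartmentFeatures",
    "PatientRecord",
    "DegenerateThresholdError",
    "measure_reference_density",
    "segment_compartments",
    "compartment_fractions",
    "first_order_features",
    "normalize_features",
    "extract_patient_features",
    "record_to_row",
]


class DegenerateThresholdError(ValidationError):
    """The malperfusion and vessel thresholds cross: no normal interval exists."""


@dataclass(frozen=True)
class ReferenceDensities:
    """Mean iodine densities (mg/mL) in the MPA and LA reference regions."""

    id_mpa: float
    id_la: float

    def __post_init__(self) -> None:
        if self.id_mpa <= 0 or self.id_la <= 0:
            raise ValidationError(f"reference densities must be > 0, got MPA={self.id_mpa}, LA={self.id_la}")
        if 0.05 * self.id_mpa >= 0.5 * self.id_la:
            raise DegenerateThresholdError(
                f"degenerate thresholds: 5% of MPA ({0.05 * self.id_mpa:.4g} mg/mL) is not below "
                f"50% of LA ({0.5 * self.id_la:.4g} mg/mL)"
            )

    @property
    def malperfusion_threshold(self) -> float:
        return 0.05 * self.id_mpa

    @property
    def vessel_threshold(self) -> float:
        return 0.5 * self.id_la


@dataclass
class CompartmentMap:
    """Voxelwise compartment labels over the volume domain."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        codes = np.unique(self.labels)
        if not np.isin(codes, [LABEL_OUTSIDE, LABEL_MALPERFUSED, LABEL_NORMAL, LABEL_VESSEL]).all():
            raise ValidationError(f"unexpected label codes {codes}")

    @property
    def lung_mask(self) -> np.ndarray:
        return self.labels != LABEL_OUTSIDE

    def compartment_mask(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass
class CompartmentFeatures:
    """First-order histogram features of one lung compartment.

    Missing values (empty or constant compartments) are NaN.
    """

    fraction_pct: float
    id_mean: float = math.nan
    id_max: float = math.nan
    id_skewness: float = math.nan
    id_kurtosis: float = math.nan
    id_mean_mpa: float = math.nan
    id_max_mpa: float = math.nan
    id_mean_la: float = math.nan
    id_max_la: float = math.nan

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_pct <= 100.0:
            raise ValidationError(f"fraction_pct must be in [0, 100], got {self.fraction_pct}")
        if np.isfinite(self.id_mean) and np.isfinite(self.id_max) and self.id_mean > self.id_max + 1e-12:
            raise ValidationError(f"id_mean ({self.id_mean}) exceeds id_max ({self.id_max})")


@dataclass
class PatientRecord:
    """One subject: group label, references, morphology, compartment features."""

    id: str
    group: str
    refs: ReferenceDensities
    morphology: MorphologicalFeatures
    normal: CompartmentFeatures
    malperfused: CompartmentFeatures
    vessel_fraction_pct: float = math.nan
    subtype: str | None = None


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def measure_reference_density(volume: IodineVolume, roi_mask: np.ndarray, lung_mask: np.ndarray | None = None) -> float:
    """Arithmetic mean iodine density over the ROI voxels (mg/mL)."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != volume.shape:
        raise ValidationError(f"ROI shape {roi_mask.shape} does not match volume shape {volume.shape}")
    if not roi_mask.any():
        raise ValidationError("empty reference ROI")
    if lung_mask is not None and (roi_mask & np.asarray(lung_mask, dtype=bool)).any():
        warnings.warn("reference ROI overlaps the lung mask (physiologically implausible)", stacklevel=2)
    return float(volume.values[roi_mask].mean())


def segment_compartments(volume: IodineVolume, lung_mask: np.ndarray, refs: ReferenceDensities) -> CompartmentMap:
    """Threshold the lung into malperfused / normal / vessel compartments.

    Strict-inequality convention: ID < 0.05*MPA is MALPERFUSED,
    0.05*MPA <= ID < 0.5*LA is NORMAL, ID >= 0.5*LA is VESSEL.
    """
    lung_mask = np.asarray(lung_mask, dtype=bool)
    if lung_mask.shape != volume.shape:
        raise ValidationError(f"lung mask shape {lung_mask.shape} does not match volume shape {volume.shape}")
    lo, hi = refs.malperfusion_threshold, refs.vessel_threshold
    logger.info("segmentation thresholds: malperfusion < %.4g mg/mL, vessel >= %.4g mg/mL", lo, hi)

    labels = np.full(volume.shape, LABEL_OUTSIDE, dtype=np.uint8)
    v = volume.values
    labels[lung_mask & (v < lo)] = LABEL_MALPERFUSED
    labels[lung_mask & (v >= lo) & (v < hi)] = LABEL_NORMAL
    labels[lung_mask & (v >= hi)] = LABEL_VESSEL
    return CompartmentMap(labels=labels)


def compartment_fractions(cmap: CompartmentMap) -> tuple[float, float, float]:
    """(% malperfused, % normal, % vessel) of lung voxels; sums to 100."""
    n_lung = int(cmap.lung_mask.sum())
    if n_lung == 0:
        raise ValidationError("empty lung mask: no voxels to apportion")
    n_mal = int((cmap.labels == LABEL_MALPERFUSED).sum())
    n_norm = int((cmap.labels == LABEL_NORMAL).sum())
    n_ves = int((cmap.labels == LABEL_VESSEL).sum())
    return (100.0 * n_mal / n_lung, 100.0 * n_norm / n_lung, 100.0 * n_ves / n_lung)


def first_order_features(volume: IodineVolume, cmap: CompartmentMap, compartment: int) -> CompartmentFeatures:
    """Raw first-order histogram features of one compartment.

    Skewness and excess kurtosis are reported as NaN for compartments with
    fewer than 2 voxels or zero variance — a 0/0 there has no defensible value.
    """
    mask = cmap.compartment_mask(compartment)
    frac_mal, frac_norm, frac_ves = compartment_fractions(cmap)
    fraction = {LABEL_MALPERFUSED: frac_mal, LABEL_NORMAL: frac_norm, LABEL_VESSEL: frac_ves}.get(compartment)
    if fraction is None:
        raise ValidationError(f"not a lung compartment label: {compartment}")
    x = volume.values[mask]
    if x.size == 0:
        return CompartmentFeatures(fraction_pct=fraction)
    feats = CompartmentFeatures(fraction_pct=fraction, id_mean=float(x.mean()), id_max=float(x.max()))
    if x.size < 2:
        return feats
    centered = x - x.mean()
    m2 = float((centered**2).mean())
    if m2 == 0.0:
        return feats
    m3 = float((centered**3).mean())
    m4 = float((centered**4).mean())
    feats.id_skewness = m3 / m2**1.5
    feats.id_kurtosis = m4 / m2**2 - 3.0
    return feats


def normalize_features(raw: CompartmentFeatures, refs: ReferenceDensities) -> CompartmentFeatures:
    """Fill the four normalized ratios; raw fields are unchanged."""
    return replace(
        raw,
        id_mean_mpa=raw.id_mean / refs.id_mpa,
        id_max_mpa=raw.id_max / refs.id_mpa,
        id_mean_la=raw.id_mean / refs.id_la,
        id_max_la=raw.id_max / refs.id_la,
    )


def extract_patient_features(case: PhantomCase, patient_id: str = "P0001", subtype: str | None = None) -> PatientRecord:
    """Run the full measurement chain on one case and assemble its record."""
    volume = case.volume
    id_mpa = measure_reference_density(volume, case.mpa_roi, case.lung_mask)
    id_la = measure_reference_density(volume, case.la_roi, case.lung_mask)
    refs = ReferenceDensities(id_mpa=id_mpa, id_la=id_la)
    cmap = segment_compartments(volume, case.lung_mask, refs)
    frac_mal, frac_norm, frac_ves = compartment_fractions(cmap)
    logger.info(
        "patient %s: malperfused %.1f%%, normal %.1f%%, vessel %.1f%%",
        patient_id, frac_mal, frac_norm, frac_ves,
    )
    normal = normalize_features(first_order_features(volume, cmap, LABEL_NORMAL), refs)
    malperfused = normalize_features(first_order_features(volume, cmap, LABEL_MALPERFUSED), refs)
    return PatientRecord(
        id=patient_id,
        group=case.group,
        refs=refs,
        morphology=case.morphology,
        normal=normal,
        malperfused=malperfused,
        vessel_fraction_pct=frac_ves,
        subtype=subtype,
    )


def record_to_row(record: PatientRecord) -> dict:
    """Flatten a patient record into one cohort-table row."""
    m = record.morphology
    row = {
        "patient_id": record.id,
        "group": record.group,
        "subtype": record.subtype,
        "id_mpa": record.refs.id_mpa,
        "id_la": record.refs.id_la,
        "mpa_dia": m.mpa_dia,
        "aorta_dia": m.aorta_dia,
        "mpa_aorta_ratio": m.mpa_aorta_ratio,
        "rv_lv_ratio": m.rv_lv_ratio,
        "bronchial_dia": m.bronchial_dia if m.bronchial_dia is not None else math.nan,
    }
    for prefix, feats in (("normal", record.normal), ("malp", record.malperfused)):
        row[f"{prefix}_fraction_pct"] = feats.fraction_pct
        for attr in ("id_mean", "id_max", "id_skewness", "id_kurtosis", "id_mean_mpa", "id_max_mpa", "id_mean_la", "id_max_la"):
            row[f"{prefix}_{attr}"] = getattr(feats, attr)
    row["vessel_fraction_pct"] = record.vessel_fraction_pct
    return row
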