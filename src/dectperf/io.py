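"""Containers and file I/O for the perfusion pipeline.

Volumes and masks travel as NIfTI-1 (``.nii.gz``), cohorts as CSV, study
configuration as YAML and reports as JSON.  The in-memory axis convention is
``(z, y, x)`` = (craniocaudal, ventral-to-dorsal, left-to-right); NIfTI files
are written with an RAS-aligned diagonal affine built from the voxel spacing.

Iodine density is always mg/mL, with no rescale slope/intercept: the number in
the array is the number in the file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "DectperfError",
    "FormatError",
    "ValidationError",
    "ConfigurationError",
    "GROUPS",
    "CTEPH_SUBTYPES",
    "LABEL_OUTSIDE",
    "LABEL_MALPERFUSED",
    "LABEL_NORMAL",
    "LABEL_VESSEL",
    "FEATURE_UNITS",
    "IodineVolume",
    "CohortTable",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "write_labels",
    "read_cohort",
    "write_cohort",
    "read_yaml",
    "write_json_report",
]


class DectperfError(Exception):
    """Base class for all typed errors raised by this package."""


class FormatError(DectperfError):
    """A file does not parse as the expected container."""


class ValidationError(DectperfError):
    """Parsed content violates a domain invariant."""


class ConfigurationError(DectperfError):
    """A configuration references unknown features, groups or parameters."""


GROUPS = ("CONTROL", "APE", "CTEPH")
CTEPH_SUBTYPES = ("cCTEPH", "pCTEPH")

# Label-map codes, fixed so label files are portable across runs.
LABEL_OUTSIDE = 0
LABEL_MALPERFUSED = 1
LABEL_NORMAL = 2
LABEL_VESSEL = 3

#: Column registry: canonical cohort column order and units.
FEATURE_UNITS: Mapping[str, str] = {
    "patient_id": "",
    "group": "",
    "subtype": "",
    "id_mpa": "mg/mL",
    "id_la": "mg/mL",
    "mpa_dia": "mm",
    "aorta_dia": "mm",
    "mpa_aorta_ratio": "",
    "rv_lv_ratio": "",
    "bronchial_dia": "mm",
    "normal_fraction_pct": "%",
    "normal_id_mean": "mg/mL",
    "normal_id_max": "mg/mL",
    "normal_id_skewness": "",
    "normal_id_kurtosis": "",
    "normal_id_mean_mpa": "",
    "normal_id_max_mpa": "",
    "normal_id_mean_la": "",
    "normal_id_max_la": "",
    "malp_fraction_pct": "%",
    "malp_id_mean": "mg/mL",
    "malp_id_max": "mg/mL",
    "malp_id_skewness": "",
    "malp_id_kurtosis": "",
    "malp_id_mean_mpa": "",
    "malp_id_max_mpa": "",
    "malp_id_mean_la": "",
    "malp_id_max_la": "",
    "vessel_fraction_pct": "%",
}

_META_COLUMNS = ("patient_id", "group", "subtype")


@dataclass
class IodineVolume:
    """A 3D iodine-density map in mg/mL with its voxel spacing in mm."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise FormatError(f"iodine volume must be 3D, got {self.values.ndim}D")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValidationError(f"voxel spacing must be three positive values, got {self.spacing_mm}")
        bad = ~np.isfinite(self.values)
        if bad.any():
            raise ValidationError(f"iodine volume contains {int(bad.sum())} non-finite voxel(s)")
        neg = self.values < 0
        if neg.any():
            raise ValidationError(f"iodine volume contains {int(neg.sum())} negative-density voxel(s)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]


def _affine(spacing_mm: tuple[float, float, float]) -> np.ndarray:
    """RAS-aligned diagonal affine; array axes (z, y, x) map to scanner axes."""
    aff = np.diag(list(spacing_mm) + [1.0]).astype(float)
    return aff


def _load_3d(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several flavours
        raise FormatError(f"{path} is not a readable NIfTI image: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D single-channel image, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    return np.asarray(data), tuple(float(z) for z in zooms)


def read_volume(path: str | Path, strict: bool = False) -> IodineVolume:
    """Read an iodine-density volume from NIfTI.

    With ``strict=True`` a volume whose values are all in {0, 1} is rejected as
    a probable mask passed in place of a density map.
    """
    data, spacing = _load_3d(path)
    data = data.astype(np.float64)
    if strict:
        uniq = np.unique(data)
        if uniq.size <= 2 and np.isin(uniq, [0.0, 1.0]).all():
            raise ValidationError(f"{path}: binary {{0,1}} values look like a mask, not an iodine-density map")
    return IodineVolume(values=data, spacing_mm=spacing)


def write_volume(volume: IodineVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(volume.values.astype(np.float64), _affine(volume.spacing_mm))
    img.header.set_zooms(volume.spacing_mm)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask; any nonzero voxel counts as inside."""
    data, _ = _load_3d(path)
    uniq = np.unique(data)
    if not np.isin(uniq, [0, 1]).all():
        raise ValidationError(f"{path}: mask values must be 0/1, found {uniq[:10]}")
    return data.astype(bool)


def write_mask(mask: np.ndarray, spacing_mm: tuple[float, float, float], path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(spacing_mm))
    img.header.set_zooms(spacing_mm)
    nib.save(img, str(path))


def write_labels(labels: np.ndarray, spacing_mm: tuple[float, float, float], path: str | Path) -> None:
    """Write a compartment label map (codes 0..3) as unsigned 8-bit NIfTI."""
    arr = np.asarray(labels)
    if not np.isin(np.unique(arr), [LABEL_OUTSIDE, LABEL_MALPERFUSED, LABEL_NORMAL, LABEL_VESSEL]).all():
        raise ValidationError("label map contains codes outside {0,1,2,3}")
    img = nib.Nifti1Image(arr.astype(np.uint8), _affine(spacing_mm))
    img.header.set_zooms(spacing_mm)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

@dataclass
class CohortTable:
    """Per-patient feature table with one row per patient.

    Wraps a :class:`pandas.DataFrame` whose columns follow the registry in
    :data:`FEATURE_UNITS`; extra numeric columns are allowed and kept in the
    order first seen.  Missing optional features are NaN, never zero.
    """

    data: pd.DataFrame
    units: Mapping[str, str] = field(default_factory=lambda: dict(FEATURE_UNITS))

    def __post_init__(self) -> None:
        df = self.data
        if "patient_id" not in df.columns or "group" not in df.columns:
            raise ValidationError("cohort table requires 'patient_id' and 'group' columns")
        ids = df["patient_id"].astype(str)
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise ValidationError(f"duplicate patient id(s): {dupes}")
        bad_groups = sorted(set(df["group"]) - set(GROUPS))
        if bad_groups:
            raise ValidationError(f"unknown group label(s) {bad_groups}; expected one of {GROUPS}")
        if "subtype" in df.columns:
            has_sub = df["subtype"].notna() & (df["subtype"].astype(str) != "")
            if (has_sub & (df["group"] != "CTEPH")).any():
                raise ValidationError("CTEPH subtype present on a non-CTEPH row")
            bad_sub = sorted(set(df.loc[has_sub, "subtype"]) - set(CTEPH_SUBTYPES))
            if bad_sub:
                raise ValidationError(f"unknown CTEPH subtype(s) {bad_sub}; expected {CTEPH_SUBTYPES}")
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortTable):
            return NotImplemented
        a, b = self.canonical().data, other.canonical().data
        return a.equals(b)

    def feature_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in _META_COLUMNS]

    def canonical(self) -> "CohortTable":
        """Columns in registry order (then extras), rows in patient-id order of appearance."""
        cols = [c for c in FEATURE_UNITS if c in self.data.columns]
        cols += [c for c in self.data.columns if c not in cols]
        return CohortTable(self.data[cols].copy(), units=self.units)

    def subset(self, mask: np.ndarray | pd.Series) -> "CohortTable":
        return CohortTable(self.data.loc[np.asarray(mask)].reset_index(drop=True), units=self.units)


def _format_cell(x: object) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return ""
    if isinstance(x, (float, np.floating)):
        return repr(float(x))  # shortest round-trip representation
    return str(x)


def write_cohort(table: CohortTable, path: str | Path) -> None:
    """Write a cohort CSV with canonical column order and round-trip-stable floats."""
    df = table.canonical().data
    lines = [",".join(df.columns)]
    for _, row in df.iterrows():
        lines.append(",".join(_format_cell(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_cohort(path: str | Path) -> CohortTable:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(
        path,
        dtype={"patient_id": str, "group": str, "subtype": str},
        float_precision="round_trip",
    )
    unknown = [c for c in df.columns if c not in FEATURE_UNITS]
    for c in df.columns:
        if c not in _META_COLUMNS:
            df[c] = pd.to_numeric(df[c], errors="raise")
    units = dict(FEATURE_UNITS)
    for c in unknown:
        units.setdefault(c, "")
    return CohortTable(df, units=units)


# ---------------------------------------------------------------------------
# Config / report
# ---------------------------------------------------------------------------

def read_yaml(path: str | Path) -> dict:
    import yaml

    with open(path) as fh:
        obj = yaml.safe_load(fh)
    if not isinstance(obj, dict):
        raise FormatError(f"{path}: expected a YAML mapping at top level")
    return obj


def write_json_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=False, allow_nan=True) + "\n")
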