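"""Desk-scale study orchestration.

``run_study`` reproduces the published analysis flow end to end: generate (or
load) a cohort, extract per-patient perfusion features in voxel mode, split
80/20 into training and validation, evaluate the configured single markers
(Youden cutoff on training, transferred to validation), fit the two-marker
linear combinations and compare anchor-alone vs combined AUC with the DeLong
test on the same subjects, then emit a machine-readable JSON report plus the
cohort CSV.

The default configuration runs feature-simulation mode with the published
group distributions and the three headline contrasts: malperfused-lung
skewness for disease vs controls, malperfused ID_mean,LA for acute embolism
vs chronic disease, and MPA diameter alone vs combined with ID_mean,LA.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import io as dio
from .cohort_stats import (
    DiagnosticPerformance,
    auc_mann_whitney,
    combine_markers,
    delong_compare,
    evaluate_marker,
    split_cohort,
)
from .io import CohortTable, ConfigurationError, ValidationError, write_json_report
from .perfusion import extract_patient_features, record_to_row
from .phantom import (
    CohortSimParams,
    build_phantom,
    group_phantom_params,
    sample_feature_cohort,
)

logger = logging.getLogger(__name__)

__version__ = "0.1.0"
REPORT_SCHEMA_VERSION = 1

__all__ = ["MarkerAnalysis", "CombinationAnalysis", "StudyConfig", "StudyReport", "run_study", "summarize_cohort", "default_study_config"]


@dataclass(frozen=True)
class MarkerAnalysis:
    """One single-marker contrast: positive/negative sides may pool groups."""

    marker: str
    positive: Any
    negative: Any
    direction: str = "higher"
    name: str | None = None

    @property
    def label(self) -> str:
        return self.name or self.marker


@dataclass(frozen=True)
class CombinationAnalysis:
    """A two-marker linear combination compared against the anchor alone."""

    anchor: str
    second: str
    positive: Any
    negative: Any
    method: str = "logistic"
    name: str | None = None

    @property
    def label(self) -> str:
        return self.name or f"{self.anchor}+{self.second}"


@dataclass
class StudyConfig:
    mode: str = "feature-simulation"  # feature-simulation | voxel-phantom | real-data
    cohort_params: CohortSimParams | None = None
    phantom_counts: dict[str, int] = field(default_factory=lambda: {"CONTROL": 2, "APE": 2, "CTEPH": 2})
    phantom_noise_sd: float = 0.0
    cohort_path: str | None = None  # real-data mode
    analyses: list[MarkerAnalysis] = field(default_factory=list)
    combinations: list[CombinationAnalysis] = field(default_factory=list)
    ratio: float = 0.8
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("feature-simulation", "voxel-phantom", "real-data"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.mode == "real-data" and not self.cohort_path:
            raise ConfigurationError("real-data mode requires cohort_path")

    @classmethod
    def from_dict(cls, obj: dict) -> "StudyConfig":
        obj = dict(obj)
        if "cohort_params" in obj and obj["cohort_params"] is not None:
            cp = dict(obj["cohort_params"])
            if "feature_params" in cp:
                cp["feature_params"] = {
                    f: {g: tuple(v) for g, v in per.items()} for f, per in cp["feature_params"].items()
                }
            if cp.get("correlation") is not None:
                cp["correlation"] = tuple(cp["correlation"])
            obj["cohort_params"] = CohortSimParams(**cp)
        obj["analyses"] = [MarkerAnalysis(**a) for a in obj.get("analyses", [])]
        obj["combinations"] = [CombinationAnalysis(**c) for c in obj.get("combinations", [])]
        return cls(**obj)


def default_study_config(seed: int = 0) -> StudyConfig:
    """The study's headline analyses on a simulated cohort (n = 57/52/22)."""
    return StudyConfig(
        mode="feature-simulation",
        cohort_params=CohortSimParams(seed=seed),
        analyses=[
            MarkerAnalysis(
                marker="malp_id_skewness",
                positive=["APE", "CTEPH"],
                negative=["CONTROL"],
                direction="higher",
                name="malp_id_skewness_disease_vs_control",
            ),
            MarkerAnalysis(marker="malp_id_mean_la", positive="CTEPH", negative="APE"),
            MarkerAnalysis(marker="mpa_dia", positive="CTEPH", negative="APE"),
        ],
        combinations=[
            CombinationAnalysis(anchor="mpa_dia", second="malp_id_mean_la", positive="CTEPH", negative="APE"),
        ],
        seed=seed,
    )


@dataclass
class StudyReport:
    schema_version: int
    provenance: dict
    cohort_summary: dict
    analyses: dict
    combinations: dict

    def to_dict(self) -> dict:
        return asdict(self)


def summarize_cohort(table: CohortTable) -> dict:
    """Per-group mean, SD, n and missing count for every numeric feature."""
    if len(table) == 0:
        raise ValidationError("empty cohort")
    df = table.data
    out: dict[str, dict] = {"n_total": len(df), "groups": {}}
    for group, sub in df.groupby("group", sort=True):
        gsum: dict[str, Any] = {"n": len(sub)}
        feats = {}
        for col in table.feature_columns():
            if col == "subtype":
                continue
            vals = pd.to_numeric(sub[col], errors="coerce")
            n_obs = int(vals.notna().sum())
            feats[col] = {
                "mean": float(vals.mean()) if n_obs else None,
                "sd": float(vals.std(ddof=1)) if n_obs > 1 else None,
                "n": n_obs,
                "n_missing": int(len(sub) - n_obs),
            }
        gsum["features"] = feats
        out["groups"][group] = gsum
    return out


def _build_cohort(config: StudyConfig) -> CohortTable:
    if config.mode == "feature-simulation":
        params = config.cohort_params or CohortSimParams(seed=config.seed)
        return sample_feature_cohort(params)
    if config.mode == "voxel-phantom":
        rows = []
        pid = 0
        rng = np.random.default_rng(config.seed)
        for group in ("APE", "CTEPH", "CONTROL"):
            for _ in range(config.phantom_counts.get(group, 0)):
                pid += 1
                case_seed = int(rng.integers(0, 2**31 - 1))
                params = group_phantom_params(group, seed=case_seed, noise_sd=config.phantom_noise_sd)
                case = build_phantom(params)
                try:
                    record = extract_patient_features(case, patient_id=f"P{pid:04d}")
                except Exception as exc:
                    raise ValidationError(f"feature extraction failed for patient P{pid:04d}: {exc}") from exc
                rows.append(record_to_row(record))
        return CohortTable(pd.DataFrame(rows))
    # real-data
    return dio.read_cohort(config.cohort_path)


def run_study(config: StudyConfig, out_dir: str | Path | None = None) -> StudyReport:
    """Execute the configured study; optionally write report.json + cohort.csv."""
    cohort = _build_cohort(config)
    split = split_cohort(cohort, ratio=config.ratio, seed=config.seed)

    analyses: dict[str, dict] = {}
    for spec in config.analyses:
        try:
            perf_tr, perf_va = evaluate_marker(
                split.train, split.validation, spec.marker, spec.positive, spec.negative,
                direction=spec.direction, alpha=config.alpha,
            )
        except ValidationError as exc:
            raise ValidationError(f"analysis {spec.label!r} failed: {exc}") from exc
        analyses[spec.label] = {
            "marker": spec.marker,
            "positive": spec.positive,
            "negative": spec.negative,
            "train": perf_tr.to_dict(),
            "validation": perf_va.to_dict(),
        }

    combinations: dict[str, dict] = {}
    for spec in config.combinations:
        df = split.train.data
        sel = df["group"].isin(
            ([spec.positive] if isinstance(spec.positive, str) else list(spec.positive))
            + ([spec.negative] if isinstance(spec.negative, str) else list(spec.negative))
        )
        sub = df.loc[sel].dropna(subset=[spec.anchor, spec.second])
        labels = sub["group"].isin([spec.positive] if isinstance(spec.positive, str) else list(spec.positive)).to_numpy()
        a = sub[spec.anchor].to_numpy(dtype=float)
        b = sub[spec.second].to_numpy(dtype=float)
        try:
            combo = combine_markers(a, b, labels, anchor=spec.anchor, second=spec.second, method=spec.method)
        except ValidationError as exc:
            raise ValidationError(f"combination {spec.label!r} failed: {exc}") from exc
        anchor_auc = auc_mann_whitney(a, labels)
        score = combo.score(a, b)
        z, p = delong_compare(score, a, labels, direction=combo.direction)
        combinations[spec.label] = {
            "anchor": spec.anchor,
            "second": spec.second,
            "coef_b": combo.coef_b,
            "intercept": combo.intercept,
            "method": combo.method,
            "direction": combo.direction,
            "anchor_train_auc": float(anchor_auc),
            "combined_train_auc": combo.train_auc,
            "delong_z": z,
            "delong_p": p,
            "n": int(len(sub)),
        }

    config_payload = {
        "mode": config.mode,
        "ratio": config.ratio,
        "alpha": config.alpha,
        "seed": config.seed,
        "analyses": [asdict(a) for a in config.analyses],
        "combinations": [asdict(c) for c in config.combinations],
    }
    config_hash = hashlib.sha256(json.dumps(config_payload, sort_keys=True, default=str).encode()).hexdigest()[:16]
    report = StudyReport(
        schema_version=REPORT_SCHEMA_VERSION,
        provenance={
            "software": "dectperf",
            "version": __version__,
            "seed": config.seed,
            "split_seed": split.seed,
            "config_hash": config_hash,
            "config": config_payload,
        },
        cohort_summary=summarize_cohort(cohort),
        analyses=analyses,
        combinations=combinations,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_json_report(report.to_dict(), out / "report.json")
        dio.write_cohort(cohort, out / "cohort.csv")
        logger.info("wrote %s and %s", out / "report.json", out / "cohort.csv")
    return report
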