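"""Diagnostic-performance statistics for two-group marker comparisons.

Implements the nonparametric toolkit used to judge perfusion markers:

* Mann-Whitney AUC with the standard half-credit tie convention,
* DeLong variance/covariance of correlated AUCs (structural components /
  placement values), giving normal-approximation confidence intervals and the
  paired two-sided DeLong test,
* Youden-index cutoffs (J = sensitivity + specificity - 1) searched over
  midpoints between adjacent distinct scores,
* predictive values from sensitivity/specificity and prevalence,
* Pepe-style linear combination of two markers: a logistic fit rescaled so
  the anchor marker's coefficient is exactly 1, yielding the reportable score
  ``A + b*B + c``; a distribution-free grid search maximizing empirical AUC
  over the coefficient is available as an alternative estimator and as the
  fallback under perfect separation,
* stratified train/validation splitting with cutoff transfer from training
  to validation.

Scores are oriented by ``direction``: with ``"higher"`` larger marker values
indicate the positive class, with ``"lower"`` smaller values do.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

from .io import CohortTable, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "DiagnosticPerformance",
    "LinearMarkerCombination",
    "SplitResult",
    "auc_mann_whitney",
    "delong_variance",
    "delong_ci",
    "delong_compare",
    "youden_cutoff",
    "predictive_values",
    "combine_markers",
    "split_cohort",
    "evaluate_marker",
]

Direction = str  # "higher" (higher-is-positive) or "lower"


def _check_direction(direction: str) -> None:
    if direction not in ("higher", "lower"):
        raise ValidationError(f"direction must be 'higher' or 'lower', got {direction!r}")


def _oriented(scores: np.ndarray, direction: str) -> np.ndarray:
    _check_direction(direction)
    return scores if direction == "higher" else -scores


def _split_classes(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels must have the same length")
    if not np.isfinite(scores).all():
        raise ValidationError("scores contain non-finite values")
    pos, neg = scores[labels], scores[~labels]
    if pos.size == 0 or neg.size == 0:
        raise ValidationError(f"need both classes present, got {pos.size} positive / {neg.size} negative")
    return pos, neg


@dataclass
class DiagnosticPerformance:
    """AUC with CI plus cutoff-based operating characteristics for one marker."""

    auc: float
    ci_low: float
    ci_high: float
    cutoff: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    direction: str
    n_pos: int
    n_neg: int

    def __post_init__(self) -> None:
        _check_direction(self.direction)
        for name in ("sensitivity", "specificity", "ppv", "npv", "auc"):
            v = getattr(self, name)
            if np.isfinite(v) and not 0.0 <= v <= 1.0 + 1e-12:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if np.isfinite(self.auc) and np.isfinite(self.ci_low) and not (self.ci_low <= self.auc + 1e-12 and self.auc <= self.ci_high + 1e-12):
            raise ValidationError(f"CI [{self.ci_low}, {self.ci_high}] does not bracket AUC {self.auc}")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "auc", "ci_low", "ci_high", "cutoff", "sensitivity", "specificity",
            "ppv", "npv", "direction", "n_pos", "n_neg",
        )}


@dataclass
class LinearMarkerCombination:
    """Score rule ``A + coef_b * B + intercept`` with marker A as the anchor."""

    anchor: str
    second: str
    coef_b: float
    intercept: float
    method: str  # "logistic" or "grid"
    train_auc: float
    direction: str = "higher"

    def score(self, values_a, values_b) -> np.ndarray:
        return np.asarray(values_a, dtype=float) + self.coef_b * np.asarray(values_b, dtype=float) + self.intercept


@dataclass
class SplitResult:
    train: CohortTable
    validation: CohortTable
    seed: int
    ratio: float


# ---------------------------------------------------------------------------
# AUC and DeLong
# ---------------------------------------------------------------------------

def auc_mann_whitney(scores, labels, direction: Direction = "higher") -> float:
    """Tie-corrected Mann-Whitney AUC.

    Equals (1/(n+ n-)) * sum over all cross-class pairs of
    [1(s+ > s-) + 0.5 * 1(s+ = s-)] after orienting by ``direction``, and
    equals the trapezoidal area under the empirical ROC curve.
    """
    pos, neg = _split_classes(_oriented(np.asarray(scores, dtype=float), direction), labels)
    n_pos, n_neg = pos.size, neg.size
    ranks = rankdata(np.concatenate([pos, neg]))
    return float((ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def _midrank(x: np.ndarray) -> np.ndarray:
    return rankdata(x, method="average")


def _delong_components(score_matrix: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """AUCs and covariance matrix for k markers scored on the same subjects.

    Uses the structural-component (placement value) formulation: per-subject
    placements V10 (positives) and V01 (negatives), with
    S = cov(V10)/n_pos + cov(V01)/n_neg.
    """
    labels = np.asarray(labels, dtype=bool)
    k = score_matrix.shape[0]
    m = int(labels.sum())
    n = int((~labels).sum())
    if m == 0 or n == 0:
        raise ValidationError("need both classes present")
    aucs = np.empty(k)
    v10 = np.empty((k, m))
    v01 = np.empty((k, n))
    for i in range(k):
        x = score_matrix[i, labels]
        y = score_matrix[i, ~labels]
        tx = _midrank(x)
        ty = _midrank(y)
        tz = _midrank(np.concatenate([x, y]))
        aucs[i] = (tz[:m].sum() / m - (m + 1) / 2.0) / n
        v10[i] = (tz[:m] - tx) / n
        v01[i] = 1.0 - (tz[m:] - ty) / m
    s10 = np.atleast_2d(np.cov(v10, ddof=1)) if m > 1 else np.zeros((k, k))
    s01 = np.atleast_2d(np.cov(v01, ddof=1)) if n > 1 else np.zeros((k, k))
    cov = s10 / m + s01 / n
    return aucs, cov


def delong_variance(scores, labels, direction: Direction = "higher") -> tuple[float, float]:
    """(AUC, DeLong variance of the AUC) for one marker."""
    scores = _oriented(np.asarray(scores, dtype=float), direction)
    labels = np.asarray(labels, dtype=bool)
    _split_classes(scores, labels)
    aucs, cov = _delong_components(scores[None, :], labels)
    return float(aucs[0]), float(cov[0, 0])


def delong_ci(scores, labels, alpha: float = 0.05, direction: Direction = "higher") -> tuple[float, float]:
    """Normal-approximation 95% (or 1-alpha) CI for the AUC, clipped to [0, 1].

    A zero-variance AUC (perfect or fully degenerate marker) yields the
    point CI [auc, auc], flagged with a warning.
    """
    auc, var = delong_variance(scores, labels, direction)
    if var <= 0:
        warnings.warn(f"degenerate DeLong CI: estimated variance is 0 at AUC={auc:.3f}", stacklevel=2)
        return auc, auc
    z = norm.ppf(1 - alpha / 2)
    half = z * math.sqrt(var)
    return max(0.0, auc - half), min(1.0, auc + half)


def delong_compare(scores_a, scores_b, labels, direction: Direction = "higher") -> tuple[float, float]:
    """Two-sided DeLong test for paired AUCs; returns (z, p).

    ``scores_a`` and ``scores_b`` must score the same subjects in the same
    order.  Identical score vectors give z=0, p=1 by definition.
    """
    a = _oriented(np.asarray(scores_a, dtype=float), direction)
    b = _oriented(np.asarray(scores_b, dtype=float), direction)
    labels = np.asarray(labels, dtype=bool)
    if a.shape != b.shape or a.shape != labels.shape:
        raise ValidationError("paired scores must cover the same subjects")
    _split_classes(a, labels)
    if np.array_equal(a, b):
        return 0.0, 1.0
    aucs, cov = _delong_components(np.vstack([a, b]), labels)
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0:
        if math.isclose(aucs[0], aucs[1], abs_tol=1e-12):
            return 0.0, 1.0
        raise ValidationError(
            f"zero estimated variance of the AUC difference with unequal AUCs ({aucs[0]:.4f} vs {aucs[1]:.4f})"
        )
    z = float((aucs[0] - aucs[1]) / math.sqrt(var_diff))
    p = float(2 * norm.sf(abs(z)))
    return z, p


# ---------------------------------------------------------------------------
# Cutoffs and predictive values
# ---------------------------------------------------------------------------

def youden_cutoff(scores, labels, direction: Direction = "higher") -> tuple[float, float, float]:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Candidate thresholds sit midway between adjacent distinct observed scores
    (plus -inf/+inf sentinels); a subject tests positive when its oriented
    score exceeds the oriented cutoff.  Ties in J resolve toward higher
    sensitivity, then toward the lower cutoff on the oriented scale.
    Returns (cutoff on the original scale, sensitivity, specificity).
    """
    raw = np.asarray(scores, dtype=float)
    oriented = _oriented(raw, direction)
    pos, neg = _split_classes(oriented, labels)
    distinct = np.unique(oriented)
    candidates = np.concatenate(([-np.inf], (distinct[:-1] + distinct[1:]) / 2.0, [np.inf]))
    best = None
    for c in candidates:
        se = float((pos > c).mean())
        sp = float((neg <= c).mean())
        j = se + sp - 1.0
        key = (j, se, -c)  # maximize J, then sensitivity, then prefer lower cutoff
        if best is None or key > best[0]:
            best = (key, c, se, sp)
    _, cutoff, se, sp = best
    return (cutoff if direction == "higher" else -cutoff), se, sp


def predictive_values(sensitivity: float, specificity: float, prevalence: float) -> tuple[float, float]:
    """PPV and NPV at a given prevalence via Bayes' rule.

    PPV = se*pi / (se*pi + (1-sp)(1-pi));
    NPV = sp(1-pi) / ((1-se)pi + sp(1-pi)).
    Degenerate denominators yield NaN with a warning.
    """
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"{name} must be in [0, 1], got {v}")
    if not 0.0 < prevalence < 1.0:
        raise ValidationError(f"prevalence must be in (0, 1), got {prevalence}")
    pi = prevalence
    ppv_den = sensitivity * pi + (1 - specificity) * (1 - pi)
    npv_den = (1 - sensitivity) * pi + specificity * (1 - pi)
    ppv = sensitivity * pi / ppv_den if ppv_den > 0 else math.nan
    npv = specificity * (1 - pi) / npv_den if npv_den > 0 else math.nan
    if math.isnan(ppv) or math.isnan(npv):
        warnings.warn("degenerate denominator in predictive values; reporting NaN", stacklevel=2)
    return ppv, npv


def _confusion_rates(scores, labels, cutoff: float, direction: Direction) -> dict:
    oriented = _oriented(np.asarray(scores, dtype=float), direction)
    c = cutoff if direction == "higher" else -cutoff
    labels = np.asarray(labels, dtype=bool)
    pred = oriented > c
    tp = int((pred & labels).sum())
    fp = int((pred & ~labels).sum())
    fn = int((~pred & labels).sum())
    tn = int((~pred & ~labels).sum())
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else math.nan,
        "specificity": tn / (tn + fp) if tn + fp else math.nan,
        "ppv": tp / (tp + fp) if tp + fp else math.nan,
        "npv": tn / (tn + fn) if tn + fn else math.nan,
        "n_pos": tp + fn,
        "n_neg": tn + fp,
    }


# ---------------------------------------------------------------------------
# Marker combination (Pepe-style)
# ---------------------------------------------------------------------------

def _grid_combine(a: np.ndarray, b: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """AUC-maximizing coefficient for score A + b*B over a sign-symmetric grid.

    The grid is scaled by sd(A)/sd(B) so the search covers relative weights
    from negligible to dominant; b=0 (A alone) is always a candidate, and the
    extreme magnitudes approach B alone.  Returns (coef_b, auc).
    """
    sa = a.std() or 1.0
    sb = b.std() or 1.0
    scale = sa / sb
    mags = np.concatenate([[0.0], np.geomspace(1e-3, 1e4, 141) * scale])
    candidates = np.concatenate([mags, -mags[1:]])
    best_b, best_auc = 0.0, -1.0
    for cand in candidates:
        auc = auc_mann_whitney(a + cand * b, labels)
        # prefer higher AUC; among ties the smaller |coefficient|
        if auc > best_auc + 1e-12 or (abs(auc - best_auc) <= 1e-12 and abs(cand) < abs(best_b)):
            best_b, best_auc = float(cand), float(auc)
    return best_b, best_auc


def combine_markers(
    values_a,
    values_b,
    labels,
    anchor: str = "A",
    second: str = "B",
    method: str = "logistic",
) -> LinearMarkerCombination:
    """Combine two markers into the linear score ``A + b*B + c``.

    ``method="logistic"`` fits an unpenalized logistic model on (A, B) and
    divides through by A's coefficient, so the linear predictor becomes a
    score anchored on marker A — the form in which such combinations are
    reported clinically.  ``method="grid"`` searches the coefficient that
    maximizes empirical AUC directly (distribution-free reading of the same
    idea); it is also the automatic fallback when the logistic fit fails by
    perfect separation.  The returned combination never has lower training
    AUC than either marker alone.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if a.shape != b.shape or a.shape != labels.shape:
        raise ValidationError("markers must be complete paired observations over the same subjects")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValidationError("markers contain missing values; drop incomplete rows first")
    _split_classes(a, labels)
    if method not in ("logistic", "grid"):
        raise ValidationError(f"method must be 'logistic' or 'grid', got {method!r}")

    auc_a = auc_mann_whitney(a, labels)
    auc_b = auc_mann_whitney(b, labels)
    best_single = max(auc_a, auc_b)

    coef_b = intercept = None
    used = method
    if method == "logistic":
        import statsmodels.api as sm

        X = sm.add_constant(np.column_stack([a, b]))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(labels.astype(float), X).fit(disp=0, maxiter=200)
            beta0, beta_a, beta_b = fit.params
            if not np.isfinite([beta0, beta_a, beta_b]).all():
                raise ValueError("non-finite logistic coefficients")
            if not fit.mle_retvals.get("converged", True):
                # perfect separation drives the MLE to infinity without converging
                raise ValueError("logistic fit did not converge (likely perfect separation)")
            scale = max(abs(beta_a), abs(beta_b), abs(beta0), 1.0)
            if abs(beta_a) < 1e-10 * scale:
                raise ValidationError(
                    f"anchor marker {anchor!r} has a near-zero fitted coefficient; anchor on {second!r} instead"
                )
            coef_b = float(beta_b / beta_a)
            intercept = float(beta0 / beta_a)
        except ValidationError:
            raise
        except Exception as exc:  # perfect separation or non-convergence
            logger.info("logistic combination failed (%s); falling back to AUC grid search", exc)
            used = "grid"

    if used == "grid" or coef_b is None:
        used = "grid"
        coef_b, _ = _grid_combine(a, b, labels)
        score = a + coef_b * b
        # report an intercept that centres the decision point at 0
        cutoff, _, _ = youden_cutoff(score, labels)
        intercept = -cutoff if np.isfinite(cutoff) else 0.0

    score = a + coef_b * b + intercept
    auc_hi = auc_mann_whitney(score, labels)
    direction = "higher" if auc_hi >= 1 - auc_hi else "lower"
    combined_auc = max(auc_hi, 1 - auc_hi)

    if combined_auc < best_single - 1e-9:
        # the logistic direction can be beaten by the empirical search; take it
        grid_b, grid_auc = _grid_combine(a, b, labels)
        if grid_auc > combined_auc:
            coef_b, combined_auc, used, direction = grid_b, grid_auc, "grid", "higher"
            cutoff, _, _ = youden_cutoff(a + coef_b * b, labels)
            intercept = -cutoff if np.isfinite(cutoff) else 0.0
    if combined_auc < best_single - 1e-9:
        raise ValidationError(
            f"combined training AUC {combined_auc:.4f} fell below the best single marker {best_single:.4f}"
        )
    return LinearMarkerCombination(
        anchor=anchor, second=second, coef_b=coef_b, intercept=intercept,
        method=used, train_auc=float(combined_auc), direction=direction,
    )


# ---------------------------------------------------------------------------
# Splitting and marker evaluation
# ---------------------------------------------------------------------------

def split_cohort(table: CohortTable, ratio: float = 0.8, seed: int = 0, stratify_by: str = "group") -> SplitResult:
    """Stratified random train/validation split.

    Each stratum contributes round(ratio*n) patients to training; the split
    is disjoint, exhaustive and deterministic given the seed.
    """
    if not 0.0 < ratio < 1.0:
        raise ValidationError(f"ratio must be in (0, 1), got {ratio}")
    df = table.data
    if stratify_by not in df.columns:
        raise ValidationError(f"stratification column {stratify_by!r} not in the cohort")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    val_idx: list[int] = []
    for stratum, sub in df.groupby(stratify_by, sort=True):
        n = len(sub)
        if n < 2:
            raise ValidationError(f"stratum {stratum!r} has only {n} member(s); need at least 2 to split")
        n_train = int(math.floor(ratio * n + 0.5))
        n_train = min(max(n_train, 1), n - 1)  # both sides non-empty
        perm = rng.permutation(n)
        idx = sub.index.to_numpy()
        train_idx.extend(idx[perm[:n_train]])
        val_idx.extend(idx[perm[n_train:]])
    train = CohortTable(df.loc[sorted(train_idx)].reset_index(drop=True), units=table.units)
    val = CohortTable(df.loc[sorted(val_idx)].reset_index(drop=True), units=table.units)
    return SplitResult(train=train, validation=val, seed=seed, ratio=ratio)


def _as_groups(side) -> list[str]:
    return [side] if isinstance(side, str) else list(side)


def _marker_arrays(table: CohortTable, marker: str, positive_group, negative_group):
    """Marker values and positive-class indicators for a two-sided contrast.

    Either side may be one group name or a list of group names (pooled)."""
    df = table.data
    pos_groups = _as_groups(positive_group)
    neg_groups = _as_groups(negative_group)
    present_groups = set(df["group"])
    for g in pos_groups + neg_groups:
        if g not in present_groups:
            raise ValidationError(f"group {g!r} absent from the cohort")
    if marker not in df.columns:
        raise ValidationError(f"marker {marker!r} not in the cohort")
    sub = df.loc[df["group"].isin(pos_groups + neg_groups)]
    present = sub[marker].notna()
    dropped = int((~present).sum())
    if dropped:
        logger.info("marker %s: dropped %d row(s) with missing values", marker, dropped)
    sub = sub.loc[present]
    return sub[marker].to_numpy(dtype=float), sub["group"].isin(pos_groups).to_numpy()


def evaluate_marker(
    train: CohortTable,
    validation: CohortTable,
    marker: str,
    positive_group,
    negative_group,
    direction: Direction = "higher",
    alpha: float = 0.05,
) -> tuple[DiagnosticPerformance, DiagnosticPerformance]:
    """Evaluate one marker: Youden cutoff on training, transferred unchanged
    to validation; AUC with DeLong CI on each set; predictive values from the
    confusion counts of the set being reported (so validation PPV/NPV use the
    validation prevalence)."""
    s_tr, y_tr = _marker_arrays(train, marker, positive_group, negative_group)
    s_va, y_va = _marker_arrays(validation, marker, positive_group, negative_group)

    cutoff, _, _ = youden_cutoff(s_tr, y_tr, direction)

    def _performance(scores, labels) -> DiagnosticPerformance:
        rates = _confusion_rates(scores, labels, cutoff, direction)
        single_class = labels.all() or not labels.any()
        if single_class:
            auc = ci_low = ci_high = math.nan
        else:
            auc = auc_mann_whitney(scores, labels, direction)
            ci_low, ci_high = delong_ci(scores, labels, alpha, direction)
        return DiagnosticPerformance(
            auc=auc, ci_low=ci_low, ci_high=ci_high, cutoff=float(cutoff),
            direction=direction, **rates,
        )

    return _performance(s_tr, y_tr), _performance(s_va, y_va)
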