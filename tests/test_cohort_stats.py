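import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from dectperf import (
    CohortTable,
    ValidationError,
    auc_mann_whitney,
    combine_markers,
    delong_ci,
    delong_compare,
    evaluate_marker,
    predictive_values,
    split_cohort,
    youden_cutoff,
)
from dectperf.cohort_stats import delong_variance

from conftest import auc_by_pair_counting


# ---------------------------------------------------------------------------
# Mann-Whitney AUC
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "pos, neg, expected",
    [
        ([3], [1, 2], 1.0),           # perfect separation
        ([1, 1], [1, 1, 1], 0.5),     # ties only
        ([3, 1, 2], [2, 0], 4.5 / 6), # mixed, half-credit ties
    ],
)
def test_auc_known_values(pos, neg, expected):
    scores = np.array(pos + neg, dtype=float)
    labels = np.array([True] * len(pos) + [False] * len(neg))
    assert auc_mann_whitney(scores, labels) == pytest.approx(expected, abs=1e-12)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    pos=st.lists(st.integers(-5, 5), min_size=1, max_size=10),
    neg=st.lists(st.integers(-5, 5), min_size=1, max_size=10),
)
def test_auc_equals_exhaustive_pair_counting(pos, neg):
    """Rank-based estimator vs brute-force pair enumeration on <= 20 subjects."""
    scores = np.array(pos + neg, dtype=float)
    labels = np.array([True] * len(pos) + [False] * len(neg))
    assert auc_mann_whitney(scores, labels) == pytest.approx(auc_by_pair_counting(pos, neg), abs=1e-12)
    # flipping the direction complements the AUC exactly, ties included
    flipped = auc_mann_whitney(scores, labels, direction="lower")
    assert flipped == pytest.approx(1.0 - auc_mann_whitney(scores, labels), abs=1e-12)


def test_auc_single_class_errors():
    with pytest.raises(ValidationError, match="both classes"):
        auc_mann_whitney([1.0, 2.0], [True, True])


# ---------------------------------------------------------------------------
# DeLong
# ---------------------------------------------------------------------------

def _simulated_marker(seed, n_pos=20, n_neg=20, shift=1.0):
    rng = np.random.default_rng(seed)
    scores = np.concatenate([rng.normal(shift, 1, n_pos), rng.normal(0, 1, n_neg)])
    labels = np.array([True] * n_pos + [False] * n_neg)
    return scores, labels


def test_delong_self_comparison_is_null():
    scores, labels = _simulated_marker(0)
    assert delong_compare(scores, scores, labels) == (0.0, 1.0)


def test_perfect_marker_gives_degenerate_point_ci():
    scores = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
    labels = np.array([False] * 3 + [True] * 3)
    with pytest.warns(UserWarning, match="degenerate"):
        lo, hi = delong_ci(scores, labels)
    assert (lo, hi) == (1.0, 1.0)


def test_delong_se_matches_bootstrap_at_n40():
    scores, labels = _simulated_marker(1, 20, 20, shift=1.0)
    _, var = delong_variance(scores, labels)
    se_delong = math.sqrt(var)
    rng = np.random.default_rng(2)
    pos, neg = scores[labels], scores[~labels]
    boot = np.empty(2000)
    for i in range(2000):
        bp = rng.choice(pos, pos.size, replace=True)
        bn = rng.choice(neg, neg.size, replace=True)
        s = np.concatenate([bp, bn])
        boot[i] = auc_mann_whitney(s, labels)
    se_boot = boot.std(ddof=1)
    assert abs(se_delong - se_boot) / se_boot < 0.15


def test_delong_variance_against_hanley_mcneil_exponential_model():
    # Exponential scores: neg ~ Exp(1), pos ~ Exp(1/theta); AUC = theta/(1+theta)
    rng = np.random.default_rng(3)
    m = n = 100
    pos = rng.exponential(3.0, m)
    neg = rng.exponential(1.0, n)
    scores = np.concatenate([pos, neg])
    labels = np.array([True] * m + [False] * n)
    auc, var = delong_variance(scores, labels)
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var_hm = (auc * (1 - auc) + (m - 1) * (q1 - auc**2) + (n - 1) * (q2 - auc**2)) / (m * n)
    assert abs(var - var_hm) / var_hm < 0.20


def test_delong_compare_detects_dominant_marker():
    rng = np.random.default_rng(4)
    n = 150
    labels = np.array([True] * n + [False] * n)
    signal = np.concatenate([rng.normal(1.5, 1, n), rng.normal(0, 1, n)])
    noise = rng.normal(0, 1, 2 * n)
    z, p = delong_compare(signal, noise, labels)
    assert z > 2 and p < 0.05


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not available")
def test_delong_matches_pROC_reference(tmp_path):
    """Cross-check CI and paired test against the pROC implementation in R."""
    rng = np.random.default_rng(5)
    n_pos, n_neg = 15, 15
    labels = np.array([True] * n_pos + [False] * n_neg)
    a = np.concatenate([rng.normal(1, 1, n_pos), rng.normal(0, 1, n_neg)])
    b = 0.5 * a + rng.normal(0, 1, 2 * n_pos)
    df = pd.DataFrame({"y": labels.astype(int), "a": a, "b": b})
    csv = tmp_path / "d.csv"
    df.to_csv(csv, index=False)
    rcode = f"""
    suppressMessages(library(pROC))
    d <- read.csv("{csv}")
    ra <- roc(d$y, d$a, direction="<", quiet=TRUE)
    ci <- ci.auc(ra, method="delong")
    tt <- roc.test(ra, roc(d$y, d$b, direction="<", quiet=TRUE), method="delong", paired=TRUE)
    cat(ci[1], ci[3], tt$statistic, tt$p.value, sep="\\n")
    """
    out = subprocess.run(["Rscript", "-e", rcode], capture_output=True, text=True, check=True)
    r_lo, r_hi, r_z, r_p = (float(x) for x in out.stdout.split())
    lo, hi = delong_ci(a, labels)
    z, p = delong_compare(a, b, labels)
    assert lo == pytest.approx(r_lo, abs=1e-6)
    assert hi == pytest.approx(r_hi, abs=1e-6)
    assert abs(z) == pytest.approx(abs(r_z), abs=1e-6)
    assert p == pytest.approx(r_p, abs=1e-6)


# ---------------------------------------------------------------------------
# Youden cutoff
# ---------------------------------------------------------------------------

def _youden_brute(scores, labels):
    """Oracle: scan every achievable dichotomy of 'score > c'."""
    pos = scores[labels]
    neg = scores[~labels]
    best = -2.0
    for c in np.concatenate(([-np.inf], np.unique(scores))):
        j = (pos > c).mean() + (neg <= c).mean() - 1.0
        best = max(best, j)
    return best


def test_youden_perfectly_separated():
    scores = np.array([5.0, 4.0, 3.0, 2.0, 2.0, 1.0])
    labels = np.array([True] * 3 + [False] * 3)
    cutoff, se, sp = youden_cutoff(scores, labels)
    assert (cutoff, se, sp) == (2.5, 1.0, 1.0)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    scores=st.lists(st.integers(0, 6), min_size=2, max_size=12),
    flags=st.lists(st.booleans(), min_size=2, max_size=12),
)
def test_youden_midpoint_search_attains_global_maximum(scores, flags):
    n = min(len(scores), len(flags))
    scores = np.array(scores[:n], dtype=float)
    labels = np.array(flags[:n])
    if labels.all() or not labels.any():
        return
    cutoff, se, sp = youden_cutoff(scores, labels)
    assert se + sp - 1.0 == pytest.approx(_youden_brute(scores, labels), abs=1e-12)


def test_youden_direction_lower():
    # positives have LOW scores
    scores = np.array([1.0, 2.0, 5.0, 6.0])
    labels = np.array([True, True, False, False])
    cutoff, se, sp = youden_cutoff(scores, labels, direction="lower")
    assert se == 1.0 and sp == 1.0
    assert cutoff == pytest.approx(3.5)


def test_youden_binormal_cutoff_converges_to_equal_density_point():
    # at large n the empirical Youden cutoff of two Gaussians approaches the
    # point where the two fitted densities cross (~0.0346 for the malperfused
    # mean-LA parameters 0.028/0.012 vs 0.040/0.016)
    from scipy.optimize import brentq

    m1, s1, m2, s2 = 0.028, 0.012, 0.040, 0.016
    cross = brentq(lambda x: norm.pdf(x, m1, s1) - norm.pdf(x, m2, s2), m1, m2)
    rng = np.random.default_rng(6)
    n = 100_000
    scores = np.concatenate([rng.normal(m2, s2, n), rng.normal(m1, s1, n)])
    labels = np.array([True] * n + [False] * n)
    cutoff, _, _ = youden_cutoff(scores, labels)
    assert cutoff == pytest.approx(cross, abs=0.002)


# ---------------------------------------------------------------------------
# Predictive values
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "se, sp, prev, expected",
    [
        (1.0, 1.0, 0.3, (1.0, 1.0)),
        (0.5, 0.5, 0.5, (0.5, 0.5)),
        (0.74, 0.64, 52 / 109, (0.652, 0.730)),
    ],
)
def test_predictive_values_formula(se, sp, prev, expected):
    ppv, npv = predictive_values(se, sp, prev)
    assert ppv == pytest.approx(expected[0], abs=0.001)
    assert npv == pytest.approx(expected[1], abs=0.001)


def test_predictive_values_degenerate_denominator_is_nan():
    with pytest.warns(UserWarning, match="degenerate"):
        ppv, _ = predictive_values(0.0, 1.0, 0.5)
    assert math.isnan(ppv)


# ---------------------------------------------------------------------------
# Marker combination
# ---------------------------------------------------------------------------

def test_pure_noise_second_marker_changes_auc_little():
    rng = np.random.default_rng(7)
    n = 5000
    labels = np.array([True] * n + [False] * n)
    a = np.concatenate([rng.normal(1, 1, n), rng.normal(0, 1, n)])
    b = rng.normal(0, 1, 2 * n)
    combo = combine_markers(a, b, labels)
    assert abs(combo.train_auc - auc_mann_whitney(a, labels)) < 0.01
    assert abs(combo.coef_b) < 0.1


def test_combination_recovers_fisher_discriminant_direction():
    rng = np.random.default_rng(8)
    n = 100_000
    sigma = np.array([[1.0, 0.4], [0.4, 2.0]])
    delta = np.array([0.8, 0.5])
    chol = np.linalg.cholesky(sigma)
    neg = rng.standard_normal((n, 2)) @ chol.T
    pos = rng.standard_normal((n, 2)) @ chol.T + delta
    x = np.vstack([pos, neg])
    labels = np.array([True] * n + [False] * n)
    combo = combine_markers(x[:, 0], x[:, 1], labels)
    w = np.linalg.solve(sigma, delta)
    expected_b = w[1] / w[0]
    assert combo.coef_b == pytest.approx(expected_b, rel=0.05)


def test_logistic_and_grid_variants_agree_on_binormal_data():
    rng = np.random.default_rng(9)
    n = 20_000
    sigma = np.array([[1.0, 0.0], [0.0, 1.5]])
    delta = np.array([0.7, 0.6])
    chol = np.linalg.cholesky(sigma)
    neg = rng.standard_normal((n, 2)) @ chol.T
    pos = rng.standard_normal((n, 2)) @ chol.T + delta
    x = np.vstack([pos, neg])
    labels = np.array([True] * n + [False] * n)
    logi = combine_markers(x[:, 0], x[:, 1], labels, method="logistic")
    grid = combine_markers(x[:, 0], x[:, 1], labels, method="grid")
    assert grid.train_auc == pytest.approx(logi.train_auc, abs=0.01)
    assert grid.coef_b == pytest.approx(logi.coef_b, rel=0.10)


def test_perfect_separation_falls_back_to_grid():
    a = np.array([0.0, 1.0, 2.0, 10.0, 11.0, 12.0])
    b = np.array([0.3, 0.1, 0.2, 0.9, 0.8, 1.0])
    labels = np.array([False] * 3 + [True] * 3)
    combo = combine_markers(a, b, labels)
    assert combo.method == "grid"
    assert combo.train_auc == 1.0


def test_combined_auc_never_below_either_single_marker():
    rng = np.random.default_rng(10)
    for trial in range(20):
        n = 30
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            continue
        a = rng.normal(labels.astype(float), 1.0)
        b = rng.normal(0.5 * labels.astype(float), 1.0)
        combo = combine_markers(a, b, labels)
        assert combo.train_auc >= max(auc_mann_whitney(a, labels), auc_mann_whitney(b, labels)) - 1e-9


# ---------------------------------------------------------------------------
# Splitting and marker evaluation
# ---------------------------------------------------------------------------

def _cohort(groups_and_sizes, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    pid = 0
    for g, n in groups_and_sizes.items():
        for _ in range(n):
            pid += 1
            rows.append({"patient_id": f"P{pid}", "group": g, "m": rng.normal()})
    return CohortTable(pd.DataFrame(rows))


def test_split_sizes_follow_rounded_ratio():
    res = split_cohort(_cohort({"APE": 10}), ratio=0.8, seed=1)
    assert (len(res.train), len(res.validation)) == (8, 2)
    res = split_cohort(_cohort({"APE": 57, "CTEPH": 52}), ratio=0.8, seed=1)
    tr = res.train.data["group"].value_counts()
    assert tr["APE"] == 46 and tr["CTEPH"] == 42


def test_split_is_disjoint_exhaustive_and_deterministic():
    table = _cohort({"APE": 13, "CTEPH": 9, "CONTROL": 5})
    res1 = split_cohort(table, seed=3)
    res2 = split_cohort(table, seed=3)
    ids_tr = set(res1.train.data["patient_id"])
    ids_va = set(res1.validation.data["patient_id"])
    assert ids_tr.isdisjoint(ids_va)
    assert ids_tr | ids_va == set(table.data["patient_id"])
    assert set(res2.train.data["patient_id"]) == ids_tr


def test_split_singleton_stratum_errors_with_name():
    with pytest.raises(ValidationError, match="CONTROL"):
        split_cohort(_cohort({"APE": 10, "CONTROL": 1}))


def test_evaluate_marker_perfect_toy_set():
    df = pd.DataFrame({
        "patient_id": [f"P{i}" for i in range(8)],
        "group": ["CTEPH"] * 4 + ["APE"] * 4,
        "m": [10.0, 11, 12, 13, 1, 2, 3, 4],
    })
    table = CohortTable(df)
    perf_tr, perf_va = evaluate_marker(table, table, "m", "CTEPH", "APE")
    assert perf_tr.auc == 1.0 and perf_va.auc == 1.0
    assert perf_tr.cutoff == perf_va.cutoff
    assert perf_tr.sensitivity == 1.0 and perf_tr.specificity == 1.0


def test_evaluate_marker_direction_flip_complements_auc(default_cohort):
    res = split_cohort(default_cohort, seed=2)
    hi_tr, _ = evaluate_marker(res.train, res.validation, "malp_id_mean_la", "CTEPH", "APE", "higher")
    lo_tr, _ = evaluate_marker(res.train, res.validation, "malp_id_mean_la", "CTEPH", "APE", "lower")
    assert lo_tr.auc == pytest.approx(1.0 - hi_tr.auc, abs=1e-12)
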