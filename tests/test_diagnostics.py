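"""Diagnostic statistics: 2x2 metrics, exact tests, logistic regression,
ROC threshold selection and the association screen, each checked against an
independent oracle where one exists."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bromolb import (ContingencyTable2x2, SeparationError, ValidationError,
                     association_screen, build_table, diagnostic_metrics,
                     fisher_exact, logistic_fit, mann_whitney_u,
                     phi_coefficient, roc_analysis)


def table_to_vectors(t: ContingencyTable2x2):
    test = np.r_[np.ones(t.tp), np.zeros(t.fn), np.ones(t.fp), np.zeros(t.tn)]
    outcome = np.r_[np.ones(t.tp + t.fn), np.zeros(t.fp + t.tn)]
    return test, outcome


def fisher_enumeration(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher p by full enumeration of fixed-margin tables."""
    row1, col1, n = t.tp + t.fn, t.tp + t.fp, t.total
    pmf = stats.hypergeom(n, row1, col1).pmf
    p_obs = pmf(t.tp)
    total = 0.0
    for a in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        pa = pmf(a)
        if pa <= p_obs * (1 + 1e-9):
            total += pa
    return float(min(total, 1.0))


# ---------------------------------------------------------------------------
# tables and 2x2 metrics
# ---------------------------------------------------------------------------

def test_build_table_cross_tabulates():
    df = pd.DataFrame({"case_id": list("abcd"),
                       "test": [True, False, True, False],
                       "outcome": [True, True, False, False]})
    t = build_table(df, "outcome", "test")
    assert (t.tp, t.fn, t.fp, t.tn) == (1, 1, 1, 1)


def test_build_table_from_reconstructed_counts():
    test, outcome = table_to_vectors(ContingencyTable2x2(27, 6, 5, 34))
    df = pd.DataFrame({"case_id": range(72), "pos": test.astype(bool),
                       "ptx": outcome.astype(bool)})
    t = build_table(df, "ptx", "pos")
    assert (t.tp, t.fn, t.fp, t.tn) == (27, 6, 5, 34)


def test_build_table_error_paths():
    with pytest.raises(ValidationError):
        build_table(pd.DataFrame(columns=["a", "b"]), "a", "b")
    df = pd.DataFrame({"case_id": ["k1", "k2"], "a": [True, None],
                       "b": [True, False]})
    with pytest.raises(ValidationError, match="k2"):
        build_table(df, "a", "b")


def test_diagnostic_metrics_values():
    m = diagnostic_metrics(ContingencyTable2x2(27, 6, 5, 34))
    assert m.sensitivity == pytest.approx(27 / 33)
    assert m.specificity == pytest.approx(34 / 39)
    assert m.auc == pytest.approx((27 / 33 + 34 / 39) / 2)
    assert m.phi == pytest.approx(0.692, abs=5e-4)
    assert m.false_negatives == 6
    perfect = diagnostic_metrics(ContingencyTable2x2(1, 0, 0, 1))
    assert (perfect.sensitivity, perfect.specificity, perfect.phi) == (1.0, 1.0, 1.0)
    assert phi_coefficient(ContingencyTable2x2(28, 5, 14, 25)) == pytest.approx(0.495, abs=5e-4)
    with pytest.raises(ValidationError):
        diagnostic_metrics(ContingencyTable2x2(0, 0, 3, 4))


def test_phi_equals_pearson_of_binary_encodings():
    # exhaustive for small totals, random sample up to total 50
    tables = [(a, b, c, d)
              for a, b, c, d in itertools.product(range(7), repeat=4)
              if 1 <= a + b + c + d <= 12]
    r = np.random.default_rng(0)
    extra = r.integers(0, 14, size=(300, 4))
    tables += [tuple(row) for row in extra if 1 <= row.sum() <= 50]
    checked = 0
    for a, b, c, d in tables:
        t = ContingencyTable2x2(a, b, c, d)
        test, outcome = table_to_vectors(t)
        if len(np.unique(test)) < 2 or len(np.unique(outcome)) < 2:
            continue  # degenerate margin: correlation undefined
        checked += 1
        assert phi_coefficient(t) == pytest.approx(
            np.corrcoef(test, outcome)[0, 1], abs=1e-12)
    assert checked > 1000


# ---------------------------------------------------------------------------
# exact tests
# ---------------------------------------------------------------------------

def test_fisher_exact_values_and_enumeration():
    assert fisher_exact(ContingencyTable2x2(5, 5, 5, 5)) == pytest.approx(1.0)
    p = fisher_exact(ContingencyTable2x2(10, 0, 0, 10))
    from math import comb
    assert p == pytest.approx(2.0 / comb(20, 10), rel=1e-9)
    assert fisher_exact(ContingencyTable2x2(27, 6, 5, 34)) < 0.001
    r = np.random.default_rng(1)
    n_checked = 0
    while n_checked < 150:
        a, b, c, d = r.integers(0, 11, size=4)
        if not 1 <= a + b + c + d <= 40:
            continue
        t = ContingencyTable2x2(int(a), int(b), int(c), int(d))
        assert fisher_exact(t) == pytest.approx(fisher_enumeration(t), abs=1e-9)
        n_checked += 1


def test_mann_whitney_examples():
    u, p = mann_whitney_u([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
    assert u == 0.0
    assert p == pytest.approx(0.1)        # 2 / C(6,3)
    _, p_same = mann_whitney_u(np.arange(30.0), np.arange(30.0))
    assert p_same == pytest.approx(1.0)
    with pytest.raises(ValidationError):
        mann_whitney_u([], [1.0])


def test_mann_whitney_detects_shift():
    hits = 0
    for seed in range(20):
        r = np.random.default_rng(seed)
        a = r.normal(0, 1, 200)
        b = r.normal(1.0, 1, 200)
        hits += mann_whitney_u(a, b)[1] < 0.01
    assert hits == 20


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

def test_logistic_saturated_2x2_matches_cross_product_ratio():
    test, outcome = table_to_vectors(ContingencyTable2x2(27, 6, 5, 34))
    fit = logistic_fit(test, outcome, names=["pos"])
    assert fit.odds_ratios[1] == pytest.approx(27 * 34 / (6 * 5), rel=1e-6)
    assert np.exp(fit.coef[1]) == fit.odds_ratios[1]
    assert np.allclose(fit.ci_low, np.exp(fit.coef - 1.96 * fit.se))
    assert fit.cohens_f2 == pytest.approx(fit.nagelkerke_r2 / (1 - fit.nagelkerke_r2))


def test_logistic_null_recovery():
    r = np.random.default_rng(2)
    X = r.normal(size=(3000, 2))
    y = r.random(3000) < 0.3
    fit = logistic_fit(X, y.astype(int))
    for i in (1, 2):
        assert fit.ci_low[i] <= 1.0 <= fit.ci_high[i]


def test_logistic_separation_raises():
    x = np.r_[np.zeros(20), np.ones(20)]
    y = x.copy()
    with pytest.raises(SeparationError):
        logistic_fit(x, y)


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def brute_force_optima(values, outcomes, thresholds):
    """Exhaustive Youden / top-left search over every candidate threshold."""
    v, y = np.asarray(values), np.asarray(outcomes, bool)
    best_j, best_d = -np.inf, np.inf
    th_j = th_d = None
    sp_j = sp_d = -1.0
    for t in thresholds:
        pos = v <= t
        se = (pos & y).sum() / y.sum()
        sp = (~pos & ~y).sum() / (~y).sum()
        j = se + sp - 1
        d = np.hypot(1 - se, 1 - sp)
        if j > best_j + 1e-12 or (abs(j - best_j) <= 1e-12 and sp > sp_j):
            best_j, th_j, sp_j = j, t, sp
        if best_d - d > 1e-12 or (abs(d - best_d) <= 1e-12 and sp > sp_d):
            best_d, th_d, sp_d = d, t, sp
    return th_j, th_d


def test_roc_perfect_separation():
    values = np.r_[np.full(10, -900.0), np.full(10, -700.0)]
    outcomes = np.r_[np.ones(10, bool), np.zeros(10, bool)]
    r = roc_analysis(values, outcomes)
    assert r.auc == pytest.approx(1.0)
    assert r.youden_threshold == pytest.approx(-800.0)
    assert r.top_left_threshold == pytest.approx(-800.0)


def test_roc_null_auc_near_half():
    r0 = np.random.default_rng(3)
    values = r0.normal(-800, 100, 1000)
    outcomes = r0.random(1000) < 0.4
    r = roc_analysis(values, outcomes)
    assert abs(r.auc - 0.5) < 0.06


def test_roc_optima_match_exhaustive_search(rng):
    values = rng.normal(-800, 120, 300)
    outcomes = rng.random(300) < 1 / (1 + np.exp((values + 820) / 40.0))
    if outcomes.all() or not outcomes.any():
        pytest.skip("degenerate draw")
    r = roc_analysis(values, outcomes)
    th_j, th_d = brute_force_optima(values, outcomes, r.thresholds)
    assert r.youden_threshold == pytest.approx(th_j)
    assert r.top_left_threshold == pytest.approx(th_d)


def test_roc_agrees_with_sklearn_auc(rng):
    from sklearn.metrics import roc_auc_score
    values = rng.normal(-800, 120, 400)
    outcomes = rng.random(400) < 1 / (1 + np.exp((values + 800) / 50.0))
    r = roc_analysis(values, outcomes)
    assert r.auc == pytest.approx(roc_auc_score(outcomes, -values), abs=1e-9)


def test_binary_score_auc_identity():
    t = ContingencyTable2x2(27, 6, 5, 34)
    test, outcome = table_to_vectors(t)
    # two-valued score: positive call encoded as a LOWER density
    score = np.where(test > 0, -900.0, -700.0)
    r = roc_analysis(score, outcome.astype(bool))
    m = diagnostic_metrics(t)
    assert r.auc == pytest.approx(m.auc)


def test_roc_rejects_single_class():
    with pytest.raises(ValidationError):
        roc_analysis([1.0, 2.0], [True, True])


# ---------------------------------------------------------------------------
# association screen
# ---------------------------------------------------------------------------

def test_association_screen_structure():
    r = np.random.default_rng(4)
    n = 1000
    x = r.normal(size=n)
    df = pd.DataFrame({
        "case_id": range(n),
        "cont_a": x,
        "cont_twin": x + r.normal(0, 0.05, n),   # near-duplicate of cont_a
        "cont_b": r.normal(size=n),
        "bin_a": r.random(n) < 0.4,
        "pneumothorax": r.random(n) < 0.3,
    })
    rep = association_screen(df)
    assert rep.spearman.loc["cont_a", "cont_a"] == pytest.approx(1.0)
    assert rep.spearman.loc["cont_a", "cont_twin"] > 0.95
    assert any({"cont_a", "cont_twin"} <= set(g) for g in rep.high_correlation_groups)
    # independent columns show only small associations
    assert abs(rep.pearson_with_outcome["cont_b"]) < 0.2
    assert rep.max_predictors_rule_of_ten == min(
        df.pneumothorax.sum(), (~df.pneumothorax).sum()) // 10
    assert len(rep.selected_predictors) <= rep.max_predictors_rule_of_ten


def test_association_screen_phi_equals_pearson_encoding():
    test, outcome = table_to_vectors(ContingencyTable2x2(27, 6, 5, 34))
    df = pd.DataFrame({"case_id": range(72), "pos": test.astype(bool),
                       "pneumothorax": outcome.astype(bool)})
    rep = association_screen(df)
    assert rep.selected_predictors == ["pos"]
    t = build_table(df, "pneumothorax", "pos")
    assert phi_coefficient(t) == pytest.approx(np.corrcoef(test, outcome)[0, 1])
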