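"""ROC curves, Mann–Whitney AUC, Youden midpoint cutoffs, confusion
metrics, and the rate-to-count consistency oracle."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from cytocascade import (
    DISEASED_VS_CONTROL, IC_VS_OAB, analyze_marker, check_table_consistency,
    confusion_from_rates, default_paper_spec, generate_cohort, load_fixtures,
    lognormal_params_from_moments, metrics_at_cutoff, optimal_cutoff,
    roc_and_auc, run_contrast,
)


def brute_force_auc(pos, neg):
    """Pair enumeration: P(pos > neg) + 0.5 P(pos = neg)."""
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


def exhaustive_cutoff_scan(pos, neg, direction="POS_HIGHER"):
    """Independent oracle: scan every midpoint candidate, maximize J with
    ties broken toward higher sens then lower threshold."""
    v = np.unique(np.concatenate([pos, neg]))
    span = v[-1] - v[0]
    pad = span / 2.0 if span > 0 else max(abs(v[0]) * 0.5, 1.0)
    cands = [v[0] - pad] + [(a + b) / 2 for a, b in zip(v[:-1], v[1:])] + [v[-1] + pad]
    best = None
    for c in cands:
        if direction == "POS_HIGHER":
            sens = np.mean(np.asarray(pos) > c)
            spec = np.mean(np.asarray(neg) <= c)
        else:
            sens = np.mean(np.asarray(pos) < c)
            spec = np.mean(np.asarray(neg) >= c)
        key = (sens + spec - 1, sens, -c)
        if best is None or key > best[0]:
            best = (key, c)
    return best[1]


def test_auc_perfect_separation():
    _, auc = roc_and_auc([2, 3], [0, 1])
    assert auc == 1.0


def test_auc_all_tied():
    curve, auc = roc_and_auc([1.0], [1.0])
    assert auc == 0.5
    assert curve.direction == "POS_HIGHER"


@given(st.lists(st.floats(0, 100), min_size=1, max_size=25),
       st.lists(st.floats(0, 100), min_size=1, max_size=25))
@settings(max_examples=200, deadline=None)
def test_auc_equals_pair_enumeration(pos, neg):
    # round to force ties so the half-credit branch is exercised
    pos = [round(p, 1) for p in pos]
    neg = [round(n, 1) for n in neg]
    _, auc = roc_and_auc(pos, neg, direction="POS_HIGHER")
    assert auc == pytest.approx(brute_force_auc(pos, neg), abs=1e-12)


def test_auc_matches_sklearn(rng):
    """Independent library cross-check on tied, skewed data."""
    from sklearn.metrics import roc_auc_score
    pos = np.round(rng.lognormal(1, 0.8, 40), 1)
    neg = np.round(rng.lognormal(0.7, 0.8, 30), 1)
    _, auc = roc_and_auc(pos, neg, direction="POS_HIGHER")
    y = np.r_[np.ones(40), np.zeros(30)]
    assert auc == pytest.approx(roc_auc_score(y, np.r_[pos, neg]), abs=1e-12)


def test_direction_flip_maps_auc():
    r = np.random.default_rng(3)
    pos, neg = r.normal(0, 1, 30), r.normal(1, 1, 30)  # pos LOWER than neg
    _, auc_raw = roc_and_auc(pos, neg, direction="POS_HIGHER")
    curve, auc_auto = roc_and_auc(pos, neg, direction="AUTO")
    assert curve.direction == "POS_LOWER"
    assert auc_auto == pytest.approx(1.0 - auc_raw, abs=1e-12)


def test_direction_flip_swaps_sens_spec_roles():
    """POS_LOWER metrics equal POS_HIGHER metrics on negated data."""
    r = np.random.default_rng(8)
    pos, neg = r.normal(0, 1, 25), r.normal(1, 1, 20)
    m_low = metrics_at_cutoff(pos, neg, 0.4, "POS_LOWER")
    m_neg = metrics_at_cutoff(-pos, -neg, -0.4, "POS_HIGHER")
    assert (m_low.tp, m_low.fp, m_low.tn, m_low.fn) == (m_neg.tp, m_neg.fp, m_neg.tn, m_neg.fn)


def test_roc_curve_hits_both_endpoints():
    r = np.random.default_rng(5)
    curve, _ = roc_and_auc(r.normal(1, 1, 20), r.normal(0, 1, 20))
    pts = set(zip(curve.sens_at, curve.spec_at))
    assert (1.0, 0.0) in pts and (0.0, 1.0) in pts


def test_cutoff_separable_midpoint():
    cut = optimal_cutoff([2, 3, 4], [0, 1])
    assert cut == 1.5
    m = metrics_at_cutoff([2, 3, 4], [0, 1], cut)
    assert m.sens == m.spec == m.ppv == m.npv == 100.0


def test_cutoff_tiebreak_matches_exhaustive_scan():
    pos, neg = [1.0, 3.0], [0.0, 2.0]
    cut = optimal_cutoff(pos, neg)
    assert cut == exhaustive_cutoff_scan(pos, neg)
    assert cut == 0.5  # J tie resolved toward higher sensitivity


@given(st.lists(st.floats(0, 20), min_size=1, max_size=15),
       st.lists(st.floats(0, 20), min_size=1, max_size=15))
@settings(max_examples=150, deadline=None)
def test_cutoff_agrees_with_scan_oracle(pos, neg):
    pos = [round(p, 1) for p in pos]
    neg = [round(n, 1) for n in neg]
    assert optimal_cutoff(pos, neg) == exhaustive_cutoff_scan(pos, neg)


def test_cutoff_symmetric_gaussian_converges_to_mid_mean():
    r = np.random.default_rng(17)
    cut = optimal_cutoff(r.normal(1, 1, 100_000), r.normal(0, 1, 100_000))
    assert abs(cut - 0.5) < 0.1


def test_metrics_basic_and_self_consistent():
    m = metrics_at_cutoff([2, 3], [0, 1], 1.5)
    assert (m.tp, m.fp, m.tn, m.fn) == (2, 0, 2, 0)
    assert m.sens == m.spec == 100.0
    assert m.sens == pytest.approx(100 * m.tp / (m.tp + m.fn))
    assert m.npv == pytest.approx(100 * m.tn / (m.tn + m.fn))


def test_metrics_empty_predicted_class_missing_not_zero():
    m = metrics_at_cutoff([1, 2], [0.5, 0.7], 10.0)
    assert m.tp == 0 and m.fp == 0
    assert m.ppv is None
    assert m.spec == 100.0


def test_empty_class_is_error():
    with pytest.raises(ValueError):
        roc_and_auc([], [1.0])


def test_auc_converges_to_binormal_closed_form(rng):
    """Gaussian classes: AUC -> Phi(dmu / sqrt(s0^2+s1^2))."""
    pos = rng.normal(1.0, 1.0, 10_000)
    neg = rng.normal(0.0, 1.0, 10_000)
    _, auc = roc_and_auc(pos, neg, direction="POS_HIGHER")
    expected = norm.cdf(1.0 / math.sqrt(2.0))
    assert abs(auc - expected) < 0.012  # ~3 MC SE


@pytest.mark.parametrize("sens,spec,n_pos,n_neg,tp,tn,ppv,npv", [
    (92.2, 44.8, 77, 29, 71, 13, 81.6, 68.4),
    (61.5, 82.1, 39, 39, 24, 32, 77.4, 68.1),
    (100.0, 100.0, 10, 10, 10, 10, 100.0, 100.0),
])
def test_confusion_from_rates_examples(sens, spec, n_pos, n_neg, tp, tn, ppv, npv):
    c = confusion_from_rates(sens, spec, n_pos, n_neg)
    assert (c.tp, c.tn) == (tp, tn)
    assert round(c.ppv, 1) == ppv
    assert round(c.npv, 1) == npv


def test_confusion_counts_partition_classes():
    c = confusion_from_rates(66.7, 42.0, 53, 31)
    assert c.tp + c.fn == 53 and c.tn + c.fp == 31


def test_published_table_internally_consistent():
    """Every published diagnostics row reproduces its printed PPV and NPV
    from sens/spec and the outlier-adjusted group sizes."""
    records = check_table_consistency()
    assert len(records) == 22
    bad = [r for r in records if not r["consistent"]]
    assert bad == []


def test_run_contrast_detects_known_directions():
    """On a large moment-matched cohort, AUTO direction finds RANTES higher
    in IC and IL-10 higher in OAB, with AUC ordering as published."""
    spec = default_paper_spec(seed=6, n_per_group={"OAB": 2000, "IC_BPS": 2000,
                                                   "CONTROL": 1500},
                              outlier_rate=0.0)
    cohort, _ = generate_cohort(spec)
    rows = {r.marker: r for r in run_contrast(cohort, IC_VS_OAB)}
    assert rows["RANTES"].direction == "POS_HIGHER"
    assert rows["IL-10"].direction == "POS_LOWER"
    assert rows["IL-10"].auc > 0.7
    mcp = {r.marker: r for r in run_contrast(cohort, DISEASED_VS_CONTROL)}["MCP-1"]
    assert mcp.direction == "POS_HIGHER" and mcp.auc > 0.6


def test_analyze_marker_reports_auc_and_cutoff_together(rng):
    pos = rng.lognormal(1.2, 0.5, 40)
    neg = rng.lognormal(0.8, 0.5, 30)
    res = analyze_marker(pos, neg, marker="X", contrast="c")
    assert res.auc == pytest.approx(brute_force_auc(list(pos), list(neg)), abs=1e-12)
    assert res.cutoff == exhaustive_cutoff_scan(pos, neg)
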