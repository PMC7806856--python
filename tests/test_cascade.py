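"""The screen -> confirm diagnostic cascade."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from cytocascade import (
    CascadeConfig, TestRule, classify_subject, default_cascade_config,
    default_paper_spec, evaluate_cascade, generate_cohort, load_fixtures,
    lognormal_params_from_moments, screen_metrics,
)
from tests.conftest import make_cohort, make_subject


def test_default_config_matches_published_rules():
    cfg = default_cascade_config()
    assert cfg.screen.marker == "MIP-1b" and cfg.screen.cutoff == 1.385
    cuts = {r.marker: r.cutoff for r in cfg.ic_rules}
    assert cuts == {"Eotaxin": 9.035, "CXCL10": 40.495, "RANTES": 9.305}
    assert all(r.positive_label == "IC_BPS" for r in cfg.ic_rules)
    (oab_rule,) = cfg.oab_rules
    assert oab_rule.marker == "IL-10" and oab_rule.cutoff == 1.025
    assert oab_rule.positive_direction == "HIGHER" and oab_rule.positive_label == "OAB"
    assert cfg.combiner == "MAJORITY" and cfg.on_conflict == "INDETERMINATE"


def test_screen_negative_short_circuits():
    cfg = default_cascade_config()
    panel = {"MIP-1b": 1.0, "Eotaxin": 50.0, "CXCL10": 200.0,
             "RANTES": 50.0, "IL-10": 5.0}
    assert classify_subject(panel, cfg) == "CONTROL"


def test_unanimous_ic_votes():
    cfg = default_cascade_config()
    panel = {"MIP-1b": 3.0, "Eotaxin": 20.0, "CXCL10": 80.0,
             "RANTES": 15.0, "IL-10": 0.5}
    assert classify_subject(panel, cfg) == "IC_BPS"


def test_conflicting_branches_indeterminate():
    cfg = default_cascade_config()
    panel = {"MIP-1b": 3.0, "Eotaxin": 20.0, "CXCL10": 80.0,
             "RANTES": 15.0, "IL-10": 2.0}
    assert classify_subject(panel, cfg) == "INDETERMINATE"
    cfg_pref = default_cascade_config()
    cfg_pref.on_conflict = "PREFER_IC"
    assert classify_subject(panel, cfg_pref) == "IC_BPS"


def test_majority_vote_boundary():
    cfg = default_cascade_config()
    panel = {"MIP-1b": 3.0, "Eotaxin": 20.0, "CXCL10": 80.0,
             "RANTES": 1.0, "IL-10": 0.5}  # 2/3 IC votes, OAB quiet
    assert classify_subject(panel, cfg) == "IC_BPS"
    panel["CXCL10"] = 1.0  # 1/3 votes: majority lost, OAB quiet -> conflict policy
    assert classify_subject(panel, cfg) == "INDETERMINATE"


def test_oab_call_when_ic_votes_lose():
    cfg = default_cascade_config()
    panel = {"MIP-1b": 3.0, "Eotaxin": 1.0, "CXCL10": 1.0,
             "RANTES": 1.0, "IL-10": 2.0}
    assert classify_subject(panel, cfg) == "OAB"


def test_missing_screen_marker_unevaluable():
    cfg = default_cascade_config()
    with pytest.raises(KeyError):
        classify_subject({"Eotaxin": 20.0}, cfg)
    cohort = make_cohort({"MIP-1b": {"OAB": [3.0, None]},
                          "IL-10": {"OAB": [2.0, 2.0]},
                          "Eotaxin": {"OAB": [1.0, 1.0]},
                          "CXCL10": {"OAB": [1.0, 1.0]},
                          "RANTES": {"OAB": [1.0, 1.0]}})
    out = evaluate_cascade(cohort, cfg)
    assert len(out.unevaluable) == 1
    assert len(out.predictions) + len(out.unevaluable) == 2


def test_label_conservation(paper_cohort_qc):
    cohort, _, _ = paper_cohort_qc
    out = evaluate_cascade(cohort, default_cascade_config())
    assert len(out.predictions) + len(out.unevaluable) == len(cohort)
    assert set(out.predictions.values()) <= {"CONTROL", "IC_BPS", "OAB", "INDETERMINATE"}
    assert out.n_screen_positive + out.n_screen_negative == len(out.predictions)


def test_raising_screen_cutoff_monotone(paper_cohort_qc):
    cohort, _, _ = paper_cohort_qc
    counts = []
    for cutoff in (0.5, 1.0, 1.385, 2.0, 3.0, 5.0):
        cfg = default_cascade_config()
        cfg.screen = TestRule("MIP-1b", cutoff, "HIGHER", "DISEASED")
        counts.append(evaluate_cascade(cohort, cfg).n_screen_positive)
    assert counts == sorted(counts, reverse=True)


def test_perfectly_separating_markers_give_perfect_rates():
    cohort = make_cohort({
        "MIP-1b": {"OAB": [10.0] * 5, "IC_BPS": [10.0] * 5, "CONTROL": [0.1] * 5},
        "Eotaxin": {"OAB": [1.0] * 5, "IC_BPS": [100.0] * 5, "CONTROL": [1.0] * 5},
        "CXCL10": {"OAB": [1.0] * 5, "IC_BPS": [100.0] * 5, "CONTROL": [1.0] * 5},
        "RANTES": {"OAB": [1.0] * 5, "IC_BPS": [100.0] * 5, "CONTROL": [1.0] * 5},
        "IL-10": {"OAB": [5.0] * 5, "IC_BPS": [0.1] * 5, "CONTROL": [0.1] * 5},
    })
    out = evaluate_cascade(cohort, default_cascade_config())
    assert out.screen_ppv == 100.0 and out.screen_npv == 100.0
    assert out.accuracy == 100.0
    assert all(rate == 100.0 for rate in out.rule_rates.values())


def test_screen_rates_match_roc_metrics(paper_cohort_qc):
    """Cross-module identity: cascade screening PPV/NPV equal the ROC
    module's confusion metrics at the same cutoff on the same subjects."""
    cohort, _, _ = paper_cohort_qc
    cfg = default_cascade_config()
    out = evaluate_cascade(cohort, cfg)
    m = screen_metrics(cohort, cfg)
    assert out.screen_ppv == pytest.approx(m.ppv, abs=1e-12)
    assert out.screen_npv == pytest.approx(m.npv, abs=1e-12)
    assert out.n_screen_positive == m.tp + m.fp


def test_shuffled_labels_make_ppv_converge_to_prevalence():
    """With labels randomized, screen PPV approaches the diseased fraction."""
    rng = np.random.default_rng(44)
    spec = default_paper_spec(seed=44, n_per_group={"OAB": 2000, "IC_BPS": 2000,
                                                    "CONTROL": 1500},
                              outlier_rate=0.0)
    cohort, _ = generate_cohort(spec)
    groups = [s.group for s in cohort.subjects]
    rng.shuffle(groups)
    for s, g in zip(cohort.subjects, groups):
        s.group = g
    out = evaluate_cascade(cohort, default_cascade_config())
    prevalence = 100.0 * 4000 / 5500
    assert out.screen_ppv == pytest.approx(prevalence, abs=3.0)


def test_screen_rates_match_analytic_lognormal_tails():
    """Screen sens/spec on a large moment-matched cohort agree with the
    closed-form lognormal tail probabilities at the published cutoff."""
    n = 10_000
    spec = default_paper_spec(seed=55, n_per_group={"OAB": n, "IC_BPS": n,
                                                    "CONTROL": n},
                              outlier_rate=0.0)
    cohort, _ = generate_cohort(spec)
    cfg = default_cascade_config()
    m = screen_metrics(cohort, cfg)
    fx = load_fixtures()
    cutoff = cfg.screen.cutoff

    def tail_above(group):
        mean, sd, _ = fx.table2("MIP-1b", group)
        mu, sigma = lognormal_params_from_moments(mean, sd)
        return 1.0 - norm.cdf((math.log(cutoff) - mu) / sigma)

    sens_true = (tail_above("OAB") + tail_above("IC_BPS")) / 2.0
    spec_true = 1.0 - tail_above("CONTROL")
    se_sens = math.sqrt(sens_true * (1 - sens_true) / (2 * n))
    se_spec = math.sqrt(spec_true * (1 - spec_true) / n)
    assert abs(m.sens / 100.0 - sens_true) < 3 * se_sens
    assert abs(m.spec / 100.0 - spec_true) < 3 * se_spec


def test_combiner_variants():
    panel = {"MIP-1b": 3.0, "Eotaxin": 20.0, "CXCL10": 1.0,
             "RANTES": 1.0, "IL-10": 0.5}  # only 1/3 IC rules fire
    any_cfg = default_cascade_config()
    any_cfg.combiner = "ANY"
    assert classify_subject(panel, any_cfg) == "IC_BPS"
    all_cfg = default_cascade_config()
    all_cfg.combiner = "ALL"
    assert classify_subject(panel, all_cfg) == "INDETERMINATE"
    single_cfg = default_cascade_config()
    single_cfg.combiner = "SINGLE"  # first IC rule is eotaxin, which fires
    assert classify_subject(panel, single_cfg) == "IC_BPS"


def test_config_validation():
    with pytest.raises(ValueError):
        CascadeConfig(screen=TestRule("MIP-1b", 1.385), ic_rules=[], oab_rules=[],
                      combiner="VOODOO")
    with pytest.raises(ValueError):
        TestRule("X", float("nan"))
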