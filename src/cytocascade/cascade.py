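"""Hierarchical screen→confirm diagnostic cascade.

The pilot algorithm: a sensitive screening marker (MIP-1β, elevated in both
disease groups) first separates diseased subjects from controls; screen
positives then pass through confirmation rules — markers elevated
specifically in IC/BPS (eotaxin, CXCL10, RANTES) versus a marker elevated
in OAB (IL-10) — to assign the final label.

The source algorithm evaluates each confirmation marker separately and
publishes no combined decision rule, so the joint rule here (``combiner``
over the IC votes, ``on_conflict`` when the IC and OAB branches disagree or
both abstain) is an explicit, configurable extension; the default is a
majority vote with conflicts left INDETERMINATE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .io_core import CohortTable
from .diagnostics import metrics_at_cutoff
from .fixtures import FixtureConstants, load_fixtures

LABELS = ("CONTROL", "IC_BPS", "OAB", "INDETERMINATE")
COMBINERS = ("MAJORITY", "ANY", "ALL", "SINGLE")
CONFLICT_POLICIES = ("INDETERMINATE", "PREFER_IC", "PREFER_OAB")


@dataclass(frozen=True)
class TestRule:
    """One threshold rule: fires when the marker crosses the cutoff."""

    __test__ = False  # despite the name, not a pytest class

    marker: str
    cutoff: float          # pg/mL
    positive_direction: str = "HIGHER"  # HIGHER | LOWER
    positive_label: str = "IC_BPS"

    def __post_init__(self) -> None:
        if not math.isfinite(self.cutoff):
            raise ValueError(f"cutoff must be finite, got {self.cutoff}")
        if self.positive_direction not in ("HIGHER", "LOWER"):
            raise ValueError(f"unknown direction {self.positive_direction!r}")

    def fires(self, value: float) -> bool:
        if self.positive_direction == "HIGHER":
            return value > self.cutoff
        return value < self.cutoff


@dataclass
class CascadeConfig:
    screen: TestRule
    ic_rules: list[TestRule]
    oab_rules: list[TestRule]
    combiner: str = "MAJORITY"
    on_conflict: str = "INDETERMINATE"

    def __post_init__(self) -> None:
        if self.combiner not in COMBINERS:
            raise ValueError(f"unknown combiner {self.combiner!r}")
        if self.on_conflict not in CONFLICT_POLICIES:
            raise ValueError(f"unknown conflict policy {self.on_conflict!r}")


@dataclass
class CascadeOutcome:
    predictions: dict[str, str]           # subject_id -> label
    unevaluable: list[str]                # screen marker missing
    screen_ppv: float | None              # % of screen-positives truly diseased
    screen_npv: float | None              # % of screen-negatives truly control
    rule_rates: dict[str, float | None]   # per-rule correct % among screen-positive diseased
    accuracy: float | None                # 3-class % over evaluable subjects
    n_screen_positive: int = 0
    n_screen_negative: int = 0


def default_cascade_config(fixtures: FixtureConstants | None = None) -> CascadeConfig:
    """The published rule set: screen MIP-1β > 1.385 pg/mL; confirm IC/BPS
    with eotaxin > 9.035, CXCL10 > 40.495, RANTES > 9.305; confirm OAB with
    IL-10 > 1.025."""
    fx = fixtures or load_fixtures()
    t3 = fx.table3

    def cut(marker: str, contrast: str) -> float:
        return t3[(marker, contrast)].cutoff

    return CascadeConfig(
        screen=TestRule("MIP-1b", cut("MIP-1b", "diseased_vs_control"),
                        "HIGHER", "DISEASED"),
        ic_rules=[
            TestRule("Eotaxin", cut("Eotaxin", "ic_vs_oab"), "HIGHER", "IC_BPS"),
            TestRule("CXCL10", cut("CXCL10", "ic_vs_oab"), "HIGHER", "IC_BPS"),
            TestRule("RANTES", cut("RANTES", "ic_vs_oab"), "HIGHER", "IC_BPS"),
        ],
        oab_rules=[TestRule("IL-10", cut("IL-10", "ic_vs_oab"), "HIGHER", "OAB")],
    )


def _votes_win(n_fired: int, n_rules: int, combiner: str) -> bool:
    if n_rules == 0:
        return False
    if combiner == "MAJORITY":
        return n_fired > n_rules / 2.0
    if combiner == "ANY":
        return n_fired >= 1
    if combiner == "ALL":
        return n_fired == n_rules
    return False  # SINGLE handled by caller


def classify_subject(panel: dict[str, float | None], config: CascadeConfig) -> str:
    """Label one subject from its marker panel.

    Screen-negative subjects are CONTROL regardless of other markers.
    Screen positives get IC_BPS when the IC votes win and the OAB branch is
    quiet, OAB when the OAB branch fires and the IC votes lose; anything
    else resolves per ``on_conflict``. Raises KeyError when the screen
    marker is missing.
    """
    v = panel.get(config.screen.marker)
    if v is None or (isinstance(v, float) and math.isnan(v)):
        raise KeyError(f"screen marker {config.screen.marker!r} missing")
    if not config.screen.fires(float(v)):
        return "CONTROL"

    def branch_call(rules: list[TestRule]) -> bool:
        fired = 0
        usable = []
        for r in rules:
            x = panel.get(r.marker)
            if x is None or (isinstance(x, float) and math.isnan(x)):
                continue
            usable.append(r)
            if r.fires(float(x)):
                fired += 1
        if config.combiner == "SINGLE":
            return bool(usable) and usable[0].fires(float(panel[usable[0].marker]))
        return _votes_win(fired, len(usable), config.combiner)

    ic_call = branch_call(config.ic_rules)
    oab_call = branch_call(config.oab_rules)
    if ic_call and not oab_call:
        return "IC_BPS"
    if oab_call and not ic_call:
        return "OAB"
    if config.on_conflict == "PREFER_IC":
        return "IC_BPS"
    if config.on_conflict == "PREFER_OAB":
        return "OAB"
    return "INDETERMINATE"


def evaluate_cascade(cohort: CohortTable, config: CascadeConfig) -> CascadeOutcome:
    """Run the cascade over a labelled cohort and score it.

    screen_ppv / screen_npv are the fraction of screen-positive subjects
    truly diseased and screen-negative subjects truly control (the screening
    stage's two diagnostic rates). Each confirmation rule is scored
    separately among screen-positive *diseased* subjects as the percentage
    whose single-rule binary call (rule's label if it fires, the opposing
    disease label otherwise) matches the true label. Accuracy is 3-class
    over all evaluable subjects, INDETERMINATE counting as wrong.
    """
    predictions: dict[str, str] = {}
    unevaluable: list[str] = []
    n_sp = n_sn = sp_diseased = sn_control = 0
    rule_hits: dict[str, list[int]] = {}
    n_correct = 0

    for s in cohort.subjects:
        try:
            label = classify_subject(s.markers, config)
        except KeyError:
            unevaluable.append(s.subject_id)
            continue
        predictions[s.subject_id] = label
        diseased = s.group in ("IC_BPS", "OAB")
        screen_pos = label != "CONTROL"
        if screen_pos:
            n_sp += 1
            sp_diseased += diseased
        else:
            n_sn += 1
            sn_control += not diseased
        if label == s.group:
            n_correct += 1
        if screen_pos and diseased:
            for rule in config.ic_rules + config.oab_rules:
                x = s.markers.get(rule.marker)
                if x is None or (isinstance(x, float) and math.isnan(x)):
                    continue
                if rule.positive_label == "IC_BPS":
                    call = "IC_BPS" if rule.fires(float(x)) else "OAB"
                else:
                    call = "OAB" if rule.fires(float(x)) else "IC_BPS"
                rule_hits.setdefault(rule.marker, []).append(int(call == s.group))

    n_eval = len(predictions)
    pct = lambda num, den: 100.0 * num / den if den else None
    return CascadeOutcome(
        predictions=predictions, unevaluable=unevaluable,
        screen_ppv=pct(sp_diseased, n_sp), screen_npv=pct(sn_control, n_sn),
        rule_rates={m: pct(sum(h), len(h)) for m, h in rule_hits.items()},
        accuracy=pct(n_correct, n_eval),
        n_screen_positive=n_sp, n_screen_negative=n_sn,
    )


def screen_metrics(cohort: CohortTable, config: CascadeConfig):
    """Screen-stage confusion metrics via the ROC module, for cross-checks.

    Applies :func:`cytocascade.diagnostics.metrics_at_cutoff` to the screen
    marker with diseased as positive class, on exactly the subjects the
    cascade can evaluate.
    """
    pos, neg = [], []
    for s in cohort.subjects:
        v = s.markers.get(config.screen.marker)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            continue
        (pos if s.group in ("IC_BPS", "OAB") else neg).append(float(v))
    direction = "POS_HIGHER" if config.screen.positive_direction == "HIGHER" else "POS_LOWER"
    return metrics_at_cutoff(pos, neg, config.screen.cutoff, direction,
                             marker=config.screen.marker, contrast="diseased_vs_control")
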