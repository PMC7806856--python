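"""Per-marker ROC diagnostics.

For each marker and contrast: the empirical ROC curve, AUC (equal to the
Mann–Whitney probability P(pos > neg) + ½·P(pos = neg)), the Youden-optimal
cutoff, and confusion-matrix metrics at that cutoff.

Conventions
-----------
* The reported cutoff is the midpoint between the two consecutive observed
  values straddling the Youden optimum, so observed values are never on the
  boundary; positivity is a strict comparison (``value > cutoff`` under
  POS_HIGHER, ``value < cutoff`` under POS_LOWER).
* Ties on Youden's J are broken toward higher sensitivity, then toward the
  lower threshold.
* ``direction="AUTO"`` orients the marker so AUC >= 0.5 and records the flip
  (markers where higher values indicate the negative class).

``confusion_from_rates`` inverts printed sensitivity/specificity back to
integer confusion counts given the class denominators — the
internal-consistency oracle linking a published diagnostics table's rate
columns to its predictive-value columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .io_core import CohortTable
from .qc_preprocess import QcResult

POS_HIGHER = "POS_HIGHER"
POS_LOWER = "POS_LOWER"


@dataclass(frozen=True)
class Contrast:
    """A binary diagnostic contrast between two sets of groups."""

    name: str
    positive: tuple[str, ...]
    negative: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.positive or not self.negative:
            raise ValueError("contrast classes must be nonempty")
        if set(self.positive) & set(self.negative):
            raise ValueError("contrast classes must be disjoint")


DISEASED_VS_CONTROL = Contrast("diseased_vs_control", ("IC_BPS", "OAB"), ("CONTROL",))
IC_VS_OAB = Contrast("ic_vs_oab", ("IC_BPS",), ("OAB",))
OAB_VS_CONTROL = Contrast("oab_vs_control", ("OAB",), ("CONTROL",))
IC_VS_CONTROL = Contrast("ic_vs_control", ("IC_BPS",), ("CONTROL",))

CONTRASTS = {c.name: c for c in
             (DISEASED_VS_CONTROL, IC_VS_OAB, OAB_VS_CONTROL, IC_VS_CONTROL)}


@dataclass(frozen=True)
class RocCurve:
    thresholds: tuple[float, ...]  # ascending candidate cutoffs (midpoints + sentinels)
    sens_at: tuple[float, ...]
    spec_at: tuple[float, ...]
    direction: str


@dataclass(frozen=True)
class DiagnosticResult:
    marker: str
    contrast: str
    auc: float | None
    cutoff: float
    direction: str
    tp: int
    fp: int
    tn: int
    fn: int
    sens: float | None  # percent
    spec: float | None
    ppv: float | None
    npv: float | None


def _auc_pos_higher(pos: np.ndarray, neg: np.ndarray) -> float:
    """Mann–Whitney AUC with ties counted half, via midranks."""
    n_pos, n_neg = pos.size, neg.size
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _candidate_cutoffs(pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    v = np.unique(np.concatenate([pos, neg]))
    inner = (v[:-1] + v[1:]) / 2.0
    span = v[-1] - v[0]
    pad = span / 2.0 if span > 0 else max(abs(v[0]) * 0.5, 1.0)
    return np.concatenate([[v[0] - pad], inner, [v[-1] + pad]])


def _sens_spec_at(pos: np.ndarray, neg: np.ndarray, cuts: np.ndarray,
                  direction: str) -> tuple[np.ndarray, np.ndarray]:
    ps, ns = np.sort(pos), np.sort(neg)
    # integer counts first so the fractions are exactly count/n
    if direction == POS_HIGHER:
        sens = (ps.size - np.searchsorted(ps, cuts, side="right")) / ps.size
        spec = np.searchsorted(ns, cuts, side="right") / ns.size
    elif direction == POS_LOWER:
        sens = np.searchsorted(ps, cuts, side="left") / ps.size
        spec = (ns.size - np.searchsorted(ns, cuts, side="left")) / ns.size
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return sens, spec


def roc_and_auc(pos_values, neg_values, direction: str = "AUTO"
                ) -> tuple[RocCurve, float]:
    """Empirical ROC curve and AUC for one marker.

    AUTO picks the direction giving AUC >= 0.5 (recording the flip); the
    returned AUC is always oriented by the returned direction, so a flip
    maps the raw AUC ``a`` to ``1 - a``.
    """
    pos = np.asarray(list(pos_values), dtype=float)
    neg = np.asarray(list(neg_values), dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be nonempty")
    auc_higher = _auc_pos_higher(pos, neg)
    if direction == "AUTO":
        direction = POS_HIGHER if auc_higher >= 0.5 else POS_LOWER
    auc = auc_higher if direction == POS_HIGHER else 1.0 - auc_higher
    cuts = _candidate_cutoffs(pos, neg)
    sens, spec = _sens_spec_at(pos, neg, cuts, direction)
    return RocCurve(tuple(cuts), tuple(sens), tuple(spec), direction), auc


def optimal_cutoff(pos_values, neg_values, direction: str = POS_HIGHER) -> float:
    """Youden-optimal midpoint cutoff.

    Maximizes J = sens + spec − 1 over midpoints between consecutive
    observed values (plus all-positive / all-negative sentinels); ties are
    broken toward higher sensitivity, then lower threshold.
    """
    pos = np.asarray(list(pos_values), dtype=float)
    neg = np.asarray(list(neg_values), dtype=float)
    cuts = _candidate_cutoffs(pos, neg)
    sens, spec = _sens_spec_at(pos, neg, cuts, direction)
    j = sens + spec - 1.0
    # lexicographic argmax: J, then sens, then -threshold
    order = np.lexsort((cuts, -sens, -j))
    return float(cuts[order[0]])


def metrics_at_cutoff(pos_values, neg_values, cutoff: float,
                      direction: str = POS_HIGHER, marker: str = "",
                      contrast: str = "", auc: float | None = None
                      ) -> DiagnosticResult:
    """Confusion counts and sens/spec/PPV/NPV (percent) at a fixed cutoff.

    A metric whose denominator is empty (e.g. PPV with no positive calls)
    is reported as missing, never as zero.
    """
    if not math.isfinite(cutoff):
        raise ValueError(f"cutoff must be finite, got {cutoff}")
    pos = np.asarray(list(pos_values), dtype=float)
    neg = np.asarray(list(neg_values), dtype=float)
    if direction == POS_HIGHER:
        tp, fp = int((pos > cutoff).sum()), int((neg > cutoff).sum())
    elif direction == POS_LOWER:
        tp, fp = int((pos < cutoff).sum()), int((neg < cutoff).sum())
    else:
        raise ValueError(f"unknown direction {direction!r}")
    fn, tn = pos.size - tp, neg.size - fp

    def pct(num: int, den: int) -> float | None:
        return 100.0 * num / den if den > 0 else None

    return DiagnosticResult(
        marker=marker, contrast=contrast, auc=auc, cutoff=float(cutoff),
        direction=direction, tp=tp, fp=fp, tn=tn, fn=fn,
        sens=pct(tp, tp + fn), spec=pct(tn, tn + fp),
        ppv=pct(tp, tp + fp), npv=pct(tn, tn + fn),
    )


def analyze_marker(pos_values, neg_values, direction: str = "AUTO",
                   marker: str = "", contrast: str = "") -> DiagnosticResult:
    """Full single-marker workup: AUC, Youden cutoff, metrics at the cutoff."""
    curve, auc = roc_and_auc(pos_values, neg_values, direction)
    cut = optimal_cutoff(pos_values, neg_values, curve.direction)
    return metrics_at_cutoff(pos_values, neg_values, cut, curve.direction,
                             marker=marker, contrast=contrast, auc=auc)


def run_contrast(data: CohortTable | QcResult, contrast: Contrast,
                 markers=None, directions: dict[str, str] | None = None
                 ) -> list[DiagnosticResult]:
    """ROC workup of every marker for one contrast, sorted by AUC descending.

    Accepts a raw cohort or a QC result (in which case the cleaned cohort
    and LOD policy are honoured). Subjects missing a marker are dropped
    pairwise from that marker's analysis.
    """
    if isinstance(data, QcResult):
        cohort = data.cleaned
        if markers is None:
            markers = data.analysis_markers()
    else:
        cohort = data
        if markers is None:
            markers = cohort.marker_names
    directions = directions or {}
    results = []
    for m in markers:
        pos = np.concatenate([cohort.marker_values(m, g) for g in contrast.positive])
        neg = np.concatenate([cohort.marker_values(m, g) for g in contrast.negative])
        if pos.size == 0 or neg.size == 0:
            continue
        results.append(analyze_marker(pos, neg, directions.get(m, "AUTO"),
                                      marker=m, contrast=contrast.name))
    return sorted(results, key=lambda r: (-(r.auc or 0.0), r.marker))


@dataclass(frozen=True)
class ConfusionFromRates:
    tp: int
    fp: int
    tn: int
    fn: int
    ppv: float | None  # percent, unrounded
    npv: float | None


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def confusion_from_rates(sens: float, spec: float, n_pos: int, n_neg: int
                         ) -> ConfusionFromRates:
    """Reconstruct integer confusion counts from printed rates.

    ``tp = round(sens·n_pos/100)``, ``tn = round(spec·n_neg/100)`` with
    half-up rounding (the convention of mainstream statistics packages,
    required for exact agreement on rows where the product lands on .5);
    PPV/NPV then follow from the counts. This is the identity that ties a
    published table's sensitivity/specificity columns to its PPV/NPV
    columns given the outlier-adjusted class sizes.
    """
    if not (0 <= sens <= 100 and 0 <= spec <= 100):
        raise ValueError("rates must be percentages in [0, 100]")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("class sizes must be >= 1")
    tp = _round_half_up(sens * n_pos / 100.0)
    tn = _round_half_up(spec * n_neg / 100.0)
    fn, fp = n_pos - tp, n_neg - tn
    ppv = 100.0 * tp / (tp + fp) if tp + fp > 0 else None
    npv = 100.0 * tn / (tn + fn) if tn + fn > 0 else None
    return ConfusionFromRates(tp=tp, fp=fp, tn=tn, fn=fn, ppv=ppv, npv=npv)


def check_table_consistency(fixtures=None) -> list[dict]:
    """Recompute PPV/NPV for every packaged diagnostics row from its printed
    sensitivity/specificity and outlier-adjusted group sizes.

    Returns one record per row with the reconstructed counts, the recomputed
    predictive values, and whether they match the printed ones at one
    decimal place.
    """
    from .fixtures import load_fixtures
    fx = fixtures or load_fixtures()
    records = []
    for row in fx.table3_rows:
        n_pos, n_neg = fx.contrast_ns(row.marker, row.contrast)
        c = confusion_from_rates(row.sens, row.spec, n_pos, n_neg)
        ppv = round(c.ppv, 1) if c.ppv is not None else None
        npv = round(c.npv, 1) if c.npv is not None else None
        records.append({
            "marker": row.marker, "contrast": row.contrast,
            "n_pos": n_pos, "n_neg": n_neg,
            "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn,
            "ppv_recomputed": ppv, "ppv_printed": row.ppv,
            "npv_recomputed": npv, "npv_printed": row.npv,
            "consistent": ppv == row.ppv and npv == row.npv,
        })
    return records
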