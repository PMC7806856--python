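"""Group summaries and the three-group comparison.

Produces per-marker per-group n / mean ± SD / outlier-count summaries on
post-QC data, and a one-way ANOVA across the three diagnosis groups with
pairwise post hoc testing. The omnibus test defaults to the classical
equal-variance ANOVA on raw concentrations (Welch and a log-transform are
available as options); the post hoc defaults to Tukey's HSD, with Bonferroni
pairwise t-tests as the alternative. Post hoc comparisons are run regardless
of the omnibus result but reported significant only at the adjusted level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .io_core import GROUPS
from .qc_preprocess import QcResult

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupSummary:
    marker: str
    group: str
    n: int
    mean: float  # pg/mL; NaN when n == 0
    sd: float    # pg/mL; NaN when n < 2
    n_outliers: int


@dataclass(frozen=True)
class AnovaResult:
    marker: str
    p_value: float
    f_stat: float
    posthoc_pairs: tuple[tuple[str, float, bool], ...]  # ("A vs B", adj p, significant)


def summarize_groups(qc: QcResult) -> list[GroupSummary]:
    """One row per marker x group: post-exclusion n, mean, SD, outlier count."""
    rows = []
    for marker in qc.cleaned.marker_names:
        for group in GROUPS:
            vals = qc.cleaned.marker_values(marker, group)
            rows.append(GroupSummary(
                marker=marker, group=group, n=int(vals.size),
                mean=float(vals.mean()) if vals.size else float("nan"),
                sd=float(vals.std(ddof=1)) if vals.size >= 2 else float("nan"),
                n_outliers=qc.n_excluded.get((marker, group), 0),
            ))
    return rows


def _welch_anova(samples: list[np.ndarray]) -> tuple[float, float]:
    """Welch's heteroscedasticity-robust one-way ANOVA (F*, p)."""
    w = np.array([len(s) / np.var(s, ddof=1) for s in samples])
    means = np.array([np.mean(s) for s in samples])
    k = len(samples)
    grand = np.sum(w * means) / np.sum(w)
    num = np.sum(w * (means - grand) ** 2) / (k - 1)
    lam = np.sum((1 - w / np.sum(w)) ** 2 / (np.array([len(s) for s in samples]) - 1))
    denom = 1 + 2 * (k - 2) / (k**2 - 1) * lam
    f = num / denom
    df2 = (k**2 - 1) / (3 * lam)
    p = stats.f.sf(f, k - 1, df2)
    return float(f), float(p)


def anova_with_posthoc(qc: QcResult, alpha: float = 0.05, posthoc: str = "tukey",
                       welch: bool = False, log_transform: bool = False
                       ) -> list[AnovaResult]:
    """Per-marker omnibus ANOVA with pairwise post hoc comparisons.

    Markers lacking two groups with at least two values each are skipped
    with a warning. ``posthoc`` is ``"tukey"`` (HSD) or ``"bonferroni"``
    (pairwise Welch t-tests, alpha and p adjusted by the number of pairs).
    """
    if posthoc not in ("tukey", "bonferroni"):
        raise ValueError(f"unknown posthoc method {posthoc!r}")
    results = []
    for marker in qc.cleaned.marker_names:
        groups, samples = [], []
        for group in GROUPS:
            vals = qc.cleaned.marker_values(marker, group)
            if log_transform:
                vals = np.log(vals[vals > 0])
            if vals.size >= 2:
                groups.append(group)
                samples.append(vals)
        if len(samples) < 2:
            logger.warning("marker %s: insufficient data for ANOVA, skipped", marker)
            continue
        if welch:
            f, p = _welch_anova(samples)
        else:
            f, p = stats.f_oneway(*samples)
        pairs = []
        if posthoc == "tukey":
            tk = stats.tukey_hsd(*samples)
            for i, j in combinations(range(len(samples)), 2):
                padj = float(tk.pvalue[i, j])
                pairs.append((f"{groups[i]} vs {groups[j]}", padj, padj < alpha))
        else:
            n_pairs = len(list(combinations(range(len(samples)), 2)))
            for i, j in combinations(range(len(samples)), 2):
                praw = stats.ttest_ind(samples[i], samples[j], equal_var=False).pvalue
                padj = min(1.0, float(praw) * n_pairs)
                pairs.append((f"{groups[i]} vs {groups[j]}", padj, padj < alpha))
        results.append(AnovaResult(marker=marker, p_value=float(p), f_stat=float(f),
                                   posthoc_pairs=tuple(pairs)))
    return results
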