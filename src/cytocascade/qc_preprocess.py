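"""Quality control: per-group 3-SD outlier exclusion and below-LOD flagging.

Two rules are applied before any inferential analysis:

1. For each marker within each diagnosis group, values strictly outside
   ``mean ± k·SD`` (k=3 by default, mean/SD computed once on the raw data,
   sample SD with n−1 denominator) are excluded as outliers. The pass is
   single, not iterative, and boundary values are kept; with SD=0 the
   interval collapses to the mean, so identical values survive.
2. A marker is flagged when any group's post-exclusion mean falls below the
   assay's minimum detectable concentration. Flagged markers stay in the
   descriptive summaries but can be withheld from downstream diagnostics
   (``lod_policy="exclude"``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_core import GROUPS, CohortTable

logger = logging.getLogger(__name__)


def exclude_outliers(values, k: float = 3.0) -> tuple[list[float], int]:
    """Single-pass ``mean ± k·SD`` exclusion on one sample.

    Mean and SD are computed once on the full input; values strictly outside
    the closed interval are dropped, and the surviving order is preserved.
    Returns ``(kept, n_excluded)``.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError(f"need >= 2 values to apply the outlier rule, got {arr.size}")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    lo, hi = mean - k * sd, mean + k * sd
    keep = (arr >= lo) & (arr <= hi)
    return [float(v) for v in arr[keep]], int((~keep).sum())


@dataclass
class QcResult:
    """Outcome of cohort-level QC."""

    cleaned: CohortTable
    outlier_log: list[tuple[str, str, str, float]]  # (marker, group, subject_id, value)
    lod_flagged_markers: list[str]
    k: float = 3.0
    lod_policy: str = "report"
    n_excluded: dict[tuple[str, str], int] = field(default_factory=dict)

    def analysis_markers(self) -> tuple[str, ...]:
        """Markers eligible for diagnostic analyses under the LOD policy."""
        if self.lod_policy == "exclude":
            flagged = set(self.lod_flagged_markers)
            return tuple(m for m in self.cleaned.marker_names if m not in flagged)
        return self.cleaned.marker_names


def apply_qc(cohort: CohortTable, lod_table: dict[str, float] | None = None,
             k: float = 3.0, lod_policy: str = "report") -> QcResult:
    """Apply both exclusion rules to a cohort.

    The outlier rule runs per marker within each group; excluded cells are
    set missing in the returned (copied) cohort and logged with their
    original values. Markers absent from ``lod_table`` cannot be flagged and
    produce a warning.
    """
    if lod_policy not in ("report", "exclude"):
        raise ValueError(f"lod_policy must be 'report' or 'exclude', got {lod_policy!r}")
    cleaned = cohort.copy()
    by_id = {s.subject_id: s for s in cleaned.subjects}
    outlier_log: list[tuple[str, str, str, float]] = []
    n_excluded: dict[tuple[str, str], int] = {}

    for marker in cohort.marker_names:
        for group in GROUPS:
            ids, vals = cohort.marker_values(marker, group, with_ids=True)
            if vals.size < 2:
                n_excluded[(marker, group)] = 0
                continue
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1))
            lo, hi = mean - k * sd, mean + k * sd
            out_mask = (vals < lo) | (vals > hi)
            n_excluded[(marker, group)] = int(out_mask.sum())
            for sid, v in zip(np.asarray(ids)[out_mask], vals[out_mask]):
                outlier_log.append((marker, group, str(sid), float(v)))
                by_id[str(sid)].markers[marker] = None

    lod_flagged: list[str] = []
    lod_table = lod_table or {}
    for marker in cohort.marker_names:
        if marker not in lod_table:
            if lod_table:
                logger.warning("marker %s missing from LOD table; cannot be flagged", marker)
            continue
        lod = lod_table[marker]
        for group in GROUPS:
            vals = cleaned.marker_values(marker, group)
            if vals.size and float(vals.mean()) < lod:
                lod_flagged.append(marker)
                break

    return QcResult(cleaned=cleaned, outlier_log=outlier_log,
                    lod_flagged_markers=lod_flagged, k=k, lod_policy=lod_policy,
                    n_excluded=n_excluded)
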