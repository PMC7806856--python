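"""Packaged study constants: published group summaries, diagnostic table,
covariate descriptives, and odds-ratio unit scales.

These constants describe a 110-subject case-control study of urinary
cytokines in ESSIC type 2 interstitial cystitis / bladder pain syndrome
(IC/BPS, n=40), medication-refractory overactive bladder (OAB, n=40), and
stress-incontinence controls (n=30): per-marker per-group mean ± SD with
outlier counts, per-marker ROC diagnostics (AUC, Youden-optimal cutoff,
sensitivity/specificity/PPV/NPV) for the diseased-vs-control and IC-vs-OAB
contrasts, and the pg/mL increments to which adjusted odds ratios were
scaled. They drive the synthetic cohort generator's moment targets, the
default diagnostic-cascade cutoffs, and the internal-consistency identities
linking printed sensitivity/specificity to printed predictive values.

Markers are keyed by ASCII alias (see :mod:`cytocascade.io_core`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from .io_core import GROUPS, PANEL_MARKERS

# ---------------------------------------------------------------------------
# Group sizes
# ---------------------------------------------------------------------------

GROUP_SIZES = {"OAB": 40, "IC_BPS": 40, "CONTROL": 30}

# ---------------------------------------------------------------------------
# Covariate descriptives per group: age mean/sd, sex counts, DM count,
# BMI mean/sd.
# ---------------------------------------------------------------------------

TABLE1_COVARIATES = {
    "OAB": {"age_mean": 64.7, "age_sd": 8.9, "n_female": 30, "n_male": 10,
            "n_dm": 13, "bmi_mean": 26.05, "bmi_sd": 3.49},
    "IC_BPS": {"age_mean": 49.3, "age_sd": 12.1, "n_female": 34, "n_male": 6,
               "n_dm": 2, "bmi_mean": 21.94, "bmi_sd": 3.92},
    "CONTROL": {"age_mean": 57.7, "age_sd": 10.1, "n_female": 30, "n_male": 0,
                "n_dm": 3, "bmi_mean": 25.60, "bmi_sd": 4.39},
}

# ---------------------------------------------------------------------------
# Per-marker per-group concentration summaries (pg/mL):
# marker -> group -> (mean, sd, n_outliers)
# ---------------------------------------------------------------------------

TABLE2_SUMMARIES: dict[str, dict[str, tuple[float, float, int]]] = {
    "MCP-1":    {"OAB": (240.83, 188.74, 2), "IC_BPS": (524.61, 511.31, 0), "CONTROL": (147.14, 109.74, 1)},
    "MIP-1a":   {"OAB": (1.60, 1.03, 0),     "IC_BPS": (1.09, 0.58, 0),     "CONTROL": (1.34, 0.75, 1)},
    "MIP-1b":   {"OAB": (2.91, 2.27, 1),     "IC_BPS": (2.93, 1.38, 2),     "CONTROL": (2.52, 1.82, 1)},
    "RANTES":   {"OAB": (6.65, 5.23, 1),     "IC_BPS": (12.75, 7.59, 1),    "CONTROL": (6.04, 5.15, 1)},
    "Eotaxin":  {"OAB": (4.65, 3.73, 2),     "IC_BPS": (11.87, 8.41, 1),    "CONTROL": (4.98, 3.70, 0)},
    "G-CSF":    {"OAB": (7.92, 7.58, 1),     "IC_BPS": (7.04, 7.05, 2),     "CONTROL": (11.72, 10.17, 1)},
    "GM-CSF":   {"OAB": (1.35, 0.48, 2),     "IC_BPS": (1.30, 0.46, 0),     "CONTROL": (1.24, 0.50, 1)},
    "VEGF":     {"OAB": (13.64, 4.95, 1),    "IC_BPS": (12.82, 6.68, 1),    "CONTROL": (10.97, 5.00, 0)},
    "NGF":      {"OAB": (0.27, 0.07, 1),     "IC_BPS": (0.35, 0.15, 1),     "CONTROL": (0.26, 0.08, 0)},
    "EGF":      {"OAB": (5454.83, 3767.41, 0), "IC_BPS": (6833.88, 4476.67, 0), "CONTROL": (6224.35, 4906.68, 0)},
    "CXCL10":   {"OAB": (24.77, 41.77, 1),   "IC_BPS": (62.24, 49.15, 2),   "CONTROL": (13.81, 18.43, 1)},
    "IFNa2":    {"OAB": (3.66, 1.75, 1),     "IC_BPS": (3.39, 1.89, 1),     "CONTROL": (3.22, 1.52, 1)},
    "IFNg":     {"OAB": (1.23, 0.19, 2),     "IC_BPS": (1.19, 0.30, 0),     "CONTROL": (1.19, 0.19, 1)},
    "TNFa":     {"OAB": (0.82, 0.34, 1),     "IC_BPS": (0.71, 0.25, 1),     "CONTROL": (0.82, 0.33, 1)},
    "TNFb":     {"OAB": (0.79, 0.13, 1),     "IC_BPS": (0.74, 0.12, 1),     "CONTROL": (0.76, 0.12, 1)},
    "IL-1a":    {"OAB": (1.80, 1.39, 0),     "IC_BPS": (1.35, 0.44, 1),     "CONTROL": (1.43, 0.75, 1)},
    "IL-1b":    {"OAB": (0.50, 0.15, 2),     "IC_BPS": (0.52, 0.16, 1),     "CONTROL": (0.56, 0.27, 1)},
    "IL-1RA":   {"OAB": (390.56, 507.03, 1), "IC_BPS": (467.29, 396.94, 1), "CONTROL": (325.52, 387.05, 1)},
    "IL-2":     {"OAB": (0.72, 0.17, 0),     "IC_BPS": (0.82, 0.17, 0),     "CONTROL": (0.80, 0.19, 1)},
    "IL-3":     {"OAB": (0.59, 0.22, 0),     "IC_BPS": (0.51, 0.17, 0),     "CONTROL": (0.64, 0.25, 0)},
    "IL-4":     {"OAB": (15.3, 10.88, 1),    "IC_BPS": (12.44, 8.57, 0),    "CONTROL": (11.07, 15.16, 1)},
    "IL-5":     {"OAB": (0.61, 0.23, 1),     "IC_BPS": (0.44, 0.11, 1),     "CONTROL": (0.54, 0.17, 1)},
    "IL-6":     {"OAB": (1.73, 2.34, 1),     "IC_BPS": (2.36, 3.18, 2),     "CONTROL": (1.29, 1.35, 1)},
    "IL-7":     {"OAB": (1.41, 0.44, 1),     "IC_BPS": (1.59, 0.63, 1),     "CONTROL": (1.52, 0.81, 1)},
    "IL-8":     {"OAB": (10.83, 12.28, 2),   "IC_BPS": (10.97, 11.06, 0),   "CONTROL": (12.45, 20.98, 1)},
    "IL-10":    {"OAB": (1.48, 0.45, 1),     "IC_BPS": (0.97, 0.31, 1),     "CONTROL": (1.23, 0.32, 1)},
    "IL-12p40": {"OAB": (0.90, 0.40, 1),     "IC_BPS": (0.99, 0.45, 0),     "CONTROL": (0.79, 0.32, 0)},
    "IL-12p70": {"OAB": (1.34, 0.33, 1),     "IC_BPS": (1.14, 0.38, 1),     "CONTROL": (1.28, 0.42, 0)},
    "IL-13":    {"OAB": (1.19, 0.38, 1),     "IC_BPS": (1.21, 0.29, 1),     "CONTROL": (1.24, 0.40, 1)},
    "IL-15":    {"OAB": (1.64, 0.91, 1),     "IC_BPS": (1.43, 0.55, 1),     "CONTROL": (1.21, 0.37, 1)},
    "IL-17A":   {"OAB": (0.93, 0.18, 1),     "IC_BPS": (0.80, 0.17, 0),     "CONTROL": (0.97, 0.20, 1)},
}

#: Markers whose group means fell below the manufacturer's minimum
#: detectable concentration in at least one study group.
LOD_FLAGGED_MARKERS = (
    "MIP-1a", "GM-CSF", "VEGF", "TNFb", "IL-1a", "IL-1b", "IL-2", "IL-3",
    "IL-5", "IL-12p40", "IL-13",
)

# ---------------------------------------------------------------------------
# Per-marker diagnostics by contrast.
#
# For the diseased-vs-control contrast the positive class is {IC_BPS, OAB};
# for ic_vs_oab it is IC_BPS. ``direction`` says which side of the cutoff is
# a positive call: POS_HIGHER means value > cutoff, POS_LOWER value < cutoff
# (markers where higher values point to the *negative* class: IL-17A for
# diseased-vs-control, and IL-10 / IL-12p70 / IL-17A for IC-vs-OAB, where
# higher values indicate OAB).
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Table3Row:
    marker: str
    contrast: str
    auc: float
    cutoff: float          # pg/mL
    sens: float            # percent
    spec: float            # percent
    ppv: float             # percent
    npv: float             # percent
    direction: str = "POS_HIGHER"


_T3 = Table3Row

TABLE3_ROWS: tuple[Table3Row, ...] = (
    # --- diseased (IC/BPS + OAB) vs control ---
    _T3("MCP-1",   "diseased_vs_control", 0.753, 204.235, 60.3, 72.4, 85.5, 40.4),
    _T3("IL-4",    "diseased_vs_control", 0.703, 10.610, 54.4, 86.2, 91.5, 41.0),
    _T3("CXCL10",  "diseased_vs_control", 0.685, 7.500, 66.2, 65.5, 83.6, 42.2),
    _T3("MIP-1b",  "diseased_vs_control", 0.674, 1.385, 92.2, 44.8, 81.6, 68.4),
    _T3("RANTES",  "diseased_vs_control", 0.666, 7.805, 53.8, 75.9, 85.7, 37.9),
    _T3("IL-8",    "diseased_vs_control", 0.651, 2.785, 82.1, 44.8, 80.0, 48.1),
    _T3("IL-17A",  "diseased_vs_control", 0.642, 0.925, 65.8, 62.1, 82.5, 40.0, "POS_LOWER"),
    _T3("IL-6",    "diseased_vs_control", 0.631, 1.165, 50.0, 79.3, 86.7, 37.7),
    _T3("NGF",     "diseased_vs_control", 0.624, 0.315, 41.0, 80.0, 84.2, 34.3),
    _T3("IL-15",   "diseased_vs_control", 0.611, 0.855, 97.4, 24.1, 77.6, 77.8),
    _T3("G-CSF",   "diseased_vs_control", 0.605, 4.820, 53.2, 72.4, 83.7, 36.8),
    _T3("Eotaxin", "diseased_vs_control", 0.604, 7.270, 40.3, 80.0, 83.8, 34.3),
    # --- IC/BPS vs OAB (positive class IC/BPS) ---
    _T3("IL-10",    "ic_vs_oab", 0.829, 1.025, 74.4, 92.3, 90.6, 78.3, "POS_LOWER"),
    _T3("RANTES",   "ic_vs_oab", 0.814, 9.305, 61.5, 82.1, 77.4, 68.1),
    _T3("Eotaxin",  "ic_vs_oab", 0.774, 9.035, 59.0, 89.5, 85.2, 68.0),
    _T3("CXCL10",   "ic_vs_oab", 0.768, 40.495, 65.8, 82.1, 78.1, 71.1),
    _T3("IL-12p70", "ic_vs_oab", 0.739, 1.085, 51.3, 94.9, 90.9, 66.1, "POS_LOWER"),
    _T3("NGF",      "ic_vs_oab", 0.725, 0.355, 35.9, 84.6, 70.0, 56.9),
    _T3("IL-6",     "ic_vs_oab", 0.716, 1.515, 52.6, 82.1, 74.1, 64.0),
    _T3("IL-17A",   "ic_vs_oab", 0.708, 0.885, 70.0, 59.0, 63.6, 65.7, "POS_LOWER"),
    _T3("MCP-1",    "ic_vs_oab", 0.704, 120.385, 90.0, 42.1, 62.1, 80.0),
    _T3("IL-1RA",   "ic_vs_oab", 0.703, 113.05, 89.7, 43.6, 61.4, 81.0),
)

# ---------------------------------------------------------------------------
# Odds-ratio unit scales (pg/mL per OR unit) from the adjusted logistic
# models; an OR is reported per this increment of the marker.
# ---------------------------------------------------------------------------

OR_UNITS = {
    "MCP-1": 100.0,
    "IL-10": 0.1,
    "CXCL10": 10.0,
    "Eotaxin": 1.0,
    "RANTES": 1.0,
    "NGF": 0.01,
    "IL-17A": 0.01,
    "IL-12p70": 0.1,
    "IFNa2": 1.0,
}


@dataclass(frozen=True)
class FixtureConstants:
    """Bundle of the published study constants."""

    group_sizes: dict[str, int] = field(default_factory=lambda: dict(GROUP_SIZES))
    table1_covariates: dict[str, dict] = field(
        default_factory=lambda: {g: dict(v) for g, v in TABLE1_COVARIATES.items()})
    table2_summaries: dict[str, dict[str, tuple[float, float, int]]] = field(
        default_factory=lambda: {m: dict(v) for m, v in TABLE2_SUMMARIES.items()})
    table3_rows: tuple[Table3Row, ...] = TABLE3_ROWS
    lod_flagged_markers: tuple[str, ...] = LOD_FLAGGED_MARKERS
    or_units: dict[str, float] = field(default_factory=lambda: dict(OR_UNITS))

    @property
    def table3(self) -> dict[tuple[str, str], Table3Row]:
        return {(r.marker, r.contrast): r for r in self.table3_rows}

    def table2(self, marker: str, group: str) -> tuple[float, float, int]:
        """(mean, sd, n_outliers) for a marker in a group."""
        return self.table2_summaries[marker][group]

    def adjusted_n(self, group: str, marker: str) -> int:
        """Group size after removing that marker's reported outliers."""
        return self.group_sizes[group] - self.table2_summaries[marker][group][2]

    def contrast_ns(self, marker: str, contrast: str) -> tuple[int, int]:
        """(n_positive, n_negative) denominators for a diagnostic row,
        i.e. enrolled group sizes minus the marker's reported outliers."""
        if contrast == "diseased_vs_control":
            n_pos = self.adjusted_n("IC_BPS", marker) + self.adjusted_n("OAB", marker)
            n_neg = self.adjusted_n("CONTROL", marker)
        elif contrast == "ic_vs_oab":
            n_pos = self.adjusted_n("IC_BPS", marker)
            n_neg = self.adjusted_n("OAB", marker)
        else:
            raise KeyError(f"unknown contrast {contrast!r}")
        return n_pos, n_neg


@lru_cache(maxsize=1)
def load_fixtures() -> FixtureConstants:
    """Return the packaged study constants (cached)."""
    fx = FixtureConstants()
    assert set(fx.table2_summaries) == set(PANEL_MARKERS)
    assert all(set(v) == set(GROUPS) for v in fx.table2_summaries.values())
    return fx


def default_lod_table(factor_flagged: float = 1.2, factor_clear: float = 0.5) -> dict[str, float]:
    """Synthetic stand-in for the manufacturer's LOD table.

    The assay vendor's minimum detectable concentrations are not published,
    only *which* markers fell below them. This constructs per-marker LODs
    from the published group means so that, on moment-matched data, exactly
    the flagged markers trip the below-LOD rule: flagged markers get an LOD
    just above their smallest group mean, all others an LOD well below it.
    """
    lod = {}
    for marker, groups in TABLE2_SUMMARIES.items():
        min_mean = min(mean for mean, _, _ in groups.values())
        factor = factor_flagged if marker in LOD_FLAGGED_MARKERS else factor_clear
        lod[marker] = round(factor * min_mean, 4)
    return lod
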