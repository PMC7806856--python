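"""Covariate-adjusted logistic odds ratios.

Fits, per marker and binary contrast, the maximum-likelihood logistic model

    logit P(case) = b0 + b1·(marker / unit_scale) + b2·age + b3·sex + b4·BMI + b5·DM

on complete cases, and reports exp(b1) — the odds ratio per ``unit_scale``
pg/mL of the marker — with a Wald 95% CI. Sex is coded F=0/M=1 and diabetes
no=0/yes=1; continuous covariates enter unscaled, so the unit scaling
applies to the marker term only. Perfect separation or optimizer failure is
reported via ``converged=False`` rather than a spurious estimate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io_core import CohortTable
from .diagnostics import Contrast, IC_VS_CONTROL, IC_VS_OAB, OAB_VS_CONTROL
from .fixtures import load_fixtures

logger = logging.getLogger(__name__)

COVARIATES = ("age", "sex_m", "bmi", "dm")


@dataclass(frozen=True)
class LogisticFit:
    contrast: str
    marker: str
    unit_scale: float            # pg/mL per OR unit
    odds_ratio: float | None
    ci95: tuple[float, float] | None
    p_value: float | None
    n: int
    converged: bool
    message: str = ""


def _design(cohort: CohortTable, contrast: Contrast, marker: str
            ) -> tuple[pd.DataFrame, pd.Series]:
    df = cohort.to_dataframe()
    df = df[df["group"].isin(contrast.positive + contrast.negative)].copy()
    df["y"] = df["group"].isin(contrast.positive).astype(int)
    df["sex_m"] = (df["sex"] == "M").astype(int)
    df = df.dropna(subset=[marker, "age", "bmi"])
    X = df[[marker, "age", "sex_m", "bmi", "dm"]].astype(float)
    return X, df["y"]


def fit_marker_logit(cohort: CohortTable, contrast: Contrast, marker: str,
                     unit_scale: float = 1.0) -> LogisticFit:
    """Adjusted logistic fit for one marker; OR per ``unit_scale`` pg/mL."""
    if unit_scale <= 0:
        raise ValueError(f"unit_scale must be > 0, got {unit_scale}")
    X, y = _design(cohort, contrast, marker)
    n = len(y)
    if n == 0 or y.nunique() < 2:
        return LogisticFit(contrast.name, marker, unit_scale, None, None, None,
                           n, False, "outcome has a single class")
    X = X.copy()
    X[marker] = X[marker] / unit_scale
    # A binary nuisance covariate whose level appears in only one outcome
    # class (e.g. sex when every control is female, so all men are cases)
    # has no finite MLE; drop it rather than let the fit diverge. The
    # marker term keeps its separation check below.
    notes = []
    for cov in ("sex_m", "dm"):
        tab = pd.crosstab(X[cov], y)
        if X[cov].nunique() < 2 or (tab.to_numpy() == 0).any():
            X = X.drop(columns=[cov])
            notes.append(f"{cov} dropped (quasi-separated or constant)")
    X = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", False))
        # near-separation shows up as an exploding Wald SE on the marker term
        if not np.isfinite(res.bse[marker]) or res.bse[marker] > 1e3:
            converged = False
    except Exception as exc:  # PerfectSeparationError and friends
        return LogisticFit(contrast.name, marker, unit_scale, None, None, None,
                           n, False, f"fit failed: {exc}")
    if not converged:
        return LogisticFit(contrast.name, marker, unit_scale, None, None, None,
                           n, False, "did not converge (possible separation)")
    beta = float(res.params[marker])
    se = float(res.bse[marker])
    z = stats.norm.ppf(0.975)
    return LogisticFit(
        contrast=contrast.name, marker=marker, unit_scale=unit_scale,
        odds_ratio=float(np.exp(beta)),
        ci95=(float(np.exp(beta - z * se)), float(np.exp(beta + z * se))),
        p_value=float(res.pvalues[marker]), n=n, converged=True,
        message="; ".join(notes),
    )


def run_or_table(cohort: CohortTable, unit_table: dict[str, float] | None = None
                 ) -> list[LogisticFit]:
    """Adjusted ORs for every marker in ``unit_table`` across the three
    pairwise contrasts (OAB vs control, IC/BPS vs control, IC/BPS vs OAB),
    sorted by contrast then marker."""
    unit_table = unit_table if unit_table is not None else load_fixtures().or_units
    fits = []
    for contrast in (OAB_VS_CONTROL, IC_VS_CONTROL, IC_VS_OAB):
        for marker in sorted(unit_table):
            fits.append(fit_marker_logit(cohort, contrast, marker, unit_table[marker]))
    return fits


# conventional alias: the adjusted-OR table is the fourth table of a
# standard biomarker report (descriptives, summaries, diagnostics, ORs)
run_table4 = run_or_table
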