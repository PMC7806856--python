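"""Synthetic cohort generation.

Simulates case-control cohorts with the statistical structure the analysis
pipeline assumes: per-group marker concentrations drawn from right-skewed
nonnegative distributions moment-matched to published group means/SDs,
covariates (age, sex, BMI, diabetes) matched to published descriptives, and
sporadic extreme outliers injected at recorded positions so QC recovery can
be scored against ground truth.

The default family is lognormal: urinary cytokine concentrations are
nonnegative and strongly right-skewed (several markers have SD of the same
order as the mean, which a symmetric positive-valued variable cannot
produce). A zero-truncated Gaussian family is available for sensitivity
analysis; its realized moments only approximate the targets when the
coefficient of variation is large, because truncation shifts them.

Markers are generated independently within subject — the source summaries
carry no covariance information — and covariates do not influence marker
levels by default. An optional per-marker log-scale covariate effect
(``covariate_effects``) exists so the covariate-adjusted regression module
can be exercised against a known signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_core import GROUPS, CohortTable, MarkerMeta, SubjectRecord, default_panel
from .fixtures import load_fixtures

FAMILIES = ("lognormal", "gaussian_truncated_at_zero")


def lognormal_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Log-scale ``(mu, sigma)`` of the lognormal with the given mean and SD.

    Uses the closed-form moment inversion ``sigma^2 = ln(1 + sd^2/mean^2)``,
    ``mu = ln(mean) - sigma^2/2``; the implied lognormal has exactly the
    requested arithmetic mean and SD. ``sd=0`` degenerates to a point mass
    at ``mean``.
    """
    if mean <= 0:
        raise ValueError(f"lognormal moment matching requires mean > 0, got {mean}")
    if sd < 0:
        raise ValueError(f"sd must be >= 0, got {sd}")
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


@dataclass(frozen=True)
class MarkerGroupSpec:
    """Distribution target for one marker in one group."""

    marker: str
    group: str
    target_mean: float  # pg/mL
    target_sd: float    # pg/mL
    family: str = "lognormal"

    def __post_init__(self) -> None:
        if self.target_mean <= 0:
            raise ValueError(f"{self.marker}/{self.group}: target_mean must be > 0")
        if self.target_sd < 0:
            raise ValueError(f"{self.marker}/{self.group}: target_sd must be >= 0")
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")


@dataclass(frozen=True)
class CovariateGroupSpec:
    """Covariate-generating parameters for one group."""

    age_mean: float
    age_sd: float
    female_prop: float
    dm_prop: float
    bmi_mean: float
    bmi_sd: float


@dataclass
class GeneratorSpec:
    """Full recipe for one synthetic cohort."""

    n_per_group: dict[str, int]
    marker_specs: list[MarkerGroupSpec]
    covariates: dict[str, CovariateGroupSpec]
    outlier_rate: float = 0.0        # per-cell injection probability
    outlier_magnitude: float = 5.0   # SD multiples beyond the mean
    covariate_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.outlier_rate <= 0.05:
            raise ValueError(f"outlier_rate must be in [0, 0.05], got {self.outlier_rate}")
        for g, n in self.n_per_group.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if n < 2:
                raise ValueError(f"n_per_group[{g!r}] must be >= 2, got {n}")

    @property
    def marker_names(self) -> tuple[str, ...]:
        seen: list[str] = []
        for ms in self.marker_specs:
            if ms.marker not in seen:
                seen.append(ms.marker)
        return tuple(seen)


@dataclass
class GroundTruth:
    """What the generator actually did, for recovery tests."""

    outlier_positions: list[tuple[str, str]]            # (subject_id, marker)
    latent_params: dict[tuple[str, str], tuple[float, float]]  # (marker, group) -> (mu, sigma)
    outlier_values: dict[tuple[str, str], float] = field(default_factory=dict)


def _draw_marker(rng: np.random.Generator, ms: MarkerGroupSpec, n: int) -> np.ndarray:
    if ms.family == "lognormal":
        mu, sigma = lognormal_params_from_moments(ms.target_mean, ms.target_sd)
        if sigma == 0.0:
            return np.full(n, ms.target_mean)
        return rng.lognormal(mean=mu, sigma=sigma, size=n)
    # zero-truncated Gaussian: rejection-free via repeated clipping-free redraw
    out = rng.normal(ms.target_mean, ms.target_sd, size=n)
    for _ in range(100):
        bad = out <= 0
        if not bad.any():
            break
        out[bad] = rng.normal(ms.target_mean, ms.target_sd, size=int(bad.sum()))
    np.clip(out, 1e-12, None, out=out)
    return out


def generate_cohort(spec: GeneratorSpec) -> tuple[CohortTable, GroundTruth]:
    """Draw one cohort from ``spec``; reproducible for a fixed seed.

    Outlier injection replaces a cell with
    ``target_mean + U(magnitude, magnitude + 3) * target_sd`` so injected
    points are guaranteed to sit far outside the bulk of the distribution;
    positions and values are recorded in the returned :class:`GroundTruth`.
    """
    rng = np.random.default_rng(spec.seed)
    specs_by_group: dict[str, list[MarkerGroupSpec]] = {g: [] for g in GROUPS}
    for ms in spec.marker_specs:
        specs_by_group[ms.group].append(ms)

    subjects: list[SubjectRecord] = []
    truth = GroundTruth(outlier_positions=[], latent_params={})

    for group in GROUPS:
        n = spec.n_per_group.get(group, 0)
        if n == 0:
            continue
        cov = spec.covariates[group]
        ages = rng.normal(cov.age_mean, cov.age_sd, size=n)
        bmis = np.clip(rng.normal(cov.bmi_mean, cov.bmi_sd, size=n), 12.0, None)
        female = rng.random(n) < cov.female_prop
        dm = rng.random(n) < cov.dm_prop
        ids = [f"{group}-{i + 1:03d}" for i in range(n)]
        records = [
            SubjectRecord(subject_id=ids[i], group=group,
                          age=float(np.clip(ages[i], 18.0, None)),
                          sex="F" if female[i] else "M",
                          bmi=float(bmis[i]), dm=bool(dm[i]), markers={})
            for i in range(n)
        ]
        for ms in specs_by_group[group]:
            values = _draw_marker(rng, ms, n)
            if ms.family == "lognormal":
                truth.latent_params[(ms.marker, group)] = lognormal_params_from_moments(
                    ms.target_mean, ms.target_sd)
            effects = spec.covariate_effects.get(ms.marker)
            if effects:
                # multiplicative (log-scale linear) covariate influence
                log_shift = np.zeros(n)
                for i, rec in enumerate(records):
                    log_shift[i] = (
                        effects.get("age", 0.0) * rec.age
                        + effects.get("bmi", 0.0) * rec.bmi
                        + effects.get("sex_m", 0.0) * (rec.sex == "M")
                        + effects.get("dm", 0.0) * rec.dm
                    )
                values = values * np.exp(log_shift)
            inject = rng.random(n) < spec.outlier_rate
            if inject.any():
                shift = rng.uniform(spec.outlier_magnitude, spec.outlier_magnitude + 3.0,
                                    size=int(inject.sum()))
                values = values.copy()
                values[inject] = ms.target_mean + shift * ms.target_sd
                for i in np.flatnonzero(inject):
                    truth.outlier_positions.append((ids[i], ms.marker))
                    truth.outlier_values[(ids[i], ms.marker)] = float(values[i])
            for i, rec in enumerate(records):
                rec.markers[ms.marker] = float(values[i])
        subjects.extend(records)

    panel = [MarkerMeta(m) for m in spec.marker_names] or default_panel()
    return CohortTable(subjects=subjects, panel=panel), truth


def default_paper_spec(seed: int = 0, n_per_group: dict[str, int] | None = None,
                       outlier_rate: float = 0.025,
                       family: str = "lognormal") -> GeneratorSpec:
    """Generator spec matching the published study conditions.

    Group sizes 40 (OAB) / 40 (IC/BPS) / 30 (control); 31 markers x 3
    groups = 93 moment targets taken from the published group summaries;
    covariates from the published descriptives (controls are all women).
    ``outlier_rate`` defaults to 0.025 so each marker-by-group cell expects
    about one injected extreme value, matching the reported 0-2 outliers
    per cell.
    """
    fx = load_fixtures()
    n_per_group = dict(n_per_group or fx.group_sizes)
    marker_specs = [
        MarkerGroupSpec(marker=m, group=g, target_mean=mean, target_sd=sd, family=family)
        for m, groups in fx.table2_summaries.items()
        for g, (mean, sd, _) in groups.items()
    ]
    covariates = {}
    for g, c in fx.table1_covariates.items():
        n_enrolled = fx.group_sizes[g]
        covariates[g] = CovariateGroupSpec(
            age_mean=c["age_mean"], age_sd=c["age_sd"],
            female_prop=c["n_female"] / n_enrolled,
            dm_prop=c["n_dm"] / n_enrolled,
            bmi_mean=c["bmi_mean"], bmi_sd=c["bmi_sd"],
        )
    return GeneratorSpec(n_per_group=n_per_group, marker_specs=marker_specs,
                         covariates=covariates, outlier_rate=outlier_rate, seed=seed)
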