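"""Shared fixtures: small hand-built cohorts and seeded generators."""

import numpy as np
import pytest

from cytocascade import (
    CohortTable, MarkerMeta, SubjectRecord, apply_qc, default_paper_spec,
    generate_cohort,
)


def make_subject(sid, group, markers, age=55.0, sex="F", bmi=24.0, dm=False):
    return SubjectRecord(subject_id=sid, group=group, age=age, sex=sex,
                         bmi=bmi, dm=dm, markers=dict(markers))


def make_cohort(marker_values: dict[str, dict[str, list[float | None]]]) -> CohortTable:
    """Build a cohort from {marker: {group: [values...]}}; subjects are
    aligned by index within each group."""
    groups = sorted({g for per in marker_values.values() for g in per})
    n_per = {g: max(len(per[g]) for per in marker_values.values() if g in per)
             for g in groups}
    subjects = []
    for g in groups:
        for i in range(n_per[g]):
            markers = {}
            for m, per in marker_values.items():
                vals = per.get(g, [])
                markers[m] = vals[i] if i < len(vals) else None
            subjects.append(make_subject(f"{g}-{i:03d}", g, markers))
    panel = [MarkerMeta(m) for m in marker_values]
    return CohortTable(subjects=subjects, panel=panel)


@pytest.fixture
def tiny_cohort():
    return make_cohort({
        "MIP-1b": {"OAB": [2.0, 3.0, 2.5], "IC_BPS": [3.0, 2.8, 3.2], "CONTROL": [1.0, 1.2, 0.9]},
        "IL-10": {"OAB": [1.6, 1.5, 1.4], "IC_BPS": [0.9, 1.0, 0.8], "CONTROL": [1.2, 1.3, 1.1]},
    })


@pytest.fixture(scope="session")
def paper_cohort_qc():
    """One seeded cohort at the study's group sizes, with QC applied."""
    cohort, truth = generate_cohort(default_paper_spec(seed=2024))
    return cohort, truth, apply_qc(cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
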