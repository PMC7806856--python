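"""Data model and file I/O for urine-cytokine cohort tables.

The cohort format is a wide CSV: one row per subject with columns
``subject_id, group, age, sex, bmi, dm`` followed by one column per marker
(concentrations in pg/mL). Marker columns use ASCII aliases (``MIP-1b``,
``IFNa2``) to avoid Unicode key bugs; :data:`DISPLAY_NAMES` maps aliases to
the conventional Greek-letter names for presentation.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

GROUPS = ("OAB", "IC_BPS", "CONTROL")
SEXES = ("F", "M")

#: ASCII marker aliases, in assay-panel order (30-plex inflammation panel + NGF).
PANEL_MARKERS = (
    "MCP-1", "MIP-1a", "MIP-1b", "RANTES", "Eotaxin", "G-CSF", "GM-CSF",
    "VEGF", "NGF", "EGF", "CXCL10", "IFNa2", "IFNg", "TNFa", "TNFb",
    "IL-1a", "IL-1b", "IL-1RA", "IL-2", "IL-3", "IL-4", "IL-5", "IL-6",
    "IL-7", "IL-8", "IL-10", "IL-12p40", "IL-12p70", "IL-13", "IL-15",
    "IL-17A",
)

DISPLAY_NAMES = {
    "MIP-1a": "MIP-1α",
    "MIP-1b": "MIP-1β",
    "IFNa2": "IFNα2",
    "IFNg": "IFNγ",
    "TNFa": "TNFα",
    "TNFb": "TNFβ",
    "IL-1a": "IL-1α",
    "IL-1b": "IL-1β",
}

COVARIATE_COLUMNS = ("subject_id", "group", "age", "sex", "bmi", "dm")


def display_name(marker: str) -> str:
    """Presentation name (Greek letters) for an ASCII marker alias."""
    return DISPLAY_NAMES.get(marker, marker)


@dataclass(frozen=True)
class MarkerMeta:
    """Panel metadata for one analyte.

    ``min_detectable_conc`` is the manufacturer's lowest reliably quantifiable
    concentration (pg/mL); ``direction_note`` records which class higher
    values point to when that is fixed a priori rather than estimated.
    """

    name: str
    min_detectable_conc: float | None = None
    direction_note: str = "AUTO"  # HIGHER_DISEASED | HIGHER_CONTROL | HIGHER_OAB | AUTO

    def __post_init__(self) -> None:
        if self.min_detectable_conc is not None and self.min_detectable_conc <= 0:
            raise ValueError(f"min_detectable_conc must be > 0, got {self.min_detectable_conc}")


@dataclass
class SubjectRecord:
    """One subject: diagnosis group, covariates, and the marker panel."""

    subject_id: str
    group: str
    age: float
    sex: str
    bmi: float
    dm: bool
    markers: dict[str, float | None] = field(default_factory=dict)

    def validate(self, panel_names: Sequence[str] | None = None) -> None:
        if self.group not in GROUPS:
            raise ValueError(
                f"subject {self.subject_id!r}: unknown group label {self.group!r} "
                f"(expected one of {GROUPS})"
            )
        if self.sex not in SEXES:
            raise ValueError(f"subject {self.subject_id!r}: unknown sex {self.sex!r}")
        for name, value in self.markers.items():
            if value is not None and value < 0:
                raise ValueError(
                    f"subject {self.subject_id!r}, marker {name!r}: "
                    f"negative concentration {value}"
                )
            if panel_names is not None and name not in panel_names:
                raise ValueError(
                    f"subject {self.subject_id!r}: marker {name!r} not in declared panel"
                )


def default_panel() -> list[MarkerMeta]:
    """The 31-analyte panel with no LOD annotations."""
    return [MarkerMeta(name) for name in PANEL_MARKERS]


@dataclass
class CohortTable:
    """A validated cohort: subjects plus the declared marker panel."""

    subjects: list[SubjectRecord]
    panel: list[MarkerMeta] = field(default_factory=default_panel)

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate subject_ids: {dupes}")
        names = self.marker_names
        for s in self.subjects:
            s.validate(panel_names=names)

    @property
    def marker_names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.panel)

    def __len__(self) -> int:
        return len(self.subjects)

    def group_subjects(self, group: str) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.group == group]

    def marker_values(self, marker: str, group: str | None = None,
                      with_ids: bool = False):
        """Non-missing values of ``marker`` (optionally restricted to a group).

        Returns an ndarray, or ``(ids, ndarray)`` when ``with_ids``.
        """
        subjects = self.subjects if group is None else self.group_subjects(group)
        ids, vals = [], []
        for s in subjects:
            v = s.markers.get(marker)
            if v is not None and not (isinstance(v, float) and math.isnan(v)):
                ids.append(s.subject_id)
                vals.append(float(v))
        arr = np.asarray(vals, dtype=float)
        return (ids, arr) if with_ids else arr

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            row: dict[str, Any] = {
                "subject_id": s.subject_id, "group": s.group, "age": s.age,
                "sex": s.sex, "bmi": s.bmi, "dm": int(s.dm),
            }
            for m in self.marker_names:
                v = s.markers.get(m)
                row[m] = np.nan if v is None else v
            rows.append(row)
        return pd.DataFrame(rows, columns=list(COVARIATE_COLUMNS) + list(self.marker_names))

    def copy(self) -> "CohortTable":
        return CohortTable(
            subjects=[dataclasses.replace(s, markers=dict(s.markers)) for s in self.subjects],
            panel=list(self.panel),
        )


def read_cohort(path: str | Path, panel: Sequence[MarkerMeta] | None = None) -> CohortTable:
    """Read a wide cohort CSV into a validated :class:`CohortTable`.

    Missing marker cells (empty or ``NA``) become missing values, never zero.
    Unknown group labels and negative concentrations are hard errors that name
    the offending row and column.
    """
    path = Path(path)
    df = pd.read_csv(path, na_values=["NA", "NaN", ""], keep_default_na=True)
    missing = [c for c in COVARIATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if panel is None:
        marker_cols = [c for c in df.columns if c not in COVARIATE_COLUMNS]
        panel = [MarkerMeta(c) for c in marker_cols]
    else:
        panel = list(panel)
        marker_cols = [m.name for m in panel if m.name in df.columns]

    subjects = []
    for idx, row in df.iterrows():
        group = str(row["group"])
        if group not in GROUPS:
            raise ValueError(
                f"{path} row {idx}: unknown group label {group!r} (expected one of {GROUPS})"
            )
        markers: dict[str, float | None] = {}
        for c in marker_cols:
            v = row[c]
            if pd.isna(v):
                markers[c] = None
            else:
                v = float(v)
                if v < 0:
                    raise ValueError(
                        f"{path} row {idx}, column {c!r}: negative concentration {v}"
                    )
                markers[c] = v
        subjects.append(SubjectRecord(
            subject_id=str(row["subject_id"]), group=group,
            age=float(row["age"]), sex=str(row["sex"]),
            bmi=float(row["bmi"]), dm=bool(int(row["dm"])), markers=markers,
        ))
    return CohortTable(subjects=subjects, panel=panel)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort back to wide CSV (inverse of :func:`read_cohort`)."""
    df = cohort.to_dataframe()
    df.to_csv(path, index=False, na_rep="NA")


def _as_record(item: Any) -> dict[str, Any]:
    if dataclasses.is_dataclass(item) and not isinstance(item, type):
        return dataclasses.asdict(item)
    if isinstance(item, Mapping):
        return dict(item)
    raise TypeError(f"cannot serialize result of type {type(item).__name__}")


def _fmt(value: Any, precision: int) -> Any:
    if isinstance(value, bool) or value is None:
        return value
    if isinstance(value, float):
        if math.isnan(value):
            return None
        return round(value, precision)
    return value


def write_report(results: Iterable[Any], path: str | Path, format: str = "tsv",
                 float_precision: int = 3, columns: Sequence[str] | None = None) -> None:
    """Serialize a homogeneous result collection to TSV or JSON.

    Column/key order follows the first record's field order (or explicit
    ``columns``) and is therefore deterministic; floats are rendered with
    fixed precision so repeated runs produce byte-identical files. An empty
    collection yields a header-only TSV (or an empty JSON array).
    """
    records = [_as_record(r) for r in results]
    path = Path(path)
    if format == "json":
        out = [{k: _fmt(v, float_precision) for k, v in r.items()} for r in records]
        path.write_text(json.dumps(out, indent=2, ensure_ascii=False) + "\n")
        return
    if format != "tsv":
        raise ValueError(f"unknown report format {format!r}")
    if not records:
        path.write_text("\t".join(columns) + "\n" if columns else "")
        return
    if columns is None:
        columns = list(records[0].keys())
    lines = ["\t".join(columns)]
    for r in records:
        cells = []
        for c in columns:
            v = _fmt(r.get(c), float_precision)
            if v is None:
                cells.append("NA")
            elif isinstance(v, float):
                cells.append(f"{v:.{float_precision}f}")
            else:
                cells.append(str(v))
        lines.append("\t".join(cells))
    path.write_text("\n".join(lines) + "\n")
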