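"""Subject-visit tables, longitudinal slopes, and the two analysis layers.

The analysis views a longitudinal cohort through two "data layers": a
baseline layer of descriptors measured at study entry, and a prognostic
layer of per-subject slopes summarising change over follow-up.  A slope
descriptor is named after its base measure with a leading ``S`` (``SFAQ``
is the 6-monthly change of ``FAQ``) and is estimated by simple linear
regression over all available visits, scaled to units of change per
6-month period.

This module reads long-format subject-visit CSV tables, applies the
inclusion rule (at least one informative post-baseline visit), computes
slope descriptors, and assembles the two row-aligned layers consumed by
the similarity and clustering stages.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, ParseError, SchemaError

logger = logging.getLogger(__name__)

#: Diagnosis codes recognised in visit tables.
DIAGNOSES = ("MCI", "Dementia", "CN")

#: Follow-up horizon in months; later visits are ignored so that cohorts
#: recruited at different times remain comparable over the same window.
DEFAULT_MAX_MONTH = 60.0

#: Descriptor categories used for reporting and network node colouring.
CATEGORIES = ("demographic", "clinical", "mri", "pet", "csf")


# ---------------------------------------------------------------------------
# Descriptor schema
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Descriptor:
    """A named measurement with a category and a direction of worsening.

    ``worse`` is ``'up'`` if larger values indicate more impairment
    (ADAS, CDR-SB, FAQ, ventricular volume, tau), ``'down'`` if smaller
    values do (MMSE, RAVLT, regional brain volumes, amyloid-beta), and
    ``'none'`` for neutral descriptors such as age or intracranial volume.
    """

    name: str
    category: str
    worse: str = "none"

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ConfigurationError(f"unknown descriptor category {self.category!r}")
        if self.worse not in ("up", "down", "none"):
            raise ConfigurationError(f"unknown worsening direction {self.worse!r}")


@dataclass(frozen=True)
class DescriptorSchema:
    """Declares the baseline descriptors and the longitudinal base measures.

    Slope descriptors are derived, not declared: every longitudinal base
    measure ``X`` contributes a slope descriptor ``SX`` that inherits the
    base measure's category.
    """

    baseline: tuple[Descriptor, ...]
    longitudinal: tuple[str, ...]

    @property
    def baseline_names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.baseline)

    @property
    def slope_names(self) -> tuple[str, ...]:
        return tuple("S" + name for name in self.longitudinal)

    @property
    def descriptor_names(self) -> tuple[str, ...]:
        return self.baseline_names + self.slope_names

    def category_of(self, name: str) -> str:
        by_name = {d.name: d.category for d in self.baseline}
        if name in by_name:
            return by_name[name]
        if name.startswith("S") and name[1:] in by_name:
            return by_name[name[1:]]
        raise ConfigurationError(f"unknown descriptor {name!r}")

    def worse_of(self, name: str) -> str:
        by_name = {d.name: d.worse for d in self.baseline}
        base = name[1:] if name.startswith("S") and name[1:] in by_name else name
        if base not in by_name:
            raise ConfigurationError(f"unknown descriptor {name!r}")
        return by_name[base]

    def to_yaml(self, path) -> None:
        doc = {
            "baseline": [
                {"name": d.name, "category": d.category, "worse": d.worse}
                for d in self.baseline
            ],
            "longitudinal": list(self.longitudinal),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "DescriptorSchema":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        baseline = tuple(
            Descriptor(d["name"], d["category"], d.get("worse", "none"))
            for d in doc["baseline"]
        )
        return cls(baseline=baseline, longitudinal=tuple(doc["longitudinal"]))


def default_schema() -> DescriptorSchema:
    """The default descriptor schema: 26 baseline and 17 slope descriptors.

    Baseline descriptors cover demographics and genetics, cognitive and
    functional scales, FreeSurfer-style regional brain volumes, PET SUVRs
    and CSF proteins.  The 17 longitudinal base measures (10 clinical +
    7 imaging) each contribute one ``S``-prefixed slope descriptor.
    """
    baseline = (
        Descriptor("AGE", "demographic"),
        Descriptor("EDUCATION", "demographic"),
        Descriptor("APOE4", "demographic", "up"),
        Descriptor("CDRSB", "clinical", "up"),
        Descriptor("ADAS11", "clinical", "up"),
        Descriptor("ADAS13", "clinical", "up"),
        Descriptor("MMSE", "clinical", "down"),
        Descriptor("MOCA", "clinical", "down"),
        Descriptor("FAQ", "clinical", "up"),
        Descriptor("RAVLT_immediate", "clinical", "down"),
        Descriptor("RAVLT_learning", "clinical", "down"),
        Descriptor("RAVLT_forgetting", "clinical", "up"),
        Descriptor("RAVLT_perc_forgetting", "clinical", "up"),
        Descriptor("LDELTOTAL", "clinical", "down"),
        Descriptor("Ventricles", "mri", "up"),
        Descriptor("Hippocampus", "mri", "down"),
        Descriptor("WholeBrain", "mri", "down"),
        Descriptor("Entorhinal", "mri", "down"),
        Descriptor("Fusiform", "mri", "down"),
        Descriptor("MidTemp", "mri", "down"),
        Descriptor("ICV", "mri"),
        Descriptor("FDG", "pet", "down"),
        Descriptor("AV45", "pet", "up"),
        Descriptor("ABETA", "csf", "down"),
        Descriptor("TAU", "csf", "up"),
        Descriptor("PTAU", "csf", "up"),
    )
    longitudinal = (
        "CDRSB", "ADAS11", "ADAS13", "MMSE", "FAQ", "MOCA",
        "RAVLT_immediate", "RAVLT_learning", "RAVLT_forgetting",
        "RAVLT_perc_forgetting",
        "Ventricles", "Hippocampus", "WholeBrain", "Entorhinal",
        "Fusiform", "MidTemp", "ICV",
    )
    return DescriptorSchema(baseline=baseline, longitudinal=longitudinal)


# ---------------------------------------------------------------------------
# Cohort containers
# ---------------------------------------------------------------------------

@dataclass
class VisitRecord:
    """One assessment visit: time in months from entry, clinician diagnosis
    (``MCI``/``Dementia``/``CN`` or ``None`` when not recorded), and the
    measurements taken at that visit."""

    subject_id: str
    month: float
    diagnosis: str | None
    measures: dict[str, float]


@dataclass
class CohortTable:
    """The study population: per-subject baseline values, visit series,
    diagnosis trajectory, and cohort/sex labels."""

    subjects: list[str]
    cohort_label: dict[str, str]
    sex: dict[str, str]
    baseline: dict[str, dict[str, float]]
    visits: dict[str, list[VisitRecord]]
    schema: DescriptorSchema = field(default_factory=default_schema)

    @property
    def n(self) -> int:
        return len(self.subjects)

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: one row per subject-visit, suitable for CSV."""
        columns = ["subject_id", "month", "diagnosis", "cohort", "sex"]
        names = sorted({k for vs in self.visits.values() for v in vs for k in v.measures})
        rows = []
        for sid in self.subjects:
            for v in self.visits[sid]:
                row = {
                    "subject_id": sid,
                    "month": v.month,
                    "diagnosis": v.diagnosis if v.diagnosis is not None else "",
                    "cohort": self.cohort_label.get(sid, ""),
                    "sex": self.sex.get(sid, ""),
                }
                for name in names:
                    row[name] = v.measures.get(name, np.nan)
                rows.append(row)
        return pd.DataFrame(rows, columns=columns + names)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class DataLayer:
    """An N x d numeric matrix view of the cohort (one of the algorithm's
    layers), with NaN as the missing-value marker.  Row order is shared
    across all layers of one analysis."""

    layer_id: str
    data: pd.DataFrame
    imputed_mask: pd.DataFrame | None = None

    @property
    def matrix(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def subjects(self) -> list[str]:
        return list(self.data.index)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="subject_id")

    @classmethod
    def from_csv(cls, path, layer_id: str | None = None) -> "DataLayer":
        data = pd.read_csv(path, index_col="subject_id")
        return cls(layer_id=layer_id or str(path), data=data)


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("subject_id", "month", "diagnosis")
_LABEL_COLUMNS = ("cohort", "sex")


def _normalise_diagnosis(raw) -> str | None:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    text = str(raw).strip()
    if text == "" or text.lower() in ("nan", "na", "missing"):
        return None
    for code in DIAGNOSES:
        if text.lower() == code.lower():
            return code
    if text.lower() in ("ad", "dementia to mci", "mci to dementia"):
        return "Dementia"
    if text.lower() in ("nl", "normal", "cognitively normal"):
        return "CN"
    raise ParseError(f"unrecognised diagnosis code {raw!r}")


def read_cohort(
    table_source,
    schema: DescriptorSchema | None = None,
    max_month: float = DEFAULT_MAX_MONTH,
) -> CohortTable:
    """Read a long-format subject-visit CSV into a :class:`CohortTable`.

    Required columns are ``subject_id``, ``month`` and ``diagnosis``;
    ``cohort`` and ``sex`` are picked up when present, and every other
    column matching a schema descriptor is treated as a measurement.
    Visits beyond ``max_month`` are discarded.  Subjects failing the
    inclusion rule — no post-baseline visit with a value for at least one
    longitudinal descriptor — are dropped and the drop count logged.

    Raises
    ------
    SchemaError
        if the file is empty or a required column is missing.
    ParseError
        on duplicate (subject, month) rows or non-numeric measurement cells.
    """
    schema = schema or default_schema()
    try:
        table = pd.read_csv(table_source)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError("input table is empty") from exc
    for col in _REQUIRED_COLUMNS:
        if col not in table.columns:
            raise SchemaError(f"required column {col!r} missing from input table")

    month = pd.to_numeric(table["month"], errors="coerce")
    bad = table.index[month.isna() & table["month"].notna()]
    if len(bad):
        raise ParseError(f"non-numeric month in row {bad[0]}")
    if month.isna().any():
        raise ParseError("missing month value")
    if (month < 0).any():
        raise ParseError("negative visit month")
    table = table.assign(month=month)

    dup = table.duplicated(subset=["subject_id", "month"])
    if dup.any():
        row = table.loc[dup, ["subject_id", "month"]].iloc[0]
        raise ParseError(
            f"duplicate visit for subject {row['subject_id']!r} at month {row['month']}"
        )

    known = set(schema.baseline_names) | set(schema.longitudinal)
    measure_cols = [c for c in table.columns if c in known]
    for col in measure_cols:
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[coerced.isna() & table[col].notna()]
        # pandas parses blanks to NaN already; anything left is a true parse failure
        bad = [i for i in bad if str(table.at[i, col]).strip() not in ("", "nan", "NA")]
        if bad:
            raise ParseError(f"non-numeric value {table.at[bad[0], col]!r} "
                             f"in column {col!r}, row {bad[0]}")
        table[col] = coerced

    table = table[table["month"] <= max_month]
    longit = [c for c in measure_cols if c in set(schema.longitudinal)]

    subjects: list[str] = []
    cohort_label: dict[str, str] = {}
    sex: dict[str, str] = {}
    baseline: dict[str, dict[str, float]] = {}
    visits: dict[str, list[VisitRecord]] = {}
    dropped = 0

    for sid, grp in table.groupby("subject_id", sort=True):
        grp = grp.sort_values("month")
        first_month = grp["month"].iloc[0]
        post = grp[grp["month"] > first_month]
        informative = bool(len(post)) and bool(
            post[longit].notna().any().any()
        ) if longit else bool(len(post))
        if not informative:
            dropped += 1
            continue
        sid = str(sid)
        subjects.append(sid)
        recs = []
        for _, row in grp.iterrows():
            measures = {
                c: float(row[c]) for c in measure_cols if pd.notna(row[c])
            }
            recs.append(VisitRecord(sid, float(row["month"]),
                                    _normalise_diagnosis(row["diagnosis"]), measures))
        visits[sid] = recs
        baseline[sid] = dict(recs[0].measures)
        for col, store in zip(_LABEL_COLUMNS, (cohort_label, sex)):
            if col in grp.columns and pd.notna(grp[col].iloc[0]):
                store[sid] = str(grp[col].iloc[0])

    if dropped:
        logger.info("read_cohort: dropped %d subject(s) without an informative "
                    "post-baseline visit", dropped)
    return CohortTable(subjects=subjects, cohort_label=cohort_label, sex=sex,
                       baseline=baseline, visits=visits, schema=schema)


# ---------------------------------------------------------------------------
# Slopes and layers
# ---------------------------------------------------------------------------

def compute_slope(months, values) -> float:
    """Least-squares slope of ``values`` against ``months``, per 6 months.

    Missing values are dropped pairwise; all remaining time points enter
    the fit.  Returns NaN (an "undefined slope", not an error) when fewer
    than two complete points remain or all months coincide.
    """
    m = np.asarray(months, dtype=float)
    v = np.asarray(values, dtype=float)
    if m.shape != v.shape:
        raise ConfigurationError("months and values must have equal length")
    keep = ~(np.isnan(m) | np.isnan(v))
    m, v = m[keep], v[keep]
    if m.size < 2:
        return float("nan")
    mc = m - m.mean()
    sxx = float(mc @ mc)
    if sxx == 0.0:
        return float("nan")
    slope_per_month = float(mc @ (v - v.mean())) / sxx
    return 6.0 * slope_per_month


def build_layers(
    cohort: CohortTable,
    baseline_names=None,
    slope_names=None,
) -> tuple[DataLayer, DataLayer]:
    """Assemble the baseline layer and the slope layer, row-aligned.

    Layer 1 holds the baseline values of ``baseline_names``; layer 2 holds
    the per-subject slopes (per 6 months) of the base measures behind
    ``slope_names``.  Subjects with insufficient visits for a slope get a
    missing cell but keep their row.
    """
    schema = cohort.schema
    baseline_names = list(baseline_names or schema.baseline_names)
    slope_names = list(slope_names or schema.slope_names)
    known_base = set(schema.baseline_names)
    for name in baseline_names:
        if name not in known_base:
            raise ConfigurationError(f"unknown baseline descriptor {name!r}")
    for name in slope_names:
        if not name.startswith("S") or name[1:] not in set(schema.longitudinal):
            raise ConfigurationError(f"unknown slope descriptor {name!r}")

    base_rows = []
    for sid in cohort.subjects:
        vals = cohort.baseline.get(sid, {})
        base_rows.append([vals.get(name, np.nan) for name in baseline_names])
    layer1 = pd.DataFrame(base_rows, index=cohort.subjects, columns=baseline_names,
                          dtype=float)

    slope_rows = []
    for sid in cohort.subjects:
        recs = cohort.visits[sid]
        row = []
        for name in slope_names:
            base = name[1:]
            months = [r.month for r in recs if base in r.measures]
            values = [r.measures[base] for r in recs if base in r.measures]
            row.append(compute_slope(months, values))
        slope_rows.append(row)
    layer2 = pd.DataFrame(slope_rows, index=cohort.subjects, columns=slope_names,
                          dtype=float)

    return (DataLayer("baseline", layer1), DataLayer("slope", layer2))


def impute_for_similarity(layer: DataLayer) -> DataLayer:
    """Median-impute missing cells for the similarity computation only.

    Returns a new layer whose NaN cells are replaced by the column median;
    the original layer is untouched and the imputation mask is retained on
    the result for reporting.  A fully-missing column is a configuration
    error, named in the message.
    """
    data = layer.data
    mask = data.isna()
    if not mask.any().any():
        return DataLayer(layer.layer_id, data.copy(), imputed_mask=mask)
    out = data.copy()
    for col in data.columns:
        if mask[col].any():
            non_missing = data[col].dropna()
            if non_missing.empty:
                raise ConfigurationError(
                    f"descriptor {col!r} has no observed values to impute from")
            out.loc[mask[col], col] = float(np.median(non_missing.to_numpy()))
    return DataLayer(layer.layer_id, out, imputed_mask=mask)
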