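"""Core domain types and long-format table I/O.

The canonical interchange format is a long ("tidy") table with one row per
observation: ``subject, omic, modality, time_days, value``.  Missing values
are encoded as an empty field or ``NA`` in files and as ``NaN`` behind a
missing mask in memory — never as a sentinel number, which would corrupt
periodograms downstream.

Times are float days from each subject's first visit (subject-relative
origin), strictly increasing within a series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

MODALITIES = ("transcript", "cytokine", "clinical", "gut_microbe", "nares_microbe")
STATUSES = ("prediabetic", "diabetic", "crossover", "control")
SEXES = ("F", "M")

LONG_COLUMNS = ["subject", "omic", "modality", "time_days", "value"]
META_COLUMNS = ["subject", "sex", "age", "status",
                "bmi", "sspg", "matsuda", "di", "isrmax"]
META_MEASURES = ["bmi", "sspg", "matsuda", "di", "isrmax"]


class DatasetError(ValueError):
    """Raised for malformed input tables (duplicate keys, parse failures)."""


@dataclass
class TimeSeries:
    """One subject-omic signal on the subject's visit grid.

    ``values`` may contain NaN at visits where the omic was not measured;
    ``observed`` gives the corresponding mask.
    """

    subject_id: str
    omic_id: str
    modality: str
    times: np.ndarray      # float days, strictly increasing
    values: np.ndarray     # float, NaN = missing

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)

    @property
    def observed(self) -> np.ndarray:
        return ~np.isnan(self.values)

    @property
    def n_observed(self) -> int:
        return int(self.observed.sum())

    @property
    def observed_times(self) -> np.ndarray:
        return self.times[self.observed]

    @property
    def observed_values(self) -> np.ndarray:
        return self.values[self.observed]

    def missing_fraction(self) -> float:
        return 1.0 - self.n_observed / len(self.times)


@dataclass
class MultiOmicsDataset:
    """Container mapping (subject, omic) -> TimeSeries.

    ``subjects`` preserves first-appearance order; ``omics_catalogue`` maps
    every omic present to its modality.
    """

    signals: dict[tuple[str, str], TimeSeries] = field(default_factory=dict)
    subjects: list[str] = field(default_factory=list)
    omics_catalogue: dict[str, str] = field(default_factory=dict)

    def add(self, ts: TimeSeries) -> None:
        key = (ts.subject_id, ts.omic_id)
        if key in self.signals:
            raise DatasetError(f"duplicate series key {key}")
        self.signals[key] = ts
        if ts.subject_id not in self.subjects:
            self.subjects.append(ts.subject_id)
        self.omics_catalogue.setdefault(ts.omic_id, ts.modality)

    def subject_signals(self, subject_id: str) -> dict[str, TimeSeries]:
        return {omic: ts for (s, omic), ts in self.signals.items()
                if s == subject_id}

    def subject_days(self, subject_id: str) -> np.ndarray:
        """Sorted union of visit days of all this subject's series."""
        days: set[float] = set()
        for (s, _), ts in self.signals.items():
            if s == subject_id:
                days.update(ts.times.tolist())
        return np.array(sorted(days))

    def n_signals(self) -> int:
        return len(self.signals)

    def modality_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for ts in self.signals.values():
            counts[ts.modality] = counts.get(ts.modality, 0) + 1
        return counts


@dataclass
class SubjectMetadata:
    """Per-subject phenotype record; any measure may be missing (NaN)."""

    subject_id: str
    sex: str
    age: float
    status: str
    bmi: float = np.nan
    sspg: float = np.nan
    matsuda: float = np.nan
    di: float = np.nan
    isrmax: float = np.nan

    def measure(self, name: str) -> float:
        return getattr(self, name.lower())


@dataclass
class ValidationReport:
    n_subjects: int
    n_signals: int
    modality_counts: dict[str, int]
    violations: list[str]

    @property
    def ok(self) -> bool:
        return not self.violations


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def _parse_float(raw: str, row: int, col: str, allow_missing: bool) -> float:
    raw = raw.strip()
    if raw in ("", "NA", "NaN", "nan"):
        if allow_missing:
            return np.nan
        raise DatasetError(f"row {row}: missing value in required column '{col}'")
    try:
        return float(raw)
    except ValueError:
        raise DatasetError(f"row {row}: cannot parse '{raw}' in column '{col}'") from None


def load_long_table(path: str | Path,
                    schema: Iterable[str] = LONG_COLUMNS) -> MultiOmicsDataset:
    """Load a long-format omics table into a :class:`MultiOmicsDataset`.

    One TimeSeries is built per (subject, omic), with times sorted ascending.
    Duplicate (subject, omic, time) rows and non-numeric time/value fields
    raise :class:`DatasetError` naming the offending row (0-based data row).
    """
    schema = list(schema)
    df = _read_table(path)
    missing_cols = [c for c in schema if c not in df.columns]
    if missing_cols:
        raise DatasetError(f"missing required columns: {missing_cols}")
    sub_c, omic_c, mod_c, time_c, val_c = schema

    records: dict[tuple[str, str], list[tuple[float, float, str]]] = {}
    seen: set[tuple[str, str, float]] = set()
    for row, rec in enumerate(df.itertuples(index=False)):
        subject = getattr(rec, sub_c)
        omic = getattr(rec, omic_c)
        modality = getattr(rec, mod_c)
        if modality not in MODALITIES:
            raise DatasetError(f"row {row}: unknown modality '{modality}'")
        t = _parse_float(getattr(rec, time_c), row, time_c, allow_missing=False)
        v = _parse_float(getattr(rec, val_c), row, val_c, allow_missing=True)
        key3 = (subject, omic, t)
        if key3 in seen:
            raise DatasetError(
                f"row {row}: duplicate (subject, omic, time) = {key3}")
        seen.add(key3)
        records.setdefault((subject, omic), []).append((t, v, modality))

    ds = MultiOmicsDataset()
    for (subject, omic), obs in records.items():
        obs.sort(key=lambda x: x[0])
        times = np.array([o[0] for o in obs])
        values = np.array([o[1] for o in obs])
        ds.add(TimeSeries(subject, omic, obs[0][2], times, values))
    return ds


def write_long_table(ds: MultiOmicsDataset, path: str | Path) -> None:
    """Write a dataset back to the long format (bit-stable given fixed input)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    rows = []
    for (subject, omic), ts in ds.signals.items():
        for t, v in zip(ts.times, ts.values):
            rows.append((subject, omic, ts.modality, repr(float(t)),
                         "NA" if np.isnan(v) else repr(float(v))))
    with open(path, "w") as fh:
        fh.write(sep.join(LONG_COLUMNS) + "\n")
        for r in rows:
            fh.write(sep.join(r) + "\n")


def load_subject_metadata(path: str | Path) -> dict[str, SubjectMetadata]:
    """Load the subject metadata table; missing measures stay missing."""
    df = _read_table(path)
    required = ["subject", "sex", "age", "status"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise DatasetError(f"missing required columns: {missing_cols}")

    meta: dict[str, SubjectMetadata] = {}
    for row, rec in enumerate(df.itertuples(index=False)):
        sid = rec.subject
        if sid in meta:
            raise DatasetError(f"row {row}: duplicated subject_id '{sid}'")
        sex = rec.sex.strip()
        if sex not in SEXES:
            raise DatasetError(f"row {row}: unknown sex label '{sex}'")
        status = rec.status.strip()
        if status not in STATUSES:
            raise DatasetError(f"row {row}: unknown status label '{status}'")
        age = _parse_float(rec.age, row, "age", allow_missing=True)
        if not np.isnan(age) and age <= 0:
            raise DatasetError(f"row {row}: age must be positive")
        measures = {}
        for m in META_MEASURES:
            raw = getattr(rec, m, "")
            measures[m] = _parse_float(raw, row, m, allow_missing=True)
        meta[sid] = SubjectMetadata(sid, sex, age, status, **measures)
    return meta


def write_subject_metadata(meta: Mapping[str, SubjectMetadata],
                           path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"

    def fmt(x: float) -> str:
        return "NA" if (isinstance(x, float) and np.isnan(x)) else repr(float(x))

    with open(path, "w") as fh:
        fh.write(sep.join(META_COLUMNS) + "\n")
        for sid, rec in meta.items():
            fh.write(sep.join([sid, rec.sex, fmt(rec.age), rec.status,
                               fmt(rec.bmi), fmt(rec.sspg), fmt(rec.matsuda),
                               fmt(rec.di), fmt(rec.isrmax)]) + "\n")


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_dataset(ds: MultiOmicsDataset) -> ValidationReport:
    """Check every TimeSeries/MultiOmicsDataset invariant; never raises."""
    violations: list[str] = []
    for (subject, omic), ts in ds.signals.items():
        tag = f"({subject}, {omic})"
        if len(ts.times) != len(ts.values):
            violations.append(f"{tag}: times/values length mismatch")
            continue
        if len(ts.times) and np.any(np.diff(ts.times) <= 0):
            violations.append(f"{tag}: times not strictly increasing")
        if len(ts.times) and np.any(ts.times < 0):
            violations.append(f"{tag}: negative day stamp")
        if ts.n_observed < 1:
            violations.append(f"{tag}: no observed value")
        if ts.omic_id not in ds.omics_catalogue:
            violations.append(f"{tag}: omic missing from catalogue")
        if ts.subject_id not in ds.subjects:
            violations.append(f"{tag}: subject missing from subject list")
    return ValidationReport(
        n_subjects=len(ds.subjects),
        n_signals=ds.n_signals(),
        modality_counts=ds.modality_counts(),
        violations=violations,
    )
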