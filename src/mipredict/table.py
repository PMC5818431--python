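"""Per-subject questionnaire/accuracy table: data model, I/O, flipping, group splits.

The central object is :class:`SubjectTable`, a validated, ordered collection of
:class:`SubjectRecord`. Each record holds one subject's pre-task answers
(sleep, substance use, pre-task accuracy prediction ``preAP``), run-averaged
inter-task answers (calmness, interest, concentration, physical/mental state,
easiness of motor imagery ``ES``, run-averaged accuracy prediction ``AP``) and
the offline decoded accuracy ``ACC`` with its spread over cross-validation
separations ``ACCSTD``.

A 52-subject reference cohort is shipped as the builtin fixture ``"table2"``.
Sex and age are not part of that fixture's columns; they can be supplied
per-subject through the ``extra`` argument of :func:`assign_groups` (synthetic
cohorts may carry them directly).

Rating items are on a 1–5 scale. The fixture stores them as printed in the
source questionnaire summary; whether that orientation is higher=better is
resolved by callers via :func:`flip_scale` (an involution, ``x -> 6 - x``),
which inverts the sign of any correlation computed against the column.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SubjectRecord",
    "SubjectTable",
    "GroupSplit",
    "TableValidationError",
    "load_subject_table",
    "save_subject_table",
    "flip_scale",
    "assign_groups",
    "BUILTIN_FIXTURES",
]

#: canonical CSV header -> record attribute
COLUMN_MAP = {
    "ID": "subject_id",
    "Hand": "handedness",
    "EXP": "prior_bci_experience",
    "SLP": "sleep_hours",
    "COFF": "hours_since_coffee",
    "ALC": "hours_since_alcohol",
    "CIG": "hours_since_cigarette",
    "CALM": "calmness",
    "INT": "interest",
    "CONCENT": "concentration",
    "BODY": "physical_state",
    "MENTAL": "mental_state",
    "NSLP": "sleep_episodes",
    "preAP": "pre_task_prediction",
    "ES": "easiness",
    "AP": "mean_run_prediction",
    "ACC": "accuracy",
    "ACCSTD": "accuracy_sd",
}
ATTR_MAP = {v: k for k, v in COLUMN_MAP.items()}

RATING_COLUMNS = ("CALM", "INT", "CONCENT", "BODY", "MENTAL", "ES")
PERCENT_COLUMNS = ("preAP", "AP", "ACC")
HOURS_COLUMNS = ("SLP", "COFF", "ALC", "CIG")

BUILTIN_FIXTURES = ("table2",)


class TableValidationError(ValueError):
    """Raised when a subject table fails validation.

    Carries ``row`` (subject id or 0-based row number) and ``column`` so the
    offending cell can be located.
    """

    def __init__(self, message: str, row=None, column=None):
        self.row = row
        self.column = column
        where = ""
        if row is not None or column is not None:
            where = f" (row={row!r}, column={column!r})"
        super().__init__(message + where)


@dataclass
class SubjectRecord:
    subject_id: str
    handedness: str = "R"  # R, L or B
    prior_bci_experience: bool = False
    sleep_hours: float = np.nan
    hours_since_coffee: float = 0.0
    hours_since_alcohol: float = 0.0
    hours_since_cigarette: float = 0.0
    calmness: float = np.nan
    interest: float = np.nan
    concentration: float = np.nan
    physical_state: float = np.nan
    mental_state: float = np.nan
    sleep_episodes: float = 0.0
    pre_task_prediction: float = np.nan
    easiness: float = np.nan
    mean_run_prediction: float = np.nan
    accuracy: float = np.nan
    accuracy_sd: float = np.nan
    #: optional per-run accuracy predictions (percent), in run order
    run_predictions: list | None = None
    #: optional demographics, absent from the builtin fixture's columns
    sex: str | None = None
    age: float | None = None

    def validate(self) -> None:
        if self.handedness not in ("R", "L", "B"):
            raise TableValidationError(
                f"handedness must be R, L or B, got {self.handedness!r}",
                row=self.subject_id, column="Hand")
        for col in RATING_COLUMNS:
            v = getattr(self, COLUMN_MAP[col])
            if np.isfinite(v) and not (1.0 <= v <= 5.0):
                raise TableValidationError(
                    f"rating {v} outside [1, 5]", row=self.subject_id, column=col)
        for col in PERCENT_COLUMNS:
            v = getattr(self, COLUMN_MAP[col])
            if np.isfinite(v) and not (0.0 <= v <= 100.0):
                raise TableValidationError(
                    f"percentage {v} outside [0, 100]", row=self.subject_id, column=col)
        for col in HOURS_COLUMNS + ("NSLP", "ACCSTD"):
            v = getattr(self, COLUMN_MAP[col])
            if np.isfinite(v) and v < 0:
                raise TableValidationError(
                    f"value {v} must be >= 0", row=self.subject_id, column=col)
        if self.run_predictions is not None:
            for i, v in enumerate(self.run_predictions):
                if not (0.0 <= v <= 100.0):
                    raise TableValidationError(
                        f"run prediction {v} outside [0, 100]",
                        row=self.subject_id, column=f"run{i + 1}")


@dataclass
class SubjectTable:
    """Ordered, validated collection of subject records."""

    records: list[SubjectRecord]
    provenance: str = ""

    def __post_init__(self):
        ids = [r.subject_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise TableValidationError(f"duplicate subject ids: {dup}")
        for r in self.records:
            r.validate()

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, subject_id: str) -> SubjectRecord:
        for r in self.records:
            if r.subject_id == subject_id:
                return r
        raise KeyError(subject_id)

    @property
    def subject_ids(self) -> list[str]:
        return [r.subject_id for r in self.records]

    def column(self, name: str) -> np.ndarray:
        """Return one column as a float array; `name` is a CSV header or attribute."""
        attr = COLUMN_MAP.get(name, name)
        return np.array([getattr(r, attr) for r in self.records], dtype=float)

    def run_prediction_matrix(self) -> np.ndarray:
        """Per-run predictions as a subjects x runs array (requires all present)."""
        missing = [r.subject_id for r in self.records if not r.run_predictions]
        if missing:
            raise TableValidationError(
                f"per-run predictions missing for {missing}")
        n_runs = {len(r.run_predictions) for r in self.records}
        if len(n_runs) != 1:
            raise TableValidationError(
                f"inconsistent run counts across subjects: {sorted(n_runs)}")
        return np.array([r.run_predictions for r in self.records], dtype=float)

    def subset(self, subject_ids: Iterable[str]) -> "SubjectTable":
        keep = set(subject_ids)
        return SubjectTable(
            [r for r in self.records if r.subject_id in keep],
            provenance=self.provenance + " (subset)")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {col: getattr(r, attr) for col, attr in COLUMN_MAP.items()}
            row["EXP"] = "Yes" if r.prior_bci_experience else ""
            if r.sex is not None:
                row["Sex"] = r.sex
            if r.age is not None:
                row["Age"] = r.age
            if r.run_predictions is not None:
                for i, v in enumerate(r.run_predictions):
                    row[f"run{i + 1}"] = v
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        recs = []
        for r in self.records:
            d = asdict(r)
            d = {k: (None if isinstance(v, float) and not np.isfinite(v) else v)
                 for k, v in d.items()}
            recs.append(d)
        return json.dumps({"provenance": self.provenance, "records": recs}, indent=1)


@dataclass
class GroupSplit:
    """Disjoint two-group partition of a table's subjects by one criterion."""

    criterion: str
    group_a_ids: list[str]
    group_b_ids: list[str]

    def __post_init__(self):
        overlap = set(self.group_a_ids) & set(self.group_b_ids)
        if overlap:
            raise TableValidationError(f"groups overlap on {sorted(overlap)}")


def _parse_frame(df: pd.DataFrame, provenance: str) -> SubjectTable:
    missing = [c for c in COLUMN_MAP if c not in df.columns and c != "EXP"]
    if missing:
        raise TableValidationError(f"missing mandatory column(s): {missing}")
    records = []
    for i, row in df.iterrows():
        sid = str(row["ID"]).strip()
        kwargs = {"subject_id": sid}
        exp = row.get("EXP", "")
        kwargs["prior_bci_experience"] = (
            str(exp).strip().lower() in ("yes", "y", "true", "1"))
        kwargs["handedness"] = str(row["Hand"]).strip()
        for col, attr in COLUMN_MAP.items():
            if col in ("ID", "Hand", "EXP"):
                continue
            raw = row[col]
            try:
                kwargs[attr] = float(raw) if str(raw).strip() != "" else np.nan
            except (TypeError, ValueError):
                raise TableValidationError(
                    f"cannot parse {raw!r} as a number", row=sid, column=col)
        if "Sex" in df.columns and str(row["Sex"]).strip() not in ("", "nan"):
            kwargs["sex"] = str(row["Sex"]).strip()
        if "Age" in df.columns and np.isfinite(float(row["Age"])):
            kwargs["age"] = float(row["Age"])
        run_cols = sorted(
            (c for c in df.columns if c.startswith("run") and c[3:].isdigit()),
            key=lambda c: int(c[3:]))
        if run_cols:
            vals = [row[c] for c in run_cols]
            if all(np.isfinite(float(v)) for v in vals):
                kwargs["run_predictions"] = [float(v) for v in vals]
        records.append(SubjectRecord(**kwargs))
    return SubjectTable(records, provenance=provenance)


def load_subject_table(source: str | Path) -> SubjectTable:
    """Load a subject table from a delimited text file or a builtin fixture name.

    The delimiter (comma or tab) is auto-detected. The builtin fixture
    ``"table2"`` is the packaged 52-subject reference cohort.
    """
    if isinstance(source, str) and source in BUILTIN_FIXTURES:
        ref = resources.files("mipredict").joinpath(f"data/{source}.csv")
        with resources.as_file(ref) as path:
            df = pd.read_csv(path, sep=None, engine="python")
        table = _parse_frame(df, provenance=f"builtin:{source}")
        if source == "table2" and len(table) != 52:
            raise TableValidationError(
                f"builtin fixture table2 must have 52 records, found {len(table)}")
        return table
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(
            f"{source!r} is neither a file nor a builtin fixture {BUILTIN_FIXTURES}")
    df = pd.read_csv(path, sep=None, engine="python")
    return _parse_frame(df, provenance=str(path))


def save_subject_table(table: SubjectTable, path: str | Path) -> None:
    """Write a table as CSV (or TSV when the suffix is .tsv)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    table.to_frame().to_csv(path, sep=sep, index=False)


def flip_scale(score):
    """Reverse a 1–5 rating: 1<->5, 2<->4, 3 fixed. Accepts scalars or arrays."""
    arr = np.asarray(score, dtype=float)
    if np.any((arr < 1.0) | (arr > 5.0)):
        raise ValueError(f"score(s) outside [1, 5]: {arr}")
    out = 6.0 - arr
    return float(out) if np.isscalar(score) else out


_SUBSTANCE_COLS = {"coffee": "COFF", "alcohol": "ALC", "cigarette": "CIG"}


def assign_groups(
    table: SubjectTable,
    criterion: str,
    extra: Mapping[str, object] | None = None,
) -> GroupSplit:
    """Split subjects into two groups by one criterion.

    ``criterion`` is one of ``sex``, ``age``, ``coffee``, ``alcohol``,
    ``cigarette``. Substance criteria place subjects who consumed within the
    last 24 h (0 < hours <= 24) in group A; 0 encodes non-consumption and
    joins group B together with >24 h. The age criterion splits at the
    cohort's mean age (older than the mean -> group A). Sex and age may be
    supplied via ``extra`` (a ``{subject_id: value}`` mapping) when the table
    does not carry them.
    """
    if criterion in _SUBSTANCE_COLS:
        hours = table.column(_SUBSTANCE_COLS[criterion])
        bad = [table.subject_ids[i] for i in np.flatnonzero(~np.isfinite(hours))]
        if bad:
            raise TableValidationError(
                f"{_SUBSTANCE_COLS[criterion]} missing for {bad}",
                column=_SUBSTANCE_COLS[criterion])
        in_a = (hours > 0) & (hours <= 24)
    elif criterion in ("sex", "age"):
        def fetch(rec):
            v = getattr(rec, criterion)
            if v is None and extra is not None:
                v = extra.get(rec.subject_id)
            if v is None:
                raise TableValidationError(
                    f"{criterion} not in table and not supplied via extra",
                    row=rec.subject_id, column=criterion)
            return v

        values = [fetch(r) for r in table.records]
        if criterion == "age":
            ages = np.array(values, dtype=float)
            in_a = ages > ages.mean()
        else:
            sexes = [str(v).upper()[:1] for v in values]
            bad = sorted({s for s in sexes if s not in ("M", "F")})
            if bad:
                raise TableValidationError(f"unrecognized sex value(s) {bad}",
                                           column="Sex")
            in_a = np.array([s == "M" for s in sexes])
    else:
        raise ValueError(
            f"unknown criterion {criterion!r}; expected sex, age, coffee, "
            f"alcohol or cigarette")
    ids = np.array(table.subject_ids)
    return GroupSplit(criterion,
                      group_a_ids=list(ids[in_a]),
                      group_b_ids=list(ids[~in_a]))
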