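"""Data model, validation and I/O for pooled long-format trial datasets.

All pipeline stages exchange one container, :class:`PooledDataset`, a thin
wrapper around a long-format :class:`pandas.DataFrame` with one row per
visit-level observation and subject covariates repeated on every row.

Conventions
-----------
* Time is days since randomization; baseline is day 0 (week 12 = day 84).
* Diary counts (``MICT``, ``UUI``) are stored as the raw sum over the diary
  window (``DIARY_D`` days); per-24 h rates are derived as ``DV / DIARY_D``.
  Keeping the raw sum keeps the Poisson likelihood exact.
* ``MVV`` and ``PVR`` are in mL; ``DIARY_D`` is empty for them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

ENDPOINTS = ("MICT", "UUI", "MVV", "PVR")
COUNT_ENDPOINTS = ("MICT", "UUI")
DOSES_MG = (0, 4, 8, 12)

#: study id -> duration in days. Two 8-week phase II studies, two 12-week
#: phase III studies.
STUDY_REGISTRY: dict[str, int] = {"P2A": 56, "P2B": 56, "P3A": 84, "P3B": 84}

CSV_COLUMNS = [
    "SUBJ", "STUDY", "DOSE_MG", "TIME_D", "ENDPOINT", "DV", "DIARY_D",
    "AGE", "SEX", "BMI", "BASE_MICT", "BASE_UUI", "BASE_MVV", "BASE_PVR",
]

#: covariate columns that must be constant within a subject
_SUBJECT_COLUMNS = [
    "STUDY", "DOSE_MG", "AGE", "SEX", "BMI",
    "BASE_MICT", "BASE_UUI", "BASE_MVV", "BASE_PVR",
]


class SchemaError(ValueError):
    """The file/table does not have the documented column schema."""


class ValidationError(ValueError):
    """The table has the right schema but violates a dataset invariant."""


@dataclass
class VisitObservation:
    subject_id: str
    study_id: str
    dose_mg: int
    time_days: float
    endpoint: str
    value: float
    diary_days: int | None = None


@dataclass
class SubjectRecord:
    subject_id: str
    study_id: str
    dose_mg: int
    age_years: float
    sex: str
    bmi: float
    baseline_mict: float
    baseline_uui: float
    baseline_mvv: float
    baseline_pvr: float
    observations: list[VisitObservation] = field(default_factory=list)


@dataclass
class PooledDataset:
    """Long-format pooled trial data plus provenance.

    ``df`` holds one row per :class:`VisitObservation` in the documented CSV
    schema; covariates are repeated per row.
    """

    df: pd.DataFrame
    provenance: str = ""

    @property
    def n_subjects(self) -> int:
        return self.df["SUBJ"].nunique()

    @property
    def n_obs(self) -> int:
        return len(self.df)

    def subject_table(self) -> pd.DataFrame:
        """One row per subject with the covariate columns."""
        cols = ["SUBJ"] + _SUBJECT_COLUMNS
        return (
            self.df[cols].drop_duplicates("SUBJ").set_index("SUBJ", drop=False)
        )

    def endpoint_frame(self, endpoint: str) -> pd.DataFrame:
        if endpoint not in ENDPOINTS:
            raise ValueError(f"unknown endpoint {endpoint!r}")
        return self.df[self.df["ENDPOINT"] == endpoint]

    def iter_subjects(self) -> Iterator[SubjectRecord]:
        for subj, grp in self.df.groupby("SUBJ", sort=False):
            first = grp.iloc[0]
            rec = SubjectRecord(
                subject_id=str(subj),
                study_id=first["STUDY"],
                dose_mg=int(first["DOSE_MG"]),
                age_years=float(first["AGE"]),
                sex=first["SEX"],
                bmi=float(first["BMI"]),
                baseline_mict=float(first["BASE_MICT"]),
                baseline_uui=float(first["BASE_UUI"]),
                baseline_mvv=float(first["BASE_MVV"]),
                baseline_pvr=float(first["BASE_PVR"]),
            )
            for _, row in grp.iterrows():
                dd = row["DIARY_D"]
                rec.observations.append(VisitObservation(
                    subject_id=str(subj),
                    study_id=row["STUDY"],
                    dose_mg=int(row["DOSE_MG"]),
                    time_days=float(row["TIME_D"]),
                    endpoint=row["ENDPOINT"],
                    value=float(row["DV"]),
                    diary_days=None if pd.isna(dd) else int(dd),
                ))
            yield rec

    def validate(self) -> "PooledDataset":
        validate_frame(self.df)
        return self


def _require_columns(df: pd.DataFrame) -> None:
    for col in CSV_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")


def validate_frame(df: pd.DataFrame) -> None:
    """Raise :class:`SchemaError`/:class:`ValidationError` on rule violations.

    Checks exactly the documented invariants: schema, categorical domains,
    non-negative values, integer counts, baseline PVR < 100 mL, constant dose
    and covariates within subject, strictly increasing times within
    (subject, endpoint), diary length >= 1 for counts, registered study ids.
    """
    _require_columns(df)
    if len(df) == 0:
        return

    bad = ~df["ENDPOINT"].isin(ENDPOINTS)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(f"row {i}: unknown ENDPOINT {df['ENDPOINT'].iloc[i]!r}")
    bad = ~df["DOSE_MG"].isin(DOSES_MG)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(f"row {i}: DOSE_MG {df['DOSE_MG'].iloc[i]!r} not in {DOSES_MG}")
    bad = ~df["SEX"].isin(("F", "M"))
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(f"row {i}: SEX must be F or M")
    unknown = set(df["STUDY"].unique()) - set(STUDY_REGISTRY)
    if unknown:
        raise ValidationError(f"study id(s) {sorted(unknown)} not in the design registry")

    dv = df["DV"].to_numpy(dtype=float)
    if np.any(dv < 0):
        i = int(np.flatnonzero(dv < 0)[0])
        raise ValidationError(f"row {i}: negative DV")
    t = df["TIME_D"].to_numpy(dtype=float)
    if np.any(t < 0):
        i = int(np.flatnonzero(t < 0)[0])
        raise ValidationError(f"row {i}: negative TIME_D")

    is_count = df["ENDPOINT"].isin(COUNT_ENDPOINTS).to_numpy()
    frac = np.abs(dv - np.round(dv)) > 1e-9
    bad = is_count & frac
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValidationError(
            f"row {i}: non-integer count {dv[i]} for {df['ENDPOINT'].iloc[i]}"
        )
    dd = pd.to_numeric(df["DIARY_D"], errors="coerce").to_numpy(dtype=float)
    bad = is_count & (np.isnan(dd) | (dd < 1))
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValidationError(f"row {i}: DIARY_D must be >= 1 for count endpoints")

    base_pvr = df["BASE_PVR"].to_numpy(dtype=float)
    bad = (base_pvr >= 100) | (base_pvr < 0)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValidationError(
            f"row {i}: baseline PVR {base_pvr[i]} outside [0, 100) "
            "(PVR > 100 mL is a trial exclusion criterion)"
        )

    per_subj = df.groupby("SUBJ", sort=False)
    for col in _SUBJECT_COLUMNS:
        if (per_subj[col].nunique() > 1).any():
            subj = per_subj[col].nunique().idxmax()
            raise ValidationError(f"subject {subj!r}: {col} not constant within subject")
    strict = (
        df.groupby(["SUBJ", "ENDPOINT"], sort=False)["TIME_D"]
        .apply(lambda s: bool(np.all(np.diff(s.to_numpy(dtype=float)) > 0)))
    )
    if not strict.all():
        subj, ep = strict.idxmin()
        raise ValidationError(
            f"subject {subj!r}, endpoint {ep}: TIME_D not strictly increasing"
        )


def read_dataset(path: str | Path) -> PooledDataset:
    """Read and validate a long-format CSV into a :class:`PooledDataset`."""
    df = pd.read_csv(
        path,
        dtype={"SUBJ": str, "STUDY": str, "ENDPOINT": str, "SEX": str},
    )
    _require_columns(df)
    df["DIARY_D"] = pd.to_numeric(df["DIARY_D"], errors="coerce").astype("Int64")
    validate_frame(df)
    return PooledDataset(df=df, provenance=str(path))


def write_dataset(data: PooledDataset, path: str | Path) -> None:
    """Write the documented CSV schema; empty DIARY_D for MVV/PVR rows."""
    df = data.df.reindex(columns=CSV_COLUMNS)
    df.to_csv(path, index=False)


def summarize_by_arm(data: PooledDataset) -> pd.DataFrame:
    """Subject counts by study x dose with a 'Total' margin row/column."""
    subj = data.subject_table()
    table = (
        subj.groupby(["STUDY", "DOSE_MG"])["SUBJ"].count()
        .unstack("DOSE_MG", fill_value=0)
        .reindex(columns=list(DOSES_MG), fill_value=0)
    )
    table.loc["Total"] = table.sum(axis=0)
    table["Total"] = table.sum(axis=1)
    return table
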