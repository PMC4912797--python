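"""Patient-level cohort container and CSV interchange.

A cohort is one row per ICU patient: demographics (age, sex, race, BMI,
surgical vs medical admission), the Deyo-Charlson Comorbidity Index (DCCI),
the APACHE II severity score, plasma 25-hydroxyvitamin D (25OHD, ng/mL), and
the 90-day all-cause mortality indicator.

The on-disk format is a plain UTF-8 CSV with header
``age,sex,race,bmi,patient_type,dcci,apache_ii,vitd_25ohd,death90`` where
``sex`` is coded F/M, ``race`` white/nonwhite, ``patient_type``
surgical/medical and ``death90`` 0/1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

COLUMNS = (
    "age",
    "sex",
    "race",
    "bmi",
    "patient_type",
    "dcci",
    "apache_ii",
    "vitd_25ohd",
    "death90",
)

SEX_LEVELS = ("female", "male")
RACE_LEVELS = ("white", "nonwhite")
TYPE_LEVELS = ("surgical", "medical")

CONTINUOUS_FIELDS = ("age", "bmi", "vitd_25ohd", "apache_ii", "dcci")
CATEGORICAL_FIELDS = ("sex", "race", "patient_type")

_SEX_CSV = {"female": "F", "male": "M"}
_SEX_FROM_CSV = {"F": "female", "M": "male"}

APACHE_MAX = 71  # fixed upper bound of the APACHE II scale


@dataclass(frozen=True)
class PatientRecord:
    """One ICU patient.

    Invariants: ``age >= 18`` (adult inclusion), ``vitd_25ohd > 0``,
    ``0 <= apache_ii <= 71``, ``dcci >= 0``, ``bmi > 0``.
    """

    age: int
    sex: str
    race: str
    bmi: float
    patient_type: str
    dcci: int
    apache_ii: int
    vitd_25ohd: float
    death90: int

    def __post_init__(self) -> None:
        if self.age < 18:
            raise ValueError(f"age must be >= 18, got {self.age}")
        if self.sex not in SEX_LEVELS:
            raise ValueError(f"sex must be one of {SEX_LEVELS}, got {self.sex!r}")
        if self.race not in RACE_LEVELS:
            raise ValueError(f"race must be one of {RACE_LEVELS}, got {self.race!r}")
        if not self.bmi > 0:
            raise ValueError(f"bmi must be positive, got {self.bmi}")
        if self.patient_type not in TYPE_LEVELS:
            raise ValueError(
                f"patient_type must be one of {TYPE_LEVELS}, got {self.patient_type!r}"
            )
        if self.dcci < 0:
            raise ValueError(f"dcci must be non-negative, got {self.dcci}")
        if not 0 <= self.apache_ii <= APACHE_MAX:
            raise ValueError(f"apache_ii must lie in [0, {APACHE_MAX}], got {self.apache_ii}")
        if not self.vitd_25ohd > 0:
            raise ValueError(f"vitd_25ohd must be positive, got {self.vitd_25ohd}")
        if self.death90 not in (0, 1):
            raise ValueError(f"death90 must be 0 or 1, got {self.death90}")


class Cohort:
    """Ordered collection of patient records backed by a DataFrame.

    Record order carries no analytical meaning; all summaries are
    permutation invariant. A cohort may be empty.
    """

    def __init__(self, frame: pd.DataFrame | None = None, label: str = "",
                 dropped_rows: int = 0):
        if frame is None:
            frame = pd.DataFrame({c: pd.Series(dtype=t) for c, t in _DTYPES.items()})
        missing = [c for c in COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"cohort frame is missing required columns: {missing}")
        frame = frame.loc[:, list(COLUMNS)].reset_index(drop=True)
        frame = frame.astype(_DTYPES)
        _validate_frame(frame)
        self.frame = frame
        self.label = label
        self.dropped_rows = dropped_rows

    # -- construction ----------------------------------------------------
    @classmethod
    def from_records(cls, records, label: str = "") -> "Cohort":
        records = list(records)
        if not records:
            return cls(label=label)
        frame = pd.DataFrame([r.__dict__ for r in records])
        return cls(frame, label=label)

    # -- container protocol ----------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self) -> Iterator[PatientRecord]:
        for row in self.frame.itertuples(index=False):
            yield PatientRecord(
                age=int(row.age), sex=row.sex, race=row.race, bmi=float(row.bmi),
                patient_type=row.patient_type, dcci=int(row.dcci),
                apache_ii=int(row.apache_ii), vitd_25ohd=float(row.vitd_25ohd),
                death90=int(row.death90),
            )

    def __eq__(self, other) -> bool:
        return isinstance(other, Cohort) and self.frame.equals(other.frame)

    @property
    def is_empty(self) -> bool:
        return len(self.frame) == 0

    def column(self, name: str) -> np.ndarray:
        return self.frame[name].to_numpy()


_DTYPES = {
    "age": "int64",
    "sex": "object",
    "race": "object",
    "bmi": "float64",
    "patient_type": "object",
    "dcci": "int64",
    "apache_ii": "int64",
    "vitd_25ohd": "float64",
    "death90": "int64",
}


def _validate_frame(frame: pd.DataFrame) -> None:
    if frame.empty:
        return
    checks = [
        ((frame["age"] >= 18).all(), "age < 18"),
        (frame["sex"].isin(SEX_LEVELS).all(), "invalid sex level"),
        (frame["race"].isin(RACE_LEVELS).all(), "invalid race level"),
        ((frame["bmi"] > 0).all(), "non-positive bmi"),
        (frame["patient_type"].isin(TYPE_LEVELS).all(), "invalid patient_type level"),
        ((frame["dcci"] >= 0).all(), "negative dcci"),
        (frame["apache_ii"].between(0, APACHE_MAX).all(), "apache_ii out of [0, 71]"),
        ((frame["vitd_25ohd"] > 0).all(), "non-positive vitd_25ohd"),
        (frame["death90"].isin([0, 1]).all(), "death90 not in {0, 1}"),
    ]
    for ok, msg in checks:
        if not ok:
            raise ValueError(f"invalid cohort frame: {msg}")


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort to CSV in the interchange coding (sex F/M)."""
    out = cohort.frame.copy()
    out["sex"] = out["sex"].map(_SEX_CSV)
    out.to_csv(path, index=False, columns=list(COLUMNS))


def read_cohort(path, label: str | None = None) -> Cohort:
    """Read a cohort CSV; complete-case with a logged dropped-row count.

    Rows with missing, unparseable, or invariant-violating required fields
    are dropped; the count is logged and exposed as ``Cohort.dropped_rows``.
    Unknown extra columns raise a warning and are ignored; missing required
    columns raise ``ValueError`` naming them.
    """
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"cohort file {path} is missing required columns: {missing}")
    extra = [c for c in raw.columns if c not in COLUMNS]
    if extra:
        warnings.warn(f"ignoring unknown columns in {path}: {extra}", stacklevel=2)

    df = pd.DataFrame(index=raw.index)
    for col in ("age", "bmi", "vitd_25ohd", "dcci", "apache_ii", "death90"):
        df[col] = pd.to_numeric(raw[col], errors="coerce")
    df["sex"] = raw["sex"].str.strip().map(_SEX_FROM_CSV)
    df["race"] = raw["race"].str.strip().where(raw["race"].str.strip().isin(RACE_LEVELS))
    df["patient_type"] = raw["patient_type"].str.strip().where(
        raw["patient_type"].str.strip().isin(TYPE_LEVELS)
    )

    valid = (
        df.notna().all(axis=1)
        & (df["age"] >= 18)
        & (df["bmi"] > 0)
        & (df["vitd_25ohd"] > 0)
        & (df["dcci"] >= 0)
        & df["apache_ii"].between(0, APACHE_MAX)
        & df["death90"].isin([0, 1])
        # integer-valued fields must parse as integers
        & (df["age"] == df["age"].round())
        & (df["dcci"] == df["dcci"].round())
        & (df["apache_ii"] == df["apache_ii"].round())
    )
    dropped = int((~valid).sum())
    if dropped:
        log.info("read_cohort(%s): dropped %d incomplete/invalid rows", path, dropped)
    df = df.loc[valid]
    return Cohort(df, label=label or str(path), dropped_rows=dropped)
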