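"""Reading, validating and summarizing heart-failure cohort tables.

The cohort is a flat per-patient table: ten clinical covariates plus
right-censored follow-up (``time`` in days, ``event`` death indicator).
Internally everything is a :class:`pandas.DataFrame` with canonical column
names; :class:`Cohort` is a thin validated wrapper so that synthetic and
real data flow through identical code paths.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterator, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

#: Canonical covariate names, in conventional reporting order.
COVARIATES: tuple[str, ...] = (
    "age",
    "anaemia",
    "cpk",
    "diabetes",
    "ejection_fraction",
    "high_bp",
    "platelets",
    "serum_creatinine",
    "serum_sodium",
    "sex",
    "smoking",
)

BINARY_COLUMNS: tuple[str, ...] = (
    "anaemia",
    "diabetes",
    "high_bp",
    "sex",
    "smoking",
    "event",
)

CONTINUOUS_COLUMNS: tuple[str, ...] = (
    "age",
    "cpk",
    "ejection_fraction",
    "platelets",
    "serum_creatinine",
    "serum_sodium",
    "time",
)

#: Columns that must be strictly positive.
POSITIVE_COLUMNS: tuple[str, ...] = (
    "age",
    "cpk",
    "platelets",
    "serum_creatinine",
    "serum_sodium",
    "time",
)

ALL_COLUMNS: tuple[str, ...] = COVARIATES + ("time", "event")

#: Header spellings of the widely circulated CSV dialect, mapped to the
#: canonical names.  ``read_cohort_csv`` accepts these by default; other
#: spellings go through an explicit ``column_map``.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "age": "age",
    "anaemia": "anaemia",
    "anemia": "anaemia",
    "creatinine_phosphokinase": "cpk",
    "cpk": "cpk",
    "diabetes": "diabetes",
    "ejection_fraction": "ejection_fraction",
    "high_blood_pressure": "high_bp",
    "high_bp": "high_bp",
    "platelets": "platelets",
    "serum_creatinine": "serum_creatinine",
    "serum_sodium": "serum_sodium",
    "sex": "sex",
    "smoking": "smoking",
    "time": "time",
    "death_event": "event",
    "event": "event",
}


class CohortError(ValueError):
    """Raised for malformed or invalid cohort input."""


class MissingColumnError(CohortError):
    """Raised when required columns are absent from the input table."""

    def __init__(self, missing: Sequence[str]):
        self.missing = tuple(missing)
        super().__init__(f"missing required columns: {', '.join(self.missing)}")


class SubjectRecord(NamedTuple):
    """One patient's covariates plus (follow-up time, death indicator)."""

    age: float
    anaemia: int
    cpk: float
    diabetes: int
    ejection_fraction: float
    high_bp: int
    platelets: float
    serum_creatinine: float
    serum_sodium: float
    sex: int
    smoking: int
    time: float
    event: int


@dataclass(frozen=True)
class Cohort:
    """A validated cohort table.

    Parameters
    ----------
    df
        DataFrame with the canonical columns (:data:`ALL_COLUMNS`).
        Validated on construction; row order is preserved.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in ALL_COLUMNS if c not in self.df.columns]
        if missing:
            raise MissingColumnError(missing)
        _validate_values(self.df)
        object.__setattr__(self, "df", self.df.reset_index(drop=True))

    # -- container protocol -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.df)

    def __len__(self) -> int:
        return self.n

    @property
    def n_events(self) -> int:
        return int(self.df["event"].sum())

    def column(self, name: str) -> np.ndarray:
        """Return one column as a float array; raises for unknown names."""
        if name not in self.df.columns:
            raise KeyError(f"unknown covariate {name!r}")
        return self.df[name].to_numpy(dtype=float)

    @property
    def time(self) -> np.ndarray:
        return self.column("time")

    @property
    def event(self) -> np.ndarray:
        return self.df["event"].to_numpy(dtype=int)

    @property
    def records(self) -> Iterator[SubjectRecord]:
        for row in self.df[list(SubjectRecord._fields)].itertuples(index=False):
            yield SubjectRecord(*row)

    def covariate_matrix(self, names: Sequence[str]) -> pd.DataFrame:
        """Sub-table of named covariates, validated to exist."""
        unknown = [n for n in names if n not in self.df.columns]
        if unknown:
            raise KeyError(f"unknown covariates: {unknown}")
        return self.df[list(names)].copy()


def _validate_values(df: pd.DataFrame) -> None:
    if len(df) == 0:  # empty container is legal; fitting operations reject it
        return
    sub = df[list(ALL_COLUMNS)]
    if sub.isna().any().any():
        rows = sub.isna().any(axis=1)
        first = int(np.flatnonzero(rows.to_numpy())[0])
        cols = sub.columns[sub.iloc[first].isna()].tolist()
        raise CohortError(
            f"missing value(s) at row {first} in column(s) {cols}; "
            "missing data is not supported"
        )
    for col in BINARY_COLUMNS:
        vals = sub[col].to_numpy()
        if not np.isin(vals, (0, 1)).all():
            bad = vals[~np.isin(vals, (0, 1))][0]
            raise CohortError(f"column {col!r} must be binary 0/1; found {bad!r}")
    for col in POSITIVE_COLUMNS:
        vals = sub[col].to_numpy(dtype=float)
        if not (vals > 0).all():
            row = int(np.flatnonzero(~(vals > 0))[0])
            raise CohortError(
                f"column {col!r} must be > 0; row {row} has {vals[row]!r}"
            )
    ef = sub["ejection_fraction"].to_numpy(dtype=float)
    if not ((ef > 0) & (ef <= 100)).all():
        row = int(np.flatnonzero(~((ef > 0) & (ef <= 100)))[0])
        raise CohortError(
            f"ejection_fraction must lie in (0, 100]; row {row} has {ef[row]!r}"
        )


def read_cohort_csv(path, column_map: Mapping[str, str] | None = None) -> Cohort:
    """Read a cohort CSV (comma separated, period decimal point, header row).

    Parameters
    ----------
    path
        File path or file-like object.
    column_map
        Optional mapping from the file's header names to canonical names.
        By default the widely circulated dialect (``DEATH_EVENT``,
        ``creatinine_phosphokinase``, ...) is accepted case-insensitively.

    Returns
    -------
    Cohort
        Validated cohort; row order preserved.

    Raises
    ------
    MissingColumnError
        If any required column is absent (all absentees listed).
    CohortError
        For non-numeric cells (with row/column), zero data rows, or
        invalid values.
    """
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if column_map is None:
        rename = {
            c: DEFAULT_COLUMN_MAP[c.strip().lower()]
            for c in raw.columns
            if c.strip().lower() in DEFAULT_COLUMN_MAP
        }
    else:
        rename = {c: column_map[c] for c in raw.columns if c in column_map}
    raw = raw.rename(columns=rename)

    missing = [c for c in ALL_COLUMNS if c not in raw.columns]
    if missing:
        raise MissingColumnError(missing)
    if len(raw) == 0:
        raise CohortError("cohort file has a header but zero data rows")

    out = {}
    for col in ALL_COLUMNS:
        parsed = pd.to_numeric(raw[col], errors="coerce")
        bad = parsed.isna() & raw[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CohortError(
                f"non-numeric value {raw[col].iloc[row]!r} at row {row}, "
                f"column {col!r}"
            )
        out[col] = parsed
    return Cohort(pd.DataFrame(out))


def write_cohort_csv(cohort: Cohort, path) -> None:
    """Write a cohort in the same dialect ``read_cohort_csv`` accepts."""
    names = {
        "cpk": "creatinine_phosphokinase",
        "high_bp": "high_blood_pressure",
        "event": "DEATH_EVENT",
    }
    df = cohort.df[list(ALL_COLUMNS)].rename(columns=names)
    df.to_csv(path, index=False)


@dataclass(frozen=True)
class SummaryStats:
    """Table-style cohort summary.

    ``continuous`` has one row per continuous column (mean, sd, min,
    quartiles, max; sd uses the n−1 denominator, quartiles linear
    interpolation between order statistics).  ``binary`` has one row per
    (column, level) with count and percent.
    """

    continuous: pd.DataFrame
    binary: pd.DataFrame
    n: int

    def to_csv(self) -> str:
        buf = io.StringIO()
        self.continuous.to_csv(buf)
        buf.write("\n")
        self.binary.to_csv(buf)
        return buf.getvalue()

    def to_text(self) -> str:
        return (
            f"n = {self.n}\n\n"
            + self.continuous.to_string(float_format=lambda v: f"{v:.3g}")
            + "\n\n"
            + self.binary.to_string()
        )


def summarize(cohort: Cohort) -> SummaryStats:
    """Compute per-column summary statistics for a cohort.

    Continuous columns get mean, SD (ddof=1), min, quartiles (linear
    interpolation) and max; binary columns get count and percent per level.
    """
    if cohort.n == 0:
        raise CohortError("cannot summarize an empty cohort")
    rows = {}
    for col in CONTINUOUS_COLUMNS:
        x = cohort.column(col)
        rows[col] = {
            "mean": float(np.mean(x)),
            "sd": float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
            "min": float(np.min(x)),
            "q25": float(np.percentile(x, 25)),
            "median": float(np.percentile(x, 50)),
            "q75": float(np.percentile(x, 75)),
            "max": float(np.max(x)),
        }
    continuous = pd.DataFrame(rows).T

    brows = []
    for col in BINARY_COLUMNS:
        x = cohort.df[col].to_numpy(dtype=int)
        for level in (0, 1):
            count = int((x == level).sum())
            brows.append(
                {
                    "column": col,
                    "level": level,
                    "count": count,
                    "percent": 100.0 * count / len(x),
                }
            )
    binary = pd.DataFrame(brows).set_index(["column", "level"])
    return SummaryStats(continuous=continuous, binary=binary, n=cohort.n)
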