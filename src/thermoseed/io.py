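"""CSV contracts and input validation for the analysis pipeline.

Canonical interchange is long/tidy CSV:

* ``elongation.csv`` — accession, seedling_id, axis, temp_set_c,
  temp_actual_c, time_h, length_mm (one row per picture per axis);
* ``germination.csv`` — accession, replicate, temp_set_c, time_h,
  germinated, total (temp_actual_c optional but recommended).

Schema violations raise :class:`SchemaError` naming the file and column;
content problems (non-monotone times, decreasing cumulative counts,
implausible lengths, duplicate keys) are returned as a machine-readable
issue list rather than raised, so a run can report everything at once.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .germination import GerminationSeries
from .schnute import ElongationSeries

__all__ = [
    "SchemaError",
    "ValidationIssue",
    "read_elongation",
    "read_germination",
    "iter_elongation_series",
    "iter_germination_series",
    "validate_inputs",
]

ELONGATION_COLUMNS = ("accession", "seedling_id", "axis", "temp_set_c",
                      "temp_actual_c", "time_h", "length_mm")
GERMINATION_COLUMNS = ("accession", "replicate", "temp_set_c", "time_h",
                       "germinated", "total")

MAX_PLAUSIBLE_LENGTH_MM = 200.0


class SchemaError(ValueError):
    """An input table does not match its declared header contract."""


@dataclass(frozen=True)
class ValidationIssue:
    file: str
    row: int  # 0-based row within the data (excluding header); -1 if n/a
    column: str
    message: str


def _check_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}"
        )


def read_elongation(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, ELONGATION_COLUMNS, path)
    return df


def read_germination(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, GERMINATION_COLUMNS, path)
    return df


ELONG_KEY = ["accession", "seedling_id", "axis", "temp_set_c"]
GERM_KEY = ["accession", "replicate", "temp_set_c"]


def iter_elongation_series(df: pd.DataFrame):
    """Yield one :class:`ElongationSeries` per seedling axis, time-sorted."""
    for key, grp in df.groupby(ELONG_KEY, sort=True):
        acc, sid, axis, tset = key
        grp = grp.sort_values("time_h")
        yield ElongationSeries(
            accession=str(acc), seedling_id=int(sid), axis=str(axis),
            temperature_set=float(tset),
            temperature_actual=float(grp["temp_actual_c"].iloc[0]),
            times=grp["time_h"].to_numpy(float),
            lengths=grp["length_mm"].to_numpy(float),
        )


def iter_germination_series(df: pd.DataFrame):
    """Yield one :class:`GerminationSeries` per replicate, time-sorted."""
    has_actual = "temp_actual_c" in df.columns
    for key, grp in df.groupby(GERM_KEY, sort=True):
        acc, rep, tset = key
        grp = grp.sort_values("time_h")
        temp = (float(grp["temp_actual_c"].iloc[0]) if has_actual
                else float(tset))
        yield GerminationSeries.from_counts(
            accession=str(acc), replicate=int(rep), temperature=temp,
            times=grp["time_h"].to_numpy(float),
            germinated=grp["germinated"].to_numpy(float),
            total=int(grp["total"].iloc[0]),
        )


def validate_inputs(elongation_path=None,
                    germination_path=None) -> list[ValidationIssue]:
    """Check input tables; returns an issue list (empty when clean)."""
    issues: list[ValidationIssue] = []
    if elongation_path is not None:
        df = read_elongation(elongation_path)
        name = str(elongation_path)
        dup = df.duplicated(subset=ELONG_KEY + ["time_h"])
        for i in np.nonzero(dup.to_numpy())[0]:
            issues.append(ValidationIssue(
                name, int(i), "time_h",
                "duplicate (accession, seedling, axis, temperature, time)"))
        bad_len = (df["length_mm"] < 0) | (
            df["length_mm"] > MAX_PLAUSIBLE_LENGTH_MM)
        for i in np.nonzero(bad_len.to_numpy())[0]:
            issues.append(ValidationIssue(
                name, int(i), "length_mm",
                f"length outside plausible range "
                f"[0, {MAX_PLAUSIBLE_LENGTH_MM}] mm"))
        for key, grp in df.groupby(ELONG_KEY, sort=True):
            t = grp.sort_index()["time_h"].to_numpy(float)
            if t.size >= 2 and not np.all(np.diff(t) > 0):
                issues.append(ValidationIssue(
                    name, int(grp.index[0]), "time_h",
                    f"times not strictly increasing for {key}"))
        rad = df[(df["axis"] == "radicle")].sort_values("time_h")
        for key, grp in rad.groupby(ELONG_KEY, sort=True):
            if float(grp["length_mm"].iloc[0]) < 1.0:
                issues.append(ValidationIssue(
                    name, int(grp.index[0]), "length_mm",
                    f"first radicle length < 1 mm for {key}"))
    if germination_path is not None:
        df = read_germination(germination_path)
        name = str(germination_path)
        dup = df.duplicated(subset=GERM_KEY + ["time_h"])
        for i in np.nonzero(dup.to_numpy())[0]:
            issues.append(ValidationIssue(
                name, int(i), "time_h",
                "duplicate (accession, replicate, temperature, time)"))
        over = df["germinated"] > df["total"]
        for i in np.nonzero(over.to_numpy())[0]:
            issues.append(ValidationIssue(
                name, int(i), "germinated", "count exceeds total seeds"))
        for key, grp in df.groupby(GERM_KEY, sort=True):
            grp = grp.sort_values("time_h")
            c = grp["germinated"].to_numpy(float)
            dec = np.nonzero(np.diff(c) < 0)[0]
            if dec.size:
                issues.append(ValidationIssue(
                    name, int(grp.index[dec[0] + 1]), "germinated",
                    f"cumulative count decreases for {key}"))
            t = grp["time_h"].to_numpy(float)
            if t.size >= 2 and not np.all(np.diff(t) > 0):
                issues.append(ValidationIssue(
                    name, int(grp.index[0]), "time_h",
                    f"times not strictly increasing for {key}"))
    return issues


def issues_to_frame(issues: list[ValidationIssue]) -> pd.DataFrame:
    return pd.DataFrame(
        [(i.file, i.row, i.column, i.message) for i in issues],
        columns=["file", "row", "column", "message"])


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
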