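"""Case-table and population CSV formats, validation, and sibling exclusion.

Case tables are plain CSV with ISO-8601 dates and projected planar
coordinates in meters (the package performs no CRS transformation; projecting
is the caller's responsibility).  Mandatory columns::

    case_id, x_birth, y_birth, birth_date, diagnosis_date

Any further columns (marker, covariates, sibling_group, truth_cluster_id) are
carried through unchanged.  Population snapshots are long-format CSV with
columns ``snapshot_date, x, y, child_count, cell_size_m``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .population import PopulationSnapshot

__all__ = [
    "SchemaError",
    "MANDATORY_CASE_COLUMNS",
    "read_case_table",
    "write_case_table",
    "read_population",
    "write_population",
    "exclude_siblings",
]

MANDATORY_CASE_COLUMNS = ("case_id", "x_birth", "y_birth", "birth_date", "diagnosis_date")
MAX_DIAGNOSIS_AGE_DAYS = 16 * 365.25
SIBLING_REVIEW_DISTANCE_M = 50.0


class SchemaError(ValueError):
    """A required column is missing from an input file."""


def _validate_rows(df: pd.DataFrame):
    """Split a raw case frame into valid rows and a row-level error report."""
    reasons = pd.Series("", index=df.index, dtype=object)

    def flag(mask, reason):
        bad = mask & (reasons == "")
        reasons[bad] = reason

    x = pd.to_numeric(df["x_birth"], errors="coerce")
    y = pd.to_numeric(df["y_birth"], errors="coerce")
    birth = pd.to_datetime(df["birth_date"], errors="coerce")
    diag = pd.to_datetime(df["diagnosis_date"], errors="coerce")
    flag(x.isna() | y.isna(), "missing or non-numeric birth coordinates")
    flag(birth.isna(), "unparseable birth_date")
    flag(diag.isna(), "unparseable diagnosis_date")
    age_days = (diag - birth).dt.days
    flag(age_days < 0, "diagnosis_date before birth_date")
    flag(age_days >= MAX_DIAGNOSIS_AGE_DAYS, "diagnosis age >= 16 years")

    ok = reasons == ""
    valid = df[ok].copy()
    valid["x_birth"] = x[ok]
    valid["y_birth"] = y[ok]
    valid["birth_date"] = birth[ok]
    valid["diagnosis_date"] = diag[ok]
    report = pd.DataFrame(
        {
            "row": df.index[~ok],
            "case_id": df.loc[~ok, "case_id"].to_numpy(),
            "reason": reasons[~ok].to_numpy(),
        }
    )
    return valid.reset_index(drop=True), report.reset_index(drop=True)


def read_case_table(path, return_report: bool = False):
    """Read and validate a case table; malformed rows are dropped with a
    per-row reason (returned when ``return_report=True``)."""
    df = pd.read_csv(path)
    missing = [c for c in MANDATORY_CASE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"case table missing mandatory columns: {missing}")
    for col in ("sibling_group", "truth_cluster_id"):
        if col in df.columns:
            df[col] = pd.array(pd.to_numeric(df[col], errors="coerce"), dtype="Int64")
    valid, report = _validate_rows(df)
    return (valid, report) if return_report else valid


def write_case_table(cases: pd.DataFrame, path) -> None:
    out = cases.copy()
    for col in ("birth_date", "diagnosis_date"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    ordered = [c for c in MANDATORY_CASE_COLUMNS if c in out.columns]
    ordered += [c for c in out.columns if c not in ordered]
    out[ordered].to_csv(path, index=False)


def read_population(path) -> list[PopulationSnapshot]:
    df = pd.read_csv(path)
    missing = [c for c in ("snapshot_date", "x", "y", "child_count") if c not in df.columns]
    if missing:
        raise SchemaError(f"population file missing mandatory columns: {missing}")
    cell_size = float(df["cell_size_m"].iloc[0]) if "cell_size_m" in df.columns else 1000.0
    snaps = []
    for date, grp in df.groupby("snapshot_date", sort=True):
        cells = grp[["x", "y", "child_count"]].reset_index(drop=True)
        snaps.append(PopulationSnapshot(date=pd.Timestamp(date), cells=cells,
                                        cell_size_m=cell_size))
    return snaps


def write_population(snapshots: list[PopulationSnapshot], path) -> None:
    frames = []
    for s in snapshots:
        f = s.cells[["x", "y", "child_count"]].copy()
        f.insert(0, "snapshot_date", pd.Timestamp(s.date).strftime("%Y-%m-%d"))
        f["cell_size_m"] = s.cell_size_m
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def exclude_siblings(cases: pd.DataFrame, review_distance_m: float = SIBLING_REVIEW_DISTANCE_M):
    """Retain one case per sibling group; list unexplained close residences.

    For every non-null ``sibling_group``, only the earliest-born case is kept
    (ties broken by lowest case_id).  Pairs of retained cases living closer
    than ``review_distance_m`` *without* a shared sibling group are kept but
    returned in a review report, mirroring the manual sibling inspection a
    registry would perform.

    Returns ``(kept_cases, review_report)``.
    """
    df = cases.reset_index(drop=True)
    if "sibling_group" in df.columns and df["sibling_group"].notna().any():
        grouped = df[df["sibling_group"].notna()]
        keep_ids = (
            grouped.sort_values(["birth_date", "case_id"])
            .groupby("sibling_group", sort=False)["case_id"]
            .first()
        )
        drop = grouped.loc[~grouped["case_id"].isin(keep_ids), "case_id"]
        df = df[~df["case_id"].isin(drop)].reset_index(drop=True)

    xy = df[["x_birth", "y_birth"]].to_numpy(float)
    review_rows = []
    if len(df) > 1:
        pairs = cKDTree(xy).query_pairs(review_distance_m, output_type="ndarray")
        sib = df["sibling_group"] if "sibling_group" in df.columns else None
        for i, j in pairs:
            same_group = (
                sib is not None
                and pd.notna(sib.iloc[i])
                and pd.notna(sib.iloc[j])
                and sib.iloc[i] == sib.iloc[j]
            )
            if not same_group:
                review_rows.append(
                    dict(case_id_1=df["case_id"].iloc[i], case_id_2=df["case_id"].iloc[j],
                         distance_m=float(np.hypot(*(xy[i] - xy[j]))))
                )
    review = pd.DataFrame(review_rows, columns=["case_id_1", "case_id_2", "distance_m"])
    return df, review
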