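"""Delimited-text specimen tables: schema, reading, validation, writing.

One row is one individual's measurements.  The canonical columns are

    taxon (mandatory), specimen_id, group (cetacean | terrestrial),
    maturity (adult | subadult | unknown), brain_mass_g,
    endocranial_volume_cm3, adnexa_mass_g, ocw_mm, body_mass_kg,
    body_length, body_length_unit, age_ma, source, override_body_mass_kg

Comma or tab dialect is auto-detected; thousands separators inside
quoted numbers ("2,240") are accepted.  Malformed rows (negative
measurements, unparseable numbers) are collected into an issue report
with line numbers rather than aborting the read.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import DataError
from .phylo import normalize_label

__all__ = [
    "NUMERIC_COLUMNS",
    "RowIssue",
    "read_specimen_table",
    "write_specimen_table",
    "load_cavity_measurements",
    "load_eocene_archaeocetes",
]

NUMERIC_COLUMNS = (
    "brain_mass_g",
    "endocranial_volume_cm3",
    "adnexa_mass_g",
    "ocw_mm",
    "body_mass_kg",
    "body_length",
    "age_ma",
    "override_body_mass_kg",
)

MANDATORY_COLUMNS = ("taxon",)

_MEASUREMENT_COLUMNS = tuple(c for c in NUMERIC_COLUMNS if c != "age_ma")


@dataclass(frozen=True)
class RowIssue:
    line: int  # 1-based line number in the file (header is line 1)
    column: str
    value: object
    reason: str


def _to_number(value) -> float:
    """Parse a number accepting thousands separators; NaN for blanks."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    s = str(value).strip().replace("−", "-")  # unicode minus
    if s == "" or s.lower() in {"na", "nan", "-", "—"}:
        return np.nan
    return float(s.replace(",", ""))


def read_specimen_table(path: str | Path) -> tuple[pd.DataFrame, list[RowIssue]]:
    """Read a specimen table; returns (records, issues).

    Rows with any invalid measurement are dropped from the records and
    reported in ``issues`` with their file line numbers.  A missing
    mandatory column raises :class:`DataError` naming it.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                     skipinitialspace=True)
    df.columns = [str(c).strip() for c in df.columns]
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"missing mandatory column(s): {missing}")

    issues: list[RowIssue] = []
    bad_rows: set[int] = set()
    for col in NUMERIC_COLUMNS:
        if col not in df.columns:
            continue
        parsed = []
        for idx, raw in df[col].items():
            line = int(idx) + 2  # header occupies line 1
            try:
                val = _to_number(raw)
            except ValueError:
                issues.append(RowIssue(line, col, raw, "not a number"))
                bad_rows.add(idx)
                parsed.append(np.nan)
                continue
            if col in _MEASUREMENT_COLUMNS and np.isfinite(val) and val <= 0:
                issues.append(RowIssue(line, col, raw, "non-positive measurement"))
                bad_rows.add(idx)
            parsed.append(val)
        df[col] = parsed

    df["taxon"] = df["taxon"].map(lambda v: normalize_label(v) if pd.notna(v) else v)
    blank_taxon = df["taxon"].isna() | (df["taxon"] == "")
    for idx in df.index[blank_taxon]:
        issues.append(RowIssue(int(idx) + 2, "taxon", df.loc[idx, "taxon"],
                               "missing taxon"))
        bad_rows.add(idx)
    present = [c for c in _MEASUREMENT_COLUMNS if c in df.columns]
    if present:
        no_measurement = df[present].isna().all(axis=1)
        for idx in df.index[no_measurement]:
            issues.append(RowIssue(int(idx) + 2, "(all)", None,
                                   "no measurement present"))
            bad_rows.add(idx)

    if "maturity" in df.columns:
        df["maturity"] = df["maturity"].fillna("unknown").str.strip().str.lower()
    else:
        df["maturity"] = "unknown"

    records = df.drop(index=sorted(bad_rows)).reset_index(drop=True)
    return records, issues


def write_specimen_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write records as CSV; round-trips losslessly with the reader."""
    records.to_csv(path, index=False)


def _load_packaged(name: str) -> pd.DataFrame:
    with resources.as_file(resources.files("whalebrain.data").joinpath(name)) as p:
        records, issues = read_specimen_table(p)
    if issues:  # packaged data must be clean
        raise DataError(f"packaged table {name} has issues: {issues}")
    return records


def load_cavity_measurements() -> pd.DataFrame:
    """Brain mass, endocranial volume and adnexa mass for the extant
    cetaceans and terrestrial artiodactyls measured in this analysis."""
    return _load_packaged("extant_cavity_measurements.csv")


def load_eocene_archaeocetes() -> pd.DataFrame:
    """The seven Eocene archaeocete records (endocranial volume, OCW, age)."""
    return _load_packaged("eocene_archaeocetes.csv")
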