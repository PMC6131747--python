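"""CSV readers and writers for response tables.

Two on-disk layouts are supported: wide (one row per assessment, one column
per item) and long (one row per person-day-item rating with columns
person_id, day, instrument, item_id, rating). Missing codes are recoded on
read via :func:`delcal.instruments.recode_missing`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .instruments import (
    DEFAULT_MISSING_CODES,
    InstrumentSpec,
    ResponseTable,
    recode_missing,
)

__all__ = ["read_responses", "write_responses", "long_to_wide", "wide_to_long"]


def long_to_wide(long: pd.DataFrame) -> pd.DataFrame:
    wide = long.pivot_table(
        index=["person_id", "day"],
        columns="item_id",
        values="rating",
        aggfunc="first",
    ).reset_index()
    wide.columns.name = None
    return wide


def wide_to_long(table: ResponseTable) -> pd.DataFrame:
    long = table.data.melt(
        id_vars=["person_id", "day"], var_name="item_id", value_name="rating"
    )
    long.insert(2, "instrument", table.instrument)
    return long.sort_values(["person_id", "day", "item_id"], kind="stable")


def read_responses(
    path: str | Path,
    spec: InstrumentSpec,
    layout: str = "wide",
    missing_codes: Iterable[str] = DEFAULT_MISSING_CODES,
) -> ResponseTable:
    """Read one instrument's ratings from CSV and validate against the spec."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if layout == "long":
        raw["rating"] = raw["rating"].replace("", pd.NA)
        raw = long_to_wide(raw)
    elif layout != "wide":
        raise ValueError(f"unknown layout {layout!r}")
    raw["day"] = raw["day"].astype(int)
    try:
        raw["person_id"] = raw["person_id"].astype(int)
    except ValueError:
        pass  # non-numeric person identifiers stay as strings
    return recode_missing(raw, spec, missing_codes)


def write_responses(table: ResponseTable, path: str | Path) -> None:
    """Write a response table as wide CSV (missing cells left empty)."""
    out = table.data.copy()
    for c in table.item_columns:
        out[c] = out[c].astype("Int64")
    out.to_csv(path, index=False)
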