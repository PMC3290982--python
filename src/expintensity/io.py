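"""Delimited-text input/output for applicator and monitoring records.

The interchange format is a comma-separated table with a header row and
columns ``id, mix_level, methods, repair, ppe_items, lifetime_days``;
``methods`` and ``ppe_items`` hold semicolon-separated labels, ``repair``
is 0/1, and ``lifetime_days`` may be empty.  Monitoring tables add
``concentration`` (µg/L) and ``analyte``.  Output files carry ``#``-prefixed
metadata lines (tool version, weight-table version, seed) before the header.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from . import __version__
from .records import ApplicatorRecord, MonitoringRecord

APPLICATOR_COLUMNS = [
    "id",
    "mix_level",
    "methods",
    "repair",
    "ppe_items",
    "lifetime_days",
]
MONITORING_COLUMNS = APPLICATOR_COLUMNS + ["concentration", "analyte"]


def _split(cell) -> tuple[str, ...]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return ()
    text = str(cell).strip()
    if not text:
        return ()
    return tuple(p.strip() for p in text.split(";") if p.strip())


def _row_to_record(row, monitoring: bool):
    common = dict(
        id=str(row["id"]),
        mix_level=str(row["mix_level"]).strip(),
        methods=_split(row["methods"]),
        repair=str(row["repair"]).strip().lower() in ("1", "yes", "true"),
        ppe_items=frozenset(_split(row.get("ppe_items"))),
        lifetime_days=(
            None
            if "lifetime_days" not in row
            or row["lifetime_days"] in (None, "")
            or (isinstance(row["lifetime_days"], float) and math.isnan(row["lifetime_days"]))
            else float(row["lifetime_days"])
        ),
    )
    if monitoring:
        return MonitoringRecord(
            concentration=float(row["concentration"]),
            analyte=str(row.get("analyte", "")),
            **common,
        )
    return ApplicatorRecord(**common)


def frame_to_records(
    df: pd.DataFrame, monitoring: Optional[bool] = None
) -> list:
    """Convert a table in the interchange format to record objects.

    Row-level problems raise with the offending row index and id.
    """
    if monitoring is None:
        monitoring = "concentration" in df.columns
    missing = {"id", "mix_level", "methods", "repair"} - set(df.columns)
    if missing:
        raise ValueError(f"input table missing columns {sorted(missing)}")
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(_row_to_record(row, monitoring))
        except (ValueError, KeyError) as exc:
            raise ValueError(f"row {idx} (id={row.get('id')!r}): {exc}") from exc
    return records


def records_to_frame(records: Iterable) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "id": r.id,
            "mix_level": r.mix_level,
            "methods": ";".join(r.methods),
            "repair": int(r.repair),
            "ppe_items": ";".join(sorted(r.ppe_items)),
            "lifetime_days": "" if r.lifetime_days is None else r.lifetime_days,
        }
        if isinstance(r, MonitoringRecord):
            row["concentration"] = r.concentration
            row["analyte"] = r.analyte
        rows.append(row)
    return pd.DataFrame(rows)


def read_applicators(path: Union[str, Path]) -> list[ApplicatorRecord]:
    df = pd.read_csv(path, comment="#", dtype={"id": str})
    if df.empty and df.columns.empty:
        return []
    return frame_to_records(df, monitoring=False)


def read_monitoring(path: Union[str, Path]) -> list[MonitoringRecord]:
    df = pd.read_csv(path, comment="#", dtype={"id": str})
    return frame_to_records(df, monitoring=True)


def write_table(
    df: pd.DataFrame,
    path: Union[str, Path],
    metadata: Optional[dict] = None,
) -> None:
    """Write a result table with ``#`` metadata lines before the header."""
    meta = {"tool_version": __version__}
    if metadata:
        meta.update(metadata)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


def write_records(
    records: Iterable, path: Union[str, Path], metadata: Optional[dict] = None
) -> None:
    write_table(records_to_frame(records), path, metadata)
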