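"""CSV/JSON input-output and validation for otolith record tables.

Canonical table columns (CSV, UTF-8, comma-separated, header mandatory):

========  ======================================================
column    meaning / unit
========  ======================================================
record_id unique identifier (string)
site      site code (string)
region    'NW' or 'W'
century   calendar century as an integer ordinal (10 = 900-999)
age       annual-increment age, integer years >= 1
otolith_width  transverse-section width, um (valid range 1e3-1e5)
true_length    simulation-only true length, cm (optional)
delta13C  permil VPDB (optional)
delta18O  permil VPDB (optional)
assay_type 'sectioned_juvenile_adult' or 'whole_otolith' (optional)
========  ======================================================

Rows violating an invariant are rejected individually with row-numbered
messages rather than failing the whole file.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("otodem")

__all__ = [
    "read_otolith_table",
    "write_otolith_table",
    "write_json",
    "read_json",
    "load_config",
    "OtolithTableError",
    "REQUIRED_COLUMNS",
    "WIDTH_RANGE_UM",
]

REQUIRED_COLUMNS = ("record_id", "site", "region", "century", "age",
                    "otolith_width")
OPTIONAL_COLUMNS = ("true_length", "true_age", "delta13C", "delta18O",
                    "assay_type", "dataset", "year")
WIDTH_RANGE_UM = (1e3, 1e5)
VALID_REGIONS = ("NW", "W")


class OtolithTableError(ValueError):
    pass


def validate_records(df: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Validate a record table; return (valid rows, row-numbered messages)."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise OtolithTableError(f"missing mandatory column(s): {missing}")
    msgs: list[str] = []
    keep = np.ones(len(df), dtype=bool)
    for i, row in df.iterrows():
        problems = []
        if row["region"] not in VALID_REGIONS:
            problems.append(f"unknown region {row['region']!r}")
        if not pd.isna(row["age"]) and row["age"] < 1:
            problems.append(f"age {row['age']} < 1")
        w = row["otolith_width"]
        if not pd.isna(w):
            if w <= 0:
                problems.append("non-positive otolith width")
            elif not (WIDTH_RANGE_UM[0] <= w <= WIDTH_RANGE_UM[1]):
                problems.append(
                    f"otolith width {w} outside the um range {WIDTH_RANGE_UM} "
                    "(is the column in the right unit?)")
        if problems:
            keep[df.index.get_loc(i)] = False
            msgs.append(f"row {i}: " + "; ".join(problems))
    for m in msgs:
        logger.warning("rejected %s", m)
    return df[keep].copy(), msgs


def read_otolith_table(path) -> pd.DataFrame:
    """Read and validate an otolith record CSV; invalid rows are dropped."""
    df = pd.read_csv(path)
    valid, _ = validate_records(df)
    if valid.empty:
        raise OtolithTableError(f"no valid rows in {path}")
    return valid


def write_otolith_table(df: pd.DataFrame, path, truth=None) -> None:
    """Write a record table (and an optional JSON truth sidecar)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6f")
    if truth is not None:
        write_json(truth, path.with_suffix(".truth.json"))


def _jsonable(obj):
    if hasattr(obj, "to_dict"):
        return _jsonable(obj.to_dict())
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def write_json(obj, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n",
                    encoding="utf-8")


def read_json(path):
    return json.loads(Path(path).read_text(encoding="utf-8"))


def load_config(path) -> dict:
    """Load a YAML pipeline configuration file."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise OtolithTableError(f"config {path} is not a mapping")
    return cfg
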