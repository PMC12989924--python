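"""Reading and writing survival tables (CSV/TSV with header).

A survival table has one row per subject: an observed-time column, a 0/1
event column and any number of numeric covariate columns.  Rows with
missing values in the used columns are dropped (complete-case handling)
with a logged count; malformed values raise descriptive errors.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["read_survival_table", "write_survival_table"]


def read_survival_table(
    path,
    time_col: str = "time",
    event_col: str = "event",
    covariate_cols: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Load and validate a survival table.

    Returns a DataFrame with columns ``time``, ``event`` and the requested
    covariates (all columns other than time/event when
    ``covariate_cols`` is None).  Rows with missing values in any used
    column are removed; the exclusion count is logged.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    for col in (time_col, event_col):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path}")
    if covariate_cols is None:
        covariate_cols = [c for c in df.columns if c not in (time_col, event_col)]
    missing_cols = [c for c in covariate_cols if c not in df.columns]
    if missing_cols:
        raise ValueError(f"covariate columns not found: {missing_cols}")

    used = [time_col, event_col, *covariate_cols]
    sub = df[used].copy()
    n_before = len(sub)
    sub = sub.dropna()
    n_dropped = n_before - len(sub)
    if n_dropped:
        logger.info(
            "read_survival_table: excluded %d rows with missing values",
            n_dropped,
        )
    if sub.empty:
        raise ValueError("no complete rows left after missing-value removal")

    times = pd.to_numeric(sub[time_col], errors="coerce")
    if times.isna().any():
        row = int(sub.index[times.isna()][0])
        raise ValueError(f"nonnumeric time value in column {time_col!r}, row {row}")
    if (times < 0).any():
        row = int(sub.index[times < 0][0])
        raise ValueError(f"negative time in column {time_col!r}, row {row}")
    events = pd.to_numeric(sub[event_col], errors="coerce")
    bad = ~events.isin([0, 1])
    if bad.any():
        row = int(sub.index[bad][0])
        raise ValueError(
            f"event column {event_col!r} must be coded 0/1; bad value in row {row}"
        )
    for c in covariate_cols:
        vals = pd.to_numeric(sub[c], errors="coerce")
        if vals.isna().any():
            row = int(sub.index[vals.isna()][0])
            raise ValueError(f"nonnumeric covariate value in column {c!r}, row {row}")
        sub[c] = vals.astype(float)

    out = pd.DataFrame({"time": times.astype(float), "event": events.astype(int)})
    for c in covariate_cols:
        out[c] = sub[c].to_numpy()
    out.attrs["n_dropped"] = n_dropped
    return out.reset_index(drop=True)


def _config_to_jsonable(cfg):
    if dataclasses.is_dataclass(cfg):
        out = {}
        for f in dataclasses.fields(cfg):
            val = getattr(cfg, f.name)
            if hasattr(val, "family"):
                out[f.name] = {"family": val.family, "tau": val.tau}
            else:
                out[f.name] = val
        return out
    return repr(cfg)


def write_survival_table(df: pd.DataFrame, path, sidecar_config: bool = True):
    """Write a dataset as CSV (full precision) plus a JSON config sidecar."""
    path = Path(path)
    df.to_csv(path, index=False)
    if sidecar_config and "config" in df.attrs:
        sidecar = path.with_suffix(path.suffix + ".config.json")
        payload = {"config": _config_to_jsonable(df.attrs["config"])}
        for key in ("informative", "unequal_censoring"):
            if key in df.attrs:
                payload[key] = df.attrs[key]
        sidecar.write_text(json.dumps(payload, indent=2))
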