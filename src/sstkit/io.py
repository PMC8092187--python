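"""CSV schemas with validating readers/writers.

All artifacts are plain CSV; every reader validates the column set and the
value domains and raises :class:`SchemaError` naming file, row, and column
of the first offense.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .race_sim import LATENT_COLUMNS, PARTICIPANT_COLUMNS, TRIAL_LOG_COLUMNS
from .ssrt_estimator import ESTIMATE_COLUMNS


class SchemaError(ValueError):
    def __init__(self, file: str, message: str, row: int | None = None,
                 column: str | None = None):
        self.file, self.row, self.column = str(file), row, column
        loc = f"{file}"
        if row is not None:
            loc += f", row {row}"
        if column is not None:
            loc += f", column {column!r}"
        super().__init__(f"{loc}: {message}")


def _read_csv(path: str | Path, required: list[str], label: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(path, f"{label} file does not exist")
    df = pd.read_csv(path)
    if len(df) == 0:
        raise SchemaError(path, f"{label} contains no rows")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(path, f"missing required column", column=missing[0])
    return df


def _check_numeric(df: pd.DataFrame, path, column: str,
                   allow_nan: bool = False, low: float | None = None) -> None:
    vals = pd.to_numeric(df[column], errors="coerce")
    bad = vals.isna() & df[column].notna()
    if bad.any():
        raise SchemaError(path, "non-numeric value",
                          row=int(bad.idxmax()), column=column)
    if not allow_nan and vals.isna().any():
        raise SchemaError(path, "missing value",
                          row=int(vals.isna().idxmax()), column=column)
    if low is not None:
        toolow = vals.notna() & (vals < low)
        if toolow.any():
            raise SchemaError(path, f"value below {low}",
                              row=int(toolow.idxmax()), column=column)
    df[column] = vals


def _check_values(df: pd.DataFrame, path, column: str, allowed: set) -> None:
    bad = ~df[column].isin(allowed)
    if bad.any():
        raise SchemaError(path, f"value not in {sorted(allowed)}",
                          row=int(bad.idxmax()), column=column)


def read_trial_log(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, TRIAL_LOG_COLUMNS, "trial log")
    _check_values(df, path, "trial_type", {"go", "stop"})
    _check_values(df, path, "responded", {0, 1})
    _check_values(df, path, "correct", {0, 1})
    _check_numeric(df, path, "ssd_ms", allow_nan=True, low=0.0)
    _check_numeric(df, path, "rt_ms", allow_nan=True, low=0.0)
    resp_no_rt = (df["responded"] == 1) & df["rt_ms"].isna()
    if resp_no_rt.any():
        raise SchemaError(path, "responded trial without RT",
                          row=int(resp_no_rt.idxmax()), column="rt_ms")
    return df


def write_trial_log(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=TRIAL_LOG_COLUMNS)


def read_participants(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, PARTICIPANT_COLUMNS, "participant table")
    _check_numeric(df, path, "bmi", low=1.0)
    _check_numeric(df, path, "age", low=0.0)
    _check_numeric(df, path, "height_cm", allow_nan=True, low=0.0)
    dup = df["participant_id"].duplicated()
    if dup.any():
        raise SchemaError(path, "duplicate participant_id",
                          row=int(dup.idxmax()), column="participant_id")
    return df


def write_participants(df: pd.DataFrame, path: str | Path) -> None:
    cols = PARTICIPANT_COLUMNS + [c for c in LATENT_COLUMNS if c in df.columns]
    df.to_csv(path, index=False, columns=cols)


def read_estimates(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, ESTIMATE_COLUMNS, "estimates table")
    _check_numeric(df, path, "p_respond_signal")
    bad = (df["p_respond_signal"] < 0) | (df["p_respond_signal"] > 1)
    if bad.any():
        raise SchemaError(path, "proportion outside [0, 1]",
                          row=int(bad.idxmax()), column="p_respond_signal")
    _check_numeric(df, path, "mean_ssd_ms", low=0.0)
    _check_numeric(df, path, "ssrt_ms", allow_nan=True)
    _check_numeric(df, path, "mean_go_rt_ms", low=0.0)
    _check_numeric(df, path, "mean_signal_respond_rt_ms", allow_nan=True, low=0.0)
    return df


def write_estimates(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=ESTIMATE_COLUMNS)
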