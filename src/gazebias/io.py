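"""CSV dialects for gaze logs, rosters, trial geometry and trial metrics.

The gaze log is a device-export-style file with one row per 150 Hz sample:

    participant_id, trial_index, time_ms, x_px, y_px, valid,
    fixation_id, blink_id, blink_duration_ms

Missing annotations (no fixation, no blink) round-trip as empty cells;
``blink_duration_ms`` is present exactly on the first sample of each
blink.  All floating-point columns are written at full precision; rounding
is presentation, not data.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import DataError
from .preprocessing import METRIC_COLUMNS
from .synthetic import SAMPLE_COLUMNS, GazeDataset

ROSTER_COLUMNS = ["participant_id", "cohort", "condition"]
GEOMETRY_COLUMNS = [
    "participant_id", "trial_index", "positive_side", "screen_w", "screen_h",
    "left_x0", "left_y0", "left_x1", "left_y1",
    "right_x0", "right_y0", "right_x1", "right_y1",
]


def write_gaze_csv(data: GazeDataset | pd.DataFrame, path) -> None:
    """Write a gaze sample table (or a dataset's samples) as CSV."""
    df = data.samples if isinstance(data, GazeDataset) else data
    out = df[SAMPLE_COLUMNS].copy()
    out["valid"] = out["valid"].astype(int)
    for col in ("fixation_id", "blink_id"):
        out[col] = out[col].astype("Int64")
    out.to_csv(path, index=False)


def read_gaze_csv(path) -> pd.DataFrame:
    """Read a gaze log, validating the dialect.

    Unknown columns raise a warning and are dropped; missing mandatory
    columns are an error; a blink without an annotated duration anywhere in
    its sample run is reported with its (1-based, header-inclusive) line
    number.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"gaze CSV is missing mandatory columns: {missing}")
    extra = [c for c in df.columns if c not in SAMPLE_COLUMNS]
    if extra:
        warnings.warn(f"ignoring unknown gaze CSV columns: {extra}")
        df = df.drop(columns=extra)
    df["valid"] = df["valid"].astype(bool)
    for col in ("x_px", "y_px", "time_ms", "fixation_id", "blink_id", "blink_duration_ms"):
        df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)

    blinks = df[df["blink_id"].notna()]
    if not blinks.empty:
        has_dur = blinks.groupby(["participant_id", "trial_index", "blink_id"])[
            "blink_duration_ms"
        ].apply(lambda s: s.notna().any())
        if not has_dur.all():
            bad = has_dur[~has_dur].index[0]
            row = blinks[
                (blinks["participant_id"] == bad[0])
                & (blinks["trial_index"] == bad[1])
                & (blinks["blink_id"] == bad[2])
            ].index[0]
            raise DataError(
                f"blink without blink_duration_ms at line {row + 2} "
                f"(participant {bad[0]}, trial {bad[1]}, blink {int(bad[2])})"
            )
        neg = blinks["blink_duration_ms"].dropna()
        if (neg <= 0).any():
            raise DataError("blink_duration_ms must be positive")
    return df


def write_roster_csv(roster: pd.DataFrame, path) -> None:
    roster[ROSTER_COLUMNS].to_csv(path, index=False)


def read_roster_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ROSTER_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"roster CSV is missing columns: {missing}")
    if df["participant_id"].duplicated().any():
        raise DataError("duplicate participant ids in roster")
    return df[ROSTER_COLUMNS]


def write_geometry_csv(geometry: pd.DataFrame, path) -> None:
    geometry[GEOMETRY_COLUMNS].to_csv(path, index=False)


def read_geometry_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in GEOMETRY_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"geometry CSV is missing columns: {missing}")
    return df[GEOMETRY_COLUMNS]


def write_metrics_csv(metrics: pd.DataFrame, path) -> None:
    cols = [c for c in METRIC_COLUMNS + ["nbi_time", "nbi_count", "first_look"]
            if c in metrics.columns]
    metrics[cols].to_csv(path, index=False)


def read_metrics_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    needed = ["participant_id", "trial_index", "dwell_pos_ms", "dwell_neg_ms"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise DataError(f"metrics CSV is missing columns: {missing}")
    return df
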