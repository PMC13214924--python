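"""Raw gaze streams -> per-trial, per-AOI metrics and dataset-level QC.

The preprocessing contract mirrors common practice for AOI-based
free-viewing analyses:

* every valid sample inside an AOI contributes one sampling interval to
  that AOI's cumulative dwell time;
* the annotated duration of any blink whose onset gaze was assigned to an
  AOI is subtracted from that AOI's dwell (blink time is signal
  interruption, not engagement), floored at zero;
* the time to first fixation (TTFF) of an AOI is the time of the first
  in-AOI sample belonging to a fixation run, and is missing (NaN) when the
  AOI was never fixated — no interpolation is ever applied;
* a trial is excluded only when both AOIs have zero dwell; no minimum
  viewing-time threshold is imposed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .synthetic import (
    SAMPLE_INTERVAL_MS,
    WINDOW_MS,
    GazeDataset,
    TrialGeometry,
    TrialRecording,
)

METRIC_COLUMNS = [
    "participant_id",
    "trial_index",
    "cohort",
    "condition",
    "dwell_pos_ms",
    "dwell_neg_ms",
    "ttff_pos_ms",
    "ttff_neg_ms",
    "fixcount_pos",
    "fixcount_neg",
    "valid",
]


@dataclass(frozen=True)
class AOIMetrics:
    """Blink-corrected metrics for one AOI within one trial."""

    valence: str
    dwell_ms: float
    ttff_ms: float  # NaN when the AOI was never fixated
    fixation_count: int


@dataclass
class QCReport:
    """Dataset-level quality-control summary after trial validity filtering."""

    n_expected: int
    n_valid: int
    n_excluded: int
    retention_pct: float
    excluded_by_cell: dict = field(default_factory=dict)
    mean_ttff_s: float = float("nan")
    mean_dwell_s: float = float("nan")
    dwell_fraction_pct: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "n_expected": self.n_expected,
            "n_valid": self.n_valid,
            "n_excluded": self.n_excluded,
            "retention_pct": self.retention_pct,
            "excluded_by_cell": {"/".join(k): v for k, v in self.excluded_by_cell.items()},
            "mean_ttff_s": self.mean_ttff_s,
            "mean_dwell_s": self.mean_dwell_s,
            "dwell_fraction_pct": self.dwell_fraction_pct,
        }

    def to_json(self, path=None) -> str:
        def clean(x):
            return None if isinstance(x, float) and math.isnan(x) else x

        text = json.dumps({k: clean(v) for k, v in self.to_dict().items()}, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def assign_aoi(sample, geometry: TrialGeometry) -> str:
    """Classify one gaze sample as 'positive', 'negative' or 'none'.

    ``sample`` is any mapping with ``x_px``, ``y_px`` and ``valid`` entries.
    Invalid samples and samples outside both AOIs map to 'none'.  AOI
    containment is half-open ([x0, x1) x [y0, y1)) so shared edges can never
    be double-assigned.
    """
    if geometry.left_rect.overlaps(geometry.right_rect):
        raise ConfigurationError("AOI rectangles overlap")
    if not bool(sample["valid"]):
        return "none"
    x, y = float(sample["x_px"]), float(sample["y_px"])
    if not (np.isfinite(x) and np.isfinite(y)):
        return "none"
    if geometry.left_rect.contains(x, y):
        side = "left"
    elif geometry.right_rect.contains(x, y):
        side = "right"
    else:
        return "none"
    return "positive" if side == geometry.positive_side else "negative"


def _trial_codes(samples: pd.DataFrame, geometry: pd.DataFrame) -> np.ndarray:
    """Integer geometry-row index for every sample (vectorized key lookup)."""
    keys = ["participant_id", "trial_index"]
    gkey = pd.MultiIndex.from_frame(geometry[keys])
    if gkey.duplicated().any():
        raise DataError("duplicate participant/trial rows in the geometry table")
    tid = gkey.get_indexer(pd.MultiIndex.from_frame(samples[keys]))
    if (tid < 0).any():
        raise DataError("samples reference trials missing from the geometry table")
    return tid


def compute_metrics_table(
    samples: pd.DataFrame,
    geometry: pd.DataFrame,
    roster: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-trial, per-AOI blink-corrected metrics for a whole sample table.

    Returns one row per trial (the rows of ``geometry``) with dwell, TTFF
    and fixation-count columns for both valences (wide layout, see
    :data:`METRIC_COLUMNS`).
    """
    tid = _trial_codes(samples, geometry)
    n_trials = len(geometry)
    n = len(samples)
    t = samples["time_ms"].to_numpy(float)
    x = samples["x_px"].to_numpy(float)
    y = samples["y_px"].to_numpy(float)
    valid = samples["valid"].to_numpy(bool)
    fix_id = samples["fixation_id"].to_numpy(float)
    blink_id = samples["blink_id"].to_numpy(float)
    blink_dur = samples["blink_duration_ms"].to_numpy(float)

    # stable sort makes trials contiguous while preserving time order
    order = np.argsort(tid, kind="stable")
    tid_s = tid[order]
    new_trial = np.empty(n, dtype=bool)
    if n:
        new_trial[0] = True
        new_trial[1:] = tid_s[1:] != tid_s[:-1]
        dt_s = np.diff(t[order])
        if np.any((dt_s <= 0) & ~new_trial[1:]):
            raise DataError(
                "samples must be strictly increasing in time within each trial"
            )

    def geom_col(name: str) -> np.ndarray:
        return geometry[name].to_numpy()[tid]

    ok = valid & np.isfinite(x) & np.isfinite(y)
    in_left = (
        ok
        & (geom_col("left_x0") <= x) & (x < geom_col("left_x1"))
        & (geom_col("left_y0") <= y) & (y < geom_col("left_y1"))
    )
    in_right = (
        ok
        & (geom_col("right_x0") <= x) & (x < geom_col("right_x1"))
        & (geom_col("right_y0") <= y) & (y < geom_col("right_y1"))
    )
    if (in_left & in_right).any():
        raise ConfigurationError("AOI rectangles overlap")
    pos_left = geometry["positive_side"].to_numpy() == "left"
    pos_left_s = pos_left[tid]
    is_pos = (in_left & pos_left_s) | (in_right & ~pos_left_s)
    is_neg = (in_left & ~pos_left_s) | (in_right & pos_left_s)

    # raw dwell: one sampling interval per assigned sample
    dwell_pos = np.bincount(tid[is_pos], minlength=n_trials) * SAMPLE_INTERVAL_MS
    dwell_neg = np.bincount(tid[is_neg], minlength=n_trials) * SAMPLE_INTERVAL_MS

    # blink correction: attribute each annotated blink to the AOI of the
    # last valid non-blink sample at or before its onset, then subtract the
    # annotated duration from that AOI's dwell (floored at zero)
    onset = np.isfinite(blink_dur)
    if onset.any():
        aoi_code = np.where(is_pos, 1, np.where(is_neg, 2, 0))  # per-sample AOI
        nonblink = ~np.isfinite(blink_id) & valid
        # per-trial forward-carry of the last non-blink sample's position,
        # implemented as a segment-wise cummax with per-trial bases so the
        # carry can never cross a trial boundary
        base = (tid_s.astype(np.int64) + 1) * (n + 1)
        marker = np.where(nonblink[order], base + np.arange(n), 0)
        carried = np.maximum.accumulate(marker) - base
        src = np.full(n, -1)
        inside = (carried >= 0) & (carried < n)
        src[inside] = order[carried[inside].astype(np.int64)]
        src_unsorted = np.empty(n, dtype=np.int64)
        src_unsorted[order] = src
        onset_idx = np.flatnonzero(onset)
        blink_aoi = np.where(
            src_unsorted[onset_idx] >= 0, aoi_code[src_unsorted[onset_idx]], 0
        )
        for code, dwell in ((1, dwell_pos), (2, dwell_neg)):
            sel = onset_idx[blink_aoi == code]
            if len(sel):
                np.subtract.at(dwell, tid[sel], blink_dur[sel])
        np.clip(dwell_pos, 0.0, None, out=dwell_pos)
        np.clip(dwell_neg, 0.0, None, out=dwell_neg)

    # TTFF and fixation counts over fixation-annotated in-AOI samples
    has_fix = np.isfinite(fix_id)
    ttff_pos = np.full(n_trials, np.inf)
    ttff_neg = np.full(n_trials, np.inf)
    np.minimum.at(ttff_pos, tid[is_pos & has_fix], t[is_pos & has_fix])
    np.minimum.at(ttff_neg, tid[is_neg & has_fix], t[is_neg & has_fix])
    ttff_pos[np.isinf(ttff_pos)] = np.nan
    ttff_neg[np.isinf(ttff_neg)] = np.nan

    def fix_count(mask: np.ndarray) -> np.ndarray:
        sel = mask & has_fix
        if not sel.any():
            return np.zeros(n_trials, dtype=int)
        pairs = np.unique(
            np.column_stack([tid[sel], fix_id[sel]]), axis=0
        )
        return np.bincount(pairs[:, 0].astype(np.int64), minlength=n_trials)

    out = geometry[["participant_id", "trial_index"]].copy()
    out["dwell_pos_ms"] = dwell_pos
    out["dwell_neg_ms"] = dwell_neg
    out["ttff_pos_ms"] = ttff_pos
    out["ttff_neg_ms"] = ttff_neg
    out["fixcount_pos"] = fix_count(is_pos)
    out["fixcount_neg"] = fix_count(is_neg)

    if roster is not None:
        out = out.merge(
            roster[["participant_id", "cohort", "condition"]],
            on="participant_id",
            how="left",
            validate="m:1",
        )
    return out


def compute_aoi_metrics(trial: TrialRecording) -> tuple[AOIMetrics, AOIMetrics]:
    """Blink-corrected metrics for a single trial (positive, negative)."""
    g = trial.geometry
    geom = pd.DataFrame(
        {
            "participant_id": [trial.participant_id],
            "trial_index": [trial.trial_index],
            "positive_side": [g.positive_side],
            "left_x0": g.left_rect.x0, "left_y0": g.left_rect.y0,
            "left_x1": g.left_rect.x1, "left_y1": g.left_rect.y1,
            "right_x0": g.right_rect.x0, "right_y0": g.right_rect.y0,
            "right_x1": g.right_rect.x1, "right_y1": g.right_rect.y1,
        }
    )
    samples = trial.samples.assign(
        participant_id=trial.participant_id, trial_index=trial.trial_index
    )
    row = compute_metrics_table(samples, geom).iloc[0]
    return (
        AOIMetrics("positive", row["dwell_pos_ms"], row["ttff_pos_ms"],
                   int(row["fixcount_pos"])),
        AOIMetrics("negative", row["dwell_neg_ms"], row["ttff_neg_ms"],
                   int(row["fixcount_neg"])),
    )


def validity_filter(metrics: pd.DataFrame) -> tuple[pd.DataFrame, QCReport]:
    """Drop trials with zero dwell in both AOIs; tally the exclusions.

    This is the only exclusion rule: trials with any nonzero dwell are kept
    regardless of how short the viewing was.
    """
    keys = ["participant_id", "trial_index"]
    if metrics.duplicated(subset=keys).any():
        raise DataError("duplicate participant/trial keys in metrics table")
    n_expected = len(metrics)
    if n_expected == 0:
        return metrics.copy(), QCReport(0, 0, 0, float("nan"))

    keep = (metrics["dwell_pos_ms"] > 0) | (metrics["dwell_neg_ms"] > 0)
    out = metrics.copy()
    out["valid"] = keep.to_numpy()
    excluded = out[~keep]
    by_cell: dict = {}
    if {"cohort", "condition"}.issubset(out.columns):
        for (g, c), grp in excluded.groupby(["cohort", "condition"], sort=True):
            by_cell[(g, c)] = int(len(grp))
    report = QCReport(
        n_expected=n_expected,
        n_valid=int(keep.sum()),
        n_excluded=int((~keep).sum()),
        retention_pct=100.0 * float(keep.sum()) / n_expected,
        excluded_by_cell=by_cell,
    )
    return out[keep].drop(columns="valid").reset_index(drop=True), report


def qc_summary(valid: pd.DataFrame, everything: pd.DataFrame) -> QCReport:
    """Full QC report: retention plus engagement summaries over valid trials."""
    _, report = validity_filter(everything)
    if len(valid):
        first_ttff = valid[["ttff_pos_ms", "ttff_neg_ms"]].min(axis=1, skipna=True)
        report.mean_ttff_s = float(first_ttff.mean(skipna=True)) / 1000.0
        total_dwell = valid["dwell_pos_ms"] + valid["dwell_neg_ms"]
        report.mean_dwell_s = float(total_dwell.mean()) / 1000.0
        report.dwell_fraction_pct = 100.0 * report.mean_dwell_s * 1000.0 / WINDOW_MS
    return report


def preprocess_dataset(dataset: GazeDataset) -> tuple[pd.DataFrame, pd.DataFrame, QCReport]:
    """Convenience wrapper: metrics table, valid subset and QC for a dataset."""
    metrics = compute_metrics_table(
        dataset.samples, dataset.geometry, dataset.roster_frame()
    )
    valid, _ = validity_filter(metrics)
    report = qc_summary(valid, metrics)
    return metrics, valid, report
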