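"""Trial-level outcome variables: dwell-time bias and first-look direction.

The Normalized Bias Index (NBI) expresses the relative split of dwell time
between the positive and the negative AOI,

    NBI = (dwell_pos - dwell_neg) / (dwell_pos + dwell_neg),

ranging from -1 (all dwell on the negative image) to +1 (all dwell on the
positive image); 0 is a balanced split.  Dividing by total dwell makes the
index invariant to how long the participant looked overall.

First-look direction is the binary early-orienting outcome: 1 when the
positive AOI received the earlier valid fixation (shorter TTFF), 0 when the
negative AOI did, and missing when neither AOI was fixated.  Exact TTFF
ties are classified missing: at a 150 Hz sample grid an exact tie carries
no directional information.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, UndefinedValueError


def nbi(dwell_pos: float, dwell_neg: float) -> float:
    """Normalized dwell-time bias index in [-1, +1]."""
    if dwell_pos < 0 or dwell_neg < 0:
        raise DataError("dwell times must be nonnegative")
    total = dwell_pos + dwell_neg
    if total <= 0:
        raise UndefinedValueError("NBI undefined when both dwell times are zero")
    return (dwell_pos - dwell_neg) / total


def fixation_count_bias(fixcount_pos: int, fixcount_neg: int) -> float:
    """Normalized fixation-count bias, the NBI form applied to counts."""
    if fixcount_pos < 0 or fixcount_neg < 0:
        raise DataError("fixation counts must be nonnegative")
    total = fixcount_pos + fixcount_neg
    if total <= 0:
        raise UndefinedValueError("count bias undefined when both counts are zero")
    return (fixcount_pos - fixcount_neg) / total


def first_look(ttff_pos: float, ttff_neg: float) -> float:
    """Binary first-fixation direction from the two TTFFs.

    Returns 1.0 (positive first), 0.0 (negative first) or NaN (neither AOI
    fixated, or an exact tie).
    """
    pos_missing = ttff_pos is None or (isinstance(ttff_pos, float) and math.isnan(ttff_pos))
    neg_missing = ttff_neg is None or (isinstance(ttff_neg, float) and math.isnan(ttff_neg))
    if not pos_missing and ttff_pos < 0 or not neg_missing and ttff_neg < 0:
        raise DataError("TTFF cannot be negative")
    if pos_missing and neg_missing:
        return float("nan")
    if pos_missing:
        return 0.0
    if neg_missing:
        return 1.0
    if ttff_pos == ttff_neg:
        return float("nan")
    return 1.0 if ttff_pos < ttff_neg else 0.0


def add_bias_columns(metrics: pd.DataFrame) -> pd.DataFrame:
    """Append nbi_time, nbi_count and first_look columns to a metrics table.

    Rows whose denominators are zero get NaN (they are expected to have
    been removed by the validity filter before modeling).
    """
    out = metrics.copy()
    dp = out["dwell_pos_ms"].to_numpy(float)
    dn = out["dwell_neg_ms"].to_numpy(float)
    if (dp < 0).any() or (dn < 0).any():
        raise DataError("dwell times must be nonnegative")
    tot = dp + dn
    with np.errstate(invalid="ignore", divide="ignore"):
        out["nbi_time"] = np.where(tot > 0, (dp - dn) / np.where(tot > 0, tot, 1.0), np.nan)
    cp = out["fixcount_pos"].to_numpy(float)
    cn = out["fixcount_neg"].to_numpy(float)
    ctot = cp + cn
    out["nbi_count"] = np.where(ctot > 0, (cp - cn) / np.where(ctot > 0, ctot, 1.0), np.nan)

    tp = out["ttff_pos_ms"].to_numpy(float)
    tn = out["ttff_neg_ms"].to_numpy(float)
    if np.any(tp < 0) or np.any(tn < 0):
        raise DataError("TTFF cannot be negative")
    fl = np.full(len(out), np.nan)
    fl[np.isnan(tn) & ~np.isnan(tp)] = 1.0
    fl[np.isnan(tp) & ~np.isnan(tn)] = 0.0
    both = ~np.isnan(tp) & ~np.isnan(tn)
    fl[both & (tp < tn)] = 1.0
    fl[both & (tp > tn)] = 0.0
    out["first_look"] = fl
    return out


def bias_correlation(trial_table: pd.DataFrame, level: str = "trial"):
    """Pearson correlation between dwell-time and fixation-count bias.

    ``level`` selects trial-level pairs (default) or subject-level means.
    Returns (r, p) from a two-sided test.
    """
    cols = trial_table[["nbi_time", "nbi_count"]].dropna()
    if level == "subject":
        cols = (
            trial_table.dropna(subset=["nbi_time", "nbi_count"])
            .groupby("participant_id")[["nbi_time", "nbi_count"]]
            .mean()
        )
    elif level != "trial":
        raise ValueError("level must be 'trial' or 'subject'")
    if len(cols) < 3:
        raise UndefinedValueError("need at least 3 complete pairs for a correlation")
    x = cols["nbi_time"].to_numpy()
    y = cols["nbi_count"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedValueError("correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
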