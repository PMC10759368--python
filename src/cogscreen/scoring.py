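"""DCR composite score (0-5), color band, and screening thresholds.

The Digital Clock and Recall composite combines a digitally analyzed clock
drawing (summary score 0-100) mapped to 0-2 points (< 60 -> 0, 60-74 -> 1,
>= 75 -> 2) with a 3-word delayed recall contributing one point per word
(0-3). Totals band as Green (4-5, no indication of impairment), Yellow (2-3,
borderline) and Red (0-1, likely impaired). Screening rules: DCR total <= 3
screens positive for impairment; MMSE >= 28 screens negative (labels
unimpaired). Immediate-recall performance never contributes to the total.

Cutoffs are literal real-valued intervals: a summary of 74.5 earns 1 point
(>= 60 and < 75), with no integer rounding. An absent (NaN) summary marks an
unanalyzable clock; such records are excluded from scoring with an explicit
marker, never imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DcrScore",
    "clock_points",
    "recall_points",
    "dcr_total",
    "dcr_screen_positive",
    "mmse_screen_negative",
    "score_records",
]

_BANDS = {0: "Red", 1: "Red", 2: "Yellow", 3: "Yellow", 4: "Green", 5: "Green"}


@dataclass(frozen=True)
class DcrScore:
    clock_points: int
    recall_points: int
    total: int
    band: str


def clock_points(dct_summary: float) -> int:
    """Clock component: < 60 -> 0, [60, 75) -> 1, >= 75 -> 2."""
    if math.isnan(dct_summary) or not 0.0 <= dct_summary <= 100.0:
        raise ValueError(f"dct_summary must lie in [0, 100], got {dct_summary}")
    if dct_summary < 60.0:
        return 0
    if dct_summary < 75.0:
        return 1
    return 2


def recall_points(words_recalled: int) -> int:
    """Delayed-recall component: one point per word, 0-3 (identity map)."""
    if words_recalled not in (0, 1, 2, 3):
        raise ValueError(f"words_recalled must be an integer in 0..3, got {words_recalled}")
    return int(words_recalled)


def dcr_total(clock: int, recall: int) -> DcrScore:
    """Combine components into the 0-5 total and its color band."""
    if clock not in (0, 1, 2):
        raise ValueError(f"clock points must be 0..2, got {clock}")
    if recall not in (0, 1, 2, 3):
        raise ValueError(f"recall points must be 0..3, got {recall}")
    total = int(clock) + int(recall)
    return DcrScore(int(clock), int(recall), total, _BANDS[total])


def dcr_screen_positive(score: DcrScore | int, cutoff: int = 3) -> bool:
    """Screen positive (flagged impaired) when the DCR total is <= cutoff."""
    total = score.total if isinstance(score, DcrScore) else int(score)
    return total <= cutoff


def mmse_screen_negative(mmse: int, cutoff: int = 28) -> bool:
    """Screen negative (labeled unimpaired) when MMSE >= cutoff."""
    if not 0 <= mmse <= 30:
        raise ValueError(f"mmse must lie in 0..30, got {mmse}")
    return mmse >= cutoff


def score_records(
    records: pd.DataFrame, dcr_cutoff: int = 3, mmse_cutoff: int = 28
) -> pd.DataFrame:
    """Append DCR/MMSE scoring columns to a population.

    Adds ``clock_points, recall_points, dcr_total, dcr_band, dcr_analyzable,
    dcr_positive, mmse_negative``. Rows with an absent clock summary get
    ``dcr_analyzable = False`` and NA scoring columns.
    """
    out = records.copy()
    summary = records["dct_summary"].to_numpy(dtype=float)
    analyzable = ~np.isnan(summary)
    valid = summary[analyzable]
    if np.any((valid < 0) | (valid > 100)):
        raise ValueError("dct_summary values must lie in [0, 100]")
    cp = np.where(valid < 60.0, 0, np.where(valid < 75.0, 1, 2))
    rp = records["delayed_recall"].to_numpy(dtype=int)
    if np.any((rp < 0) | (rp > 3)):
        raise ValueError("delayed_recall values must lie in 0..3")

    clock_col = np.full(len(records), np.nan)
    clock_col[analyzable] = cp
    total_col = np.full(len(records), np.nan)
    total_col[analyzable] = cp + rp[analyzable]
    band_col = np.array(
        [(_BANDS[int(t)] if not math.isnan(t) else None) for t in total_col],
        dtype=object,
    )

    out["clock_points"] = pd.array(clock_col, dtype="Int64")
    out["recall_points"] = rp
    out["dcr_total"] = pd.array(total_col, dtype="Int64")
    out["dcr_band"] = band_col
    out["dcr_analyzable"] = analyzable
    out["dcr_positive"] = pd.array(
        np.where(np.isnan(total_col), None, total_col <= dcr_cutoff), dtype="boolean"
    )
    out["mmse_negative"] = records["mmse"].to_numpy(dtype=int) >= mmse_cutoff
    return out
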