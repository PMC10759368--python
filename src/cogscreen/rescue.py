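"""Threshold-based misclassification and rescue analysis.

Among participants with RAVLT-confirmed verbal memory impairment (age-normed
z at or below -1 SD), cross-tabulate the two screening rules:

* MMSE-missed: memory-impaired yet labeled unimpaired by MMSE >= 28; of
  those, DCR-rescued means a DCR total <= 3 flagged them anyway.
* DCR-missed: memory-impaired yet DCR total >= 4; of those, MMSE-rescued
  means MMSE < 28 flagged them anyway.

Records with an unanalyzable clock (absent ``dct_summary``) are excluded
from DCR-side denominators and counted separately — never imputed. Rates
are reported as raw percentages with explicit denominators, plus a one-
decimal half-up rounding for display; an empty denominator yields ``None``
(undefined), never zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohorts import ravlt_zscore
from .norms import Norms

__all__ = ["RescueThresholds", "RescueTable", "memory_impairment_mask",
           "build_rescue_table"]


@dataclass(frozen=True)
class RescueThresholds:
    ravlt_sd_cut: float = 1.0
    mmse_cutoff: int = 28
    dcr_cutoff: int = 3


def _round1(x: float | None) -> float | None:
    """Half-up rounding to one decimal (display convention)."""
    if x is None:
        return None
    return math.floor(x * 10.0 + 0.5) / 10.0


def _rate(num: int, den: int) -> float | None:
    return 100.0 * num / den if den else None


@dataclass(frozen=True)
class RescueTable:
    """Counts, explicit denominators and rates of the rescue cross-tab."""

    n_memory_impaired: int
    n_dcr_analyzable_impaired: int
    n_dcr_unanalyzable_impaired: int
    mmse_missed: int
    mmse_missed_dcr_analyzable: int
    dcr_rescued: int
    dcr_missed: int
    mmse_rescued: int

    @property
    def mmse_missed_rate(self) -> float | None:
        """Percent of memory-impaired missed by the MMSE rule."""
        return _rate(self.mmse_missed, self.n_memory_impaired)

    @property
    def dcr_rescue_rate(self) -> float | None:
        """Percent of (DCR-analyzable) MMSE-missed flagged by the DCR."""
        return _rate(self.dcr_rescued, self.mmse_missed_dcr_analyzable)

    @property
    def dcr_missed_rate(self) -> float | None:
        """Percent of DCR-analyzable memory-impaired missed by the DCR."""
        return _rate(self.dcr_missed, self.n_dcr_analyzable_impaired)

    @property
    def mmse_rescue_rate(self) -> float | None:
        """Percent of DCR-missed flagged by the MMSE."""
        return _rate(self.mmse_rescued, self.dcr_missed)

    def to_dict(self) -> dict:
        d = {
            "n_memory_impaired": self.n_memory_impaired,
            "n_dcr_analyzable_impaired": self.n_dcr_analyzable_impaired,
            "n_dcr_unanalyzable_impaired": self.n_dcr_unanalyzable_impaired,
            "mmse_missed": self.mmse_missed,
            "mmse_missed_dcr_analyzable": self.mmse_missed_dcr_analyzable,
            "dcr_rescued": self.dcr_rescued,
            "dcr_missed": self.dcr_missed,
            "mmse_rescued": self.mmse_rescued,
        }
        for name in ("mmse_missed_rate", "dcr_rescue_rate", "dcr_missed_rate",
                     "mmse_rescue_rate"):
            raw = getattr(self, name)
            d[name] = raw
            d[f"{name}_display"] = _round1(raw)
        return d


def memory_impairment_mask(
    records: pd.DataFrame, norms: Norms, sd_cut: float = 1.0
) -> np.ndarray:
    """True where the age-normed RAVLT z is at or below ``-sd_cut``."""
    z = ravlt_zscore(records["ravlt_long_delay"].to_numpy(),
                     records["age"].to_numpy(), norms.ravlt)
    return z <= -sd_cut


def build_rescue_table(
    records: pd.DataFrame,
    norms: Norms,
    thresholds: RescueThresholds = RescueThresholds(),
) -> RescueTable:
    """Cross-tabulate memory impairment against the two screening rules.

    ``records`` must carry ``mmse``, ``dct_summary``, ``delayed_recall`` (a
    ``dcr_total`` column is used if present, otherwise computed) plus the
    RAVLT/age columns needed for z-scoring.
    """
    impaired = memory_impairment_mask(records, norms, thresholds.ravlt_sd_cut)
    mmse = records["mmse"].to_numpy(dtype=int)
    if "dcr_total" in records.columns:
        total = records["dcr_total"].to_numpy(dtype=float)
    else:
        from .scoring import score_records

        total = score_records(records)["dcr_total"].to_numpy(dtype=float)
    analyzable = ~np.isnan(total)

    mmse_neg = mmse >= thresholds.mmse_cutoff
    dcr_pos = analyzable & (total <= thresholds.dcr_cutoff)
    dcr_neg = analyzable & (total > thresholds.dcr_cutoff)

    mmse_missed = impaired & mmse_neg
    dcr_missed = impaired & dcr_neg
    return RescueTable(
        n_memory_impaired=int(impaired.sum()),
        n_dcr_analyzable_impaired=int((impaired & analyzable).sum()),
        n_dcr_unanalyzable_impaired=int((impaired & ~analyzable).sum()),
        mmse_missed=int(mmse_missed.sum()),
        mmse_missed_dcr_analyzable=int((mmse_missed & analyzable).sum()),
        dcr_rescued=int((mmse_missed & dcr_pos).sum()),
        dcr_missed=int(dcr_missed.sum()),
        mmse_rescued=int((dcr_missed & ~mmse_neg).sum()),
    )
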