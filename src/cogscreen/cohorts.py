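"""Rules-based cohort classification from norm-referenced impairment flags.

A participant is flagged on three axes — verbal memory (RAVLT long-delay
recall at or below -1 SD of the age-adjusted mean), executive function
(TMT-B completion time at or above +1 SD), and functional dependence
(FAQ >= 6) — and participants with FAQ > 9 are excluded as likely beyond
the mild stage. The flags map deterministically onto five cohorts:

========================  =========================================
flags                     label
========================  =========================================
none                      healthy
memory only               aMCI (single-domain amnestic MCI)
memory + executive        mdMCI (multi-domain amnestic MCI)
executive only            naMCI (dysexecutive / non-amnestic MCI)
functional + cognitive    probable mild ADRD
functional only           excluded by default (configurable; a
                          dementia label requires a cognitive deficit)
========================  =========================================

Cohorts other than healthy collapse to a binary "impaired" label; excluded
participants are dropped from classification analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .norms import NormTable, Norms

__all__ = [
    "CohortLabel",
    "ImpairmentThresholds",
    "ImpairmentFlags",
    "ravlt_zscore",
    "tmtb_zscore",
    "flag_impairments",
    "classify_cohort",
    "binarize",
    "classify_records",
]


class CohortLabel(str, Enum):
    healthy = "healthy"
    aMCI = "aMCI"
    mdMCI = "mdMCI"
    naMCI = "naMCI"
    probable_mild_ADRD = "probable_mild_ADRD"
    excluded = "excluded"


@dataclass(frozen=True)
class ImpairmentThresholds:
    """Cut points of the decision tree.

    ``ravlt_sd_cut`` admits a stricter 1.5-SD sensitivity variant. FAQ cuts:
    >= ``faq_functional_cut`` flags functional impairment, > ``faq_exclusion_cut``
    (strict) excludes as likely moderate-to-severe.
    """

    ravlt_sd_cut: float = 1.0
    tmtb_sd_cut: float = 1.0
    faq_functional_cut: int = 6
    faq_exclusion_cut: int = 9

    def __post_init__(self):
        if not self.ravlt_sd_cut > 0 or not self.tmtb_sd_cut > 0:
            raise ValueError("SD cuts must be > 0")
        if not 0 <= self.faq_functional_cut <= self.faq_exclusion_cut <= 30:
            raise ValueError(
                "require 0 <= faq_functional_cut <= faq_exclusion_cut <= 30"
            )


@dataclass(frozen=True)
class ImpairmentFlags:
    memory_impaired: bool
    executive_impaired: bool
    functionally_impaired: bool
    excluded_severe: bool
    ravlt_z: float
    tmtb_z: float


def ravlt_zscore(ravlt_long_delay, age, norms: NormTable):
    """Age-referenced z of RAVLT long-delay recall; negative = worse."""
    mean, sd = norms.lookup_arrays(np.atleast_1d(np.asarray(age, dtype=float)))
    z = (np.atleast_1d(np.asarray(ravlt_long_delay, dtype=float)) - mean) / sd
    return z if np.ndim(ravlt_long_delay) else float(z[0])


def tmtb_zscore(tmtb_seconds, age, norms: NormTable):
    """Age-referenced z of TMT-B completion time; positive = worse (slower)."""
    mean, sd = norms.lookup_arrays(np.atleast_1d(np.asarray(age, dtype=float)))
    z = (np.atleast_1d(np.asarray(tmtb_seconds, dtype=float)) - mean) / sd
    return z if np.ndim(tmtb_seconds) else float(z[0])


def flag_impairments(
    record, norms: Norms, thresholds: ImpairmentThresholds = ImpairmentThresholds()
) -> ImpairmentFlags:
    """Compute the three impairment flags plus severe-functional exclusion.

    ``record`` is any mapping with keys ``ravlt_long_delay``, ``tmtb_seconds``,
    ``faq`` and ``age`` (e.g. a DataFrame row). All cognitive boundaries are
    inclusive; the FAQ exclusion boundary is strict.
    """
    rz = ravlt_zscore(record["ravlt_long_delay"], record["age"], norms.ravlt)
    tz = tmtb_zscore(record["tmtb_seconds"], record["age"], norms.tmtb)
    faq = int(record["faq"])
    return ImpairmentFlags(
        memory_impaired=bool(rz <= -thresholds.ravlt_sd_cut),
        executive_impaired=bool(tz >= thresholds.tmtb_sd_cut),
        functionally_impaired=bool(faq >= thresholds.faq_functional_cut),
        excluded_severe=bool(faq > thresholds.faq_exclusion_cut),
        ravlt_z=float(rz),
        tmtb_z=float(tz),
    )


def classify_cohort(
    flags: ImpairmentFlags,
    functional_only_label: CohortLabel = CohortLabel.excluded,
) -> CohortLabel:
    """Map impairment flags to a cohort label.

    Severe-functional exclusion is evaluated first. Functional impairment
    with at least one cognitive deficit yields probable mild ADRD; functional
    impairment with no cognitive deficit is assigned ``functional_only_label``
    (excluded by default — a dementia label requires a cognitive deficit).
    """
    if flags.excluded_severe:
        return CohortLabel.excluded
    cognitive = flags.memory_impaired or flags.executive_impaired
    if flags.functionally_impaired:
        return CohortLabel.probable_mild_ADRD if cognitive else functional_only_label
    if flags.memory_impaired and flags.executive_impaired:
        return CohortLabel.mdMCI
    if flags.memory_impaired:
        return CohortLabel.aMCI
    if flags.executive_impaired:
        return CohortLabel.naMCI
    return CohortLabel.healthy


def binarize(label: CohortLabel) -> str:
    """Collapse cohorts to ``impaired`` / ``unimpaired`` / ``excluded``."""
    if label is CohortLabel.healthy:
        return "unimpaired"
    if label is CohortLabel.excluded:
        return "excluded"
    return "impaired"


def classify_records(
    records: pd.DataFrame,
    norms: Norms,
    thresholds: ImpairmentThresholds = ImpairmentThresholds(),
    functional_only_label: CohortLabel = CohortLabel.excluded,
) -> pd.DataFrame:
    """Vectorized classification of a population.

    Returns a copy of ``records`` with appended columns ``ravlt_z, tmtb_z,
    memory_impaired, executive_impaired, functionally_impaired,
    excluded_severe, cohort, impairment`` (the binary label).
    """
    out = records.copy()
    rz = ravlt_zscore(records["ravlt_long_delay"].to_numpy(),
                      records["age"].to_numpy(), norms.ravlt)
    tz = tmtb_zscore(records["tmtb_seconds"].to_numpy(),
                     records["age"].to_numpy(), norms.tmtb)
    faq = records["faq"].to_numpy()
    mem = rz <= -thresholds.ravlt_sd_cut
    exe = tz >= thresholds.tmtb_sd_cut
    fun = faq >= thresholds.faq_functional_cut
    sev = faq > thresholds.faq_exclusion_cut

    labels = np.empty(len(records), dtype=object)
    cognitive = mem | exe
    labels[:] = CohortLabel.healthy.value
    labels[mem & ~exe & ~fun] = CohortLabel.aMCI.value
    labels[mem & exe & ~fun] = CohortLabel.mdMCI.value
    labels[~mem & exe & ~fun] = CohortLabel.naMCI.value
    labels[fun & cognitive] = CohortLabel.probable_mild_ADRD.value
    labels[fun & ~cognitive] = functional_only_label.value
    labels[sev] = CohortLabel.excluded.value

    out["ravlt_z"] = rz
    out["tmtb_z"] = tz
    out["memory_impaired"] = mem
    out["executive_impaired"] = exe
    out["functionally_impaired"] = fun
    out["excluded_severe"] = sev
    out["cohort"] = labels
    out["impairment"] = [binarize(CohortLabel(v)) for v in labels]
    return out
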