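"""Age-binned normative tables for norm-referenced z-scoring.

Neuropsychological raw scores (RAVLT long-delay recall, TMT-B completion time)
are interpreted against age-adjusted population means and SDs tabulated in
contiguous age bins. Bins follow the half-open convention ``[low, high)``:
a boundary age belongs to the bin that starts at it.

The tables shipped with :func:`default_norms` are synthetic fixtures with
plausible magnitudes; they are not published normative data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "NormTable",
    "Norms",
    "NormRangeError",
    "generate_norm_table",
    "default_norms",
    "read_norms_json",
    "write_norms_json",
]


class NormRangeError(ValueError):
    """Raised when a queried age falls outside every bin of a norm table."""


@dataclass(frozen=True)
class NormTable:
    """Age-binned (mean, sd) lookup for one test.

    Parameters
    ----------
    bins
        Contiguous, non-overlapping half-open intervals ``[low, high)``,
        sorted ascending.
    means, sds
        Per-bin population mean and SD; ``sds`` must be positive.
    """

    bins: tuple[tuple[float, float], ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]

    @property
    def age_min(self) -> float:
        return self.bins[0][0]

    @property
    def age_max(self) -> float:
        return self.bins[-1][1]

    def lookup(self, age: float) -> tuple[float, float]:
        """Return ``(mean, sd)`` of the bin whose ``[low, high)`` contains age."""
        for (low, high), mean, sd in zip(self.bins, self.means, self.sds):
            if low <= age < high:
                return mean, sd
        raise NormRangeError(
            f"age {age} outside norm coverage [{self.age_min}, {self.age_max})"
        )

    def lookup_arrays(self, ages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized :meth:`lookup`; raises on any out-of-range age."""
        ages = np.asarray(ages, dtype=float)
        edges = np.array([b[0] for b in self.bins] + [self.age_max])
        if np.any(ages < edges[0]) or np.any(ages >= edges[-1]):
            bad = ages[(ages < edges[0]) | (ages >= edges[-1])][0]
            raise NormRangeError(
                f"age {bad} outside norm coverage [{edges[0]}, {edges[-1]})"
            )
        idx = np.searchsorted(edges, ages, side="right") - 1
        return np.asarray(self.means)[idx], np.asarray(self.sds)[idx]


def generate_norm_table(
    age_bins: Sequence[tuple[float, float]],
    means: Sequence[float],
    sds: Sequence[float],
) -> NormTable:
    """Build a validated :class:`NormTable`.

    Bins must be sorted, contiguous (each bin starts where the previous one
    ends) and non-degenerate; every SD must be positive.
    """
    if not (len(age_bins) == len(means) == len(sds)):
        raise ValueError("age_bins, means and sds must have equal length")
    if len(age_bins) == 0:
        raise ValueError("at least one age bin is required")
    for i, (low, high) in enumerate(age_bins):
        if not low < high:
            raise ValueError(f"bin {i} is degenerate: [{low}, {high})")
        if i > 0 and age_bins[i - 1][1] != low:
            raise ValueError(
                f"bins not contiguous at index {i}: previous ends at "
                f"{age_bins[i - 1][1]}, next starts at {low}"
            )
    for i, sd in enumerate(sds):
        if not sd > 0:
            raise ValueError(f"sd for bin {i} must be > 0, got {sd}")
    return NormTable(
        bins=tuple((float(a), float(b)) for a, b in age_bins),
        means=tuple(float(m) for m in means),
        sds=tuple(float(s) for s in sds),
    )


@dataclass(frozen=True)
class Norms:
    """Normative tables for the two norm-referenced tests."""

    ravlt: NormTable
    tmtb: NormTable


_DEFAULT_BINS = [(55.0, 60.0), (60.0, 65.0), (65.0, 70.0), (70.0, 75.0),
                 (75.0, 80.0), (80.0, 85.0), (85.0, 90.0)]


def default_norms() -> Norms:
    """Synthetic normative fixture covering ages [55, 90).

    RAVLT long-delay means decline mildly with age around ~9 words (SD 3);
    TMT-B means rise from ~95 s to ~142 s (SD 40). Magnitudes are realistic
    for ages 55-90 but the values are synthetic, not published norms.
    """
    ravlt = generate_norm_table(
        _DEFAULT_BINS,
        means=[9.8, 9.4, 9.0, 8.6, 8.2, 7.8, 7.4],
        sds=[3.0] * 7,
    )
    tmtb = generate_norm_table(
        _DEFAULT_BINS,
        means=[95.0, 102.0, 110.0, 118.0, 126.0, 134.0, 142.0],
        sds=[40.0] * 7,
    )
    return Norms(ravlt=ravlt, tmtb=tmtb)


def _table_to_dict(t: NormTable) -> dict:
    return {"bins": [list(b) for b in t.bins], "means": list(t.means), "sds": list(t.sds)}


def write_norms_json(norms: Norms, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(
            {"ravlt": _table_to_dict(norms.ravlt), "tmtb": _table_to_dict(norms.tmtb)},
            fh,
            indent=2,
        )


def read_norms_json(path) -> Norms:
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    tables = {
        name: generate_norm_table(raw[name]["bins"], raw[name]["means"], raw[name]["sds"])
        for name in ("ravlt", "tmtb")
    }
    return Norms(ravlt=tables["ravlt"], tmtb=tables["tmtb"])
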