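"""Growth and viability arithmetic.

Three small, exact computations accompany the electrophysiology:

* per-day cell-count summaries over replicate electrodes, normalized to
  the final day (the on-chip growth table);
* MTT percent viability relative to an untreated negative control, with
  replicate-based standard errors;
* the final blocker concentration after adding a small stock volume to
  the culture medium.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError


# ---------------------------------------------------------------------------
# growth table
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class CellCountTable:
    """Cell counts, rows = replicate electrodes, columns = days."""

    counts: np.ndarray
    day_labels: tuple

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "day_labels", tuple(self.day_labels))
        if counts.ndim != 2:
            raise InputError("counts must be a 2-D electrodes × days matrix")
        if counts.shape[0] < 2:
            raise InputError("need at least 2 electrodes for an S.E.M")
        if counts.shape[1] != len(self.day_labels):
            raise InputError("day_labels must match the number of columns")
        if (counts < 0).any():
            raise InputError("counts must be non-negative")
        days = list(self.day_labels)
        if any(b <= a for a, b in zip(days, days[1:])):
            raise InputError("day labels must be strictly increasing")

    @classmethod
    def from_csv(cls, path) -> "CellCountTable":
        df = pd.read_csv(path, comment="#")
        return cls(df.to_numpy(dtype=float),
                   tuple(float(c) for c in df.columns))


@dataclass(frozen=True)
class GrowthSummary:
    """Per-day mean, S.E.M, and final-day-normalized versions.

    Normalized averages are reported to 4 decimals; the final day is
    exactly 1.0 by construction.  S.E.M uses the sample (n−1) standard
    deviation over electrodes.
    """

    day_labels: tuple
    average: np.ndarray
    sem: np.ndarray
    normalized_average: np.ndarray
    normalized_sem: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [self.average, self.sem, self.normalized_average,
             self.normalized_sem],
            index=["average", "sem", "normalized_average", "normalized_sem"],
            columns=list(self.day_labels),
        )


def growth_summary(table: CellCountTable) -> GrowthSummary:
    """Summarise an electrode-count table day by day.

    average = mean over electrodes; S.E.M = sample sd / √n_electrodes;
    the normalized rows divide by the final-day average.
    """
    counts = table.counts
    n = counts.shape[0]
    average = counts.mean(axis=0)
    sem = counts.std(axis=0, ddof=1) / np.sqrt(n)
    final = average[-1]
    if not final > 0:
        raise InputError("final-day average must be positive to normalize")
    return GrowthSummary(
        day_labels=table.day_labels,
        average=average,
        sem=sem,
        normalized_average=np.round(average / final, 4),
        normalized_sem=sem / final,
    )


def normalized_averages(averages) -> np.ndarray:
    """Final-day-normalized per-day averages, to 4 decimals."""
    averages = np.asarray(averages, dtype=float)
    if averages.size < 2:
        raise InputError("need at least two days")
    if not averages[-1] > 0:
        raise InputError("final-day average must be positive")
    return np.round(averages / averages[-1], 4)


# ---------------------------------------------------------------------------
# MTT viability
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class MTTPlate:
    """Absorbance readings per condition; needs ≥3 replicates each.

    ``negative_control`` names the untreated (100%-viability) condition;
    an optional ``positive_control`` names the deliberately cytotoxic one.
    """

    absorbance: dict
    negative_control: str = "negative_control"
    positive_control: str | None = None

    def __post_init__(self):
        readings = {k: np.asarray(v, dtype=float)
                    for k, v in self.absorbance.items()}
        object.__setattr__(self, "absorbance", readings)
        for cond, vals in readings.items():
            if vals.size < 3:
                raise InputError(
                    f"condition {cond!r} has fewer than 3 replicates")
        if self.negative_control not in readings:
            raise InputError("negative control condition missing")


def percent_viability(plate: MTTPlate,
                      cytotoxic_below_pct: float = 90.0) -> pd.DataFrame:
    """Mean percent viability and S.E.M per condition.

    viability% = 100 × condition mean / negative-control mean, the
    control mean treated as fixed; the S.E.M propagates the condition's
    replicate spread only.  Conditions below ``cytotoxic_below_pct`` are
    flagged cytotoxic.  Scale-invariant in the absorbance units.
    """
    control = plate.absorbance[plate.negative_control]
    control_mean = control.mean()
    if not control_mean > 0:
        raise InputError("negative-control mean must be positive")
    rows = []
    for cond, vals in plate.absorbance.items():
        pct = 100.0 * vals.mean() / control_mean
        sem = 100.0 * vals.std(ddof=1) / np.sqrt(vals.size) / control_mean
        rows.append({"condition": cond, "viability_pct": pct,
                     "sem_pct": sem,
                     "cytotoxic": bool(pct < cytotoxic_below_pct)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dilution
# ---------------------------------------------------------------------------
def dilution_concentration(added_volume_ul: float,
                           stock_concentration_mm: float,
                           medium_volume_ul: float) -> float:
    """Final concentration (µM) after adding stock to the medium.

    c = stock × V_added / (V_added + V_medium); homogeneous of degree 1
    in the stock concentration and → 0 as the added volume → 0.
    """
    if not added_volume_ul > 0 or not medium_volume_ul > 0:
        raise ParameterError("volumes must be positive")
    if stock_concentration_mm < 0:
        raise ParameterError("stock concentration must be >= 0")
    fraction = added_volume_ul / (added_volume_ul + medium_volume_ul)
    return stock_concentration_mm * 1000.0 * fraction
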