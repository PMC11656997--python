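"""Pain-interference x depression-severity medication crosstab.

Summed instrument scores (Brief Pain Inventory for pain interference, PHQ-9
for depression severity) are rounded half-up and binned into the instruments'
named severity categories; within each BPI x PHQ-9 cell the cohort splits
into four medication groups derived from ATC counts: opioid-only (N02A > 0,
N06A = 0), antidepressant-only, both, or neither.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .was import ClinicalMatrix

#: stratum label for a total score of 0 (below every named bin)
NONE_LABEL = "none"

MED_GROUPS = ("opioid-only", "antidepressant-only", "both", "neither")


@dataclass(frozen=True)
class SeverityBins:
    """Contiguous, non-overlapping integer bins for one instrument."""

    instrument: str
    edges: tuple  # ((lo, hi, label), ...) inclusive integer bounds

    def __post_init__(self):
        prev_hi = 0
        for lo, hi, _ in self.edges:
            if lo != prev_hi + 1 or hi < lo:
                raise ValueError(f"{self.instrument}: bins must be contiguous integers")
            prev_hi = hi

    @property
    def labels(self) -> list[str]:
        return [lab for _, _, lab in self.edges]

    @property
    def max_total(self) -> int:
        return self.edges[-1][1]


BPI_BINS = SeverityBins("BPI", ((1, 4, "mild"), (5, 6, "moderate"), (7, 10, "severe")))
PHQ9_BINS = SeverityBins(
    "PHQ9",
    (
        (1, 4, "minimal"),
        (5, 9, "mild"),
        (10, 14, "moderate"),
        (15, 19, "moderately severe"),
        (20, 27, "severe"),
    ),
)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def bin_score(total: float, bins: SeverityBins) -> str:
    """Label of the bin containing the rounded total.

    Zero falls below every named bin and maps to the excluded "none"
    stratum; totals outside [0, max] are an error.
    """
    t = _round_half_up(float(total))
    if t == 0:
        return NONE_LABEL
    if t < 0 or t > bins.max_total:
        raise ValueError(f"{bins.instrument} total {total} outside [0, {bins.max_total}]")
    for lo, hi, label in bins.edges:
        if lo <= t <= hi:
            return label
    raise AssertionError("bins are total over the valid range")  # pragma: no cover


def bin_scores(totals: pd.Series, bins: SeverityBins) -> pd.Series:
    return totals.map(lambda t: bin_score(t, bins))


def medication_groups(atc_matrix: ClinicalMatrix) -> pd.Series:
    """Four-way grouping from the N02A (opioid) and N06A (antidepressant)
    level-3 counts."""
    data = atc_matrix.data
    opioid = data["N02A"].to_numpy() > 0 if "N02A" in data else np.zeros(len(data), bool)
    antidep = data["N06A"].to_numpy() > 0 if "N06A" in data else np.zeros(len(data), bool)
    group = np.where(
        opioid & antidep,
        "both",
        np.where(opioid, "opioid-only", np.where(antidep, "antidepressant-only", "neither")),
    )
    return pd.Series(group, index=data.index, name="med_group")


def med_crosstab(
    bpi_labels: pd.Series,
    phq_labels: pd.Series,
    atc_matrix: ClinicalMatrix,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per BPI x PHQ-9 cell: participant counts and within-cell proportions
    of the four medication groups.

    Participants in a "none" stratum on either instrument are excluded from
    the grid. Returns (proportions, counts); empty cells carry NaN
    proportions and are flagged by a zero count.
    """
    shared = bpi_labels.index.intersection(phq_labels.index).intersection(
        atc_matrix.data.index
    )
    bpi = bpi_labels.loc[shared]
    phq = phq_labels.loc[shared]
    med = medication_groups(atc_matrix).loc[shared]
    in_grid = (bpi != NONE_LABEL) & (phq != NONE_LABEL)
    df = pd.DataFrame({"bpi": bpi, "phq": phq, "med": med})[in_grid]

    index = pd.MultiIndex.from_product(
        [BPI_BINS.labels, PHQ9_BINS.labels], names=["bpi", "phq"]
    )
    counts = pd.DataFrame(0, index=index, columns=list(MED_GROUPS))
    grouped = df.groupby(["bpi", "phq", "med"], observed=True).size()
    for (b, p, m), c in grouped.items():
        counts.loc[(b, p), m] = c
    totals = counts.sum(axis=1)
    props = counts.div(totals.where(totals > 0), axis=0)
    counts["n"] = totals
    return props, counts
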