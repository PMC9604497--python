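"""Polyenviromic risk score (PERS) and variably-methylated-site detection.

PERS is the sum over *present* early-environment exposures of the natural log
of the exposure's literature odds ratio for the disease.  The three exposures
used here are season of birth (SOB, winter = December-February), obstetric
complications (OC) and adverse childhood experiences (ACE), with OR weights
1.04, 1.84 and 2.87; the weights are literature constants, never estimated
from data.

A variably methylated site (VMS) is a cytosine whose cohort-averaged
methylation lies within [0.20, 0.80], bounds inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PersWeights", "compute_pers", "pers_scores", "VmsReport", "detect_vms",
           "EXPOSURES", "WINTER_MONTHS"]

EXPOSURES = ("SOB", "OC", "ACE")

#: Winter birth months defining the SOB exposure.
WINTER_MONTHS = (12, 1, 2)


@dataclass(frozen=True)
class PersWeights:
    """Odds-ratio weights for the three exposures; weights are ln(OR)."""

    or_sob: float = 1.04
    or_oc: float = 1.84
    or_ace: float = 2.87

    def __post_init__(self):
        if min(self.or_sob, self.or_oc, self.or_ace) <= 0:
            raise ValueError("odds ratios must be positive")

    @property
    def weights(self) -> dict[str, float]:
        return {
            "SOB": math.log(self.or_sob),
            "OC": math.log(self.or_oc),
            "ACE": math.log(self.or_ace),
        }


def compute_pers(exposures, weights: PersWeights | None = None) -> float:
    """Sum of ln(OR) over present exposures.

    ``exposures`` maps exposure name -> presence flag (or is a sequence of
    flags in SOB/OC/ACE order).
    """
    weights = weights or PersWeights()
    w = weights.weights
    if not hasattr(exposures, "get"):
        exposures = dict(zip(EXPOSURES, exposures))
    return float(sum(w[k] for k in EXPOSURES if exposures.get(k)))


def pers_scores(subjects: pd.DataFrame, weights: PersWeights | None = None) -> pd.Series:
    """Vectorised PERS over a subject table with boolean SOB/OC/ACE columns."""
    weights = weights or PersWeights()
    w = weights.weights
    total = np.zeros(len(subjects))
    for k in EXPOSURES:
        total = total + subjects[k].astype(float).to_numpy() * w[k]
    return pd.Series(total, index=subjects.index, name="pers")


@dataclass
class VmsReport:
    low: float
    high: float
    table: pd.DataFrame  # columns: site, mean, vms_flag (+ per-group means)

    @property
    def vms_sites(self) -> list[str]:
        return list(self.table.loc[self.table["vms_flag"], "site"])


def detect_vms(
    subject_methylation: pd.DataFrame,
    low: float = 0.20,
    high: float = 0.80,
    group: pd.Series | None = None,
) -> VmsReport:
    """Flag sites whose mean methylation over all subjects pooled lies in
    [low, high] (inclusive).

    ``subject_methylation``: rows subjects, columns sites, values in [0, 1]
    (NaN allowed for subjects without data at a site; sites with no data at
    all are excluded).  ``group`` optionally adds per-group means for
    inspection; the VMS decision always pools groups.
    """
    means = subject_methylation.mean(axis=0, skipna=True)
    means = means.dropna()
    table = pd.DataFrame(
        {
            "site": means.index,
            "mean": means.to_numpy(),
            "vms_flag": (means.to_numpy() >= low) & (means.to_numpy() <= high),
        }
    ).reset_index(drop=True)
    if group is not None:
        for g, sub in subject_methylation.groupby(group):
            table[f"mean_{g}"] = table["site"].map(sub.mean(axis=0, skipna=True))
    return VmsReport(low=low, high=high, table=table)
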