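"""Normative cervical alignment statistics from a large clinical cohort.

Per-posture distribution summaries of the C2-C7 angle, C2 slope and C7
slope, established from expert-consensus measurements on 4546 lateral
radiographs of 1674 patients (flexion n=1458, neutral n=1645, extension
n=1443).  These values serve two roles in this package:

* defaults for the synthetic phantom generator, so generated cohorts
  match clinically observed posture-conditional alignment distributions;
* reference bounds (2.5th / 97.5th percentiles) for flagging measured
  values that fall outside the normally observed range.

All values are degrees, clockwise positive, negative C2-C7 angle =
lordosis.  ``POSTURE_CONFUSION`` holds the posture confusion counts
achieved by the clinically trained measurement system on the same
cohort, used as a worked example for the confusion-metrics routines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

__all__ = [
    "QuantityStats",
    "PostureStats",
    "POSTURES",
    "COHORT_STATS",
    "POSTURE_CONFUSION",
]

#: Fixed posture label order used throughout the package (and as the
#: row/column order of confusion matrices).
POSTURES = ("flexion", "neutral", "extension")


@dataclass(frozen=True)
class QuantityStats:
    """Distribution summary of one angular quantity (degrees)."""

    mean: float
    sd: float
    max: float
    p97_5: float
    p2_5: float
    min: float


@dataclass(frozen=True)
class PostureStats:
    """Cohort statistics of the three angular quantities at one posture."""

    n_xrays: int
    c2c7_angle: QuantityStats
    c2_slope: QuantityStats
    c7_slope: QuantityStats


COHORT_STATS: Dict[str, PostureStats] = {
    "flexion": PostureStats(
        n_xrays=1458,
        c2c7_angle=QuantityStats(14.3, 15.6, 110.0, 45.5, -15.0, -36.0),
        c2_slope=QuantityStats(-44.2, 14.8, 11.0, -16.0, -75.0, -96.0),
        c7_slope=QuantityStats(-29.9, 11.5, 32.7, -8.0, -52.0, -74.7),
    ),
    "neutral": PostureStats(
        n_xrays=1645,
        c2c7_angle=QuantityStats(-9.4, 15.8, 110.0, 22.0, -37.0, -61.0),
        c2_slope=QuantityStats(-17.2, 12.8, 34.0, 4.0, -47.9, -90.0),
        c7_slope=QuantityStats(-26.6, 10.6, 37.0, -7.2, -48.0, -67.0),
    ),
    "extension": PostureStats(
        n_xrays=1443,
        c2c7_angle=QuantityStats(-25.1, 18.6, 99.6, 11.0, -58.9, -73.0),
        c2_slope=QuantityStats(0.33, 16.3, 53.0, 30.9, -32.9, -92.0),
        c7_slope=QuantityStats(-24.8, 10.7, 35.0, -3.1, -46.0, -61.9),
    ),
}

#: Posture confusion counts (rows = true posture, columns = predicted,
#: order flexion/neutral/extension) of the clinically trained system over
#: the full 4546-radiograph cohort.
POSTURE_CONFUSION: np.ndarray = np.array(
    [
        [1437, 5, 16],
        [15, 1620, 10],
        [15, 14, 1414],
    ],
    dtype=np.int64,
)


def posture_stats(posture: str) -> PostureStats:
    """Cohort statistics for one posture label (raises on unknown labels)."""
    try:
        return COHORT_STATS[posture]
    except KeyError:
        raise ValueError(
            f"unknown posture {posture!r}; expected one of {POSTURES}"
        ) from None


def quantity_stats(posture: str, quantity: str) -> QuantityStats:
    """Cohort statistics for one (posture, quantity) pair."""
    stats = posture_stats(posture)
    if quantity not in ("c2c7_angle", "c2_slope", "c7_slope"):
        raise ValueError(f"unknown quantity {quantity!r}")
    return getattr(stats, quantity)


def cohort_slope_means(posture: str) -> Tuple[float, float]:
    """(C2 slope mean, C7 slope mean) for one posture."""
    stats = posture_stats(posture)
    return stats.c2_slope.mean, stats.c7_slope.mean
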