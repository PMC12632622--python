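"""Cytometry competition fitness and plate-based screen scores.

A strain of interest (unlabelled, "dark") is competed 1:1 against a
GFP-labelled tester. Events are singlet-gated on the forward-scatter
area/height ratio, a fluorescence threshold is calibrated on pure GFP and
pure dark control cultures, and the strain's frequency at each timepoint
is the fraction of events below the threshold. Relative fitness is the
difference of the areas under the dark-fraction-versus-time curves of a
clone and its ancestor (arbitrary units). Flocculation and ploidy scores
for pre-screen strain triage round out the module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "CompetitionSeries",
    "DarkFraction",
    "FlocculationScore",
    "ThresholdCalibration",
    "auc_fitness",
    "calibrate_threshold",
    "dark_fraction",
    "flocculation_score",
    "gate_singlets",
    "ploidy_score",
]

SINGLET_RATIO = (0.9, 1.03)
MIN_EVENTS = 10_000


def gate_singlets(
    events: pd.DataFrame,
    lo: float = SINGLET_RATIO[0],
    hi: float = SINGLET_RATIO[1],
    with_report: bool = False,
):
    """Keep events whose fsc_a/fsc_h ratio lies in [lo, hi] (inclusive).

    Events with non-positive height (no ratio) are removed and counted.
    Idempotent: gating a gated table changes nothing.
    """
    ok_height = events["fsc_h"] > 0
    ratio = np.where(ok_height, events["fsc_a"] / events["fsc_h"].where(ok_height, 1.0), np.nan)
    keep = ok_height & (ratio >= lo) & (ratio <= hi)
    gated = events[keep].reset_index(drop=True)
    if with_report:
        return gated, {
            "input": len(events),
            "kept": len(gated),
            "removed_ratio": int((ok_height & ~keep).sum()),
            "removed_zero_height": int((~ok_height).sum()),
        }
    return gated


@dataclass
class ThresholdCalibration:
    threshold: float
    gfp_misclassified: float  # fraction of GFP control below threshold
    dark_misclassified: float  # fraction of dark control above threshold


def calibrate_threshold(
    gfp_control: pd.DataFrame | np.ndarray,
    dark_control: pd.DataFrame | np.ndarray,
    channel: str = "fl",
    max_misclassification: float = 0.4,
) -> ThresholdCalibration:
    """Fluorescence cut between the dark and GFP control populations.

    Scans candidate cuts (midpoints between adjacent observed values) and
    picks the one minimising the controls' total misclassification; with
    perfect separation this is the midpoint of the separating gap.
    Refuses controls that appear swapped (dark brighter than GFP) or that
    overlap beyond ``max_misclassification``.
    """
    gfp = np.sort(np.asarray(gfp_control[channel] if hasattr(gfp_control, "columns")
                             else gfp_control, float))
    dark = np.sort(np.asarray(dark_control[channel] if hasattr(dark_control, "columns")
                              else dark_control, float))
    if len(gfp) == 0 or len(dark) == 0:
        raise ValueError("both control tables must be non-empty after gating")
    values = np.unique(np.concatenate([gfp, dark]))
    cuts = (values[:-1] + values[1:]) / 2.0
    # misclassified = GFP events below cut + dark events above cut
    gfp_below = np.searchsorted(gfp, cuts, side="right")
    dark_above = len(dark) - np.searchsorted(dark, cuts, side="right")
    total = gfp_below / len(gfp) + dark_above / len(dark)
    best = int(np.argmin(total))
    rate = total[best] / 2.0
    if rate > max_misclassification:
        # would flipping the labels fix it? then they were swapped
        flipped = (np.searchsorted(dark, cuts, side="right") / len(dark)
                   + (len(gfp) - np.searchsorted(gfp, cuts, side="right")) / len(gfp))
        if flipped.min() / 2.0 <= max_misclassification:
            raise ValueError(
                "controls appear swapped: the dark control is brighter than the "
                "GFP control; check the labels")
        raise ValueError(
            f"controls are inseparable (misclassification {rate:.0%}); re-acquire "
            "the control cultures")
    return ThresholdCalibration(
        threshold=float(cuts[best]),
        gfp_misclassified=float(gfp_below[best] / len(gfp)),
        dark_misclassified=float(dark_above[best] / len(dark)),
    )


class DarkFraction(NamedTuple):
    fraction: float
    n_events: int
    low_events: bool  # fewer than the required minimum after gating


def dark_fraction(
    events: pd.DataFrame | np.ndarray,
    threshold: float,
    channel: str = "fl",
    min_events: int = MIN_EVENTS,
) -> DarkFraction:
    """Fraction of (gated) events below the fluorescence threshold —
    the unlabelled strain of interest. Values from fewer than
    ``min_events`` events carry a low-event flag."""
    fl = np.asarray(events[channel] if hasattr(events, "columns") else events, float)
    n = len(fl)
    if n == 0:
        raise ValueError("no events")
    return DarkFraction(float((fl < threshold).mean()), n, n < min_events)


@dataclass
class CompetitionSeries:
    """Dark-fraction trajectory of one strain in a tester competition."""

    days: np.ndarray
    fraction: np.ndarray
    strain_id: str = ""
    media: str = ""

    def __post_init__(self):
        self.days = np.asarray(self.days, float)
        self.fraction = np.asarray(self.fraction, float)
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if np.any((self.fraction < 0) | (self.fraction > 1)):
            raise ValueError("fractions must be in [0, 1]")


def auc_fitness(series_clone: CompetitionSeries, series_ancestor: CompetitionSeries) -> float:
    """Relative fitness (arbitrary units) = AUC(clone) - AUC(ancestor).

    Areas under the dark-fraction-vs-time curves by the trapezoid rule
    over the overlapping time window; both series are linearly
    interpolated onto the union grid within that window. Antisymmetric
    and zero for identical series by construction.
    """
    lo = max(series_clone.days.min(), series_ancestor.days.min())
    hi = min(series_clone.days.max(), series_ancestor.days.max())
    if hi <= lo:
        raise ValueError("series time windows do not overlap")
    grid = np.union1d(series_clone.days, series_ancestor.days)
    grid = grid[(grid >= lo) & (grid <= hi)]
    clone = np.interp(grid, series_clone.days, series_clone.fraction)
    anc = np.interp(grid, series_ancestor.days, series_ancestor.fraction)
    return float(np.trapezoid(clone, grid) - np.trapezoid(anc, grid))


class FlocculationScore(NamedTuple):
    score: float
    undefined: bool


def flocculation_score(
    od_top: float,
    od_bottom: float,
    od_blank: float = 0.0,
    factor_on: str = "denominator",
) -> FlocculationScore:
    """Settling score from top/bottom optical densities after blank
    subtraction.

    A flocculant settles, emptying the top fraction: score -> 1. The 0.8
    factor compensates the EDTA dilution of the bottom fraction; by
    default it scales the denominator (score = 1 - top / (0.8 * bottom)),
    so a fully suspended culture whose top keeps 80% of bottom density
    scores 0. ``factor_on="ratio"`` applies the alternative reading
    (score = 1 - 0.8 * top / bottom). Blank subtraction first makes the
    score invariant to a constant offset on all three ODs.
    """
    top = od_top - od_blank
    bottom = od_bottom - od_blank
    if bottom <= 0:
        return FlocculationScore(np.nan, True)
    if top < 0:
        top = 0.0
    if factor_on == "denominator":
        return FlocculationScore(1.0 - top / (0.8 * bottom), False)
    if factor_on == "ratio":
        return FlocculationScore(1.0 - 0.8 * top / bottom, False)
    raise ValueError("factor_on must be 'denominator' or 'ratio'")


def ploidy_score(
    sample_median_fluor: float,
    haploid_ctrl: float,
    diploid_ctrl: float,
):
    """DNA-content ploidy class (1, 2 or "higher") on the control scale.

    The haploid and diploid control medians define a linear DNA-content
    axis (haploid -> 1, diploid -> 2); the sample is classified by the
    midpoints between successive integer ploidies on that axis.
    """
    if not diploid_ctrl > haploid_ctrl > 0:
        raise ValueError("controls inverted: need diploid_ctrl > haploid_ctrl > 0")
    n = 1.0 + (sample_median_fluor - haploid_ctrl) / (diploid_ctrl - haploid_ctrl)
    if n < 1.5:
        return 1
    if n < 2.5:
        return 2
    return "higher"
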