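"""Occupancy and positioning statistics over dyad tracks.

Two per-position statistics summarise a dyad count track:

* **Occupancy** — each dyad is extrapolated ``half_footprint`` (73) bp
  in both directions to the canonical 147 bp nucleosome footprint, and
  occupancy at a position is the number of footprints covering it:
  ``occ[p] = Σ_{d : |p−d| ≤ 73} counts[d]``.

* **Positioning score** — dyads within the inner window (±10 bp, 21
  positions) divided by dyads within the outer window (±150 bp, 301
  positions), both inclusive.  A score of 1 means every nearby
  nucleosome sits exactly at that locus; a locus with an empty outer
  window scores 0 by convention.

Windows and footprints are truncated at the reference ends — both
numerator and denominator only ever count real in-range dyads.

Region summaries (total occupancy over an interval, ratio to a control
construct) and the flank-aligned cross-construct comparison live here
too, as does the array sequencing-coverage estimate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constructs import (
    ConstructSpec,
    Interval,
    interval_center_positions,
    to_report_coordinates,
)
from .fragments import DyadTrack

__all__ = [
    "OccupancyProfile",
    "PositioningProfile",
    "RegionSummary",
    "ArrayCoverageEstimate",
    "NoSignalError",
    "occupancy_from_dyads",
    "normalize_occupancy",
    "positioning_scores",
    "region_total_occupancy",
    "ratio_to_control",
    "align_flanking_profiles",
    "positioning_at_element",
    "estimate_array_coverage",
    "profile_table",
]

logger = logging.getLogger(__name__)


class NoSignalError(ValueError):
    """Raised when a profile with no signal cannot be normalized."""


def _window_sums(counts: np.ndarray, half: int) -> np.ndarray:
    """Inclusive ±half window sums at every position, truncated at ends.

    Integer cumulative sums keep the arithmetic exact (no float
    accumulation), so results equal a literal per-position recount.
    """
    counts = np.asarray(counts, dtype=np.int64)
    cs = np.concatenate(([0], np.cumsum(counts)))
    n = counts.size
    idx = np.arange(n)
    hi = np.minimum(idx + half + 1, n)
    lo = np.maximum(idx - half, 0)
    return cs[hi] - cs[lo]


@dataclass
class OccupancyProfile:
    """Per-position nucleosome occupancy for one sample."""

    reference_id: str
    values: np.ndarray
    normalized: bool = False
    normalization_method: str | None = None
    half_footprint: int = 73

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if (self.values < 0).any():
            raise ValueError("occupancy values must be non-negative")


@dataclass
class PositioningProfile:
    """Per-position positioning scores in [0, 1] for one sample."""

    reference_id: str
    scores: np.ndarray
    inner_half: int = 10
    outer_half: int = 150

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if ((self.scores < 0) | (self.scores > 1)).any():
            raise ValueError("positioning scores must lie in [0, 1]")


@dataclass(frozen=True)
class RegionSummary:
    """Total occupancy over a region, optionally relative to a control."""

    construct: str
    interval: tuple[int, int]  # report coordinates
    total_occupancy: float
    ratio_to_control: float | None = None


@dataclass(frozen=True)
class ArrayCoverageEstimate:
    """Per-copy sequencing coverage range for a multi-copy array.

    With ``copies_low``–``copies_high`` tandem copies of the transgene
    on the array, the same mapped yield spread over more copies means
    each copy is sequenced less deeply, so the high copy number gives
    the low coverage bound and vice versa.
    """

    mapped_pairs: int
    probe_length: int
    copies_low: int
    copies_high: int
    coverage_low: float
    coverage_high: float
    formula: str


def occupancy_from_dyads(track: DyadTrack, half_footprint: int = 73) -> OccupancyProfile:
    """Raw occupancy: dyad counts extrapolated ±half_footprint bp.

    Footprints are clipped at the reference ends (no wraparound), so a
    dyad at least ``half_footprint`` from both ends contributes exactly
    ``2*half_footprint + 1`` to the profile total.
    """
    if half_footprint < 0:
        raise ValueError("half_footprint must be >= 0")
    values = _window_sums(track.counts, half_footprint).astype(np.float64)
    return OccupancyProfile(
        track.reference_id, values, normalized=False, half_footprint=half_footprint
    )


def normalize_occupancy(
    profile: OccupancyProfile,
    method: str = "max",
    window: Interval | None = None,
) -> OccupancyProfile:
    """Scale an occupancy profile to a 0–1-ish axis.

    ``method="max"`` divides by the maximum over the analysis window
    (default: whole reference), ``"mean"`` by the mean.  An all-zero
    window cannot be normalized and raises :class:`NoSignalError`.
    """
    lo, hi = (window.start, window.end) if window is not None else (0, profile.values.size)
    segment = profile.values[lo:hi]
    if segment.size == 0:
        raise NoSignalError("empty normalization window")
    if method == "max":
        denom = float(segment.max())
    elif method == "mean":
        denom = float(segment.mean())
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    if denom == 0.0:
        raise NoSignalError("no signal: occupancy is zero over the normalization window")
    return OccupancyProfile(
        profile.reference_id,
        profile.values / denom,
        normalized=True,
        normalization_method=f"{method}[{lo},{hi})",
        half_footprint=profile.half_footprint,
    )


def positioning_scores(
    track: DyadTrack, inner_half: int = 10, outer_half: int = 150
) -> PositioningProfile:
    """Positioning score at every position of the reference.

    score[p] = dyads in [p−inner_half, p+inner_half] /
               dyads in [p−outer_half, p+outer_half]
    (both windows inclusive, truncated at the ends).  Positions whose
    outer window holds no dyads score 0: with no nucleosome nearby,
    none is positioned there.
    """
    if not (0 <= inner_half <= outer_half):
        raise ValueError("require 0 <= inner_half <= outer_half")
    inner = _window_sums(track.counts, inner_half)
    outer = _window_sums(track.counts, outer_half)
    n_zero = int((outer == 0).sum())
    if n_zero:
        logger.info("%s: %d positions with empty outer window scored 0",
                    track.reference_id, n_zero)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(outer > 0, inner / np.maximum(outer, 1), 0.0)
    return PositioningProfile(track.reference_id, scores, inner_half, outer_half)


def region_total_occupancy(profile: OccupancyProfile, interval: Interval) -> float:
    """Sum of occupancy values over an interval (additive over disjoint ones)."""
    if interval.end > profile.values.size:
        raise ValueError("interval extends past the reference")
    if len(interval) == 0:
        warnings.warn("empty interval: total occupancy is 0", stacklevel=2)
        return 0.0
    return float(profile.values[interval.start:interval.end].sum())


def ratio_to_control(sample_total: float, control_total: float) -> float:
    """Region total divided by the control construct's total."""
    if control_total <= 0:
        raise ValueError("control total occupancy must be positive")
    if sample_total < 0:
        raise ValueError("sample total occupancy must be non-negative")
    return sample_total / control_total


def align_flanking_profiles(
    profiles: Mapping[str, OccupancyProfile],
    removed_intervals: Mapping[str, Interval | Sequence[Interval]],
) -> dict[str, pd.DataFrame]:
    """Re-index profiles onto a shared flank axis after excising a region.

    For each construct the removed interval (enhancer plus inserted
    elements, one contiguous block) is dropped; upstream flank positions
    get offsets …, −2, −1 ending at its left edge and downstream
    positions get +1, +2, … starting at its right edge.  Values are
    never changed — only their coordinate labels — so constructs with
    different insert lengths become directly comparable.
    """
    out: dict[str, pd.DataFrame] = {}
    for name, profile in profiles.items():
        removal = removed_intervals[name]
        interval = _as_contiguous(removal)
        n = profile.values.size
        if interval.end > n:
            raise ValueError(f"{name}: removed interval extends past the reference")
        a, b = interval.start, interval.end
        offsets = np.concatenate([np.arange(a) - a, np.arange(b, n) - b + 1])
        values = np.concatenate([profile.values[:a], profile.values[b:]])
        out[name] = pd.DataFrame({"offset": offsets, "value": values})
    return out


def _as_contiguous(removal: Interval | Sequence[Interval]) -> Interval:
    if isinstance(removal, Interval):
        return removal
    intervals = sorted(removal, key=lambda iv: iv.start)
    if not intervals:
        raise ValueError("no removal interval given")
    for prev, nxt in zip(intervals, intervals[1:]):
        if nxt.start > prev.end:
            raise ValueError(
                "non-contiguous removal request: "
                f"gap between {prev} and {nxt}"
            )
    return Interval(intervals[0].start, max(iv.end for iv in intervals))


def positioning_at_element(
    profile: PositioningProfile, spec: ConstructSpec, element_name: str
) -> list[tuple[int, float]]:
    """Positioning score at an element's center, in report coordinates.

    Odd-length elements yield one (position, score) pair per placement;
    even-length elements ("no true center") yield the two pairs at the
    positions flanking the center.  Elements placed at both cloning
    sites contribute pairs for each placement, upstream first.
    """
    labels = spec.element_labels(element_name)  # KeyError if unknown
    anns = sorted(
        (spec.element_intervals[lbl] for lbl in labels),
        key=lambda ann: ann.interval.start,
    )
    pairs: list[tuple[int, float]] = []
    for ann in anns:
        for pos in interval_center_positions(ann.interval):
            pairs.append(
                (to_report_coordinates(spec, pos), float(profile.scores[pos]))
            )
    return pairs


def profile_table(
    spec: ConstructSpec,
    values: np.ndarray,
    column: str = "value",
) -> pd.DataFrame:
    """Per-position table with both internal and report coordinates.

    Columns: ``position`` (0-based internal), ``report_position``
    (signed enhancer-centered offset) and the profile values.
    """
    values = np.asarray(values)
    if values.size != len(spec):
        raise ValueError(
            f"profile length {values.size} != construct length {len(spec)}"
        )
    positions = np.arange(values.size)
    return pd.DataFrame({
        "position": positions,
        "report_position": positions - spec.enhancer_center,
        column: values,
    })


def estimate_array_coverage(
    mapped_pairs: int,
    effective_bases_per_pair: float,
    probe_length: int,
    copies_low: int = 70,
    copies_high: int = 300,
) -> ArrayCoverageEstimate:
    """Per-copy coverage range for a 70–300-copy extrachromosomal array.

    coverage = mapped_pairs × effective_bases_per_pair /
               (probe_length × copies)

    evaluated at both ends of the copy-number range;
    ``effective_bases_per_pair`` defaults in the pipeline to the mean
    reconstructed fragment length (an explicit assumption, recorded in
    the returned object's ``formula``).
    """
    if mapped_pairs < 0:
        raise ValueError("mapped_pairs must be >= 0")
    if probe_length <= 0:
        raise ValueError("probe_length must be positive")
    if effective_bases_per_pair <= 0:
        raise ValueError("effective_bases_per_pair must be positive")
    if not (0 < copies_low <= copies_high):
        raise ValueError("require 0 < copies_low <= copies_high")
    formula = "mapped_pairs * effective_bases_per_pair / (probe_length * copies)"
    low = mapped_pairs * effective_bases_per_pair / (probe_length * copies_high)
    high = mapped_pairs * effective_bases_per_pair / (probe_length * copies_low)
    return ArrayCoverageEstimate(
        mapped_pairs=mapped_pairs,
        probe_length=probe_length,
        copies_low=copies_low,
        copies_high=copies_high,
        coverage_low=low,
        coverage_high=high,
        formula=formula,
    )
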