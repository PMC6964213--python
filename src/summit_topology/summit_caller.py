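"""Valley-based splitting of peak coverage profiles into sub-peak summits.

A peak region can harbour more than one binding event; its coverage
profile then shows several local maxima separated by valleys. Two
candidate maxima are treated as distinct summits when the valley between
them drops below ``valley_ratio`` times the lower maximum, otherwise the
lower one is merged into the higher. One summit per retained sub-peak is
reported at the apex (plateau midpoint for flat tops).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import CoverageTrack

__all__ = ["Summit", "SplitParams", "find_local_maxima", "split_peak"]


@dataclass(frozen=True)
class Summit:
    """Single-base summit of one sub-peak."""

    chrom: str
    position: int
    height: float
    peak_id: str = ""
    experiment_id: str = ""


@dataclass(frozen=True)
class SplitParams:
    """Knobs of the valley-splitting rule.

    valley_ratio: a valley separates two maxima when its floor is below
        ``valley_ratio * min(height_1, height_2)``.
    min_height: summits below this coverage are dropped (the tallest
        summit of a peak is always kept).
    min_separation: minimum distance in bp between distinct summits.
    """

    valley_ratio: float = 0.6
    min_height: float = 0.0
    min_separation: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.valley_ratio < 1.0:
            raise ValueError("valley_ratio must be in (0, 1)")
        if self.min_height < 0:
            raise ValueError("min_height must be >= 0")
        if self.min_separation < 1:
            raise ValueError("min_separation must be >= 1")


def find_local_maxima(track: CoverageTrack) -> list[tuple[int, float]]:
    """Positions (track-relative) and heights of maximal plateaus.

    A plateau is maximal when both flanks descend (or hit the track
    boundary). Each plateau is reported once at its midpoint, taking the
    left-median base for even plateau lengths. Zero-height plateaus are
    not summit candidates.
    """
    values = track.values
    n = len(values)
    maxima: list[tuple[int, float]] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[j + 1] == values[i]:
            j += 1
        left_ok = i == 0 or values[i - 1] < values[i]
        right_ok = j == n - 1 or values[j + 1] < values[i]
        if left_ok and right_ok and values[i] > 0:
            maxima.append((i + (j - i) // 2, float(values[i])))
        i = j + 1
    return maxima


def _merge_pass(
    summits: list[tuple[int, float]],
    values: np.ndarray,
    params: SplitParams,
) -> bool:
    """One left-to-right scan; merge the first inseparable adjacent pair."""
    for i in range(len(summits) - 1):
        (p1, h1), (p2, h2) = summits[i], summits[i + 1]
        valley = float(values[p1 : p2 + 1].min())
        separable = (
            p2 - p1 >= params.min_separation
            and valley < params.valley_ratio * min(h1, h2)
        )
        if not separable:
            # drop the lower summit; on a tie keep the leftmost
            del summits[i if h1 < h2 else i + 1]
            return True
    return False


def split_peak(
    track: CoverageTrack,
    params: SplitParams = SplitParams(),
    peak_id: str = "",
    experiment_id: str = "",
) -> list[Summit]:
    """Split one peak's coverage profile into summits.

    Candidate maxima are merged pairwise until every adjacent pair is
    separated by a qualifying valley. Any track with a positive value
    yields at least one summit, regardless of ``min_height``.
    """
    candidates = find_local_maxima(track)
    if not candidates:
        return []
    summits = list(candidates)
    while _merge_pass(summits, track.values, params):
        pass
    kept = [s for s in summits if s[1] >= params.min_height]
    if not kept:
        top = max(summits, key=lambda s: s[1])  # leftmost of the tallest
        kept = [top]
    offset = track.interval.start
    return [
        Summit(
            chrom=track.interval.chrom,
            position=offset + pos,
            height=height,
            peak_id=peak_id,
            experiment_id=experiment_id,
        )
        for pos, height in kept
    ]
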