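"""Shape-based filtering of called peaks.

ChIP-seq peak sets contain artifact regions — PCR towers, clipped
plateaus, coverage shelves — whose summits are meaningless for distance
statistics. This module scores each peak's coverage profile with a small
set of explicit shape metrics and removes peaks violating any bound of a
configurable policy. The metric set targets the canonical artifact
shapes rather than reproducing any particular published filter.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io_formats import CoverageTrack
from .summit_caller import Summit

__all__ = ["ShapeMetrics", "FilterPolicy", "compute_shape_metrics", "filter_peaks"]


@dataclass(frozen=True)
class ShapeMetrics:
    """Shape descriptors of one peak's coverage profile.

    height: maximum coverage.
    width: peak region length in bp.
    half_max_width: contiguous run of bases around the summit with
        coverage >= height / 2 (FWHM on the sampled grid).
    edge_ratio: mean coverage over the outer 10% of bases on each side,
        divided by height. Near 1 for rectangular towers.
    plateau_fraction: fraction of bases within 95% of height. Near 1 for
        flat-topped artifacts.
    symmetry: 1 - |area_left - area_right| / total area, split at the
        summit base.
    """

    peak_id: str
    height: float
    width: int
    half_max_width: int
    edge_ratio: float
    plateau_fraction: float
    symmetry: float


@dataclass(frozen=True)
class FilterPolicy:
    max_edge_ratio: float = 0.25
    max_plateau_fraction: float = 0.5
    min_half_max_width: int = 5
    max_half_max_width: int = 500
    min_height: float = 5.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FilterPolicy":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown policy keys: {sorted(unknown)}")
        return cls(**data)


def compute_shape_metrics(track: CoverageTrack, summit: Summit) -> ShapeMetrics:
    values = track.values
    height = float(values.max())
    if height <= 0:
        raise ValueError("zero-height track: no peak to measure")
    if not track.interval.contains(summit.position):
        raise ValueError("summit lies outside the track interval")
    width = len(values)
    si = summit.position - track.interval.start

    half = height / 2.0
    lo = si
    while lo > 0 and values[lo - 1] >= half:
        lo -= 1
    hi = si
    while hi + 1 < width and values[hi + 1] >= half:
        hi += 1
    half_max_width = hi - lo + 1 if values[si] >= half else 0

    k = max(1, int(0.1 * width))
    edge_mean = float(np.concatenate([values[:k], values[-k:]]).mean())
    edge_ratio = edge_mean / height

    plateau_fraction = float(np.mean(values >= 0.95 * height))

    total = float(values.sum())
    left = float(values[:si].sum())
    right = float(values[si + 1 :].sum())
    symmetry = 1.0 - abs(left - right) / total if total > 0 else 0.0

    return ShapeMetrics(
        peak_id=summit.peak_id,
        height=height,
        width=width,
        half_max_width=half_max_width,
        edge_ratio=edge_ratio,
        plateau_fraction=plateau_fraction,
        symmetry=symmetry,
    )


def _violations(metrics: ShapeMetrics, policy: FilterPolicy) -> list[str]:
    rules = []
    if metrics.edge_ratio > policy.max_edge_ratio:
        rules.append("edge_ratio")
    if metrics.plateau_fraction > policy.max_plateau_fraction:
        rules.append("plateau_fraction")
    if metrics.half_max_width < policy.min_half_max_width:
        rules.append("half_max_width_min")
    if metrics.half_max_width > policy.max_half_max_width:
        rules.append("half_max_width_max")
    if metrics.height < policy.min_height:
        rules.append("height")
    return rules


def filter_peaks(
    peaks: list[tuple[CoverageTrack, Summit]],
    policy: FilterPolicy = FilterPolicy(),
) -> tuple[
    list[tuple[CoverageTrack, Summit]],
    list[tuple[CoverageTrack, Summit]],
    pd.DataFrame,
]:
    """Partition ``peaks`` into kept and removed under ``policy``.

    A peak is removed iff it violates at least one policy bound. The
    report table lists every peak's metrics and the rules it violated.
    """
    kept: list[tuple[CoverageTrack, Summit]] = []
    removed: list[tuple[CoverageTrack, Summit]] = []
    rows = []
    for track, summit in peaks:
        metrics = compute_shape_metrics(track, summit)
        rules = _violations(metrics, policy)
        (removed if rules else kept).append((track, summit))
        rows.append(
            {
                "peak_id": metrics.peak_id,
                "height": metrics.height,
                "width": metrics.width,
                "half_max_width": metrics.half_max_width,
                "edge_ratio": round(metrics.edge_ratio, 6),
                "plateau_fraction": round(metrics.plateau_fraction, 6),
                "symmetry": round(metrics.symmetry, 6),
                "removed": bool(rules),
                "violated_rules": ",".join(rules),
            }
        )
    report = pd.DataFrame(
        rows,
        columns=[
            "peak_id",
            "height",
            "width",
            "half_max_width",
            "edge_ratio",
            "plateau_fraction",
            "symmetry",
            "removed",
            "violated_rules",
        ],
    )
    return kept, removed, report
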