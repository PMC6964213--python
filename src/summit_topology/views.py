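"""Exportable analytics: rolling-mean shift histograms and scatter tables.

The shift histogram counts summit-to-motif-center distances at 1 bp
resolution and smooths the counts with a centered 5 bp rolling mean; the
highest point of the smoothed curve marks the most likely position of
the protein relative to the motif. Secondary maxima ("shoulders") are
reported as well — distances of ~11 or ~22 bp between maxima correspond
to one or two turns of the double helix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .topology import DistanceRecord, ExperimentSummary

__all__ = ["ShiftHistogram", "shift_histogram", "pairshift_table", "motifview_table"]


@dataclass
class ShiftHistogram:
    """Distance histogram of one experiment against one motif set."""

    experiment_id: str
    motif_name: str
    limit: int
    bin_centers: np.ndarray
    raw_counts: np.ndarray
    smoothed: np.ndarray
    modes: list[int] = field(default_factory=list)
    n_records: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "experiment_id": self.experiment_id,
                "motif_name": self.motif_name,
                "distance": self.bin_centers,
                "raw_count": self.raw_counts,
                "smoothed": self.smoothed,
            }
        )


def _smooth(raw: np.ndarray, window: int) -> np.ndarray:
    """Centered rolling mean with truncated windows at the edges."""
    kernel = np.ones(window)
    sums = np.convolve(raw.astype(float), kernel, mode="same")
    effective = np.convolve(np.ones_like(raw, dtype=float), kernel, mode="same")
    return sums / effective


def _find_modes(
    smoothed: np.ndarray, limit: int, prominence_fraction: float
) -> list[int]:
    if smoothed.max() <= 0:
        return []
    idx, _ = find_peaks(
        smoothed, prominence=prominence_fraction * float(smoothed.max())
    )
    modes = [int(i) - limit for i in idx]
    # edge bins cannot be detected by find_peaks; treat a strictly
    # descending-from-the-edge global max as a mode
    if smoothed[0] >= smoothed.max() and smoothed[0] > smoothed[1]:
        modes.insert(0, -limit)
    if smoothed[-1] >= smoothed.max() and smoothed[-1] > smoothed[-2]:
        modes.append(limit)
    return modes


def shift_histogram(
    records: Sequence[DistanceRecord],
    limit: int = 50,
    smooth_window: int = 5,
    prominence_fraction: float = 0.1,
    experiment_id: str = "",
    motif_name: str = "",
) -> ShiftHistogram:
    """Histogram of distances in [-limit, limit] with rolling-mean smoothing.

    ``smooth_window`` must be odd. Edge bins are smoothed over the
    truncated window that fits (divide by the actual bin count), so they
    are unbiased rather than zero-padded. Local maxima of the smoothed
    curve with prominence at least ``prominence_fraction`` of the global
    maximum are reported as modes.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be a positive odd integer")
    distances = np.asarray([r.distance for r in records], dtype=int)
    in_range = distances[(distances >= -limit) & (distances <= limit)]
    raw = np.bincount(in_range + limit, minlength=2 * limit + 1)
    smoothed = _smooth(raw, smooth_window)
    if not experiment_id and records:
        ids = {r.experiment_id for r in records}
        if len(ids) == 1:
            experiment_id = next(iter(ids))
    if not motif_name and records:
        names = {r.motif_name for r in records}
        if len(names) == 1:
            motif_name = next(iter(names))
    return ShiftHistogram(
        experiment_id=experiment_id,
        motif_name=motif_name,
        limit=limit,
        bin_centers=np.arange(-limit, limit + 1),
        raw_counts=raw,
        smoothed=smoothed,
        modes=_find_modes(smoothed, limit, prominence_fraction),
        n_records=int(raw.sum()),
    )


def pairshift_table(
    experiment_ids: Sequence[str],
    motif_name: str,
    records: Sequence[DistanceRecord],
    limit: int = 50,
    smooth_window: int = 5,
) -> list[ShiftHistogram]:
    """One histogram per experiment, all over the same motif's sites."""
    if not 1 <= len(experiment_ids) <= 3:
        raise ValueError("between 1 and 3 experiment ids required")
    relevant = [r for r in records if r.motif_name == motif_name]
    available = {r.experiment_id for r in relevant}
    histograms = []
    for experiment_id in experiment_ids:
        if experiment_id not in available:
            raise ValueError(
                f"unknown experiment id {experiment_id!r} for motif "
                f"{motif_name!r}"
            )
        histograms.append(
            shift_histogram(
                [r for r in relevant if r.experiment_id == experiment_id],
                limit=limit,
                smooth_window=smooth_window,
                experiment_id=experiment_id,
                motif_name=motif_name,
            )
        )
    return histograms


def motifview_table(
    summaries: Sequence[ExperimentSummary],
    min_overlap: int = 100,
    direct_only: bool = False,
    antibodies: Sequence[str] | None = None,
    cell_types: Sequence[str] | None = None,
    metadata: Mapping[str, Mapping[str, str]] | None = None,
    sort_by: str = "n_overlap",
) -> pd.DataFrame:
    """Scatter table behind the per-motif summary view.

    ``metadata`` optionally maps experiment id to ``antibody`` and
    ``cell_type`` annotations used by the corresponding filters.
    """
    rows = []
    for summary in summaries:
        meta = (metadata or {}).get(summary.experiment_id, {})
        antibody = meta.get("antibody", "")
        cell_type = meta.get("cell_type", "")
        if summary.n_overlap < min_overlap:
            continue
        if direct_only and not summary.is_direct:
            continue
        if antibodies is not None and antibody not in antibodies:
            continue
        if cell_types is not None and cell_type not in cell_types:
            continue
        rows.append(
            {
                "experiment_id": summary.experiment_id,
                "motif_name": summary.motif_name,
                "antibody": antibody,
                "cell_type": cell_type,
                "n_overlap": summary.n_overlap,
                "mean_distance": summary.mean_distance,
                "sd_distance": summary.sd_distance,
                "is_direct": summary.is_direct,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "experiment_id",
            "motif_name",
            "antibody",
            "cell_type",
            "n_overlap",
            "mean_distance",
            "sd_distance",
            "is_direct",
        ],
    )
    if sort_by not in ("n_overlap", "experiment_id"):
        raise ValueError("sort_by must be 'n_overlap' or 'experiment_id'")
    ascending = sort_by == "experiment_id"
    if not frame.empty:
        frame = frame.sort_values(
            sort_by, ascending=ascending, kind="mergesort"
        ).reset_index(drop=True)
    return frame
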