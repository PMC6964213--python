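"""Motif-center versus peak-summit distance statistics.

The core statistic of the pipeline: for every consensus motif site, the
signed distances to all peak summits within a window (50 bp by default),
aggregated per (experiment, motif) into overlap count, mean shift and
standard deviation. Distances are strand-oriented — ``summit - center``
for plus-strand sites and ``center - summit`` for minus-strand sites —
so that a protein sitting 3 bp downstream of the motif center scores +3
regardless of which genomic strand carries the motif.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .motif_engine import MotifSite
from .summit_caller import Summit

__all__ = [
    "DistanceRecord",
    "ExperimentSummary",
    "compute_distances",
    "summarize_experiment",
    "overlap_site_sets",
    "snp_overlap",
    "records_to_frame",
    "frame_to_records",
]


@dataclass(frozen=True)
class DistanceRecord:
    """One (site, summit) pair within the window."""

    motif_name: str
    chrom: str
    site_center: int
    experiment_id: str
    summit_position: int
    distance: int


@dataclass(frozen=True)
class ExperimentSummary:
    """Per (experiment, motif) aggregate of the distance list."""

    experiment_id: str
    motif_name: str
    n_overlap: int
    mean_distance: float
    sd_distance: float
    is_direct: bool = False


def compute_distances(
    sites: Sequence[MotifSite],
    summits: Sequence[Summit],
    window: int = 50,
) -> list[DistanceRecord]:
    """All (site, summit) pairs with ``|summit - center| <= window``.

    The window boundary is inclusive. A summit near two sites yields two
    records and vice versa.
    """
    by_chrom: dict[str, list[Summit]] = {}
    for summit in summits:
        by_chrom.setdefault(summit.chrom, []).append(summit)
    positions: dict[str, tuple[list[int], list[Summit]]] = {}
    for chrom, group in by_chrom.items():
        group.sort(key=lambda s: s.position)
        positions[chrom] = ([s.position for s in group], group)

    records: list[DistanceRecord] = []
    for site in sites:
        chrom = site.interval.chrom
        if chrom not in positions:
            continue
        pos_list, group = positions[chrom]
        lo = bisect_left(pos_list, site.center - window)
        hi = bisect_right(pos_list, site.center + window)
        sign = 1 if site.strand == "+" else -1
        for summit in group[lo:hi]:
            records.append(
                DistanceRecord(
                    motif_name=site.motif_name,
                    chrom=chrom,
                    site_center=site.center,
                    experiment_id=summit.experiment_id,
                    summit_position=summit.position,
                    distance=sign * (summit.position - site.center),
                )
            )
    return records


def summarize_experiment(
    records: Sequence[DistanceRecord],
    min_overlap: int = 100,
    direct_map: Mapping[str, str] | None = None,
) -> list[ExperimentSummary]:
    """Mean and population SD of distances per (experiment, motif).

    Groups with fewer than ``min_overlap`` records are excluded (the
    overlap-count threshold of the scatter view). ``direct_map`` maps an
    experiment id to its antibody's cognate motif name; a summary is
    flagged direct when its motif matches.
    """
    groups: dict[tuple[str, str], list[int]] = {}
    for record in records:
        groups.setdefault(
            (record.experiment_id, record.motif_name), []
        ).append(record.distance)
    summaries = []
    for (experiment_id, motif_name) in sorted(groups):
        distances = np.asarray(groups[(experiment_id, motif_name)], dtype=float)
        if len(distances) < min_overlap:
            continue
        summaries.append(
            ExperimentSummary(
                experiment_id=experiment_id,
                motif_name=motif_name,
                n_overlap=len(distances),
                mean_distance=float(distances.mean()),
                sd_distance=float(distances.std()),  # population SD
                is_direct=bool(
                    direct_map is not None
                    and direct_map.get(experiment_id) == motif_name
                ),
            )
        )
    return summaries


def overlap_site_sets(
    summits_by_experiment: Mapping[str, Sequence[Summit]],
    sites: Sequence[MotifSite],
    window: int = 50,
) -> dict[tuple[str, ...], int]:
    """Counts of the 7 Venn regions over three experiments.

    A site belongs to an experiment when that experiment has a summit
    within ``window`` bp of the site center. The 7 counts partition the
    sites with at least one membership; sites overlapped by no
    experiment are not counted.
    """
    experiment_ids = list(summits_by_experiment)
    if len(experiment_ids) != 3 or len(set(experiment_ids)) != 3:
        raise ValueError("exactly 3 distinct experiment ids required")
    counts: dict[tuple[str, ...], int] = {}
    for r in range(1, 8):
        key = tuple(
            exp for i, exp in enumerate(experiment_ids) if r >> i & 1
        )
        counts[key] = 0
    by_exp_chrom: dict[str, dict[str, list[int]]] = {}
    for exp in experiment_ids:
        per: dict[str, list[int]] = {}
        for summit in summits_by_experiment[exp]:
            per.setdefault(summit.chrom, []).append(summit.position)
        for chrom in per:
            per[chrom].sort()
        by_exp_chrom[exp] = per

    for site in sites:
        members = []
        for exp in experiment_ids:
            pos_list = by_exp_chrom[exp].get(site.interval.chrom, [])
            lo = bisect_left(pos_list, site.center - window)
            hi = bisect_right(pos_list, site.center + window)
            if hi > lo:
                members.append(exp)
        if members:
            counts[tuple(members)] += 1
    return counts


def snp_overlap(
    snps: Sequence[tuple[str, int, str, str, str]],
    sites: Sequence[MotifSite],
) -> pd.DataFrame:
    """One row per (SNP, site) pair with the SNP inside the site span.

    ``offset_in_motif`` indexes the motif logo as displayed: on a minus
    strand site, the last genomic base of the span is logo position 0.
    """
    by_chrom: dict[str, list[MotifSite]] = {}
    for site in sites:
        by_chrom.setdefault(site.interval.chrom, []).append(site)
    for group in by_chrom.values():
        group.sort(key=lambda s: s.interval.start)
    rows = []
    for chrom, position, snp_id, ref, alt in snps:
        for site in by_chrom.get(chrom, ()):
            if site.interval.start > position:
                break
            if not site.interval.contains(position):
                continue
            if site.strand == "+":
                offset = position - site.interval.start
            else:
                offset = site.interval.end - 1 - position
            rows.append(
                {
                    "snp_id": snp_id,
                    "motif_name": site.motif_name,
                    "chrom": chrom,
                    "position": position,
                    "ref": ref,
                    "alt": alt,
                    "site_start": site.interval.start,
                    "site_end": site.interval.end,
                    "strand": site.strand,
                    "offset_in_motif": offset,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "snp_id",
            "motif_name",
            "chrom",
            "position",
            "ref",
            "alt",
            "site_start",
            "site_end",
            "strand",
            "offset_in_motif",
        ],
    )


_RECORD_COLUMNS = [
    "motif_name",
    "chrom",
    "site_center",
    "experiment_id",
    "summit_position",
    "distance",
]


def records_to_frame(records: Sequence[DistanceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "motif_name": r.motif_name,
                "chrom": r.chrom,
                "site_center": r.site_center,
                "experiment_id": r.experiment_id,
                "summit_position": r.summit_position,
                "distance": r.distance,
            }
            for r in records
        ],
        columns=_RECORD_COLUMNS,
    )


def frame_to_records(frame: pd.DataFrame) -> list[DistanceRecord]:
    return [
        DistanceRecord(
            motif_name=row.motif_name,
            chrom=row.chrom,
            site_center=int(row.site_center),
            experiment_id=str(row.experiment_id),
            summit_position=int(row.summit_position),
            distance=int(row.distance),
        )
        for row in frame.itertuples(index=False)
    ]
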