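"""PWM scanning, 2-of-3 scanner consensus, and iterative matrix refinement.

Binding sites are mapped on the union of the peak regions of all
experiments sharing a consensus motif. Three scanner parameterizations
(differing in score threshold and pseudocount) scan those regions and a
site is retained when at least two scanners report it at (almost) the
same position — a consensus site verified by independent scoring rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .io_formats import (
    BASES,
    GenomicInterval,
    MotifMatrix,
    reverse_complement,
)

__all__ = [
    "MotifSite",
    "ScannerConfig",
    "DEFAULT_SCANNERS",
    "merge_peak_regions",
    "score_window",
    "scan",
    "consensus_sites",
    "OptimizationResult",
    "optimize_pwm",
]

_BASE_TO_INDEX = {b: i for i, b in enumerate(BASES)}
_BASE_TO_INDEX["N"] = 4


@dataclass(frozen=True)
class MotifSite:
    """Genomic placement of a motif match.

    ``center`` is the genomic coordinate of the matrix center column,
    strand-projected: on the minus strand matrix position 0 aligns with
    the interval's last base.
    """

    interval: GenomicInterval
    strand: str
    score: float
    center: int
    motif_name: str
    supporting_scanners: int = 1

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("site strand must be + or -")
        if not self.interval.contains(self.center):
            raise ValueError("center must lie inside the site interval")


@dataclass(frozen=True)
class ScannerConfig:
    """One scanner parameterization.

    score_threshold_fraction: fraction of the matrix's maximum achievable
        log-odds a window must reach to be reported.
    """

    id: str
    score_threshold_fraction: float
    pseudocount: float = 0.1
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if not 0.0 < self.score_threshold_fraction <= 1.0:
            raise ValueError("score_threshold_fraction must be in (0, 1]")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


#: The three scanner parameterizations used for the 2-of-3 consensus rule.
DEFAULT_SCANNERS: tuple[ScannerConfig, ...] = (
    ScannerConfig("strict", 0.85, 0.1),
    ScannerConfig("standard", 0.80, 0.5),
    ScannerConfig("lenient", 0.75, 1.0),
)


def merge_peak_regions(
    interval_sets: Sequence[Sequence[GenomicInterval]],
) -> list[GenomicInterval]:
    """Union of all intervals: sorted, non-overlapping, touching merged."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for intervals in interval_sets:
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        spans = sorted(by_chrom[chrom])
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged


def _log_odds_with_n(
    matrix: MotifMatrix, config: ScannerConfig | None
) -> np.ndarray:
    """L x 5 log2-odds, 5th column the N contribution.

    An N scores the log2 of the background-weighted mean odds ratio at
    that column, which is 0 under the scanner's own background.
    """
    if config is None:
        pc, bg = matrix.pseudocount, matrix.background
    else:
        pc, bg = config.pseudocount, np.asarray(config.background)
    lo = matrix.log_odds(pseudocount=pc, background=bg)
    probs = matrix.probabilities(pseudocount=pc)
    n_col = np.log2((probs * bg).sum(axis=1) / (bg * bg).sum())
    return np.column_stack([lo, n_col])


def _encode(seq: str) -> np.ndarray:
    return np.fromiter(
        (_BASE_TO_INDEX.get(b, 4) for b in seq.upper()),
        dtype=np.int64,
        count=len(seq),
    )


def score_window(
    seq: str,
    matrix: MotifMatrix,
    strand: str = "+",
    config: ScannerConfig | None = None,
) -> float:
    """Log2-odds score of one window of length L.

    On the minus strand the reverse complement of ``seq`` is scored.
    """
    if len(seq) != len(matrix):
        raise ValueError(
            f"sequence length {len(seq)} does not match motif length "
            f"{len(matrix)}"
        )
    if strand == "-":
        seq = reverse_complement(seq)
    elif strand != "+":
        raise ValueError("strand must be + or -")
    lo = _log_odds_with_n(matrix, config)
    idx = _encode(seq)
    return float(lo[np.arange(len(matrix)), idx].sum())


def _site_center(start: int, length: int, center_index: int, strand: str) -> int:
    if strand == "+":
        return start + center_index
    return start + (length - 1 - center_index)


def scan(
    regions: Sequence[GenomicInterval],
    genome: Mapping[str, str],
    matrix: MotifMatrix,
    config: ScannerConfig,
) -> list[MotifSite]:
    """Report every window on both strands scoring at or above threshold.

    The threshold is ``score_threshold_fraction`` times the maximum
    achievable log-odds sum. Windows are enumerated within each region
    independently; sites are returned sorted by (chrom, start, strand).
    """
    L = len(matrix)
    lo = _log_odds_with_n(matrix, config)
    # minus-strand windows scored in place via the reverse-complemented matrix
    lo_rev = lo[::-1, [3, 2, 1, 0, 4]]
    max_score = float(lo[:, :4].max(axis=1).sum())
    threshold = config.score_threshold_fraction * max_score

    sites: list[MotifSite] = []
    for region in regions:
        if region.chrom not in genome:
            raise ValueError(f"region chromosome {region.chrom!r} not in genome")
        chrom_seq = genome[region.chrom]
        if region.end > len(chrom_seq):
            raise ValueError(
                f"region {region.chrom}:[{region.start},{region.end}) "
                f"exceeds sequence length {len(chrom_seq)}"
            )
        if len(region) < L:
            continue
        idx = _encode(chrom_seq[region.start : region.end])
        windows = np.lib.stride_tricks.sliding_window_view(idx, L)
        pos = np.arange(L)
        fwd = lo[pos, windows].sum(axis=1)
        rev = lo_rev[pos, windows].sum(axis=1)
        for offsets, scores, strand in (
            (np.nonzero(fwd >= threshold)[0], fwd, "+"),
            (np.nonzero(rev >= threshold)[0], rev, "-"),
        ):
            for off in offsets:
                start = region.start + int(off)
                sites.append(
                    MotifSite(
                        interval=GenomicInterval(region.chrom, start, start + L),
                        strand=strand,
                        score=float(scores[off]),
                        center=_site_center(start, L, matrix.center_index, strand),
                        motif_name=matrix.name,
                        supporting_scanners=1,
                    )
                )
    sites.sort(key=lambda s: (s.interval.chrom, s.interval.start, s.strand))
    return sites


def consensus_sites(
    hits_per_scanner: Sequence[Sequence[MotifSite]],
    tolerance: int = 2,
) -> list[MotifSite]:
    """Keep sites reported by at least 2 of exactly 3 scanners.

    Hits agree when chromosome and strand match and their start
    coordinates differ by at most ``tolerance`` bp; agreement groups are
    the connected components of that relation. Each group supported by
    >= 2 distinct scanners emits one site at the position of its highest
    scoring member (ties: leftmost, then lowest scanner index), with
    ``supporting_scanners`` set to the number of distinct scanners.
    """
    if len(hits_per_scanner) != 3:
        raise ValueError(
            f"expected exactly 3 scanner hit lists, got {len(hits_per_scanner)}"
        )
    pooled: dict[tuple[str, str], list[tuple[int, float, int, MotifSite]]] = {}
    for scanner_idx, hits in enumerate(hits_per_scanner):
        for site in hits:
            key = (site.interval.chrom, site.strand)
            pooled.setdefault(key, []).append(
                (site.interval.start, site.score, scanner_idx, site)
            )
    out: list[MotifSite] = []
    for key in pooled:
        members = sorted(pooled[key], key=lambda m: (m[0], m[2]))
        group: list[tuple[int, float, int, MotifSite]] = []
        for member in members:
            if group and member[0] - group[-1][0] > tolerance:
                out.extend(_emit_group(group))
                group = []
            group.append(member)
        out.extend(_emit_group(group))
    out.sort(key=lambda s: (s.interval.chrom, s.interval.start, s.strand))
    return out


def _emit_group(
    group: list[tuple[int, float, int, MotifSite]],
) -> list[MotifSite]:
    if not group:
        return []
    scanners = {m[2] for m in group}
    if len(scanners) < 2:
        return []
    best = max(group, key=lambda m: (m[1], -m[0], -m[2]))
    return [replace(best[3], supporting_scanners=len(scanners))]


@dataclass
class OptimizationResult:
    matrix: MotifMatrix
    converged: bool
    no_sites: bool
    history: list[dict] = field(default_factory=list)


def optimize_pwm(
    regions: Sequence[GenomicInterval],
    genome: Mapping[str, str],
    seed_matrix: MotifMatrix,
    max_iter: int = 10,
    top_n: int = 5000,
    tol: float = 1e-4,
    threshold_fraction: float = 0.7,
) -> OptimizationResult:
    """Iteratively refine a PFM on merged peak regions.

    Each iteration scans with the current matrix, keeps the ``top_n``
    best-scoring sites, re-estimates the count matrix from their aligned
    sequences and renormalizes. Stops when no probability cell moves by
    more than ``tol``, or after ``max_iter`` iterations. If an iteration
    finds no sites, the seed matrix is returned flagged.
    """
    if not regions:
        raise ValueError("no regions to optimize on")
    current = seed_matrix
    history: list[dict] = []
    converged = False
    config = ScannerConfig(
        "optimizer", threshold_fraction, seed_matrix.pseudocount
    )
    for iteration in range(max_iter):
        hits = scan(regions, genome, current, config)
        if not hits:
            return OptimizationResult(
                matrix=seed_matrix, converged=False, no_sites=True,
                history=history,
            )
        hits.sort(
            key=lambda s: (
                -s.score,
                s.interval.chrom,
                s.interval.start,
                s.strand,
            )
        )
        top = hits[:top_n]
        counts = np.zeros((len(seed_matrix), 4))
        for site in top:
            seq = genome[site.interval.chrom][
                site.interval.start : site.interval.end
            ].upper()
            if site.strand == "-":
                seq = reverse_complement(seq)
            for i, base in enumerate(seq):
                if base in _BASE_TO_INDEX and base != "N":
                    counts[i, _BASE_TO_INDEX[base]] += 1
        refined = MotifMatrix(
            name=seed_matrix.name,
            counts=counts,
            background=seed_matrix.background,
            pseudocount=seed_matrix.pseudocount,
            center_index=seed_matrix.center_index,
        )
        delta = float(
            np.abs(refined.probabilities() - current.probabilities()).max()
        )
        history.append(
            {"iteration": iteration, "n_sites": len(top), "max_delta": delta}
        )
        current = refined
        if delta < tol:
            converged = True
            break
    return OptimizationResult(
        matrix=current, converged=converged, no_sites=False, history=history
    )
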