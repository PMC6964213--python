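"""Readers and writers for the genomic text formats the pipeline consumes.

All coordinates are 0-based, half-open (BED convention). Summit positions
are single 0-based base indices. The module owns the domain containers
(:class:`GenomicInterval`, :class:`CoverageTrack`, :class:`MotifMatrix`)
that every downstream stage shares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "GenomicInterval",
    "CoverageTrack",
    "MotifMatrix",
    "BedGraph",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_pfm",
    "write_pfm",
    "write_summits",
    "read_summits",
    "load_genome",
    "write_fasta",
    "read_snps",
    "read_sites_table",
    "write_sites_table",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic span ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str = "."
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end


@dataclass
class CoverageTrack:
    """Per-base coverage attached to one interval."""

    interval: GenomicInterval
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.interval):
            raise ValueError(
                f"coverage length {len(self.values)} does not match interval "
                f"length {len(self.interval)}"
            )
        if np.any(self.values < 0):
            raise ValueError("coverage values must be non-negative")


@dataclass
class MotifMatrix:
    """Position frequency matrix with a defined center column.

    ``counts`` is an L x 4 array over the alphabet ACGT. The probability
    matrix is derived with a flat pseudocount: ``p = (c + k) / (N + 4k)``
    per row. ``center_index`` is the matrix column the distance statistics
    are measured from (logo position 0); it defaults to the left-of-center
    column, ``floor((L - 1) / 2)``.
    """

    name: str
    counts: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 0.1
    center_index: int | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("counts must be an L x 4 matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        self.background = np.asarray(self.background, dtype=float)
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("background must sum to 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.center_index is None:
            self.center_index = (len(self) - 1) // 2
        if not 0 <= self.center_index < len(self):
            raise ValueError("center_index out of range")

    def __len__(self) -> int:
        return self.counts.shape[0]

    def probabilities(self, pseudocount: float | None = None) -> np.ndarray:
        k = self.pseudocount if pseudocount is None else pseudocount
        totals = self.counts.sum(axis=1, keepdims=True)
        return (self.counts + k) / (totals + 4.0 * k)

    def log_odds(
        self,
        pseudocount: float | None = None,
        background: np.ndarray | None = None,
    ) -> np.ndarray:
        """L x 4 log2-odds matrix ``log2(p / background)``."""
        bg = self.background if background is None else np.asarray(background)
        return np.log2(self.probabilities(pseudocount) / bg)

    def max_score(
        self,
        pseudocount: float | None = None,
        background: np.ndarray | None = None,
    ) -> float:
        return float(self.log_odds(pseudocount, background).max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=1))

    def information_content(self) -> float:
        """Total information in bits, Σ_i (2 + Σ_b p log2 p)."""
        p = self.probabilities()
        return float((2.0 + (p * np.log2(p)).sum(axis=1)).sum())


# ---------------------------------------------------------------------------
# BED

_SKIP_PREFIXES = ("track", "browser", "#")


def _data_lines(path: str | Path):
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(_SKIP_PREFIXES):
                continue
            yield lineno, stripped


def read_bed(path: str | Path, expect_score: bool = False) -> list[GenomicInterval]:
    """Read a BED3/BED5/BED6 file into intervals, in file order.

    Track, browser and ``#`` comment lines are skipped. With
    ``expect_score`` a missing score column is a parse error.
    """
    intervals: list[GenomicInterval] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path} line {lineno}: fewer than 3 fields")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(
                f"{path} line {lineno}: non-integer coordinates"
            ) from exc
        name = fields[3] if len(fields) > 3 and fields[3] != "." else None
        score: float | None = None
        if len(fields) > 4 and fields[4] != ".":
            try:
                score = float(fields[4])
            except ValueError as exc:
                raise ParseError(
                    f"{path} line {lineno}: non-numeric score"
                ) from exc
        elif expect_score:
            raise ParseError(f"{path} line {lineno}: missing score column")
        strand = fields[5] if len(fields) > 5 else "."
        try:
            intervals.append(
                GenomicInterval(chrom, start, end, name=name, strand=strand,
                                score=score)
            )
        except ValueError as exc:
            raise ParseError(f"{path} line {lineno}: {exc}") from exc
    return intervals


def _format_score(score: float) -> str:
    # repr round-trips floats exactly; integral values print as integers
    value = float(score)
    return str(int(value)) if value.is_integer() else repr(value)


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as handle:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand != ".":
                fields.append(iv.name if iv.name is not None else ".")
            if iv.score is not None or iv.strand != ".":
                fields.append(
                    _format_score(iv.score) if iv.score is not None else "."
                )
            if iv.strand != ".":
                fields.append(iv.strand)
            handle.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# BEDGRAPH

class BedGraph:
    """Sparse per-chromosome coverage: sorted non-overlapping fragments.

    Bases absent from the file have coverage 0. Overlapping fragments are
    rejected because they would make the coverage ambiguous.
    """

    def __init__(self, fragments: Mapping[str, Sequence[tuple[int, int, float]]]):
        self.fragments: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, frags in fragments.items():
            ordered = sorted(frags)
            for (s1, e1, v1), (s2, e2, v2) in zip(ordered, ordered[1:]):
                if s2 < e1:
                    raise ParseError(
                        f"overlapping coverage fragments on {chrom}: "
                        f"[{s1},{e1}) and [{s2},{e2})"
                    )
            for s, e, v in ordered:
                if v < 0:
                    raise ParseError(
                        f"negative coverage value {v} on {chrom}:[{s},{e})"
                    )
                if e <= s:
                    raise ParseError(
                        f"empty coverage fragment on {chrom}:[{s},{e})"
                    )
            self.fragments[chrom] = ordered

    def track(self, interval: GenomicInterval) -> CoverageTrack:
        """Per-base expansion over ``interval``; absent bases are 0."""
        values = np.zeros(len(interval))
        for s, e, v in self.fragments.get(interval.chrom, ()):
            if e <= interval.start or s >= interval.end:
                continue
            lo = max(s, interval.start) - interval.start
            hi = min(e, interval.end) - interval.start
            values[lo:hi] = v
        return CoverageTrack(interval, values)

    def total_mass(self) -> float:
        return sum(
            (e - s) * v
            for frags in self.fragments.values()
            for s, e, v in frags
        )


def read_bedgraph(path: str | Path) -> BedGraph:
    fragments: dict[str, list[tuple[int, int, float]]] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 4:
            raise ParseError(f"{path} line {lineno}: fewer than 4 fields")
        try:
            start, end = int(fields[1]), int(fields[2])
            value = float(fields[3])
        except ValueError as exc:
            raise ParseError(f"{path} line {lineno}: malformed fields") from exc
        if value < 0:
            raise ParseError(f"{path} line {lineno}: negative coverage value")
        fragments.setdefault(fields[0], []).append((start, end, value))
    return BedGraph(fragments)


def write_bedgraph(bedgraph: BedGraph, path: str | Path) -> None:
    with open(path, "w") as handle:
        for chrom in sorted(bedgraph.fragments):
            for s, e, v in bedgraph.fragments[chrom]:
                handle.write(f"{chrom}\t{s}\t{e}\t{_format_score(v)}\n")


# ---------------------------------------------------------------------------
# JASPAR-style PFM

def read_pfm(path: str | Path) -> MotifMatrix:
    """Read a JASPAR-style PFM (bracketed or bare row dialect)."""
    name = None
    rows: dict[str, list[float]] = {}
    order: list[str] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    break  # only the first motif in the file
                name = line[1:].split()[0] if line[1:].split() else "motif"
                continue
            cleaned = line.replace("[", " ").replace("]", " ")
            tokens = cleaned.split()
            if tokens and tokens[0].rstrip(":").upper() in ("A", "C", "G", "T"):
                base = tokens[0].rstrip(":").upper()
                tokens = tokens[1:]
            else:
                base = "ACGT"[len(order)] if len(order) < 4 else None
            if base is None or base in rows:
                raise ParseError(f"{path} line {lineno}: unexpected matrix row")
            try:
                values = [float(t) for t in tokens]
            except ValueError as exc:
                raise ParseError(
                    f"{path} line {lineno}: non-numeric count"
                ) from exc
            if any(v < 0 for v in values):
                raise ParseError(f"{path} line {lineno}: negative count")
            rows[base] = values
            order.append(base)
    if set(rows) != {"A", "C", "G", "T"}:
        raise ParseError(f"{path}: expected 4 rows (A, C, G, T)")
    lengths = {len(v) for v in rows.values()}
    if len(lengths) != 1:
        raise ParseError(f"{path}: matrix rows have unequal lengths")
    counts = np.array([rows[b] for b in BASES]).T
    return MotifMatrix(name or "motif", counts)


def write_pfm(matrix: MotifMatrix, path: str | Path) -> None:
    """Write in the bracketed JASPAR dialect."""
    with open(path, "w") as handle:
        handle.write(f">{matrix.name}\n")
        for i, base in enumerate(BASES):
            row = " ".join(_format_score(v) for v in matrix.counts[:, i])
            handle.write(f"{base} [ {row} ]\n")


# ---------------------------------------------------------------------------
# Summits

def write_summits(summits: Iterable, path: str | Path) -> None:
    """Write summits as BED5: start=position, end=position+1, score=height."""
    with open(path, "w") as handle:
        for summit in summits:
            name = summit.peak_id if summit.peak_id else "."
            handle.write(
                f"{summit.chrom}\t{summit.position}\t{summit.position + 1}"
                f"\t{name}\t{_format_score(summit.height)}\n"
            )


def read_summits(path: str | Path, experiment_id: str = "") -> list:
    from .summit_caller import Summit

    summits = []
    for iv in read_bed(path, expect_score=True):
        if len(iv) != 1:
            raise ParseError(
                f"{path}: summit interval {iv.chrom}:[{iv.start},{iv.end}) "
                "is not a single base"
            )
        summits.append(
            Summit(
                chrom=iv.chrom,
                position=iv.start,
                height=iv.score if iv.score is not None else 0.0,
                peak_id=iv.name or "",
                experiment_id=experiment_id,
            )
        )
    return summits


# ---------------------------------------------------------------------------
# FASTA

def load_genome(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into an in-memory chrom -> sequence mapping."""
    from pyfaidx import Fasta

    fasta = Fasta(str(path), as_raw=True, sequence_always_upper=True)
    return {name: str(fasta[name][:]) for name in fasta.keys()}


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as handle:
        for chrom, seq in genome.items():
            handle.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# SNPs (BED-like positions with id and alleles)

def read_snps(path: str | Path) -> list[tuple[str, int, str, str, str]]:
    """Read SNPs from a BED-like file: chrom, start, end, id, ref, alt.

    Returns (chrom, position, id, ref, alt) tuples; positions are the
    0-based start of the single-base interval.
    """
    snps = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 4:
            raise ParseError(f"{path} line {lineno}: fewer than 4 fields")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(
                f"{path} line {lineno}: non-integer coordinates"
            ) from exc
        if end != start + 1:
            raise ParseError(
                f"{path} line {lineno}: SNP must span a single base"
            )
        ref = fields[4] if len(fields) > 4 else "."
        alt = fields[5] if len(fields) > 5 else "."
        snps.append((fields[0], start, fields[3], ref, alt))
    return snps


# ---------------------------------------------------------------------------
# Motif-site tables (extended TSV with center coordinate)

_SITE_COLUMNS = [
    "chrom",
    "start",
    "end",
    "motif_name",
    "score",
    "strand",
    "center",
    "supporting_scanners",
]


def write_sites_table(sites: Iterable, path: str | Path) -> None:
    from .motif_engine import MotifSite  # noqa: F401  (documented row type)

    rows = [
        {
            "chrom": s.interval.chrom,
            "start": s.interval.start,
            "end": s.interval.end,
            "motif_name": s.motif_name,
            "score": round(s.score, 6),
            "strand": s.strand,
            "center": s.center,
            "supporting_scanners": s.supporting_scanners,
        }
        for s in sites
    ]
    pd.DataFrame(rows, columns=_SITE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_sites_table(path: str | Path) -> list:
    from .motif_engine import MotifSite

    frame = pd.read_csv(path, sep="\t")
    missing = set(_SITE_COLUMNS) - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    sites = []
    for row in frame.itertuples(index=False):
        sites.append(
            MotifSite(
                interval=GenomicInterval(row.chrom, int(row.start), int(row.end)),
                strand=row.strand,
                score=float(row.score),
                center=int(row.center),
                motif_name=row.motif_name,
                supporting_scanners=int(row.supporting_scanners),
            )
        )
    return sites
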