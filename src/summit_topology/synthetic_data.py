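"""Seeded generator of synthetic genomes, motif sites, summits and coverage.

The generator emulates the data structure the pipeline assumes: a genome
with planted, non-overlapping motif instances; per-experiment peak
summits displaced from the motif centers by a configurable mean shift
and SD (optionally a two-component mixture to produce a "shoulder");
fragment-pileup coverage bumps over the peaks; and rectangular artifact
towers for the shape filter. Everything is driven by one integer seed
through a single numpy Generator, so runs are fully reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .io_formats import (
    BASES,
    BedGraph,
    GenomicInterval,
    MotifMatrix,
    CoverageTrack,
    read_pfm,
    reverse_complement,
    write_bed,
    write_bedgraph,
    write_fasta,
    write_pfm,
    write_summits,
    write_sites_table,
)
from .motif_engine import MotifSite, merge_peak_regions, score_window, _site_center
from .summit_caller import Summit

__all__ = [
    "ExperimentDesign",
    "SimulationDesign",
    "SimulationResult",
    "default_motif",
    "place_sites",
    "simulate_genome_with_sites",
    "simulate_summits",
    "simulate_coverage",
    "simulate",
    "write_simulation",
    "make_filter_benchmark",
]

_SITE_MARGIN = 10  # bp kept free on each side of a planted site


def default_motif(name: str = "SYNMOT1") -> MotifMatrix:
    """A 12-column, high-information PFM used as the default planted motif.

    Planted instances are then near-exact consensus copies, so the
    three-scanner consensus recovers almost all of them and the distance
    statistics are dominated by summit placement, not scanner loss.
    """
    consensus = "TGACGTCATCGC"
    counts = np.ones((len(consensus), 4))
    for i, base in enumerate(consensus):
        counts[i, BASES.index(base)] = 997.0
    return MotifMatrix(name=name, counts=counts)


def place_sites(
    n: int,
    spacing: int = 1000,
    length: int = 12,
    motif_name: str = "SYNMOT1",
    chrom: str = "chrSim",
) -> list[MotifSite]:
    """Regularly spaced motif sites with alternating strands.

    A sequence-free site layout for distance-statistics studies where
    only summit placement matters; spacing should exceed twice the
    distance window so summits pair with a single site.
    """
    center_index = (length - 1) // 2
    sites = []
    for i in range(n):
        start = _SITE_MARGIN + i * spacing
        strand = "+" if i % 2 == 0 else "-"
        sites.append(
            MotifSite(
                interval=GenomicInterval(chrom, start, start + length),
                strand=strand,
                score=0.0,
                center=_site_center(start, length, center_index, strand),
                motif_name=motif_name,
            )
        )
    return sites


@dataclass(frozen=True)
class ExperimentDesign:
    """Summit-placement model of one simulated ChIP-seq experiment.

    mean_shift/sd: strand-oriented displacement of the summit from the
        motif center, in bp, drawn from Normal(mean_shift, sd) and
        rounded to an integer.
    overlap_fraction: probability that a site receives a summit at all.
    shoulder: optional (offset, weight) mixture component — with
        probability ``weight`` the draw comes from
        Normal(mean_shift + offset, sd) instead.
    """

    experiment_id: str
    mean_shift: float
    sd: float
    overlap_fraction: float = 1.0
    shoulder: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must be in [0, 1]")
        if self.shoulder is not None and not 0.0 <= self.shoulder[1] <= 1.0:
            raise ValueError("shoulder weight must be in [0, 1]")


def _default_experiments() -> list[ExperimentDesign]:
    return [
        ExperimentDesign("direct", mean_shift=-3.0, sd=8.0, overlap_fraction=0.9),
        ExperimentDesign("cofactor", mean_shift=15.0, sd=12.0, overlap_fraction=0.6),
        ExperimentDesign("indirect", mean_shift=0.0, sd=18.0, overlap_fraction=0.7),
        ExperimentDesign(
            "shouldered",
            mean_shift=-3.0,
            sd=2.0,
            overlap_fraction=0.8,
            shoulder=(11.0, 0.3),
        ),
    ]


@dataclass
class SimulationDesign:
    """Full design of one synthetic study.

    The defaults emulate a 2 Mb genome with 1000 planted sites and four
    experiments: a directly bound TF (mode -3, SD 8), a shifted
    co-factor (+15, SD 12), an indirectly tethered protein (0, SD 18)
    and a sharply positioned TF with a secondary arrangement one helical
    turn away (shoulder at +11, 30% weight).
    """

    genome_length: int = 2_000_000
    n_sites: int = 1000
    motif: MotifMatrix = field(default_factory=default_motif)
    experiments: list[ExperimentDesign] = field(
        default_factory=_default_experiments
    )
    artifact_peaks: int = 30
    fragment_sd: float = 50.0
    peak_halfwidth: int = 150
    min_site_gap: int = 200
    chrom: str = "chrSim"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationDesign":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        kwargs: dict = {}
        for key in (
            "genome_length",
            "n_sites",
            "artifact_peaks",
            "fragment_sd",
            "peak_halfwidth",
            "min_site_gap",
            "chrom",
            "seed",
        ):
            if key in data:
                kwargs[key] = data[key]
        if "motif" in data:
            kwargs["motif"] = read_pfm(data["motif"])
        if "experiments" in data:
            kwargs["experiments"] = [
                ExperimentDesign(
                    experiment_id=e["id"],
                    mean_shift=float(e["mean_shift"]),
                    sd=float(e["sd"]),
                    overlap_fraction=float(e.get("overlap_fraction", 1.0)),
                    shoulder=(
                        (
                            float(e["shoulder"]["offset"]),
                            float(e["shoulder"]["weight"]),
                        )
                        if e.get("shoulder")
                        else None
                    ),
                )
                for e in data["experiments"]
            ]
        return cls(**kwargs)


def simulate_genome_with_sites(
    design: SimulationDesign,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], list[MotifSite]]:
    """Uniform-background genome with non-overlapping planted motif sites.

    Each placement draws its strand Bernoulli(0.5) and its sequence from
    the motif's count frequencies; minus-strand sites are planted as the
    reverse complement. Returns the genome mapping and the true site
    list with strand-projected centers and rescored log-odds.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    L = len(design.motif)
    # sites stay >= min_site_gap apart so that within the distance window
    # every summit is attributable to a single site
    gap = max(design.min_site_gap, 2 * _SITE_MARGIN)
    slot = L + gap
    if design.n_sites * slot > design.genome_length:
        raise ValueError(
            f"cannot pack {design.n_sites} sites of slot {slot} bp into "
            f"{design.genome_length} bp"
        )
    background = rng.integers(0, 4, size=design.genome_length)
    seq = np.array(list(BASES))[background]

    slack = design.genome_length - design.n_sites * slot
    offsets = np.sort(rng.integers(0, slack + 1, size=design.n_sites))
    starts = offsets + gap // 2 + np.arange(design.n_sites) * slot

    probs = design.motif.counts / design.motif.counts.sum(axis=1, keepdims=True)
    sites: list[MotifSite] = []
    genome: dict[str, str] = {}
    for start in starts:
        strand = "+" if rng.random() < 0.5 else "-"
        drawn = "".join(
            BASES[rng.choice(4, p=probs[i])] for i in range(L)
        )
        planted = drawn if strand == "+" else reverse_complement(drawn)
        seq[start : start + L] = list(planted)
        sites.append((int(start), strand))
    chrom_seq = "".join(seq)
    genome[design.chrom] = chrom_seq

    true_sites = []
    for start, strand in sites:
        window = chrom_seq[start : start + L]
        true_sites.append(
            MotifSite(
                interval=GenomicInterval(design.chrom, start, start + L),
                strand=strand,
                score=score_window(window, design.motif, strand=strand),
                center=_site_center(
                    start, L, design.motif.center_index, strand
                ),
                motif_name=design.motif.name,
            )
        )
    return genome, true_sites


def simulate_summits(
    true_sites: Sequence[MotifSite],
    experiment: ExperimentDesign,
    rng: np.random.Generator,
    genome_length: int | None = None,
) -> list[Summit]:
    """Summits displaced from site centers by the experiment's shift model.

    Each site is covered independently with probability
    ``overlap_fraction``. The displacement draw is strand-projected:
    a +d draw places the summit d bp downstream in motif orientation.
    Heights are placeholders (1.0) until coverage is simulated.
    """
    summits: list[Summit] = []
    for index, site in enumerate(true_sites):
        if rng.random() >= experiment.overlap_fraction:
            continue
        mean = experiment.mean_shift
        if experiment.shoulder is not None:
            offset, weight = experiment.shoulder
            if rng.random() < weight:
                mean = experiment.mean_shift + offset
        draw = int(np.rint(rng.normal(mean, experiment.sd)))
        sign = 1 if site.strand == "+" else -1
        position = site.center + sign * draw
        if genome_length is not None:
            position = min(max(position, 0), genome_length - 1)
        summits.append(
            Summit(
                chrom=site.interval.chrom,
                position=position,
                height=1.0,
                peak_id=f"peak_{index}",
                experiment_id=experiment.experiment_id,
            )
        )
    return summits


def simulate_coverage(
    summits: Sequence[Summit],
    design: SimulationDesign,
    rng: np.random.Generator,
) -> tuple[list[GenomicInterval], BedGraph, list[Summit]]:
    """Fragment-pileup coverage: Gaussian bumps plus artifact towers.

    Each summit receives a bump of random height (30-80) and SD
    ``fragment_sd``; ``artifact_peaks`` rectangular towers are dropped
    at random positions. Peak regions are the merged union of
    summit +/- peak_halfwidth spans and tower footprints; coverage is
    emitted only within peak regions. Returns the peak regions, the
    coverage, and the summits with heights updated to the coverage at
    their position.
    """
    n = design.genome_length
    coverage = np.zeros(n)
    spans: list[GenomicInterval] = []
    for summit in summits:
        height = rng.integers(30, 81)
        lo = max(0, summit.position - 3 * int(design.fragment_sd))
        hi = min(n, summit.position + 3 * int(design.fragment_sd) + 1)
        x = np.arange(lo, hi)
        coverage[lo:hi] += height * np.exp(
            -((x - summit.position) ** 2) / (2.0 * design.fragment_sd**2)
        )
        spans.append(
            GenomicInterval(
                design.chrom,
                max(0, summit.position - design.peak_halfwidth),
                min(n, summit.position + design.peak_halfwidth + 1),
            )
        )
    for _ in range(design.artifact_peaks):
        width = int(rng.integers(30, 81))
        height = int(rng.integers(40, 121))
        start = int(rng.integers(0, n - width))
        coverage[start : start + width] += height
        # the caller would report the enriched footprint itself
        spans.append(GenomicInterval(design.chrom, start, start + width))
    coverage = np.rint(coverage)

    peaks = merge_peak_regions([spans])
    fragments: dict[str, list[tuple[int, int, float]]] = {design.chrom: []}
    for peak in peaks:
        values = coverage[peak.start : peak.end]
        change = np.nonzero(np.diff(values))[0] + 1
        bounds = np.concatenate([[0], change, [len(values)]])
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            value = float(values[lo])
            if value > 0:
                fragments[design.chrom].append(
                    (peak.start + int(lo), peak.start + int(hi), value)
                )
    updated = [
        replace(s, height=float(coverage[s.position])) for s in summits
    ]
    return peaks, BedGraph(fragments), updated


@dataclass
class ExperimentData:
    design: ExperimentDesign
    summits: list[Summit]
    peaks: list[GenomicInterval] | None = None
    coverage: BedGraph | None = None


@dataclass
class SimulationResult:
    design: SimulationDesign
    genome: dict[str, str]
    sites: list[MotifSite]
    experiments: dict[str, ExperimentData]

    def truth(self) -> dict:
        return {
            "genome_length": self.design.genome_length,
            "n_sites": self.design.n_sites,
            "motif_name": self.design.motif.name,
            "motif_consensus": self.design.motif.consensus,
            "seed": self.design.seed,
            "experiments": [
                {
                    "id": e.design.experiment_id,
                    "mean_shift": e.design.mean_shift,
                    "sd": e.design.sd,
                    "overlap_fraction": e.design.overlap_fraction,
                    "shoulder": (
                        list(e.design.shoulder) if e.design.shoulder else None
                    ),
                    "n_summits": len(e.summits),
                }
                for e in self.experiments.values()
            ],
        }


def simulate(
    design: SimulationDesign, with_coverage: bool = True
) -> SimulationResult:
    """Run the full generator for one design under its seed."""
    rng = np.random.default_rng(design.seed)
    genome, sites = simulate_genome_with_sites(design, rng)
    experiments: dict[str, ExperimentData] = {}
    for experiment in design.experiments:
        summits = simulate_summits(
            sites, experiment, rng, genome_length=design.genome_length
        )
        if with_coverage:
            peaks, coverage, summits = simulate_coverage(summits, design, rng)
            experiments[experiment.experiment_id] = ExperimentData(
                experiment, summits, peaks, coverage
            )
        else:
            experiments[experiment.experiment_id] = ExperimentData(
                experiment, summits
            )
    return SimulationResult(design, genome, sites, experiments)


def write_simulation(result: SimulationResult, outdir: str | Path) -> None:
    """Write genome.fa, sites.tsv/.bed, per-experiment files and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(result.genome, outdir / "genome.fa")
    write_pfm(result.design.motif, outdir / "motif.pfm")
    write_sites_table(result.sites, outdir / "sites.tsv")
    write_bed(
        [
            replace(
                s.interval,
                name=s.motif_name,
                score=round(s.score, 3),
                strand=s.strand,
            )
            for s in result.sites
        ],
        outdir / "sites.bed",
    )
    for exp_id, data in result.experiments.items():
        write_summits(data.summits, outdir / f"{exp_id}.summits.bed")
        if data.peaks is not None:
            write_bed(data.peaks, outdir / f"{exp_id}.peaks.bed")
        if data.coverage is not None:
            write_bedgraph(data.coverage, outdir / f"{exp_id}.cov.bedgraph")
    with open(outdir / "truth.json", "w") as handle:
        json.dump(result.truth(), handle, indent=2)


def make_filter_benchmark(
    n_true: int = 70,
    n_artifact: int = 30,
    seed: int = 0,
    chrom: str = "chrBench",
) -> list[tuple[CoverageTrack, Summit, str]]:
    """Labelled peak shapes for the filter: Gaussians vs rectangular towers.

    True peaks are Gaussian bumps (SD 15-35 bp, height 30-100); artifact
    peaks are constant-height towers (width 30-60 bp, height 30-120),
    the canonical PCR-duplicate / clipped-signal shape.
    """
    rng = np.random.default_rng(seed)
    peaks: list[tuple[CoverageTrack, Summit, str]] = []
    cursor = 0
    for i in range(n_true):
        sigma = rng.uniform(15, 35)
        height = rng.uniform(30, 100)
        halfwidth = int(3 * sigma)
        x = np.arange(-halfwidth, halfwidth + 1)
        values = np.rint(height * np.exp(-(x**2) / (2 * sigma**2)))
        interval = GenomicInterval(chrom, cursor, cursor + len(values))
        apex = cursor + halfwidth
        peaks.append(
            (
                CoverageTrack(interval, values),
                Summit(chrom, apex, float(values.max()), f"true_{i}"),
                "true",
            )
        )
        cursor += len(values) + 100
    for i in range(n_artifact):
        width = int(rng.integers(30, 61))
        height = float(np.rint(rng.uniform(30, 120)))
        values = np.full(width, height)
        interval = GenomicInterval(chrom, cursor, cursor + width)
        peaks.append(
            (
                CoverageTrack(interval, values),
                Summit(chrom, cursor + (width - 1) // 2, height, f"tower_{i}"),
                "artifact",
            )
        )
        cursor += width + 100
    return peaks
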