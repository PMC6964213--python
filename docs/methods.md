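# Methods

## The statistic

For a motif site set `S` (one consensus motif mapped genome-wide) and an
experiment's summit set `T`, the pipeline records every pair
`(s ∈ S, t ∈ T)` on the same chromosome with `|pos(t) − center(s)| ≤ w`
(window `w = 50` bp by default, boundary inclusive). The signed
distance is strand-oriented:

```
d = pos(t) − center(s)   for + sites
d = center(s) − pos(t)   for − sites
```

so `d` is expressed in motif orientation: +3 always means "3 bp
downstream of the logo". Distances are *not* oriented in the source
material this analysis style comes from — but shifted, asymmetric
distributions are only comparable across sites if they are expressed in
motif coordinates; mixing orientations would symmetrize every
distribution and erase the signal. This is therefore a deliberate design
choice of this package.

Per (experiment, motif) group the pipeline reports `n` (overlap count),
the mean of `d`, and the *population* SD (divide by `n`). At the
`n ≥ 100` threshold used for reporting, the sample/population
distinction is numerically immaterial, but it must be fixed for
reproducibility. A summit near two sites contributes two records and
vice versa; no deduplication is attempted, matching the all-pairs
definition above.

The motif **center** is the matrix column distances are measured from
(logo position 0). For a matrix of length `L` it defaults to
`floor((L−1)/2)` — the left-of-center column for even `L`; the
convention is arbitrary but must be uniform for distances to be
comparable across motifs. On minus-strand sites the center coordinate is
strand-projected (matrix column 0 aligns with the last genomic base of
the span).

## Summit calling

A peak's coverage profile may contain several binding events. Candidate
summits are the maximal plateaus of the profile (reported at the plateau
midpoint, left-median for even plateaus — a deterministic tie-break is
required for reproducible distances). Adjacent candidates `m1, m2`
remain separate iff the valley between them drops below
`valley_ratio × min(h1, h2)` and they are at least `min_separation` bp
apart; otherwise the lower one is merged into the higher (ties keep the
leftmost). The default `valley_ratio = 0.6` mirrors the published
default of the valley-splitting tools this stage re-implements. The
merge relation is confluent — the test suite checks the implementation
against a brute-force fixed point computed with a different merge order.
Bases absent from the BEDGRAPH count as coverage 0, which can split a
peak; this matches the file semantics (coverage is only reported within
peak regions).

## Peak filtering

The filter is an explicit, documented stand-in for shape-based artifact
removal: the upstream criteria this step models are not public, so
equivalence with any particular pipeline is not claimed. Metrics per
peak (coverage track + summit):

| metric | definition | default bound | targets |
|---|---|---|---|
| height | max coverage | ≥ 5 | noise blobs |
| half_max_width | contiguous run around the summit ≥ height/2 | 5–500 bp | spikes / mega-peaks |
| edge_ratio | mean coverage of the outer 10% of bases each side ÷ height | ≤ 0.25 | clipped edges, shelves |
| plateau_fraction | fraction of bases within 95% of height | ≤ 0.5 | PCR towers, saturated plateaus |
| symmetry | 1 − |areaL − areaR| ÷ area (split at summit) | reported, unused | — |

A peak is removed iff it violates at least one bound; the report names
the violated rules. All bounds live in a YAML-loadable policy so the
filter can be swapped without code changes. The removal *rate* is an
outcome, never a target — the filter is benchmarked on labelled
synthetic shapes (Gaussian bumps vs rectangular towers) for sensitivity
≥ 0.95 and false-removal ≤ 0.05, not tuned to remove any quota.

## Motif mapping

Peak regions of all experiments assigned to one consensus motif are
merged (interval union, touching intervals coalesce) and scanned on
both strands with the motif's position weight matrix. Scoring is
standard log-odds: `Σ_i log2(p_i(base) / bg(base))` with a flat
pseudocount `p = (c + k) / (N + 4k)` per column (this matches the
normalization used by common motif libraries, which the tests exploit
as an independent oracle). An `N` base contributes the log2 of the
background-weighted mean odds at that column (0 under a uniform
background). A window is reported when its score reaches a fraction of
the maximum achievable score.

The "three scanners" are realized as three parameterizations of this
scanner differing in threshold fraction and pseudocount
(0.85/0.1, 0.80/0.5, 0.75/1.0); the hit lists are pluggable, so
externally produced hit sets can be substituted. Sites are equated
across scanners when chromosome and strand match and starts differ by
≤ 2 bp (exact-start equality is too strict across scanners that trim
differently); agreement groups are connected components of that
relation, and groups supported by ≥ 2 of the 3 scanners emit one
consensus site at the highest-scoring member. Whether the original
analysis required strand agreement is unknown; requiring it is the
conservative choice (a motif and its reverse complement are different
objects at non-palindromic matrices).

PWM refinement re-estimates the count matrix from the top-scoring 5000
sites at threshold fraction 0.7, iterating until no probability cell
moves by more than 1e-4 (max 10 iterations); ties in the score ranking
break deterministically by coordinate. Manual matrix curation is out of
scope — the iteration log supports human review instead.

## Views

The distance histogram counts records at 1 bp resolution over
[−limit, +limit] (default ±50) and smooths with a centered 5 bp rolling
mean. Edge bins average over the truncated window that fits (divide by
the actual bin count): truncation keeps edge bins unbiased, whereas
zero-padding would bias them low. Histograms are raw counts, not
normalized per curve — curve height carries the overlap count. Local
maxima of the smoothed curve with prominence ≥ 10% of the global
maximum are reported as modes, which captures genuine shoulders without
a hand-tuned shoulder definition. The scatter table applies the overlap
threshold (`min_overlap = 100` by default), the direct-binding flag
(experiment's antibody target has this motif as cognate site, supplied
as an explicit experiment → motif mapping) and optional
antibody/cell-type selections.

## Synthetic data

The generator emulates exactly the structure the statistics assume:

- **Genome**: uniform-background sequence (no GC skew — none of the
  tested statistics depend on composition; a biased background would
  only change scanner false-positive rates, which the high-information
  default motif makes negligible anyway).
- **Sites**: `n_sites` placements, strand Bernoulli(0.5), sequences
  drawn per column from the motif's count frequencies, minus-strand
  instances planted as reverse complements. Sites keep a minimum gap
  (default 200 bp > 2× the distance window) so every summit within the
  window is attributable to a single site — the condition under which
  recovering planted parameters is meaningful. The default motif is a
  12-column, near-consensus matrix, so planted instances are recovered
  almost completely by the 2-of-3 consensus at the default thresholds;
  real motifs are fuzzier, and scanner loss on degenerate motifs is a
  real-data feature the default simulation deliberately excludes from
  the statistics under test.
- **Summits**: each site is covered with probability
  `overlap_fraction`; the summit sits at
  `center ± round(Normal(shift, sd))` (strand-projected), optionally
  drawing from a second component `Normal(shift + offset, sd)` with
  probability `weight` to produce a shoulder. Rounding happens in the
  generator; truncation to the ±50 window happens only in the distance
  stage, so window-boundary behaviour is itself under test.
- **Coverage**: a Gaussian bump (SD `fragment_sd` = 50 bp, height
  30–80) around each summit emulates extended-read pileup; peak regions
  are summit ± 150 bp, merged when they touch. Artifact peaks are
  rectangular towers (width 30–80 bp, height 40–120) at random
  positions, with the called region equal to the tower footprint.
- **Default design**: 2 Mb genome, 1000 sites, four experiments —
  direct (−3, SD 8, overlap 0.9), shifted co-factor (+15, SD 12, 0.6),
  indirect (0, SD 18, 0.7) and a sharply positioned TF with a secondary
  arrangement one helical turn away (−3, SD 2, shoulder +11 at 30%).
  The shift values mirror the canonical phenomenology this analysis
  style resolves: a direct TF a few bp off its motif center, a partner
  protein one to two helical turns away, and a tethered protein with
  high SD. One seed drives a single numpy Generator through genome,
  sites, summits and coverage, so outputs are bit-identical across runs
  and platforms.

What passing on this generator does *not* show: robustness to GC-biased
backgrounds, degenerate motifs, copy-number or mappability artifacts
beyond the tower shape, or peak-caller idiosyncrasies — the pipeline
consumes peak regions and coverage as given.

## Numerical and scale choices

- Coordinates are 0-based half-open everywhere (BED convention);
  summit BED lines span `[pos, pos+1)`. Unknown chromosome names pass
  through unvalidated so synthetic genomes work.
- The distance window boundary is inclusive at |d| = 50.
- Statistical tests run at the sizes their tolerances are derived from:
  2000 pairs for shift recovery (mean tolerance ±0.5 bp ≈ 1–2 standard
  errors depending on σ), 100 replicates × n=1000 for SD-layer
  ordering, n=5000 for shoulder detection. Shift-recovery tests use a
  window wide enough (200 bp) that the Normal(−18, 20) case is not
  truncated; with the analysis window of 50 bp a distribution that wide
  is visibly clipped (its truncated mean is ≈ −15.7), which is a
  property of the statistic, not an estimation error.
- The shoulder mixture uses component SD 2 (variance 4). At component
  separation 11 bp a mixture with component SD 4 is barely bimodal (the
  analytic dip between modes is ≈ 0.5% of the main mode), so no
  finite-sample histogram can resolve it; SD 2 yields two well-separated
  modes exactly 11 bp apart.
- The end-to-end chain filters peaks first and calls summits on the
  kept regions; tolerances there (mean ±1.5 bp, SD ±10%) account for
  the smaller per-experiment overlap counts (600–900) and the ≈ 4%
  SD shrinkage the ±50 bp window imposes on the SD-18 experiment.

## Known limitations

- The shape filter is this package's own metric set; it is validated
  against canonical artifact shapes, not against any pipeline's
  unpublished criteria.
- The three scanner parameterizations stand in for three independent
  mapping programs; the consensus machinery accepts external hit lists
  for users who want genuinely independent scanners.
- SNP overlap reports positions only; no attempt is made to score the
  allele's effect on binding affinity.
- Summit calling assumes the coverage profile within a peak is a
  faithful pileup; no control-track normalization is performed.
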