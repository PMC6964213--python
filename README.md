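# summit-topology

Summit-centric analysis of ChIP-seq experiments: where does a protein
sit on the DNA relative to the sequence motif it (or its partner) binds?

ChIP-seq reports genomic regions that co-precipitate with a protein, but
a large fraction of peaks for a transcription factor (TF) do not contain
its cognate binding motif — the protein can reach the DNA indirectly,
tethered through another DNA-bound TF. The single base of maximal
coverage inside a peak (the *summit*) is the protein's most likely
crosslink point, and the distribution of summit positions around motif
centers carries topological information:

- the **mean** of the signed, strand-oriented distance
  `d = summit − motif center` (sign flipped on minus-strand sites) is
  the protein's preferred position along the DNA relative to the motif;
- the **standard deviation** of `d` is a proximity proxy: a protein
  bound directly to its site crosslinks tightly around one point (low
  SD), while a protein held at a distance through protein–protein
  contacts crosslinks diffusely (high SD);
- secondary maxima ("shoulders") in the distance histogram, often ~11
  or ~22 bp from the main mode (one or two helical turns), indicate
  alternative arrangements on the same face of the double helix.

This package implements the full pipeline producing those statistics
from standard text formats, plus a seeded synthetic-data generator so
every stage is testable without any external data:

| stage | module | what it does |
|---|---|---|
| summit calling | `summit_caller` | splits each peak's coverage profile at valleys; one summit per sub-peak |
| peak filtering | `peak_filter` | removes artifact-shaped peaks (towers, plateaus, clipped edges) by explicit shape metrics |
| motif mapping | `motif_engine` | merges peak regions, scans them with a PWM under three scanner settings, keeps 2-of-3 consensus sites, optionally refines the PWM |
| distance statistics | `topology` | per-(experiment, motif) overlap count, mean shift, SD; 3-way Venn counts; SNP-in-motif overlap |
| analytics | `views` | 5 bp rolling-mean distance histograms with mode/shoulder detection; filterable scatter tables |
| simulation | `synthetic_data` | genomes with planted motif instances, summits displaced by configurable shift/SD/mixtures, fragment-pileup coverage, artifact peaks |
| I/O | `io_formats` | BED, BEDGRAPH, FASTA, JASPAR-style PFM, TSV tables; 0-based half-open coordinates throughout |

## Worked example

Three simulated experiments share one set of 2000 motif sites: a TF
bound directly at its motif (true shift −3 bp, SD 8), a co-factor
displaced one and a half helical turns downstream (+15, SD 12) and a
tethered protein with no positional preference (0, SD 18):

```python
import numpy as np
from summit_topology import (
    ExperimentDesign, compute_distances, summarize_experiment,
    shift_histogram,
)
from summit_topology.synthetic_data import place_sites, simulate_summits

sites = place_sites(2000)
rng = np.random.default_rng(7)
for exp in (
    ExperimentDesign("TF_direct", mean_shift=-3, sd=8),
    ExperimentDesign("cofactor", mean_shift=15, sd=12),
    ExperimentDesign("tethered", mean_shift=0, sd=18),
):
    summits = simulate_summits(sites, exp, rng)
    records = compute_distances(sites, summits, window=50)
    (s,) = summarize_experiment(records, min_overlap=100)
    print(f"{s.experiment_id:10s} n={s.n_overlap}  "
          f"mean={s.mean_distance:+.2f} bp  sd={s.sd_distance:.2f} bp")

mix = ExperimentDesign("shouldered", mean_shift=-3, sd=2, shoulder=(11, 0.3))
summits = simulate_summits(sites, mix, rng)
hist = shift_histogram(compute_distances(sites, summits, window=50))
print("smoothed modes:", hist.modes)
```

prints

```
TF_direct  n=2000  mean=-3.47 bp  sd=7.98 bp
cofactor   n=1999  mean=+14.71 bp  sd=12.08 bp
tethered   n=1990  mean=+0.61 bp  sd=17.30 bp
smoothed modes: [-3, 8]
```

The mean shifts and SDs recover the planted values, the SD rank order
(direct < co-factor < tethered) reflects the proximity hypothesis, and
the two-component experiment shows its main mode at −3 with a shoulder
11 bp away.

The same analysis runs file-to-file through the CLI:

```sh
summit-topology simulate --outdir sim/
summit-topology filter-peaks --peaks sim/direct.peaks.bed \
    --coverage sim/direct.cov.bedgraph --out kept.bed --report report.tsv
summit-topology call-summits --peaks kept.bed \
    --coverage sim/direct.cov.bedgraph --experiment-id direct \
    --out direct.summits.bed
summit-topology map-motifs --regions kept.bed --genome sim/genome.fa \
    --pfm sim/motif.pfm --out sites.tsv
summit-topology distances --sites sites.tsv \
    --summits direct.summits.bed --out dist.tsv
summit-topology summarize --dist dist.tsv --out motifview.tsv
```

See `docs/methods.md` for the model, parameter and design notes.

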