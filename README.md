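# sfnet

Genome-wide transcription start site (TSS) calling from **size-fractionated
NET-Seq** coverage tracks, with the downstream statistics used to describe
pervasive and divergent transcription architecture, and a synthetic-track
simulator for testing the whole pipeline at desk scale.

## The problem

NET-Seq maps the 3′ nucleotide in the active site of engaged RNA polymerase II.
When the nascent RNA is split into size fractions before library construction
(20–50, 50–170, 170–500 and 500–1000 nt), each fraction's 3′-end coverage is
confined to a distance band downstream of the transcription unit's TSS: a
polymerase that has made *d* nucleotides leaves a 3′-end count at offset
*d* − 1, on the track of the fraction whose interval [L, U) contains *d*.
The shortest fraction is additionally mapped by its 5′ ends, which pile up at
the TSS itself. A TSS therefore announces itself as a nested "staircase"
across the four tracks, and overlapping transcription units that are
inseparable in conventional NET-Seq resolve into distinct staircases.

`sfnet` turns this into a caller:

1. each track is smoothed with a zero-phase low-pass Butterworth filter
   (order 12, half-power frequency 0.05 × Nyquist, applied forward and
   backward so peaks do not shift);
2. a **reference pattern** is built by averaging the smoothed tracks over
   annotated TSSs (a metagene per fraction) and concatenating the first
   400 nt of the four metagenes, each z-scored per track;
3. every genome position *p* on each strand is scored by the Pearson
   correlation *r* between the reference and the equivalent concatenated
   400-nt window starting at *p*;
4. peaks of the correlation curve (minimum spacing 50 bp) above a height
   threshold — by default calibrated on the data to a false-discovery rate
   of 10⁻³ using a circular-rotation null, with the canonical 0.34 as the
   grid floor — become putative TSSs;
5. putative TSSs with fewer than 10 raw reads in the downstream 100 nt
   (summed over the four matched tracks) are discarded.

Downstream, the package assigns calls to existing annotations (< 70 bp,
strand-aware), removes polyadenylation/splice-site cleavage artifacts,
and computes the architecture statistics: up/downstream read ratios,
TSS density around gene TSS/PAS anchors, one-sided Fisher tests for the
co-occurrence of units flanking the PAS (log-space, so log₁₀ *p* ≈ −300
stays finite), a per-feature two-sample Kolmogorov–Smirnov screen with its
E-value, and resampling-based signal enrichment with quantile bands and an
empirical p-value.

## Worked example

```sh
python examples/01_simulate_and_call.py
```

simulates a 200-kb genome with 100 planted units (expected polymerase counts
200–1000, Poisson background 0.02 reads/base/track), builds the reference
from the planted TSSs and calls TSSs back:

```
planted units : 100
TSS calls     : 92
sensitivity   : 0.92  (units recovered within +/-20 bp)
precision     : 1.00  (calls within +/-20 bp of a unit)
first call    : chrS:2464 (-) height 0.78, 74 downstream reads
```

92 of the 100 planted units are recovered to within ±20 bp and every call
sits on a planted unit; the FDR-calibrated threshold for this dataset is
0.66. The other examples annotate the call set
(`02_annotate_calls.py`), recover planted divergent architecture around
polyadenylation sites (`03_architecture_stats.py`, one-sided Fisher
p = 5.9 × 10⁻⁴), and detect a planted ChIP-like bump 40 bp downstream of a
gene group against resampling bands (`04_signal_enrichment.py`,
p = 5 × 10⁻⁵).

The same steps are available from the shell:

```sh
sfnet simulate --scenario basic --seed 1 --out sim/
sfnet call --config run.yaml        # smooth -> reference -> scan -> filter
sfnet stats --config run.yaml --calls out/calls.annotated.tsv
```

with every intermediate (smoothed tracks, reference TSV, correlation
bedGraph, calls BED/TSV, class summary, manifest with checksums and seeds)
written to the output directory.

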