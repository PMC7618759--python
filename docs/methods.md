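# Methods

This note records the model behind `sfnet`, the parameters that matter,
what the simulator does and does not emulate, and the numerical and design
choices made where the design was genuinely open.

## Signal model

A transcription unit is a TSS plus a downstream extent on one strand.
Size fractionation of nascent RNA partitions the polymerase population by
how far each polymerase has transcribed: a polymerase *d* nucleotides into
a unit contributes one 3′-end count at offset *d* − 1 from the TSS, on the
coverage track of the size fraction whose interval [L, U) contains *d*
(defaults [20, 50), [50, 170), [170, 500), [500, 1000) nt). Fraction
[L, U) therefore cannot show 3′-end signal closer than L − 1 bases to the
TSS — the nested staircase that makes the TSS identifiable. The 20–50 nt
fraction is also mapped by 5′ ends, all of which fall on the TSS base.
Alkaline fragmentation of the longer fractions is irrelevant to this model
because only 3′-end positions are counted and fragmentation preserves the
3′ end.

Note a structural consequence used throughout: within the 400-nt matching
window the 500–1000 nt fraction can contain no signal from its own unit.
Its template segment carries neighbourhood/background information only, and
is excluded from template-stability claims in the tests.

## Smoothing

Tracks are smoothed per chromosome per strand with a low-pass Butterworth
(order 12, half-power frequency 0.05 of Nyquist; the squared single-pass
magnitude is 1/2 at that frequency) realised as second-order sections —
order-12 transfer-function polynomials are numerically unstable — and
applied forward and backward, so the effective magnitude response is
squared and the phase is exactly zero: smoothing never shifts a peak,
which matters because calls are reported at single-base resolution.
Edges are handled by odd-reflection padding. The pad length is derived
from the slowest pole radius (transient < 10⁻¹⁰; 1128 samples for the
default filter) rather than the conventional 3 × order, because with poles
at radius 0.98 a 36-sample pad leaves edge transients of order 0.5 that
propagate through the whole chromosome and break zero-phase symmetry;
with the derived pad, reversal symmetry and linearity hold to 10⁻⁹.
Chromosomes shorter than the pad pass through unfiltered with a warning;
the caller never reports positions within one window of a chromosome end.

## Reference pattern and genome scan

The reference concatenates the first 400 nt of the four smoothed-track
metagenes (default track order: the 5′-aligned 20–50 nt track, then the
three 3′-aligned longer fractions), each segment standardised to mean 0,
variance 1. Per-track z-scoring is the default because raw concatenation
lets the deepest library dominate the Pearson statistic; raw mode is
implemented and selectable, and the mode is recorded in the reference
metadata and must match between reference and scan. Anchors whose window
leaves the chromosome are skipped, not zero-padded (padding would bias the
template tail).

Every position on each strand is scored by assembling the test vector
exactly as a single-anchor reference would be (same orientation rule, same
per-track normalisation, degenerate windows → zeros) and correlating it
with the reference. The production scan uses running window moments and
FFT cross-correlation; a direct per-position Pearson implementation ships
in the package as the oracle, and the two agree to better than 10⁻⁹ over a
50-kb genome. Zero-variance windows score 0, not NaN, so peak calling
needs no special cases. Scores at positions within one window of the
relevant chromosome edge are 0 and flagged invalid.

## Peak calling and thresholding

Peak candidates are strict local maxima (leftmost index of a flat run
higher than both flanks); candidates are processed in descending height,
keeping one only if every kept peak is more than 50 bp away. An exhaustive
brute-force reference implementation is used to validate this routine
position-for-position on random curves.

**Height threshold.** The canonical fixed height is 0.34 with minimum peak
distance 50 bp, and a fixed-threshold mode retains exactly that behaviour.
The default mode instead calibrates the threshold on the data to a target
false-discovery rate of 10⁻³, for a reason visible in the synthetic data:
a correlation height tuned on one dataset does not transfer to data with a
different depth and noise structure. Partial template matches (the
template's own autocorrelation side lobes, e.g. at ~+83 bp where the
170–500 nt plateau onset aligns with the 50–170 nt one) and sparse
background windows amplified by per-window z-scoring both reach r ≈ 0.4–0.6
here, well above 0.34, while true matches sit at 0.6–0.9. The
false-discovery rate is the quantity one actually wants controlled, so it
is the default criterion, with 0.34 as the floor of the threshold grid.

Calibration builds null curves by circularly rotating every (track,
strand, chromosome) array independently — destroying the cross-track joint
pattern while preserving each track's marginal autocorrelation — and
estimates FDR(h) = (1 + total null peak count) / (R × observed count),
read filter applied to both sides. The add-one pseudocount mirrors the
standard empirical-p rule: a finite null ensemble can bound, but never
certify, a zero false-discovery rate. When the certificate is
resolution-limited (clean null but 1/(R × observed) above target) the
rotation count R grows adaptively (12 → 48 cap); when no grid point
reaches the target — e.g. on background-only data, where the measurable
FDR is ~1 everywhere — the grid maximum is returned with a warning, which
on null data correctly yields zero calls. The estimator is conservative:
in crowded genomes the rotation null is strong and the calibrated
threshold rises (≈0.66 on the sparse basic scenario, ≈0.76 on the dense
divergent scenario), trading sensitivity for specificity exactly as an
FDR criterion should.

**Read filter.** Calls with fewer than 10 raw reads in the strand-oriented
downstream 100 nt, summed over the four matched tracks, are dropped. Raw
(not smoothed) values are used: a count threshold implies counts. This
absolute cutoff intentionally breaks scale invariance (doubling coverage
can only add calls); the correlation stage itself is scale-free to 10⁻⁹.

## Annotation and artifact removal

A call is assigned the nearest same-strand annotation with |distance|
strictly below 70 bp; ties break by class priority (coding, then the
noncoding classes CUT, SUT, XUT, NUT, snRNA, other) and then id, and the
tie-break is logged. Cleavage-artifact screening applies only to
unannotated calls — a call near a polyadenylation or splice site is a free
5′ end generated co-transcriptionally, not initiation — with PAS checked
before splice so double matches count as PAS. Every filter's input/output
counts are reported so the arithmetic of a run can be audited.

## Architecture statistics

* **Up/downstream log-ratio**: log₂((down + 1)/(up + 1)) over 100-nt
  strand-oriented windows; genuine initiation sites are strongly positive,
  background is centred at 0. The window size mirrors the read-filter
  window; it is configurable.
* **KS test**: D is the supremum ECDF difference; p comes from the
  asymptotic Kolmogorov distribution at √(nm/(n+m))·D. At n = m = 20 this
  sits within 0.016 of a 100 000-permutation p (measured over 50 random
  instances); a seeded permutation mode is provided for small samples.
* **Co-occurrence Fisher**: per gene, "upstream present" means ≥1 call on
  the antisense strand within 400 bp upstream of the PAS, "downstream
  present" ≥1 sense call within 400 bp downstream (the 400-nt extent
  matches the density windows; configurable). The one-sided p is the
  upper hypergeometric tail computed with log-gamma in log space;
  log₁₀ p is returned alongside p and stays finite (≈ −300 and beyond)
  when p underflows a double. The upper tail is the enrichment direction
  (units occurring in pairs).
* **Feature screen**: per-feature two-sample KS between two region groups;
  significance at p < α (default 10⁻⁵); the E-value α × n_features
  (0.015 for 1453 features) is the number of features expected to pass by
  chance. A row-subset argument supports expression-matched regrouping.
* **Signal enrichment**: observed group metagene vs per-offset 1%/50%/99%
  quantiles of 500 same-size draws from the anchor universe (without
  replacement); the statistic is the metagene maximum over [0, 100) bp
  downstream (where roadblock-factor binding concentrates); the empirical
  p uses the add-one rule, is never 0, and its resolution adapts by
  growing the resample count (up to 10⁶) until ~10 exceedances are seen.

## The simulator

`simulate_bundle` draws N ~ Poisson(rate) polymerases per unit; each
draws a nascent length from a mixture (probability 0.3 of the
promoter-proximal zone, uniform on 20–80 nt; otherwise uniform over the
unit length, both truncated at the unit length), deposits one 3′-end count
on the gated fraction track and, for the shortest fraction, one 5′-end
count at the TSS; lengths below 20 or at/above 1000 nt are lost to the
library prep. Per-base Poisson background (default 0.02 reads/base/track)
is added to every raw track on both strands. Identical seed and
configuration give byte-identical bedGraph output.

Canned scenarios: `basic` (200 kb, 100 well-separated units, rates
200–1000), `expression_range` (rates spanning exactly 100×, 200–20000,
floored where units are adequately sampled), `divergent_pairs` (genes with
divergent promoter partners at −200 and strongly correlated PAS-flanking
partners at −60 antisense / +150 sense), `tandem_overlap` (read-through
tandem pairs) and `null` (background only).

What the simulator does **not** emulate, and what that means for the
tests: all units share one occupancy law, so promoters have no shape
heterogeneity — correlation heights then differ only through sampling
noise and necessarily rank-correlate with depth (measured Spearman ρ ≈ 0.7
across a 100× rate range), whereas in real data heights reflect how
template-like each promoter is. Passing tests therefore demonstrate
localisation, specificity and statistical calibration, not the empirical
rate-independence of heights seen in real libraries. Real 20–50 nt
degradation background has spatial structure that is modelled only as
uniform noise; elongation kinetics beyond the proximal bump, sequence-level
reads, and alignment artifacts are out of scope.

## Known limitations

* Unit 3′ ends (termination) are not inferred; the matched window defines
  only the TSS.
* FDR certification needs enough discoveries: with fewer than
  ~1/(target_fdr × R_max) observed peaks the calibrator cannot certify the
  target and falls back to the grid maximum (reported with a warning);
  use the fixed-threshold mode for tiny datasets.
* Opposite-strand peaks never suppress each other; divergent pairs closer
  than 50 bp are reported on both strands.
* Minus-strand bedGraphs are read and written with non-negative values;
  dialects using negative values need a sign flip upstream.
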