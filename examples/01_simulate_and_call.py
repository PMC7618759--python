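"""Simulate size-fraction tracks with planted transcription units and
call their TSSs back.

The caller smooths each fraction track with a zero-phase Butterworth
low-pass, builds a 4 x 400 nt concatenated metagene template anchored at
the annotated TSSs, slides it over the genome computing a Pearson
correlation at every base on both strands, keeps correlation peaks above
an FDR-calibrated height, and discards peaks with fewer than 10 raw
reads in the downstream 100 nt.
"""

from sfnet import smoothing
from sfnet.caller import CallerParams, call_tss
from sfnet.reference import build_reference
from sfnet.simulate import (
    make_scenario,
    score_calls,
    simulate_bundle,
    truth_annotations,
)

cfg = make_scenario("basic", seed=1)  # 200 kb, 100 units, background 0.02
bundle, truth = simulate_bundle(cfg)
smoothing.smooth_bundle(bundle)

ref = build_reference(bundle, truth_annotations(truth))
calls = call_tss(bundle, ref, CallerParams(seed=1))
score = score_calls(calls, truth, tol=20)

print(f"planted units : {score['n_truth']}")
print(f"TSS calls     : {score['n_calls']}")
print(f"sensitivity   : {score['sensitivity']:.2f}  (units recovered within +/-20 bp)")
print(f"precision     : {score['precision']:.2f}  (calls within +/-20 bp of a unit)")
print(f"first call    : {calls[0].chrom}:{calls[0].pos} ({calls[0].strand}) "
      f"height {calls[0].height:.2f}, {calls[0].downstream_reads:.0f} downstream reads")
# Sensitivity near 1 with precision 1 means the concatenated-fraction
# template localises initiation sites without calling background noise.
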