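"""Resampling test: is a ChIP-like signal enriched over a gene group?

A +40 bp signal bump is planted downstream of 30 of 120 anchor sites.
The observed group metagene is compared with 500 random same-size draws
from all anchors (1%/50%/99% bands), and the maximum over the first
100 bp downstream is the test statistic with an add-one empirical p.
"""

import numpy as np

from sfnet.archstats import EnrichmentParams, signal_enrichment
from sfnet.genome_io import GenomeCoords, StrandedTrack

rng = np.random.default_rng(9)
coords = GenomeCoords.from_dict({"c": 200_000})
pair = {s: StrandedTrack(coords, s) for s in "+-"}
pair["+"].values["c"] = rng.poisson(2.0, 200_000).astype(float)
pair["-"].values["c"] = rng.poisson(2.0, 200_000).astype(float)

universe = [("c", 2000 + i * 1500, "+") for i in range(120)]
group = universe[:30]
for _, pos, _ in group:
    pair["+"].values["c"][pos + 30: pos + 50] += 6.0  # the planted bump

params = EnrichmentParams(seed=5, max_p_sims=20_000)
res = signal_enrichment(pair, group, universe, params)

hw = params.halfwidth
peak_offset = int(np.argmax(res.observed[hw:hw + 100]))
print(f"observed statistic (max over [0,100) bp): {res.statistic:.2f}")
print(f"signal peaks {peak_offset} bp downstream of the anchor")
above = (res.observed[hw:hw + 100] > res.bands[0.99][hw:hw + 100]).sum()
print(f"offsets above the 99% resampling band: {above}/100")
print(f"empirical p = {res.p_value:.2e} over {res.n_sims} resamples "
      f"(floor 1/(N+1) = {1/(res.n_sims+1):.1e})")
# Exceeding the 99% band around +40 with p << 0.01 recovers the planted
# enrichment; on an unenriched group p would be ~uniform.
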