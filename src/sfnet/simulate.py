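"""Synthetic size-fraction track bundles with planted transcription units.

The generative model mirrors what size fractionation of nascent RNA does
to the mapped read positions: a polymerase that has transcribed d
nucleotides from a unit's TSS deposits one 3'-end count at offset d-1,
on the track of the size fraction whose [L, U) interval contains d, so a
fraction's signal can never appear closer than L bases to the TSS (the
"staircase" the caller exploits). The shortest fraction (20-50 nt) is
additionally mapped by its 5' ends, which all pile up at the TSS itself.

Polymerase occupancy is uniform along the unit with an optional
promoter-proximal bump (offsets 20-80); the caller must not depend on the
occupancy law, only on the fraction gating.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_io import (
    DEFAULT_FRACTION_BOUNDS,
    DEFAULT_MATCH_ORDER,
    FractionLibrary,
    GeneModel,
    GenomeCoords,
    StrandedTrack,
    TrackBundle,
    write_bedgraph,
)

TRACK_LABELS = ("A5", "A3", "B", "C", "D")
PROXIMAL_ZONE = (20, 80)  # inclusive offsets of the promoter-proximal bump


@dataclass(frozen=True)
class PlantedUnit:
    id: str
    chrom: str
    strand: str
    tss_pos: int
    length: int
    rate: float  # expected polymerase count (Poisson lambda)
    klass: str = "coding"  # {coding, noncoding}

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("unit length must be >= 1")
        if self.rate < 0:
            raise ValueError("rate must be >= 0")

    @property
    def pas_pos(self) -> int:
        return self.tss_pos + self.length - 1 if self.strand == "+" else self.tss_pos - self.length + 1


@dataclass
class SimConfig:
    coords: GenomeCoords
    units: list[PlantedUnit]
    fraction_bounds: tuple[tuple[int, int], ...] = DEFAULT_FRACTION_BOUNDS
    background_rate: float = 0.02  # expected reads per base per track
    proximal_frac: float = 0.3
    tss_jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo = 0
        for a, b in self.fraction_bounds:
            if not lo <= a < b:
                raise ValueError("fraction bounds must be ascending and non-overlapping")
            lo = b
        if self.background_rate < 0 or not 0 <= self.proximal_frac <= 1:
            raise ValueError("rates must be non-negative, proximal_frac in [0,1]")
        for u in self.units:
            length = self.coords.length_of(u.chrom)
            if not 0 <= u.tss_pos < length:
                raise ValueError(f"{u.id}: TSS outside chromosome")
            if not 0 <= u.pas_pos < length:
                raise ValueError(f"{u.id}: unit exceeds chromosome")


def simulate_bundle(config: SimConfig) -> tuple[TrackBundle, pd.DataFrame]:
    """Generate raw tracks and the planted-truth table.

    Per unit, N ~ Poisson(rate) polymerases each draw a nascent length d
    (promoter-proximal uniform 20..80 with probability ``proximal_frac``,
    else uniform 1..length; both truncated at the unit length). Each d
    contributes one 3'-end count at the strand-oriented position
    tss + d - 1 on the fraction track whose [L, U) contains d; d in the
    shortest fraction also contributes one 5'-end count at the TSS on the
    A5 track. d below the smallest or at/above the largest bound is lost
    to the library prep. Poisson background is then added per base to
    every raw track on both strands.
    """
    rng = np.random.default_rng([int(config.seed) % (2**31), 1])
    coords = config.coords
    tracks = {
        label: {s: StrandedTrack.zeros(coords, s) for s in "+-"} for label in TRACK_LABELS
    }
    bounds = config.fraction_bounds
    frac_labels = ("A3", "B", "C", "D")
    d_min = bounds[0][0]
    d_max = bounds[-1][1]

    rows = []
    for unit in config.units:
        n = rng.poisson(unit.rate)
        rows.append(
            dict(
                id=unit.id, chrom=unit.chrom, strand=unit.strand, tss_pos=unit.tss_pos,
                length=unit.length, rate=unit.rate, klass=unit.klass, n_polymerases=int(n),
            )
        )
        if n == 0:
            continue
        proximal = rng.random(n) < config.proximal_frac
        d = rng.integers(1, unit.length + 1, size=n)
        if proximal.any():
            d_prox = rng.integers(PROXIMAL_ZONE[0], PROXIMAL_ZONE[1] + 1, size=int(proximal.sum()))
            d[proximal] = np.minimum(d_prox, unit.length)
        if config.tss_jitter_sd > 0:
            jitter = np.rint(rng.normal(0.0, config.tss_jitter_sd, size=n)).astype(int)
        else:
            jitter = np.zeros(n, dtype=int)
        sign = 1 if unit.strand == "+" else -1
        tss_eff = unit.tss_pos + sign * jitter
        end_pos = tss_eff + sign * (d - 1)
        length = coords.length_of(unit.chrom)
        in_range = (d >= d_min) & (d < d_max) & (end_pos >= 0) & (end_pos < length)
        in_range &= (tss_eff >= 0) & (tss_eff < length)
        for (lo, hi), label in zip(bounds, frac_labels):
            sel = in_range & (d >= lo) & (d < hi)
            if not sel.any():
                continue
            np.add.at(tracks[label][unit.strand].values[unit.chrom], end_pos[sel], 1.0)
            if label == "A3":  # shortest fraction: 5' ends map to the TSS
                np.add.at(tracks["A5"][unit.strand].values[unit.chrom], tss_eff[sel], 1.0)

    if config.background_rate > 0:
        for label in TRACK_LABELS:
            for strand in "+-":
                for chrom, length in coords.items():
                    tracks[label][strand].values[chrom] += rng.poisson(
                        config.background_rate, size=length
                    )

    size_of = {"A5": bounds[0], "A3": bounds[0], "B": bounds[1], "C": bounds[2], "D": bounds[3]}
    libraries = {
        label: FractionLibrary(
            label=label,
            size_range=size_of[label],
            end_aligned="5prime" if label == "A5" else "3prime",
            raw=tracks[label],
        )
        for label in TRACK_LABELS
    }
    bundle = TrackBundle(libraries, match_order=DEFAULT_MATCH_ORDER)
    truth = pd.DataFrame(
        rows,
        columns=["id", "chrom", "strand", "tss_pos", "length", "rate", "klass", "n_polymerases"],
    )
    return bundle, truth


# ---------------------------------------------------------------------------
# Canned scenarios


SCENARIOS = ("basic", "divergent_pairs", "tandem_overlap", "expression_range", "null")


def make_scenario(name: str, seed: int = 1) -> SimConfig:
    """Canned configurations reproducing the transcription architectures
    the pipeline is meant to resolve.

    basic
        200-kb genome, 100 well-separated units on both strands, rates
        200-1000 expected polymerases, background 0.02 reads/base/track.
    divergent_pairs
        Coding genes with antisense noncoding partners upstream of the
        TSS (-200) and flanking the PAS (antisense at -60, tandem sense
        coding at +150), planted with correlated presence.
    tandem_overlap
        Tandem same-strand gene pairs whose upstream unit reads through
        the downstream unit's TSS.
    expression_range
        Unit rates spanning exactly two orders of magnitude.
    null
        Background noise only.
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    rng = np.random.default_rng([int(seed) % (2**31), 0])

    if name == "null":
        coords = GenomeCoords.from_dict({"chrS": 100_000})
        return SimConfig(coords=coords, units=[], seed=seed)

    if name == "basic":
        coords = GenomeCoords.from_dict({"chrS": 200_000})
        units = []
        for i in range(100):
            strand = "+" if rng.random() < 0.5 else "-"
            length = int(rng.integers(800, 1500))
            anchor = 1000 + i * 1980 + int(rng.integers(-150, 150))
            tss = anchor if strand == "+" else anchor + length - 1
            units.append(
                PlantedUnit(
                    id=f"U{i:03d}", chrom="chrS", strand=strand, tss_pos=tss,
                    length=length, rate=float(rng.integers(200, 1000)),
                    klass="coding" if rng.random() < 0.6 else "noncoding",
                )
            )
        return SimConfig(coords=coords, units=units, seed=seed)

    if name == "expression_range":
        coords = GenomeCoords.from_dict({"chrS": 200_000})
        n = 60
        rates = np.geomspace(200.0, 20000.0, n)  # exactly 100x, floor as in "basic"
        order = rng.permutation(n)
        units = []
        for i in range(n):
            strand = "+" if rng.random() < 0.5 else "-"
            length = int(rng.integers(800, 1500))
            anchor = 1200 + i * 3280 + int(rng.integers(-150, 150))
            tss = anchor if strand == "+" else anchor + length - 1
            units.append(
                PlantedUnit(
                    id=f"E{i:03d}", chrom="chrS", strand=strand, tss_pos=tss,
                    length=length, rate=float(rates[order[i]]), klass="coding",
                )
            )
        return SimConfig(coords=coords, units=units, seed=seed)

    if name == "divergent_pairs":
        coords = GenomeCoords.from_dict({"chrS": 400_000})
        units = []
        n_genes = 100
        for i in range(n_genes):
            g_tss = 2500 + i * 3900
            g_len = 1000
            g_pas = g_tss + g_len - 1
            units.append(
                PlantedUnit(f"G{i:03d}", "chrS", "+", g_tss, g_len, 800.0, "coding")
            )
            # divergent noncoding unit at the gene promoter
            units.append(
                PlantedUnit(f"G{i:03d}div", "chrS", "-", g_tss - 200, 500, 500.0, "noncoding")
            )
            # PAS-flanking partners: strongly correlated presence (the
            # architecture whose co-occurrence the statistics must detect)
            r = rng.random()
            has_up = r < 0.55 or (0.55 <= r < 0.63)
            has_down = r < 0.55 or (0.63 <= r < 0.71)
            if has_up:
                units.append(
                    PlantedUnit(f"G{i:03d}pasUp", "chrS", "-", g_pas - 60, 500, 600.0, "noncoding")
                )
            if has_down:
                units.append(
                    PlantedUnit(f"G{i:03d}pasDn", "chrS", "+", g_pas + 150, 900, 700.0, "coding")
                )
        return SimConfig(coords=coords, units=units, seed=seed)

    # tandem_overlap
    coords = GenomeCoords.from_dict({"chrS": 200_000})
    units = []
    for i in range(40):
        base = 2000 + i * 4800
        up_len = 2400
        units.append(PlantedUnit(f"T{i:03d}a", "chrS", "+", base, up_len, 500.0, "coding"))
        # downstream unit starting inside the upstream unit's body
        units.append(PlantedUnit(f"T{i:03d}b", "chrS", "+", base + 1400, 1200, 500.0, "coding"))
    return SimConfig(coords=coords, units=units, seed=seed)


def truth_annotations(truth: pd.DataFrame):
    """Planted units as annotation-like anchors (chrom, pos, strand)."""
    return [(r.chrom, int(r.tss_pos), r.strand) for r in truth.itertuples()]


def gene_models_from_truth(truth: pd.DataFrame) -> list[GeneModel]:
    genes = []
    for r in truth.itertuples():
        if r.klass != "coding":
            continue
        if r.strand == "+":
            genes.append(GeneModel(r.id, r.chrom, "+", int(r.tss_pos), int(r.tss_pos + r.length - 1)))
        else:
            genes.append(GeneModel(r.id, r.chrom, "-", int(r.tss_pos), int(r.tss_pos - r.length + 1)))
    return genes


def score_calls(calls, truth: pd.DataFrame, tol: int = 20) -> dict:
    """Sensitivity/precision of a call set against the planted truth.

    A planted unit is recovered if a same-strand call lies within ``tol``
    bp of its TSS; a call is a true positive if it lies within ``tol`` of
    any same-strand planted TSS.
    """
    truth_pos: dict[tuple[str, str], np.ndarray] = {}
    for (chrom, strand), grp in truth.groupby(["chrom", "strand"]):
        truth_pos[(chrom, strand)] = np.sort(grp["tss_pos"].to_numpy())
    call_pos: dict[tuple[str, str], list[int]] = {}
    for c in calls:
        call_pos.setdefault((c.chrom, c.strand), []).append(c.pos)

    n_truth = len(truth)
    recovered = 0
    for key, tpos in truth_pos.items():
        cpos = np.sort(call_pos.get(key, []))
        for t in tpos:
            if len(cpos) and np.min(np.abs(cpos - t)) <= tol:
                recovered += 1
    tp_calls = 0
    n_calls = len(list(calls))
    for key, cs in call_pos.items():
        tpos = truth_pos.get(key, np.empty(0))
        for c in cs:
            if len(tpos) and np.min(np.abs(tpos - c)) <= tol:
                tp_calls += 1
    return {
        "n_truth": n_truth,
        "n_calls": n_calls,
        "recovered": recovered,
        "sensitivity": recovered / n_truth if n_truth else float("nan"),
        "precision": tp_calls / n_calls if n_calls else float("nan"),
    }


def write_simulation(bundle: TrackBundle, truth: pd.DataFrame, outdir) -> None:
    """Write raw tracks as bedGraph plus the truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for label, lib in bundle.libraries.items():
        for strand, suffix in (("+", "plus"), ("-", "minus")):
            write_bedgraph(lib.raw[strand], outdir / f"{label}.{suffix}.bedgraph")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
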