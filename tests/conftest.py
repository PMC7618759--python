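import numpy as np
import pytest

from sfnet import smoothing
from sfnet.genome_io import FractionLibrary, GenomeCoords, StrandedTrack, TrackBundle
from sfnet.reference import build_reference
from sfnet.simulate import make_scenario, simulate_bundle, truth_annotations


def make_bundle(coords: GenomeCoords, arrays: dict[str, dict[str, dict[str, np.ndarray]]] | None = None,
                labels=("A5", "B", "C", "D")) -> TrackBundle:
    """Hand-built bundle; arrays[label][strand][chrom] overrides zeros."""
    size_of = {"A5": (20, 50), "A3": (20, 50), "B": (50, 170), "C": (170, 500), "D": (500, 1000)}
    libs = {}
    for label in labels:
        raw = {}
        for strand in "+-":
            t = StrandedTrack.zeros(coords, strand)
            if arrays and label in arrays and strand in arrays[label]:
                for chrom, arr in arrays[label][strand].items():
                    t.values[chrom] = np.asarray(arr, dtype=float)
            raw[strand] = t
        libs[label] = FractionLibrary(label, size_of[label],
                                      "5prime" if label == "A5" else "3prime", raw)
    return TrackBundle(libs, tuple(labels[:4]))


@pytest.fixture(scope="session")
def basic_sim():
    """The 200-kb, 100-unit scenario: smoothed bundle, truth, reference."""
    cfg = make_scenario("basic", seed=1)
    bundle, truth = simulate_bundle(cfg)
    smoothing.smooth_bundle(bundle)
    ref = build_reference(bundle, truth_annotations(truth))
    return bundle, truth, ref


@pytest.fixture(scope="session")
def small_sim():
    """A 50-kb simulation with a handful of units, for oracle comparisons."""
    from sfnet.simulate import PlantedUnit, SimConfig

    coords = GenomeCoords.from_dict({"chrS": 50_000})
    rng = np.random.default_rng(42)
    units = []
    for i in range(12):
        strand = "+" if i % 2 else "-"
        length = int(rng.integers(800, 1400))
        anchor = 1500 + i * 3900
        tss = anchor if strand == "+" else anchor + length - 1
        units.append(PlantedUnit(f"S{i:02d}", "chrS", strand, tss, length,
                                 float(rng.integers(300, 900)), "coding"))
    cfg = SimConfig(coords=coords, units=units, seed=7)
    bundle, truth = simulate_bundle(cfg)
    smoothing.smooth_bundle(bundle)
    ref = build_reference(bundle, truth_annotations(truth))
    return bundle, truth, ref
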