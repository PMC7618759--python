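"""Reference-pattern construction: per-track metagenes anchored at
annotated TSS, concatenated over the first 400 nt downstream.

Each size-fraction library contributes one 400-nt metagene segment; the
concatenation of the four segments (in the bundle's match order) is the
template the genome scan correlates against. Segments are z-scored per
track by default so that the deepest library does not dominate the
Pearson statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome_io import StrandedTrack, TrackBundle

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 400
_VAR_TOL = 1e-18  # below this a segment/window counts as degenerate


@dataclass
class ReferencePattern:
    window: int
    track_order: tuple[str, ...]
    segments: dict[str, np.ndarray]
    normalization: str  # {"ztrack", "raw"}
    n_anchors_used: int

    def __post_init__(self) -> None:
        if len(self.segments) != 4:
            raise ValueError("reference needs exactly 4 segments")
        for label, seg in self.segments.items():
            if len(seg) != self.window:
                raise ValueError(f"segment {label} length != window")

    def concat(self) -> np.ndarray:
        return np.concatenate([self.segments[l] for l in self.track_order])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# window={self.window}\n")
            fh.write(f"# track_order={','.join(self.track_order)}\n")
            fh.write(f"# normalization={self.normalization}\n")
            fh.write(f"# n_anchors_used={self.n_anchors_used}\n")
            fh.write("offset\t" + "\t".join(self.track_order) + "\n")
            for i in range(self.window):
                vals = "\t".join(repr(float(self.segments[l][i])) for l in self.track_order)
                fh.write(f"{i}\t{vals}\n")

    @classmethod
    def from_tsv(cls, path) -> "ReferencePattern":
        meta: dict[str, str] = {}
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("#"):
                    key, _, val = line[1:].strip().partition("=")
                    meta[key.strip()] = val.strip()
                elif line and not line.startswith("offset"):
                    rows.append([float(x) for x in line.split("\t")])
        arr = np.asarray(rows)
        order = tuple(meta["track_order"].split(","))
        segments = {l: arr[:, i + 1].copy() for i, l in enumerate(order)}
        return cls(
            window=int(meta["window"]),
            track_order=order,
            segments=segments,
            normalization=meta["normalization"],
            n_anchors_used=int(meta["n_anchors_used"]),
        )


def oriented_window(track_pair: dict[str, StrandedTrack], chrom: str, pos: int,
                    strand: str, window: int) -> np.ndarray | None:
    """The strand-oriented window with offset 0 at the anchor base.

    + strand: values at pos..pos+window-1 on the + track;
    - strand: values at pos, pos-1, .. pos-window+1 on the - track
    (read right-to-left, so offset k is k bases downstream in the
    transcription direction on both strands). Returns None if the window
    leaves the chromosome.
    """
    arr = track_pair[strand].values.get(chrom)
    if arr is None:
        return None
    if strand == "+":
        if pos < 0 or pos + window > len(arr):
            return None
        return arr[pos:pos + window]
    if pos - window + 1 < 0 or pos >= len(arr):
        return None
    return arr[pos - window + 1:pos + 1][::-1]


def metagene(track_pair: dict[str, StrandedTrack], anchors, window: int = DEFAULT_WINDOW
             ) -> tuple[np.ndarray, int, int]:
    """Elementwise mean of the oriented windows over usable anchors.

    ``anchors`` is an iterable of (chrom, pos, strand). Anchors whose
    window leaves the chromosome are skipped (not zero-padded, which
    would bias the template tail) and counted. Returns
    (metagene, n_used, n_skipped).
    """
    acc = np.zeros(window)
    used = skipped = 0
    for chrom, pos, strand in anchors:
        w = oriented_window(track_pair, chrom, int(pos), strand, window)
        if w is None:
            skipped += 1
            continue
        acc += w
        used += 1
    if used == 0:
        raise ValueError("no usable anchors (all windows leave the chromosome)")
    return acc / used, used, skipped


def zscore_segment(seg: np.ndarray) -> np.ndarray:
    """Standardise to mean 0, population variance 1; an (effectively)
    constant segment maps to all zeros."""
    mu = seg.mean()
    var = ((seg - mu) ** 2).mean()
    if var <= _VAR_TOL:
        return np.zeros_like(seg)
    return (seg - mu) / np.sqrt(var)


def build_reference(bundle: TrackBundle, anchors, window: int = DEFAULT_WINDOW,
                    normalization: str = "ztrack") -> ReferencePattern:
    """Build the concatenated reference pattern from a smoothed bundle."""
    if normalization not in ("ztrack", "raw"):
        raise ValueError("normalization must be 'ztrack' or 'raw'")
    if not bundle.is_smoothed():
        raise ValueError("bundle must be smoothed before building a reference")
    anchors = list(anchors)
    if not anchors:
        raise ValueError("anchor list is empty")
    segments: dict[str, np.ndarray] = {}
    n_used = 0
    for label in bundle.match_order:
        lib = bundle.libraries[label]
        seg, used, _ = metagene(lib.smoothed, anchors, window)
        n_used = used
        if normalization == "ztrack":
            z = zscore_segment(seg)
            if not z.any() and seg.size:
                logger.warning("reference segment %s has zero variance; stored as zeros", label)
            seg = z
        segments[label] = seg
    return ReferencePattern(
        window=window,
        track_order=bundle.match_order,
        segments=segments,
        normalization=normalization,
        n_anchors_used=n_used,
    )
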