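"""Coordinate model, stranded coverage tracks and annotation I/O.

Conventions shared by every module:

* coordinates are 0-based, half-open, matching bedGraph;
* each strand of each size fraction lives in its own track, and
  minus-strand values are stored non-negative;
* a "track pair" is the (+, -) pair of :class:`StrandedTrack` for one
  library.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

STRANDS = ("+", "-")

#: closed set of annotation classes (yeast noncoding transcript families
#: plus coding and a catch-all).
ANNOTATION_CLASSES = (
    "coding",
    "CUT",
    "SUT",
    "XUT",
    "NUT",
    "snRNA",
    "other_noncoding",
)

#: tie-break priority when a call is equidistant from two annotations.
CLASS_PRIORITY = {k: i for i, k in enumerate(ANNOTATION_CLASSES)}


class BedGraphError(ValueError):
    """Malformed or inconsistent bedGraph input."""


@dataclass(frozen=True)
class GenomeCoords:
    """Ordered chromosome names and lengths."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(set(self.chrom_names)):
            raise ValueError("duplicate chromosome names")
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("names/lengths mismatch")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")

    @classmethod
    def from_dict(cls, lengths: Mapping[str, int]) -> "GenomeCoords":
        return cls(tuple(lengths), tuple(lengths.values()))

    def length_of(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[self.chrom_names.index(chrom)]
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_names

    def items(self):
        return zip(self.chrom_names, self.chrom_lengths)


@dataclass
class StrandedTrack:
    """Dense per-base coverage for one strand of a genome."""

    coords: GenomeCoords
    strand: str
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for chrom, length in self.coords.items():
            arr = self.values.get(chrom)
            if arr is None:
                self.values[chrom] = np.zeros(length, dtype=float)
            elif len(arr) != length:
                raise ValueError(
                    f"{chrom}: array length {len(arr)} != chromosome length {length}"
                )

    @classmethod
    def zeros(cls, coords: GenomeCoords, strand: str) -> "StrandedTrack":
        return cls(coords, strand)

    def copy(self) -> "StrandedTrack":
        return StrandedTrack(
            self.coords, self.strand, {c: v.copy() for c, v in self.values.items()}
        )

    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))


@dataclass
class FractionLibrary:
    """One size fraction: raw (and optionally smoothed) track pair.

    ``label`` is one of A5/A3/B/C/D; A5 and A3 are the 5'- and 3'-end
    alignments of the shortest (20-50 nt) fraction, B/C/D are the
    3'-end-aligned longer fractions.
    """

    label: str
    size_range: tuple[int, int]
    end_aligned: str  # "5prime" | "3prime"
    raw: dict[str, StrandedTrack]
    smoothed: dict[str, StrandedTrack] | None = None

    def __post_init__(self) -> None:
        if self.end_aligned not in ("5prime", "3prime"):
            raise ValueError("end_aligned must be 5prime or 3prime")
        if set(self.raw) != set(STRANDS):
            raise ValueError("raw must hold one track per strand")
        lo, hi = self.size_range
        if not 0 < lo < hi:
            raise ValueError("size_range must be an ascending positive interval")


DEFAULT_FRACTION_BOUNDS = ((20, 50), (50, 170), (170, 500), (500, 1000))
DEFAULT_MATCH_ORDER = ("A5", "B", "C", "D")


@dataclass
class TrackBundle:
    """Ordered set of fraction libraries used for pattern matching."""

    libraries: dict[str, FractionLibrary]
    match_order: tuple[str, ...] = DEFAULT_MATCH_ORDER

    def __post_init__(self) -> None:
        self.match_order = tuple(self.match_order)
        if len(self.match_order) != 4 or len(set(self.match_order)) != 4:
            raise ValueError("match_order must list exactly 4 distinct labels")
        missing = [l for l in self.match_order if l not in self.libraries]
        if missing:
            raise ValueError(f"match_order labels missing from bundle: {missing}")

    @property
    def coords(self) -> GenomeCoords:
        first = next(iter(self.libraries.values()))
        return first.raw["+"].coords

    def match_libraries(self) -> list[FractionLibrary]:
        return [self.libraries[l] for l in self.match_order]

    def is_smoothed(self) -> bool:
        return all(self.libraries[l].smoothed is not None for l in self.match_order)


@dataclass(frozen=True)
class AnnotationRecord:
    id: str
    chrom: str
    strand: str
    tss_pos: int
    klass: str = "other_noncoding"

    def __post_init__(self) -> None:
        if self.klass not in ANNOTATION_CLASSES:
            raise ValueError(f"unknown annotation class {self.klass!r}")


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding transcription unit with TSS and PAS.

    On the + strand ``tss_pos < pas_pos``; on the - strand the gene is
    read right-to-left so ``tss_pos > pas_pos``.
    """

    id: str
    chrom: str
    strand: str
    tss_pos: int
    pas_pos: int

    def __post_init__(self) -> None:
        if self.strand == "+" and not self.tss_pos < self.pas_pos:
            raise ValueError(f"{self.id}: + strand gene needs tss < pas")
        if self.strand == "-" and not self.tss_pos > self.pas_pos:
            raise ValueError(f"{self.id}: - strand gene needs tss > pas")


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(path, coords: GenomeCoords, strand: str) -> StrandedTrack:
    """Expand a 4-column bedGraph into a dense per-base track.

    Intervals must not overlap; overlapping input is rejected rather than
    summed, because genomecov output is non-overlapping and silent summing
    would hide corrupt input. ``track``/``#`` header lines are skipped.
    """
    track = StrandedTrack.zeros(coords, strand)
    last_end: dict[str, int] = {}
    seen: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise BedGraphError(f"{path}:{lineno}: expected 4 columns")
            chrom, start_s, end_s, value_s = parts[:4]
            if chrom not in coords:
                raise BedGraphError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            try:
                start, end, value = int(start_s), int(end_s), float(value_s)
            except ValueError as exc:
                raise BedGraphError(f"{path}:{lineno}: {exc}") from None
            length = coords.length_of(chrom)
            if start < 0 or end > length or start >= end:
                raise BedGraphError(
                    f"{path}:{lineno}: interval [{start},{end}) outside [0,{length})"
                )
            if value < 0:
                raise BedGraphError(f"{path}:{lineno}: negative value {value}")
            arr = track.values[chrom]
            if np.any(arr[start:end] != 0) and _overlaps(seen.setdefault(chrom, []), start, end):
                raise BedGraphError(f"{path}:{lineno}: overlapping interval")
            seen.setdefault(chrom, []).append((start, end))
            arr[start:end] = value
    return track


def _overlaps(intervals: list[tuple[int, int]], start: int, end: int) -> bool:
    return any(s < end and start < e for s, e in intervals)


def write_bedgraph(track: StrandedTrack, path) -> None:
    """Write maximal equal-value non-zero runs as bedGraph intervals."""
    with open(path, "w") as fh:
        for chrom, _ in track.coords.items():
            arr = track.values[chrom]
            for start, end, value in _runs(arr):
                fh.write(f"{chrom}\t{start}\t{end}\t{_fmt(value)}\n")


def _runs(arr: np.ndarray) -> Iterable[tuple[int, int, float]]:
    if len(arr) == 0:
        return
    change = np.flatnonzero(np.diff(arr) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [len(arr)]))
    for s, e in zip(starts, ends):
        v = arr[s]
        if v != 0:
            yield int(s), int(e), float(v)


def _fmt(value: float) -> str:
    if value == int(value):
        return str(int(value))
    return repr(value)


# ---------------------------------------------------------------------------
# BED annotations


def read_tss_bed(path, class_map: Mapping[str, str] | None = None) -> list[AnnotationRecord]:
    """Read a BED6 of annotated transcripts; the TSS is the strand-aware
    5' end of each record.

    ``class_map`` maps name-field prefixes to annotation classes, e.g.
    ``{"CUT": "CUT", "Y": "coding"}``; unmatched names default to
    ``other_noncoding``. Duplicate (chrom, strand, tss) records collapse
    to the first id.
    """
    records: list[AnnotationRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected BED6")
            chrom, start_s, end_s, name, _score, strand = parts[:6]
            if strand not in STRANDS:
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            tss = start if strand == "+" else end - 1
            records.append(
                AnnotationRecord(name, chrom, strand, tss, _classify(name, class_map))
            )
    records.sort(key=lambda r: (r.chrom, r.tss_pos, r.strand, r.id))
    out: list[AnnotationRecord] = []
    seen: set[tuple[str, str, int]] = set()
    for rec in records:
        key = (rec.chrom, rec.strand, rec.tss_pos)
        if key not in seen:
            seen.add(key)
            out.append(rec)
    return out


def _classify(name: str, class_map: Mapping[str, str] | None) -> str:
    if class_map:
        for prefix, klass in class_map.items():
            if name.startswith(prefix):
                return klass
    for klass in ("CUT", "SUT", "XUT", "NUT", "snRNA"):
        if name.startswith(klass):
            return klass
    return "other_noncoding"


def read_gene_models(path) -> list[GeneModel]:
    """Read gene models from BED6 where (start, end) span TSS..PAS
    inclusive in genomic order."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected BED6")
            chrom, start_s, end_s, name, _score, strand = parts[:6]
            if strand not in STRANDS:
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            start, end = int(start_s), int(end_s)
            if end - start < 2:
                raise ValueError(f"{path}:{lineno}: zero-length gene")
            if strand == "+":
                genes.append(GeneModel(name, chrom, strand, start, end - 1))
            else:
                genes.append(GeneModel(name, chrom, strand, end - 1, start))
    genes.sort(key=lambda g: (g.chrom, min(g.tss_pos, g.pas_pos)))
    return genes


def write_tss_bed(records: Sequence, path) -> None:
    """Write TSS-like records (anything with chrom/strand/tss_pos/id) as
    single-base BED6."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(
                f"{rec.chrom}\t{rec.tss_pos}\t{rec.tss_pos + 1}\t{rec.id}\t0\t{rec.strand}\n"
            )
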