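"""Assignment of called TSS to existing annotations, removal of
co-transcriptional cleavage artifacts, and positional-accuracy summaries.

A call is assigned the identity of the nearest same-strand annotation
strictly closer than 70 bp (the signed distance is reported in the
transcription direction). Unannotated calls that sit near a known
polyadenylation or splice site are treated as RNA-cleavage artifacts —
free 5' ends generated co-transcriptionally, not initiation events — and
removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .caller import TssCall
from .genome_io import CLASS_PRIORITY, AnnotationRecord

logger = logging.getLogger(__name__)

DEFAULT_MAX_DIST = 70


@dataclass(frozen=True)
class LabelledCall:
    call: TssCall
    assigned_id: str | None
    assigned_klass: str  # annotation class or "unannotated"
    signed_distance: int | None  # call - annotation, transcription direction

    @property
    def chrom(self):
        return self.call.chrom

    @property
    def strand(self):
        return self.call.strand

    @property
    def pos(self):
        return self.call.pos


def assign_annotations(calls, annotations, max_dist: int = DEFAULT_MAX_DIST) -> list[LabelledCall]:
    """Label each call with its nearest same-strand annotation within
    ``max_dist`` (strict).

    Ties in |distance| break by class priority (coding first, then CUT,
    SUT, XUT, NUT, snRNA, other), then lexicographic id. Annotations may
    label several calls.
    """
    by_key: dict[tuple[str, str], list[AnnotationRecord]] = {}
    for a in annotations:
        by_key.setdefault((a.chrom, a.strand), []).append(a)
    for recs in by_key.values():
        recs.sort(key=lambda r: r.tss_pos)
    out: list[LabelledCall] = []
    for call in calls:
        recs = by_key.get((call.chrom, call.strand), [])
        best = None
        for rec in recs:  # lists are small; linear scan keeps ties exact
            d = abs(call.pos - rec.tss_pos)
            if d >= max_dist:
                continue
            key = (d, CLASS_PRIORITY[rec.klass], rec.id)
            if best is None or key < best[0]:
                best = (key, rec)
        if best is None:
            out.append(LabelledCall(call, None, "unannotated", None))
        else:
            rec = best[1]
            signed = call.pos - rec.tss_pos if call.strand == "+" else rec.tss_pos - call.pos
            if best[0][0] == abs(call.pos - rec.tss_pos) and _tie_count(recs, call.pos, best[0][0]) > 1:
                logger.debug("tie at %s:%d broken by class priority", call.chrom, call.pos)
            out.append(LabelledCall(call, rec.id, rec.klass, int(signed)))
    return out


def _tie_count(recs, pos: int, dist: int) -> int:
    return sum(1 for r in recs if abs(pos - r.tss_pos) == dist)


def remove_cleavage_artifacts(labelled, pas_sites, splice_sites,
                              max_dist: int = DEFAULT_MAX_DIST
                              ) -> tuple[list[LabelledCall], list[LabelledCall], list[LabelledCall]]:
    """Split unannotated calls near known PAS/splice sites out of the
    call set; assigned calls are never touched. PAS is checked before
    splice, so a call near both counts as a PAS artifact.

    Site lists are iterables of (chrom, pos, strand).
    """
    pas = _site_index(pas_sites)
    splice = _site_index(splice_sites)
    kept, removed_pas, removed_splice = [], [], []
    for lc in labelled:
        if lc.assigned_klass != "unannotated":
            kept.append(lc)
        elif _near(pas, lc, max_dist):
            removed_pas.append(lc)
        elif _near(splice, lc, max_dist):
            removed_splice.append(lc)
        else:
            kept.append(lc)
    return kept, removed_pas, removed_splice


def _site_index(sites) -> dict[tuple[str, str], np.ndarray]:
    idx: dict[tuple[str, str], list[int]] = {}
    for chrom, pos, strand in sites:
        idx.setdefault((chrom, strand), []).append(int(pos))
    return {k: np.sort(v) for k, v in idx.items()}


def _near(idx, lc: LabelledCall, max_dist: int) -> bool:
    pos = idx.get((lc.chrom, lc.strand))
    if pos is None or len(pos) == 0:
        return False
    return bool(np.min(np.abs(pos - lc.pos)) < max_dist)


def deviation_histogram(labelled, bin_width: int = 5,
                        max_dist: int = DEFAULT_MAX_DIST) -> dict[str, dict]:
    """Per-class histogram of signed call-annotation distances over
    [-max_dist, max_dist), with median and modal bin centre."""
    edges = np.arange(-max_dist, max_dist + bin_width, bin_width)
    out: dict[str, dict] = {}
    by_klass: dict[str, list[int]] = {}
    for lc in labelled:
        if lc.signed_distance is not None:
            by_klass.setdefault(lc.assigned_klass, []).append(lc.signed_distance)
    for klass, dists in by_klass.items():
        d = np.asarray(dists)
        counts, _ = np.histogram(d, bins=edges)
        mode_bin = int(np.argmax(counts))
        out[klass] = {
            "edges": edges,
            "counts": counts,
            "n": len(d),
            "median": float(np.median(d)),
            "mode": float((edges[mode_bin] + edges[mode_bin + 1]) / 2),
            "sd": float(d.std()),
        }
    return out


def classify_summary(labelled) -> pd.DataFrame:
    """Counts and fractions per assigned class, plus coding / noncoding /
    unannotated totals."""
    rows = []
    n = len(list(labelled))
    counts: dict[str, int] = {}
    for lc in labelled:
        counts[lc.assigned_klass] = counts.get(lc.assigned_klass, 0) + 1
    for klass in sorted(counts):
        rows.append({"group": klass, "count": counts[klass],
                     "fraction": counts[klass] / n if n else 0.0})
    coding = counts.get("coding", 0)
    unann = counts.get("unannotated", 0)
    noncoding = n - coding - unann
    for name, c in (("total_coding", coding), ("total_noncoding_annotated", noncoding),
                    ("total_unannotated", unann)):
        rows.append({"group": name, "count": c, "fraction": c / n if n else 0.0})
    return pd.DataFrame(rows, columns=["group", "count", "fraction"])


def labelled_to_frame(labelled) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": lc.chrom, "strand": lc.strand, "pos": lc.pos,
                "height": lc.call.height, "downstream_reads": lc.call.downstream_reads,
                "assigned_id": lc.assigned_id or "", "assigned_klass": lc.assigned_klass,
                "signed_distance": lc.signed_distance,
            }
            for lc in labelled
        ]
    )
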