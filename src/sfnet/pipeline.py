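"""End-to-end orchestration: file-based configuration, staged execution
with intermediates written to disk, and a reproducibility manifest.

Every intermediate (smoothed tracks, reference pattern, correlation
curve, calls, summaries) is written; the manifest records parameter
values, input checksums, the seed and per-stage record counts so the
filter arithmetic of a run can be audited afterwards.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import archstats
from .annotate import (
    assign_annotations,
    classify_summary,
    labelled_to_frame,
    remove_cleavage_artifacts,
)
from .caller import CallerParams, TssCall, apply_read_filter, correlation_scan, call_tss
from .genome_io import (
    DEFAULT_FRACTION_BOUNDS,
    FractionLibrary,
    GenomeCoords,
    StrandedTrack,
    TrackBundle,
    read_bedgraph,
    read_gene_models,
    read_tss_bed,
    write_bedgraph,
)
from .reference import ReferencePattern, build_reference
from .smoothing import FilterSpec, smooth_bundle

logger = logging.getLogger(__name__)

_SIZE_OF = {"A5": (20, 50), "A3": (20, 50), "B": (50, 170), "C": (170, 500), "D": (500, 1000)}


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass
class RunConfig:
    chrom_lengths: dict[str, int]
    tracks: dict[str, dict[str, str]]  # label -> {"+": path, "-": path}
    tss_annotations: str | None = None
    gene_models: str | None = None
    pas_sites: str | None = None
    splice_sites: str | None = None
    match_order: tuple[str, ...] = ("A5", "B", "C", "D")
    window: int = 400
    normalization: str = "ztrack"
    filter_order: int = 12
    half_power_freq: float = 0.05
    caller: dict = field(default_factory=dict)  # extra CallerParams fields
    seed: int = 0
    outdir: str = "sfnet_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for label in self.match_order:
            if label not in self.tracks:
                raise ConfigError(f"match_order label {label!r} has no track files")
        for label, per_strand in self.tracks.items():
            for strand, path in per_strand.items():
                if not Path(path).exists():
                    raise ConfigError(f"missing track file for {label}{strand}: {path}")
        for name in ("tss_annotations", "gene_models", "pas_sites", "splice_sites"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise ConfigError(f"missing {name} file: {path}")

    def caller_params(self) -> CallerParams:
        return CallerParams(window=self.window, normalization=self.normalization,
                            seed=self.seed, **self.caller)

    def filter_spec(self) -> FilterSpec:
        return FilterSpec(order=self.filter_order, half_power_freq=self.half_power_freq)


def load_bundle(config: RunConfig) -> TrackBundle:
    config.validate()
    coords = GenomeCoords.from_dict(config.chrom_lengths)
    libraries = {}
    for label, per_strand in config.tracks.items():
        raw = {}
        for strand in "+-":
            if strand not in per_strand:
                raise ConfigError(f"track {label} missing strand {strand}")
            raw[strand] = read_bedgraph(per_strand[strand], coords, strand)
        libraries[label] = FractionLibrary(
            label=label, size_range=_SIZE_OF.get(label, (20, 50)),
            end_aligned="5prime" if label == "A5" else "3prime", raw=raw,
        )
    return TrackBundle(libraries, tuple(config.match_order))


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _calls_frame(calls: list[TssCall]):
    import pandas as pd

    return pd.DataFrame(
        [
            {"chrom": c.chrom, "strand": c.strand, "pos": c.pos,
             "height": c.height, "downstream_reads": c.downstream_reads}
            for c in calls
        ],
        columns=["chrom", "strand", "pos", "height", "downstream_reads"],
    )


def run_call(config: RunConfig) -> dict:
    """smooth -> build_reference -> call_tss -> annotate -> summarise,
    writing every intermediate under ``config.outdir``."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {k: v for k, v in dataclasses.asdict(config).items()},
        "inputs": {},
        "stages": {},
    }
    for label, per_strand in config.tracks.items():
        for strand, path in per_strand.items():
            manifest["inputs"][f"{label}{strand}"] = _checksum(path)

    stage = "load"
    try:
        bundle = load_bundle(config)
        manifest["stages"]["load"] = {"tracks": len(bundle.libraries)}

        stage = "smooth"
        spec = config.filter_spec()
        smooth_bundle(bundle, spec)
        for label in bundle.match_order:
            lib = bundle.libraries[label]
            for strand, suffix in (("+", "plus"), ("-", "minus")):
                write_bedgraph(lib.smoothed[strand], out / f"smoothed.{label}.{suffix}.bedgraph")

        stage = "reference"
        if config.tss_annotations is None:
            raise ConfigError("tss_annotations required to build the reference")
        annotations = read_tss_bed(config.tss_annotations)
        anchors = [(a.chrom, a.tss_pos, a.strand) for a in annotations]
        ref = build_reference(bundle, anchors, config.window, config.normalization)
        ref.to_tsv(out / "reference.tsv")
        manifest["stages"]["reference"] = {"anchors_used": ref.n_anchors_used}

        stage = "call"
        params = config.caller_params()
        curve = correlation_scan(bundle, ref, params)
        for strand, suffix in (("+", "plus"), ("-", "minus")):
            t = StrandedTrack(bundle.coords, strand,
                              {c: np.round(np.maximum(curve.scores[(c, strand)], 0.0), 4)
                               for c in bundle.coords.chrom_names})
            write_bedgraph(t, out / f"correlation.{suffix}.bedgraph")
        calls = call_tss(bundle, ref, params)
        _calls_frame(calls).to_csv(out / "calls.tsv", sep="\t", index=False)
        with open(out / "calls.bed", "w") as fh:
            for c in calls:
                fh.write(f"{c.chrom}\t{c.pos}\t{c.pos + 1}\t"
                         f"TSS|{c.height:.3f}|{c.downstream_reads:g}\t0\t{c.strand}\n")
        manifest["stages"]["call"] = {"n_calls": len(calls)}

        stage = "annotate"
        labelled = assign_annotations(calls, annotations)
        site_args = []
        for name in ("pas_sites", "splice_sites"):
            path = getattr(config, name)
            if path is None:
                site_args.append([])
            else:
                recs = read_tss_bed(path)
                site_args.append([(r.chrom, r.tss_pos, r.strand) for r in recs])
        kept, removed_pas, removed_splice = remove_cleavage_artifacts(labelled, *site_args)
        labelled_to_frame(kept).to_csv(out / "calls.annotated.tsv", sep="\t", index=False)
        summary = classify_summary(kept)
        summary.to_csv(out / "class_summary.tsv", sep="\t", index=False)
        manifest["stages"]["annotate"] = {
            "n_labelled": len(labelled),
            "removed_pas": len(removed_pas),
            "removed_splice": len(removed_splice),
            "n_kept": len(kept),
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["seed"] = config.seed
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return {"calls": calls, "labelled": kept, "summary": summary, "manifest": manifest}


def run_stats(config: RunConfig, labelled) -> dict:
    """Architecture statistics over an existing call set: TSS density
    around gene anchors, PAS-flanking co-occurrence, and the up/down
    read-ratio distribution."""
    config.validate()
    if config.gene_models is None:
        raise ConfigError("gene_models required for architecture statistics")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    genes = read_gene_models(config.gene_models)
    bundle = load_bundle(config)

    results: dict = {}
    anchors = [(g.id + ":TSS", g.chrom, g.tss_pos, g.strand) for g in genes]
    anchors += [(g.id + ":PAS", g.chrom, g.pas_pos, g.strand) for g in genes]
    density = archstats.tss_density(anchors, labelled)
    density.to_csv(out / "tss_density.tsv", sep="\t", index=False)
    results["density_pairs"] = len(density)

    table, p, log10p = archstats.cooccurrence_fisher(genes, labelled)
    results["cooccurrence"] = {
        "table": [table.a, table.b, table.c, table.d], "p": p, "log10_p": log10p,
    }

    a5 = bundle.libraries[config.match_order[0]].raw
    ratios = archstats.updown_log_ratio(labelled, a5)
    results["updown_log_ratio_median"] = float(np.median(ratios)) if ratios else None

    with open(out / "stats.json", "w") as fh:
        json.dump(results, fh, indent=2)
    return results
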