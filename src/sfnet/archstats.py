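"""Transcription-architecture statistics downstream of TSS calling.

Covers: up/downstream read-ratio validation of called units, TSS-density
profiles around gene anchors, co-occurrence Fisher tests for the
transcription units flanking polyadenylation sites, the genomic-feature
Kolmogorov-Smirnov screen, and resampling-based signal (e.g. ChIP)
enrichment with quantile bands and an empirical p-value.

The Fisher test is computed in log space with log-gamma so that the
extreme co-occurrence p-values this analysis produces (log10 p near
-300) stay finite even when the p-value itself underflows a double.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .genome_io import GeneModel, StrandedTrack
from .reference import oriented_window

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Up/downstream read ratio


def updown_log_ratio(calls, track_pair: dict[str, StrandedTrack], window: int = 100,
                     pseudocount: float = 1.0) -> list[float]:
    """log2 of (downstream + pc) / (upstream + pc) read totals around each
    call, strand-oriented; a genuine initiation site has much more signal
    downstream than upstream. Calls whose windows leave the chromosome
    are skipped."""
    out = []
    for c in calls:
        down = oriented_window(track_pair, c.chrom, c.pos, c.strand, window)
        if c.strand == "+":
            up = oriented_window(track_pair, c.chrom, c.pos - window, c.strand, window)
        else:
            up = oriented_window(track_pair, c.chrom, c.pos + window, c.strand, window)
        if down is None or up is None:
            continue
        out.append(float(np.log2((down.sum() + pseudocount) / (up.sum() + pseudocount))))
    return out


# ---------------------------------------------------------------------------
# Two-sample Kolmogorov-Smirnov


def ks_two_sample(x, y, mode: str = "asymptotic", n_permutations: int = 10_000,
                  seed: int = 0) -> tuple[float, float]:
    """Two-sided two-sample KS test.

    D is the supremum ECDF difference; the asymptotic p comes from the
    Kolmogorov distribution evaluated at sqrt(nm/(n+m)) * D. A
    permutation mode is available for small samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    d = _ks_statistic(x, y)
    n, m = len(x), len(y)
    en = math.sqrt(n * m / (n + m))
    if mode == "asymptotic":
        p = float(special.kolmogorov(en * d))
    elif mode == "permutation":
        rng = np.random.default_rng(int(seed) % (2**31))
        pooled = np.concatenate([x, y])
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            if _ks_statistic(perm[:n], perm[n:]) >= d - 1e-12:
                hits += 1
        p = (hits + 1) / (n_permutations + 1)
    else:
        raise ValueError("mode must be 'asymptotic' or 'permutation'")
    return float(d), min(float(p), 1.0)


def _ks_statistic(x: np.ndarray, y: np.ndarray) -> float:
    xs = np.sort(x)
    ys = np.sort(y)
    grid = np.concatenate([xs, ys])
    cdf_x = np.searchsorted(xs, grid, side="right") / len(xs)
    cdf_y = np.searchsorted(ys, grid, side="right") / len(ys)
    return float(np.max(np.abs(cdf_x - cdf_y)))


# ---------------------------------------------------------------------------
# TSS density around gene anchors


def tss_density(anchors, calls, halfwidth: int = 1000) -> pd.DataFrame:
    """Signed distances of calls around anchors.

    ``anchors`` is an iterable of (id, chrom, pos, strand) where strand is
    the gene's transcription direction; every (anchor, call) pair within
    ±halfwidth yields one row with the transcription-direction signed
    distance and whether the call is sense or antisense to the gene.
    """
    rows = []
    call_idx: dict[str, list] = {}
    for c in calls:
        call_idx.setdefault(c.chrom, []).append(c)
    for chrom in call_idx:
        call_idx[chrom].sort(key=lambda c: c.pos)
    for aid, chrom, pos, strand in anchors:
        cs = call_idx.get(chrom, [])
        positions = np.array([c.pos for c in cs])
        if len(positions) == 0:
            continue
        lo = np.searchsorted(positions, pos - halfwidth, side="left")
        hi = np.searchsorted(positions, pos + halfwidth, side="right")
        for c in cs[lo:hi]:
            dist = c.pos - pos if strand == "+" else pos - c.pos
            if abs(dist) > halfwidth:
                continue
            klass = getattr(c, "assigned_klass", getattr(c, "klass", "call"))
            rows.append(
                {
                    "anchor_id": aid, "klass": klass, "distance": int(dist),
                    "relative_strand": "sense" if c.strand == strand else "antisense",
                }
            )
    return pd.DataFrame(rows, columns=["anchor_id", "klass", "distance", "relative_strand"])


def density_histogram(density: pd.DataFrame, halfwidth: int = 1000, bin_width: int = 20
                      ) -> dict[tuple[str, str], dict]:
    """Per-(class, relative strand) histograms and modal positions."""
    edges = np.arange(-halfwidth, halfwidth + bin_width, bin_width)
    out = {}
    if density.empty:
        return out
    for (klass, rel), grp in density.groupby(["klass", "relative_strand"]):
        counts, _ = np.histogram(grp["distance"], bins=edges)
        mode_bin = int(np.argmax(counts))
        out[(klass, rel)] = {
            "edges": edges, "counts": counts, "n": int(counts.sum()),
            "mode": float((edges[mode_bin] + edges[mode_bin + 1]) / 2),
        }
    return out


# ---------------------------------------------------------------------------
# PAS-flanking co-occurrence (one-sided Fisher)


@dataclass(frozen=True)
class Contingency2x2:
    """Rows: upstream unit present/absent; cols: downstream present/absent."""

    a: int  # up present,  down present
    b: int  # up present,  down absent
    c: int  # up absent,   down present
    d: int  # up absent,   down absent

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class ArchWindows:
    """PAS-flanking windows: [0, pas_flank) downstream on the sense strand
    and [-pas_flank, 0) upstream on the antisense strand."""

    pas_flank: int = 400
    density_halfwidth: int = 1000

    def __post_init__(self) -> None:
        if self.pas_flank <= 0 or self.density_halfwidth <= 0:
            raise ValueError("window widths must be positive")


def fisher_one_sided(table: Contingency2x2) -> tuple[float, float]:
    """Upper-tail hypergeometric p = P(X >= a) computed in log space.

    Returns (p, log10 p); log10 p stays finite when p underflows.
    Degenerate margins give p = 1 with a warning.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        logger.warning("degenerate 2x2 margins; p = 1")
        return 1.0, 0.0
    n = table.n
    k_min = max(0, c1 - r2)
    if a <= k_min:
        return 1.0, 0.0  # entire support is in the tail
    k_max = min(r1, c1)
    ks = np.arange(a, k_max + 1)
    logpmf = (
        special.gammaln(r1 + 1) - special.gammaln(ks + 1) - special.gammaln(r1 - ks + 1)
        + special.gammaln(r2 + 1) - special.gammaln(c1 - ks + 1)
        - special.gammaln(r2 - c1 + ks + 1)
        - (special.gammaln(n + 1) - special.gammaln(c1 + 1) - special.gammaln(n - c1 + 1))
    )
    logp = float(special.logsumexp(logpmf))
    logp = min(logp, 0.0)
    return float(np.exp(logp)), logp / math.log(10)


def pas_flanking_presence(genes, calls, windows: ArchWindows | None = None,
                          up_classes=None, down_classes=None) -> pd.DataFrame:
    """Per gene: is there >=1 call of the chosen class in the antisense
    window upstream of the PAS, and in the sense window downstream?

    Class filters test the call's ``assigned_klass``/``klass`` attribute
    when given (e.g. {"coding"} or {"unannotated"}); None accepts any.
    """
    windows = windows or ArchWindows()
    flank = windows.pas_flank
    rows = []
    call_idx: dict[tuple[str, str], list] = {}
    for c in calls:
        call_idx.setdefault((c.chrom, c.strand), []).append(c)
    for key in call_idx:
        call_idx[key].sort(key=lambda c: c.pos)

    def present(chrom, strand, lo, hi, classes) -> bool:
        cs = call_idx.get((chrom, strand), [])
        positions = np.array([c.pos for c in cs])
        if len(positions) == 0:
            return False
        i0 = np.searchsorted(positions, lo, side="left")
        i1 = np.searchsorted(positions, hi, side="left")
        if classes is None:
            return i1 > i0
        for c in cs[i0:i1]:
            if getattr(c, "assigned_klass", getattr(c, "klass", None)) in classes:
                return True
        return False

    for g in genes:
        pas = g.pas_pos
        sense, anti = g.strand, ("-" if g.strand == "+" else "+")
        if g.strand == "+":
            up = present(g.chrom, anti, pas - flank, pas, up_classes)
            down = present(g.chrom, sense, pas, pas + flank, down_classes)
        else:
            up = present(g.chrom, anti, pas + 1, pas + flank + 1, up_classes)
            down = present(g.chrom, sense, pas - flank + 1, pas + 1, down_classes)
        rows.append({"gene": g.id, "up": up, "down": down})
    return pd.DataFrame(rows, columns=["gene", "up", "down"])


def cooccurrence_fisher(genes, calls, windows: ArchWindows | None = None,
                        up_classes=None, down_classes=None
                        ) -> tuple[Contingency2x2, float, float]:
    """One-sided Fisher test for co-presence of an antisense unit upstream
    of the PAS and a sense unit downstream, over all genes."""
    pres = pas_flanking_presence(genes, calls, windows, up_classes, down_classes)
    a = int((pres.up & pres.down).sum())
    b = int((pres.up & ~pres.down).sum())
    c = int((~pres.up & pres.down).sum())
    d = int((~pres.up & ~pres.down).sum())
    table = Contingency2x2(a, b, c, d)
    p, log10p = fisher_one_sided(table)
    return table, p, log10p


# ---------------------------------------------------------------------------
# Genomic-feature KS screen


def feature_ks_screen(features: pd.DataFrame, group_labels, alpha: float = 1e-5,
                      subset=None) -> tuple[pd.DataFrame, float]:
    """Per-feature two-sample KS between two groups of regions.

    ``features`` has one row per region, one column per genomic feature;
    ``group_labels`` assigns each row to one of exactly two groups.
    ``subset`` restricts rows (e.g. for expression-matched regrouping).
    Returns the per-feature table and the screen's E-value
    (alpha x number of features, two significant figures): the number of
    features expected to pass by chance alone.
    """
    labels = pd.Series(list(group_labels), index=features.index)
    if subset is not None:
        features = features.loc[subset]
        labels = labels.loc[subset]
    groups = labels.unique()
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {list(groups)}")
    ga, gb = groups
    rows = []
    for col in features.columns:
        x = features.loc[labels == ga, col].dropna().to_numpy()
        y = features.loc[labels == gb, col].dropna().to_numpy()
        if len(x) < 2 or len(y) < 2:
            rows.append({"feature": col, "D": np.nan, "p": np.nan,
                         "significant": False, "testable": False})
            continue
        d, p = ks_two_sample(x, y)
        rows.append({"feature": col, "D": d, "p": p,
                     "significant": bool(p < alpha), "testable": True})
    e_value = _round_sig(alpha * len(features.columns), 2)
    return pd.DataFrame(rows), e_value


def _round_sig(x: float, sig: int) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


# ---------------------------------------------------------------------------
# Resampling-based signal enrichment


@dataclass(frozen=True)
class EnrichmentParams:
    halfwidth: int = 400
    n_band_resamples: int = 500
    band_quantiles: tuple[float, ...] = (0.01, 0.5, 0.99)
    max_p_sims: int = 1_000_000
    stat_window: tuple[int, int] = (0, 100)  # offsets relative to the anchor
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_band_resamples < 2:
            raise ValueError("n_band_resamples must be >= 2")
        if not all(0 < q < 1 for q in self.band_quantiles):
            raise ValueError("band quantiles must lie in (0, 1)")


@dataclass
class EnrichmentResult:
    offsets: np.ndarray
    observed: np.ndarray  # group metagene
    bands: dict[float, np.ndarray]  # quantile -> per-offset resampled level
    statistic: float
    p_value: float
    n_sims: int


def _anchor_matrix(track_pair, anchors, halfwidth: int) -> np.ndarray:
    """Rows = anchors, columns = offsets -halfwidth..halfwidth-1 in the
    anchor's transcription direction. Out-of-range anchors are dropped."""
    rows = []
    for chrom, pos, strand in anchors:
        start = pos - halfwidth if strand == "+" else pos + halfwidth
        w = oriented_window(track_pair, chrom, start, strand, 2 * halfwidth)
        if w is not None:
            rows.append(w)
    if not rows:
        raise ValueError("no usable anchors")
    return np.asarray(rows)


def signal_enrichment(track_pair: dict[str, StrandedTrack], group_anchors,
                      universe_anchors, params: EnrichmentParams | None = None
                      ) -> EnrichmentResult:
    """Is a signal (e.g. ChIP coverage) higher over a group of anchored
    windows than over random same-size draws from a universe of anchors?

    The observed metagene is the per-offset mean over the group; bands
    are per-offset quantiles over ``n_band_resamples`` random draws
    without replacement from the universe. The test statistic is the
    metagene maximum over ``stat_window``; its empirical p-value is
    (1 + #{resample statistic >= observed}) / (1 + N), with N grown
    adaptively up to ``max_p_sims`` until at least ~10 exceedances are
    seen, so the add-one rule keeps p > 0 and resolution adapts to how
    extreme the observation is.
    """
    params = params or EnrichmentParams()
    group = list(group_anchors)
    universe = list(universe_anchors)
    if len(group) > len(universe):
        raise ValueError("group larger than universe")
    rng = np.random.default_rng(int(params.seed) % (2**31))
    hw = params.halfwidth
    offsets = np.arange(-hw, hw)
    mat = _anchor_matrix(track_pair, universe, hw)
    gmat = _anchor_matrix(track_pair, group, hw)
    observed = gmat.mean(axis=0)

    lo, hi = params.stat_window
    sw = slice(int(lo + hw), int(hi + hw))
    stat = float(observed[sw].max())
    g = len(gmat)
    n_univ = len(mat)

    # bands over the full window
    band_stack = np.empty((params.n_band_resamples, 2 * hw))
    resample_stats = np.empty(params.n_band_resamples)
    for i in range(params.n_band_resamples):
        idx = rng.choice(n_univ, size=g, replace=False)
        m = mat[idx].mean(axis=0)
        band_stack[i] = m
        resample_stats[i] = m[sw].max()
    bands = {q: np.quantile(band_stack, q, axis=0) for q in params.band_quantiles}

    # adaptive empirical p on the statistic only (cheap per resample)
    sub = np.ascontiguousarray(mat[:, sw])
    hits = int((resample_stats >= stat).sum())
    n_sims = params.n_band_resamples
    while n_sims < params.max_p_sims:
        p = (hits + 1) / (n_sims + 1)
        if p * n_sims >= 10:
            break
        batch = min(max(n_sims, 1000), params.max_p_sims - n_sims)
        for start in range(0, batch, 2048):
            chunk = min(2048, batch - start)
            # without-replacement draws: smallest-g ranks of uniform keys
            keys = rng.random((chunk, n_univ))
            idx = np.argpartition(keys, g - 1, axis=1)[:, :g]
            stats_chunk = sub[idx].mean(axis=1).max(axis=1)
            hits += int((stats_chunk >= stat).sum())
        n_sims += batch
    p = (hits + 1) / (n_sims + 1)
    return EnrichmentResult(offsets, observed, bands, stat, float(p), n_sims)
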