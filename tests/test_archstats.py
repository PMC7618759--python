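import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sfnet.archstats import (
    ArchWindows,
    Contingency2x2,
    EnrichmentParams,
    cooccurrence_fisher,
    feature_ks_screen,
    fisher_one_sided,
    ks_two_sample,
    pas_flanking_presence,
    signal_enrichment,
    tss_density,
    updown_log_ratio,
)
from sfnet.caller import TssCall
from sfnet.genome_io import GeneModel, GenomeCoords, StrandedTrack


def call(pos, strand="+", chrom="c", klass=None):
    c = TssCall(chrom, strand, pos, 0.8, 50.0, True)
    if klass is not None:
        c = SimpleCall(chrom, strand, pos, klass)
    return c


class SimpleCall:
    def __init__(self, chrom, strand, pos, klass):
        self.chrom, self.strand, self.pos, self.klass = chrom, strand, pos, klass


def hypergeom_upper_exact(a, b, c, d) -> Fraction:
    """Exact one-sided p by integer enumeration of the hypergeometric
    upper tail; the independent oracle for the log-space route."""
    r1, c1, n = a + b, a + c, a + b + c + d
    num = sum(math.comb(r1, k) * math.comb(n - r1, c1 - k)
              for k in range(a, min(r1, c1) + 1))
    return Fraction(num, math.comb(n, c1))


class TestUpdownLogRatio:
    @pytest.fixture
    def pair(self):
        coords = GenomeCoords.from_dict({"c": 1000})
        return {s: StrandedTrack(coords, s) for s in "+-"}

    def test_symmetric_counts_give_zero(self, pair):
        pair["+"].values["c"][400:500] = 0.15  # 15 up, 15 down around 500
        pair["+"].values["c"][500:600] = 0.15
        [r] = updown_log_ratio([call(500)], pair, window=100)
        assert r == pytest.approx(0.0)

    def test_downstream_only(self, pair):
        pair["+"].values["c"][500:531] = 1.0  # 31 reads downstream
        [r] = updown_log_ratio([call(500)], pair, window=100)
        assert r == pytest.approx(5.0)  # log2(32/1)

    def test_minus_strand_orientation(self, pair):
        pair["-"].values["c"][401:501] = 0.31
        [r] = updown_log_ratio([call(500, "-")], pair, window=100)
        assert r == pytest.approx(5.0)

    def test_out_of_range_calls_skipped(self, pair):
        assert updown_log_ratio([call(10)], pair, window=100) == []


class TestKsTwoSample:
    def test_identical_samples(self):
        x = np.arange(10.0)
        d, p = ks_two_sample(x, x)
        assert d == 0.0 and p == 1.0

    def test_disjoint_supports(self):
        d, p = ks_two_sample(np.arange(10.0), np.arange(100.0, 110.0))
        assert d == 1.0 and p < 1e-4

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])

    def test_statistic_matches_scipy_and_p_close(self):
        """D agrees exactly with the library implementation; the p-value
        uses the plain Kolmogorov limit at sqrt(nm/(n+m))*D, which sits
        within a few percent of scipy's corrected asymptotic variant."""
        rng = np.random.default_rng(1)
        for _ in range(10):
            x, y = rng.normal(size=30), rng.normal(0.5, 1.2, size=25)
            d, p = ks_two_sample(x, y)
            ref = sps.ks_2samp(x, y, method="asymp")
            assert d == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=0.1)

    def test_asymptotic_close_to_permutation_at_n20(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=20), rng.normal(0.8, 1, size=20)
        d, p_asym = ks_two_sample(x, y)
        _, p_perm = ks_two_sample(x, y, mode="permutation",
                                  n_permutations=20_000, seed=3)
        assert abs(p_asym - p_perm) < 0.05


class TestTssDensity:
    def test_call_at_anchor_same_strand(self):
        df = tss_density([("g", "c", 1000, "+")], [call(1000)])
        assert df.iloc[0].distance == 0 and df.iloc[0].relative_strand == "sense"

    def test_minus_gene_pas_downstream_sense(self):
        """150 bp 3' of a - strand gene's PAS = genomic position pas-150,
        same strand as the gene -> distance +150, sense."""
        df = tss_density([("g:PAS", "c", 5000, "-")], [call(4850, "-")])
        assert df.iloc[0].distance == 150 and df.iloc[0].relative_strand == "sense"

    def test_antisense_label(self):
        df = tss_density([("g", "c", 1000, "+")], [call(800, "-")])
        assert df.iloc[0].distance == -200 and df.iloc[0].relative_strand == "antisense"

    def test_out_of_range_excluded_and_counts_conserved(self):
        calls = [call(p) for p in (500, 900, 1000, 1100, 2500)]
        df = tss_density([("g", "c", 1000, "+")], calls, halfwidth=400)
        assert len(df) == 3
        assert sorted(df.distance) == [-100, 0, 100]


class TestFisher:
    def test_five_zero_zero_five(self):
        p, log10p = fisher_one_sided(Contingency2x2(5, 0, 0, 5))
        assert p == pytest.approx(1 / 252, rel=1e-12)

    def test_a_zero_with_positive_margins(self):
        p, _ = fisher_one_sided(Contingency2x2(0, 5, 5, 5))
        assert p == 1.0

    def test_degenerate_margins_warn_and_return_one(self, caplog):
        with caplog.at_level("WARNING"):
            p, log10p = fisher_one_sided(Contingency2x2(0, 0, 3, 4))
        assert p == 1.0 and log10p == 0.0

    def test_matches_exact_enumeration_small_tables(self):
        """Log-space p vs exact rational enumeration, all margins <= 6."""
        for a in range(6):
            for b in range(6):
                for c in range(6):
                    for d in range(6):
                        t = Contingency2x2(a, b, c, d)
                        if min(a + b, c + d, a + c, b + d) == 0:
                            continue
                        p, _ = fisher_one_sided(t)
                        exact = float(hypergeom_upper_exact(a, b, c, d))
                        assert p == pytest.approx(exact, rel=1e-10)

    def test_matches_scipy_one_sided(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b, c, d = rng.integers(1, 40, 4)
            p, _ = fisher_one_sided(Contingency2x2(a, b, c, d))
            ref = sps.fisher_exact([[a, b], [c, d]], alternative="greater")[1]
            assert p == pytest.approx(ref, rel=1e-9)

    def test_huge_margins_no_underflow(self):
        """log10 p stays finite (~-300) where p itself underflows."""
        p, log10p = fisher_one_sided(Contingency2x2(2500, 100, 100, 2300))
        assert math.isfinite(log10p) and log10p < -250
        assert p == 0.0 or p < 1e-250


class TestCooccurrence:
    def genes(self, n=40, length=1000, spacing=3000):
        return [GeneModel(f"g{i}", "c", "+", 2000 + i * spacing,
                          2000 + i * spacing + length - 1) for i in range(n)]

    def test_presence_windows(self):
        g = GeneModel("g", "c", "+", 1000, 1999)  # pas at 1999
        calls = [call(1700, "-"), call(2100, "+")]
        pres = pas_flanking_presence([g], calls)
        assert bool(pres.up[0]) and bool(pres.down[0])
        # outside the 400 bp windows
        pres2 = pas_flanking_presence([g], [call(1500, "-"), call(2500, "+")])
        assert not pres2.up[0] and not pres2.down[0]

    def test_minus_strand_gene_windows(self):
        g = GeneModel("g", "c", "-", 3000, 2001)  # pas at 2001
        calls = [call(2300, "+"), call(1800, "-")]
        pres = pas_flanking_presence([g], calls)
        assert bool(pres.up[0]) and bool(pres.down[0])

    def test_planted_dependence_detected(self):
        rng = np.random.default_rng(5)
        genes = self.genes(200)
        calls = []
        for g in genes:
            r = rng.random()
            if r < 0.45 or 0.45 <= r < 0.55:
                calls.append(call(g.pas_pos - 60, "-"))
            if r < 0.45 or r >= 0.9:
                calls.append(call(g.pas_pos + 150, "+"))
        table, p, log10p = cooccurrence_fisher(genes, calls)
        assert p < 1e-3
        assert log10p == pytest.approx(math.log10(p), abs=1e-6)

    def test_independent_presence_p_uniform(self):
        """Under independent planted presence the one-sided p is roughly
        uniform across replicate seeds."""
        genes = self.genes(120)
        ps = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            calls = []
            for g in genes:
                if rng.random() < 0.4:
                    calls.append(call(g.pas_pos - 60, "-"))
                if rng.random() < 0.4:
                    calls.append(call(g.pas_pos + 150, "+"))
            _, p, _ = cooccurrence_fisher(genes, calls)
            ps.append(p)
        ks_p = sps.kstest(ps, "uniform").pvalue
        assert ks_p > 0.01


class TestFeatureScreen:
    def test_e_value_for_1453_features(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(8, 1453)),
                          columns=[f"f{i}" for i in range(1453)])
        labels = ["a"] * 4 + ["b"] * 4
        _, e_value = feature_ks_screen(df, labels, alpha=1e-5)
        assert e_value == 0.015

    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(1)
        block = rng.normal(size=(30, 50))
        df = pd.DataFrame(np.vstack([block, block]))
        labels = ["a"] * 30 + ["b"] * 30
        out, _ = feature_ks_screen(df, labels)
        assert not out.significant.any()

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(400, 30)))
        df.iloc[:200, 0] += 3.0  # 3-sigma location shift in feature 0
        labels = ["a"] * 200 + ["b"] * 200
        out, _ = feature_ks_screen(df, labels, alpha=1e-5)
        assert bool(out.loc[out.feature == 0, "significant"].iloc[0])
        assert out.significant.sum() <= 2  # others at null rates

    def test_untestable_feature_flagged(self):
        df = pd.DataFrame({"f": [1.0, np.nan, 2.0, 3.0]})
        out, _ = feature_ks_screen(df, ["a", "a", "b", "b"])
        assert not out.testable.iloc[0]

    def test_subset_regrouping(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(100, 5)))
        labels = ["a"] * 50 + ["b"] * 50
        out, _ = feature_ks_screen(df, labels, subset=df.index[10:90])
        assert len(out) == 5


class TestSignalEnrichment:
    @pytest.fixture
    def track_pair(self):
        coords = GenomeCoords.from_dict({"c": 100_000})
        pair = {s: StrandedTrack(coords, s) for s in "+-"}
        rng = np.random.default_rng(0)
        pair["+"].values["c"] = rng.poisson(2.0, 100_000).astype(float)
        pair["-"].values["c"] = rng.poisson(2.0, 100_000).astype(float)
        return pair

    def anchors(self, n=60, start=2000, spacing=1500):
        return [("c", start + i * spacing, "+") for i in range(n)]

    def test_group_equals_universe_p_one(self, track_pair):
        anchors = self.anchors()
        params = EnrichmentParams(n_band_resamples=50, max_p_sims=50, seed=1)
        res = signal_enrichment(track_pair, anchors, anchors, params)
        assert res.p_value == 1.0
        np.testing.assert_allclose(res.bands[0.5], res.observed)

    def test_group_larger_than_universe_rejected(self, track_pair):
        with pytest.raises(ValueError):
            signal_enrichment(track_pair, self.anchors(10), self.anchors(5))

    def test_minimum_reportable_p(self, track_pair):
        """The add-one rule floors p at 1/(N+1)."""
        anchors = self.anchors()
        group = anchors[:20]
        track_pair["+"].values["c"][:] += 0.0
        for chrom, pos, _ in group:
            track_pair["+"].values["c"][pos + 30: pos + 50] += 500.0
        params = EnrichmentParams(n_band_resamples=100, max_p_sims=2000, seed=2)
        res = signal_enrichment(track_pair, group, anchors, params)
        assert res.p_value == pytest.approx(1 / (res.n_sims + 1))
        assert res.n_sims == 2000

    def test_planted_bump_recovery(self, track_pair):
        """A +40 bp signal bump planted for a gene group exceeds the 99%
        resampling band near +40 and gives small empirical p."""
        anchors = self.anchors(80)
        group = anchors[:25]
        for chrom, pos, _ in group:
            track_pair["+"].values["c"][pos + 30: pos + 50] += 6.0
        params = EnrichmentParams(n_band_resamples=500, max_p_sims=20_000, seed=3)
        res = signal_enrichment(track_pair, group, anchors, params)
        hw = params.halfwidth
        near40 = slice(hw + 30, hw + 50)
        assert (res.observed[near40] > res.bands[0.99][near40]).any()
        assert res.p_value < 0.01

    def test_p_monotone_in_observed_statistic(self, track_pair):
        anchors = self.anchors(80)
        group = anchors[:25]
        ps = []
        for bump in (0.0, 3.0, 8.0):
            pair = {s: t.copy() for s, t in track_pair.items()}
            for chrom, pos, _ in group:
                pair["+"].values["c"][pos + 35: pos + 45] += bump
            params = EnrichmentParams(n_band_resamples=200, max_p_sims=200, seed=4)
            ps.append(signal_enrichment(pair, group, anchors, params).p_value)
        assert ps[0] >= ps[1] >= ps[2]
        assert all(p > 0 for p in ps)
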