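"""Genome-scale summaries: levels, symmetry, windows, metaplots."""

import numpy as np
import pandas as pd
import pytest

import methatlas as ma
from conftest import make_sites


class TestWeightedLevel:
    def test_direct_summation(self):
        sites = make_sites(
            [("c", 1, "+", "CGT", 2, 4), ("c", 5, "+", "CGA", 1, 6)]
        )
        assert ma.weighted_level(sites, "CG") == pytest.approx(3 / 10)

    def test_extremes(self):
        full = make_sites([("c", 1, "+", "CGT", 4, 4)])
        none = make_sites([("c", 1, "+", "CGT", 0, 4)])
        assert ma.weighted_level(full, "CG") == 1.0
        assert ma.weighted_level(none, "CG") == 0.0

    def test_no_covered_sites_is_missing(self):
        sites = make_sites([("c", 1, "+", "CGT", 0, 0)])
        assert np.isnan(ma.weighted_level(sites, "CG"))
        assert np.isnan(ma.weighted_level(sites, "CHH"))

    def test_union_is_read_weighted_mean_of_parts(self, called_sites):
        """Conservation: the level of a union of disjoint site sets is the
        read-count-weighted mean of the parts."""
        df = called_sites
        half = len(df) // 2
        a, b = df.iloc[:half], df.iloc[half:]
        for ctx in ma.CONTEXTS:
            la, lb = ma.weighted_level(a, ctx), ma.weighted_level(b, ctx)
            ta = a[(a.context == ctx) & (a.total_reads >= 1)].total_reads.sum()
            tb = b[(b.context == ctx) & (b.total_reads >= 1)].total_reads.sum()
            combined = ma.weighted_level(df, ctx)
            assert combined == pytest.approx((la * ta + lb * tb) / (ta + tb))


class TestContextProportions:
    def test_direct_fractions(self):
        rows, called = [], []
        for i in range(50):
            rows.append(("c", 3 * i + 1, "+", "CGA", 3, 3)); called.append("methylated")
        for i in range(30):
            rows.append(("c", 300 + 3 * i, "+", "CAG", 3, 3)); called.append("methylated")
        for i in range(20):
            rows.append(("c", 600 + 3 * i, "+", "CAA", 3, 3)); called.append("methylated")
        sites = make_sites(rows, called)
        props = ma.context_proportions(sites)
        assert props == {"CG": 0.5, "CHG": 0.3, "CHH": 0.2}

    def test_single_context(self):
        sites = make_sites([("c", 1, "+", "CGT", 3, 3)], ["methylated"])
        assert ma.context_proportions(sites) == {"CG": 1.0, "CHG": 0.0, "CHH": 0.0}

    def test_no_methylated_sites_undefined(self):
        sites = make_sites([("c", 1, "+", "CGT", 0, 3)], ["unmethylated"])
        assert all(np.isnan(v) for v in ma.context_proportions(sites).values())

    def test_matches_brute_force_tally(self, called_sites):
        counts = {c: 0 for c in ma.CONTEXTS}
        for row in called_sites.head(20_000).itertuples():
            if row.called == "methylated" and row.context in counts:
                counts[row.context] += 1
        total = sum(counts.values())
        props = ma.context_proportions(called_sites.head(20_000))
        for c in ma.CONTEXTS:
            assert props[c] == pytest.approx(counts[c] / total)


class TestPerSiteDistribution:
    def test_full_methylation_at_one(self):
        sites = make_sites([("c", 1, "+", "CGT", 3, 3)], ["methylated"])
        counts, edges = ma.per_site_distribution(sites, "CG", bins=10)
        assert counts[-1] == 1 and counts[:-1].sum() == 0

    def test_tally(self):
        sites = make_sites(
            [("c", 1, "+", "CGT", 2, 4), ("c", 5, "+", "CGT", 3, 6),
             ("c", 9, "+", "CGT", 3, 3)],
            ["methylated"] * 3,
        )
        counts, edges = ma.per_site_distribution(sites, "CG", bins=4)
        assert counts[2] == 2  # two sites at level 0.5 -> bin [0.5, 0.75)
        assert counts[3] == 1  # one at 1.0
        assert counts.sum() == 3

    def test_unmethylated_sites_excluded(self):
        sites = make_sites([("c", 1, "+", "CGT", 0, 5)], ["unmethylated"])
        counts, _ = ma.per_site_distribution(sites, "CG")
        assert counts.sum() == 0


class TestSymmetry:
    def _pair(self, mc_p, tot_p, mc_m, tot_m, context="CG"):
        tri = "CGA" if context == "CG" else "CAG"
        offset = 1 if context == "CG" else 2
        called_p = "methylated" if mc_p / tot_p > 0.5 else "unmethylated"
        called_m = "methylated" if mc_m / tot_m > 0.5 else "unmethylated"
        return make_sites(
            [("c", 10, "+", tri, mc_p, tot_p),
             ("c", 10 + offset, "-", tri, mc_m, tot_m)],
            [called_p, called_m],
        )

    def test_fully_methylated_pair_symmetric(self):
        _, frac = ma.symmetry_analysis(self._pair(10, 10, 10, 10), "CG")
        assert frac == 0.0

    def test_low_partner_asymmetric_at_40pct(self):
        sites = self._pair(9, 10, 3, 10)  # partner level 0.35 < 0.40
        _, frac = ma.symmetry_analysis(sites, "CG", threshold=0.40)
        assert frac == 1.0

    def test_chg_offset_two(self):
        _, frac = ma.symmetry_analysis(
            self._pair(10, 10, 10, 10, context="CHG"), "CHG"
        )
        assert frac == 0.0

    def test_chh_rejected(self, called_sites):
        with pytest.raises(ValueError, match="CHH"):
            ma.symmetry_analysis(called_sites, "CHH")

    def test_fraction_matches_enumeration(self, called_sites):
        """Brute-force re-count of asymmetric methylated CG sites."""
        sub = called_sites[called_sites.chrom == "chr1"]
        pairs, frac = ma.symmetry_analysis(sub, "CG", threshold=0.4)
        lookup = {}
        cg = sub[(sub.context == "CG") & (sub.total_reads >= 3)]
        for row in cg.itertuples():
            lookup[(row.pos, row.strand)] = row
        sym = asym = 0
        for (pos, strand), row in lookup.items():
            partner = lookup.get((pos + 1, "-") if strand == "+" else (pos - 1, "+"))
            if partner is None or row.called != "methylated":
                continue
            if partner.mc_reads / partner.total_reads >= 0.4:
                sym += 1
            else:
                asym += 1
        assert sym + asym > 0
        assert frac == pytest.approx(asym / (sym + asym))


class TestWindows:
    def test_tiling_arithmetic(self):
        sites = make_sites([("c", 1, "+", "CGT", 1, 2)])
        win = ma.window_profile(sites, None, {"c": 150_000})
        assert [(w.start, w.end) for w in win.itertuples()] == [
            (0, 100_000), (50_000, 150_000)
        ]
        assert list(win.partial) == [False, False]

    def test_window_smaller_than_step_rejected(self):
        sites = make_sites([("c", 1, "+", "CGT", 1, 2)])
        with pytest.raises(ValueError):
            ma.window_profile(sites, None, {"c": 10_000}, window=100, step=200)

    def test_uniform_sites_uniform_levels(self):
        rows = [("c", p, "+", "CGT", 1, 2) for p in range(1, 300_000, 1000)]
        win = ma.window_profile(make_sites(rows), None, {"c": 300_000})
        assert np.allclose(win.level_CG, 0.5)

    def test_hot_window_recovered(self, nuclear_called, sim_result):
        """The heterochromatic compartment carries the highest mCG windows."""
        win = ma.window_profile(
            nuclear_called, sim_result.annotation,
            {"chr1": sim_result.truth.config.chrom_length},
        )
        het = next(c for c in sim_result.truth.compartments
                   if c[3] == "heterochromatin")
        hottest = win.loc[win.level_CG.idxmax()]
        assert hottest.start >= het[1] - 100_000 and hottest.end <= het[2] + 100_000

    def test_gene_counts_by_midpoint(self, sim_result):
        win = ma.window_profile(
            sim_result.sites.head(100), sim_result.annotation,
            {"chr1": sim_result.truth.config.chrom_length},
        )
        mids = [(g.start + g.end) // 2 for g in sim_result.annotation.genes]
        for row in win.itertuples():
            expect = sum(1 for m in mids if row.start <= m < row.end)
            assert row.gene_count == expect


class TestWindowGeneCorrelation:
    def _win(self, counts, levels):
        return pd.DataFrame({"gene_count": counts, "level_CG": levels})

    def test_perfect_positive(self):
        assert ma.window_gene_correlation(
            self._win([1, 2, 3, 4], [0.1, 0.2, 0.3, 0.4]), "CG"
        ) == pytest.approx(1.0)

    def test_perfect_negative(self):
        assert ma.window_gene_correlation(
            self._win([1, 2, 3, 4], [0.9, 0.7, 0.5, 0.3]), "CG"
        ) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 50, 40).astype(float)
        y = rng.random(40)
        r = ma.window_gene_correlation(self._win(x, y), "CG")
        xc, yc = x - x.mean(), y - y.mean()
        oracle = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_undefined(self):
        assert np.isnan(
            ma.window_gene_correlation(self._win([2, 2, 2], [0.1, 0.5, 0.9]), "CG")
        )


class TestMetaplot:
    def test_uniform_methylation_flat(self):
        rows = [("c", p, "+", "CGT", 1, 2) for p in range(1, 10_000, 20)]
        prof = ma.feature_metaplot(
            make_sites(rows), [("c", 4000, 6000, "+")], flank=2000
        )
        cg = prof[prof.context == "CG"]
        assert np.allclose(cg.level.dropna(), 0.5)

    def test_body_enrichment(self):
        rows = [("c", p, "+", "CGT", 1 if 4000 < p <= 6000 else 0, 2)
                for p in range(1, 10_000, 20)]
        prof = ma.feature_metaplot(
            make_sites(rows), [("c", 4000, 6000, "+")], flank=2000
        )
        cg = prof[prof.context == "CG"]
        body = cg[cg.segment == "body"].level.mean()
        flank = cg[cg.segment != "body"].level.mean()
        assert body > flank

    def test_hand_binned_single_feature(self):
        # feature [100, 300) with flank 100, 2 flank bins, 2 body bins
        rows = [
            ("c", 31, "+", "CGT", 1, 2),    # upstream bin 0: pos0 30 in [0, 50)
            ("c", 91, "+", "CGT", 2, 2),    # upstream bin 1: pos0 90 in [50, 100)
            ("c", 150, "+", "CGT", 2, 4),   # body bin 0
            ("c", 250, "+", "CGT", 4, 4),   # body bin 1
            ("c", 340, "+", "CGT", 0, 2),   # downstream bin 0
        ]
        prof = ma.feature_metaplot(
            make_sites(rows), [("c", 100, 300, "+")],
            flank=100, body_bins=2, flank_bins=2,
        )
        cg = prof[prof.context == "CG"].set_index("bin")
        assert cg.loc[0].level == pytest.approx(0.5)
        assert cg.loc[1].level == pytest.approx(1.0)
        assert cg.loc[2].level == pytest.approx(0.5)
        assert cg.loc[3].level == pytest.approx(1.0)
        assert cg.loc[4].level == pytest.approx(0.0)
        assert np.isnan(cg.loc[5].level)

    def test_strand_flip_reverses_profile(self, nuclear_called, sim_result):
        genes = sim_result.annotation.genes
        fwd = ma.feature_metaplot(nuclear_called, genes, flank=1000,
                                  body_bins=10, flank_bins=10)
        flipped = [
            (g.chrom, g.start, g.end, "-" if g.strand == "+" else "+")
            for g in genes
        ]
        rev = ma.feature_metaplot(nuclear_called, flipped, flank=1000,
                                  body_bins=10, flank_bins=10)
        for c in ma.CONTEXTS:
            a = fwd[fwd.context == c].sort_values("bin").level.to_numpy()
            b = rev[rev.context == c].sort_values("bin").level.to_numpy()
            np.testing.assert_allclose(a, b[::-1])

    def test_short_feature_pooled_into_one_bin(self):
        rows = [("c", 105, "+", "CGT", 2, 2)]
        prof = ma.feature_metaplot(
            make_sites(rows), [("c", 100, 110, "+")],
            flank=100, body_bins=20, flank_bins=2,
        )
        cg = prof[prof.context == "CG"]
        body = cg[cg.segment == "body"]
        assert body.level.notna().sum() == 1
        assert body.dropna(subset=["level"]).bin.iloc[0] == 2
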