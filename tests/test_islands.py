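"""mCHH island detection and expression association."""

import numpy as np
import pandas as pd
import pytest

import methatlas as ma
from conftest import make_sites
from methatlas.io import GeneModel, GenomeAnnotation


def flank_sites(chrom, start, end, level, depth=10, step=5, called_level=0.25):
    """Dense CHH sites across [start, end) (0-based) at a fixed level."""
    rows, called = [], []
    for p0 in range(start, end, step):
        mc = int(round(level * depth))
        rows.append((chrom, p0 + 1, "+", "CAA", mc, depth))
        called.append("methylated" if level >= called_level else "unmethylated")
    return rows, called


def background_with_holes(chrom, start, end, holes, level=0.02):
    """Low-mCHH background across [start, end) skipping the hole spans."""
    rows, called = [], []
    cursor = start
    for hs, he in sorted(holes) + [(end, end)]:
        r, c = flank_sites(chrom, cursor, hs, level)
        rows += r
        called += c
        cursor = he
    return rows, called


def one_gene(start=10_000, end=12_000, strand="+", gene_id="g"):
    return GenomeAnnotation(
        genes=[GeneModel(gene_id, "c", strand, start, end,
                         exons=[(start, end)], cds=[(start, end)])]
    )


class TestCallIslands:
    def test_qualifying_upstream_window(self):
        ann = one_gene()
        rows, called = background_with_holes("c", 8000, 10_000, [(9400, 9500)])
        irows, icalled = flank_sites("c", 9400, 9500, 0.30)
        sites = make_sites(rows + irows, called + icalled)
        islands = ma.call_islands(sites, ann)
        up = [i for i in islands if i.side == "upstream"]
        assert len(up) == 1
        assert (up[0].start, up[0].end) == (9400, 9500)
        assert up[0].level >= 0.25 and up[0].n_mc >= 5
        assert up[0].window_index == 6  # 500-600 bp from the gene edge

    def test_no_chh_methylation_no_islands(self):
        ann = one_gene()
        rows, called = flank_sites("c", 8000, 12_000, 0.02)
        sites = make_sites(rows, called)
        assert ma.call_islands(sites, ann) == []

    def test_min_mc_enforced(self):
        ann = one_gene()
        rows, called = background_with_holes("c", 8000, 10_000, [(9400, 9500)])
        # high-level window but only 4 methylated sites
        irows, icalled = flank_sites("c", 9400, 9500, 0.30, step=25)
        sites = make_sites(rows + irows, called + icalled)
        assert all(i.side != "upstream" for i in ma.call_islands(sites, ann))

    def test_missing_data_filter_drops_gene_side(self):
        ann = one_gene()
        # only 5 of 20 upstream windows have any covered CHH site
        rows, called = flank_sites("c", 9500, 10_000, 0.30)
        sites = make_sites(rows, called)
        assert ma.call_islands(sites, ann) == []

    def test_anchor_tie_breaks_toward_gene(self):
        ann = one_gene()
        rows, called = background_with_holes(
            "c", 8000, 10_000, [(9000, 9100), (9700, 9800)]
        )
        near, ncalled = flank_sites("c", 9700, 9800, 0.30)
        far, fcalled = flank_sites("c", 9000, 9100, 0.30)
        sites = make_sites(rows + near + far, called + ncalled + fcalled)
        up = [i for i in ma.call_islands(sites, ann) if i.side == "upstream"]
        assert len(up) == 1
        assert up[0].start == 9700

    def test_strand_aware_sides(self):
        ann = one_gene(strand="-")
        rows, called = background_with_holes("c", 8000, 10_000, [(9400, 9500)])
        irows, icalled = flank_sites("c", 9400, 9500, 0.30)
        rows2, called2 = flank_sites("c", 12_000, 14_000, 0.02)
        sites = make_sites(rows + irows + rows2, called + icalled + called2)
        islands = ma.call_islands(sites, ann)
        # left of a minus-strand gene is its downstream side
        assert [i.side for i in islands] == ["downstream"]

    def test_at_most_one_island_per_gene_side(self, nuclear_called, sim_result):
        islands = ma.call_islands(nuclear_called, sim_result.annotation)
        keys = [(i.gene_id, i.side) for i in islands]
        assert len(keys) == len(set(keys))

    def test_planted_islands_recovered(self, nuclear_called, sim_result):
        islands = ma.call_islands(nuclear_called, sim_result.annotation)
        planted = {(t["gene_id"], t["side"]): t for t in sim_result.truth.islands}
        found = {(i.gene_id, i.side): i for i in islands}
        hits = sum(
            1
            for key, t in planted.items()
            if key in found and abs(found[key].start - t["start"]) <= 100
        )
        assert hits >= 0.95 * len(planted)

    def test_invariant_to_gene_order_and_chrom_rename(self, nuclear_called,
                                                      sim_result):
        ann = sim_result.annotation
        shuffled = GenomeAnnotation(genes=list(reversed(ann.genes)),
                                    repeats=ann.repeats)
        a = ma.call_islands(nuclear_called, ann)
        b = ma.call_islands(nuclear_called, shuffled)
        assert sorted((i.gene_id, i.side, i.start) for i in a) == sorted(
            (i.gene_id, i.side, i.start) for i in b
        )
        renamed_sites = nuclear_called.assign(
            chrom=nuclear_called.chrom.str.replace("chr1", "scaffold_9")
        )
        renamed_genes = [
            GeneModel(g.gene_id, "scaffold_9", g.strand, g.start, g.end,
                      exons=g.exons, cds=g.cds)
            for g in ann.genes
        ]
        c = ma.call_islands(renamed_sites, GenomeAnnotation(genes=renamed_genes))
        assert sorted((i.gene_id, i.side, i.start) for i in c) == sorted(
            (i.gene_id, i.side, i.start) for i in a
        )


class TestIslandProfile:
    def test_profile_centered_and_oriented(self):
        ann = one_gene()
        bg, bgc = background_with_holes("c", 7000, 10_000, [(9400, 9500)])
        isl, islc = flank_sites("c", 9400, 9500, 0.40)
        sites = make_sites(bg + isl, bgc + islc)
        islands = ma.call_islands(sites, ann)
        prof = ma.island_profile(islands, sites, ann)
        chh = prof[prof.context == "CHH"].set_index("offset_bp")
        # the anchor bin itself carries the island level
        assert chh.loc[0, "level"] == pytest.approx(0.40, abs=0.02)

    def test_no_sites_all_missing(self):
        ann = one_gene()
        isl = [ma.ChhIsland("g", "upstream", "c", 9400, 9500, 0.3, 6, 6)]
        empty = make_sites([("q", 1, "+", "CAA", 0, 5)], ["unmethylated"])
        prof = ma.island_profile(isl, empty, ann)
        assert prof.level.isna().all()


class TestExpressionAssociation:
    def test_quartile_construction(self):
        expr = pd.Series(
            {"a": 0.0, "b": 1.0, "c": 2.0, "d": 3.0, "e": 4.0},
        )
        cats = ma.islands.expression_categories(expr)
        assert cats["a"] == "NE"
        assert cats["b"] == "Q1" and cats["e"] == "Q4"

    def test_all_ne_errors(self):
        expr = pd.Series({"a": 0.0, "b": 0.0})
        with pytest.raises(ValueError):
            ma.expression_association([], expr)

    def test_planted_preference_significant(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(500)]
        expr = pd.Series(rng.lognormal(1, 1, 500), index=genes)
        cats = ma.islands.expression_categories(expr)
        islands = []
        for g in genes:
            p = 0.6 if cats[g] == "Q4" else 0.1
            if rng.random() < p:
                islands.append(
                    ma.ChhIsland(g, "upstream", "c", 0, 100, 0.3, 6, 3)
                )
        assoc = ma.expression_association(islands, expr)
        up = assoc[assoc.side == "upstream"].set_index("category")
        assert up.loc["Q4", "proportion"] > up.loc["Q1", "proportion"]
        assert up.loc["Q1", "p_vs_Q4"] < 0.01
        assert bool(up.loc["Q1", "significant"])

    def test_uniform_assignment_mostly_null(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(400)]
        expr = pd.Series(rng.lognormal(1, 1, 400), index=genes)
        sig = 0
        reps = 20
        for rep in range(reps):
            islands = [
                ma.ChhIsland(g, "upstream", "c", 0, 100, 0.3, 6, 3)
                for g in genes
                if rng.random() < 0.2
            ]
            assoc = ma.expression_association(islands, expr)
            up = assoc[(assoc.side == "upstream") & (assoc.category != "Q4")]
            sig += int(up["significant"].any())
        # 4 comparisons per rep at alpha 0.01 -> expect ~0.04 reps flagged
        assert sig <= 3
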