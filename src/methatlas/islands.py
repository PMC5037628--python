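"""mCHH island detection in gene flanks and expression association.

mCHH islands are short (100-bp scale) patches of dense CHH methylation
within 2 kb of genes, thought to mark the boundary between euchromatin
and flanking heterochromatin.  A flank window qualifies when its
weighted mCHH level is at least 25 % and it holds at least five
methylated CHH sites; the island anchor is the qualifying window of
highest level.  Genes whose flank is mostly uncovered (missing data in
more than half of the flank windows) are excluded from consideration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .io import CONTEXTS, GenomeAnnotation

SIDES = ("upstream", "downstream")

EXPRESSION_CATEGORIES = ("NE", "Q1", "Q2", "Q3", "Q4")


@dataclass
class ChhIsland:
    """A gene-flank mCHH island anchored on its maximal 100-bp window."""

    gene_id: str
    side: str  # upstream / downstream, strand-aware
    chrom: str
    start: int  # 0-based half-open anchor window
    end: int
    level: float
    n_mc: int
    window_index: int  # 1 = window abutting the gene


def _flank_windows(gene, side: str, flank: int, win: int):
    """Yield (window_index, start, end) tuples from the gene edge outward."""
    n = flank // win
    # genomic coordinates: upstream of a + gene (and downstream of a -
    # gene) lies left of the interval
    left = (side == "upstream") == (gene.strand == "+")
    for k in range(1, n + 1):
        if left:
            s, e = gene.start - k * win, gene.start - (k - 1) * win
        else:
            s, e = gene.end + (k - 1) * win, gene.end + k * win
        yield k, s, e


def call_islands(
    called_sites: pd.DataFrame,
    annotation: GenomeAnnotation,
    flank: int = 2000,
    win: int = 100,
    min_level: float = 0.25,
    min_mc: int = 5,
    max_missing: float = 0.5,
    min_coverage: int = 1,
) -> list[ChhIsland]:
    """Detect at most one mCHH island per gene per side.

    Flank windows are tiled from the gene edge outward (window 1 abuts
    the gene).  A window with zero covered CHH sites is "missing"; a
    gene-side with missing data in more than ``max_missing`` of its
    windows is dropped.  Among qualifying windows (weighted mCHH >=
    ``min_level`` and >= ``min_mc`` methylated CHH sites) the island is
    anchored on the window of highest level; ties break toward the
    gene, then toward the lower coordinate.
    """
    chh = called_sites[called_sites["context"] == "CHH"]
    by_chrom = {}
    for chrom, sub in chh.groupby("chrom"):
        sub = sub.sort_values("pos", kind="stable")
        pos0 = sub["pos"].to_numpy() - 1
        cov = (sub["total_reads"] >= min_coverage).to_numpy()
        mc = sub["mc_reads"].to_numpy() * cov
        tot = sub["total_reads"].to_numpy() * cov
        meth = ((sub["called"] == "methylated").to_numpy()).astype(int)
        by_chrom[chrom] = (
            pos0,
            np.concatenate([[0], np.cumsum(mc)]),
            np.concatenate([[0], np.cumsum(tot)]),
            np.concatenate([[0], np.cumsum(meth)]),
            np.concatenate([[0], np.cumsum(cov.astype(int))]),
        )
    islands: list[ChhIsland] = []
    n_windows = flank // win
    for g in annotation.genes:
        data = by_chrom.get(g.chrom)
        for side in SIDES:
            best = None  # (level, window_index, start) with tie rules
            n_missing = 0
            for k, s, e in _flank_windows(g, side, flank, win):
                if data is None or s >= e:
                    n_missing += 1
                    continue
                pos0, mc_cum, tot_cum, meth_cum, cov_cum = data
                lo, hi = np.searchsorted(pos0, [max(s, 0), max(e, 0)])
                if cov_cum[hi] - cov_cum[lo] == 0:
                    n_missing += 1
                    continue
                total = tot_cum[hi] - tot_cum[lo]
                level = (mc_cum[hi] - mc_cum[lo]) / total if total else 0.0
                n_mc = int(meth_cum[hi] - meth_cum[lo])
                if level >= min_level and n_mc >= min_mc:
                    cand = (level, -k, -s)  # max level, then closest, then left
                    if best is None or cand > best[0]:
                        best = (cand, k, s, e, level, n_mc)
            if n_missing > max_missing * n_windows:
                continue
            if best is not None:
                _, k, s, e, level, n_mc = best
                islands.append(
                    ChhIsland(
                        gene_id=g.gene_id,
                        side=side,
                        chrom=g.chrom,
                        start=max(s, 0),
                        end=e,
                        level=float(level),
                        n_mc=n_mc,
                        window_index=k,
                    )
                )
    return islands


def island_profile(
    islands,
    called_sites: pd.DataFrame,
    annotation: GenomeAnnotation,
    span: int = 2000,
    win: int = 100,
    min_coverage: int = 1,
) -> pd.DataFrame:
    """Methylation around island anchors, gene side fixed to the left.

    Pools reads in ``win``-bp bins across [anchor - span, anchor +
    span) per context, flipping islands whose gene lies on the right so
    that bin 0 is always the gene-proximal end and the last bin the
    distal (heterochromatin-facing) end.
    """
    genes = {g.gene_id: g for g in annotation.genes}
    half = span // win
    n_bins = 2 * half + 1  # the anchor window is the central bin
    mc = {c: np.zeros(n_bins) for c in CONTEXTS}
    tot = {c: np.zeros(n_bins) for c in CONTEXTS}
    covered = called_sites[called_sites["total_reads"] >= min_coverage]
    by_chrom = {
        chrom: sub.sort_values("pos", kind="stable")
        for chrom, sub in covered.groupby("chrom")
    }
    for isl in islands:
        sub = by_chrom.get(isl.chrom)
        if sub is None:
            continue
        lo_coord = isl.start - half * win
        hi_coord = isl.start + (half + 1) * win
        pos0 = sub["pos"].to_numpy() - 1
        lo, hi = np.searchsorted(pos0, [lo_coord, hi_coord])
        if hi <= lo:
            continue
        p = pos0[lo:hi]
        bins = ((p - lo_coord) // win).astype(int)
        g = genes[isl.gene_id]
        gene_center = (g.start + g.end) // 2
        if gene_center > isl.start:  # gene to the right -> flip
            bins = n_bins - 1 - bins
        sctx = sub["context"].to_numpy()[lo:hi]
        smc = sub["mc_reads"].to_numpy()[lo:hi]
        stot = sub["total_reads"].to_numpy()[lo:hi]
        for c in CONTEXTS:
            m = sctx == c
            if m.any():
                np.add.at(mc[c], bins[m], smc[m])
                np.add.at(tot[c], bins[m], stot[m])
    rows = []
    for c in CONTEXTS:
        for b in range(n_bins):
            rows.append(
                {
                    "bin": b,
                    "offset_bp": (b - half) * win,
                    "context": c,
                    "level": mc[c][b] / tot[c][b] if tot[c][b] else np.nan,
                }
            )
    return pd.DataFrame(rows)


def expression_categories(expression: pd.Series) -> pd.Series:
    """NE for zero expression; quartiles Q1-Q4 over positive values."""
    expression = expression.astype(float)
    if (expression < 0).any():
        raise ValueError("expression values must be non-negative")
    cats = pd.Series("NE", index=expression.index, dtype=object)
    pos = expression[expression > 0]
    if len(pos) >= 4:
        edges = np.quantile(pos, [0.25, 0.5, 0.75])
        cats.loc[pos.index] = np.array(["Q1", "Q2", "Q3", "Q4"])[
            np.searchsorted(edges, pos.to_numpy(), side="left")
        ]
    elif len(pos) > 0:
        cats.loc[pos.index] = "Q4"
    return cats


def expression_association(
    islands,
    expression: pd.Series,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Island frequency per expression category with tests against Q4.

    Genes are split into non-expressed (NE) plus four quartiles of
    positive expression; per category and side, the proportion of genes
    bearing an island is compared with the fourth quartile by a
    two-proportion chi-square test with continuity correction.
    """
    cats = expression_categories(expression)
    if cats.nunique() < 2:
        raise ValueError("need at least two non-empty expression categories")
    has_island = {side: set() for side in SIDES}
    for isl in islands:
        has_island[isl.side].add(isl.gene_id)
    rows = []
    for side in SIDES:
        genes_with = has_island[side]
        counts = {}
        for cat in EXPRESSION_CATEGORIES:
            idx = cats.index[cats == cat]
            n = len(idx)
            k = sum(1 for g in idx if g in genes_with)
            counts[cat] = (k, n)
        k4, n4 = counts.get("Q4", (0, 0))
        for cat in EXPRESSION_CATEGORIES:
            k, n = counts[cat]
            if n == 0:
                continue
            if cat == "Q4" or n4 == 0:
                p = np.nan
            else:
                table = np.array([[k, n - k], [k4, n4 - k4]])
                if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
                    p = 1.0
                else:
                    p = float(chi2_contingency(table, correction=True)[1])
            rows.append(
                {
                    "side": side,
                    "category": cat,
                    "n_genes": n,
                    "n_island": k,
                    "proportion": k / n if n else np.nan,
                    "p_vs_Q4": p,
                    "significant": bool(p < alpha) if not np.isnan(p) else False,
                }
            )
    return pd.DataFrame(rows)
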