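"""Genome-scale methylation summaries.

Weighted methylation level, per-context proportions of all methylated
sites, per-site level distributions, strand symmetry of CG/CHG
methylation, sliding chromosomal windows with gene-density
correlations, and feature-anchored metaplots.

The *weighted* level of a set of cytosines is
``sum(mc_reads) / sum(total_reads)`` — each read is one observation, so
deep sites weigh more and the statistic is robust to uneven coverage.
The *per-site* level ``mc_reads / total_reads`` of a single cytosine
estimates the fraction of cells methylated there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CONTEXTS, GenomeAnnotation

_SYMMETRY_OFFSET = {"CG": 1, "CHG": 2}


def weighted_level(
    sites: pd.DataFrame, context: str | None = None, min_coverage: int = 1
) -> float:
    """Weighted methylation level over the covered sites of a context.

    Returns NaN (missing, not zero) when no site reaches
    ``min_coverage`` reads.
    """
    sub = sites
    if context is not None:
        sub = sub[sub["context"] == context]
    sub = sub[sub["total_reads"] >= min_coverage]
    total = sub["total_reads"].sum()
    if total == 0:
        return float("nan")
    return float(sub["mc_reads"].sum() / total)


def context_proportions(called_sites: pd.DataFrame) -> dict[str, float]:
    """Fraction each context contributes to all methylated-called sites."""
    meth = called_sites[called_sites["called"] == "methylated"]
    n = len(meth)
    if n == 0:
        return {c: float("nan") for c in CONTEXTS}
    counts = meth["context"].value_counts()
    return {c: float(counts.get(c, 0)) / n for c in CONTEXTS}


def per_site_distribution(
    called_sites: pd.DataFrame, context: str, bins=20
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of per-site levels of methylated-called cytosines.

    Only sites called methylated enter (their coverage already met the
    calling floor).  Returns (counts, bin_edges) over [0, 1].
    """
    sub = called_sites[
        (called_sites["context"] == context)
        & (called_sites["called"] == "methylated")
    ]
    levels = sub["mc_reads"].to_numpy() / sub["total_reads"].to_numpy()
    return np.histogram(levels, bins=bins, range=(0.0, 1.0))


def symmetry_pairs(
    called_sites: pd.DataFrame, context: str, min_coverage: int = 3
) -> pd.DataFrame:
    """Pair Watson/Crick cytosines of a symmetric context.

    CG partners sit at plus-strand pos i / minus-strand pos i+1; CHG at
    i / i+2 (minus-strand sites are keyed by the position of the G on
    the reference).  Only pairs with both partners at or above
    ``min_coverage`` are returned, with per-site levels and call flags.
    """
    if context not in _SYMMETRY_OFFSET:
        raise ValueError(
            f"symmetry is defined for CG and CHG only (CHH is asymmetric); "
            f"got {context!r}"
        )
    offset = _SYMMETRY_OFFSET[context]
    sub = called_sites[
        (called_sites["context"] == context)
        & (called_sites["total_reads"] >= min_coverage)
    ]
    plus = sub[sub["strand"] == "+"].copy()
    minus = sub[sub["strand"] == "-"].copy()
    minus = minus.assign(partner_pos=minus["pos"] - offset)
    merged = plus.merge(
        minus,
        left_on=["chrom", "pos"],
        right_on=["chrom", "partner_pos"],
        suffixes=("_plus", "_minus"),
    )
    if merged.empty:
        return pd.DataFrame(
            columns=[
                "chrom", "pos", "plus_level", "minus_level",
                "plus_methylated", "minus_methylated",
            ]
        )
    out = pd.DataFrame(
        {
            "chrom": merged["chrom"],
            "pos": merged["pos_plus"],
            "plus_level": merged["mc_reads_plus"] / merged["total_reads_plus"],
            "minus_level": merged["mc_reads_minus"] / merged["total_reads_minus"],
            "plus_methylated": merged["called_plus"] == "methylated",
            "minus_methylated": merged["called_minus"] == "methylated",
        }
    )
    return out


def symmetry_analysis(
    called_sites: pd.DataFrame,
    context: str,
    threshold: float = 0.40,
    min_coverage: int = 3,
) -> tuple[pd.DataFrame, float]:
    """Classify methylated cytosines as symmetric or asymmetric.

    A methylated site whose strand partner's per-site level is at or
    above ``threshold`` (default 40 %) counts as symmetrically
    methylated; below it, asymmetric.  Returns the pair table plus the
    asymmetry fraction over all methylated members of covered pairs
    (NaN when there are none).
    """
    pairs = symmetry_pairs(called_sites, context, min_coverage=min_coverage)
    if pairs.empty:
        return pairs, float("nan")
    sym = 0
    asym = 0
    plus_m = pairs["plus_methylated"].to_numpy()
    minus_m = pairs["minus_methylated"].to_numpy()
    plus_l = pairs["plus_level"].to_numpy()
    minus_l = pairs["minus_level"].to_numpy()
    sym += int(np.sum(plus_m & (minus_l >= threshold)))
    asym += int(np.sum(plus_m & (minus_l < threshold)))
    sym += int(np.sum(minus_m & (plus_l >= threshold)))
    asym += int(np.sum(minus_m & (plus_l < threshold)))
    frac = asym / (sym + asym) if (sym + asym) else float("nan")
    return pairs, frac


def window_profile(
    sites: pd.DataFrame,
    annotation: GenomeAnnotation | None,
    chrom_lengths: dict[str, int],
    window: int = 100_000,
    step: int = 50_000,
    min_coverage: int = 1,
) -> pd.DataFrame:
    """Per-window weighted levels and gene counts across chromosomes.

    Windows of ``window`` bp slide every ``step`` bp; the trailing
    window is truncated at the chromosome end and flagged ``partial``.
    Genes are assigned to every window containing their interval
    midpoint.
    """
    if window < step:
        raise ValueError("window must be >= step")
    gene_mid: dict[str, np.ndarray] = {}
    if annotation is not None:
        for chrom, genes in annotation.genes_by_chrom().items():
            gene_mid[chrom] = np.sort(
                np.array([(g.start + g.end) // 2 for g in genes])
            )
    rows = []
    for chrom, length in chrom_lengths.items():
        sub = sites[(sites["chrom"] == chrom) & (sites["total_reads"] >= min_coverage)]
        sub = sub.sort_values("pos", kind="stable")
        pos0 = sub["pos"].to_numpy() - 1
        mc_cum = np.concatenate([[0], np.cumsum(sub["mc_reads"].to_numpy())])
        tot_cum = np.concatenate([[0], np.cumsum(sub["total_reads"].to_numpy())])
        ctx = sub["context"].to_numpy()
        ctx_cums = {}
        for c in CONTEXTS:
            m = ctx == c
            ctx_cums[c] = (
                np.concatenate([[0], np.cumsum(sub["mc_reads"].to_numpy() * m)]),
                np.concatenate([[0], np.cumsum(sub["total_reads"].to_numpy() * m)]),
            )
        mids = gene_mid.get(chrom, np.array([], dtype=int))
        for start in range(0, length, step):
            end = min(start + window, length)
            if end <= start:
                continue
            lo, hi = np.searchsorted(pos0, [start, end])
            row = {
                "chrom": chrom,
                "start": start,
                "end": end,
                "partial": end - start < window,
                "gene_count": int(
                    np.searchsorted(mids, end) - np.searchsorted(mids, start)
                ),
            }
            for c in CONTEXTS:
                mcc, totc = ctx_cums[c]
                tot = totc[hi] - totc[lo]
                row[f"level_{c}"] = (mcc[hi] - mcc[lo]) / tot if tot else np.nan
            rows.append(row)
            if end >= length:
                break
    return pd.DataFrame(rows)


def window_gene_correlation(windows: pd.DataFrame, context: str) -> float:
    """Pearson correlation between per-window gene count and level.

    NaN when fewer than 3 informative windows remain or either variable
    is constant.
    """
    col = f"level_{context}"
    sub = windows.dropna(subset=[col])
    if len(sub) < 3:
        return float("nan")
    x = sub["gene_count"].to_numpy(dtype=float)
    y = sub[col].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y)[0])


def feature_metaplot(
    sites: pd.DataFrame,
    features,
    flank: int = 2000,
    body_bins: int = 20,
    flank_bins: int = 20,
    min_coverage: int = 1,
) -> pd.DataFrame:
    """Pooled methylation profile upstream, across, and downstream of features.

    Flanks are cut into ``flank_bins`` fixed-width bins; the feature
    body is length-normalised into ``body_bins`` bins (a body shorter
    than ``body_bins`` bp is pooled into its first body bin).  Features
    on the minus strand are reversed so bin 0 is always the distal 5'
    flank.  Read counts are pooled over all features per (bin, context)
    and returned as weighted levels in a tidy frame with columns bin,
    segment (upstream/body/downstream), context, level, mc_reads,
    total_reads.

    ``features`` may be GeneModel/RepeatFeature objects or
    (chrom, start, end, strand) tuples.
    """
    n_bins = 2 * flank_bins + body_bins
    mc = {c: np.zeros(n_bins) for c in CONTEXTS}
    tot = {c: np.zeros(n_bins) for c in CONTEXTS}
    covered = sites[sites["total_reads"] >= min_coverage]
    by_chrom = {
        chrom: sub.sort_values("pos", kind="stable")
        for chrom, sub in covered.groupby("chrom")
    }
    flank_width = flank / flank_bins
    for feat in features:
        if isinstance(feat, tuple):
            chrom, start, end, strand = feat
        else:
            chrom, start, end, strand = feat.chrom, feat.start, feat.end, feat.strand
        sub = by_chrom.get(chrom)
        if sub is None or end <= start:
            continue
        pos0 = sub["pos"].to_numpy() - 1
        lo, hi = np.searchsorted(pos0, [start - flank, end + flank])
        if hi <= lo:
            continue
        p = pos0[lo:hi]
        smc = sub["mc_reads"].to_numpy()[lo:hi]
        stot = sub["total_reads"].to_numpy()[lo:hi]
        sctx = sub["context"].to_numpy()[lo:hi]
        length = end - start
        bins = np.empty(len(p), dtype=int)
        up = p < start
        down = p >= end
        body = ~up & ~down
        bins[up] = np.minimum(
            flank_bins - 1, ((p[up] - (start - flank)) / flank_width).astype(int)
        )
        if length < body_bins:
            bins[body] = flank_bins  # pooled into one bin
        else:
            bins[body] = flank_bins + np.minimum(
                body_bins - 1, ((p[body] - start) * body_bins // length).astype(int)
            )
        bins[down] = flank_bins + body_bins + np.minimum(
            flank_bins - 1, ((p[down] - end) / flank_width).astype(int)
        )
        if strand == "-":
            bins = n_bins - 1 - bins
        for c in CONTEXTS:
            m = sctx == c
            if m.any():
                np.add.at(mc[c], bins[m], smc[m])
                np.add.at(tot[c], bins[m], stot[m])
    segment = (
        ["upstream"] * flank_bins + ["body"] * body_bins + ["downstream"] * flank_bins
    )
    rows = []
    for c in CONTEXTS:
        with np.errstate(invalid="ignore", divide="ignore"):
            level = np.where(tot[c] > 0, mc[c] / np.maximum(tot[c], 1), np.nan)
        for b in range(n_bins):
            rows.append(
                {
                    "bin": b,
                    "segment": segment[b],
                    "context": c,
                    "level": level[b],
                    "mc_reads": mc[c][b],
                    "total_reads": tot[c][b],
                }
            )
    return pd.DataFrame(rows)
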