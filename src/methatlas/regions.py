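"""Segmentation of methylated cytosines into context-specific regions.

For one context at a time, the genome is tiled into 25-bp windows;
windows holding at least one methylated-called cytosine of that context
are kept and merged when the gap between them is at most 100 bp.  Each
merged block is then trimmed so that its boundaries are the first and
last methylated cytosine, the weighted level is recomputed over *all*
covered sites of the context inside the trimmed span, and blocks with
fewer than five methylated cytosines are discarded.  Regions are graded
into four level groups: 1 (< 5 %), 2 (5–15 %), 3 (15–25 %),
4 (>= 25 %), levels as fractions with half-open-upward tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CONTEXTS


@dataclass
class MethRegion:
    """A methylated region; start/end are 1-based inclusive mC positions."""

    chrom: str
    start: int
    end: int
    context: str
    n_mc: int
    level: float
    group: int

    @property
    def size(self) -> int:
        return self.end - self.start + 1


def grade_region(level: float) -> int:
    """Map a weighted level (fraction) to level group 1-4."""
    if level < 0.05:
        return 1
    if level < 0.15:
        return 2
    if level < 0.25:
        return 3
    return 4


def call_regions(
    called_sites: pd.DataFrame,
    context: str,
    window: int = 25,
    merge_distance: int = 100,
    min_mc: int = 5,
    min_coverage: int = 1,
) -> list[MethRegion]:
    """Segment one context's methylated cytosines into regions.

    Window tiling is anchored at position 0 of every chromosome; two
    kept windows are merged when the gap between the end of one and the
    start of the next is at most ``merge_distance`` bp.  The level of a
    region is the weighted methylation over all covered sites of the
    context within the refined span (methylated or not).
    """
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r}")
    sub = called_sites[called_sites["context"] == context]
    regions: list[MethRegion] = []
    for chrom, chrom_sites in sub.groupby("chrom", sort=True):
        chrom_sites = chrom_sites.sort_values("pos", kind="stable")
        covered = chrom_sites[chrom_sites["total_reads"] >= min_coverage]
        cov_pos = covered["pos"].to_numpy()
        cov_mc = covered["mc_reads"].to_numpy()
        cov_tot = covered["total_reads"].to_numpy()
        mc_cum = np.concatenate([[0], np.cumsum(cov_mc)])
        tot_cum = np.concatenate([[0], np.cumsum(cov_tot)])
        meth_pos = chrom_sites.loc[
            chrom_sites["called"] == "methylated", "pos"
        ].to_numpy()
        if len(meth_pos) == 0:
            continue
        wins = np.unique((meth_pos - 1) // window)
        # merge consecutive kept windows: gap (in bp) between window
        # intervals [w*window, (w+1)*window) must be <= merge_distance
        breaks = np.nonzero((np.diff(wins) - 1) * window > merge_distance)[0]
        block_starts = np.concatenate([[0], breaks + 1])
        block_ends = np.concatenate([breaks, [len(wins) - 1]])
        for bs, be in zip(block_starts, block_ends):
            span_lo = wins[bs] * window + 1  # 1-based window span
            span_hi = (wins[be] + 1) * window
            in_span = meth_pos[(meth_pos >= span_lo) & (meth_pos <= span_hi)]
            start, end = int(in_span[0]), int(in_span[-1])
            n_mc = len(in_span)
            if n_mc < min_mc:
                continue
            lo, hi = np.searchsorted(cov_pos, [start, end + 1])
            total = tot_cum[hi] - tot_cum[lo]
            level = float((mc_cum[hi] - mc_cum[lo]) / total) if total else 0.0
            regions.append(
                MethRegion(
                    chrom=chrom,
                    start=start,
                    end=end,
                    context=context,
                    n_mc=n_mc,
                    level=level,
                    group=grade_region(level),
                )
            )
    return regions


def region_size_summary(regions) -> pd.DataFrame:
    """Per-group counts with size and level quantiles.

    Quantiles are 0/25/50/75/100 % of region size (end - start + 1, bp)
    and weighted level.  Empty input yields an empty frame.
    """
    if not regions:
        return pd.DataFrame(
            columns=["group", "count"]
            + [f"size_q{q}" for q in (0, 25, 50, 75, 100)]
            + [f"level_q{q}" for q in (0, 25, 50, 75, 100)]
        )
    df = pd.DataFrame(
        {
            "group": [r.group for r in regions],
            "size": [r.size for r in regions],
            "level": [r.level for r in regions],
        }
    )
    rows = []
    for group, sub in df.groupby("group"):
        row = {"group": group, "count": len(sub)}
        for q in (0, 25, 50, 75, 100):
            row[f"size_q{q}"] = float(np.percentile(sub["size"], q))
            row[f"level_q{q}"] = float(np.percentile(sub["level"], q))
        rows.append(row)
    return pd.DataFrame(rows)
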