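"""Gene methylation-state classification.

Genes are sorted into four classes by binomial tests on the number of
methylated cytosines in the coding sequence (CDS) of the primary
transcript, per context, against a *pooled* expected rate — the
fraction of methylated CDS cytosines over all coding regions of all
samples/species analysed together.  Pooling to a single expected rate
keeps the classification comparable across genomes that differ wildly
in repeat content and global methylation.

Classes (tested in this order, which makes them mutually exclusive):

* ``mCHH`` — >= 20 covered CHH sites and CHH q < alpha (CG/CHG free);
* ``mCHG`` — >= 20 covered CHG sites, CHG q < alpha, CHH not
  significant (CG free);
* ``gbM``  — gene-body CG methylation: >= 20 covered CG sites, CG
  q < alpha, neither CHG nor CHH significant;
* ``UM``   — unmethylated: >= 20 covered sites in every context and no
  significant context;
* ``NA``   — coverage too shallow to decide.

q-values are Benjamini–Hochberg adjusted per context across all genes
of a sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CONTEXTS, GenomeAnnotation

GENE_CLASSES = ("gbM", "mCHG", "mCHH", "UM", "NA")

RATE_FLOOR = 1e-4  # degenerate binomial null guard


@dataclass
class ExpectedRates:
    """Pooled per-context expected CDS methylation rates."""

    rates: dict[str, float]
    covered: dict[str, int]
    methylated: dict[str, int]

    def __getitem__(self, context: str) -> float:
        return self.rates[context]


def gene_context_counts(
    called_sites: pd.DataFrame,
    annotation: GenomeAnnotation,
    feature: str = "cds",
) -> pd.DataFrame:
    """Count covered and methylated cytosines per gene per context.

    "Covered" means the site met the calling coverage floor (it was
    tested); "methylated" means it was called methylated.  Sites are
    assigned to a gene when they fall inside any of its CDS (or exon /
    gene-span) intervals, on either strand.

    Returns a frame indexed by gene id with columns
    ``covered_<CTX>`` / ``meth_<CTX>``.
    """
    tested = called_sites[called_sites["called"] != "untested"]
    by_chrom = {}
    for chrom, sub in tested.groupby("chrom"):
        sub = sub.sort_values("pos", kind="stable")
        pos0 = sub["pos"].to_numpy() - 1
        ctx = sub["context"].to_numpy()
        meth = (sub["called"] == "methylated").to_numpy()
        cums = {}
        for c in CONTEXTS:
            m = ctx == c
            cums[c] = (
                np.concatenate([[0], np.cumsum(m)]),
                np.concatenate([[0], np.cumsum(m & meth)]),
            )
        by_chrom[chrom] = (pos0, cums)
    rows = []
    for g in annotation.genes:
        row = {"gene_id": g.gene_id}
        for c in CONTEXTS:
            row[f"covered_{c}"] = 0
            row[f"meth_{c}"] = 0
        if g.chrom in by_chrom:
            pos0, cums = by_chrom[g.chrom]
            if feature == "cds":
                intervals = g.cds
            elif feature == "exon":
                intervals = g.exons
            else:
                intervals = [(g.start, g.end)]
            for s, e in intervals:
                lo, hi = np.searchsorted(pos0, [s, e])
                for c in CONTEXTS:
                    cov_cum, meth_cum = cums[c]
                    row[f"covered_{c}"] += int(cov_cum[hi] - cov_cum[lo])
                    row[f"meth_{c}"] += int(meth_cum[hi] - meth_cum[lo])
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")


def pooled_expected_rates(count_tables: Iterable[pd.DataFrame]) -> ExpectedRates:
    """Pool methylated / covered CDS site counts over samples.

    The rate per context is the summed methylated count divided by the
    summed covered count (not a mean of per-sample rates).  A context
    with zero covered sites raises; a pooled rate of exactly zero is
    floored at 1e-4.
    """
    covered = {c: 0 for c in CONTEXTS}
    meth = {c: 0 for c in CONTEXTS}
    for tab in count_tables:
        for c in CONTEXTS:
            covered[c] += int(tab[f"covered_{c}"].sum())
            meth[c] += int(tab[f"meth_{c}"].sum())
    rates = {}
    for c in CONTEXTS:
        if covered[c] == 0:
            raise ValueError(f"no covered CDS sites in context {c}")
        rates[c] = max(meth[c] / covered[c], RATE_FLOOR)
    return ExpectedRates(rates=rates, covered=covered, methylated=meth)


def classify_genes(
    counts: pd.DataFrame,
    rates: ExpectedRates,
    min_sites: int = 20,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Binomial tests per gene per context, BH per context, class labels.

    For each gene and context with at least one covered site the
    one-sided upper-tail p-value P[X >= meth | covered, expected rate]
    is computed; q-values are BH-adjusted per context over the genes
    meeting the ``min_sites`` coverage rule (the testable set).

    Returns the counts frame augmented with ``p_<CTX>``, ``q_<CTX>``
    and ``gene_class``.
    """
    if (counts[[f"meth_{c}" for c in CONTEXTS]].to_numpy() < 0).any() or (
        counts[[f"covered_{c}" for c in CONTEXTS]].to_numpy() < 0
    ).any():
        raise ValueError("negative site counts")
    out = counts.copy()
    for c in CONTEXTS:
        n = out[f"covered_{c}"].to_numpy()
        k = out[f"meth_{c}"].to_numpy()
        p = np.full(len(out), np.nan)
        has = n > 0
        p[has] = stats.binom.sf(k[has] - 1, n[has], rates[c])
        q = np.full(len(out), np.nan)
        testable = n >= min_sites
        if testable.any():
            q[testable] = multipletests(p[testable], method="fdr_bh")[1]
        out[f"p_{c}"] = p
        out[f"q_{c}"] = q

    def sig(ctx, row):
        qv = row[f"q_{ctx}"]
        return (not np.isnan(qv)) and qv < alpha

    def ok(ctx, row):
        return row[f"covered_{ctx}"] >= min_sites

    labels = []
    for _, row in out.iterrows():
        if ok("CHH", row) and sig("CHH", row):
            labels.append("mCHH")
        elif ok("CHG", row) and sig("CHG", row) and not sig("CHH", row):
            labels.append("mCHG")
        elif (
            ok("CG", row)
            and sig("CG", row)
            and not sig("CHG", row)
            and not sig("CHH", row)
        ):
            labels.append("gbM")
        elif ok("CG", row) and ok("CHG", row) and ok("CHH", row):
            labels.append("UM")
        else:
            labels.append("NA")
    out["gene_class"] = labels
    return out


def find_mcg_tss_genes(
    cg_regions: Sequence,
    chg_regions: Sequence,
    chh_regions: Sequence,
    annotation: GenomeAnnotation,
    flank: int = 1000,
) -> set[str]:
    """Genes whose TSS lies in a CG region with no non-CG region nearby.

    The TSS is the strand-aware first transcribed base; "nearby" means
    any mCHG or mCHH region intersecting the gene interval extended by
    ``flank`` bp on both sides.
    """

    def by_chrom(regions):
        out: dict[str, list] = {}
        for r in regions:
            out.setdefault(r.chrom, []).append((r.start - 1, r.end))  # 0-based
        return out

    cg = by_chrom(cg_regions)
    noncg = by_chrom(list(chg_regions) + list(chh_regions))
    hits = set()
    for g in annotation.genes:
        tss = g.tss_base
        in_cg = any(s <= tss < e for s, e in cg.get(g.chrom, ()))
        if not in_cg:
            continue
        lo, hi = g.start - flank, g.end + flank
        blocked = any(s < hi and e > lo for s, e in noncg.get(g.chrom, ()))
        if not blocked:
            hits.add(g.gene_id)
    return hits


def te_proximity_flags(
    annotation: GenomeAnnotation, flank: int = 2000
) -> pd.DataFrame:
    """Per-gene booleans: repeat/TE within ``flank`` bp upstream, within,
    or ``flank`` bp downstream (upstream/downstream are strand-aware)."""
    reps: dict[str, list[tuple[int, int]]] = {}
    for r in annotation.repeats:
        reps.setdefault(r.chrom, []).append((r.start, r.end))
    rows = []
    for g in annotation.genes:
        chrom_reps = reps.get(g.chrom, ())

        def overlaps(lo, hi):
            return any(s < hi and e > lo for s, e in chrom_reps)

        if g.strand == "+":
            up = overlaps(g.start - flank, g.start)
            down = overlaps(g.end, g.end + flank)
        else:
            up = overlaps(g.end, g.end + flank)
            down = overlaps(g.start - flank, g.start)
        rows.append(
            {
                "gene_id": g.gene_id,
                "upstream": up,
                "within": overlaps(g.start, g.end),
                "downstream": down,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")
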