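"""Binomial methylation-site calling against the bisulfite non-conversion rate.

Bisulfite treatment converts unmethylated cytosines to uracil (read as
T); methylated cytosines are protected.  Conversion is imperfect, so an
unmethylated site still shows a small fraction of C reads — the
non-conversion rate, estimated from DNA known to be unmethylated
(spiked-in lambda phage or the chloroplast genome).  A cytosine is
called methylated when its methylated-read count is improbably high
under a Binomial(total_reads, non-conversion) null, with
Benjamini–Hochberg control of the false discovery rate across all
tested sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CALLED = ("methylated", "unmethylated", "untested")


@dataclass
class NonConversionEstimate:
    """Estimated rate at which unmethylated cytosines escape conversion."""

    rate: float
    source: str = "configured"
    n_reads: int = 0

    def __post_init__(self):
        if not 0 <= self.rate < 1:
            raise ValueError(f"non-conversion rate must be in [0, 1); got {self.rate}")


def estimate_nonconversion(
    sites: pd.DataFrame,
    control_seqs: Iterable[str] | None = None,
    source: str | None = None,
) -> NonConversionEstimate:
    """Pool reads over control-sequence cytosines (all contexts).

    rate = sum(mc_reads) / sum(total_reads).  A rate of exactly zero is
    floored at 1 / (2 * total control reads) so the downstream binomial
    null is non-degenerate.
    """
    sub = sites
    if control_seqs is not None:
        control_seqs = list(control_seqs)
        sub = sites[sites["chrom"].isin(control_seqs)]
    total = int(sub["total_reads"].sum())
    if total == 0:
        raise ValueError(
            "no control reads available to estimate the non-conversion rate; "
            "provide a configured rate instead"
        )
    mc = int(sub["mc_reads"].sum())
    rate = mc / total
    if rate == 0.0:
        rate = 1.0 / (2.0 * total)
    if rate >= 1.0:
        raise ValueError("control reads are fully methylated; not a valid control")
    if source is None:
        source = ",".join(control_seqs) if control_seqs else "all-sites"
    return NonConversionEstimate(rate=rate, source=source, n_reads=total)


def call_sites(
    sites: pd.DataFrame,
    est: NonConversionEstimate | float,
    min_coverage: int = 3,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Call each sufficiently covered cytosine as methylated or not.

    For sites with ``total_reads >= min_coverage`` the one-sided
    upper-tail binomial p-value P[X >= mc_reads | n, rate] is computed
    and BH-adjusted jointly over all tested sites (all contexts
    pooled).  ``called`` is ``methylated`` iff q < fdr; sites below the
    coverage floor are ``untested``.

    Returns a copy of the table with ``p``, ``q`` and ``called``
    columns; the result does not depend on input row order.
    """
    if isinstance(est, (int, float)):
        est = NonConversionEstimate(rate=float(est))
    if not 0 < fdr < 1:
        raise ValueError(f"fdr must be in (0, 1); got {fdr}")
    df = sites.copy()
    n = df["total_reads"].to_numpy()
    k = df["mc_reads"].to_numpy()
    tested = n >= min_coverage
    p = np.full(len(df), np.nan)
    # upper tail including the observed count: sf(k-1) = P[X >= k]
    p[tested] = stats.binom.sf(k[tested] - 1, n[tested], est.rate)
    q = np.full(len(df), np.nan)
    if tested.any():
        q[tested] = multipletests(p[tested], method="fdr_bh")[1]
    called = np.where(
        ~tested, "untested", np.where(q < fdr, "methylated", "unmethylated")
    )
    df["p"] = p
    df["q"] = q
    df["called"] = called
    return df


def is_methylated(sites: pd.DataFrame) -> np.ndarray:
    """Boolean mask of sites called methylated (requires a called table)."""
    return (sites["called"] == "methylated").to_numpy()


def is_covered(sites: pd.DataFrame) -> np.ndarray:
    """Boolean mask of sites that were tested (coverage floor met)."""
    return (sites["called"] != "untested").to_numpy()
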