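"""Gene-level sequence features and permutation comparisons.

CG observed/expected ratio, CDS length and exon number per gene, and a
label-permutation test used to compare gene-body-methylated (gbM)
against unmethylated (UM) gene groups.  A depressed CG [O/E] is the
classic footprint of historical deamination of methylated cytosines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenomeAnnotation, revcomp

STOP_CODONS = ("TAA", "TGA", "TAG")


def cg_observed_expected(cds_sequence: str) -> float:
    """CG dinucleotide observed/expected ratio of a coding sequence.

    O/E = (N_CG * L) / (N_C * N_G): the count of CG dinucleotides over
    all L-1 adjacent pairs, relative to the expectation from the
    sequence's own C and G content.  A sequence with no CG dinucleotide
    scores 0.
    """
    seq = cds_sequence.upper()
    length = len(seq)
    if length == 0:
        raise ValueError("empty CDS sequence")
    n_cg = seq.count("CG")
    if n_cg == 0:
        return 0.0
    n_c = seq.count("C")
    n_g = seq.count("G")
    return n_cg * length / (n_c * n_g)


@dataclass
class PermutationResult:
    observed: float
    p_value: float
    reps: int


def permutation_test(
    values_a,
    values_b,
    reps: int = 100_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> PermutationResult:
    """Two-group label-permutation test on |mean(a) - mean(b)|.

    The group labels are shuffled ``reps`` times and
    p = (1 + #{permuted statistic >= observed}) / (reps + 1); the +1
    correction keeps p away from zero.  Seeded and reproducible.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    observed = abs(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    n_a, n = len(a), len(pooled)
    total = pooled.sum()
    if rng is None:
        rng = np.random.default_rng(seed)
    hits = 0
    chunk = max(1, min(reps, 20_000_000 // max(n, 1)))
    done = 0
    while done < reps:
        r = min(chunk, reps - done)
        # random subsets of size n_a via argpartition of random keys
        keys = rng.random((r, n))
        idx = np.argpartition(keys, n_a - 1, axis=1)[:, :n_a]
        sum_a = np.take(pooled, idx).sum(axis=1)
        mean_a = sum_a / n_a
        mean_b = (total - sum_a) / (n - n_a)
        stat = np.abs(mean_a - mean_b)
        hits += int(np.sum(stat >= observed - 1e-12))
        done += r
    return PermutationResult(
        observed=observed, p_value=(1 + hits) / (reps + 1), reps=reps
    )


def extract_cds_sequence(gene, genome: dict[str, str]) -> str:
    """Spliced, strand-oriented CDS sequence of a gene."""
    seq = genome[gene.chrom]
    parts = [seq[s:e] for s, e in sorted(gene.cds)]
    cds = "".join(parts).upper()
    if gene.strand == "-":
        cds = revcomp(cds)
    return cds


def feature_table(annotation: GenomeAnnotation, genome) -> pd.DataFrame:
    """CDS length, exon count, CG [O/E] and ORF validity per gene.

    ``full_orf`` flags CDS that start with ATG, end with a stop codon,
    and have a length divisible by 3; it is informational, not a
    filter.  Genes with no CDS are skipped with a diagnostic column in
    mind — they simply do not appear.
    """
    from .io import load_fasta
    from collections.abc import Mapping

    if not isinstance(genome, Mapping):
        genome = load_fasta(genome)
    rows = []
    for g in annotation.genes:
        if g.cds_length == 0:
            continue
        cds = extract_cds_sequence(g, genome)
        rows.append(
            {
                "gene_id": g.gene_id,
                "cds_length": len(cds),
                "exon_count": g.exon_count,
                "cg_oe": cg_observed_expected(cds),
                "full_orf": (
                    cds.startswith("ATG")
                    and cds[-3:] in STOP_CODONS
                    and len(cds) % 3 == 0
                ),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["cds_length", "exon_count", "cg_oe", "full_orf"]
        ).rename_axis("gene_id")
    return pd.DataFrame(rows).set_index("gene_id")


def compare_gene_groups(
    features: pd.DataFrame,
    classes: pd.Series,
    group_a: str = "gbM",
    group_b: str = "UM",
    columns=("cds_length", "exon_count", "cg_oe"),
    reps: int = 100_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Permutation comparison of gene features between two classes."""
    classes = classes.reindex(features.index)
    a = features[classes == group_a]
    b = features[classes == group_b]
    rows = []
    for col in columns:
        res = permutation_test(a[col], b[col], reps=reps, seed=seed)
        rows.append(
            {
                "feature": col,
                f"mean_{group_a}": float(a[col].mean()),
                f"mean_{group_b}": float(b[col].mean()),
                "observed_diff": res.observed,
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(rows)
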