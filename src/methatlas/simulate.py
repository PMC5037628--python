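"""Synthetic methylome generator with planted, recorded ground truth.

The generator emulates the structure of a small plant genome as seen by
whole-genome bisulfite sequencing:

* a compartmentalised chromosome — a central repeat-rich
  heterochromatic block flanked by gene-rich euchromatic arms;
* context- and compartment-specific methylation: every cytosine is
  either truly methylated (then reads report C at a per-context
  per-site level) or unmethylated (reads report C only through
  bisulfite non-conversion); the fraction of methylated cytosines per
  compartment is chosen so that the *weighted* methylation level of the
  compartment matches a configured target rate;
* genes planted with a methylation class (gbM / mCHG / mCHH / UM) that
  sets the fraction of methylated cytosines per context in the CDS;
* optional mCHH islands — a single 100-bp flank window per selected
  gene where every CHH site is methylated at the island level;
* an unmethylated lambda-like control sequence for non-conversion
  estimation;
* Poisson read depth and binomial methylated-read counts with
  configurable non-conversion noise.

The same seed always yields byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .io import (
    CONTEXTS,
    GeneModel,
    GenomeAnnotation,
    RepeatFeature,
    contexts_from_fasta,
    revcomp,
    write_fasta,
    write_gff3,
    write_site_table,
)

GENE_CLASS_NAMES = ("gbM", "mCHG", "mCHH", "UM")


def _default_class_mixture():
    return {"gbM": 0.30, "mCHG": 0.05, "mCHH": 0.05, "UM": 0.60}


def _default_meth_levels():
    # per-site level of a truly methylated cytosine, by context
    return {"CG": 0.8, "CHG": 0.4, "CHH": 0.1}


def _default_compartment_rates():
    # target weighted methylation level per compartment and context
    return {
        "heterochromatin": {"CG": 0.8, "CHG": 0.4, "CHH": 0.1},
        "euchromatin": {"CG": 0.3, "CHG": 0.05, "CHH": 0.02},
    }


def _default_class_site_fracs():
    # probability that a CDS cytosine is truly methylated, by class
    return {
        "gbM": {"CG": 0.8, "CHG": 0.01, "CHH": 0.01},
        "mCHG": {"CG": 0.6, "CHG": 0.6, "CHH": 0.01},
        "mCHH": {"CG": 0.6, "CHG": 0.6, "CHH": 0.4},
        "UM": {"CG": 0.02, "CHG": 0.01, "CHH": 0.01},
    }


def _default_expression():
    # per class: (probability of zero expression, lognormal mu, sigma)
    return {
        "gbM": (0.02, 2.0, 1.0),
        "UM": (0.20, 1.0, 1.0),
        "mCHG": (0.60, 0.0, 1.0),
        "mCHH": (0.60, 0.0, 1.0),
    }


@dataclass
class SimConfig:
    """Parameters of a synthetic methylome; defaults give a 0.8-Mb
    two-compartment genome at 10x depth with 60 classed genes."""

    seed: int = 0
    n_chroms: int = 1
    chrom_length: int = 800_000
    gc: float = 0.36
    het_fraction: float = 0.4
    repeat_density_het: float = 0.25
    repeat_density_eu: float = 0.01
    repeat_length: int = 400
    n_genes: int = 60
    exons_per_gene: tuple[int, int] = (2, 6)
    exon_length: int = 300
    intron_length: int = 150
    gene_spacing: tuple[int, int] = (4200, 5200)
    class_mixture: dict = field(default_factory=_default_class_mixture)
    meth_levels: dict = field(default_factory=_default_meth_levels)
    compartment_rates: dict = field(default_factory=_default_compartment_rates)
    class_site_fracs: dict = field(default_factory=_default_class_site_fracs)
    island_fraction: float = 0.0
    island_level: float = 0.35
    island_window_range: tuple[int, int] = (3, 12)
    mean_depth: float = 10.0
    nonconversion_rate: float = 0.005
    control_length: int = 20_000
    control_name: str = "lambda"
    expression: dict = field(default_factory=_default_expression)

    def __post_init__(self):
        total = sum(self.class_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class mixture must sum to 1; sums to {total}")
        if self.mean_depth < 0:
            raise ValueError("mean depth must be >= 0")
        for frac in (self.gc, self.het_fraction, self.island_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")


@dataclass
class SyntheticTruth:
    """Planted parameters, recorded for recovery tests."""

    compartments: list  # (chrom, start, end, label) 0-based half-open
    gene_classes: dict  # gene id -> class
    islands: list  # dicts: gene_id, side, chrom, start, end (0-based)
    site_level: np.ndarray  # true per-site level, aligned with sites rows
    site_methylated: np.ndarray  # true binary status, aligned with sites rows
    config: SimConfig

    def compartment_of(self, chrom: str, pos0: int) -> str:
        for c, s, e, label in self.compartments:
            if c == chrom and s <= pos0 < e:
                return label
        return "none"


@dataclass
class SimResult:
    genome: dict
    annotation: GenomeAnnotation
    sites: pd.DataFrame
    expression: pd.Series
    truth: SyntheticTruth


def _random_sequence(rng, length: int, gc: float) -> np.ndarray:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.array(list("ACGT"), dtype="U1"), size=length, p=p)


def _place_genes(rng, cfg: SimConfig, arms, chrom: str):
    """Walk the euchromatic arms placing non-overlapping gene models."""
    genes = []
    margin = 2100  # keeps 2-kb flanks inside the arm
    for arm_start, arm_end in arms:
        cursor = arm_start + margin
        while True:
            gap = int(rng.integers(cfg.gene_spacing[0], cfg.gene_spacing[1] + 1))
            n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
            span = n_ex * cfg.exon_length + (n_ex - 1) * cfg.intron_length
            start = cursor
            end = start + span
            if end + margin > arm_end:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            exons = [
                (
                    start + i * (cfg.exon_length + cfg.intron_length),
                    start + i * (cfg.exon_length + cfg.intron_length)
                    + cfg.exon_length,
                )
                for i in range(n_ex)
            ]
            gid = f"gene_{chrom}_{len(genes):04d}"
            genes.append(
                GeneModel(gid, chrom, strand, start, end,
                          exons=exons, cds=list(exons))
            )
            cursor = end + gap
    return genes


def _place_repeats(rng, cfg: SimConfig, chrom: str, het, arms, genes):
    """Repeats tile the heterochromatic block densely, the arms sparsely,
    skipping gene intervals."""
    repeats = []
    gene_iv = sorted((g.start - 50, g.end + 50) for g in genes)

    def clashes(s, e):
        return any(gs < e and ge > s for gs, ge in gene_iv)

    for (lo, hi), density in [(het, cfg.repeat_density_het)] + [
        (a, cfg.repeat_density_eu) for a in arms
    ]:
        if density <= 0 or hi - lo < cfg.repeat_length:
            continue
        mean_gap = cfg.repeat_length * (1 - density) / density
        cursor = lo + int(rng.exponential(mean_gap))
        while cursor + cfg.repeat_length <= hi:
            s, e = cursor, cursor + cfg.repeat_length
            if not clashes(s, e):
                repeats.append(RepeatFeature(chrom, s, e, repeat_class="TE"))
            cursor = e + max(1, int(rng.exponential(mean_gap)))
    return repeats


def _plant_orfs(seq: np.ndarray, genes) -> None:
    """Overwrite start/stop codons so each CDS is a plausible ORF."""
    for g in genes:
        first = sorted(g.cds)[0]
        last = sorted(g.cds)[-1]
        if g.strand == "+":
            seq[first[0] : first[0] + 3] = list("ATG")
            seq[last[1] - 3 : last[1]] = list("TAA")
        else:
            seq[last[1] - 3 : last[1]] = list(revcomp("ATG"))
            seq[first[0] : first[0] + 3] = list(revcomp("TAA"))


def simulate_methylome(config: SimConfig, outdir=None) -> SimResult:
    """Generate genome, annotation, site table, expression, and truth.

    With ``outdir`` set, writes genome.fa, annotation.gff3, sites.tsv,
    expression.tsv and truth.json (per-site truth stays in memory).
    Identical seeds yield byte-identical files.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genome: dict[str, str] = {}
    annotation = GenomeAnnotation()
    compartments = []
    islands_truth = []
    gene_classes: dict[str, str] = {}

    class_names = sorted(cfg.class_mixture)
    class_probs = np.array([cfg.class_mixture[c] for c in class_names])

    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        L = cfg.chrom_length
        seq = _random_sequence(rng, L, cfg.gc)
        het_len = int(L * cfg.het_fraction)
        het_start = (L - het_len) // 2
        het = (het_start, het_start + het_len)
        arms = [(0, het_start), (het[1], L)]
        compartments.append((chrom, het[0], het[1], "heterochromatin"))
        for s, e in arms:
            if e > s:
                compartments.append((chrom, s, e, "euchromatin"))
        genes = _place_genes(rng, cfg, arms, chrom)
        repeats = _place_repeats(rng, cfg, chrom, het, arms, genes)
        _plant_orfs(seq, genes)
        genome[chrom] = "".join(seq)
        annotation.genes.extend(genes)
        annotation.repeats.extend(repeats)

    # trim / check requested gene count
    if cfg.n_genes:
        if len(annotation.genes) < cfg.n_genes:
            raise ValueError(
                f"gene placement infeasible: requested {cfg.n_genes} genes, "
                f"only {len(annotation.genes)} fit; enlarge the genome or "
                f"shrink spacing"
            )
        keep = set(g.gene_id for g in annotation.genes[: cfg.n_genes])
        annotation.genes = [g for g in annotation.genes if g.gene_id in keep]
    else:
        annotation.genes = []

    # assign classes and islands
    for g in annotation.genes:
        gene_classes[g.gene_id] = class_names[
            int(rng.choice(len(class_names), p=class_probs))
        ]
    if cfg.island_fraction > 0 and annotation.genes:
        n_isl = int(round(cfg.island_fraction * len(annotation.genes)))
        chosen = rng.choice(len(annotation.genes), size=n_isl, replace=False)
        for gi in np.sort(chosen):
            g = annotation.genes[int(gi)]
            side = "upstream" if rng.random() < 0.5 else "downstream"
            k = int(
                rng.integers(cfg.island_window_range[0],
                             cfg.island_window_range[1] + 1)
            )
            left = (side == "upstream") == (g.strand == "+")
            if left:
                s, e = g.start - k * 100, g.start - (k - 1) * 100
            else:
                s, e = g.end + (k - 1) * 100, g.end + k * 100
            islands_truth.append(
                {
                    "gene_id": g.gene_id,
                    "side": side,
                    "chrom": g.chrom,
                    "start": int(s),
                    "end": int(e),
                    "window_index": k,
                }
            )

    if cfg.control_length > 0:
        genome[cfg.control_name] = "".join(
            _random_sequence(rng, cfg.control_length, cfg.gc)
        )

    sites = contexts_from_fasta(genome)

    # --- true methylation status and per-site level -----------------------
    n_sites = len(sites)
    frac = np.zeros(n_sites)
    level = np.zeros(n_sites)
    chrom_arr = sites["chrom"].to_numpy()
    pos0_arr = sites["pos"].to_numpy() - 1
    ctx_arr = sites["context"].to_numpy()
    for c in CONTEXTS:
        level[ctx_arr == c] = cfg.meth_levels[c]

    rep_by_chrom: dict[str, list] = {}
    for r in annotation.repeats:
        rep_by_chrom.setdefault(r.chrom, []).append((r.start, r.end))

    for chrom, s, e, label in compartments:
        m = (chrom_arr == chrom) & (pos0_arr >= s) & (pos0_arr < e)
        for c in CONTEXTS:
            mc = m & (ctx_arr == c)
            target = cfg.compartment_rates[label][c]
            frac[mc] = min(1.0, target / cfg.meth_levels[c])
    # repeats behave like heterochromatin wherever they sit
    for chrom, intervals in rep_by_chrom.items():
        sel = chrom_arr == chrom
        sub_mask = _interval_mask_sorted(pos0_arr, sel, intervals)
        for c in CONTEXTS:
            mc = sub_mask & (ctx_arr == c)
            target = cfg.compartment_rates["heterochromatin"][c]
            frac[mc] = min(1.0, target / cfg.meth_levels[c])
    # gene CDS overrides by class
    for g in annotation.genes:
        cls = gene_classes[g.gene_id]
        sel = chrom_arr == g.chrom
        sub_mask = _interval_mask_sorted(pos0_arr, sel, g.cds)
        for c in CONTEXTS:
            mc = sub_mask & (ctx_arr == c)
            frac[mc] = cfg.class_site_fracs[cls][c]
    # islands: every CHH site in the anchor window methylated at island level
    for isl in islands_truth:
        sel = chrom_arr == isl["chrom"]
        sub_mask = _interval_mask_sorted(
            pos0_arr, sel, [(isl["start"], isl["end"])]
        )
        mc = sub_mask & (ctx_arr == "CHH")
        frac[mc] = 1.0
        level[mc] = cfg.island_level
    # control is fully unmethylated
    if cfg.control_length > 0:
        frac[chrom_arr == cfg.control_name] = 0.0
    # undefined contexts carry no signal
    frac[~np.isin(ctx_arr, CONTEXTS)] = 0.0

    status = rng.random(n_sites) < frac
    true_level = np.where(status, level, 0.0)

    total = rng.poisson(cfg.mean_depth, n_sites)
    p_read = true_level + (1.0 - true_level) * cfg.nonconversion_rate
    mc_reads = rng.binomial(total, p_read)
    sites = sites.assign(mc_reads=mc_reads, total_reads=total)
    sites = sites[
        ["chrom", "pos", "strand", "trinucleotide", "mc_reads", "total_reads",
         "context"]
    ]

    # expression per gene by class
    expr = {}
    for g in annotation.genes:
        p_zero, mu, sigma = cfg.expression[gene_classes[g.gene_id]]
        if rng.random() < p_zero:
            expr[g.gene_id] = 0.0
        else:
            expr[g.gene_id] = float(rng.lognormal(mu, sigma))
    expression = pd.Series(expr, name="fpkm", dtype=float)
    expression.index.name = "gene_id"

    truth = SyntheticTruth(
        compartments=compartments,
        gene_classes=gene_classes,
        islands=islands_truth,
        site_level=true_level,
        site_methylated=status,
        config=cfg,
    )
    result = SimResult(genome, annotation, sites, expression, truth)
    if outdir is not None:
        _write_result(result, Path(outdir))
    return result


def _interval_mask_sorted(pos0, chrom_sel, intervals) -> np.ndarray:
    """Mask over all sites: on the selected chromosome and inside any
    interval.  Site positions are sorted within each chromosome."""
    mask = np.zeros(len(pos0), dtype=bool)
    idx = np.nonzero(chrom_sel)[0]
    if len(idx) == 0:
        return mask
    sub = pos0[idx]
    for s, e in intervals:
        lo, hi = np.searchsorted(sub, [s, e])
        mask[idx[lo:hi]] = True
    return mask


def _write_result(result: SimResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(result.genome, outdir / "genome.fa")
    write_gff3(result.annotation, outdir / "annotation.gff3")
    write_site_table(result.sites, outdir / "sites.tsv")
    result.expression.to_csv(outdir / "expression.tsv", sep="\t")
    truth = result.truth
    payload = {
        "config": dataclasses.asdict(truth.config),
        "compartments": truth.compartments,
        "gene_classes": truth.gene_classes,
        "islands": truth.islands,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(payload, fh, indent=1, default=str)


# ---------------------------------------------------------------------------
# phylogenetic simulation
# ---------------------------------------------------------------------------

def random_tree(n_tips: int, seed: int) -> dendropy.Tree:
    """Random coalescent topology with exponential branch lengths."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    from dendropy.simulate import treesim

    tns = dendropy.TaxonNamespace([f"t{i}" for i in range(n_tips)])
    tree = treesim.pure_kingman_tree(
        taxon_namespace=tns, pop_size=1.0, rng=random.Random(seed)
    )
    return tree


def simulate_brownian_traits(
    tree,
    slope: float,
    sigma2: float,
    seed: int,
    x_sigma2: float = 1.0,
    root_x: float = 0.0,
) -> pd.DataFrame:
    """Evolve a predictor x by Brownian motion and y = slope*x + BM noise.

    The noise trait accrues variance ``sigma2`` per unit branch length,
    so y has exactly the phylogenetic error structure PGLS assumes.
    """
    if sigma2 < 0 or x_sigma2 < 0:
        raise ValueError("variances must be non-negative")
    t = tree if isinstance(tree, dendropy.Tree) else dendropy.Tree.get(
        data=str(tree), schema="newick"
    )
    rng = np.random.default_rng(seed)
    x_val: dict = {}
    e_val: dict = {}
    for node in t.preorder_node_iter():
        if node.parent_node is None:
            x_val[node] = root_x
            e_val[node] = 0.0
            continue
        bl = node.edge.length or 0.0
        x_val[node] = x_val[node.parent_node] + rng.normal(
            0.0, np.sqrt(bl * x_sigma2)
        )
        e_val[node] = e_val[node.parent_node] + rng.normal(
            0.0, np.sqrt(bl * sigma2)
        )
    rows = {}
    for leaf in t.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon else str(leaf)
        rows[label] = {"x": x_val[leaf], "y": slope * x_val[leaf] + e_val[leaf]}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "species"
    return df
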