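"""Readers and writers for methylome site tables, genomes, and annotations.

The pipeline's core in-memory container is a pandas DataFrame of cytosine
sites ("site table") with one row per cytosine per strand:

==============  =======================================================
column          meaning
==============  =======================================================
chrom           chromosome / contig name
pos             1-based position of the cytosine *on its own strand*;
                for a minus-strand cytosine this is the position of the
                G on the reference (plus) strand
strand          ``+`` or ``-``
trinucleotide   3-mer starting at the cytosine, read 5'->3' on the
                cytosine's strand
context         ``CG`` / ``CHG`` / ``CHH`` (H = A, T, or C), or
                ``undefined`` when the two downstream bases run off the
                sequence end or contain N
mc_reads        reads supporting methylation (cytosine retained)
total_reads     all reads covering the site
==============  =======================================================

Site calling (:mod:`methatlas.calling`) appends ``p``, ``q`` and
``called`` columns.

Coordinate conventions: site positions are 1-based (allc convention);
all internal interval arithmetic is 0-based half-open; the GFF3
interface is 1-based closed, BED 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CONTEXTS = ("CG", "CHG", "CHH")
UNDEFINED = "undefined"

SITE_COLUMNS = ["chrom", "pos", "strand", "trinucleotide", "mc_reads", "total_reads"]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# context derivation
# ---------------------------------------------------------------------------

def trinucleotide_context(trinucleotides) -> np.ndarray:
    """Assign CG/CHG/CHH context to 3-mers starting with C.

    H is A, T, or C.  Anything else (N anywhere, a first base that is
    not C, or a short string) maps to ``undefined``.
    """
    s = pd.Series(np.asarray(trinucleotides, dtype="U3")).str.upper()
    b1, b2, b3 = s.str[0], s.str[1], s.str[2]
    # both downstream bases must be known: a trailing N or a truncated
    # 3-mer at a contig end leaves the context undefined
    valid = (b1 == "C") & b2.isin(list("ACGT")) & b3.isin(list("ACGT"))
    out = np.select(
        [
            valid & (b2 == "G"),
            valid & (b3 == "G"),
            valid,
        ],
        ["CG", "CHG", "CHH"],
        default=UNDEFINED,
    )
    return out


def _complement_array(arr: np.ndarray) -> np.ndarray:
    return np.select(
        [arr == "A", arr == "C", arr == "G", arr == "T"],
        ["T", "G", "C", "A"],
        default="N",
    )


def load_fasta(path) -> dict[str, str]:
    """Read a FASTA file into a dict of upper-case sequences."""
    from pyfaidx import Fasta

    with Fasta(str(path), rebuild=False) as fa:
        return {name: str(fa[name][:]).upper() for name in fa.keys()}


def write_fasta(genome: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def contexts_from_fasta(genome) -> pd.DataFrame:
    """Enumerate every cytosine on both strands with its context.

    Parameters
    ----------
    genome
        Mapping of chromosome name to sequence, or a FASTA path.

    Returns
    -------
    DataFrame with columns chrom, pos, strand, trinucleotide, context,
    sorted by (chrom, pos, strand).  A plus-strand C at 0-based offset
    ``i`` gets pos ``i+1``; a minus-strand C (a G on the reference) at
    offset ``i`` also gets pos ``i+1``, so symmetric CG partners sit at
    pos ``i`` / ``i+1`` and CHG partners at ``i`` / ``i+2``.
    """
    if not isinstance(genome, Mapping):
        genome = load_fasta(genome)
    frames = []
    for chrom in genome:
        seq = genome[chrom].upper()
        if not seq:
            continue
        arr = np.array(list(seq), dtype="U1")
        pad = np.concatenate([arr, np.array(["N", "N"], dtype="U1")])
        # plus strand: every C
        idx_c = np.nonzero(arr == "C")[0]
        tri_plus = np.char.add(np.char.add(pad[idx_c], pad[idx_c + 1]), pad[idx_c + 2])
        # minus strand: every G on the reference, read 5'->3' on minus
        idx_g = np.nonzero(arr == "G")[0]
        lpad = np.concatenate([np.array(["N", "N"], dtype="U1"), arr])
        comp = _complement_array(lpad)
        tri_minus = np.char.add(
            np.char.add(comp[idx_g + 2], comp[idx_g + 1]), comp[idx_g]
        )
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": np.concatenate([idx_c, idx_g]) + 1,
                    "strand": np.repeat(["+", "-"], [len(idx_c), len(idx_g)]),
                    "trinucleotide": np.concatenate([tri_plus, tri_minus]),
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["chrom", "pos", "strand", "trinucleotide", "context"]
        )
    df = pd.concat(frames, ignore_index=True)
    df["context"] = trinucleotide_context(df["trinucleotide"].to_numpy())
    df = df.sort_values(["chrom", "pos", "strand"], kind="stable").reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# site tables
# ---------------------------------------------------------------------------

def read_site_table(path, *, on_bad: str = "warn") -> pd.DataFrame:
    """Read an allc-style TSV of per-cytosine methylation counts.

    Expects tab-separated columns chrom, pos, strand, trinucleotide,
    mc_reads, total_reads (a header naming them is optional; extra
    columns such as p/q/called from a previous calling run are kept).
    Rows violating ``mc_reads <= total_reads`` are dropped with a
    diagnostic naming the offending line numbers; an unknown strand
    symbol raises.
    """
    if on_bad not in ("warn", "error"):
        raise ValueError("on_bad must be 'warn' or 'error'")
    path = Path(path)
    n_skip = 0
    header = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                n_skip += 1
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 2 and not fields[1].lstrip("-").isdigit():
                header = [f.strip() for f in fields]
                n_skip += 1
            break
    names = header if header is not None else SITE_COLUMNS
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        skiprows=n_skip,
        names=names,
        dtype={"chrom": str, "strand": str, "trinucleotide": str},
    )
    if df.empty:
        df = pd.DataFrame(columns=names)
    for col in ("pos", "mc_reads", "total_reads"):
        if col not in df.columns:
            raise ValueError(f"site table {path} lacks required column {col!r}")
        df[col] = df[col].astype(np.int64)
    df["strand"] = df["strand"].replace({"−": "-"})  # unicode minus
    bad_strand = ~df["strand"].isin(("+", "-"))
    if bad_strand.any():
        raise ValueError(
            f"unknown strand symbol(s) {sorted(df.loc[bad_strand, 'strand'].unique())} "
            f"in {path}"
        )
    bad = (df["mc_reads"] > df["total_reads"]) | (df["mc_reads"] < 0) | (
        df["total_reads"] < 0
    )
    if bad.any():
        lines = (df.index[bad] + n_skip + 1).tolist()
        msg = (
            f"{int(bad.sum())} row(s) with mc_reads > total_reads or negative "
            f"counts rejected in {path} (line numbers: {lines[:20]}"
            + ("...)" if len(lines) > 20 else ")")
        )
        if on_bad == "error":
            raise ValueError(msg)
        warnings.warn(msg)
        df = df[~bad]
    if "context" not in df.columns:
        df["context"] = trinucleotide_context(df["trinucleotide"].to_numpy())
    df = df.sort_values(["chrom", "pos", "strand"], kind="stable").reset_index(drop=True)
    return df


def write_site_table(sites: pd.DataFrame, path) -> None:
    """Write a site table as TSV with a header row (round-trips exactly)."""
    cols = [c for c in SITE_COLUMNS if c in sites.columns]
    cols += [c for c in ("context", "p", "q", "called") if c in sites.columns]
    sites.to_csv(path, sep="\t", index=False, columns=cols)


def validate_sites_against_fasta(sites: pd.DataFrame, genome) -> pd.DataFrame:
    """Cross-check site trinucleotides against the genome sequence.

    Returns the rows whose recorded trinucleotide disagrees with the
    3-mer extracted from the FASTA at (chrom, pos, strand).
    """
    if not isinstance(genome, Mapping):
        genome = load_fasta(genome)
    expected = contexts_from_fasta(genome)
    key = ["chrom", "pos", "strand"]
    merged = sites.merge(
        expected[key + ["trinucleotide"]].rename(
            columns={"trinucleotide": "expected_trinucleotide"}
        ),
        on=key,
        how="left",
    )
    mismatch = merged["trinucleotide"] != merged["expected_trinucleotide"]
    return merged[mismatch]


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A gene with 0-based half-open intervals on the reference strand."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)

    @property
    def tss(self) -> int:
        """Strand-aware 5' end in interval coordinates (start or end)."""
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def tss_base(self) -> int:
        """0-based coordinate of the first transcribed base."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def exon_count(self) -> int:
        return max(1, len(self.exons))


@dataclass
class RepeatFeature:
    chrom: str
    start: int
    end: int
    repeat_class: str = "repeat"
    strand: str = "+"


@dataclass
class GenomeAnnotation:
    genes: list[GeneModel] = field(default_factory=list)
    repeats: list[RepeatFeature] = field(default_factory=list)

    def genes_by_chrom(self) -> dict[str, list[GeneModel]]:
        out: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            out.setdefault(g.chrom, []).append(g)
        for genes in out.values():
            genes.sort(key=lambda g: g.start)
        return out

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


_REPEAT_TYPES = {"repeat_region", "transposable_element", "repeat", "TE",
                 "transposon_fragment", "dispersed_repeat"}


def read_annotation(path) -> GenomeAnnotation:
    """Read gene (and repeat) models from GFF3 or BED.

    GFF3 is 1-based closed; BED 0-based half-open.  Both are unified to
    internal 0-based half-open intervals with strand-aware TSS/TTS.
    Child features that fall outside their parent gene are dropped with
    a warning.  A BED file yields single-exon genes spanning the whole
    interval.
    """
    path = Path(path)
    if path.suffix.lower() in (".bed", ".bed6"):
        return _read_bed_annotation(path)
    return _read_gff3_annotation(path)


def _read_bed_annotation(path) -> GenomeAnnotation:
    genes = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name = f[3] if len(f) > 3 else f"{chrom}:{start}-{end}"
            strand = f[5] if len(f) > 5 and f[5] in "+-" else "+"
            genes.append(
                GeneModel(name, chrom, strand, start, end,
                          exons=[(start, end)], cds=[(start, end)])
            )
    return GenomeAnnotation(genes=genes)


def _read_gff3_annotation(path) -> GenomeAnnotation:
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    repeats: list[RepeatFeature] = []
    for g in db.features_of_type("gene"):
        model = GeneModel(
            gene_id=g.id,
            chrom=g.seqid,
            strand=g.strand if g.strand in "+-" else "+",
            start=g.start - 1,
            end=g.end,
        )
        # primary transcript = first mRNA child; fall back to direct children
        mrnas = list(db.children(g, featuretype="mRNA", order_by="start"))
        parent = mrnas[0] if mrnas else g
        ok = True
        for ftype, target in (("exon", model.exons), ("CDS", model.cds)):
            for child in db.children(parent, featuretype=ftype, order_by="start"):
                s, e = child.start - 1, child.end
                if s < model.start or e > model.end or s >= e:
                    warnings.warn(
                        f"{ftype} {s}-{e} outside gene {g.id} "
                        f"({model.start}-{model.end}); gene dropped"
                    )
                    ok = False
                    break
                target.append((s, e))
            if not ok:
                break
        if not ok:
            continue
        if not model.exons:
            model.exons = [(model.start, model.end)]
        if not model.cds:
            model.cds = list(model.exons)
        genes.append(model)
    for ftype in _REPEAT_TYPES:
        try:
            feats = list(db.features_of_type(ftype))
        except Exception:
            feats = []
        for r in feats:
            repeats.append(
                RepeatFeature(r.seqid, r.start - 1, r.end,
                              repeat_class=r.attributes.get("class", [ftype])[0])
            )
    repeats.sort(key=lambda r: (r.chrom, r.start))
    return GenomeAnnotation(genes=genes, repeats=repeats)


def write_gff3(annotation: GenomeAnnotation, path) -> None:
    """Write genes (gene/mRNA/exon/CDS) and repeats to GFF3 (1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in annotation.genes:
            gid = g.gene_id
            fh.write(
                f"{g.chrom}\tmethatlas\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={gid}\n"
            )
            fh.write(
                f"{g.chrom}\tmethatlas\tmRNA\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={gid}.1;Parent={gid}\n"
            )
            for i, (s, e) in enumerate(sorted(g.exons), 1):
                fh.write(
                    f"{g.chrom}\tmethatlas\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={gid}.1.exon{i};Parent={gid}.1\n"
                )
            for i, (s, e) in enumerate(sorted(g.cds), 1):
                fh.write(
                    f"{g.chrom}\tmethatlas\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={gid}.1.cds{i};Parent={gid}.1\n"
                )
        for r in annotation.repeats:
            fh.write(
                f"{r.chrom}\tmethatlas\trepeat_region\t{r.start + 1}\t{r.end}\t.\t"
                f"{r.strand}\t.\tID={r.chrom}:{r.start}-{r.end};"
                f"class={r.repeat_class}\n"
            )


def read_bed_intervals(path) -> list[tuple[str, int, int, str]]:
    """Read plain BED intervals as (chrom, start, end, name) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append((f[0], int(f[1]), int(f[2]), f[3] if len(f) > 3 else "."))
    return out


def write_regions_bed(regions: Sequence, path) -> None:
    """Write methylated regions as BED6+2 (start/end 0-based half-open).

    Columns: chrom, start, end, name=context, score=level*1000 clamped
    to [0, 1000], strand ('.'), n_mc, group.
    """
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tcontext\tscore\tstrand\tn_mc\tgroup\n")
        for r in regions:
            score = int(min(1000, max(0, round(r.level * 1000))))
            fh.write(
                f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.context}\t{score}\t.\t"
                f"{r.n_mc}\t{r.group}\n"
            )
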