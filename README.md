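# methatlas

Comparative analysis of plant DNA methylomes from whole-genome
bisulfite sequencing (WGBS), at single-base resolution.

Plant genomes carry cytosine methylation in three sequence contexts —
CG, CHG and CHH (H = A, T or C) — maintained by distinct pathways and
distributed very differently across euchromatin, heterochromatin,
genes and transposons. Comparing methylomes across species (or
samples) requires a consistent statistical toolchain: deciding which
cytosines are methylated at all, summarising methylation at the scale
of genomes, windows, regions and genes, and testing cross-species
associations without ignoring phylogeny. `methatlas` implements that
toolchain as a library plus a thin `atlas` command line, and ships a
synthetic-methylome generator with planted ground truth so every stage
is testable end to end without any sequencing data.

## What it computes

* **Site calling** — a cytosine with `total_reads >= 3` is called
  methylated when its methylated-read count `mc` is improbable under
  Binomial(n, ε), where ε is the bisulfite non-conversion rate
  estimated from unmethylated control DNA (lambda spike-in or
  chloroplast): one-sided p = P[X ≥ mc], Benjamini–Hochberg FDR over
  all tested sites, q < 0.05.
* **Genome metrics** — weighted methylation level Σmc/Σtotal per
  context; per-site level distributions; the proportion each context
  contributes to all methylated sites; Watson/Crick symmetry of
  CG/CHG sites (40 % partner-level threshold); 100-kb windows sliding
  every 50 kb with Pearson correlation of methylation against gene
  density; strand-aware metaplots over any feature set.
* **Methylated regions** — 25-bp windows holding a methylated
  cytosine, merged when ≤ 100 bp apart, trimmed to the first/last
  methylated cytosine, kept with ≥ 5 mC, graded into four level
  groups (< 5 %, 5–15 %, 15–25 %, ≥ 25 %).
* **Gene classes** — binomial tests on methylated CDS cytosine counts
  per context against pooled expected CDS rates classify genes as
  gbM (gene-body CG methylation only), mCHG, mCHH, or unmethylated
  (UM), with a ≥ 20-covered-site rule and per-context BH correction;
  plus detection of genes whose TSS sits under a CG region with no
  non-CG region within 1 kb.
* **Gene features** — CG dinucleotide observed/expected ratio
  O/E = N_CG·L / (N_C·N_G), CDS length, exon number, and seeded
  label-permutation tests (default 100,000 replicates) comparing gbM
  vs UM genes.
* **mCHH islands** — 100-bp windows within 2 kb of a gene with
  weighted mCHH ≥ 25 % and ≥ 5 methylated CHH sites; anchored on the
  maximal window; gene flanks with mostly missing data are excluded;
  island incidence is compared across expression quartiles by
  two-proportion chi-square tests.
* **Cross-species statistics** — phylogenetic generalized least
  squares under Brownian motion (V[i,j] = shared root-to-MRCA branch
  length), Bonferroni adjustment, and Fisher's exact tests for
  transposon enrichment near methylated gene classes.
* **Synthetic data** — a deterministic generator producing genome
  FASTA, GFF3 annotation, allc-style site tables, expression tables
  and a recorded truth object: compartmentalised chromosomes, planted
  gene classes, planted flanking mCHH islands, Poisson coverage and
  non-conversion noise.

## Worked example

Simulate a 0.8-Mb methylome, call sites, and classify genes:

```sh
$ atlas simulate --seed 5 --out simdir
295840 sites, 60 genes, 0 planted islands -> simdir

$ atlas call --sites simdir/sites.tsv --control-seqs lambda -o called.tsv
non-conversion rate 0.00474563 (lambda); 77863/295840 sites called methylated -> called.tsv

$ atlas metrics --sites called.tsv --out metrics.json
{
 "weighted_mCG": 0.4820927371112879,
 "weighted_mCHG": 0.18827603052330183,
 "weighted_mCHH": 0.054112649949534644,
 ...
}

$ atlas genes rates --sites called.tsv --gff simdir/annotation.gff3 -o rates.json
{
 "CG": 0.2841063458179701,
 "CHG": 0.08302497687326549,
 "CHH": 0.012160152931180968
}

$ atlas genes classify --sites called.tsv --gff simdir/annotation.gff3 \
      --rates rates.json -o classes.tsv
gene_class
UM      40
gbM     13
mCHH     4
mCHG     3
```

Reading the numbers: about 0.5 % of lambda control reads survived
bisulfite conversion, which becomes the binomial null for site
calling. The genome-wide weighted levels (48 % mCG, 19 % mCHG, 5 %
mCHH) fall in the range typical of angiosperm leaf methylomes and
reflect the heterochromatin-heavy simulation defaults. The pooled CDS
rates are much lower than the genome-wide levels — coding sequence is
relatively methylation-poor — and against them 13/60 genes show
CG-only enrichment (gbM) while 40 are confidently unmethylated.

Region segmentation and island detection follow the same pattern:

```sh
$ atlas regions --sites called.tsv --context CHH -o chh.bed
422 CHH regions -> chh.bed

$ atlas islands --sites called.tsv --gff simdir/annotation.gff3 -o islands.tsv
0 islands -> islands.tsv      # none planted in this run
```

The same operations are available as library functions
(`methatlas.call_sites`, `methatlas.call_regions`,
`methatlas.classify_genes`, `methatlas.pgls_fit`, ...); see the module
docstrings and `docs/methods.md`.

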