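# Methods

This note documents the statistical models, conventions and design
choices behind `methatlas`, and what the synthetic-data experiments
do and do not demonstrate.

## Coordinates and data model

Site tables are allc-style TSVs: one row per cytosine per strand with
1-based positions. A minus-strand cytosine is keyed by the position of
its complementary G on the reference strand, so the two members of a
symmetric pair sit at positions i and i+1 (CG) or i and i+2 (CHG) —
this makes strand-pair lookups unambiguous. All internal interval
arithmetic is 0-based half-open; GFF3 input/output is 1-based closed
and BED 0-based half-open, each format's native convention. A
cytosine's context is determined by its two downstream bases on its
own strand; if those run past the contig end or contain N the context
is `undefined` and the site is excluded from all statistics rather
than guessed.

## Site calling

The null hypothesis for a cytosine is that it is unmethylated and its
C-reads are bisulfite non-conversion events. The non-conversion rate
ε is the pooled ratio Σmc/Σtotal over all cytosines of an
unmethylated control sequence (lambda spike-in or chloroplast); a
control that happens to show zero escapes is floored at
1/(2·total reads) so the null is never degenerate. Each site with at
least 3 reads gets a one-sided upper-tail binomial p-value
P[X ≥ mc | n, ε]; sites below that floor are reported `untested`, not
unmethylated — absence of data is not evidence of absence.

Two decisions here were genuinely open. The test is one-sided because
only an excess of methylation over non-conversion is biologically
interpretable. Benjamini–Hochberg correction is applied once over all
tested sites with the three contexts pooled, because the calling
question ("is this cytosine methylated?") is the same for every
context; per-context FDR variants are deliberately out of scope.

## Weighted vs per-site levels

The weighted level of any site set is Σmc/Σtotal: every read is one
Bernoulli observation, so deep sites carry more weight and the
statistic is insensitive to coverage variation. Sets with no covered
site return NaN (missing), never 0. The per-site level mc/total of an
individual cytosine estimates the fraction of cells methylated there;
per-site distributions are computed over sites *called* methylated,
matching how such distributions characterise maintenance fidelity.
Context proportions are site-count based (the fraction of
methylated-called sites in each context), not read-count based.

Symmetry analysis pairs Watson/Crick CG (offset 1) and CHG (offset 2)
cytosines where both partners have calling-level coverage; a
methylated site whose partner's per-site level is below 40 % counts
as asymmetric. The 40 % threshold is a configurable default; its
empirical derivation (from a CHG-methyltransferase-null control) is
upstream of this package.

Chromosomal windows are 100 kb sliding every 50 kb; the trailing
partial window is kept and flagged, since discarding it would bias
telomeric levels. Genes are assigned to windows by interval midpoint,
which avoids double counting in overlapping windows. Metaplots bin
fixed-width flanks and a length-normalised body (bodies shorter than
the bin count are pooled into one bin), reversing minus-strand
features so bin 0 is always the distal 5' flank.

## Methylated regions

Per context: 25-bp windows anchored at position 0 of each chromosome
(a fixed phase, chosen for determinism); windows holding at least one
methylated-called site are kept; kept windows merge when the gap
between them is at most 100 bp ("within 100 bp" read as the most
permissive gap interpretation); merged blocks are trimmed to the
first/last methylated cytosine; blocks with fewer than five
methylated cytosines are dropped. The region's level is recomputed as
the weighted level over *all* covered sites of the context in the
trimmed span — including unmethylated ones — because a region's level
should reflect its read evidence, not only its called sites. Level
groups partition [0,1] half-open upward: group 1 < 5 %, group 2
5–15 %, group 3 15–25 %, group 4 ≥ 25 %. The region caller is tested
for exact equivalence against an independent repeated-pass merge
oracle on randomised instances.

## Gene classification

For each gene, covered (tested) and methylated cytosines are counted
per context within the CDS of the primary transcript. Expected rates
are pooled over all samples analysed together — summed methylated
counts over summed covered counts, not a mean of per-sample rates —
which keeps classification comparable across genomes with wildly
different repeat loads; a pooled rate of zero is floored at 1e-4.
One-sided binomial tests per gene per context are BH-corrected per
context across genes with at least 20 covered sites in that context
(the testable set; shallower genes cannot reach significance and
would only dilute the correction).

The class cascade mCHH → mCHG → gbM encodes the biology that non-CG
methylation co-occurs with mCG: an mCHH gene may be anything in CG
and CHG; an mCHG gene must not be CHH-significant; a gbM gene must be
CG-significant only. UM ("unmethylated") demands ≥ 20 covered sites
in *every* context with nothing significant — unmethylated is a
positive claim, so genes with inadequate coverage are NA rather than
UM. mCG-TSS genes are those whose strand-aware first transcribed base
lies inside a CG region with no CHG/CHH region intersecting the gene
± 1 kb.

## Gene features and permutation tests

CG [O/E] uses the classical form N_CG·L/(N_C·N_G), the observed
CG-dinucleotide count over all L−1 adjacent pairs relative to the
expectation from the sequence's own C and G counts; a sequence with
no CG dinucleotide scores 0 (the N_C·N_G = 0 corner can then never
arise with a nonzero numerator). Group comparisons use a
label-permutation test on |mean difference| with the +1 small-sample
correction, p = (1 + #{perm ≥ obs})/(reps + 1); the default 100,000
replicates make the Monte-Carlo error negligible at the effect sizes
of interest. The difference of means was chosen as the statistic
because the comparisons of interest are directional shifts in length,
exon number and O/E.

## mCHH islands

Gene flanks of 2 kb are tiled into 100-bp windows outward from the
gene edge (window 1 abuts the gene), per side, strand-aware. A window
qualifies with weighted mCHH ≥ 25 % and ≥ 5 methylated CHH sites.
"Missing" windows have zero covered CHH sites; a gene-side with
missing data in more than half of its 20 windows is excluded, since
island absence cannot be asserted there. The island anchors on the
qualifying window of highest level, ties broken toward the gene and
then toward the lower coordinate (determinism). Profiles around
anchors use the anchor window as the exact central bin and orient the
gene to the left, so the distal (heterochromatin-facing) side is
always right. Expression association splits genes into non-expressed
(expression exactly 0) plus quartiles of the positive values — NE is
a fifth category, not part of the quartiles — and compares island
incidence per category against the top quartile with two-proportion
chi-square tests with continuity correction at p < 0.01.

## Phylogenetic GLS

Species traits are not independent; under Brownian motion the
covariance of two tips is the branch length shared from the root to
their most recent common ancestor. `brownian_covariance` builds V by
a single post-order pass; `pgls_fit` solves the GLS normal equations
through a Cholesky whitening of V, with β = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y and a
slope t-test on n−2 degrees of freedom using the unbiased GLS
residual variance. With V ∝ I this reduces exactly to OLS (tested to
1e-10). No Pagel's λ or Ornstein–Uhlenbeck extensions are offered:
the model is plain Brownian motion. A singular V raises unless the
caller opts into a pseudo-inverse. Multiple comparisons across trait
pairs are Bonferroni-adjusted (p·m clamped at 1). TE enrichment per
gene class and position (2 kb upstream / within / 2 kb downstream)
uses two-sided Fisher tests against the background of all genes, so
depletion registers as well as enrichment.

## Synthetic methylomes

The generator emulates what matters statistically about a small plant
genome as WGBS sees it:

* **Genome** — i.i.d. sequence at a configurable GC fraction (default
  0.36, plant-like); a central heterochromatic block (default 40 % of
  the chromosome) flanked by euchromatic arms.
* **Methylation** — every cytosine is either truly methylated or not.
  A methylated cytosine emits C-reads at a per-context per-site level
  (defaults 0.8 CG, 0.4 CHG, 0.1 CHH), emulating realistic per-site
  level distributions in which CG methylation is near-binary and CHH
  methylation is mosaic. The *fraction* of methylated cytosines in a
  compartment is set to target-rate/level, so the compartment's
  expected weighted level equals its configured target (defaults: het
  0.8/0.4/0.1, eu 0.3/0.05/0.02 for CG/CHG/CHH). Repeats take
  heterochromatin rates wherever they sit; CDS cytosines take
  class-specific fractions (gbM genes 0.8 of CG sites methylated,
  non-CG near zero; UM genes near zero everywhere); planted island
  windows set every CHH site methylated at the island level (default
  0.35).
* **Reads** — coverage is Poisson (default 10x); methylated-read
  counts are Binomial(total, level + (1−level)·ε) with ε the
  configured non-conversion rate (default 0.005), applied equally to
  the unmethylated fraction of reads at methylated sites. An
  unmethylated lambda-like control sequence (20 kb) supports
  non-conversion estimation. Coverage overdispersion (negative
  binomial) is deliberately not modelled; the generator calibrates
  estimators, it does not imitate library artefacts.
* **Determinism** — one integer seed drives a single `numpy`
  Generator; identical seeds give byte-identical output files.

What passing tests on this generator shows: the estimators are
calibrated and recover planted truth under the stated read model.
What it does not show: robustness to mapping artefacts, copy-number
variation, overdispersed coverage, sequence-composition biases or
incomplete genome assemblies — real-data concerns that live upstream
of this package's inputs.

## Problem sizes in the shipped experiments

The test suite and acceptance script size their simulations to be
informative while remaining quick on a single CPU: calibration of the
site caller on 1-Mb all-unmethylated genomes over 10 seeds;
compartment-rate recovery on 1 Mb at 10x (binomial sampling error
well below the ±0.02 check); classifier recovery on 500 genes in a
2-Mb genome; island recovery on 200 genes with 80 planted islands;
1,000 randomised region-caller instances against the brute-force
oracle; 200–500 replicates for PGLS bias and null-rate checks. These
sizes are the package's chosen experiment design; all scale linearly
if larger runs are wanted.

## Known limitations

* The site caller assumes independent reads; PCR duplicates must be
  removed upstream.
* Pooled expected rates make gene classes comparable across samples
  but tie every sample's null to the pool; adding a sample changes
  everyone's expected rate by construction.
* The region caller's 25-bp tiling phase is fixed at 0; segmentations
  are deterministic but not tiling-phase invariant.
* PGLS assumes the supplied tree and Brownian errors; no measurement
  error in traits is modelled.
* The synthetic expression model (class-conditional log-normals) is a
  placeholder for testing the association machinery, not a model of
  transcriptional biology.
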