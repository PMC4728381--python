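# Methods

## Coordinate model

All coordinates inside the package are 0-based, half-open (BED-native);
GFF3's 1-based closed convention is converted at the file boundary in
both directions. Genes carry a body span (transcription start to end)
and ordered, non-overlapping CDS exons; because the gene models this
pipeline consumes are CDS-only predictions, the gene body is taken to
be the prediction span and no UTR compartment exists. When a gene has
several transcripts the one with the longest summed CDS is kept, with
ties broken on transcript id so parsing is deterministic. Enrichment
peaks are treated as unstranded (they derive from double-stranded
pull-down); gene strand only orients the flank windows.

## Element classes

The genome is partitioned into eight classes: merged CDS exons of all
genes; introns (gene-body bases not covered by an exon of *any* gene);
and 1/5/10 kb windows upstream of the TSS and downstream of the TES,
strand-aware and clipped at contig ends. Three deliberate choices:

* **Ownership priority** is CDS exons > introns > flanks. A base inside
  any gene body is removed from every flank window, so genic and flank
  compartments never double-count against each other. Whether a
  neighbouring gene's body should be excluded from a flank window is
  genuinely open; the choice is recorded in the element map's metadata
  (`gene_bodies_removed_from_flanks`) so downstream readers can see it.
* **Nested windows are cumulative supersets**, not annuli: the 5 kb
  window contains the 1 kb window. Cumulative nesting is the only
  convention under which per-window tag counts are guaranteed monotone
  in window size, which is the behaviour the density table asserts. A
  "disjoint" counting mode (credit only the smallest window a peak
  touches, per side) is available behind a flag.
* Flank windows of different genes, and the TSS vs TES sides, may
  overlap; such bases count in both totals. Intergenic bases beyond
  10 kb belong to no class and appear only in the `unassigned_bases`
  diagnostic — the density table has no intergenic row.

Peak assignment mirrors the priority: ≥ 1 bp of overlap with an exon
makes a peak exonic and silences every other class for that peak;
otherwise intron; otherwise every flank window it touches. A
`midpoint` criterion (classify by the peak's centre base) is switchable
for users whose peak caller reports wide intervals.

Reported tags/kb is rounded half-up at two decimals, only at output;
ratios always use unrounded densities.

## PPKM and gene groups

PPKM = n / (L/10³) / (N/10⁶) with n the peaks overlapping the gene
*body* (introns included), L the summed CDS length and N the total peak
count. Counting over the body while normalising by coding length is the
literal reading of a gene-body density normalised to protein-coding
DNA; an exon-only counting mode exists behind `count_mode="exon"`.
Groups: *high* iff PPKM ≥ 10 (inclusive), *void* iff no peak overlaps
any CDS exon, else *neither*. Intronic peaks can push a gene over the
PPKM threshold while its exons stay peak-free; the tie resolves to
*high* so the two groups used for GO comparison are disjoint. Note the
void rule is exon-based by definition: a gene with only intronic peaks
and low PPKM is void, not neither.

Optionally, regions whose sequencing depth exceeds a threshold
(default 50×) are masked and peaks overlapping them discarded before
scoring. The source protocol excluded high-coverage *reads* before peak
calling; this package consumes called peaks, so the filter necessarily
operates on peaks — a coarser but analogous exclusion, and optional
because many peak files arrive pre-filtered (absence of a coverage file
passes peaks through with a logged warning).

## GO-term comparison

For each term annotated to at least one gene of each group, a 2×2 table
(genes with/without the term × group) is tested with a two-sided Fisher
exact test: the hypergeometric distribution over all tables with the
observed margins is enumerated and probabilities ≤ the observed table's
(relative tolerance 1e-7, so exact ties are included — the convention
of R's `fisher.test`) are summed. A p-value that lands within 1e-9 of
1 from accumulated float error is snapped to exactly 1. Frequencies
count genes, not annotation lines; GO ancestry is not propagated.
Selection uses the asymmetric raw-p cut-offs (0.01 high-enriched, 0.05
void-enriched); BH q-values are reported but never used for selection,
matching the upstream analysis this reimplements. The test choice
itself is a design decision — the upstream description names no
statistic — and Fisher was chosen because it is exact, standard for
small gene-set tables, and verifiable by enumeration.

## qPCR modification percent

percent = 100/(1+E)^ΔCT, ΔCT the difference of arithmetic replicate-CT
means (digested − mock). E is a *fraction* (E = 1 is perfect doubling):
interpreting the efficiency symbol as a percentage (e.g. 95) would make
the base of the exponent ≈ 96 and the formula meaningless. E is fitted
as 10^(−1/slope) − 1 from the least-squares slope of CT on
log₁₀(relative input) over ≥ 3 dilutions; a non-negative slope is an
error, E outside [0.6, 1.2] a warning flag. ΔCT < 0 (digested
amplifying earlier than mock) clamps the percent to 100 with a warning
rather than erroring — it signals pipetting or normalisation problems,
not an impossible computation. Fewer than 4 replicates is flagged.
Each enzyme configuration reports what it can see (e.g. MspI/HpaII
percent includes glucosylation-protected species); no cross-assay
deconvolution of 5-mC vs 5-hmC is attempted.

## Synthetic data

The generators exist so every stage is testable end to end:

* **Genome**: genes placed left-to-right on equal-length contigs with
  random intergenic gaps; exon counts default to 4–11 and exon/intron
  lengths to 80–400/60–500 bp, the scale of small multi-exon arthropod
  genes; default 60 genes on 5 × 200 kb contigs. Deterministic given
  the seed.
* **Peaks**: class counts are multinomial (given `n_peaks`) or Poisson
  with weights intensity × class size, over disjoint placement regions
  (exon, intron, flank annuli, intergenic). Each peak is placed
  *entirely inside* an interval of its drawn class, shrinking to the
  interval if it is shorter than the drawn peak length. Allowing peaks
  to straddle class boundaries would let the exon-priority assignment
  rule systematically steal intron-drawn peaks, biasing the measured
  exon:intron ratio above the planted intensity ratio; full containment
  keeps the generator's contract (planted 2:1 ⇒ measured ≈ 2:1) exact.
  The default intensity preset (exon 0.61/kb, intron 0.27/kb, flanks
  0.05–0.08/kb, intergenic 0.02/kb) mirrors the density structure the
  analysis is designed to detect. An optional `hot_genes` map plants
  extra body peaks in chosen genes for classification-recovery tests.
* **GO**: planted terms are Bernoulli per gene with group-specific
  frequencies; background terms are group-independent.
* **qPCR**: mock CTs are Normal(baseline, σ); digested CTs add the
  model shift −log₍₁₊E₎(fraction); the standard curve is generated
  noiselessly so fitting recovers E exactly.

Each generator draws from its own seeded substream, so adding one never
perturbs another's output and identical specs give byte-identical
files. What the generators do *not* emulate: sequence composition,
read-level noise, enrichment chemistry, peak-caller artefacts,
correlated annotations along the GO DAG, or inter-locus efficiency
differences. Passing tests therefore demonstrate correctness of the
*computations* under the stated statistical structure, not robustness
to real-data pathologies.

## Problem sizes and numerical choices

Property and acceptance tests run on: 100 random 80-kb genomes for the
per-base oracle equivalence; a 1-Mb genome with 10⁴ peaks for density
and PPKM recovery (the ratio check uses a ±3 standard-error band via
the delta method, SE(ratio) ≈ ratio·√(1/n_exon + 1/n_intron)); all 2×2
tables with margins ≤ 12 for Fisher exactness plus a 1000-term null
simulation for type-I control; 50–100 seeds for GO power. These sizes
give stable statistics at interactive runtimes.

Degenerate inputs: empty peak lists yield all-zero density rows; an
empty 2×2 table has p = 1; single-exon genes have no introns; flank
windows fully clipped at a contig edge are omitted; a gene set that
cannot fit on the requested contigs is an error with advice rather than
a silent truncation.

## Known limitations

* The published study's dataset-dependent numbers (total peak count,
  group sizes 1663/2121, assembly statistics) require the original
  reads, assembly and gene predictions and are out of reach by design;
  the package reproduces the *methods* and verifies them on synthetic
  data plus the published count table's arithmetic.
* Flank handling across neighbouring genes has no published ground
  truth; both the chosen rule and the window-counting convention are
  flagged in output metadata and switchable.
* The GO comparison treats genes as exchangeable and terms as
  independent; it inherits Fisher's conservatism at small counts.
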