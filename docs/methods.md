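# Methods

## The analysis model

The pipeline connects two measurements made on the same biological contrast
(a perturbed or disease condition **A** versus a control condition **B**):

* a *splicing* readout — how often a block of variant cassette exons is
  included in the mature transcript, estimated from junction-spanning reads
  anchored at a flanking constant exon; and
* a *methylation* readout — enrichment counts of methylated DNA in genomic
  bins or regions of interest (ROIs), compared between the two groups.

The scientific question is directional: when variant-exon inclusion drops in
condition A, is gene-body methylation also reduced there (concordant), or
not? The package quantifies each readout, calls differential methylated
regions, and classifies shared splicing events from two independent systems
by the agreement of the two signs.

### Anchor-exon inclusion

For an anchor constant exon adjacent to the variant block (C5 upstream or
C16 downstream in the CD44 nomenclature), every junction with one boundary
abutting the anchor is classified by its other boundary: a variant exon
gives an *inclusion* junction, the constant exon on the far side of the
block gives the *skipping* junction (the fully skipped isoform), anything
else — intronic boundaries, same-side constant exons, junctions not
involving the anchor — is *other* and excluded from the statistic. The
per-sample inclusion percentage is read-weighted:

    inclusion_pct = 100 · Σ reads(inclusion) / Σ reads(inclusion ∪ skipping)

Junctions enter a sample's sums only when detected by at least `min_reads`
reads in that sample (default 2). A junction-count-weighted variant is
available (`weight="junctions"`) because the percentage could defensibly be
defined either way; the read-weighted form is the default since the
denominator counts *reads* of junctions. Samples with an empty denominator
are reported missing, never as 0 %.

Boundary abutment is coordinate-exact: a junction's intron must start at an
exon end (donor) or end at an exon start (acceptor), with all coordinates
held 0-based half-open internally (the spliced-aligner junction dialect is
1-based inclusive and converted on input). Junctions whose known strand
contradicts the gene model are ignored; unknown-strand junctions match on
coordinates alone.

Group comparisons use the paired Student t-test or the Wilcoxon signed-rank
test (paired only). Zero differences are dropped (standard signed-rank
convention); with ≤ 25 informative pairs the exact null distribution is
used, beyond that a normal approximation with continuity correction. All-zero
differences return p = 1 with a warning; zero-variance nonzero paired
differences make t undefined and are flagged rather than silently computed.

### Expression stages

CPM normalization scales each library to 1e6 over the genes in the matrix.
QC exclusion uses strict inequalities — a library is dropped iff uniquely
mapped < 60 % **or** assigned-to-annotation < 10 %; a missing metric makes a
sample *unevaluable* rather than silently kept. Expression-range selection
keeps samples whose value lies inside the closed min–max range of a
reference (control) set. The paired differential-expression rule operates
on log2(CPM + 1): per-gene paired two-tailed t-test, call up/down iff
|log2FC| > 1 and p < 0.05. A count-model fit with dispersion shrinkage (the
DESeq2/edgeR family) is deliberately not reimplemented; log2(CPM+1) with a
paired t-test is the documented, simpler substitute — adequate here because
every downstream consumer of this stage needs only the conjunction rule,
not the count likelihood.

### Methylation and DMR calling

Targeted MeDIP assays are expressed as percent of input DNA
(100·IP/input; zero-input loci are missing). Locus-group comparisons
(constant exons, variant exons, assayed introns, their unions) use a paired
two-tailed t-test across loci against a baseline cell line.

Binned enrichment counts are compared per ROI: bin counts are summed into
ROIs, normalized by TMM scale factors times library size to log2(CPM + 1),
tested with a two-sample Welch t-test, and Bonferroni-corrected over the
number of ROIs (Bonferroni, not BH, is the method's stated correction). The
log2 fold change is mean(A) − mean(B) on the log2 scale; a significant ROI
with a negative value is a *hypo* DMR (less methylation in the test group).

TMM is implemented in the package: pairwise weighted trimmed mean of
M-values against a reference sample (the one whose upper-quartile fraction
is closest to the mean), trimming 30 % of M-values and 5 % of A-values on
each side, precision weights from the delta-method variance, factors
renormalized to geometric mean 1. The implementation reproduces edgeR's
factors on shared fixtures and an independent brute-force reimplementation
in the test suite. TMM assumes most regions are unchanged; the synthetic
generator therefore surrounds planted DMRs with unchanged background bins
(see below). The exact-test machinery of MEDIPS/edgeR is not reproduced;
the t-test on normalized log2-CPM is this package's documented substitute.

### Concordance classification

Events from two systems are matched per gene by shared splice-site
coordinates (exact by default, `site_tolerance` optional); each gene
contributes its best pair (most shared sites, then smallest span). Pairs
are sub-classified: *alt_promoter* if either event is an alternative
promoter, *different_event* if only one site is shared, otherwise
*same_local*. For same-local pairs, DMRs overlapping the splice-site span
± 5 kb (the default "neighborhood"; configurable, since DMRs need not sit
on the cassette exon itself) are collected per system. The nearest
*significant* DMR fixes each system's methylation sign; conflicting
significant signs within a system, or no significant DMR among the matches,
leave that system undecided. The category is *concordant* when
sign(dPSI) = sign(log2FC) in **both** systems, *opposite* when both
disagree, *meDNA_absent* with no matched DMR in either system, and
*uncertain* otherwise. An `require_both=False` mode accepts single-system
evidence when the other system is undecided. Sign conventions are fixed
project-wide: condition A is the perturbed/tumor state, positive dPSI means
more inclusion in A, positive log2FC means more methylation in A.

`tally_categories` reports counts, the DMR-proximal count
(same-local minus meDNA-absent) and both exact and nearest-integer-rounded
percentages; callers that need a different rounding style have the exact
fractions.

## The synthetic-data generator

`SimConfig` fixes the study conditions; all generators are bit-reproducible
given (seed, config).

| parameter | default | meaning |
|---|---|---|
| `n_samples` | 6 | samples per group |
| `depth` | 1e4 | mean anchor-junction reads per sample (NB) |
| `beta` | 4.0 | methylation→inclusion coupling, log-odds per unit methylation |
| `baseline_logit` | −2.0 | inclusion log-odds at methylation 0 |
| `meth_a`, `meth_b` | 0.2, 0.8 | variant-region methylation per group (4-fold depletion in A) |
| `meth_constant` | 0.5 | background methylation, both groups |
| `nb_dispersion` | 0.1 | NB dispersion (var = μ + φμ²) |
| `bin_width` | 100 bp | methylation bin size |
| `flank_margin` | 8000 bp | unchanged background flanking the gene |
| `meth_depth` | 250 | mean bin counts at methylation 1 (≥ ~50 in the depleted group) |

The gene model is topological: 100 bp exons, 300 bp introns, constant
C1–C5, variant v2–v10, constant C16–C17 on '+'. No operation depends on
real genomic coordinates.

Junction counts: each variant exon's inclusion probability is
π = logistic(baseline_logit + β·meth). Each anchor read picks a variant
exon uniformly and becomes an inclusion read with probability π (else a
skipping read), so the expected read-weighted inclusion percentage is
exactly 100·mean(π) — the closed form used as an oracle in the tests. The
logistic link is the generator's own minimal monotone model: the underlying
biology asserts a direction for the coupling, not a functional form.
Variant→variant junctions are generated at a tenth of the anchor depth and
are excluded from the anchor statistic by construction.

Methylation coverage: NB bin counts with mean = meth·`meth_depth`. Bins
overlapping the variant-block span carry the group-specific level; all
other bins, including the flanking margin, the shared background level.
The margin keeps planted bins a small minority (~15 %) so that TMM's
majority-unchanged assumption holds, as it does in genome-scale enrichment
data; with half the bins shifted TMM partially absorbs the effect (verified
against edgeR, which behaves identically). True-DMR truth records every bin
whose group levels differ by ≥ `dmr_truth_fold` (default 2); contiguous
truth bins merge into region-level truth, the natural ROI unit.

What the generator does **not** emulate: mappability and GC structure,
CpG-density-dependent enrichment efficiency, correlated noise between
neighbouring bins, transcriptome-wide alternative isoform complexity, and
partial/ambiguous junction alignments. Passing tests therefore demonstrate
the correctness and calibration of the statistical machinery under the
declared noise model, not performance on real libraries.

## Numerical choices and degenerate inputs

* Pseudocount 1 for every log2 transform (CPM and methylation log2-CPM).
* Exact Wilcoxon null up to 25 informative pairs; continuity-corrected
  normal approximation beyond.
* Welch (unequal-variance) t for two-sample DMR tests; paired t elsewhere
  as stated. Genes/ROIs with undefined variance yield p = 1 (DMR, treated
  as null) or a missing flagged value (paired comparisons), never a
  fabricated significance.
* Bonferroni: p_adj = min(1, m·p_raw); significance is strict (<).
* Ties in event matching break toward the smallest combined genomic span.
* Zero-denominator inclusion percentages, zero-input %input loci and
  all-zero genes are reported missing, with warnings where a silent NaN
  could be mistaken for a measurement.

## Problem sizes used in validation

The validation suites run the DMR null calibration on pooled replicate null
simulations (10 × 200 ROIs, 6 vs 6 samples) so the false-positive-rate
estimate carries a binomial standard error of ~0.005, well inside the
0.03–0.07 acceptance band; the coupled end-to-end recovery study uses 50
genes at β = 4 and 150 genes at β = 0 (two systems each). These sizes give
stable estimates while keeping the whole suite fast on a single CPU.

## Known limitations

* The DMR caller tests normalized means; it does not model count overdispersion
  explicitly and will be conservative at very low counts.
* TMM under-corrects when a large fraction of ROIs is truly differential;
  use a background-inclusive ROI panel.
* The concordance classifier consumes externally computed dPSI/confidence
  values; it does not re-estimate splicing uncertainty.
* Multi-gene annotation handling, isoform enumeration and peak calling are
  out of scope; ROIs and event tables are inputs.
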