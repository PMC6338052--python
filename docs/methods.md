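# Methods

## Model and estimators

### PRE/POST segmentation

Each gene is represented by its canonical transcript: the one with maximal
exonic length, ties broken by lexicographically smallest transcript id so
the choice is reproducible. All internal coordinates are 0-based half-open;
GTF input (1-based closed) is converted at the parser boundary, BED is
written as-is. The 3′UTR comes from explicit `three_prime_utr` features or,
failing that, is inferred as the exonic span 3′ of the `stop_codon`.

The proximal polyA site is the most 5′ (in transcript orientation)
annotated site inside the 3′UTR. When a transcript has no 3′UTR site —
about 6.7% of transcripts in typical mouse annotations, which is the
default fraction the generator emulates — the same most-5′ rule is applied
to sites anywhere in the transcript's exons; genes with no usable site are
excluded with reason `no_apa_site`. This fallback is a documented
interpretation, not an annotated standard: the alternative (excluding all
such genes) would silently drop ~7% of the genome, while this reading keeps
them with a well-defined, if conservative, PRE/POST split.

The exonic bases are cut at the proximal site's coordinate (PRE strictly 5′
of the site on the plus strand, mirrored on minus). A cut that would leave
either side empty raises `degenerate PRE`/`degenerate POST`; in batch mode
these become per-gene exclusion reasons rather than errors. By
construction `pre_length + post_length` equals the canonical exonic length
— asserted on every emitted segmentation.

### Read counting

A primary, mapped alignment overlapping a gene's PRE or POST by at least
one base is assigned to that gene. A read overlapping **both** regions is
assigned to POST only (default `boundary=post`): such a read spans the
proximal site and can only derive from the long isoform, so it carries
long-isoform information; `boundary=both` is available for sensitivity
analyses. Counting is unstranded by default (`stranded=forward|reverse`
enable strand matching), secondary/supplementary/unmapped records are
skipped, duplicates are kept, and reads overlapping several genes count in
each (logged). `library_size` is the number of primary mapped alignments,
used by the FPKM filter:
`FPKM = count / ((length/1000) · (library_size/10^6))`.

### m/M, roar and testing

With long-isoform molar fraction `f`, every molecule covers PRE and only
the long isoform covers POST, so per-base coverage rates satisfy
`pre_rate ∝ 1` and `post_rate ∝ f`, giving the estimator
`m/M = pre_rate/post_rate − 1 = (1−f)/f`. It is undefined at
`post_count = 0` (`zero_post`) and negative values (`negative_mM`) flag a
violation of the generative model (e.g. internal priming, overlapping
transcription); flagged genes are excluded from classification rather than
clamped.

`roar = (m/M)_contrast / (m/M)_baseline` with the later/differentiated
condition in the numerator, so roar > 1 reads as shortening during
differentiation. It is computed on replicate-pooled counts, while
significance is assessed per replicate pairing: one two-sided Fisher exact
test of `[[pre_b, post_b], [pre_c, post_c]]` for each (baseline, contrast)
replicate pair. The Fisher p-value is computed by exact integer
enumeration: table probabilities are compared as exact integer numerators
over the common denominator `C(n, c1)`, and the final rational sum is
converted to float once. This makes the implementation agree with
exhaustive hypergeometric enumeration to < 1e-12 (the only rounding is the
final conversion) at any table size reachable in practice; tables with an
all-zero row or column return NaN, which downstream logic treats as
non-significant.

### Classification and consensus

SHORTENED: roar > 1, all pairings p < α, both conditions' PRE FPKM > the
cutoff, validity flag ok. LENGTHENED mirrors with roar < 1. Inequalities
are strict: roar exactly at the boundary or p exactly at α fail. Defaults
α = 0.05 (nominal, uncorrected — the all-pairings conjunction is the
stringency mechanism), FPKM cutoff 1, roar boundary 1. Testable genes
failing a criterion are UNCHANGED with machine-readable reasons; FPKM or
validity failures give NOT_TESTABLE. Raising α can only grow the called
sets; raising the FPKM cutoff can only shrink the testable set (both
property-tested).

Consensus across a time course intersects the per-comparison call sets;
a gene NOT_TESTABLE in any comparison cannot appear in an intersection
(it is absent from that comparison's call set). Venn region counts are
exact set algebra over all non-empty membership patterns. Intersections
require the full call (direction and significance) in every comparison,
not merely direction agreement.

### Binding-site enrichment

Sites are filtered to robust clusters (FDR < 0.01 **or** BC ≥ 5; sites
missing both scores are dropped and counted). Overlap is evaluated on the
whole genomic span of the canonical transcript, strand-blind — binding
anywhere in the locus is taken as potentially regulatory since the
mechanism of polyA-site control is not fully positional. Enrichment of
overlap among target genes versus the rest of the analyzed universe (all
genes with a segmentation, not all annotated genes) uses a one-sided
(greater) Fisher test by default, matching the directional question
"are the lengthened genes enriched in targets?"; two-sided is available.
Degenerate 2×2 margins (no overlapping gene anywhere, or target =
universe) admit only the observed table and return p = 1.

### qPCR quantification

ΔΔCt with amplification efficiency fixed at 2 by default (configurable):
per replicate `index = E^−(Ct_long − Ct_common)`; the reference-gene Ct
must be present (it cancels within a replicate but anchors the design and
is validated). Replicates combine by geometric mean — equivalent to
arithmetic averaging of Ct values. The condition ratio
`index_contrast / index_baseline` exceeds 1 under relative lengthening.
Standard-curve quantification is not implemented; the efficiency parameter
covers the usual correction range.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, on
a genome of five synthetic chromosomes:

* 1–4 exons per gene, internal exons 200–1200 bp, the transcript-3′ exon
  700–2000 bp hosting a 3′UTR of 60–80% of its length; the distal (POST)
  segment is 40–70% of the UTR. This yields PRE:POST length ratios of
  roughly 2–6, matching the geometry under which the m/M estimator and the
  all-pairings test are intended to operate; genes separated by 10 kb so
  toy reads never cross loci.
* one proximal polyA site per gene (placed upstream of the 3′UTR for a
  configurable 6.7% of genes to exercise the fallback rule), occasional
  decoy distal sites, and a shorter second transcript for 20% of genes to
  exercise canonical selection.
* per-gene long fractions: UNCHANGED genes constant in (0.3, 0.9);
  planted LENGTHENED genes move 0.2 → 0.8 linearly across the conditions
  (SHORTENED mirrored), i.e. true m/M 4 → 0.25.
* counts: total fragments per gene/replicate are negative binomial with
  mean `expression_level × mean_depth` and `variance = μ + φμ²`
  (`φ = dispersion`, Poisson at φ = 0); the PRE/POST split is binomial
  with weights `pre_length` and `f · post_length`. Per-gene expression
  levels are lognormal with unit mean (σ = 0.6 by default; σ = 0 makes
  "depth" exact per gene — the setting used in the calibration and
  power scenarios, where depth is the controlled variable).
* toy alignments: unspliced single-end reads placed fully inside one
  interval of the region their count is assigned to, so re-counting the
  SAM reproduces the counts exactly (reads longer than the interval are
  shortened to fit). The four-time-point preset is T0–T3 with 3/3/3/2
  replicates.

What the generator does **not** model: sequence content and error, GC or
positional coverage bias, spliced reads, paired-end fragments, internal
priming, overlapping genes and antisense transcription. Passing tests
therefore demonstrate the statistical machinery is correct and calibrated
under the stated generative model, not that real libraries are free of
those artifacts.

Measured under the generator's conditions (fixed seeds; sizes chosen to
keep the whole suite fast): 2,000 null genes at depth 200, dispersion 0.1
give a 0% shortened/lengthened call rate and per-pairing rejection rates
≤ 0.045 at α = 0.05 (Fisher's discreteness makes it conservative); 50+50
planted effects at depth 300 are recovered with ≥ 84% sensitivity per
class, zero observed false discoveries and 100% direction agreement
across seeds tried; the m/M estimator errs < 10% at 10⁵ reads for true
ratios 0.25–4.

## Numerical and design choices

* Exact integer arithmetic for Fisher enumeration; cost is O(support) big
  integer operations per table — negligible at sequencing-realistic depths
  (hundreds per region) and still fast at the few-thousand scale.
* A polyA site exactly on an exon boundary belongs to the exon whose
  half-open interval contains it; unplaced contigs are processed like any
  chromosome.
* Gene universes, output rows and JSON keys are sorted; all randomness
  flows through a single numpy Generator, so every artifact is a pure
  function of config + seed (the demo rerun is byte-identical).
* The counts-table and SAM paths are interchangeable: counting emitted
  alignments equals reading the written table (round-trip tested).

## Known limitations

* Single proximal site per gene: multi-site 3′UTRs are reduced to the most
  5′-proximal cut; intermediate isoforms fold into PRE/POST.
* The m/M estimator assumes uniform per-base coverage within regions; 3′
  bias in real libraries shifts m/M multiplicatively and partially cancels
  in roar but is not modeled.
* Negative m/M genes are dropped, not modeled; heavy antisense or
  overlapping transcription will reduce the testable set.
* The all-pairings rule is deliberately conservative; power depends
  strongly on POST-region depth (≈ depth × f × post_len / pre_len), so
  genes with short POST segments need correspondingly deeper libraries.
* No FDR control across genes, matching the nominal-p design; downstream
  users wanting genome-wide error control should correct the per-gene
  minimum p themselves.
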