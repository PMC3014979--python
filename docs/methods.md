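# Methods

## Tract detection and region model

A poly-Q tract is seeded as a maximal run of at least `min_q = 5`
consecutive glutamine residues in the protein; the scan is on amino
acids, so CAA-encoded glutamines count toward seeding exactly as
CAG-encoded ones. Five is the conventional threshold at which a
glutamine homopolymer is statistically distinguishable from the
composition of an average protein.

Seeds are widened into repeat *regions* by greedily absorbing
neighbouring glutamine runs (of any length) separated by at most
`max_gap = 4` non-Q codons, iterating outward to a fixed point. The
default of 4 is the largest interruption observed inside any tract of
the packaged survey (`…G1N4G5`); with a smaller gap such tracts would
fragment into several regions. Regions always begin and end on a
glutamine codon. Overlapping extensions from different seeds collapse
to one region, and both the merged region count and the raw seed count
are reported per gene, since "number of tracts" is ambiguous between
the two.

Coordinates are 0-based half-open codon indices internally and 1-based
inclusive amino-acid positions in reports. A codon that translates to
glutamine but is neither CAG nor CAA cannot occur under the standard
nuclear code; encountering one is treated as a hard error (it indicates
a frame bug), and genes whose CDS length disagrees with the protein are
skipped with a logged error rather than silently truncated.

The purity grammar run-length encodes a region's codons as `G` (CAG),
`A` (CAA) and `N` (any non-glutamine codon). Parsing accepts a bare
letter as count 1 and merges adjacent same-letter tokens; canonical
emission always writes the digit. The region's position within the
protein (used for the positional-enrichment test) is the region
midpoint divided by protein length.

## Splice-junction context

Gene models (exons, per-transcript exon sets, CDS of the reference
transcript — the mRNA with the longest CDS) are read from GFF3 via
`gffutils`; 1-based inclusive GFF3 coordinates are converted to 0-based
half-open. A region's codon span maps to per-exon genomic intervals in
transcription order, strand-aware; re-extracting and splicing the
projected sequence reproduces the region's codons exactly (this
round-trip is a test oracle).

Classification precedence is fixed: `TRAVERSES` (projection spans an
intron) > `SMALL_ALT_EXON` (region inside an exon ≤ 120 nt that is
absent from at least one annotated transcript of the gene) >
`ADJACENT` (edge-to-junction distance < 5 bp) > `INTERNAL`. Every
region receives exactly one category. Distances are genomic
nucleotides from either region edge to the intron-facing exon boundary;
both edges are measured and the minimum reported. Gene termini are
never junctions. The donor is the transcription-downstream end of an
exon, the acceptor the upstream end. "Small" is not quantified in the
literature this models; 120 nt is comfortably below the median internal
exon and configurable. "Alternatively spliced" means absent from ≥ 1
annotated transcript — computable from the GFF3 alone, without EST
alignment.

Transcript repeat-length counting locates two fixed flanking anchors
(≥ 10 nt, required unique per transcript) and counts whole CAG units
between them; a sample whose transcripts yield more than one distinct
count while the genomic locus is monomorphic is flagged as a splice
variant, the signature of repeat-length isoforms generated by
alternative splice-site choice within the repeat.

## Prioritization

Criteria are binary; the score is their sum. Criterion 1 is a pure CAG
run ≥ 5 anywhere in the gene. Criterion 2 compares the multiset of
tract lengths (≥ `min_q`) between the focal species and each
comparison species exactly; a species with no qualifying tract counts
as non-conserved and additionally marks the gene species-unique. An
optional integer tolerance relaxes the length comparison (default 0 —
exact). Criteria 3–5 summarise literature/database evidence and are
inputs, not computations. The tie-break key is the maximum pure-CAG run
length over the gene's regions (multi-tract handling is otherwise
unspecified), with a final deterministic lexicographic tie-break on
gene id so that rankings are reproducible and permutation-invariant.

## Allele calling and panel statistics

An observed amplicon size is converted to repeat units by snapping
`observed − reference` to the nearest whole unit (3 bp), rounding half
away from zero; the call warns when the off-grid residual exceeds
`tolerance = 1.0` bp. Alleles are identified by unit count, not raw bp,
because off-grid sizes in fragment analysis reflect the size
calibration rather than non-trinucleotide indels. A single peak is
recorded as homozygous (dosage is not resolved). Calls implying < 1
unit raise an error.

The differentiation test is a two-sided Fisher exact test under the
probability-ordering convention: p is the total probability of all
fixed-margin tables no more probable than the observed one. Tables
with at most 200 000 fixed-margin completions (every 2×2 in practice)
are enumerated completely; larger tables fall back to a seeded Monte
Carlo sample of fixed-margin tables (Patefield sampling via
`scipy.stats.random_table`, default 10⁵ draws) with the add-one
estimator (k+1)/(reps+1), which cannot report p = 0. All-zero rows and
columns are trimmed with a warning. On 2×2 tables the enumeration
agrees with `scipy.stats.fisher_exact` to ~10⁻⁹ relative error.

A trio passes the Mendelian check when the child's two alleles can be
partitioned with one present in the sire's genotype and the other in
the dam's. Missing genotypes mark a trio untested, not failed. The
diversity regression is ordinary least squares of allele count on
maximum repeat length; a constant response is reported as slope 0 and
r = 0 by convention and flagged, and constant repeat lengths are an
error.

## Dataset statistics

Standard deviations are sample (n−1) values. "Pure CAG gene" admits two
readings, so both counts are emitted: *strict* (some region is a single
uninterrupted `G` token of ≥ `min_q`) and *run* (some region contains a
pure CAG run of ≥ `min_q`). Tract-length moments are likewise reported
both per tract and per gene (longest tract), since "mean tract length
over genes" is ambiguous between the two. Tie-breaks in the
maximum-tract fields are lexicographic, keeping the summary
order-invariant. The protein-size screen is a Welch (unequal-variance)
two-sided t-test; the positional screen bins region midpoints into
protein-length thirds (right-closed final bin) and applies a 2-df
chi-square goodness-of-fit test against uniformity.

## Synthetic data

The generator emulates the study design end to end. Genes: background
codons never encode glutamine, so planted repeat regions are the only
glutamine runs and truth is unambiguous; an optional decoy mode plants
sub-threshold runs (`min_q − 1`) to exercise the seeding boundary.
Repeat placements plant the region internally, split codon-aligned
across an intron, within 0–3 bp of a junction, or inside a ≤ 120 nt
exon that a second annotated transcript skips. Random purity patterns
draw 1–3 glutamine runs (first ≥ `min_q`, ~15% CAA) joined by 1–4 codon
interruptions — within the merge gap, so each planted region scans as
one region. Strands are random; introns are 60–300 nt; incidental
junctions keep ≥ 6 nt clear of the region so the planted category is
the true one. Panels: diploid genotypes are drawn i.i.d. from
per-population allele-frequency spectra; amplicon sizes are reference +
units·3 + Gaussian jitter (default sd 0.5 bp — sub-unit, as calibration
drift is in practice; the real artefact distribution is not
characterised, so Gaussian is a modelling choice). Homozygotes emit a
single peak. Trios sample two parents from the first population and
transmit one allele from each, mutating it ±1 unit with the configured
per-meiosis probability. All randomness flows from one seeded NumPy
generator; outputs are byte-identical for a fixed config.

What the simulations do not model: linkage and relatedness within
populations, PCR stutter, multi-step mutations, realistic breed
demography, and non-codon-aligned splice junctions. Passing tests
therefore demonstrate correctness of the algorithms under the stated
generative model, not robustness to every artefact of real
electropherograms or annotation errors in real gene models.

## Test and acceptance conditions

Simulation sizes mirror the study they model and are fixed in the test
configuration: 100 random gene configurations × 4 genes for
planted-truth recovery; Fisher null calibration on 500 2×2 tables at
the diversity panel's group sizes (150 + 35 diploid animals, allele
frequency 0.5, the densest lattice); power at planted spectra
(0.9, 0.1) vs (0.1, 0.9) with 50 animals per group over 100 replicates;
1000 trios at per-meiosis mutation rate 0.05 on an allele grid spaced ≥
3 units so every single-step mutation is detectable, making the
expected failure fraction exactly 1 − (1 − μ)²; and 100 replicates of
the protein-size screen at the observed group moments (1034 ± 913 aa,
n = 155 vs 365 ± 276 aa, n = 14 985, draws truncated at 1 aa).
`scripts/acceptance.py` recomputes all of these from scratch from a
single command-line seed.

## Known limitations

* Criterion 2 requires ortholog tract lengths as input; it does not
  align or detect orthologs.
* Splice classification trusts the supplied gene models; it performs no
  de novo splice-site prediction and cannot see alternative splicing
  that is not annotated as a transcript.
* The exact-test enumerator is exponential in table size by nature; the
  Monte Carlo fallback is an estimator, and its add-one convention
  slightly overestimates very small p.
* Allele calling assumes one locus per amplicon and at most two peaks;
  it does not model stutter or null alleles.
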