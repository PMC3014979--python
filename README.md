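# polyq

Codon-aware annotation of poly-glutamine (poly-Q) tracts in coding
sequences, and the population genetics of their repeat-length
polymorphism.

Glutamine is encoded by two codons, CAG and CAA. Long uninterrupted CAG
runs are trinucleotide microsatellites: they mutate by whole repeat
units at rates orders of magnitude above point-substitution rates, and
their length variation underlies both normal phenotypic variation and a
family of repeat-expansion diseases (Huntington disease being the
prototype). Interruption of a run — even by the synonymous CAA —
stabilises it. `polyq` is for researchers surveying the poly-Q gene
repertoire of a genome and asking which of those genes are likely to be,
or demonstrably are, polymorphic in a population.

## What the package does

* **Tract detection and purity encoding** (`polyq.repeat_annotation`) —
  scan proteins for runs of ≥ 5 consecutive Q (irrespective of codon),
  merge nearby runs (gap ≤ 4 codons) into repeat regions on the
  in-frame CDS, and encode each region's composition as a purity string
  over `G` (CAG), `A` (CAA) and `N` (interruption): `G10A1`, `G5A1G13`,
  `G6N1G1…`.
* **Splice-junction context** (`polyq.splice_context`) — project a
  region's codons onto genomic coordinates through its gene model and
  classify it as `TRAVERSES` (split across an intron), `SMALL_ALT_EXON`,
  `ADJACENT` (< 5 bp from a junction) or `INTERNAL`; count
  repeat-length transcript isoforms between fixed flanks in mRNA panels.
* **Prioritization** (`polyq.prioritization`) — rank genes for
  polymorphism propensity by five binary criteria (pure CAG run ≥ 5;
  tract length not conserved in orthologs; reported polymorphism in
  other mammals; disease association of the ortholog; cDNA/genome
  discordance), cumulative score, ties broken by pure-CAG run length.
* **Panel genetics** (`polyq.panel_genetics`) — call repeat-unit
  alleles from fragment-analysis amplicon sizes (3-bp grid with
  calibration jitter), tabulate allele frequencies per subpopulation,
  test differentiation with a two-sided Fisher exact test for r×c
  tables (complete enumeration, seeded Monte Carlo fallback), check
  Mendelian trio consistency, and regress allele counts on repeat
  length.
* **Dataset statistics** (`polyq.summary_stats`) and a **synthetic-data
  generator** (`polyq.synthetic_data`) that emits genomes, GFF3 gene
  models, protein/CDS pairs, genotyping panels and trios with planted
  ground truth.

A published genotyping survey of 22 bovine poly-Q genes on a 185-animal
cattle diversity panel is packaged as a fixture
(`polyq.datasets.load_polyq_panel`).

## Worked example

```python
from polyq import load_polyq_panel, panel_gene_summary, diversity_regression
from polyq.repeat_annotation import CodonGene, scan_proteome

cds = "ATGGCT" + "CAG"*10 + "CAA" + "GCTGCC" + "TAA"
gene = CodonGene.from_cds("FXC1_like", cds)
regions, per_gene, errors = scan_proteome([gene])
print(regions[["geneId","startAA","endAA","qCount","purity","longestPureCag"]])

genes = panel_gene_summary()
poly = genes[genes["alleles"] > 1]
fit = diversity_regression(list(zip(poly["maxPureCag"], poly["alleles"])))
print(f"slope={fit.slope:.3f} alleles per CAG unit, r={fit.pearson_r:.3f}")
```

prints

```
   geneId  startAA  endAA  qCount purity  longestPureCag
FXC1_like        3     13      11  G10A1              10
slope=0.390 alleles per CAG unit, r=0.312
```

The tract spans residues 3–13, contains 11 glutamines encoded as ten
CAG followed by one CAA (`G10A1`), and its longest pure CAG run is 10 —
the quantity used both for criterion 1 and as the ranking tie-break.
Across the 16 polymorphic loci of the packaged survey, allele number
rises with pure-CAG length (positive slope and correlation), the
relationship that motivates the prioritization.

The same steps are available as a CLI: `polyq simulate`, `polyq scan`,
`polyq splice-context`, `polyq prioritize`, `polyq genotype`,
`polyq compare`, `polyq trios`, `polyq summarize` (see `polyq --help`).

## Layout

```
src/polyq/            library modules
src/polyq/data/       packaged survey fixture (TSV)
tests/                pytest suite (unit, property and acceptance tests)
scripts/acceptance.py end-to-end recomputation of headline numbers
docs/methods.md       models, defaults and design notes
```
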