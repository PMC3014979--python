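"""Genomic projection of repeat regions and splice-junction context.

A repeat region detected on the protein occupies a nucleotide footprint in
the genome that may be split across exons.  Relative to the splice
junctions of its gene each region is assigned exactly one category, in
this precedence order:

* ``TRAVERSES`` — the footprint spans at least one intron (the codons of
  the tract are split between exons, as in the NFYA Q-tract whose three
  CAG lie at the end of exon 2 and two at the start of exon 3);
* ``SMALL_ALT_EXON`` — contained in a short exon (<= ``small_exon_bp``)
  that is absent from at least one annotated transcript of the gene;
* ``ADJACENT`` — within ``adjacency_bp`` (exclusive) of a splice
  junction; gene termini are never junctions;
* ``INTERNAL`` — everything else.

Junction-spanning and junction-adjacent CAG tracts matter because the
splice donor consensus ((A/C)AG at the exon 3' end) and acceptor
consensus (intronic ...AG) resemble the repeat itself, letting the tract
shift splice-site choice and generate repeat-length transcript variants
without any genomic polymorphism.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Category",
    "GeneModel",
    "SpliceContext",
    "CoordinateError",
    "project_region",
    "classify_context",
    "transcript_repeat_lengths",
    "gene_models_from_gff3",
]

DEFAULT_ADJACENCY_BP = 5
DEFAULT_SMALL_EXON_BP = 120


class Category(str, Enum):
    TRAVERSES = "TRAVERSES"
    SMALL_ALT_EXON = "SMALL_ALT_EXON"
    ADJACENT = "ADJACENT"
    INTERNAL = "INTERNAL"


class CoordinateError(ValueError):
    """Region does not fit the gene model's CDS."""


@dataclass(frozen=True)
class GeneModel:
    """Exon/CDS structure of one gene on one contig.

    All intervals are 0-based half-open genomic coordinates sorted by
    start.  ``transcripts`` maps transcript id -> indices into ``exons``;
    ``cds_intervals`` is the coding footprint of the reference transcript
    (``ref_transcript``), whose concatenated length must be a multiple
    of 3.
    """

    gene_id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_intervals: tuple[tuple[int, int], ...]
    transcripts: dict[str, frozenset[int]] = field(default_factory=dict)
    ref_transcript: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        for ivs in (self.exons, self.cds_intervals):
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"{self.gene_id}: overlapping/unsorted intervals")
        if sum(e - s for s, e in self.cds_intervals) % 3:
            raise ValueError(f"{self.gene_id}: CDS length not divisible by 3")

    @property
    def cds_tx_order(self) -> tuple[tuple[int, int], ...]:
        """CDS intervals in transcription order."""
        return self.cds_intervals if self.strand == "+" else tuple(reversed(self.cds_intervals))

    def ref_exon_indices(self) -> tuple[int, ...]:
        """Genomic-order exon indices of the reference transcript."""
        if self.ref_transcript and self.ref_transcript in self.transcripts:
            return tuple(sorted(self.transcripts[self.ref_transcript]))
        return tuple(range(len(self.exons)))


@dataclass(frozen=True)
class SpliceContext:
    gene_id: str
    start_codon: int
    end_codon: int
    category: Category
    distance_bp: int | None  # nt to the nearest junction; 0 if traversing
    junction_side: str  # donor | acceptor | both | none


def project_region(
    model: GeneModel, start_codon: int, end_codon: int
) -> list[tuple[int, int]]:
    """Genomic footprint of a codon span, as per-exon intervals.

    Intervals are returned in transcription order and sum to
    ``3 * (end_codon - start_codon)`` nucleotides.
    """
    if start_codon < 0 or end_codon <= start_codon:
        raise CoordinateError(f"{model.gene_id}: bad codon span ({start_codon}, {end_codon})")
    nt_lo, nt_hi = 3 * start_codon, 3 * end_codon
    total = sum(e - s for s, e in model.cds_intervals)
    if nt_hi > total:
        raise CoordinateError(
            f"{model.gene_id}: span ends at CDS nt {nt_hi} but CDS is {total} nt"
        )
    out: list[tuple[int, int]] = []
    offset = 0
    for s, e in model.cds_tx_order:
        length = e - s
        lo = max(nt_lo, offset)
        hi = min(nt_hi, offset + length)
        if lo < hi:
            if model.strand == "+":
                out.append((s + (lo - offset), s + (hi - offset)))
            else:  # transcription runs right-to-left on the genome
                out.append((e - (hi - offset), e - (lo - offset)))
        offset += length
    return out


def _exon_index_containing(model: GeneModel, interval: tuple[int, int]) -> int:
    for i, (s, e) in enumerate(model.exons):
        if s <= interval[0] and interval[1] <= e:
            return i
    raise CoordinateError(f"{model.gene_id}: projected interval {interval} not inside an exon")


def _junction_distances(
    model: GeneModel, exon_idx: int, interval: tuple[int, int]
) -> list[tuple[int, str]]:
    """(distance, side) for each intron-facing boundary of the exon.

    The transcription-downstream end of an exon is the donor site, the
    upstream end the acceptor; gene termini are excluded.
    """
    ref = model.ref_exon_indices()
    if exon_idx not in ref:
        ref = tuple(sorted(set(ref) | {exon_idx}))
    first, last = ref[0], ref[-1]
    s, e = model.exons[exon_idx]
    rs, re_ = interval
    out: list[tuple[int, str]] = []
    if exon_idx != first:  # left genomic boundary is a junction
        side = "acceptor" if model.strand == "+" else "donor"
        out.append((rs - s, side))
    if exon_idx != last:  # right genomic boundary is a junction
        side = "donor" if model.strand == "+" else "acceptor"
        out.append((e - re_, side))
    return out


def classify_context(
    model: GeneModel,
    start_codon: int,
    end_codon: int,
    adjacency_bp: int = DEFAULT_ADJACENCY_BP,
    small_exon_bp: int = DEFAULT_SMALL_EXON_BP,
) -> SpliceContext:
    """Classify one repeat region's position relative to splice junctions."""
    if adjacency_bp < 1 or small_exon_bp < 1:
        raise ValueError("adjacency_bp and small_exon_bp must be >= 1")
    proj = project_region(model, start_codon, end_codon)
    if len(proj) > 1:
        return SpliceContext(
            model.gene_id, start_codon, end_codon, Category.TRAVERSES, 0, "both"
        )
    interval = proj[0]
    exon_idx = _exon_index_containing(model, interval)
    exon_s, exon_e = model.exons[exon_idx]

    skipped = any(
        exon_idx not in exon_set for exon_set in model.transcripts.values()
    )
    if (exon_e - exon_s) <= small_exon_bp and skipped:
        category: Category = Category.SMALL_ALT_EXON
    else:
        category = Category.INTERNAL

    dists = _junction_distances(model, exon_idx, interval)
    if dists:
        dmin = min(d for d, _ in dists)
        sides = {side for d, side in dists if d == dmin}
        side = sides.pop() if len(sides) == 1 else "both"
    else:
        dmin, side = None, "none"

    if category is Category.INTERNAL and dmin is not None and dmin < adjacency_bp:
        category = Category.ADJACENT
    return SpliceContext(model.gene_id, start_codon, end_codon, category, dmin, side)


def classify_regions(
    models: dict[str, GeneModel],
    regions: pd.DataFrame,
    adjacency_bp: int = DEFAULT_ADJACENCY_BP,
    small_exon_bp: int = DEFAULT_SMALL_EXON_BP,
) -> pd.DataFrame:
    """Classify every region in a tract table against its gene model."""
    rows = []
    for rec in regions.itertuples():
        model = models[rec.geneId]
        ctx = classify_context(
            model, rec.startCodon, rec.endCodon, adjacency_bp, small_exon_bp
        )
        rows.append(
            {
                "geneId": rec.geneId,
                "startAA": rec.startAA,
                "endAA": rec.endAA,
                "category": ctx.category.value,
                "distanceBp": ctx.distance_bp,
                "junctionSide": ctx.junction_side,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["geneId", "startAA", "endAA", "category", "distanceBp", "junctionSide"],
    )


def transcript_repeat_lengths(
    transcripts: Iterable[tuple[str, str]],
    flank5: str,
    flank3: str,
    genomic_monomorphic: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Count CAG units between fixed flanks in a panel of mRNA sequences.

    Each record is ``(sample_label, sequence)``; both anchors must occur
    exactly once and be at least 10 nt.  Returns per-record unit counts,
    a per-label summary (distinct counts; ``splice_variant`` flagged when
    one label yields more than one distinct count while the genomic locus
    is monomorphic), and skipped-record messages.
    """
    for name, flank in (("flank5", flank5), ("flank3", flank3)):
        if len(flank) < 10:
            raise ValueError(f"{name} must be >= 10 nt")
    rows: list[dict] = []
    errors: list[str] = []
    for label, seq in transcripts:
        seq = seq.upper().replace("U", "T")
        counts5 = [m.start() for m in re.finditer(re.escape(flank5.upper()), seq)]
        counts3 = [m.start() for m in re.finditer(re.escape(flank3.upper()), seq)]
        if len(counts5) != 1 or len(counts3) != 1:
            errors.append(
                f"{label}: anchors found {len(counts5)}x/{len(counts3)}x; record skipped"
            )
            continue
        between = seq[counts5[0] + len(flank5) : counts3[0]]
        if len(between) % 3 or not re.fullmatch(r"(CAG)*", between):
            errors.append(f"{label}: inter-anchor segment is not a pure CAG run; skipped")
            continue
        rows.append({"sampleLabel": label, "repeatUnitCount": len(between) // 3})
    per_record = pd.DataFrame(rows, columns=["sampleLabel", "repeatUnitCount"])
    summaries = []
    for label, grp in per_record.groupby("sampleLabel", sort=True):
        distinct = sorted(grp["repeatUnitCount"].unique())
        summaries.append(
            {
                "sampleLabel": label,
                "distinctCounts": ",".join(map(str, distinct)),
                "spliceVariant": bool(len(distinct) > 1 and genomic_monomorphic),
            }
        )
    summary = pd.DataFrame(
        summaries, columns=["sampleLabel", "distinctCounts", "spliceVariant"]
    )
    return per_record, summary, errors


def gene_models_from_gff3(gff3: str, from_string: bool = False) -> dict[str, GeneModel]:
    """Build :class:`GeneModel` objects from a GFF3 file or string.

    Expects gene/mRNA/exon/CDS features with Parent links.  GFF3 is
    1-based inclusive; coordinates are converted to 0-based half-open.
    The reference transcript of each gene is the mRNA with the longest
    CDS; mRNAs without CDS features still contribute exon sets (used to
    recognise alternatively spliced exons).
    """
    import gffutils

    db = gffutils.create_db(
        gff3,
        dbfn=":memory:",
        from_string=from_string,
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene"):
        exon_set: set[tuple[int, int]] = set()
        per_tx_exons: dict[str, set[tuple[int, int]]] = {}
        per_tx_cds: dict[str, list[tuple[int, int]]] = {}
        for mrna in db.children(gene, featuretype="mRNA"):
            exons = {
                (f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")
            }
            per_tx_exons[mrna.id] = exons
            exon_set |= exons
            cds = sorted((f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS"))
            if cds:
                per_tx_cds[mrna.id] = cds
        exons_sorted = tuple(sorted(exon_set))
        index_of = {iv: i for i, iv in enumerate(exons_sorted)}
        if not per_tx_cds:
            continue
        ref = max(per_tx_cds, key=lambda t: sum(e - s for s, e in per_tx_cds[t]))
        models[gene.id] = GeneModel(
            gene_id=gene.id,
            contig=gene.seqid,
            strand=gene.strand,
            exons=exons_sorted,
            cds_intervals=tuple(per_tx_cds[ref]),
            transcripts={
                tid: frozenset(index_of[iv] for iv in ivs)
                for tid, ivs in per_tx_exons.items()
            },
            ref_transcript=ref,
        )
    return models
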