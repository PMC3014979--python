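"""Codon-aware detection and purity encoding of poly-glutamine tracts.

Glutamine is encoded by exactly two codons, CAG and CAA.  Runs of CAG are
mutation-prone trinucleotide microsatellites; interruptions (CAA, or codons
for other residues) stabilise them.  This module finds runs of consecutive
glutamines in a protein, maps them onto the in-frame CDS, merges nearby
runs into repeat *regions*, and encodes each region's codon composition as
a purity string: run-length tokens over the alphabet

    G = CAG,  A = CAA,  N = any codon not encoding glutamine

e.g. ``G10A1`` is ten CAG followed by one CAA; ``G6N1G1`` contains a one
codon interruption.  On parsing, a bare letter counts as 1 (``G6NG1`` ==
``G6N1G1``); canonical emission always writes the digit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio.Data import CodonTable

__all__ = [
    "CodonGene",
    "QSeed",
    "RepeatRegion",
    "PurityError",
    "StructuralError",
    "parse_purity",
    "emit_purity",
    "find_q_seeds",
    "extend_region",
    "encode_purity",
    "longest_pure_cag",
    "region_from_span",
    "scan_gene",
    "scan_proteome",
]

DEFAULT_MIN_Q = 5
DEFAULT_MAX_GAP = 4

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
#: codon -> one-letter residue, stop codons mapped to '*'
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    CODON_TO_AA[_stop] = "*"

Q_CODONS = frozenset({"CAG", "CAA"})


class StructuralError(ValueError):
    """Protein/CDS pair is inconsistent (length or translation mismatch)."""


class PurityError(ValueError):
    """Malformed purity string or invalid region boundary."""


@dataclass(frozen=True)
class CodonGene:
    """A protein together with its in-frame CDS codons.

    ``codons`` are in transcription orientation with the stop codon
    excluded, so ``codons[i]`` encodes ``protein[i]``.
    """

    gene_id: str
    protein: str
    codons: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.codons) != len(self.protein):
            raise StructuralError(
                f"{self.gene_id}: {len(self.codons)} codons vs "
                f"{len(self.protein)} residues"
            )
        for i, (codon, aa) in enumerate(zip(self.codons, self.protein)):
            expected = CODON_TO_AA.get(codon.upper())
            if expected is None:
                raise StructuralError(f"{self.gene_id}: invalid codon {codon!r} at {i}")
            if expected != aa.upper():
                raise StructuralError(
                    f"{self.gene_id}: codon {codon} at position {i} encodes "
                    f"{expected}, protein has {aa}"
                )

    @classmethod
    def from_cds(cls, gene_id: str, cds: str) -> "CodonGene":
        """Build from a CDS string; a trailing stop codon is stripped."""
        cds = cds.upper().replace("U", "T")
        if len(cds) % 3:
            raise StructuralError(f"{gene_id}: CDS length {len(cds)} not divisible by 3")
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        if codons and CODON_TO_AA.get(codons[-1]) == "*":
            codons = codons[:-1]
        protein = "".join(CODON_TO_AA.get(c, "X") for c in codons)
        if "*" in protein:
            raise StructuralError(f"{gene_id}: internal stop codon")
        return cls(gene_id, protein, tuple(codons))


@dataclass(frozen=True)
class QSeed:
    """A maximal run of >= min_q consecutive glutamines (codon indices)."""

    start_codon: int
    end_codon: int

    @property
    def length(self) -> int:
        return self.end_codon - self.start_codon


@dataclass(frozen=True)
class RepeatRegion:
    """A glutamine-rich codon span with its purity encoding.

    Coordinates are 0-based half-open codon indices; reports use 1-based
    inclusive amino-acid positions (``start_aa``/``end_aa``).
    """

    gene_id: str
    start_codon: int
    end_codon: int
    purity: str
    q_count: int
    longest_pure_cag: int
    position_fraction: float

    @property
    def start_aa(self) -> int:
        return self.start_codon + 1

    @property
    def end_aa(self) -> int:
        return self.end_codon


_TOKEN_RE = re.compile(r"([GAN])(\d*)")


def parse_purity(s: str) -> tuple[tuple[str, int], ...]:
    """Parse a purity string into (letter, count) tokens.

    Bare letters count as 1.  Adjacent tokens with the same letter are
    merged so that the result is always maximal run-length encoded.
    """
    s = s.strip()
    if not s:
        raise PurityError("empty purity string")
    pos = 0
    tokens: list[tuple[str, int]] = []
    while pos < len(s):
        m = _TOKEN_RE.match(s, pos)
        if m is None:
            raise PurityError(f"invalid purity string {s!r} at offset {pos}")
        letter, digits = m.groups()
        count = int(digits) if digits else 1
        if count < 1:
            raise PurityError(f"zero-count token in {s!r}")
        if tokens and tokens[-1][0] == letter:
            tokens[-1] = (letter, tokens[-1][1] + count)
        else:
            tokens.append((letter, count))
        pos = m.end()
    return tuple(tokens)


def emit_purity(tokens: Iterable[tuple[str, int]]) -> str:
    """Canonical emission: every token carries an explicit count."""
    return "".join(f"{letter}{count}" for letter, count in tokens)


def find_q_seeds(gene: CodonGene, min_q: int = DEFAULT_MIN_Q) -> list[QSeed]:
    """All maximal runs of >= ``min_q`` consecutive Q residues.

    The scan is on the protein, so CAA-encoded glutamines count toward
    seeding exactly as CAG-encoded ones.
    """
    if min_q < 1:
        raise ValueError("min_q must be >= 1")
    if not gene.protein:
        raise ValueError(f"{gene.gene_id}: empty protein")
    return [
        QSeed(m.start(), m.end())
        for m in re.finditer(rf"Q{{{min_q},}}", gene.protein)
    ]


def _q_runs(protein: str) -> list[tuple[int, int]]:
    return [(m.start(), m.end()) for m in re.finditer(r"Q+", protein)]


def extend_region(
    gene: CodonGene, seed: QSeed, max_gap_codons: int = DEFAULT_MAX_GAP
) -> tuple[int, int]:
    """Greedily widen a seed by absorbing nearby Q runs.

    Neighbouring runs of glutamine codons (of any length) are merged into
    the region whenever they are separated from it by at most
    ``max_gap_codons`` non-Q codons, iterating outward to a fixed point.
    The returned span starts and ends on a glutamine codon.
    """
    if max_gap_codons < 0:
        raise ValueError("max_gap_codons must be >= 0")
    runs = _q_runs(gene.protein)
    idx = next(
        (i for i, (s, e) in enumerate(runs) if s <= seed.start_codon and seed.end_codon <= e),
        None,
    )
    if idx is None:
        raise ValueError(f"{gene.gene_id}: seed {seed} is not a glutamine run")
    lo = hi = idx
    while lo > 0 and runs[lo][0] - runs[lo - 1][1] <= max_gap_codons:
        lo -= 1
    while hi < len(runs) - 1 and runs[hi + 1][0] - runs[hi][1] <= max_gap_codons:
        hi += 1
    return runs[lo][0], runs[hi][1]


def encode_purity(gene: CodonGene, span: tuple[int, int]) -> str:
    """Run-length purity encoding of a codon span (canonical form).

    Raises :class:`PurityError` if a boundary codon does not encode
    glutamine, and :class:`StructuralError` for a codon that translates
    to Q but is neither CAG nor CAA (impossible under the standard code;
    indicates a frame bug upstream).
    """
    start, end = span
    if not (0 <= start < end <= len(gene.codons)):
        raise PurityError(f"{gene.gene_id}: span {span} out of bounds")
    letters: list[str] = []
    for i in range(start, end):
        codon = gene.codons[i]
        if codon in Q_CODONS:
            letters.append("G" if codon == "CAG" else "A")
        elif gene.protein[i] == "Q":
            raise StructuralError(
                f"{gene.gene_id}: codon {codon} at {i} encodes Q but is not CAG/CAA"
            )
        else:
            letters.append("N")
    if letters[0] == "N" or letters[-1] == "N":
        raise PurityError(f"{gene.gene_id}: region boundary at non-Q codon")
    tokens: list[tuple[str, int]] = []
    for letter in letters:
        if tokens and tokens[-1][0] == letter:
            tokens[-1] = (letter, tokens[-1][1] + 1)
        else:
            tokens.append((letter, 1))
    return emit_purity(tokens)


def longest_pure_cag(purity: str) -> int:
    """Longest uninterrupted CAG run (max G-token count; 0 if none)."""
    return max((n for letter, n in parse_purity(purity) if letter == "G"), default=0)


def q_count(purity: str) -> int:
    """Number of glutamines in a region (sum of G and A token counts)."""
    return sum(n for letter, n in parse_purity(purity) if letter in "GA")


def region_from_span(gene: CodonGene, span: tuple[int, int]) -> RepeatRegion:
    purity = encode_purity(gene, span)
    start, end = span
    return RepeatRegion(
        gene_id=gene.gene_id,
        start_codon=start,
        end_codon=end,
        purity=purity,
        q_count=q_count(purity),
        longest_pure_cag=longest_pure_cag(purity),
        position_fraction=((start + end) / 2) / len(gene.protein),
    )


def scan_gene(
    gene: CodonGene,
    min_q: int = DEFAULT_MIN_Q,
    max_gap_codons: int = DEFAULT_MAX_GAP,
) -> tuple[list[RepeatRegion], int]:
    """Regions of one gene plus the raw (pre-merge) seed count.

    Distinct seeds whose extended spans coincide or overlap collapse to a
    single reported region.
    """
    seeds = find_q_seeds(gene, min_q)
    spans = sorted({extend_region(gene, s, max_gap_codons) for s in seeds})
    merged: list[tuple[int, int]] = []
    for s, e in spans:  # overlapping extensions merge (extension is monotone,
        if merged and s <= merged[-1][1]:  # so this is belt-and-braces)
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return [region_from_span(gene, sp) for sp in merged], len(seeds)


REGION_COLUMNS = [
    "geneId",
    "startAA",
    "endAA",
    "startCodon",
    "endCodon",
    "qCount",
    "purity",
    "longestPureCag",
    "positionFraction",
]


def scan_proteome(
    genes: Iterable[CodonGene],
    min_q: int = DEFAULT_MIN_Q,
    max_gap_codons: int = DEFAULT_MAX_GAP,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Scan a set of genes for poly-Q repeat regions.

    Returns ``(regions, per_gene, errors)``: one region row per repeat
    region sorted by gene then start codon; a per-gene table with the
    merged tract count, raw seed count and maximum pure-CAG run; and a
    list of per-gene structural error messages (those genes are skipped).
    """
    region_rows: list[dict] = []
    gene_rows: list[dict] = []
    errors: list[str] = []
    for gene in genes:
        try:
            regions, n_seeds = scan_gene(gene, min_q, max_gap_codons)
        except (StructuralError, ValueError) as exc:
            errors.append(str(exc))
            continue
        if not regions:
            continue
        for r in regions:
            region_rows.append(
                {
                    "geneId": r.gene_id,
                    "startAA": r.start_aa,
                    "endAA": r.end_aa,
                    "startCodon": r.start_codon,
                    "endCodon": r.end_codon,
                    "qCount": r.q_count,
                    "purity": r.purity,
                    "longestPureCag": r.longest_pure_cag,
                    "positionFraction": r.position_fraction,
                }
            )
        gene_rows.append(
            {
                "geneId": gene.gene_id,
                "tractCount": len(regions),
                "seedCount": n_seeds,
                "maxLongestPureCag": max(r.longest_pure_cag for r in regions),
                "maxQCount": max(r.q_count for r in regions),
                "proteinLength": len(gene.protein),
            }
        )
    regions_df = pd.DataFrame(region_rows, columns=REGION_COLUMNS)
    per_gene = pd.DataFrame(
        gene_rows,
        columns=[
            "geneId",
            "tractCount",
            "seedCount",
            "maxLongestPureCag",
            "maxQCount",
            "proteinLength",
        ],
    )
    regions_df = regions_df.sort_values(["geneId", "startCodon"], kind="stable").reset_index(drop=True)
    per_gene = per_gene.sort_values("geneId", kind="stable").reset_index(drop=True)
    return regions_df, per_gene, errors
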