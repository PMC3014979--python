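"""Polymorphism-propensity ranking of poly-Q encoding genes.

Long, pure (uninterrupted) CAG runs are the strongest known predictor of
repeat-length polymorphism; interruption by the alternative glutamine
codon CAA stabilises a tract.  Genes are scored on five binary criteria
and ranked by cumulative score, with ties broken by the length of the
longest pure CAG run:

1. the gene carries a pure CAG run of at least 5 codons;
2. the tract lengths are not conserved across mammalian orthologs;
3. polymorphic variation reported in another mammalian species;
4. polymorphism of the human/mouse ortholog causes disease;
5. discordance between cDNA and the reference genome at the tract.

Criteria 3-5 summarise literature and database evidence and are consumed
as supplied annotation flags; criteria 1-2 are computed here from the
tract table and ortholog tract lengths.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "OrthologTracts",
    "criterion_pure_cag",
    "criterion_nonconserved",
    "rank_genes",
    "build_priority_table",
]

PURE_CAG_MIN = 5


@dataclass(frozen=True)
class OrthologTracts:
    """Tract Q-lengths for one gene across species; the focal species
    must be present (its list may include tracts of any length)."""

    gene_id: str
    focal_species: str
    lengths_by_species: Mapping[str, Sequence[int]]

    def __post_init__(self) -> None:
        if self.focal_species not in self.lengths_by_species:
            raise ValueError(f"{self.gene_id}: focal species missing from ortholog table")


def criterion_pure_cag(longest_pure_cags: Iterable[int], min_run: int = PURE_CAG_MIN) -> int:
    """1 iff any region of the gene has a pure CAG run >= ``min_run``."""
    return int(any(l >= min_run for l in longest_pure_cags))


def criterion_nonconserved(
    orth: OrthologTracts, min_q: int = 5, tolerance: int = 0
) -> tuple[int, bool]:
    """Tract-length conservation across orthologs.

    Compares the multiset of tract lengths >= ``min_q`` in the focal
    species against each comparison species.  Returns ``(flag,
    species_unique)``: flag is 1 iff any comparison species differs (a
    species with no qualifying tract counts as differing); species_unique
    is True iff some comparison species has no qualifying tract at all.
    With ``tolerance > 0`` two multisets match if they have equal size
    and can be paired within +/- tolerance (sorted order pairing).
    """
    focal = sorted(l for l in orth.lengths_by_species[orth.focal_species] if l >= min_q)
    if not focal:
        raise ValueError(f"{orth.gene_id}: focal species has no tract >= {min_q}")

    def matches(other: list[int]) -> bool:
        if len(other) != len(focal):
            return False
        if tolerance == 0:
            return Counter(other) == Counter(focal)
        return all(abs(a - b) <= tolerance for a, b in zip(focal, sorted(other)))

    flag = 0
    species_unique = False
    for species, lengths in orth.lengths_by_species.items():
        if species == orth.focal_species:
            continue
        qualifying = sorted(l for l in lengths if l >= min_q)
        if not qualifying:
            species_unique = True
        if not matches(qualifying):
            flag = 1
    return flag, species_unique


def rank_genes(records: pd.DataFrame) -> pd.DataFrame:
    """Rank genes by cumulative criterion score.

    ``records`` needs columns ``geneId, c1..c5, tieKey``.  Sort is
    descending on (score, tieKey) with a final deterministic lexicographic
    tie-break on geneId; ranks are 1..N.
    """
    required = ["geneId", "c1", "c2", "c3", "c4", "c5", "tieKey"]
    missing = [c for c in required if c not in records.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    out = records.copy()
    for c in ("c1", "c2", "c3", "c4", "c5"):
        bad = ~out[c].isin((0, 1))
        if bad.any():
            raise ValueError(f"criterion column {c} must be binary")
    out["score"] = out[["c1", "c2", "c3", "c4", "c5"]].sum(axis=1)
    out = out.sort_values(
        ["score", "tieKey", "geneId"],
        ascending=[False, False, True],
        kind="stable",
    ).reset_index(drop=True)
    out["rank"] = range(1, len(out) + 1)
    return out


def build_priority_table(
    per_gene: pd.DataFrame,
    orthologs: Mapping[str, OrthologTracts] | None,
    annotations: pd.DataFrame,
    min_q: int = 5,
) -> pd.DataFrame:
    """Assemble the full ranking table from pipeline outputs.

    ``per_gene`` is the per-gene summary from the proteome scan
    (``geneId, maxLongestPureCag, ...``); ``annotations`` supplies
    ``geneId, c3, c4, c5``.  Genes annotated but absent from the tract
    table are excluded with a warning; genes without annotation rows get
    c3 = c4 = c5 = 0, and genes without ortholog rows get c2 = 0.
    """
    known = set(per_gene["geneId"])
    orphan = sorted(set(annotations["geneId"]) - known)
    if orphan:
        warnings.warn(f"annotations for genes absent from tract table: {orphan}")
    ann = annotations[annotations["geneId"].isin(known)].set_index("geneId")
    rows = []
    for rec in per_gene.itertuples():
        c2 = 0
        if orthologs and rec.geneId in orthologs:
            c2, _ = criterion_nonconserved(orthologs[rec.geneId], min_q=min_q)
        flags = (
            ann.loc[rec.geneId, ["c3", "c4", "c5"]].astype(int).tolist()
            if rec.geneId in ann.index
            else [0, 0, 0]
        )
        rows.append(
            {
                "geneId": rec.geneId,
                "c1": criterion_pure_cag([rec.maxLongestPureCag]),
                "c2": c2,
                "c3": flags[0],
                "c4": flags[1],
                "c5": flags[2],
                "tieKey": rec.maxLongestPureCag,
            }
        )
    return rank_genes(pd.DataFrame(rows))
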