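"""Readers and writers for the pipeline's file formats.

FASTA goes through Biopython; everything tabular is plain TSV via
pandas.  Protein and CDS FASTA files are paired by identical record ids.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .panel_genetics import LocusDef
from .prioritization import OrthologTracts
from .repeat_annotation import CodonGene, StructuralError

__all__ = [
    "read_fasta",
    "read_codon_genes",
    "read_tracts",
    "write_tracts",
    "read_loci",
    "read_sizes",
    "read_pedigree",
    "read_orthologs",
    "read_annotations",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_codon_genes(
    protein_fa: str | Path, cds_fa: str | Path
) -> tuple[list[CodonGene], list[str]]:
    """Pair protein and CDS records into :class:`CodonGene` objects.

    Records failing the frame/translation invariants (including CDS
    length != 3 x protein length) are skipped and reported in the second
    return value.
    """
    proteins = read_fasta(protein_fa)
    cds = read_fasta(cds_fa)
    genes: list[CodonGene] = []
    errors: list[str] = []
    for gene_id, prot in proteins.items():
        if gene_id not in cds:
            errors.append(f"{gene_id}: no CDS record")
            continue
        try:
            gene = CodonGene.from_cds(gene_id, cds[gene_id])
            if gene.protein != prot.upper().rstrip("*"):
                raise StructuralError(f"{gene_id}: CDS translation differs from protein")
            genes.append(gene)
        except StructuralError as exc:
            errors.append(str(exc))
    return genes, errors


def read_tracts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tracts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_loci(path: str | Path) -> dict[str, LocusDef]:
    df = pd.read_csv(path, sep="\t")
    return {
        r.locusId: LocusDef(
            r.locusId,
            int(r.referenceAmpliconBp),
            int(r.referenceRepeatUnits),
            int(getattr(r, "unitBp", 3)),
        )
        for r in df.itertuples()
    }


def read_sizes(path: str | Path) -> pd.DataFrame:
    """Amplicon peaks: animalId, population, subtype, locusId, sizeBp."""
    return pd.read_csv(path, sep="\t")


def read_pedigree(path: str | Path) -> list[tuple[str, str, str]]:
    df = pd.read_csv(path, sep="\t")
    return [(r.sire, r.dam, r.child) for r in df.itertuples()]


def read_orthologs(path: str | Path, focal_species: str) -> dict[str, OrthologTracts]:
    """Ortholog tract tables: geneId, species, lengths (comma separated)."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, OrthologTracts] = {}
    for gene_id, grp in df.groupby("geneId"):
        lengths = {
            r.species: [int(x) for x in str(r.lengths).split(",") if str(x).strip()]
            if str(r.lengths) not in ("", "nan")
            else []
            for r in grp.itertuples()
        }
        out[gene_id] = OrthologTracts(gene_id, focal_species, lengths)
    return out


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Supplied criterion flags: geneId, c3, c4, c5 (binary)."""
    return pd.read_csv(path, sep="\t")
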