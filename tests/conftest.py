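import numpy as np
import pytest

from polyq.repeat_annotation import CODON_TO_AA, CodonGene

# one representative codon per residue (Q deliberately CAG; tests that
# need CAA or interruptions build codons explicitly)
_AA_TO_CODON = {}
for codon, aa in sorted(CODON_TO_AA.items()):
    _AA_TO_CODON.setdefault(aa, codon)
_AA_TO_CODON["Q"] = "CAG"


def gene_from_protein(gene_id: str, protein: str, codons=None) -> CodonGene:
    """CodonGene with canonical codons unless explicit codons are given."""
    if codons is None:
        codons = tuple(_AA_TO_CODON[aa] for aa in protein)
    return CodonGene(gene_id, protein, tuple(codons))


def gene_from_codons(gene_id: str, codons) -> CodonGene:
    protein = "".join(CODON_TO_AA[c] for c in codons)
    return CodonGene(gene_id, protein, tuple(codons))


@pytest.fixture(scope="session")
def panel_fixture():
    from polyq.datasets import load_polyq_panel

    return load_polyq_panel()


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
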