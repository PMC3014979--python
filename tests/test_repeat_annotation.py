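"""Tract detection, region extension and purity encoding."""

import re

import numpy as np
import pytest

from polyq.repeat_annotation import (
    CodonGene,
    QSeed,
    StructuralError,
    PurityError,
    emit_purity,
    encode_purity,
    find_q_seeds,
    extend_region,
    longest_pure_cag,
    parse_purity,
    scan_gene,
    scan_proteome,
)

from conftest import gene_from_protein, gene_from_codons

NON_Q = "GCT"  # alanine


def brute_force_seeds(protein: str, min_q: int):
    """Independent oracle: test every substring for being a maximal Q-run."""
    out = []
    n = len(protein)
    for i in range(n):
        for j in range(i + min_q, n + 1):
            if (
                all(protein[k] == "Q" for k in range(i, j))
                and (i == 0 or protein[i - 1] != "Q")
                and (j == n or protein[j] != "Q")
            ):
                out.append((i, j))
    return out


class TestFindQSeeds:
    def test_threshold_run_found(self):
        gene = gene_from_protein("g", "AAQQQQQAA")
        assert [(s.start_codon, s.end_codon) for s in find_q_seeds(gene, 5)] == [(2, 7)]

    def test_below_threshold_empty(self):
        gene = gene_from_protein("g", "AAQQQQAA")
        assert find_q_seeds(gene, 5) == []

    def test_matches_bruteforce_on_random_proteins(self, rng):
        for _ in range(30):
            protein = "".join(rng.choice(list("QAL"), p=[0.4, 0.3, 0.3], size=200))
            gene = gene_from_protein("g", protein)
            got = [(s.start_codon, s.end_codon) for s in find_q_seeds(gene, 5)]
            assert got == brute_force_seeds(protein, 5)

    def test_empty_protein_rejected(self):
        with pytest.raises(ValueError):
            find_q_seeds(gene_from_protein("g", ""), 5)


def oracle_extended_span(protein: str, seed: tuple[int, int], max_gap: int):
    """Exhaustive oracle: merge all Q-runs reachable through <=max_gap bridges."""
    runs = [(m.start(), m.end()) for m in re.finditer(r"Q+", protein)]
    merged = {next(i for i, r in enumerate(runs) if r[0] <= seed[0] and seed[1] <= r[1])}
    changed = True
    while changed:
        changed = False
        for i, run in enumerate(runs):
            if i in merged:
                continue
            for j in merged:
                gap = max(runs[j][0], run[0]) - min(runs[j][1], run[1])
                if gap <= max_gap:
                    merged.add(i)
                    changed = True
                    break
    return min(runs[i][0] for i in merged), max(runs[i][1] for i in merged)


class TestExtendRegion:
    def test_gap_within_threshold_merges(self):
        codons = ["CAG"] * 6 + [NON_Q] * 4 + ["CAG"] * 5
        gene = gene_from_codons("g", codons)
        seed = find_q_seeds(gene, 5)[0]
        assert extend_region(gene, seed, 4) == (0, 15)

    def test_gap_beyond_threshold_splits(self):
        codons = ["CAG"] * 6 + [NON_Q] * 5 + ["CAG"] * 5
        gene = gene_from_codons("g", codons)
        regions, _ = scan_gene(gene, 5, 4)
        assert [(r.start_codon, r.end_codon) for r in regions] == [(0, 6), (11, 16)]

    def test_matches_merge_oracle_on_random_genes(self, rng):
        for _ in range(30):
            codons = rng.choice(["CAG", "CAA", NON_Q], p=[0.3, 0.1, 0.6], size=120).tolist()
            gene = gene_from_codons("g", codons)
            for seed in find_q_seeds(gene, 5):
                got = extend_region(gene, seed, 4)
                want = oracle_extended_span(gene.protein, (seed.start_codon, seed.end_codon), 4)
                assert got == want


class TestPurity:
    def test_canonical_examples(self):
        gene = gene_from_codons("g", ["CAG"] * 10 + ["CAA"])
        assert encode_purity(gene, (0, 11)) == "G10A1"
        gene = gene_from_codons("g", ["CAG"] * 15)
        assert encode_purity(gene, (0, 15)) == "G15"

    def test_bare_letter_equivalence(self):
        assert parse_purity("G6NG1") == parse_purity("G6N1G1")

    def test_roundtrip_on_published_strings(self, panel_fixture):
        for s in panel_fixture["purity"]:
            tokens = parse_purity(s)
            canonical = emit_purity(tokens)
            assert parse_purity(canonical) == tokens
            # maximal RLE: adjacent tokens differ in letter
            assert all(a[0] != b[0] for a, b in zip(tokens, tokens[1:]))

    def test_boundary_on_non_q_codon_rejected(self):
        gene = gene_from_codons("g", [NON_Q] + ["CAG"] * 5)
        with pytest.raises(PurityError):
            encode_purity(gene, (0, 6))

    @pytest.mark.parametrize(
        "purity,expected",
        [("G5A1G13", 13), ("A1G4", 4), ("A7", 0), ("G15", 15)],
    )
    def test_longest_pure_cag(self, purity, expected):
        assert longest_pure_cag(purity) == expected


class TestScanProteome:
    def _planted(self, qlens):
        genes = []
        for i, qlen in enumerate(qlens):
            codons = [NON_Q] * 10 + ["CAG"] * qlen + [NON_Q] * 10
            genes.append(gene_from_codons(f"g{i}", codons))
        return genes

    def test_planted_tracts_recovered(self):
        regions, per_gene, errors = scan_proteome(self._planted([5, 7, 33]))
        assert errors == []
        assert sorted(regions["qCount"]) == [5, 7, 33]
        assert (regions["startAA"] == 11).all()
        assert (per_gene["tractCount"] == 1).all()

    def test_two_seeds_merged_into_one_region(self):
        codons = ["CAG"] * 6 + [NON_Q] * 3 + ["CAG"] * 5
        regions, n_seeds = scan_gene(gene_from_codons("g", codons), 5, 4)
        assert n_seeds == 2
        assert len(regions) == 1
        assert regions[0].purity == "G6N3G5"

    def test_empty_input(self):
        regions, per_gene, errors = scan_proteome([])
        assert regions.empty and per_gene.empty and errors == []

    def test_order_invariance(self, rng):
        genes = []
        for i in range(10):
            codons = rng.choice(["CAG", "CAA", NON_Q], p=[0.25, 0.1, 0.65], size=150).tolist()
            genes.append(gene_from_codons(f"g{i}", codons))
        fwd, _, _ = scan_proteome(genes)
        rev, _, _ = scan_proteome(genes[::-1])
        assert fwd.equals(rev)

    def test_region_invariants_on_random_genes(self, rng):
        genes = [
            gene_from_codons(
                f"g{i}", rng.choice(["CAG", "CAA", NON_Q], p=[0.3, 0.15, 0.55], size=200).tolist()
            )
            for i in range(15)
        ]
        regions, _, _ = scan_proteome(genes)
        assert (regions["qCount"] >= regions["longestPureCag"]).all()
        assert regions["positionFraction"].between(0, 1).all()
        # every region carries at least one seed of >= 5 Q
        assert (
            regions["purity"].map(
                lambda p: max(
                    (sum(n for _, n in run) for run in _q_token_runs(p)), default=0
                )
            )
            >= 5
        ).all()

    def test_structural_errors_skip_gene(self):
        good = gene_from_codons("good", [NON_Q] * 5 + ["CAG"] * 6)
        bad = CodonGene("bad", "", ())
        regions, per_gene, errors = scan_proteome([good, bad])
        assert list(per_gene["geneId"]) == ["good"]
        assert len(errors) == 1

    def test_frame_mismatch_raises(self):
        with pytest.raises(StructuralError):
            CodonGene("g", "QQ", ("CAG",))
        with pytest.raises(StructuralError):
            CodonGene("g", "A", ("CAG",))


def _q_token_runs(purity):
    """Maximal stretches of G/A tokens (split at N) from a purity string."""
    runs, cur = [], []
    for tok in parse_purity(purity):
        if tok[0] == "N":
            if cur:
                runs.append(cur)
            cur = []
        else:
            cur.append(tok)
    if cur:
        runs.append(cur)
    return runs
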