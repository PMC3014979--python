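"""Synthetic genomes, gene models and genotyping panels with planted truth.

The generator emulates the study design the pipeline is built for:

* multi-exon protein-coding genes carrying embedded CAG/CAA repeat
  regions, with the repeat placed internally, across a splice junction,
  within ``adjacency`` of a junction, or inside a small alternatively
  spliced exon;
* a two-subpopulation diversity panel genotyped at repeat loci by
  amplicon size, with sub-trinucleotide Gaussian calibration jitter;
* parent-parent-offspring trios with a configurable per-meiosis
  single-unit mutation rate.

Background codons never encode glutamine, so every planted repeat region
is unambiguous and the emitted truth tables score the downstream stages
exactly.  All randomness flows from one seeded ``numpy`` generator;
outputs are byte-identical for a fixed config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .repeat_annotation import (
    CODON_TO_AA,
    parse_purity,
    emit_purity,
)

__all__ = [
    "RepeatSpec",
    "LocusSpec",
    "PopulationSpec",
    "SimConfig",
    "SimulatedGenes",
    "SimulatedPanel",
    "simulate_genes",
    "simulate_panel",
    "random_purity",
]

PLACEMENTS = ("internal", "junction", "adjacent", "smallAltExon")

#: sense codons that do not encode glutamine
NON_Q_CODONS = tuple(
    sorted(c for c, aa in CODON_TO_AA.items() if aa not in ("Q", "*"))
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RepeatSpec:
    """One planted repeat region: its purity pattern and placement."""

    q_length: int
    purity: str | None = None  # None -> pure CAG run of q_length
    placement: str = "internal"

    def __post_init__(self) -> None:
        if self.placement not in PLACEMENTS:
            raise ValueError(f"unknown placement {self.placement!r}")
        if self.purity is None and self.q_length < 1:
            raise ValueError("q_length must be >= 1")

    def tokens(self) -> tuple[tuple[str, int], ...]:
        if self.purity is not None:
            toks = parse_purity(self.purity)
            if toks[0][0] == "N" or toks[-1][0] == "N":
                raise ValueError("purity pattern must start and end with G or A")
            return toks
        return (("G", self.q_length),)


@dataclass(frozen=True)
class LocusSpec:
    locus_id: str
    reference_amplicon_bp: int = 200
    reference_repeat_units: int = 10
    unit_bp: int = 3


@dataclass(frozen=True)
class PopulationSpec:
    """A subpopulation with its per-locus allele-frequency spectra.

    ``freqs`` maps locus id -> {repeat units: frequency}; each spectrum
    must sum to 1 within 1e-9.
    """

    label: str
    subtype: str
    n_animals: int
    freqs: Mapping[str, Mapping[int, float]]

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError(f"{self.label}: n_animals must be >= 1")
        for locus, spectrum in self.freqs.items():
            total = sum(spectrum.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{self.label}/{locus}: frequencies sum to {total}")
            if any(u < 1 for u in spectrum):
                raise ValueError(f"{self.label}/{locus}: allele units must be >= 1")


@dataclass(frozen=True)
class SimConfig:
    seed: int
    n_genes: int = 4
    exon_count_range: tuple[int, int] = (2, 4)
    repeat_specs: tuple[RepeatSpec, ...] | None = None
    min_q: int = 5
    decoys: bool = False
    loci: tuple[LocusSpec, ...] = ()
    populations: tuple[PopulationSpec, ...] = ()
    jitter_sd_bp: float = 0.5
    trio_count: int = 0
    meiosis_mutation_rate: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.exon_count_range
        if lo < 1 or hi < lo:
            raise ValueError("bad exon_count_range")
        if not 0.0 <= self.meiosis_mutation_rate <= 1.0:
            raise ValueError("meiosis_mutation_rate must be in [0, 1]")
        if self.jitter_sd_bp < 0:
            raise ValueError("jitter_sd_bp must be >= 0")
        if self.trio_count > 0:
            if not self.populations:
                raise ValueError("trios require at least one population")
            if self.populations[0].n_animals < 2:
                raise ValueError("population used for trios needs >= 2 animals")


def random_purity(rng: np.random.Generator, min_q: int = 5) -> str:
    """A random realistic purity pattern.

    One to three glutamine runs (the first of at least ``min_q`` Q so the
    region always seeds a scan), mostly CAG with occasional CAA, joined
    by interruptions of 1-4 non-Q codons (within the merge gap).
    """
    n_runs = int(rng.integers(1, 4))
    tokens: list[tuple[str, int]] = []
    for i in range(n_runs):
        if i:
            tokens.append(("N", int(rng.integers(1, 5))))
        run_len = int(rng.integers(min_q, min_q + 12)) if i == 0 else int(rng.integers(1, 9))
        letters = ["G" if rng.random() > 0.15 else "A" for _ in range(run_len)]
        # boundaries of the whole region must be glutamine codons
        for letter in letters:
            if tokens and tokens[-1][0] == letter:
                tokens[-1] = (letter, tokens[-1][1] + 1)
            else:
                tokens.append((letter, 1))
    return emit_purity(tokens)


def _codons_for_tokens(
    tokens: Sequence[tuple[str, int]], rng: np.random.Generator
) -> list[str]:
    out: list[str] = []
    for letter, count in tokens:
        if letter == "G":
            out.extend(["CAG"] * count)
        elif letter == "A":
            out.extend(["CAA"] * count)
        else:
            out.extend(rng.choice(NON_Q_CODONS, size=count).tolist())
    return out


@dataclass
class SimulatedGenes:
    contigs: dict[str, str]
    gff3: str
    proteins: dict[str, str]
    cds: dict[str, str]
    truth: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_fasta(outdir / "genome.fa", self.contigs)
        _write_fasta(outdir / "proteins.fa", self.proteins)
        _write_fasta(outdir / "cds.fa", self.cds)
        (outdir / "genes.gff3").write_text(self.gff3)
        self.truth.to_csv(outdir / "truth_regions.tsv", sep="\t", index=False)


def _write_fasta(path: Path, records: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for name in records:
            fh.write(f">{name}\n")
            seq = records[name]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(("A", "C", "G", "T"), size=n).tolist())


def _choose_junctions(
    rng: np.random.Generator,
    cfg: SimConfig,
    spec: RepeatSpec,
    region_nt: tuple[int, int],
    cds_len: int,
) -> tuple[list[int], int | None]:
    """Junction positions (CDS nt, codon-aligned) honouring the placement.

    Returns (junctions, small_exon_index) where the index refers to the
    exon segment that must be alternatively spliced, or None.
    """
    rs, re_ = region_nt
    buffer_nt = 6  # keeps incidental junctions outside the adjacency window
    min_exon = 30

    fixed: list[int] = []
    small_interval: tuple[int, int] | None = None
    if spec.placement == "junction":
        n_codons = (re_ - rs) // 3
        split = int(rng.integers(1, n_codons))
        fixed = [rs + 3 * split]
    elif spec.placement == "adjacent":
        d = int(rng.choice((0, 3)))
        side = rng.random() < 0.5
        fixed = [rs - d] if side else [re_ + d]
    elif spec.placement == "smallAltExon":
        if (re_ - rs) > 120 - 12:
            raise ValueError("repeat too long for a small alternatively spliced exon")
        a, b = rs - 6, re_ + 6
        fixed = [a, b]
        small_interval = (a, b)

    lo_n, hi_n = cfg.exon_count_range
    n_exons = int(rng.integers(lo_n, hi_n + 1))
    extra_needed = max(0, n_exons - 1 - len(fixed))
    forbidden_lo, forbidden_hi = rs - buffer_nt, re_ + buffer_nt
    candidates = [
        p
        for p in range(min_exon, cds_len - min_exon + 1, 3)
        if not (forbidden_lo <= p <= forbidden_hi)
        and all(abs(p - f) >= min_exon for f in fixed)
    ]
    extras: list[int] = []
    order = rng.permutation(len(candidates))
    for p in (candidates[i] for i in order):
        if len(extras) >= extra_needed:
            break
        if all(abs(p - q) >= min_exon for q in extras):
            extras.append(p)
    junctions = sorted(set(fixed) | set(extras))
    junctions = [j for j in junctions if 0 < j < cds_len]
    small_idx = None
    if small_interval is not None:
        bounds = [0] + junctions + [cds_len]
        small_idx = bounds.index(small_interval[0])
    return junctions, small_idx


def _build_gene(
    rng: np.random.Generator, cfg: SimConfig, gene_id: str, spec: RepeatSpec
) -> dict:
    tokens = spec.tokens()
    region_len = sum(n for _, n in tokens)
    purity = emit_purity(tokens)
    q_total = sum(n for letter, n in tokens if letter in "GA")

    L = int(rng.integers(max(90, region_len + 60), max(180, region_len + 140)))
    r0 = int(rng.integers(20, L - region_len - 20))
    codons = rng.choice(NON_Q_CODONS, size=L).tolist()
    codons[r0 : r0 + region_len] = _codons_for_tokens(tokens, rng)
    if cfg.decoys:
        decoy_len = cfg.min_q - 1
        pos = r0 - 12 if r0 - 12 - decoy_len >= 2 else r0 + region_len + 8
        if 0 <= pos and pos + decoy_len <= L and (
            pos + decoy_len < r0 - 5 or pos > r0 + region_len + 5
        ):
            codons[pos : pos + decoy_len] = ["CAG"] * decoy_len

    cds_seq = "".join(codons)
    cds_len = 3 * L
    region_nt = (3 * r0, 3 * (r0 + region_len))
    junctions, small_idx = _choose_junctions(rng, cfg, spec, region_nt, cds_len)
    bounds = [0] + junctions + [cds_len]
    segments = list(zip(bounds, bounds[1:]))

    # assemble forward-orientation contig
    introns = [_random_nt(rng, int(rng.integers(60, 300))) for _ in range(len(segments) - 1)]
    flank5 = _random_nt(rng, int(rng.integers(40, 120)))
    flank3 = _random_nt(rng, int(rng.integers(40, 120)))
    parts = [flank5]
    exon_fwd: list[tuple[int, int]] = []
    pos = len(flank5)
    for i, (s, e) in enumerate(segments):
        parts.append(cds_seq[s:e])
        exon_fwd.append((pos, pos + (e - s)))
        pos += e - s
        if i < len(introns):
            parts.append(introns[i])
            pos += len(introns[i])
    parts.append(flank3)
    fwd = "".join(parts)

    strand = "+" if rng.random() < 0.5 else "-"
    if strand == "+":
        contig_seq = fwd
        exons = exon_fwd
    else:
        contig_seq = _revcomp(fwd)
        total = len(fwd)
        exons = sorted((total - e, total - s) for s, e in exon_fwd)
        if small_idx is not None:
            small_idx = len(segments) - 1 - small_idx

    protein = "".join(CODON_TO_AA[c] for c in codons)
    return {
        "gene_id": gene_id,
        "contig_seq": contig_seq,
        "strand": strand,
        "exons": exons,
        "small_idx": small_idx,
        "protein": protein,
        "cds": cds_seq,
        "truth": {
            "geneId": gene_id,
            "startCodon": r0,
            "endCodon": r0 + region_len,
            "startAA": r0 + 1,
            "endAA": r0 + region_len,
            "purity": purity,
            "qCount": q_total,
            "longestPureCag": max((n for l, n in tokens if l == "G"), default=0),
            "category": {
                "internal": "INTERNAL",
                "junction": "TRAVERSES",
                "adjacent": "ADJACENT",
                "smallAltExon": "SMALL_ALT_EXON",
            }[spec.placement],
            "strand": strand,
        },
    }


def _gff3_for_gene(g: dict) -> str:
    gene_id = g["gene_id"]
    contig = gene_id
    exons = g["exons"]
    strand = g["strand"]
    lines = []
    gmin, gmax = exons[0][0] + 1, exons[-1][1]
    lines.append(
        f"{contig}\tsim\tgene\t{gmin}\t{gmax}\t.\t{strand}\t.\tID={gene_id}"
    )
    tx1 = f"{gene_id}.t1"
    lines.append(
        f"{contig}\tsim\tmRNA\t{gmin}\t{gmax}\t.\t{strand}\t.\tID={tx1};Parent={gene_id}"
    )
    tx_exons = exons if strand == "+" else list(reversed(exons))
    cum = 0
    phases = []
    for s, e in tx_exons:
        phases.append((3 - cum % 3) % 3)
        cum += e - s
    phase_by_exon = dict(zip(tx_exons, phases))
    for s, e in exons:
        lines.append(
            f"{contig}\tsim\texon\t{s + 1}\t{e}\t.\t{strand}\t.\tID={tx1}.exon.{s};Parent={tx1}"
        )
        lines.append(
            f"{contig}\tsim\tCDS\t{s + 1}\t{e}\t.\t{strand}\t{phase_by_exon[(s, e)]}\tID={tx1}.cds;Parent={tx1}"
        )
    if g["small_idx"] is not None:
        tx2 = f"{gene_id}.t2"
        kept = [iv for i, iv in enumerate(exons) if i != g["small_idx"]]
        lines.append(
            f"{contig}\tsim\tmRNA\t{gmin}\t{gmax}\t.\t{strand}\t.\tID={tx2};Parent={gene_id}"
        )
        for s, e in kept:
            lines.append(
                f"{contig}\tsim\texon\t{s + 1}\t{e}\t.\t{strand}\t.\tID={tx2}.exon.{s};Parent={tx2}"
            )
    return "\n".join(lines)


def simulate_genes(config: SimConfig) -> SimulatedGenes:
    """Generate genome, gene models and protein/CDS pairs with truth."""
    rng = np.random.default_rng(config.seed)
    specs = config.repeat_specs
    genes = []
    for i in range(config.n_genes):
        if specs:
            spec = specs[i % len(specs)]
        else:
            spec = RepeatSpec(
                q_length=0,
                purity=random_purity(rng, config.min_q),
                placement=PLACEMENTS[int(rng.integers(0, len(PLACEMENTS)))],
            )
        genes.append(_build_gene(rng, config, f"gene{i:03d}", spec))

    gff3 = "##gff-version 3\n" + "\n".join(_gff3_for_gene(g) for g in genes) + "\n"
    truth = pd.DataFrame([g["truth"] for g in genes])
    return SimulatedGenes(
        contigs={g["gene_id"]: g["contig_seq"] for g in genes},
        gff3=gff3,
        proteins={g["gene_id"]: g["protein"] for g in genes},
        cds={g["gene_id"]: g["cds"] for g in genes},
        truth=truth,
    )


@dataclass
class SimulatedPanel:
    genotypes: pd.DataFrame  # truth, incl. trio animals
    sizes: pd.DataFrame  # one row per distinct amplicon peak
    pedigree: pd.DataFrame
    n_mutations: int  # total mutated meioses across all trios/loci

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.genotypes.to_csv(outdir / "truth_genotypes.tsv", sep="\t", index=False)
        self.sizes.to_csv(outdir / "sizes.tsv", sep="\t", index=False)
        self.pedigree.to_csv(outdir / "pedigree.tsv", sep="\t", index=False)


def _draw_genotype(
    rng: np.random.Generator, spectrum: Mapping[int, float]
) -> tuple[int, int]:
    units = np.array(sorted(spectrum), dtype=int)
    probs = np.array([spectrum[u] for u in units], dtype=float)
    probs = probs / probs.sum()
    a, b = rng.choice(units, size=2, p=probs)
    return (int(a), int(b)) if a <= b else (int(b), int(a))


def simulate_panel(config: SimConfig) -> SimulatedPanel:
    """Generate a genotyped diversity panel, amplicon sizes and trios."""
    if not config.loci or not config.populations:
        raise ValueError("panel simulation needs loci and populations")
    rng = np.random.default_rng(config.seed)
    loci = {l.locus_id: l for l in config.loci}
    geno_rows: list[dict] = []
    size_rows: list[dict] = []

    def emit(animal: str, pop: PopulationSpec, locus: LocusSpec, g: tuple[int, int]) -> None:
        geno_rows.append(
            {
                "animalId": animal,
                "population": pop.label,
                "subtype": pop.subtype,
                "locusId": locus.locus_id,
                "allele1Units": g[0],
                "allele2Units": g[1],
            }
        )
        for units in sorted(set(g)):  # homozygotes give a single peak
            size = (
                locus.reference_amplicon_bp
                + (units - locus.reference_repeat_units) * locus.unit_bp
                + (rng.normal(0.0, config.jitter_sd_bp) if config.jitter_sd_bp else 0.0)
            )
            size_rows.append(
                {
                    "animalId": animal,
                    "population": pop.label,
                    "subtype": pop.subtype,
                    "locusId": locus.locus_id,
                    "sizeBp": round(float(size), 2),
                }
            )

    for pop in config.populations:
        for i in range(pop.n_animals):
            animal = f"{pop.label}_{i:04d}"
            for locus_id, spectrum in pop.freqs.items():
                emit(animal, pop, loci[locus_id], _draw_genotype(rng, spectrum))

    ped_rows: list[dict] = []
    n_mutations = 0
    trio_pop = config.populations[0] if config.populations else None
    for t in range(config.trio_count):
        sire, dam, child = (f"trio{t:03d}_{role}" for role in ("sire", "dam", "child"))
        ped_rows.append({"sire": sire, "dam": dam, "child": child})
        for locus_id, spectrum in trio_pop.freqs.items():
            locus = loci[locus_id]
            gs = _draw_genotype(rng, spectrum)
            gd = _draw_genotype(rng, spectrum)
            passed = []
            for parent_g in (gs, gd):
                allele = int(parent_g[int(rng.integers(0, 2))])
                if rng.random() < config.meiosis_mutation_rate:
                    allele = max(1, allele + (1 if rng.random() < 0.5 else -1))
                    n_mutations += 1
                passed.append(allele)
            gc = (min(passed), max(passed))
            emit(sire, trio_pop, locus, gs)
            emit(dam, trio_pop, locus, gd)
            emit(child, trio_pop, locus, gc)

    genotypes = pd.DataFrame(
        geno_rows,
        columns=["animalId", "population", "subtype", "locusId", "allele1Units", "allele2Units"],
    )
    sizes = pd.DataFrame(
        size_rows, columns=["animalId", "population", "subtype", "locusId", "sizeBp"]
    )
    pedigree = pd.DataFrame(ped_rows, columns=["sire", "dam", "child"])
    return SimulatedPanel(genotypes, sizes, pedigree, n_mutations)
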