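"""Executable worked examples on a synthetic spliceosome-gene-like reference.

The reference CDS is randomly generated except for pinned codon anchors
that reproduce the residue contexts of the published resistant/sensitive
alleles (Q at 157, the DAPDATPGIG motif at 223-232, the LPLMKPEDYQYFGTL
motif at 442-456, the H-K-K-G run at 1048-1051 with AAG lysines, A at
1064). Flank codons next to each anchor are fixed so that indel
normalization lands on a unique canonical placement.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np

from .genotyping import DnaVariant, apply_variants
from .seqcore import DomainTable, GeneModel, NucleotideSequence, build_gene_model

#: All 61 sense codons (random flank material; keeps the CDS stop-free).
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]

#: Pinned codons, 1-based residue -> codon.
_ANCHORS: dict[int, str] = {
    1: "ATG",
    156: "GGA", 157: "CAA", 158: "TTC",                    # Q157 context
    222: "TCA", 233: "TCT",                                # DAPDATPGIG flanks
    **{223 + i: c for i, c in enumerate(
        ["GAT", "GCT", "CCA", "GAC", "GCA", "ACT", "CCT", "GGA", "ATT", "GGC"]
    )},                                                    # D A P D A T P G I G
    441: "GAA", 457: "GCA",                                # 15-mer motif flanks
    **{442 + i: c for i, c in enumerate(
        ["CTT", "CCA", "CTG", "ATG", "AAA", "CCG", "GAA", "GAT",
         "TAT", "CAA", "TAC", "TTT", "GGT", "ACT", "CTC"]
    )},                                                    # L P L M K P E D Y Q Y F G T L
    1047: "GAA", 1048: "CAT", 1049: "AAG", 1050: "AAG",    # E H K K
    1051: "GGT", 1052: "CCT",                              # G P
    1064: "GCT",                                           # A (for the A->S passenger)
}

#: Example PTG parts for demos only — placeholder sequences, not asserted
#: to match any published vector.
EXAMPLE_TRNA = (
    "AACAAAGCACCAGTGGTCTAGTGGTAGAATAGTACCCTGCCACGGTACAGACCCGGGTTCGATTCCCGGCTGGTGCA"
)
EXAMPLE_SCAFFOLD = (
    "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCGTTATCAACTTGAAAAAGTGGCACCGAGTCGGTGC"
)

#: Demo domain table: an invented conserved-repeat window around the
#: drug-interaction residues, plus an N-terminal region.
DEMO_DOMAINS = (
    ("N-loop", 140, 240),
    ("HR15-17", 1030, 1090),
)


def reference_model(seed: int = 0, n_res: int = 1120) -> GeneModel:
    """Deterministic synthetic coding gene with the pinned residue anchors."""
    if n_res < 1065:
        raise ValueError("reference needs at least 1065 residues for the anchors")
    rng = np.random.default_rng(seed)
    codons = [str(c) for c in rng.choice(_SENSE_CODONS, size=n_res)]
    for res, codon in _ANCHORS.items():
        codons[res - 1] = codon
    cds = "".join(codons) + "TAA"
    return build_gene_model("synthetic-spliceosome-gene", cds=cds)


def domain_table(model: GeneModel) -> DomainTable:
    return DomainTable.from_rows(DEMO_DOMAINS, model.n_residues)


def _codon_start(res: int) -> int:
    return 3 * (res - 1)


def worked_alleles(model: GeneModel) -> list[tuple[str, NucleotideSequence, tuple[str, ...]]]:
    """Mutant alleles mirroring the published variant set.

    Returns (allele_id, mutant sequence, expected protein labels) triples;
    the expected labels are what the genotype -> consequence pipeline
    should report after normalization.
    """
    ref = model.cds.seq
    k1049 = _codon_start(1049)  # start of the first AAG of the K-K run

    specs: list[tuple[str, list[DnaVariant], tuple[str, ...]]] = [
        # one codon-aligned Q deletion
        ("SGR1", [DnaVariant("deletion", _codon_start(157), "CAA", "")], ("Q157del",)),
        # 30-nt codon-aligned deletion of a 10-residue motif
        (
            "SGR2",
            [DnaVariant("deletion", _codon_start(223), ref[_codon_start(223):_codon_start(233)], "")],
            ("D223_G232del",),
        ),
        # one AAG removed from the AAG-AAG run -> normalizes to the 3' lysine
        ("SGR3", [DnaVariant("deletion", k1049, "AAG", "")], ("K1050del",)),
        # 9-nt replacement decomposing into three consecutive substitutions
        (
            "SGR4",
            [DnaVariant("delins", k1049, ref[k1049:k1049 + 9], "AGGGAGCAT")],
            ("K1049R", "K1050E", "G1051H"),
        ),
        # non-codon-aligned 3-nt deletion across the H/K codon boundary
        ("SGR5", [DnaVariant("deletion", k1049 - 1, ref[k1049 - 1:k1049 + 2], "")],
         ("H1048Q", "K1049del")),
        # the same compound edit plus a distant passenger substitution
        (
            "SGR6",
            [
                DnaVariant("deletion", k1049 - 1, ref[k1049 - 1:k1049 + 2], ""),
                DnaVariant("substitution", _codon_start(1064), "G", "T"),
            ],
            ("H1048Q", "K1049del", "A1064S"),
        ),
        # 45-nt codon-aligned deletion of the 15-residue motif
        (
            "SGS1",
            [DnaVariant("deletion", _codon_start(442), ref[_codon_start(442):_codon_start(457)], "")],
            ("L442_L456del",),
        ),
    ]
    out = []
    for allele_id, variants, expected in specs:
        seq = apply_variants(ref, variants)
        out.append((allele_id, NucleotideSequence(allele_id, seq), expected))
    return out
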