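"""Cloning artifacts: BsaI-overhang oligo pairs and polycistronic
tRNA-gRNA (PTG) assemblies."""
from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .guide_design import GuideTarget
from .seqcore import NucleotideSequence, revcomp

FORWARD_OVERHANG = "GGCA"
REVERSE_OVERHANG = "AAAC"

BSAI_SITES = ("GGTCTC", "GAGACC")


@dataclass(frozen=True)
class OligoPair:
    """Annealing-ready oligo pair for Golden Gate spacer cloning.

    The duplex of forward vs reverse oligo has a perfectly complementary
    20-nt core and 4-nt 5' single-stranded overhangs (the two constants).
    """

    guide_id: str
    forward_oligo: str
    reverse_oligo: str


def design_cloning_oligos(
    guide: GuideTarget,
    forward_overhang: str = FORWARD_OVERHANG,
    reverse_overhang: str = REVERSE_OVERHANG,
    guide_len: int = 20,
    prepend_g: bool = False,
) -> OligoPair:
    """Build the annealed oligo pair for one guide.

    ``prepend_g`` adds a 5' G to the spacer (and its complement to the
    reverse oligo) for vectors that require a transcribed G; off by default.
    """
    proto = guide.protospacer
    if len(proto) != guide_len:
        raise ValueError(
            f"{guide.guide_id}: protospacer length {len(proto)} != {guide_len}"
        )
    spacer = ("G" + proto) if prepend_g and not proto.startswith("G") else proto
    return OligoPair(
        guide_id=guide.guide_id,
        forward_oligo=forward_overhang + spacer,
        reverse_oligo=reverse_overhang + revcomp(spacer),
    )


def validate_bsai(
    protospacer: str,
    forward_overhang: str = FORWARD_OVERHANG,
    reverse_overhang: str = REVERSE_OVERHANG,
) -> list[str]:
    """Warn about internal BsaI recognition sites in the assembled duplex.

    An internal GGTCTC/GAGACC anywhere in either full oligo (overhang
    included, so junction-spanning sites are caught) would be re-cut during
    Golden Gate assembly.
    """
    warnings_out = []
    for name, oligo in (
        ("forward", forward_overhang + protospacer),
        ("reverse", reverse_overhang + revcomp(protospacer)),
    ):
        for site in BSAI_SITES:
            pos = oligo.find(site)
            if pos != -1:
                warnings_out.append(
                    f"internal BsaI site {site} in {name} oligo at position {pos + 1}"
                )
    return warnings_out


@dataclass(frozen=True)
class PTGConstruct:
    """Polycistronic tRNA-gRNA fusion: tandem (tRNA + spacer + scaffold)
    units, optionally bracketed by flank strings."""

    name: str
    unit_order: tuple[str, ...]
    trna: str
    scaffold: str
    sequence: str


def assemble_ptg(
    guides: Sequence[GuideTarget],
    trna: str,
    scaffold: str,
    flank5: str = "",
    flank3: str = "",
    name: str = "ptg",
    allow_duplicates: bool = False,
) -> PTGConstruct:
    """Concatenate one tRNA-spacer-scaffold unit per guide, in input order."""
    if not guides:
        raise ValueError("PTG assembly requires at least one guide")
    if not trna or not scaffold:
        raise ValueError("tRNA and scaffold sequences must be non-empty")
    ids = [g.guide_id for g in guides]
    if len(set(ids)) != len(ids) and not allow_duplicates:
        raise ValueError(f"duplicate guide ids in PTG: {ids}")
    trna = trna.upper()
    scaffold = scaffold.upper()
    body = "".join(trna + g.protospacer + scaffold for g in guides)
    return PTGConstruct(
        name=name,
        unit_order=tuple(ids),
        trna=trna,
        scaffold=scaffold,
        sequence=flank5.upper() + body + flank3.upper(),
    )


def ptg_to_fasta_record(construct: PTGConstruct) -> NucleotideSequence:
    return NucleotideSequence(construct.name, construct.sequence)


def write_oligo_sheet(pairs: Sequence[OligoPair], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["guide_id", "forward_oligo", "reverse_oligo"])
        for p in pairs:
            w.writerow([p.guide_id, p.forward_oligo, p.reverse_oligo])
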