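"""Exhaustive protospacer enumeration and domain-focused guide selection.

Every PAM-adjacent site on both strands is reported — overlapping and
nested guides included; no composition filters are applied by default.
"""
from __future__ import annotations

import csv
import dataclasses
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .seqcore import GeneModel, NucleotideSequence, SequenceError, revcomp

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class GuideTarget:
    """One protospacer+PAM hit.

    ``protospacer`` and ``pam`` are strand-oriented 5'->3'. ``start`` is the
    0-based plus-strand coordinate of the leftmost protospacer base (so the
    plus-strand slice ``region[start:start+len]`` reproduces the protospacer
    directly for + guides and via reverse complement for - guides).
    ``cut_pos`` marks the blunt cut: the bond after this plus-strand index
    is cleaved (3 nt 5' of the PAM, between protospacer positions 17|18).
    """

    guide_id: str
    protospacer: str
    pam: str
    strand: str
    start: int
    cut_pos: int
    cut_res: int | None = None
    in_cds: bool = True


def _matches(seq: str, pattern: str) -> bool:
    return len(seq) == len(pattern) and all(
        base in IUPAC[p] for base, p in zip(seq, pattern)
    )


def cut_site(start: int, strand: str, guide_len: int = 20) -> int:
    """Plus-strand coordinate of the blunt SpCas9 cut for a guide.

    The bond 3' of the returned index is cleaved: ``start + guide_len - 4``
    for + guides, ``start + 2`` for - guides (whose PAM lies to the left).
    """
    if strand == "+":
        return start + guide_len - 4
    if strand == "-":
        return start + 2
    raise ValueError(f"bad strand {strand!r}")


def enumerate_guides(
    region: str | NucleotideSequence,
    guide_len: int = 20,
    pam_pattern: str = "NGG",
    require_5prime: str | None = None,
) -> list[GuideTarget]:
    """Enumerate every protospacer adjacent to ``pam_pattern`` on both strands.

    Output is sorted by plus-strand start, + before -, with deterministic
    ids ``sg-001`` onward. ``require_5prime`` optionally keeps only guides
    whose strand-oriented first base matches (pol III promoter preference);
    default keeps everything.
    """
    seq = region.seq if isinstance(region, NucleotideSequence) else region.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise SequenceError(f"illegal characters in region: {sorted(bad)}")
    plen = len(pam_pattern)
    if len(seq) < guide_len + plen:
        warnings.warn(
            f"region length {len(seq)} shorter than guide+PAM ({guide_len + plen}); no guides"
        )
        return []
    rc_pattern = revcomp(pam_pattern) if set(pam_pattern) <= set("ACGTN") else "".join(
        # complement of an IUPAC pattern: complement each code, then reverse
        {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N",
         "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
         "B": "V", "V": "B", "D": "H", "H": "D"}[c]
        for c in reversed(pam_pattern)
    )

    hits: list[tuple[int, str, str, str]] = []  # (start, strand, protospacer, pam)
    for i in range(len(seq) - guide_len - plen + 1):
        pam = seq[i + guide_len : i + guide_len + plen]
        if _matches(pam, pam_pattern):
            hits.append((i, "+", seq[i : i + guide_len], pam))
    # minus strand: plus-strand pattern revcomp(PAM) immediately 5' of the
    # protospacer footprint
    for j in range(len(seq) - plen - guide_len + 1):
        if _matches(seq[j : j + plen], rc_pattern):
            start = j + plen
            proto = revcomp(seq[start : start + guide_len])
            hits.append((start, "-", proto, revcomp(seq[j : j + plen])))

    hits.sort(key=lambda h: (h[0], 0 if h[1] == "+" else 1))
    guides = []
    n = 0
    for start, strand, proto, pam in hits:
        if require_5prime and proto[0] != require_5prime.upper():
            continue
        n += 1
        guides.append(
            GuideTarget(
                guide_id=f"sg-{n:03d}",
                protospacer=proto,
                pam=pam,
                strand=strand,
                start=start,
                cut_pos=cut_site(start, strand, guide_len),
            )
        )
    return guides


def attach_gene_model(guides: Sequence[GuideTarget], model: GeneModel) -> list[GuideTarget]:
    """Annotate guides (enumerated on the model's genomic or CDS sequence)
    with ``in_cds`` and the residue whose codon contains the cut."""
    out = []
    for g in guides:
        cds_pos = model.genomic_to_cds(g.cut_pos)
        if cds_pos is None or cds_pos >= 3 * model.n_residues:
            out.append(dataclasses.replace(g, in_cds=False, cut_res=None))
        else:
            out.append(
                dataclasses.replace(g, in_cds=True, cut_res=cds_pos // 3 + 1)
            )
    return out


def filter_by_residue_range(
    guides: Sequence[GuideTarget],
    model: GeneModel,
    start_res: int,
    end_res: int,
) -> list[GuideTarget]:
    """Keep guides whose cut falls inside the CDS window spanned by the
    residue range (1-based inclusive); annotates ``cut_res`` on the output.

    Guides are assumed enumerated on the model's CDS (or on its genomic
    sequence when exons are attached, in which case cuts are mapped first).
    """
    if not 1 <= start_res <= end_res <= model.n_residues:
        raise ValueError(
            f"residue range {start_res}-{end_res} out of 1..{model.n_residues}"
        )
    lo = model.residue_interval(start_res)[0]
    hi = model.residue_interval(end_res)[1]
    kept = []
    for g in guides:
        cds_pos = model.genomic_to_cds(g.cut_pos)
        if cds_pos is None:
            continue
        if lo <= cds_pos < hi:
            kept.append(dataclasses.replace(g, cut_res=cds_pos // 3 + 1, in_cds=True))
    return kept


LIBRARY_COLUMNS = [
    "guide_id", "protospacer", "pam", "strand",
    "start_1based", "cut_pos_1based", "cut_res", "in_cds",
]


def write_library_table(guides: Sequence[GuideTarget], path: str | Path) -> None:
    """Write the guide library as a TSV (1-based user-facing coordinates)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(LIBRARY_COLUMNS)
        for g in guides:
            w.writerow([
                g.guide_id, g.protospacer, g.pam, g.strand,
                g.start + 1, g.cut_pos + 1,
                "" if g.cut_res is None else g.cut_res,
                int(g.in_cds),
            ])


def read_library_table(path: str | Path) -> list[GuideTarget]:
    guides = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            guides.append(
                GuideTarget(
                    guide_id=row["guide_id"],
                    protospacer=row["protospacer"],
                    pam=row["pam"],
                    strand=row["strand"],
                    start=int(row["start_1based"]) - 1,
                    cut_pos=int(row["cut_pos_1based"]) - 1,
                    cut_res=int(row["cut_res"]) if row["cut_res"] else None,
                    in_cds=bool(int(row["in_cds"])),
                )
            )
    return guides
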