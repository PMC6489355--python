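"""Sequence and gene-model primitives shared by the rest of the toolkit.

Internal coordinates are 0-based half-open throughout; user-facing reports
(library tables, variant labels) convert to 1-based inclusive at the edge.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

STRICT_ALPHABET = frozenset("ACGT")
QUERY_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SequenceError(ValueError):
    """Raised on malformed sequence input (bad alphabet, bad FASTA, ...)."""


@dataclass(frozen=True)
class NucleotideSequence:
    """An uppercased DNA sequence with an identifier.

    ``allow_n`` relaxes the alphabet to {A,C,G,T,N}; references must stay
    strict, genotyping queries may carry N.
    """

    id: str
    seq: str
    allow_n: bool = field(default=False, compare=False, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        if not self.seq:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        alphabet = QUERY_ALPHABET if self.allow_n else STRICT_ALPHABET
        bad = set(self.seq) - alphabet
        if bad:
            raise SequenceError(
                f"record {self.id!r}: illegal characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    bad = set(seq.upper()) - QUERY_ALPHABET
    if bad:
        raise SequenceError(f"illegal characters for revcomp: {sorted(bad)}")
    return seq.upper().translate(_COMPLEMENT)[::-1]


def translate(cds: str, to_first_stop: bool = False) -> str:
    """Standard-code translation; stops render as ``*``.

    By default the full length is translated (embedded stops visible);
    ``to_first_stop`` truncates at the first stop codon.
    """
    if len(cds) % 3 != 0:
        raise SequenceError(
            f"CDS length {len(cds)} is not divisible by 3"
        )
    aa = str(Seq(cds).translate())
    if to_first_stop:
        cut = aa.find("*")
        if cut != -1:
            aa = aa[:cut]
    return aa


def residue_to_cds(res: int, protein_length: int) -> tuple[int, int]:
    """Map a 1-based residue index to its half-open 0-based CDS interval."""
    if not 1 <= res <= protein_length:
        raise ValueError(
            f"residue {res} out of range 1..{protein_length}"
        )
    return 3 * (res - 1), 3 * res


def read_fasta(path: str | Path, allow_n: bool = False) -> list[NucleotideSequence]:
    """Read a multi-record FASTA; rejects empty files and duplicate ids."""
    records: list[NucleotideSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(NucleotideSequence(rec.id, str(rec.seq), allow_n=allow_n))
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[NucleotideSequence], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


@dataclass(frozen=True)
class GeneModel:
    """A coding gene: CDS, translated protein, optional genomic context.

    Invariants (enforced by :func:`build_gene_model`): exons sorted and
    non-overlapping, concatenated exon slices equal the CDS, CDS length
    divisible by 3, ATG start, no internal stop. The terminal stop codon
    belongs to the CDS but is excluded from residue numbering.
    """

    gene_id: str
    cds: NucleotideSequence
    protein: str
    genomic: NucleotideSequence | None = None
    exons: tuple[tuple[int, int], ...] | None = None

    @property
    def n_residues(self) -> int:
        return len(self.protein)

    def residue_interval(self, res: int) -> tuple[int, int]:
        return residue_to_cds(res, len(self.protein))

    def genomic_to_cds(self, pos: int) -> int | None:
        """Map a 0-based genomic position into CDS space (None if intronic)."""
        if self.exons is None:
            return pos if 0 <= pos < len(self.cds.seq) else None
        offset = 0
        for start, end in self.exons:
            if start <= pos < end:
                return offset + (pos - start)
            offset += end - start
        return None


def build_gene_model(
    gene_id: str,
    cds: str | NucleotideSequence | None = None,
    genomic: str | NucleotideSequence | None = None,
    exons: Sequence[tuple[int, int]] | None = None,
    permissive_start: bool = False,
) -> GeneModel:
    """Construct a validated :class:`GeneModel`.

    Either ``cds`` is given directly, or ``genomic`` + ``exons`` (0-based
    half-open) from which the CDS is spliced. Invariant violations raise;
    a non-ATG start is demoted to a warning under ``permissive_start``.
    """
    genomic_rec: NucleotideSequence | None = None
    exon_tuple: tuple[tuple[int, int], ...] | None = None

    if genomic is not None:
        genomic_rec = (
            genomic
            if isinstance(genomic, NucleotideSequence)
            else NucleotideSequence(f"{gene_id}:genomic", genomic)
        )
        if exons is None:
            raise ValueError("genomic sequence given without exon intervals")
        exon_tuple = tuple((int(s), int(e)) for s, e in exons)
        for s, e in exon_tuple:
            if not 0 <= s < e <= len(genomic_rec.seq):
                raise ValueError(f"exon [{s},{e}) outside genomic sequence")
        for (s1, e1), (s2, e2) in zip(exon_tuple, exon_tuple[1:]):
            if s2 < e1:
                raise ValueError(
                    f"exons [{s1},{e1}) and [{s2},{e2}) overlap or are unsorted"
                )
        spliced = "".join(genomic_rec.seq[s:e] for s, e in exon_tuple)
        if cds is not None:
            given = cds.seq if isinstance(cds, NucleotideSequence) else cds.upper()
            if given != spliced:
                raise ValueError("provided CDS does not match spliced exons")
        cds = spliced
    elif cds is None:
        raise ValueError("either cds or genomic+exons must be provided")

    cds_rec = (
        cds
        if isinstance(cds, NucleotideSequence)
        else NucleotideSequence(f"{gene_id}:cds", cds)
    )
    if len(cds_rec.seq) % 3 != 0:
        raise ValueError(f"CDS length {len(cds_rec.seq)} not divisible by 3")
    if not cds_rec.seq.startswith("ATG"):
        msg = f"CDS of {gene_id} does not begin with ATG"
        if permissive_start:
            warnings.warn(msg)
        else:
            raise ValueError(msg)
    aa = translate(cds_rec.seq)
    protein = aa[:-1] if aa.endswith("*") else aa
    if "*" in protein:
        pos = protein.index("*") + 1
        raise ValueError(f"internal stop codon at residue {pos} in {gene_id}")
    return GeneModel(
        gene_id=gene_id,
        cds=cds_rec,
        protein=protein,
        genomic=genomic_rec,
        exons=exon_tuple,
    )


@dataclass(frozen=True)
class DomainTable:
    """Named residue ranges, 1-based inclusive."""

    entries: tuple[tuple[str, int, int], ...]

    @classmethod
    def from_rows(
        cls, rows: Iterable[tuple[str, int, int]], protein_length: int | None = None
    ) -> "DomainTable":
        entries = []
        for name, start, end in rows:
            start, end = int(start), int(end)
            if not 1 <= start <= end:
                raise ValueError(f"domain {name!r}: bad range {start}-{end}")
            if protein_length is not None and end > protein_length:
                raise ValueError(
                    f"domain {name!r}: end {end} beyond protein length {protein_length}"
                )
            entries.append((name, start, end))
        return cls(tuple(entries))

    @classmethod
    def read_tsv(cls, path: str | Path, protein_length: int | None = None) -> "DomainTable":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                name, start, end = line.split("\t")[:3]
                if name == "name" and not start.isdigit():
                    continue  # header
                rows.append((name, int(start), int(end)))
        return cls.from_rows(rows, protein_length)


def read_exons_tsv(path: str | Path) -> list[tuple[int, int]]:
    """Minimal exon table: one `start<TAB>end` per line, 1-based inclusive."""
    exons = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            start, end = line.split("\t")[:2]
            exons.append((int(start) - 1, int(end)))
    if not exons:
        raise ValueError(f"no exon rows in {path}")
    return exons


def read_exons_gff3(path: str | Path, feature: str = "CDS") -> list[tuple[int, int]]:
    """Extract CDS feature intervals from a GFF3 file (converted to 0-based)."""
    exons = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 8 or cols[2] != feature:
                continue
            exons.append((int(cols[3]) - 1, int(cols[4])))
    if not exons:
        raise ValueError(f"no {feature} features in {path}")
    return sorted(exons)
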