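"""Amplicon genotyping: affine-gap global alignment, DNA variant calling,
and 3'-shifting normalization of indels.

Scoring convention (pinned for exact score tests): a gap of length L costs
``gap_open + L * gap_extend`` — the opening column is charged both terms.
Traceback tie-break order is diagonal > up > left.
"""
from __future__ import annotations

import json
import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from numba import njit

from .seqcore import GeneModel, NucleotideSequence, SequenceError

_ENCODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

NEG = np.int32(-(2**30))


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_ENCODE[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        raise SequenceError(f"illegal character {exc.args[0]!r} in sequence") from None


@njit(cache=False)
def _gotoh_fill(r, q, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n = r.shape[0]
    m = q.shape[0]
    M = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    X = np.full((n + 1, m + 1), NEG, dtype=np.int32)  # gap in query (up)
    Y = np.full((n + 1, m + 1), NEG, dtype=np.int32)  # gap in ref (left)
    M[0, 0] = 0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + i * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = gap_open + j * gap_extend
    for i in range(1, n + 1):
        ri = r[i - 1]
        for j in range(1, m + 1):
            if ri == q[j - 1] and ri < 4:
                s = match
            else:
                s = mismatch
            best = M[i - 1, j - 1]
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
            M[i, j] = best + s
            xo = M[i - 1, j] + gap_open + gap_extend
            xe = X[i - 1, j] + gap_extend
            X[i, j] = xo if xo >= xe else xe
            yo = M[i, j - 1] + gap_open + gap_extend
            ye = Y[i, j - 1] + gap_extend
            Y[i, j] = yo if yo >= ye else ye
    return M, X, Y


@dataclass(frozen=True)
class AlignmentResult:
    ref_aln: str
    qry_aln: str
    score: int

    @property
    def identity(self) -> float:
        same = sum(a == b for a, b in zip(self.ref_aln, self.qry_aln))
        return same / len(self.ref_aln)


def align_global(
    ref: str,
    qry: str,
    match: int = 2,
    mismatch: int = -3,
    gap_open: int = -10,
    gap_extend: int = -1,
) -> AlignmentResult:
    """Optimal global alignment (Gotoh affine-gap DP) with deterministic
    traceback: at score ties, diagonal beats up (gap in query) beats left."""
    if not ref or not qry:
        raise ValueError("align_global requires two non-empty sequences")
    r = _encode(ref.upper())
    q = _encode(qry.upper())
    M, X, Y = _gotoh_fill(r, q, match, mismatch, gap_open, gap_extend)

    i, j = len(ref), len(qry)
    # state selection priority: M (diag) > X (up) > Y (left)
    scores = (M[i, j], X[i, j], Y[i, j])
    score = int(max(scores))
    state = scores.index(max(scores))

    ref_parts: list[str] = []
    qry_parts: list[str] = []
    ref_u = ref.upper()
    qry_u = qry.upper()
    while i > 0 or j > 0:
        if state == 0:  # M: consumed ref[i-1], qry[j-1]
            ref_parts.append(ref_u[i - 1])
            qry_parts.append(qry_u[j - 1])
            a, b = r[i - 1], q[j - 1]
            s = match if (a == b and a < 4) else mismatch
            prev = M[i, j] - s
            if M[i - 1, j - 1] == prev:
                state = 0
            elif X[i - 1, j - 1] == prev:
                state = 1
            else:
                state = 2
            i -= 1
            j -= 1
        elif state == 1:  # X: gap in query, consumed ref[i-1]
            ref_parts.append(ref_u[i - 1])
            qry_parts.append("-")
            if i == 1 and j == 0:
                state = 0  # boundary
            elif M[i - 1, j] + gap_open + gap_extend == X[i, j]:
                state = 0
            else:
                state = 1
            i -= 1
        else:  # Y: gap in ref, consumed qry[j-1]
            ref_parts.append("-")
            qry_parts.append(qry_u[j - 1])
            if j == 1 and i == 0:
                state = 0
            elif M[i, j - 1] + gap_open + gap_extend == Y[i, j]:
                state = 0
            else:
                state = 2
            j -= 1
    return AlignmentResult("".join(reversed(ref_parts)), "".join(reversed(qry_parts)), score)


@dataclass(frozen=True)
class DnaVariant:
    """A normalized reference-vs-allele difference in CDS coordinates.

    ``cds_start`` is 0-based; the reference slice
    ``ref[cds_start : cds_start + len(ref_allele)]`` equals ``ref_allele``.
    Insertions have an empty ``ref_allele`` and sit before ``cds_start``'s
    base; deletions have an empty ``alt_allele``.
    """

    kind: str  # substitution | deletion | insertion | delins
    cds_start: int
    ref_allele: str
    alt_allele: str
    normalized: bool = False

    @property
    def net(self) -> int:
        return len(self.alt_allele) - len(self.ref_allele)

    @property
    def cds_end(self) -> int:
        return self.cds_start + len(self.ref_allele)


def _classify_kind(ref_allele: str, alt_allele: str) -> str:
    if ref_allele and not alt_allele:
        return "deletion"
    if alt_allele and not ref_allele:
        return "insertion"
    if len(ref_allele) == len(alt_allele):
        return "substitution"
    return "delins"


def call_dna_variants(aln: AlignmentResult, ref_offset: int = 0) -> list[DnaVariant]:
    """Collapse contiguous non-match alignment columns into variants.

    Runs separated by at least one matching column stay separate; pure gap
    runs become deletions/insertions, gapless mismatch runs substitutions,
    mixed runs delins. Coordinates are reference-space (plus ``ref_offset``).
    """
    variants: list[DnaVariant] = []
    ref_pos = ref_offset
    run_ref: list[str] = []
    run_alt: list[str] = []
    run_start = 0

    def flush() -> None:
        nonlocal run_ref, run_alt
        if run_ref or run_alt:
            ra, aa = "".join(run_ref), "".join(run_alt)
            variants.append(DnaVariant(_classify_kind(ra, aa), run_start, ra, aa))
            run_ref, run_alt = [], []

    for rc, qc in zip(aln.ref_aln, aln.qry_aln):
        if rc == qc and rc != "-":
            flush()
            ref_pos += 1
            continue
        if not (run_ref or run_alt):
            run_start = ref_pos
        if rc != "-":
            run_ref.append(rc)
            ref_pos += 1
        if qc != "-":
            run_alt.append(qc)
    flush()
    return variants


def normalize_3prime(v: DnaVariant, ref: str) -> DnaVariant:
    """Shift a pure indel to its 3'-most equivalent placement (HGVS style).

    Idempotent; never changes the implied mutant sequence. Substitutions
    and delins are returned unchanged (marked normalized).
    """
    if v.kind == "deletion":
        pos, length = v.cds_start, len(v.ref_allele)
        while pos + length < len(ref) and ref[pos] == ref[pos + length]:
            pos += 1
        return replace(v, cds_start=pos, ref_allele=ref[pos : pos + length], normalized=True)
    if v.kind == "insertion":
        pos, alt = v.cds_start, v.alt_allele
        while pos < len(ref) and alt[0] == ref[pos]:
            alt = alt[1:] + ref[pos]
            pos += 1
        return replace(v, cds_start=pos, alt_allele=alt, normalized=True)
    return replace(v, normalized=True)


def apply_variants(ref: str, variants: Sequence[DnaVariant]) -> str:
    """Splice a variant set into the reference; variants must not overlap."""
    ordered = sorted(variants, key=lambda v: (v.cds_start, v.cds_end))
    out: list[str] = []
    pos = 0
    for v in ordered:
        if v.cds_start < pos:
            raise ValueError(f"overlapping variants at CDS position {v.cds_start}")
        if ref[v.cds_start : v.cds_end] != v.ref_allele:
            raise ValueError(
                f"ref allele mismatch at {v.cds_start}: "
                f"expected {v.ref_allele!r}, reference has {ref[v.cds_start:v.cds_end]!r}"
            )
        out.append(ref[pos : v.cds_start])
        out.append(v.alt_allele)
        pos = v.cds_end
    out.append(ref[pos:])
    return "".join(out)


def genotype(
    model: GeneModel,
    allele: NucleotideSequence | str,
    amplicon: tuple[int, int] | None = None,
    match: int = 2,
    mismatch: int = -3,
    gap_open: int = -10,
    gap_extend: int = -1,
    min_identity: float = 0.5,
) -> list[DnaVariant]:
    """Call normalized DNA variants of an allele against the model CDS.

    ``amplicon`` restricts the reference to a 0-based half-open CDS window
    (sub-amplicon genotyping); variant coordinates are lifted back to full
    CDS space. Alleles that align below ``min_identity`` are rejected.
    """
    qry = allele.seq if isinstance(allele, NucleotideSequence) else allele.upper()
    offset = 0
    ref = model.cds.seq
    if amplicon is not None:
        start, end = amplicon
        if not 0 <= start < end <= len(ref):
            raise ValueError(f"amplicon [{start},{end}) outside CDS")
        ref = ref[start:end]
        offset = start
    aln = align_global(ref, qry, match, mismatch, gap_open, gap_extend)
    if aln.identity < min_identity:
        raise ValueError(
            f"amplicon does not match locus (identity {aln.identity:.2f} < {min_identity})"
        )
    variants = call_dna_variants(aln, ref_offset=offset)
    return [normalize_3prime(v, model.cds.seq) for v in variants]


VARIANT_COLUMNS = ["allele_id", "kind", "cds_start_1based", "ref", "alt", "normalized"]


def write_variant_table(
    calls: Sequence[tuple[str, Sequence[DnaVariant]]], path: str | Path
) -> None:
    """Write per-allele variant calls as a TSV (1-based start coordinates)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(VARIANT_COLUMNS)
        for allele_id, variants in calls:
            for v in variants:
                w.writerow([
                    allele_id, v.kind, v.cds_start + 1,
                    v.ref_allele or ".", v.alt_allele or ".",
                    int(v.normalized),
                ])


def variants_to_json(calls: Sequence[tuple[str, Sequence[DnaVariant]]]) -> str:
    payload = {
        allele_id: [
            {
                "kind": v.kind,
                "cds_start_1based": v.cds_start + 1,
                "ref": v.ref_allele,
                "alt": v.alt_allele,
                "normalized": v.normalized,
            }
            for v in variants
        ]
        for allele_id, variants in calls
    }
    return json.dumps(payload, indent=2, sort_keys=True)
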