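"""Protein-level consequences of DNA variants: frame classification,
residue-level decomposition of in-frame edits, and domain annotation.

Decomposition policy: the codon window touched by each variant group is
re-diffed at residue level with unit costs; ties are broken toward
substitutions over indels and toward the 3'-most indel placement, so a
one-residue deletion inside a repeat run is reported at the highest
residue number.
"""
from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

from .genotyping import DnaVariant, apply_variants
from .seqcore import DomainTable, GeneModel, translate

AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "Ter",
}


@dataclass(frozen=True)
class ProteinChange:
    kind: str  # substitution | deletion | insertion | delins | frameshift | silent
    start_res: int  # 1-based inclusive
    end_res: int
    ref_aa: str
    alt_aa: str
    label: str


@dataclass(frozen=True)
class ConsequenceReport:
    allele_id: str
    frame: str  # in_frame | frameshift | silent
    changes: tuple[ProteinChange, ...]
    domains_hit: tuple[str, ...] = ()
    knockout_candidate: bool = False
    metadata: dict = field(default_factory=dict, compare=False)


def classify_frame(
    variants: Sequence[DnaVariant], model: GeneModel | None = None
) -> str:
    """Frame class from net indel length: frameshift iff net mod 3 != 0.

    With a model attached, alleles whose mutant protein equals wild type
    (no variants, or synonymous-only substitutions) are called silent.
    """
    if not variants:
        return "silent"
    net = sum(v.net for v in variants)
    if net % 3 != 0:
        return "frameshift"
    if model is not None:
        mutant = apply_variants(model.cds.seq, variants)
        if translate(mutant) == translate(model.cds.seq):
            return "silent"
    return "in_frame"


def _make_label(kind: str, start: int, end: int, ref: str, alt: str) -> str:
    if kind == "substitution":
        return f"{ref}{start}{alt}"
    if kind == "deletion":
        if start == end:
            return f"{ref}{start}del"
        return f"{ref[0]}{start}_{ref[-1]}{end}del"
    if kind == "insertion":
        return f"{start}_{end}ins{alt}"
    if kind == "delins":
        if start == end:
            return f"{ref}{start}delins{alt}"
        return f"{ref[0]}{start}_{ref[-1]}{end}delins{alt}"
    if kind == "frameshift":
        return f"{ref}{start}fs"
    return "="


def label_three_letter(change: ProteinChange) -> str:
    """HGVS-style three-letter rendering of a change label."""
    def aa3(s: str) -> str:
        return "".join(AA3.get(c, "Xaa") for c in s)

    k, s, e, r, a = change.kind, change.start_res, change.end_res, change.ref_aa, change.alt_aa
    if k == "substitution":
        return f"p.{aa3(r)}{s}{aa3(a)}"
    if k == "deletion":
        return f"p.{aa3(r[0])}{s}del" if s == e else f"p.{aa3(r[0])}{s}_{aa3(r[-1])}{e}del"
    if k == "insertion":
        return f"p.{s}_{e}ins{aa3(a)}"
    if k == "delins":
        head = f"{aa3(r)}{s}" if s == e else f"{aa3(r[0])}{s}_{aa3(r[-1])}{e}"
        return f"p.{head}delins{aa3(a)}"
    if k == "frameshift":
        return f"p.{aa3(r)}{s}fs"
    return "p.="


def _levenshtein_path(ref: str, alt: str) -> list[tuple[str, int, int]]:
    """Minimal unit-cost edit path as (op, ref_idx, alt_idx) in forward order.

    Backward tie-break prefers up (deletion) > left (insertion) > diagonal,
    which places equal-cost indels at the 3' end of the window.
    """
    n, m = len(ref), len(alt)
    D = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        D[i][0] = i
    for j in range(1, m + 1):
        D[0][j] = j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = D[i - 1][j - 1] + (ref[i - 1] != alt[j - 1])
            dele = D[i - 1][j] + 1
            ins = D[i][j - 1] + 1
            D[i][j] = min(sub, dele, ins)
    ops: list[tuple[str, int, int]] = []
    i, j = n, m
    while i > 0 or j > 0:
        here = D[i][j]
        if i > 0 and D[i - 1][j] + 1 == here:
            ops.append(("del", i - 1, j))
            i -= 1
        elif j > 0 and D[i][j - 1] + 1 == here:
            ops.append(("ins", i, j - 1))
            j -= 1
        else:
            op = "match" if ref[i - 1] == alt[j - 1] else "sub"
            ops.append((op, i - 1, j - 1))
            i -= 1
            j -= 1
    ops.reverse()
    return ops


def _diff_protein_window(
    wt_protein: str, ref_aa: str, alt_aa: str, window_res0: int
) -> list[ProteinChange]:
    """Decompose one residue window diff into ProteinChange records.

    ``window_res0`` is the 0-based residue index of the window start in the
    wild-type protein. A sole pure indel is 3'-shifted through repeat
    context beyond the window; an indel accompanied by other changes stays
    inside the edited codon window (so a compound substitution+deletion is
    reported at the residues the DNA edit actually touched)."""
    # trim common prefix/suffix (non-overlapping)
    pre = 0
    while pre < min(len(ref_aa), len(alt_aa)) and ref_aa[pre] == alt_aa[pre]:
        pre += 1
    suf = 0
    while (
        suf < min(len(ref_aa), len(alt_aa)) - pre
        and ref_aa[len(ref_aa) - 1 - suf] == alt_aa[len(alt_aa) - 1 - suf]
    ):
        suf += 1
    core_ref = ref_aa[pre : len(ref_aa) - suf]
    core_alt = alt_aa[pre : len(alt_aa) - suf]
    base = window_res0 + pre  # 0-based residue of core start
    if not core_ref and not core_alt:
        return []

    ops = _levenshtein_path(core_ref, core_alt)
    # collapse the path into records
    raw: list[tuple[str, int, str, str]] = []  # (kind, ref_idx0, ref_seg, alt_seg)
    k = 0
    while k < len(ops):
        op, i, j = ops[k]
        if op == "match":
            k += 1
            continue
        if op == "sub":
            raw.append(("substitution", i, core_ref[i], core_alt[j]))
            k += 1
            continue
        # gap run: collect contiguous del/ins ops into one (possibly mixed) run
        del_seg: list[str] = []
        ins_seg: list[str] = []
        run_i = i
        while k < len(ops) and ops[k][0] in ("del", "ins"):
            op2, i2, j2 = ops[k]
            if op2 == "del":
                del_seg.append(core_ref[i2])
            else:
                ins_seg.append(core_alt[j2])
            k += 1
        if del_seg and ins_seg:
            raw.append(("delins", run_i, "".join(del_seg), "".join(ins_seg)))
        elif del_seg:
            raw.append(("deletion", run_i, "".join(del_seg), ""))
        else:
            raw.append(("insertion", run_i, "", "".join(ins_seg)))

    window_end0 = window_res0 + len(ref_aa)  # 0-based exclusive window end
    changes: list[ProteinChange] = []
    for idx, (kind, i, ref_seg, alt_seg) in enumerate(raw):
        res0 = base + i  # 0-based residue in wild-type protein
        if kind == "deletion":
            # 3'-shift through repeats, bounded by the next change's position
            limit = base + raw[idx + 1][1] if idx + 1 < len(raw) else len(wt_protein)
            if len(raw) > 1:
                limit = min(limit, window_end0)
            length = len(ref_seg)
            while res0 + length < limit and wt_protein[res0] == wt_protein[res0 + length]:
                res0 += 1
            ref_seg = wt_protein[res0 : res0 + length]
            start, end = res0 + 1, res0 + length
        elif kind == "insertion":
            limit = base + raw[idx + 1][1] if idx + 1 < len(raw) else len(wt_protein)
            if len(raw) > 1:
                limit = min(limit, window_end0)
            while res0 < limit and alt_seg[0] == wt_protein[res0]:
                alt_seg = alt_seg[1:] + wt_protein[res0]
                res0 += 1
            # flanking residues: inserted between res0 and res0+1 (1-based)
            start, end = res0, res0 + 1
        elif kind == "substitution":
            start = end = res0 + 1
        else:  # delins
            start, end = res0 + 1, res0 + len(ref_seg)
        changes.append(
            ProteinChange(
                kind=kind,
                start_res=start,
                end_res=end,
                ref_aa=ref_seg,
                alt_aa=alt_seg,
                label=_make_label(kind, start, end, ref_seg, alt_seg),
            )
        )
    return changes


def _variant_codon_window(v: DnaVariant) -> tuple[int, int]:
    ws = v.cds_start // 3
    if v.ref_allele:
        we = (v.cds_end + 2) // 3
    elif v.cds_start % 3 == 0:
        we = ws  # insertion exactly between codons: empty reference window
    else:
        we = ws + 1
    return ws, we


def _group_variants(variants: Sequence[DnaVariant]) -> list[list[DnaVariant]]:
    """Split variants into independently decomposable groups.

    A group closes once its net length change is a multiple of 3 (local
    frame restored) and the next variant's codon window does not overlap.
    """
    groups: list[list[DnaVariant]] = []
    current: list[DnaVariant] = []
    net = 0
    end_codon = -1
    for v in sorted(variants, key=lambda v: v.cds_start):
        ws, we = _variant_codon_window(v)
        if current and net % 3 == 0 and ws >= end_codon:
            groups.append(current)
            current, net, end_codon = [], 0, -1
        current.append(v)
        net += v.net
        end_codon = max(end_codon, we)
    if current:
        groups.append(current)
    return groups


def protein_consequence(
    model: GeneModel,
    variants: Sequence[DnaVariant],
    allele_id: str = "allele",
    domain_table: DomainTable | None = None,
) -> ConsequenceReport:
    """Decompose an allele's DNA variants into protein-level changes.

    Frameshift alleles report only the first affected residue ("<aa><pos>fs");
    the downstream peptide and new stop position go into metadata. In-frame
    alleles get residue-exact substitution/deletion/insertion records whose
    application to the wild-type protein reproduces the mutant protein.
    """
    wt_cds = model.cds.seq
    wt_protein = model.protein
    for v in variants:
        if not 0 <= v.cds_start <= v.cds_end <= len(wt_cds):
            raise ValueError(f"variant at {v.cds_start} outside CDS")

    mutant_cds = apply_variants(wt_cds, variants)
    net = sum(v.net for v in variants)

    if net % 3 != 0:
        mutant_aa = translate(mutant_cds[: len(mutant_cds) // 3 * 3])
        div = 0
        while (
            div < len(wt_protein)
            and div < len(mutant_aa)
            and wt_protein[div] == mutant_aa[div]
        ):
            div += 1
        res = min(div, len(wt_protein) - 1)
        ref_aa = wt_protein[res]
        change = ProteinChange(
            kind="frameshift",
            start_res=res + 1,
            end_res=res + 1,
            ref_aa=ref_aa,
            alt_aa="",
            label=_make_label("frameshift", res + 1, res + 1, ref_aa, ""),
        )
        stop_at = mutant_aa.find("*", div)
        meta = {
            "fs_peptide": mutant_aa[div : stop_at + 1 if stop_at != -1 else len(mutant_aa)],
            "fs_new_stop_res": stop_at + 1 if stop_at != -1 else None,
        }
        report = ConsequenceReport(
            allele_id=allele_id,
            frame="frameshift",
            changes=(change,),
            knockout_candidate=True,
            metadata=meta,
        )
        return annotate_domains(report, domain_table) if domain_table else report

    mutant_aa_full = translate(mutant_cds)
    wt_aa_full = translate(wt_cds)
    if mutant_aa_full == wt_aa_full:
        report = ConsequenceReport(allele_id=allele_id, frame="silent", changes=())
        return annotate_domains(report, domain_table) if domain_table else report

    changes: list[ProteinChange] = []
    offset = 0
    for group in _group_variants(variants):
        c0 = min(_variant_codon_window(v)[0] for v in group)
        c1 = max(_variant_codon_window(v)[1] for v in group)
        group_net = sum(v.net for v in group)
        ref_nt = wt_cds[c0 * 3 : c1 * 3]
        alt_nt = mutant_cds[c0 * 3 + offset : c1 * 3 + offset + group_net]
        offset += group_net
        ref_window = translate(ref_nt)
        alt_window = translate(alt_nt)
        if ref_window == alt_window:
            continue
        changes.extend(_diff_protein_window(wt_protein + "*", ref_window, alt_window, c0))

    knockout = any("*" in c.alt_aa for c in changes)
    report = ConsequenceReport(
        allele_id=allele_id,
        frame="in_frame",
        changes=tuple(changes),
        knockout_candidate=knockout,
    )
    return annotate_domains(report, domain_table) if domain_table else report


def annotate_domains(report: ConsequenceReport, table: DomainTable) -> ConsequenceReport:
    """Flag domains whose residue range intersects any reported change.

    A frameshift at residue r affects everything downstream, so all domains
    ending at or after r are flagged."""
    hit: list[str] = []
    for name, dstart, dend in table.entries:
        for c in report.changes:
            if c.kind == "frameshift":
                if dend >= c.start_res:
                    hit.append(name)
                    break
            elif c.start_res <= dend and c.end_res >= dstart:
                hit.append(name)
                break
    return replace(report, domains_hit=tuple(hit))


CONSEQUENCE_COLUMNS = [
    "allele_id", "frame", "changes", "domains_hit", "knockout_candidate",
]


def write_consequence_table(reports: Sequence[ConsequenceReport], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(CONSEQUENCE_COLUMNS)
        for r in reports:
            w.writerow([
                r.allele_id,
                r.frame,
                ";".join(c.label for c in r.changes) or ".",
                ";".join(r.domains_hit) or ".",
                int(r.knockout_candidate),
            ])


def reports_to_json(reports: Sequence[ConsequenceReport]) -> str:
    payload = {
        r.allele_id: {
            "frame": r.frame,
            "changes": [
                {
                    "kind": c.kind,
                    "start_res": c.start_res,
                    "end_res": c.end_res,
                    "ref_aa": c.ref_aa,
                    "alt_aa": c.alt_aa,
                    "label": c.label,
                }
                for c in r.changes
            ],
            "domains_hit": list(r.domains_hit),
            "knockout_candidate": r.knockout_candidate,
            "metadata": {k: v for k, v in r.metadata.items()},
        }
        for r in reports
    }
    return json.dumps(payload, indent=2, sort_keys=True)
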