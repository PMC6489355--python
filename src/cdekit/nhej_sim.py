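"""Synthetic Cas9 cut-and-repair outcomes with recorded ground truth.

Event sizes follow truncated geometric laws and deletions are placed to
span the cut; the defaults are invented fixture parameters (no published
repair spectrum backs them) chosen to produce the 1-30 nt event mixture
typical of NHEJ alleles.
"""
from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .consequence import classify_frame
from .genotyping import DnaVariant, apply_variants
from .guide_design import GuideTarget
from .seqcore import GeneModel, NucleotideSequence

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class RepairParams:
    """Parameters of the synthetic repair spectrum (invented defaults)."""

    p_deletion: float = 0.7
    deletion_size_geometric_p: float = 0.3
    insertion_size_geometric_p: float = 0.3
    max_event: int = 30
    seed: int = 0
    #: degenerate laws for tests: force every event to one exact size
    fixed_deletion_size: int | None = None
    fixed_insertion_size: int | None = None

    def __post_init__(self) -> None:
        for name in ("p_deletion", "deletion_size_geometric_p", "insertion_size_geometric_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.max_event < 1:
            raise ValueError("max_event must be >= 1")


@dataclass(frozen=True)
class SimulatedAllele:
    allele_id: str
    guide_id: str
    sequence: NucleotideSequence
    truth: tuple[DnaVariant, ...]
    truth_frame: str


def _truncated_geometric(rng: np.random.Generator, p: float, cap: int) -> int:
    for _ in range(10_000):
        size = int(rng.geometric(p))
        if size <= cap:
            return size
    raise RuntimeError("truncated geometric draw failed to land under cap")


def _one_event(
    ref: str, cut_pos: int, params: RepairParams, rng: np.random.Generator
) -> DnaVariant:
    rejections = 0
    while True:
        if rng.random() < params.p_deletion:
            if params.fixed_deletion_size is not None:
                size = params.fixed_deletion_size
            else:
                size = _truncated_geometric(
                    rng, params.deletion_size_geometric_p, params.max_event
                )
            left = int(rng.integers(0, size + 1))  # deleted bases left of the cut
            start = cut_pos + 1 - left
            if start < 0 or start + size > len(ref):
                rejections += 1
                if rejections == 100:
                    warnings.warn(
                        f"cut at {cut_pos} too close to sequence end; "
                        "still resampling event placement"
                    )
                if rejections >= 10_000:
                    raise RuntimeError(
                        f"no valid event placement at cut {cut_pos} after {rejections} draws"
                    )
                continue
            return DnaVariant("deletion", start, ref[start : start + size], "")
        if params.fixed_insertion_size is not None:
            size = params.fixed_insertion_size
        else:
            size = _truncated_geometric(
                rng, params.insertion_size_geometric_p, params.max_event
            )
        ins = "".join(rng.choice(BASES, size=size))
        return DnaVariant("insertion", cut_pos + 1, "", ins)


def simulate_repair(
    model: GeneModel,
    guide: GuideTarget,
    params: RepairParams,
    n: int,
) -> list[SimulatedAllele]:
    """Draw ``n`` single-cut repair alleles at the guide's cut site.

    Fully reproducible from ``params.seed``; each allele records its truth
    edit and frame class.
    """
    ref = model.cds.seq
    if not 0 <= guide.cut_pos < len(ref):
        raise ValueError(f"cut site {guide.cut_pos} outside model CDS")
    rng = np.random.default_rng(params.seed)
    alleles = []
    for k in range(n):
        truth = _one_event(ref, guide.cut_pos, params, rng)
        seq = apply_variants(ref, [truth])
        alleles.append(
            SimulatedAllele(
                allele_id=f"{guide.guide_id}-sim-{k:04d}",
                guide_id=guide.guide_id,
                sequence=NucleotideSequence(f"{guide.guide_id}-sim-{k:04d}", seq),
                truth=(truth,),
                truth_frame=classify_frame([truth]),
            )
        )
    return alleles


def simulate_ptg_repair(
    model: GeneModel,
    guide_a: GuideTarget,
    guide_b: GuideTarget,
    params: RepairParams,
    n: int,
    p_excision: float = 0.5,
) -> list[SimulatedAllele]:
    """Dual-guide simulation: with probability ``p_excision`` the fragment
    between the two cuts drops out; otherwise the two cuts repair
    independently."""
    ref = model.cds.seq
    lo, hi = sorted((guide_a.cut_pos, guide_b.cut_pos))
    rng = np.random.default_rng(params.seed)
    sub_params = params
    alleles = []
    for k in range(n):
        if rng.random() < p_excision:
            truth: tuple[DnaVariant, ...] = (
                DnaVariant("deletion", lo + 1, ref[lo + 1 : hi + 1], ""),
            )
        else:
            ev_lo = _one_event(ref, lo, sub_params, rng)
            ev_hi = _one_event(ref, hi, sub_params, rng)
            if ev_lo.cds_end >= ev_hi.cds_start:  # collided events: keep one
                truth = (ev_lo,)
            else:
                truth = (ev_lo, ev_hi)
        seq = apply_variants(ref, truth)
        aid = f"{guide_a.guide_id}+{guide_b.guide_id}-sim-{k:04d}"
        alleles.append(
            SimulatedAllele(
                allele_id=aid,
                guide_id=f"{guide_a.guide_id}+{guide_b.guide_id}",
                sequence=NucleotideSequence(aid, seq),
                truth=truth,
                truth_frame=classify_frame(list(truth)),
            )
        )
    return alleles


def in_frame_filter(alleles: Sequence[SimulatedAllele]) -> list[SimulatedAllele]:
    """Keep survivable alleles: the selection pressure removes frameshifts."""
    return [a for a in alleles if a.truth_frame == "in_frame"]


def write_truth_table(alleles: Sequence[SimulatedAllele], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["allele_id", "guide_id", "kind", "cds_start_1based", "ref", "alt", "frame"])
        for a in alleles:
            for v in a.truth:
                w.writerow([
                    a.allele_id, a.guide_id, v.kind, v.cds_start + 1,
                    v.ref_allele or ".", v.alt_allele or ".", a.truth_frame,
                ])


def truth_to_json(alleles: Sequence[SimulatedAllele]) -> str:
    payload = {
        a.allele_id: {
            "guide_id": a.guide_id,
            "frame": a.truth_frame,
            "truth": [
                {
                    "kind": v.kind,
                    "cds_start_1based": v.cds_start + 1,
                    "ref": v.ref_allele,
                    "alt": v.alt_allele,
                }
                for v in a.truth
            ],
        }
        for a in alleles
    }
    return json.dumps(payload, indent=2, sort_keys=True)
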