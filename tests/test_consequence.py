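import random

import pytest

from cdekit import demo
from cdekit.consequence import (
    annotate_domains,
    classify_frame,
    label_three_letter,
    protein_consequence,
)
from cdekit.genotyping import DnaVariant, apply_variants, genotype
from cdekit.seqcore import DomainTable, build_gene_model, translate

from conftest import SENSE_CODONS, random_orf
from oracles import levenshtein_oracle


def apply_protein_changes(wt: str, changes) -> str:
    """Oracle: splice reported residue changes back into the WT protein."""
    edits = []
    for c in changes:
        if c.kind == "substitution":
            edits.append((c.start_res - 1, c.end_res, c.alt_aa))
        elif c.kind == "deletion":
            edits.append((c.start_res - 1, c.end_res, ""))
        elif c.kind == "insertion":
            edits.append((c.start_res, c.start_res, c.alt_aa))
        elif c.kind == "delins":
            edits.append((c.start_res - 1, c.end_res, c.alt_aa))
    out = wt
    for start, end, alt in sorted(edits, reverse=True):
        out = out[:start] + alt + out[end:]
    return out


class TestClassifyFrame:
    def test_three_nt_deletion_in_frame(self):
        assert classify_frame([DnaVariant("deletion", 30, "CAA", "")]) == "in_frame"

    def test_single_nt_deletion_frameshift(self):
        assert classify_frame([DnaVariant("deletion", 30, "C", "")]) == "frameshift"

    def test_compound_net_minus_three_in_frame(self):
        variants = [
            DnaVariant("deletion", 10, "A", ""),
            DnaVariant("deletion", 30, "ACGT", ""),
            DnaVariant("insertion", 60, "", "GG"),
        ]
        # oracle: (-1) + (-4) + (+2) = -3, divisible by 3
        assert classify_frame(variants) == "in_frame"

    def test_no_variants_silent(self):
        assert classify_frame([]) == "silent"

    def test_synonymous_substitution_silent_with_model(self):
        m = build_gene_model("g", cds="ATGCAACAGTAA")
        v = DnaVariant("substitution", 5, "A", "G")  # CAA -> CAG, both Q
        assert classify_frame([v], m) == "silent"
        assert classify_frame([v]) == "in_frame"  # without model: length-based only


@pytest.fixture(scope="module")
def results(demo_model):
    out = {}
    for allele_id, seq, expected in demo.worked_alleles(demo_model):
        variants = genotype(demo_model, seq)
        report = protein_consequence(demo_model, variants, allele_id=allele_id)
        out[allele_id] = (variants, report, expected)
    return out


class TestWorkedExamples:
    """Golden alleles from the published variant set, reproduced end to end."""

    @pytest.mark.parametrize("allele_id", [
        "SGR1", "SGR2", "SGR3", "SGR4", "SGR5", "SGR6", "SGS1",
    ])
    def test_labels_match(self, results, allele_id):
        _, report, expected = results[allele_id]
        assert report.frame == "in_frame"
        assert tuple(c.label for c in report.changes) == expected

    def test_single_q_deletion(self, results):
        variants, report, _ = results["SGR1"]
        assert len(variants) == 1 and len(variants[0].ref_allele) == 3
        (c,) = report.changes
        assert (c.kind, c.start_res, c.ref_aa) == ("deletion", 157, "Q")

    def test_ten_residue_deletion(self, results):
        _, report, _ = results["SGR2"]
        (c,) = report.changes
        assert c.kind == "deletion"
        assert (c.start_res, c.end_res) == (223, 232)
        assert c.ref_aa == "DAPDATPGIG"
        assert c.end_res - c.start_res + 1 == 10

    def test_kk_run_deletion_normalized_to_high_residue(self, results):
        _, report, _ = results["SGR3"]
        (c,) = report.changes
        assert (c.kind, c.start_res, c.ref_aa) == ("deletion", 1050, "K")

    def test_nine_nt_replacement_is_three_substitutions(self, results):
        _, report, _ = results["SGR4"]
        assert [c.kind for c in report.changes] == ["substitution"] * 3
        assert [c.start_res for c in report.changes] == [1049, 1050, 1051]

    def test_compound_substitution_plus_deletion(self, results):
        _, report, _ = results["SGR5"]
        kinds = [(c.kind, c.start_res) for c in report.changes]
        assert kinds == [("substitution", 1048), ("deletion", 1049)]

    def test_fifteen_residue_deletion(self, results):
        _, report, _ = results["SGS1"]
        (c,) = report.changes
        assert c.ref_aa == "LPLMKPEDYQYFGTL"
        assert (c.start_res, c.end_res) == (442, 456)

    def test_in_frame_changes_reproduce_mutant_protein(self, demo_model, results):
        for allele_id, (variants, report, _) in results.items():
            mutant = translate(apply_variants(demo_model.cds.seq, variants))
            mutant = mutant[:-1] if mutant.endswith("*") else mutant
            assert apply_protein_changes(demo_model.protein, report.changes) == mutant


class TestFrameshiftReporting:
    def test_single_nt_deletion_report(self, toy_model):
        ref = toy_model.cds.seq
        v = DnaVariant("deletion", 60, ref[60], "")
        report = protein_consequence(toy_model, [v], allele_id="fs")
        assert report.frame == "frameshift"
        assert report.knockout_candidate
        (c,) = report.changes
        assert c.kind == "frameshift"
        assert c.label.endswith("fs")
        # first affected residue: the edit hits codon 21; divergence cannot
        # start before it
        assert c.start_res >= 21
        assert "fs_peptide" in report.metadata

    def test_nonsense_substitution_flags_knockout(self):
        m = build_gene_model("g", cds="ATGTGGCAGTAA")  # M W Q
        v = DnaVariant("substitution", 3, "TGG", "TGA")  # W -> stop
        report = protein_consequence(m, [v], allele_id="x")
        assert report.frame == "in_frame"
        assert report.knockout_candidate
        assert any("*" in c.alt_aa for c in report.changes)


class TestDecomposition:
    def test_insertion_label(self, toy_model):
        ref = toy_model.cds.seq
        v = DnaVariant("insertion", 30, "", "GATGAT")
        report = protein_consequence(toy_model, [v], allele_id="ins")
        assert report.frame == "in_frame"
        (c,) = report.changes
        assert c.kind == "insertion" and c.alt_aa == "DD"
        assert c.label == "10_11insDD"

    def test_changed_residue_count_is_minimal(self, demo_model):
        # number of changed residues equals the residue-level edit distance
        rng = random.Random(71)
        ref = demo_model.cds.seq
        for _ in range(40):
            codon0 = rng.randrange(20, 1000)
            span = rng.randrange(1, 10)  # up to 30 nt
            keep = rng.randrange(0, span + 1)
            alt = "".join(rng.choice(SENSE_CODONS) for _ in range(keep))
            v = DnaVariant(
                "delins", codon0 * 3, ref[codon0 * 3 : (codon0 + span) * 3], alt
            )
            if v.ref_allele == v.alt_allele:
                continue
            report = protein_consequence(demo_model, [v], allele_id="r")
            if report.frame != "in_frame":
                continue
            mutant = translate(apply_variants(ref, [v]))[:-1]
            reported = sum(
                len(c.ref_aa) if c.kind == "deletion" else
                len(c.alt_aa) if c.kind == "insertion" else
                len(c.ref_aa) + len(c.alt_aa) if c.kind == "delins" else 1
                for c in report.changes
            )
            # edit distance over the affected window == reported changed residues
            lo = codon0 - 1
            hi = codon0 + span + 1
            dist = levenshtein_oracle(
                demo_model.protein[lo:hi], mutant[lo : hi + (len(alt) - span * 3) // 3]
            )
            assert reported == dist

    def test_protein_level_3prime_shift_without_identical_codons(self):
        # K-K run encoded AAA AAG: deleting the AAA codon cannot shift at the
        # DNA level, but the protein report still names the 3' lysine
        cds = "ATG" + "AAA" + "AAG" + "GGT" + "TAA"  # M K K G
        m = build_gene_model("g", cds=cds)
        v = DnaVariant("deletion", 3, "AAA", "")
        report = protein_consequence(m, [v], allele_id="x")
        (c,) = report.changes
        assert (c.kind, c.start_res, c.ref_aa) == ("deletion", 3, "K")


class TestDomains:
    def test_hit_by_interval_intersection(self, demo_model):
        table = DomainTable.from_rows([("HR", 1040, 1080)], demo_model.n_residues)
        v = DnaVariant("deletion", 3 * 1049, "AAG", "")  # K1050 region
        report = protein_consequence(
            demo_model, [v], allele_id="x", domain_table=table
        )
        assert report.domains_hit == ("HR",)

    def test_empty_table_no_hits(self, demo_model):
        v = DnaVariant("deletion", 3 * 1049, "AAG", "")
        report = protein_consequence(demo_model, [v], allele_id="x")
        report = annotate_domains(report, DomainTable.from_rows([]))
        assert report.domains_hit == ()

    def test_miss_outside_interval(self, demo_model):
        table = DomainTable.from_rows([("N", 1, 100)], demo_model.n_residues)
        v = DnaVariant("deletion", 3 * 1049, "AAG", "")
        report = protein_consequence(demo_model, [v], allele_id="x", domain_table=table)
        assert report.domains_hit == ()

    def test_frameshift_hits_all_downstream_domains(self, demo_model):
        table = DomainTable.from_rows(
            [("early", 1, 100), ("late", 1040, 1080)], demo_model.n_residues
        )
        v = DnaVariant("deletion", 600, demo_model.cds.seq[600], "")  # fs ~res 201
        report = protein_consequence(demo_model, [v], allele_id="x", domain_table=table)
        assert report.frame == "frameshift"
        assert report.domains_hit == ("late",)


class TestLabels:
    def test_three_letter_rendering(self, demo_model):
        for allele_id, seq, expected in demo.worked_alleles(demo_model):
            if allele_id != "SGR3":
                continue
            variants = genotype(demo_model, seq)
            report = protein_consequence(demo_model, variants, allele_id=allele_id)
            assert label_three_letter(report.changes[0]) == "p.Lys1050del"
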