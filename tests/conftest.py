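import random

import pytest

from cdekit import demo
from cdekit.seqcore import build_gene_model

from oracles import CODON_TABLE, random_dna

SENSE_CODONS = sorted(c for c, aa in CODON_TABLE.items() if aa != "*")


def random_orf(rng: random.Random, n_codons: int, start_atg: bool = True) -> str:
    codons = [rng.choice(SENSE_CODONS) for _ in range(n_codons)]
    if start_atg:
        codons[0] = "ATG"
    return "".join(codons)


@pytest.fixture(scope="session")
def toy_model():
    """Small 100-residue CDS used across genotyping/consequence tests."""
    rng = random.Random(7)
    cds = random_orf(rng, 100) + "TAA"
    return build_gene_model("toy", cds=cds)


@pytest.fixture(scope="session")
def demo_model():
    """The full-length synthetic reference with pinned residue anchors."""
    return demo.reference_model(seed=1)


@pytest.fixture()
def rng():
    return random.Random(12345)


__all__ = ["random_dna", "random_orf", "SENSE_CODONS"]
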