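"""Independent reference implementations used only as test oracles.

Everything here is deliberately written from first principles, without
importing the code paths it is meant to check.
"""
from __future__ import annotations

import random

# ---------------------------------------------------------------------------
# genetic code, typed out by hand (second, independent implementation)

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate_oracle(cds: str) -> str:
    assert len(cds) % 3 == 0
    return "".join(CODON_TABLE[cds[i : i + 3]] for i in range(0, len(cds), 3))


_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp_oracle(seq: str) -> str:
    return "".join(_RC[c] for c in reversed(seq))


# ---------------------------------------------------------------------------
# guide enumeration: literal per-offset scan (no regex, no shared helpers)

def scan_guides_oracle(seq: str, guide_len: int = 20) -> list[tuple[int, str, str, str]]:
    """All (start, strand, protospacer, pam) NGG hits on both strands.

    ``start`` is the plus-strand coordinate of the leftmost protospacer
    base, matching the library convention.
    """
    hits = []
    n = len(seq)
    for i in range(n):
        # plus: protospacer at [i, i+guide_len), PAM = N G G right after
        if i + guide_len + 3 <= n:
            pam = seq[i + guide_len : i + guide_len + 3]
            if pam[1] == "G" and pam[2] == "G":
                hits.append((i, "+", seq[i : i + guide_len], pam))
        # minus: plus-strand CCN at [i-3, i), protospacer footprint [i, i+guide_len)
        if i - 3 >= 0 and i + guide_len <= n:
            left = seq[i - 3 : i]
            if left[0] == "C" and left[1] == "C":
                hits.append(
                    (i, "-", revcomp_oracle(seq[i : i + guide_len]), revcomp_oracle(left))
                )
    hits.sort(key=lambda h: (h[0], 0 if h[1] == "+" else 1))
    return hits


# ---------------------------------------------------------------------------
# alignment oracles

def affine_score_bruteforce(
    ref: str, qry: str, match: int, mismatch: int, gap_open: int, gap_extend: int
) -> int:
    """Optimal affine-gap global score by exhaustive path enumeration.

    Plain recursion over every alignment path (no memoisation); only
    usable for tiny sequences. Gap convention: opening charges
    gap_open + gap_extend.
    """

    best = [-(10**9)]

    def walk(i: int, j: int, prev: str, acc: int) -> None:
        if i == len(ref) and j == len(qry):
            best[0] = max(best[0], acc)
            return
        if i < len(ref) and j < len(qry):
            s = match if ref[i] == qry[j] else mismatch
            walk(i + 1, j + 1, "d", acc + s)
        if i < len(ref):
            cost = gap_extend if prev == "u" else gap_open + gap_extend
            walk(i + 1, j, "u", acc + cost)
        if j < len(qry):
            cost = gap_extend if prev == "l" else gap_open + gap_extend
            walk(i, j + 1, "l", acc + cost)

    walk(0, 0, "", 0)
    return best[0]


def affine_score_dp(
    ref: str, qry: str, match: int, mismatch: int, gap_open: int, gap_extend: int
) -> int:
    """Independent plain-Python three-state DP (score only)."""
    NEG = -(10**9)
    n, m = len(ref), len(qry)
    M = [NEG] * (m + 1)
    X = [NEG] * (m + 1)
    Y = [NEG] * (m + 1)
    M[0] = 0
    for j in range(1, m + 1):
        Y[j] = gap_open + j * gap_extend
    for i in range(1, n + 1):
        dM, dX, dY = M[:], X[:], Y[:]
        M = [NEG] * (m + 1)
        X = [NEG] * (m + 1)
        Y = [NEG] * (m + 1)
        X[0] = gap_open + i * gap_extend
        for j in range(1, m + 1):
            s = match if ref[i - 1] == qry[j - 1] else mismatch
            M[j] = max(dM[j - 1], dX[j - 1], dY[j - 1]) + s
            X[j] = max(dM[j] + gap_open + gap_extend, dX[j] + gap_extend)
            Y[j] = max(M[j - 1] + gap_open + gap_extend, Y[j - 1] + gap_extend)
    return max(M[m], X[m], Y[m])


def levenshtein_oracle(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
        prev = cur
    return prev[-1]


# ---------------------------------------------------------------------------
# geometric law helpers

def truncated_geometric_pmf(p: float, cap: int) -> list[float]:
    """pmf over sizes 1..cap of a geometric(p) conditioned on <= cap."""
    raw = [(1 - p) ** (k - 1) * p for k in range(1, cap + 1)]
    total = sum(raw)
    return [x / total for x in raw]


def inframe_mass(p: float, cap: int) -> float:
    """P(size is a multiple of 3) under the truncated geometric law."""
    pmf = truncated_geometric_pmf(p, cap)
    return sum(pmf[k - 1] for k in range(1, cap + 1) if k % 3 == 0)


def truncated_geometric_mean(p: float, cap: int) -> float:
    pmf = truncated_geometric_pmf(p, cap)
    return sum(k * pmf[k - 1] for k in range(1, cap + 1))


def random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))
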