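"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by the most direct method possible
(exhaustive scans, textbook dynamic programming) and share no code with
the implementation paths they check.
"""

from __future__ import annotations

import numpy as np

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

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
STOPS = {"TAA", "TAG", "TGA"}


def revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def translate_codons(s: str) -> str:
    out = []
    for i in range(0, len(s) - len(s) % 3, 3):
        codon = s[i : i + 3]
        out.append(CODON_TABLE.get(codon, "X"))
    return "".join(out)


def brute_force_orfs(seq: str, min_len_nt: int, both_strands: bool = True):
    """Every ATG tested against its first in-frame stop, all six frames.

    Returns a set of (start, end, strand) triples in forward coordinates
    (half-open), mirroring the contract of the ORF finder under test.
    """
    n = len(seq)
    found = set()
    strands = ("+", "-") if both_strands else ("+",)
    for strand in strands:
        s = seq if strand == "+" else revcomp(seq)
        for i in range(n - 2):
            if s[i : i + 3] != "ATG":
                continue
            j = i + 3
            while j + 3 <= n:
                codon = s[j : j + 3]
                if codon in STOPS:
                    if j + 3 - i >= min_len_nt:
                        if strand == "+":
                            found.add((i, j + 3, "+"))
                        else:
                            found.add((n - (j + 3), n - i, "-"))
                    break
                j += 3
    return found


def brute_force_motifs(seq: str, classes: list[set[str]]) -> list[int]:
    """0-based start positions where every class matches, by direct scan."""
    k = len(classes)
    return [
        i
        for i in range(len(seq) - k + 1)
        if all(seq[i + j] in classes[j] for j in range(k))
    ]


def gotoh_local_score(
    q: str,
    t: str,
    matrix,
    open_gap: float = -11.0,
    extend_gap: float = -1.0,
) -> float:
    """Exhaustive Smith-Waterman with affine gaps (Gotoh, full DP).

    A gap of length L costs ``-(|open| + (L-1)|extend|)``, matching the
    convention where the opening column already pays the open score.
    """
    n, m = len(q), len(t)
    NEG = -1e9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in query (consume t)
    F = np.full((n + 1, m + 1), NEG)  # gap in target (consume q)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + open_gap, E[i][j - 1] + extend_gap)
            F[i][j] = max(H[i - 1][j] + open_gap, F[i - 1][j] + extend_gap)
            s = matrix[q[i - 1], t[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def levenshtein(a: str, b: str) -> int:
    """Plain quadratic edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(
                min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb))
            )
        prev = cur
    return prev[-1]


def infix_edit_distance(q: str, t: str) -> int:
    """Edit distance of q against the best-matching substring of t."""
    prev = [0] * (len(t) + 1)  # free leading gaps in target
    for i, ca in enumerate(q, 1):
        cur = [i]
        for j, cb in enumerate(t, 1):
            cur.append(
                min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb))
            )
        prev = cur
    return min(prev)
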