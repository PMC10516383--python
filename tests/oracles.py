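"""Independent oracles used by the test-suite (and the acceptance script).

These deliberately re-derive results by brute force or textbook dynamic
programming, sharing no code with the package's implementation paths.
"""

from __future__ import annotations

import numpy as np

NEG = -1e9

# standard-code codon table, written out so translation checks do not share
# Biopython with the implementation
_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate_oracle(nt: str) -> str:
    return "".join(_CODON_TABLE[nt[i:i + 3]] for i in range(0, len(nt) - len(nt) % 3, 3))


def revcomp_oracle(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def gotoh_identity(a: str, b: str, match: int = 1, mismatch: int = -2,
                   gap_open: int = 7, gap_extend: int = 1) -> float:
    """Percent identity of the optimal global affine-gap alignment of a vs b.

    Plain Gotoh three-matrix DP with full traceback; identity = match columns
    over all alignment columns (each gap column counts once). A gap of length
    k costs gap_open + (k-1) * gap_extend... here open covers the first base
    at -(gap_open) and each further base -(gap_extend), i.e. cost(k) =
    gap_open + (k-1)*gap_extend, matching open 6+1 convention when
    gap_open=7.
    """
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (a consumed)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (b consumed)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if ai == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend)
            Y[i, j] = max(M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend)
    i, j = n, m
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    matches = columns = 0
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            matches += a[i - 1] == b[j - 1]
            columns += 1
            prev = int(np.argmax([M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]))
            i, j, state = i - 1, j - 1, prev
        elif state == 1 and i > 0:
            columns += 1
            if X[i, j] == M[i - 1, j] - gap_open:
                state = 0
            i -= 1
        elif state == 2 and j > 0:
            columns += 1
            if Y[i, j] == M[i, j - 1] - gap_open:
                state = 0
            j -= 1
        elif i > 0:
            columns += 1
            i -= 1
            state = 0
        else:
            columns += 1
            j -= 1
            state = 0
    return 100.0 * matches / columns


def brute_force_clusters(offsets: list[int], window: int, min_support: int
                         ) -> list[tuple[int, int]]:
    """Single-linkage clustering of 1-D breakpoints by exhaustive chaining.

    Returns (modal_breakpoint, size) per surviving cluster, modal ties to the
    smallest offset.
    """
    remaining = sorted(offsets)
    clusters: list[list[int]] = []
    while remaining:
        seed_off = remaining.pop(0)
        members = [seed_off]
        changed = True
        while changed:
            changed = False
            for off in list(remaining):
                if any(abs(off - x) <= window for x in members):
                    members.append(off)
                    remaining.remove(off)
                    changed = True
        clusters.append(members)
    out = []
    for members in clusters:
        if len(members) < min_support:
            continue
        counts = {}
        for x in members:
            counts[x] = counts.get(x, 0) + 1
        modal = min(counts, key=lambda k: (-counts[k], k))
        out.append((modal, len(members)))
    return sorted(out)


def binomial_99_interval(n: int, p: float) -> tuple[int, int]:
    """Central 99% interval of Binomial(n, p)."""
    from scipy.stats import binom
    return int(binom.ppf(0.005, n, p)), int(binom.ppf(0.995, n, p))
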