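"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths (and libraries) they validate:
naive substring scanning, dictionary-based k-mer enumeration, an
explicit 64-entry codon table, and a Gotoh-style dynamic program for
semi-global alignment scores.
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


# NCBI standard genetic code, codons enumerated in TCAG order.
_TCAG = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
CODON_TABLE = {
    a + b + c: _AA[16 * i + 4 * j + k]
    for i, a in enumerate(_TCAG)
    for j, b in enumerate(_TCAG)
    for k, c in enumerate(_TCAG)
}


def naive_translate(cds: str) -> str:
    assert len(cds) % 3 == 0
    return "".join(CODON_TABLE[cds[i : i + 3]] for i in range(0, len(cds), 3))


def naive_scan(contig_seq: str, signatures: dict[str, str]):
    """Every exact occurrence of every signature, testing each offset."""
    hits = []
    for sig_id, sig in signatures.items():
        m = len(sig)
        rc = naive_revcomp(sig)
        for start in range(len(contig_seq) - m + 1):
            window = contig_seq[start : start + m]
            if window == sig:
                hits.append((sig_id, "+", start, start + m))
            if window == rc:
                hits.append((sig_id, "-", start, start + m))
    return sorted(hits, key=lambda h: (h[2], h[0], h[1]))


def naive_canonical_kmers(seqs: list[str], k: int) -> dict[str, int]:
    """Canonical k-mer counts by direct enumeration; N windows skipped."""
    counts: dict[str, int] = {}
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            canon = min(kmer, naive_revcomp(kmer))
            counts[canon] = counts.get(canon, 0) + 1
    return counts


def semiglobal_score(
    a: str,
    b: str,
    match: float = 2,
    mismatch: float = -1,
    gap_open: float = -5,
    gap_extend: float = -1,
) -> float:
    """Optimal semi-global affine-gap score with free end gaps (Gotoh).

    Opening a gap costs ``gap_open`` for its first residue and
    ``gap_extend`` per additional residue.  End gaps in either sequence
    are free.
    """
    neg = float("-inf")
    n, m = len(a), len(b)
    # M: a[i] aligned to b[j]; X: gap in b (a residue unmatched);
    # Y: gap in a.  Internal gap scores only; end gaps handled by the
    # free initialization row/column and the final max over borders.
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]
    Y = [[neg] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        M[i][0] = 0.0  # free leading gap in b
    for j in range(1, m + 1):
        M[0][j] = 0.0  # free leading gap in a
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend)
    best = neg
    for i in range(n + 1):  # free trailing gap in b
        best = max(best, M[i][m], X[i][m], Y[i][m])
    for j in range(m + 1):  # free trailing gap in a
        best = max(best, M[n][j], X[n][j], Y[n][j])
    return best
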