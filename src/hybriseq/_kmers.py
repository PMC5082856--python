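"""Bit-packed k-mer primitives shared by the assembler and quantifier.

k-mers are encoded 2 bits per base (A=0, C=1, G=2, T=3) into uint64,
which bounds k at 31; the pipeline uses odd k in [15, 31] so that no
k-mer is its own reverse complement.  Counting is strand-insensitive via
canonical k-mers (lexicographic minimum of a k-mer and its reverse
complement, which coincides with the numeric minimum in this encoding).
Windows containing any non-ACGT base are skipped.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

_BASES = "ACGT"

_M2 = np.uint64(0x3333333333333333)
_M4 = np.uint64(0x0F0F0F0F0F0F0F0F)
_M8 = np.uint64(0x00FF00FF00FF00FF)
_M16 = np.uint64(0x0000FFFF0000FFFF)
_FULL = np.uint64(0xFFFFFFFFFFFFFFFF)


def kmer_mask(k: int) -> np.uint64:
    return np.uint64((1 << (2 * k)) - 1)


def encode_kmer(seq: str) -> int:
    """Encode an ACGT string (len <= 31) as a 2-bit packed integer."""
    val = 0
    for ch in seq:
        val = (val << 2) | _BASES.index(ch)
    return val


def decode_kmer(val: int, k: int) -> str:
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append(_BASES[(val >> shift) & 3])
    return "".join(out)


def revcomp_kmers(kmers: np.ndarray, k: int) -> np.ndarray:
    """Vectorized reverse complement of packed k-mers."""
    x = kmers.astype(np.uint64) ^ _FULL  # complement: base -> 3 - base
    x = ((x >> np.uint64(2)) & _M2) | ((x & _M2) << np.uint64(2))
    x = ((x >> np.uint64(4)) & _M4) | ((x & _M4) << np.uint64(4))
    x = ((x >> np.uint64(8)) & _M8) | ((x & _M8) << np.uint64(8))
    x = ((x >> np.uint64(16)) & _M16) | ((x & _M16) << np.uint64(16))
    x = (x >> np.uint64(32)) | (x << np.uint64(32))
    return x >> np.uint64(64 - 2 * k)


def _code_matrix(seqs: Sequence[str]) -> np.ndarray:
    """Byte-encode equal-length sequences into an (n, L) uint8 code matrix."""
    data = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return _CODE[data].reshape(len(seqs), -1)


def _group_kmers(codes: np.ndarray, k: int) -> np.ndarray:
    """Canonical k-mer occurrences for an (n, L) code matrix (1D output)."""
    n, length = codes.shape
    if length < k:
        return np.empty(0, dtype=np.uint64)
    valid = codes < 4
    fwd_codes = np.where(valid, codes, 0).astype(np.uint64)
    rev_codes = np.where(valid, 3 - codes, 0).astype(np.uint64)[:, ::-1]
    mask = kmer_mask(k)
    two = np.uint64(2)

    def rolling(c: np.ndarray) -> np.ndarray:
        acc = np.zeros(n, dtype=np.uint64)
        cols = []
        for j in range(length):
            acc = ((acc << two) | c[:, j]) & mask
            if j >= k - 1:
                cols.append(acc.copy())
        return np.stack(cols, axis=1)

    fwd = rolling(fwd_codes)
    rev = rolling(rev_codes)[:, ::-1]  # align window i of rc to fwd window i
    bad = np.cumsum(~valid, axis=1, dtype=np.int32)
    bad = np.concatenate([np.zeros((n, 1), dtype=np.int32), bad], axis=1)
    ok = (bad[:, k:] - bad[:, : length - k + 1]) == 0
    return np.minimum(fwd, rev)[ok]


def canonical_kmer_counts(
    seqs: Iterable[str], k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Count canonical k-mers over all sequences.

    Returns (sorted unique canonical k-mers as uint64, occurrence counts).
    """
    by_len: dict[int, list[str]] = {}
    for s in seqs:
        by_len.setdefault(len(s), []).append(s)
    chunks = [
        _group_kmers(_code_matrix(group), k)
        for group in by_len.values()
    ]
    if not chunks:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    occurrences = np.concatenate(chunks)
    if occurrences.size == 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    kmers, counts = np.unique(occurrences, return_counts=True)
    return kmers, counts.astype(np.int64)


def canonical_kmer_rows(
    seqs: Sequence[str], k: int
) -> list[np.ndarray]:
    """Per-sequence arrays of canonical k-mer occurrences.

    Sequences may have mixed lengths; those shorter than k yield empty
    arrays.  Batched internally by length for speed.
    """
    by_len: dict[int, tuple[list[int], list[str]]] = {}
    for idx, s in enumerate(seqs):
        by_len.setdefault(len(s), ([], []))[0].append(idx)
        by_len[len(s)][1].append(s)
    rows: list[np.ndarray] = [np.empty(0, dtype=np.uint64)] * len(seqs)
    for length, (indices, group) in by_len.items():
        if length < k:
            continue
        codes = _code_matrix(group)
        n = len(group)
        valid = codes < 4
        fwd_codes = np.where(valid, codes, 0).astype(np.uint64)
        rev_codes = np.where(valid, 3 - codes, 0).astype(np.uint64)[:, ::-1]
        mask = kmer_mask(k)
        two = np.uint64(2)

        def rolling(c: np.ndarray) -> np.ndarray:
            acc = np.zeros(n, dtype=np.uint64)
            cols = []
            for j in range(length):
                acc = ((acc << two) | c[:, j]) & mask
                if j >= k - 1:
                    cols.append(acc.copy())
            return np.stack(cols, axis=1)

        canon = np.minimum(rolling(fwd_codes), rolling(rev_codes)[:, ::-1])
        bad = np.cumsum(~valid, axis=1, dtype=np.int32)
        bad = np.concatenate([np.zeros((n, 1), dtype=np.int32), bad], axis=1)
        ok = (bad[:, k:] - bad[:, : length - k + 1]) == 0
        for row, i in enumerate(indices):
            rows[i] = canon[row][ok[row]]
    return rows
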