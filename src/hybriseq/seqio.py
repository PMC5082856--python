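"""Sequence records, paired reads, and FASTA/FASTQ input/output.

All nucleotide sequences are handled in DNA space over {A,C,G,T,N},
uppercased on read.  FASTQ qualities are Phred+33 (modern Illumina);
offset-64 files are rejected.  Gzipped input is detected by magic bytes.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from itertools import zip_longest
from typing import Iterable, Iterator

from Bio.Seq import Seq

from .errors import (
    AlphabetError,
    FastaParseError,
    FastqPairingError,
    FastqParseError,
    FrameError,
    TranslationError,
)

NUCLEOTIDES = frozenset("ACGTN")
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY*")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class SequenceRecord:
    """A named nucleotide or protein sequence."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadPair:
    """A paired-end read: two mates with per-base Phred+33 qualities."""

    id: str
    seq1: str
    seq2: str
    qual1: str = ""
    qual2: str = ""

    def __post_init__(self) -> None:
        if self.qual1 and len(self.qual1) != len(self.seq1):
            raise ValueError(f"pair {self.id!r}: mate1 quality length mismatch")
        if self.qual2 and len(self.qual2) != len(self.seq2):
            raise ValueError(f"pair {self.id!r}: mate2 quality length mismatch")


def _open_text(path) -> io.TextIOWrapper:
    """Open a possibly gzipped text file, sniffing the magic bytes."""
    raw = open(path, "rb")
    magic = raw.read(2)
    raw.seek(0)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw), encoding="ascii")
    return io.TextIOWrapper(raw, encoding="ascii")


def validate_nucleotides(seq: str, context: str = "sequence") -> str:
    """Uppercase ``seq`` and check it is DNA over {A,C,G,T,N}."""
    seq = seq.upper()
    bad = set(seq) - NUCLEOTIDES
    if bad:
        raise AlphabetError(
            f"{context}: invalid nucleotide characters {sorted(bad)!r} "
            "(expected A/C/G/T/N; RNA 'U' is not accepted)"
        )
    return seq


def read_fasta(path) -> list[SequenceRecord]:
    """Parse a (possibly gzipped) FASTA file into SequenceRecords.

    Sequences are uppercased and line breaks removed.  Raises
    FastaParseError naming the offending line for malformed input.
    """
    records: list[SequenceRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []
    seen: set[str] = set()

    def flush(line_no: int) -> None:
        nonlocal header, chunks
        if header is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise FastaParseError(
                f"{path}: empty sequence for record starting at line {header_line}"
            )
        rid, _, desc = header.partition(" ")
        if not rid:
            raise FastaParseError(f"{path}: empty header at line {header_line}")
        if rid in seen:
            raise FastaParseError(f"{path}: duplicate record id {rid!r}")
        seen.add(rid)
        records.append(SequenceRecord(id=rid, sequence=seq, description=desc))
        header, chunks = None, []

    line_no = 0
    with _open_text(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith(">"):
                flush(line_no)
                header = line[1:].strip()
                header_line = line_no
            else:
                if header is None:
                    raise FastaParseError(
                        f"{path}: sequence data before any header at line {line_no}"
                    )
                chunks.append(line.strip())
        flush(line_no + 1 if records or header else 1)
    return records


def write_fasta(records: Iterable[SequenceRecord], path, line_width: int = 70) -> None:
    """Write records as wrapped FASTA; round-trips through read_fasta."""
    with open(path, "w") as fh:
        for rec in records:
            head = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{head}\n")
            for i in range(0, len(rec.sequence), line_width):
                fh.write(rec.sequence[i : i + line_width] + "\n")


def _iter_fastq(path) -> Iterator[tuple[str, str, str]]:
    with _open_text(path) as fh:
        while True:
            head = fh.readline()
            if not head:
                return
            head = head.rstrip()
            if not head.startswith("@"):
                raise FastqParseError(f"{path}: expected '@' header, got {head!r}")
            seq = fh.readline().rstrip()
            plus = fh.readline().rstrip()
            qual = fh.readline().rstrip()
            if not qual and not seq:
                raise FastqParseError(f"{path}: truncated record {head!r}")
            if not plus.startswith("+"):
                raise FastqParseError(f"{path}: missing '+' separator after {head!r}")
            if len(seq) != len(qual):
                raise FastqParseError(
                    f"{path}: sequence/quality length mismatch for {head!r}"
                )
            # Phred+64 sanity check: offset-33 qualities of modern data
            # always contain characters below 'A' (ASCII < 64).
            if qual and min(qual) >= "K" and max(qual) > "J":
                raise FastqParseError(
                    f"{path}: qualities look Phred+64 encoded for {head!r}; "
                    "only Phred+33 is supported"
                )
            yield head[1:].split()[0], seq.upper(), qual


def read_fastq_pairs(path1, path2) -> list[ReadPair]:
    """Read two mate FASTQ files into ReadPairs, matched positionally."""
    pairs: list[ReadPair] = []
    it1, it2 = _iter_fastq(path1), _iter_fastq(path2)
    for r1, r2 in zip_longest(it1, it2):
        if r1 is None or r2 is None:
            raise FastqPairingError(
                f"{path1} and {path2} have different record counts "
                f"(extra records in the {'mate2' if r1 is None else 'mate1'} file)"
            )
        id1, seq1, q1 = r1
        _, seq2, q2 = r2
        pairs.append(ReadPair(id=id1, seq1=seq1, seq2=seq2, qual1=q1, qual2=q2))
    return pairs


def write_fastq_pairs(pairs: Iterable[ReadPair], path1, path2, compress=None) -> None:
    """Write pairs as two FASTQ files; gzip if paths end in .gz."""

    def opener(path):
        p = str(path)
        use_gz = compress if compress is not None else p.endswith(".gz")
        if use_gz:
            # mtime=0 keeps rewrites of identical data byte-identical
            return io.TextIOWrapper(
                gzip.GzipFile(p, "wb", mtime=0), encoding="ascii"
            )
        return open(p, "w")

    with opener(path1) as f1, opener(path2) as f2:
        for pair in pairs:
            q1 = pair.qual1 or "I" * len(pair.seq1)
            q2 = pair.qual2 or "I" * len(pair.seq2)
            f1.write(f"@{pair.id}/1\n{pair.seq1}\n+\n{q1}\n")
            f2.write(f"@{pair.id}/2\n{pair.seq2}\n+\n{q2}\n")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string; N maps to N."""
    seq = validate_nucleotides(seq, "reverse_complement")
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str, trim_at_stop: bool = False) -> str:
    """Translate an in-frame DNA coding sequence with the standard code.

    Stop codons become '*'.  With ``trim_at_stop`` translation is cut at
    the first stop.  Length must be divisible by 3 and codons may not
    contain N or other ambiguity codes.
    """
    cds = validate_nucleotides(cds, "translate")
    if len(cds) % 3 != 0:
        raise FrameError(f"CDS length {len(cds)} is not divisible by 3")
    if "N" in cds:
        pos = cds.index("N")
        raise TranslationError(f"codon at nt {pos - pos % 3} contains N")
    protein = str(Seq(cds).translate())
    if trim_at_stop and "*" in protein:
        protein = protein[: protein.index("*")]
    return protein
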