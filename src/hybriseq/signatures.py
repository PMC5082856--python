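"""Constant-region signature catalogs and exact two-strand contig scanning.

A *signature* is a short (20-30 bp) nucleotide string unique to one
immunoglobulin constant-region gene.  A contig containing a signature is
thereby anchored to that chain and subclass: the heavy-chain signatures
distinguish the IgG subclasses (IgG1, IgG2a, ...), and the light-chain
signatures distinguish kappa from the lambda types.  Matching is exact
and performed on both strands, because de novo contigs have arbitrary
orientation; sequencing errors are expected to be absorbed by the
assembly consensus rather than by fuzzy matching.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Mapping

from .errors import CatalogError
from .seqio import SequenceRecord, reverse_complement, validate_nucleotides

HEAVY = "heavy"
KAPPA = "kappa"
LAMBDA = "lambda"
AMBIGUOUS = "ambiguous"
NONE = "none"

CHAIN_FAMILIES = (HEAVY, KAPPA, LAMBDA)


@dataclass(frozen=True)
class Signature:
    """A constant-region anchor sequence for one chain/subclass."""

    id: str
    species: str
    chain: str
    subclass: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SignatureHit:
    """An exact signature occurrence on a contig.

    ``start``/``end`` are 0-based half-open coordinates on the forward
    strand of the contig; strand '-' means the reverse complement of the
    contig substring equals the signature.
    """

    signature_id: str
    contig_id: str
    strand: str
    start: int
    end: int


# Rat heavy-chain (IgG subclass) and light-chain constant-region signatures.
_RAT = [
    ("rat-Ighg1", HEAVY, "IgG1", "TGTGCCCAGAAACTGTGGAG"),
    ("rat-Ighg2a", HEAVY, "IgG2a", "GCCAAGGGAATGCAATCCTTG"),
    ("rat-Ighg2b", HEAVY, "IgG2b", "CAAACAACAGCCCCATCTGTCTAT"),
    ("rat-Ighg2c", HEAVY, "IgG2c", "AGAACAACAGCCCCATCTGTCTA"),
    ("rat-Igl1", LAMBDA, "lambda1", "CAACCCAAGGCTACGCCCTC"),
    ("rat-Igl2", LAMBDA, "lambda2", "CAGCCCAAGTCCACTCCCAC"),
    ("rat-Igk", KAPPA, "kappa", "ACCAACTGTATCTATCTTCCCACCATCCAC"),
]

# Mouse catalog: five IgG subclasses, four lambda types, kappa.
_MOUSE = [
    ("mouse-Ighg1", HEAVY, "IgG1", "CCAAAACGACACCCCCATCT"),
    ("mouse-Ighg2a", HEAVY, "IgG2a", "GTGTGTGGAGATACAACTGGCT"),
    ("mouse-Ighg2b", HEAVY, "IgG2b", "CCAAAACAACACCCCCATCAG"),
    ("mouse-Ighg2c", HEAVY, "IgG2c", "GTGTGGAGGTACAACTGGCTCCT"),
    ("mouse-Ighg3", HEAVY, "IgG3", "CTACAACAACAGCCCCATCTG"),
    ("mouse-Igl1", LAMBDA, "lambda1", "GCCAGCCCAAGTCTTCGCCAT"),
    ("mouse-Igl2", LAMBDA, "lambda2", "GTCAGCCCAAGTCCACTCCCACTC"),
    ("mouse-Igl3", LAMBDA, "lambda3", "GTCAGCCCAAGTCCACTCCCACAC"),
    ("mouse-Igl4", LAMBDA, "lambda4", "GCCAACCCAAGGCTACACCCTCAG"),
    ("mouse-Igk", KAPPA, "kappa", "GGGCTGATGCTGCACCAACTG"),
]

_BUILTIN = {"rat": _RAT, "mouse": _MOUSE}


def _validate_catalog(signatures: Iterable[Signature]) -> dict[str, Signature]:
    catalog: dict[str, Signature] = {}
    for sig in signatures:
        if sig.id in catalog:
            raise CatalogError(f"duplicate signature id {sig.id!r}")
        if not 20 <= len(sig.sequence) <= 30:
            raise CatalogError(
                f"signature {sig.id!r} has length {len(sig.sequence)}, "
                "expected 20-30 bp"
            )
        if set(sig.sequence) - set("ACGT"):
            raise CatalogError(f"signature {sig.id!r} is not over A/C/G/T")
        if sig.chain not in CHAIN_FAMILIES:
            raise CatalogError(
                f"signature {sig.id!r}: chain must be one of {CHAIN_FAMILIES}"
            )
        catalog[sig.id] = sig
    for a in catalog.values():
        for b in catalog.values():
            if a.id != b.id and a.sequence in b.sequence:
                raise CatalogError(
                    f"signature {a.id!r} is a substring of {b.id!r}; "
                    "anchors must be mutually non-nested"
                )
    return catalog


def builtin_catalog(species: str) -> dict[str, Signature]:
    """Built-in signature catalog for ``species`` ('rat' or 'mouse')."""
    if species not in _BUILTIN:
        raise CatalogError(
            f"unknown species {species!r}; built-in catalogs: {sorted(_BUILTIN)}"
        )
    return _validate_catalog(
        Signature(id=i, species=species, chain=c, subclass=s, sequence=q)
        for i, c, s, q in _BUILTIN[species]
    )


def load_catalog_tsv(path) -> dict[str, Signature]:
    """Load a user catalog from TSV (id, species, chain, subclass, sequence)."""
    required = {"id", "species", "chain", "subclass", "sequence"}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise CatalogError(
                f"{path}: expected tab-separated columns {sorted(required)}"
            )
        sigs = [
            Signature(
                id=row["id"],
                species=row["species"],
                chain=row["chain"],
                subclass=row["subclass"],
                sequence=row["sequence"].upper(),
            )
            for row in reader
        ]
    if not sigs:
        raise CatalogError(f"{path}: catalog is empty")
    return _validate_catalog(sigs)


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    start = 0
    while True:
        idx = haystack.find(needle, start)
        if idx == -1:
            return
        yield idx
        start = idx + 1


def scan_contig(
    contig: SequenceRecord, catalog: Mapping[str, Signature]
) -> list[SignatureHit]:
    """All exact signature occurrences on either strand, sorted by start."""
    seq = validate_nucleotides(contig.sequence, f"contig {contig.id!r}")
    hits: list[SignatureHit] = []
    n = len(seq)
    for sig in catalog.values():
        for pos in _find_all(seq, sig.sequence):
            hits.append(
                SignatureHit(sig.id, contig.id, "+", pos, pos + len(sig.sequence))
            )
        rc = reverse_complement(sig.sequence)
        for pos in _find_all(seq, rc):
            hits.append(
                SignatureHit(sig.id, contig.id, "-", pos, pos + len(sig.sequence))
            )
    hits.sort(key=lambda h: (h.start, h.signature_id, h.strand))
    return hits


def classify_chain(
    hits: Iterable[SignatureHit], catalog: Mapping[str, Signature]
) -> str:
    """Chain family of a contig's hits: heavy/kappa/lambda/ambiguous/none."""
    families = {catalog[h.signature_id].chain for h in hits}
    if not families:
        return NONE
    if len(families) > 1:
        return AMBIGUOUS
    return families.pop()
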