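"""Immunoglobulin CDS extraction from assembled contigs.

The core selection logic: a contig is a candidate immunoglobulin
transcript if it (a) contains a constant-region signature of exactly one
chain family and (b) is long enough to hold a full-length chain (heavy
contigs strictly > 1200 nt, light strictly > 600 nt).  From each
candidate the coding sequence is recovered as the longest open reading
frame (ATG through stop, any forward frame after orienting the contig by
its signature) that contains the signature and encodes at least 400
(heavy) or 200 (light) amino acids — the minimum sizes of complete
chains.  The anchoring signature also determines the isotype/subclass.
An optional semi-global alignment against a known constant-region
protein delineates the variable (V) and constant (C) regions.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import Align

from .assembler import Contig
from .errors import NoValidOrfError, ReportError
from .seqio import SequenceRecord, reverse_complement, translate, write_fasta
from .signatures import (
    AMBIGUOUS,
    HEAVY,
    NONE,
    Signature,
    SignatureHit,
    classify_chain,
    scan_contig,
)

logger = logging.getLogger(__name__)

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class FilterParams:
    """Length gates for candidate contigs and their open reading frames.

    Contig thresholds are strict inequalities; the amino-acid floors are
    the minimum plausible sizes of complete heavy and light chains.
    """

    min_len_heavy: int = 1200
    min_len_light: int = 600
    min_aa_heavy: int = 400
    min_aa_light: int = 200

    def __post_init__(self) -> None:
        if self.min_len_heavy < 3 * self.min_aa_heavy:
            raise ValueError("min_len_heavy must be >= 3 * min_aa_heavy")
        if self.min_len_light < 3 * self.min_aa_light:
            raise ValueError("min_len_light must be >= 3 * min_aa_light")

    def min_len(self, chain: str) -> int:
        return self.min_len_heavy if chain == HEAVY else self.min_len_light

    def min_aa(self, chain: str) -> int:
        return self.min_aa_heavy if chain == HEAVY else self.min_aa_light


@dataclass
class CdsRecord:
    """An extracted immunoglobulin coding sequence.

    ``cds`` runs from ATG through the stop codon inclusive; ``protein``
    is its translation without the terminal '*'.  Coordinates are
    0-based half-open on the oriented contig (signature on the forward
    strand).  ``v_region``/``c_region`` are 1-based inclusive protein
    intervals, set by align_constant_region.
    """

    contig_id: str
    chain: str
    isotype: str
    cds: str
    protein: str
    orf_start: int
    orf_end: int
    signature_id: str
    signature_span: tuple[int, int]
    primary: bool = False
    v_region: tuple[int, int] | None = None
    c_region: tuple[int, int] | None = None


@dataclass
class ConstantAlignment:
    """Semi-global alignment of an Ig protein to a constant-region reference.

    Coordinates are 1-based inclusive; identity is over the aligned
    region (excluding free end overhangs).
    """

    query_start: int
    query_end: int
    ref_start: int
    ref_end: int
    percent_identity: float
    aligned_query: str
    aligned_ref: str


def filter_contigs(
    contigs: Iterable[Contig],
    catalog: Mapping[str, Signature],
    params: FilterParams | None = None,
) -> list[tuple[Contig, list[SignatureHit], str]]:
    """Keep contigs with single-family signature hits and proper length."""
    params = params or FilterParams()
    kept: list[tuple[Contig, list[SignatureHit], str]] = []
    for contig in contigs:
        rec = SequenceRecord(id=contig.id, sequence=contig.sequence)
        hits = scan_contig(rec, catalog)
        chain = classify_chain(hits, catalog)
        if chain == NONE:
            continue
        if chain == AMBIGUOUS:
            logger.warning(
                "contig %s matches signatures from multiple chain families; "
                "excluded", contig.id,
            )
            continue
        if len(contig.sequence) > params.min_len(chain):
            kept.append((contig, hits, chain))
    return kept


def _orient_by_hits(
    contig: Contig, hits: Sequence[SignatureHit], catalog: Mapping[str, Signature]
) -> tuple[str, list[SignatureHit]]:
    """Flip the contig so the (majority-strand) signature reads forward."""
    n_minus = sum(1 for h in hits if h.strand == "-")
    if n_minus * 2 <= len(hits):
        return contig.sequence, list(hits)
    seq = reverse_complement(contig.sequence)
    rec = SequenceRecord(id=contig.id, sequence=seq)
    return seq, scan_contig(rec, catalog)


def _orfs_in_frame(seq: str, frame: int) -> Iterable[tuple[int, int]]:
    """Longest ORF per stop codon in one frame: (atg_start, end_after_stop).

    For each stop codon, the reported ORF starts at the earliest ATG
    after the previous in-frame stop, which is the longest ORF ending at
    that stop.
    """
    first_atg: int | None = None
    for pos in range(frame, len(seq) - 2, 3):
        codon = seq[pos : pos + 3]
        if codon in _STOPS:
            if first_atg is not None:
                yield first_atg, pos + 3
            first_atg = None
        elif codon == "ATG" and first_atg is None:
            first_atg = pos


def extract_cds(
    contig: Contig,
    hits: Sequence[SignatureHit],
    chain: str,
    catalog: Mapping[str, Signature],
    params: FilterParams | None = None,
) -> CdsRecord:
    """Extract the longest qualifying ORF containing the signature anchor.

    The contig is first oriented so the signature lies on the forward
    strand; candidate ORFs (any forward frame) must fully contain the
    signature span and encode at least the chain's amino-acid floor.
    Ties in length are broken by the smaller start coordinate.
    """
    params = params or FilterParams()
    seq, oriented_hits = _orient_by_hits(contig, hits, catalog)
    fwd_hits = [h for h in oriented_hits if h.strand == "+"]
    if not fwd_hits:
        raise NoValidOrfError(
            f"contig {contig.id}: no forward-strand signature after orientation"
        )
    anchor = fwd_hits[0]
    min_nt = 3 * (params.min_aa(chain) + 1)  # amino acids + stop codon
    best: tuple[int, int] | None = None
    longest: tuple[int, int] | None = None
    for frame in range(3):
        for start, end in _orfs_in_frame(seq, frame):
            if longest is None or (end - start) > (longest[1] - longest[0]):
                longest = (start, end)
            if not (start <= anchor.start and anchor.end <= end):
                continue
            if (end - start) < min_nt:
                continue
            if best is None or (end - start, -start) > (
                best[1] - best[0],
                -best[0],
            ):
                best = (start, end)
    if best is None:
        raise NoValidOrfError(
            f"contig {contig.id}: no ORF contains the {anchor.signature_id} "
            f"anchor and encodes >= {params.min_aa(chain)} aa "
            f"(longest ORF found: "
            f"{(longest[1] - longest[0]) if longest else 0} nt)",
            longest_orf=seq[longest[0] : longest[1]] if longest else None,
        )
    start, end = best
    cds = seq[start:end]
    protein = translate(cds)
    assert protein.endswith("*") and "*" not in protein[:-1]
    return CdsRecord(
        contig_id=contig.id,
        chain=chain,
        isotype=catalog[anchor.signature_id].subclass,
        cds=cds,
        protein=protein[:-1],
        orf_start=start,
        orf_end=end,
        signature_id=anchor.signature_id,
        signature_span=(anchor.start, anchor.end),
    )


def call_isotype(record: CdsRecord) -> str:
    """Subclass label of the anchoring signature (e.g. 'IgG2b', 'kappa')."""
    return record.isotype


def find_cds_records(
    contigs: Iterable[Contig],
    catalog: Mapping[str, Signature],
    params: FilterParams | None = None,
) -> list[CdsRecord]:
    """Run the full contig filter + CDS extraction, skipping failures.

    Within each chain family the longest CDS is flagged primary.
    """
    params = params or FilterParams()
    records: list[CdsRecord] = []
    for contig, hits, chain in filter_contigs(contigs, catalog, params):
        try:
            records.append(extract_cds(contig, hits, chain, catalog, params))
        except NoValidOrfError as exc:
            logger.info("contig %s rejected: %s", contig.id, exc)
    by_chain: dict[str, CdsRecord] = {}
    for rec in records:
        cur = by_chain.get(rec.chain)
        if cur is None or len(rec.cds) > len(cur.cds):
            by_chain[rec.chain] = rec
    for rec in by_chain.values():
        rec.primary = True
    return records


def align_constant_region(
    query_protein: str,
    constant_protein: str,
    match: float = 2,
    mismatch: float = -1,
    gap_open: float = -5,
    gap_extend: float = -1,
) -> ConstantAlignment:
    """Semi-global protein alignment with free end gaps on the query.

    The query (full Ig chain) may overhang the constant-region reference
    without penalty, so the reference localizes the C region within the
    query.  Opening a gap costs ``gap_open`` for its first residue and
    ``gap_extend`` for each additional one.
    """
    if not query_protein or not constant_protein:
        raise ValueError("both protein sequences must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aligner.end_insertion_score = 0  # free query overhang
    aligner.end_deletion_score = 0  # free reference overhang
    aln = aligner.align(query_protein, constant_protein)[0]
    qblocks, rblocks = aln.aligned
    qs, qe = int(qblocks[0][0]), int(qblocks[-1][1])
    rs, re = int(rblocks[0][0]), int(rblocks[-1][1])
    # identity over the aligned region (gaps count as columns)
    matches = 0
    columns = 0
    qi, ri = qs, rs
    for (qa, qb), (ra, rb) in zip(qblocks, rblocks):
        columns += (qa - qi) + (ra - ri)  # internal gap columns
        for off in range(qb - qa):
            columns += 1
            if query_protein[qa + off] == constant_protein[ra + off]:
                matches += 1
        qi, ri = qb, rb
    pct = 100.0 * matches / columns if columns else 0.0
    return ConstantAlignment(
        query_start=qs + 1,
        query_end=qe,
        ref_start=rs + 1,
        ref_end=re,
        percent_identity=pct,
        aligned_query=query_protein[qs:qe],
        aligned_ref=constant_protein[rs:re],
    )


def delineate_regions(record: CdsRecord, constant_protein: str) -> ConstantAlignment:
    """Align to a constant-region reference and set V/C protein intervals."""
    report = align_constant_region(record.protein, constant_protein)
    record.v_region = (1, report.query_start - 1) if report.query_start > 1 else None
    record.c_region = (report.query_start, report.query_end)
    return report


_REPORT_COLUMNS = [
    "contig_id",
    "chain",
    "isotype",
    "cds_len_nt",
    "protein_len_aa",
    "signature_id",
    "signature_start",
    "orf_start",
    "orf_end",
    "primary",
    "v_region",
    "c_region",
]


def _interval_str(iv: tuple[int, int] | None) -> str:
    return f"{iv[0]}-{iv[1]}" if iv else ""


def write_report(records: Sequence[CdsRecord], out_dir) -> dict[str, Path]:
    """Write the CDS report TSV plus companion nucleotide/protein FASTAs."""
    seen: set[str] = set()
    dups = sorted(
        {r.contig_id for r in records if r.contig_id in seen or seen.add(r.contig_id)}
    )
    if dups:
        raise ReportError(f"duplicate contig ids in report: {dups}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tsv": out_dir / "ig_cds_report.tsv",
        "cds_fasta": out_dir / "ig_cds.fasta",
        "protein_fasta": out_dir / "ig_protein.fasta",
    }
    with open(paths["tsv"], "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_REPORT_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.contig_id,
                    r.chain,
                    r.isotype,
                    len(r.cds),
                    len(r.protein),
                    r.signature_id,
                    r.signature_span[0],
                    r.orf_start,
                    r.orf_end,
                    int(r.primary),
                    _interval_str(r.v_region),
                    _interval_str(r.c_region),
                ]
            )
    write_fasta(
        [
            SequenceRecord(r.contig_id, r.cds, f"{r.chain} {r.isotype} CDS")
            for r in records
        ]
        or [],
        paths["cds_fasta"],
    )
    write_fasta(
        [
            SequenceRecord(r.contig_id, r.protein, f"{r.chain} {r.isotype} protein")
            for r in records
        ]
        or [],
        paths["protein_fasta"],
    )
    return paths
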