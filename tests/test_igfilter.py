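"""Contig filtering, ORF/CDS extraction, isotype calls, and V/C alignment."""

import random

import pytest

from hybriseq.assembler import Contig
from hybriseq.errors import NoValidOrfError, ReportError
from hybriseq.igfilter import (
    FilterParams,
    align_constant_region,
    call_isotype,
    delineate_regions,
    extract_cds,
    filter_contigs,
    find_cds_records,
    write_report,
)
from hybriseq.seqio import SequenceRecord, read_fasta, reverse_complement, translate
from hybriseq.signatures import builtin_catalog, scan_contig
from hybriseq.simulate import make_ig_transcript

from .conftest import random_dna
from .oracles import semiglobal_score

AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_protein(rng, n):
    return "".join(rng.choice(AA) for _ in range(n))


def _upstream_open(utr: str) -> bool:
    """True if an in-frame upstream ATG (no intervening stop) exists."""
    stops = {"TAA", "TAG", "TGA"}
    for i in range(len(utr) - 3, -1, -3):
        codon = utr[i : i + 3]
        if codon in stops:
            return False
        if codon == "ATG":
            return True
    return False


def _heavy_contig(seed=1, utr5=80, utr3=60):
    """Synthetic heavy-chain contig with controlled UTR lengths.

    The 5'UTR is drawn so it cannot extend the reading frame upstream,
    keeping the longest qualifying ORF equal to the planted CDS.
    """
    _, cds = make_ig_transcript("rat", "IgG2b", "heavy", seed=seed)
    rng = random.Random(seed + 5000)
    while True:
        left = random_dna(rng, utr5)
        if _upstream_open(left):
            continue
        contig = left + cds + random_dna(rng, utr3)
        sig = builtin_catalog("rat")["rat-Ighg2b"].sequence
        if contig.count(sig) == 1 and reverse_complement(contig).count(sig) == 0:
            return Contig(id="hc", sequence=contig), cds


class TestFilterContigs:
    def _contig_with(self, rng, sig, length):
        pad = length - len(sig)
        left = pad // 2
        return Contig(
            id="c", sequence=random_dna(rng, left) + sig + random_dna(rng, pad - left)
        )

    @pytest.mark.parametrize(
        "length,sig_id,expected_kept",
        [
            (1395, "rat-Ighg2b", True),
            (1201, "rat-Ighg2b", True),
            (1200, "rat-Ighg2b", False),  # strict inequality
            (705, "rat-Igk", True),
            (601, "rat-Igk", True),
            (600, "rat-Igk", False),
        ],
    )
    def test_length_thresholds_are_strict(
        self, rat_catalog, length, sig_id, expected_kept
    ):
        rng = random.Random(length)
        sig = rat_catalog[sig_id].sequence
        contig = self._contig_with(rng, sig, length)
        kept = filter_contigs([contig], rat_catalog)
        assert bool(kept) == expected_kept
        if kept:
            _, hits, chain = kept[0]
            assert chain == rat_catalog[sig_id].chain
            assert hits

    def test_ambiguous_family_contig_excluded(self, rat_catalog, caplog):
        rng = random.Random(0)
        seq = (
            random_dna(rng, 600)
            + rat_catalog["rat-Ighg2b"].sequence
            + random_dna(rng, 600)
            + rat_catalog["rat-Igk"].sequence
            + random_dna(rng, 100)
        )
        with caplog.at_level("WARNING"):
            assert filter_contigs([Contig("c", seq)], rat_catalog) == []
        assert "multiple chain families" in caplog.text

    def test_signature_free_contig_ignored(self, rat_catalog):
        rng = random.Random(1)
        assert filter_contigs([Contig("c", random_dna(rng, 2000))], rat_catalog) == []


class TestExtractCds:
    def test_heavy_worked_example_geometry(self, rat_catalog):
        contig, cds = _heavy_contig()
        [(c, hits, chain)] = filter_contigs([contig], rat_catalog)
        rec = extract_cds(c, hits, chain, rat_catalog)
        assert len(rec.cds) == 1395
        assert rec.cds == cds
        assert len(rec.protein) == 464
        assert rec.cds.startswith("ATG")
        assert rec.cds[-3:] in {"TAA", "TAG", "TGA"}
        assert rec.isotype == "IgG2b"
        # the anchor lies inside the CDS on the oriented contig
        s, e = rec.signature_span
        assert rec.orf_start <= s < e <= rec.orf_end
        assert rec.cds == contig.sequence[rec.orf_start : rec.orf_end]

    def test_reverse_complemented_contig_gives_identical_record(self, rat_catalog):
        contig, _ = _heavy_contig(seed=2)
        flipped = Contig(id="hc", sequence=reverse_complement(contig.sequence))
        recs = []
        for c in (contig, flipped):
            [(cc, hits, chain)] = filter_contigs([c], rat_catalog)
            recs.append(extract_cds(cc, hits, chain, rat_catalog))
        assert recs[0].cds == recs[1].cds
        assert recs[0].protein == recs[1].protein
        assert recs[0].orf_start == recs[1].orf_start

    def test_short_orf_rejected_with_diagnostic(self, rat_catalog):
        rng = random.Random(9)
        sig = rat_catalog["rat-Ighg2b"].sequence
        # 150-codon ORF containing the signature, inside a long contig
        inner = "ATG" + "GCT" * 50 + sig + "GCT" * 91 + "TAA"
        seq = ("TAA" + random_dna(rng, 600) + "TAGTAA" + inner + "TGA"
               + random_dna(rng, 600))
        contig = Contig("c", seq)
        hits = scan_contig(SequenceRecord("c", seq), rat_catalog)
        hits = [h for h in hits if h.signature_id == "rat-Ighg2b"]
        with pytest.raises(NoValidOrfError) as err:
            extract_cds(contig, hits, "heavy", rat_catalog)
        assert err.value.longest_orf is not None

    def test_light_chain_geometry(self, rat_catalog):
        transcript, cds = make_ig_transcript("rat", "kappa", "kappa", seed=3)
        contig = Contig("lc", transcript.sequence)
        [(c, hits, chain)] = filter_contigs([contig], rat_catalog)
        rec = extract_cds(c, hits, chain, rat_catalog)
        assert rec.cds == cds
        assert len(rec.cds) == 645
        assert len(rec.protein) == 214
        assert rec.chain == "kappa"
        assert call_isotype(rec) == "kappa"

    def test_translation_consistency_invariant(self, rat_catalog):
        contig, _ = _heavy_contig(seed=4)
        [(c, hits, chain)] = filter_contigs([contig], rat_catalog)
        rec = extract_cds(c, hits, chain, rat_catalog)
        assert translate(rec.cds) == rec.protein + "*"
        assert "*" not in rec.protein


class TestIsotypeCalls:
    @pytest.mark.parametrize(
        "species,isotype,chain",
        [("rat", "IgG2b", "heavy"), ("rat", "kappa", "kappa"),
         ("mouse", "IgG3", "heavy")],
    )
    def test_subclass_from_anchor(self, species, isotype, chain):
        catalog = builtin_catalog(species)
        transcript, _ = make_ig_transcript(species, isotype, chain, seed=8)
        contig = Contig("c", transcript.sequence)
        [(c, hits, ch)] = filter_contigs([contig], catalog)
        rec = extract_cds(c, hits, ch, catalog)
        assert call_isotype(rec) == isotype


class TestConstantRegionAlignment:
    def test_identical_sequences(self):
        rng = random.Random(21)
        ref = _random_protein(rng, 332)
        rep = align_constant_region(ref, ref)
        assert (rep.query_start, rep.query_end) == (1, 332)
        assert rep.percent_identity == 100.0

    def test_v_region_offset_reproduces_133(self):
        rng = random.Random(22)
        ref = _random_protein(rng, 332)
        query = _random_protein(rng, 132) + ref
        rep = align_constant_region(query, ref)
        assert rep.query_start == 133
        assert rep.query_end == 464
        assert rep.percent_identity == 100.0

    def test_single_substitution_identity(self):
        rng = random.Random(23)
        ref = _random_protein(rng, 332)
        mutated = list(ref)
        mutated[150] = "W" if ref[150] != "W" else "Y"
        query = _random_protein(rng, 50) + "".join(mutated)
        rep = align_constant_region(query, ref)
        assert rep.percent_identity == pytest.approx(100.0 * 331 / 332)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            align_constant_region("", "ACD")

    def test_score_matches_brute_force_dp(self):
        rng = random.Random(24)
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 2
        aligner.mismatch_score = -1
        aligner.open_gap_score = -5
        aligner.extend_gap_score = -1
        aligner.end_insertion_score = 0
        aligner.end_deletion_score = 0
        for _ in range(40):
            a = _random_protein(rng, rng.randint(1, 30))
            b = _random_protein(rng, rng.randint(1, 30))
            assert aligner.score(a, b) == pytest.approx(semiglobal_score(a, b))

    def test_delineate_sets_v_and_c_regions(self, rat_catalog):
        contig, cds = _heavy_contig(seed=6)
        [(c, hits, chain)] = filter_contigs([contig], rat_catalog)
        rec = extract_cds(c, hits, chain, rat_catalog)
        constant = rec.protein[132:]  # known constant region, 332 aa
        rep = delineate_regions(rec, constant)
        assert rec.v_region == (1, 132)
        assert rec.c_region == (133, 464)
        assert rep.percent_identity == 100.0


class TestReport:
    def test_heavy_plus_light_report(self, tmp_path, rat_catalog):
        records = []
        for isotype, chain, seed in [("IgG2b", "heavy", 31), ("kappa", "kappa", 32)]:
            transcript, _ = make_ig_transcript("rat", isotype, chain, seed=seed)
            contig = Contig(f"c_{chain}", transcript.sequence)
            [(c, hits, ch)] = filter_contigs([contig], rat_catalog)
            records.append(extract_cds(c, hits, ch, rat_catalog))
        paths = write_report(records, tmp_path)
        lines = paths["tsv"].read_text().splitlines()
        assert len(lines) == 3  # header + 2 rows
        assert lines[0].startswith("contig_id\tchain\tisotype")
        cds_records = read_fasta(paths["cds_fasta"])
        assert [r.sequence for r in cds_records] == [r.cds for r in records]
        proteins = read_fasta(paths["protein_fasta"])
        assert [r.sequence for r in proteins] == [r.protein for r in records]

    def test_empty_report_is_header_only(self, tmp_path):
        paths = write_report([], tmp_path)
        assert len(paths["tsv"].read_text().splitlines()) == 1

    def test_duplicate_contig_ids_rejected(self, tmp_path, rat_catalog):
        transcript, _ = make_ig_transcript("rat", "IgG2b", "heavy", seed=33)
        contig = Contig("dup", transcript.sequence)
        [(c, hits, ch)] = filter_contigs([contig], rat_catalog)
        rec = extract_cds(c, hits, ch, rat_catalog)
        with pytest.raises(ReportError):
            write_report([rec, rec], tmp_path)


class TestFindCdsRecords:
    def test_primary_flag_marks_longest_per_chain(self, rat_catalog):
        t1, _ = make_ig_transcript("rat", "IgG2b", "heavy", seed=41)
        t2, _ = make_ig_transcript("rat", "kappa", "kappa", seed=42)
        contigs = [Contig("h", t1.sequence), Contig("l", t2.sequence)]
        records = find_cds_records(contigs, rat_catalog)
        assert {r.chain for r in records} == {"heavy", "kappa"}
        assert all(r.primary for r in records)
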