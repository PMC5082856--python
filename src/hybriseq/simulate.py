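"""Synthetic hybridoma mRNA-seq generator.

Emulates the statistical structure the identification method relies on:
a transcriptome in which one heavy-chain and one light-chain
immunoglobulin transcript each receive a few percent of all fragments
(putting them at the top of the expression ranking with FPKM far above
10,000) over a log-normally expressed background, sequenced as
paired-end reads with independent substitution errors.

The synthetic constant regions are random stop-free codon runs with the
genuine catalog signature embedded in frame — what the identification
method actually keys on is the anchor, not the surrounding constant-region
sequence.  A real constant-region protein FASTA can still be supplied
downstream for V/C delineation.  The generator guarantees the planted
signature occurs exactly once across the whole transcriptome (both
strands) and that background transcripts are signature-free.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import CatalogError, ParameterError
from .seqio import (
    ReadPair,
    SequenceRecord,
    reverse_complement,
    write_fasta,
    write_fastq_pairs,
)
from .signatures import HEAVY, KAPPA, LAMBDA, Signature, builtin_catalog

_STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]
_SIG_CODON_OFFSET = 90  # nt offset of the signature within the constant region

# default codon counts: ATG + V-region codons, then constant-region codons
_V_CODONS = {HEAVY: 132, "light": 107}
_C_CODONS = {HEAVY: 332, "light": 107}


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic hybridoma clone."""

    species: str = "rat"
    heavy_isotype: str = "IgG2b"
    light_isotype: str = "kappa"
    n_background: int = 500
    background_len_range: tuple[int, int] = (400, 4000)
    expr_mu: float = 2.0
    expr_sigma: float = 1.5
    ig_fraction_heavy: float = 0.04
    ig_fraction_light: float = 0.04
    read_len: int = 50
    fragment_len_mean: float = 250.0
    fragment_len_sd: float = 25.0
    error_rate: float = 0.001
    n_pairs: int = 50000
    seed: int = 0
    light_v_codons: int | None = None  # override, e.g. 127 for a 705-nt CDS

    def __post_init__(self) -> None:
        if self.ig_fraction_heavy + self.ig_fraction_light >= 1:
            raise ParameterError("immunoglobulin fragment fractions must sum to < 1")
        if self.read_len not in (50, 100):
            raise ParameterError("read_len must be 50 or 100")
        if self.read_len > self.fragment_len_mean:
            raise ParameterError("read_len must not exceed the mean fragment length")
        if not 0 <= self.error_rate <= 1:
            raise ParameterError("error_rate must be a probability")
        if self.n_pairs < 0 or self.n_background < 0:
            raise ParameterError("counts must be non-negative")


@dataclass
class HybridomaTruth:
    """Ground truth of a simulated clone: transcripts, CDSs, weights."""

    heavy_transcript: SequenceRecord
    light_transcript: SequenceRecord
    heavy_cds: str
    light_cds: str
    heavy_isotype: str
    light_isotype: str
    background_transcripts: list[SequenceRecord]
    expression_weights: dict[str, float]

    def all_transcripts(self) -> list[SequenceRecord]:
        return [self.heavy_transcript, self.light_transcript] + list(
            self.background_transcripts
        )

    def true_fpkm(self) -> dict[str, float]:
        """Expected FPKM per transcript under the expression weights."""
        lengths = {t.id: len(t.sequence) for t in self.all_transcripts()}
        return {
            tid: w * 1e6 / (lengths[tid] / 1000.0)
            for tid, w in self.expression_weights.items()
        }


def _signature_for(
    catalog: dict[str, Signature], species: str, chain_kind: str, isotype: str
) -> Signature:
    for sig in catalog.values():
        if sig.subclass == isotype and (
            (chain_kind == HEAVY) == (sig.chain == HEAVY)
        ):
            return sig
    raise CatalogError(
        f"no {species} signature with subclass {isotype!r} for {chain_kind} chain"
    )


def _random_nt(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def _stopfree_codons(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(_NONSTOP_CODONS) for _ in range(n))


def _occurs(haystack: str, needle: str) -> int:
    return haystack.count(needle) + haystack.count(reverse_complement(needle))


def _upstream_closed(utr5: str) -> bool:
    """True if no in-frame upstream ATG could extend the CDS's reading frame.

    Scanning codon-by-codon upstream from the start codon, a stop must
    appear before any ATG (as in real 5'UTRs, where the annotated start
    is the first usable one); otherwise the longest-ORF rule downstream
    would legitimately call a longer CDS than the one planted.
    """
    i = len(utr5) - 3
    while i >= 0:
        codon = utr5[i : i + 3]
        if codon in _STOPS:
            return True
        if codon == "ATG":
            return False
        i -= 3
    return True


def make_ig_transcript(
    species: str,
    isotype: str,
    chain: str,
    seed: int,
    v_codons: int | None = None,
) -> tuple[SequenceRecord, str]:
    """Build one synthetic Ig transcript: 5'UTR + CDS + 3'UTR.

    The CDS is ATG, random stop-free V-region codons, a synthetic
    constant region carrying the catalog signature in frame, and a stop
    codon.  Default geometry: heavy 132 V + 332 C codons (1395-nt CDS,
    464-aa protein), light 107 V + 107 C codons (645-nt CDS, 214 aa).
    """
    catalog = builtin_catalog(species)
    chain_kind = HEAVY if chain == HEAVY else "light"
    sig = _signature_for(catalog, species, chain_kind, isotype)
    n_v = v_codons if v_codons is not None else _V_CODONS[chain_kind]
    n_c = _C_CODONS[chain_kind]
    rng = random.Random(seed)
    all_sigs = [s.sequence for s in catalog.values()]
    for _ in range(1000):
        v_nt = "ATG" + _stopfree_codons(rng, n_v - 1)
        c_nt = _stopfree_codons(rng, n_c)
        c_nt = (
            c_nt[:_SIG_CODON_OFFSET]
            + sig.sequence
            + c_nt[_SIG_CODON_OFFSET + len(sig.sequence) :]
        )
        cds = v_nt + c_nt + rng.choice(sorted(_STOPS))
        body = cds[:-3]
        if any(body[i : i + 3] in _STOPS for i in range(0, len(body), 3)):
            continue
        utr5 = _random_nt(rng, rng.randint(40, 120))
        if not _upstream_closed(utr5):
            continue
        utr3 = _random_nt(rng, rng.randint(50, 200))
        transcript = utr5 + cds + utr3
        counts = {s: _occurs(transcript, s) for s in all_sigs}
        if counts[sig.sequence] != 1 or any(
            c != 0 for s, c in counts.items() if s != sig.sequence
        ):
            continue
        rec = SequenceRecord(
            id=f"{species}_{chain}_{isotype}",
            sequence=transcript,
            description=f"synthetic {chain}-chain transcript ({isotype})",
        )
        return rec, cds
    raise RuntimeError("could not construct a valid Ig transcript")  # pragma: no cover


def _capped_background_weights(
    raw: np.ndarray, lengths: np.ndarray, total: float, ig_fpkm_min: float
) -> np.ndarray:
    """Normalize log-normal draws to ``total``, capping per-transcript FPKM.

    A hybridoma's defining expression feature is that the two Ig
    transcripts outrank everything else, so each background transcript's
    true FPKM is capped at half the smaller Ig FPKM (the log-normal tail
    would otherwise occasionally push one background gene above the Ig
    pair).  If the caps cannot absorb ``total`` (very few background
    transcripts), weights fall back to cap-proportional.
    """
    if raw.size == 0 or total <= 0:
        return np.zeros_like(raw)
    if ig_fpkm_min <= 0:  # no Ig expression: plain normalization
        return raw / raw.sum() * total
    cap = 0.5 * ig_fpkm_min * (lengths / 1000.0) / 1e6  # max fragment share
    if cap.sum() <= total:
        return cap * (total / cap.sum())
    w = raw / raw.sum() * total
    capped = np.zeros(raw.size, dtype=bool)
    for _ in range(raw.size):
        over = (w > cap) & ~capped
        if not over.any():
            break
        capped |= over
        w[capped] = cap[capped]
        free = ~capped
        remaining = total - cap[capped].sum()
        if not free.any() or remaining <= 0:
            break
        w[free] *= remaining / w[free].sum()
    return w


def simulate_transcriptome(config: SimulationConfig) -> HybridomaTruth:
    """Generate the clone's transcriptome and expression weights."""
    rng = random.Random(config.seed)
    heavy_seed = rng.randrange(2**31)
    light_seed = rng.randrange(2**31)
    heavy_rec, heavy_cds = make_ig_transcript(
        config.species, config.heavy_isotype, HEAVY, heavy_seed
    )
    light_chain = KAPPA if config.light_isotype == KAPPA else LAMBDA
    light_rec, light_cds = make_ig_transcript(
        config.species,
        config.light_isotype,
        light_chain,
        light_seed,
        v_codons=config.light_v_codons,
    )
    catalog = builtin_catalog(config.species)
    all_sigs = [s.sequence for s in catalog.values()]
    lo, hi = config.background_len_range
    background: list[SequenceRecord] = []
    for i in range(config.n_background):
        while True:
            seq = _random_nt(rng, rng.randint(lo, hi))
            if all(_occurs(seq, s) == 0 for s in all_sigs):
                break
        background.append(
            SequenceRecord(id=f"bg_{i + 1:04d}", sequence=seq)
        )
    bg_weight_total = 1.0 - config.ig_fraction_heavy - config.ig_fraction_light
    raw = np.array(
        [rng.lognormvariate(config.expr_mu, config.expr_sigma) for _ in background]
    )
    weights = {
        heavy_rec.id: config.ig_fraction_heavy,
        light_rec.id: config.ig_fraction_light,
    }
    bg_weights = _capped_background_weights(
        raw,
        np.array([len(r.sequence) for r in background]),
        bg_weight_total,
        ig_fpkm_min=min(
            config.ig_fraction_heavy * 1e6 / (len(heavy_rec.sequence) / 1000.0),
            config.ig_fraction_light * 1e6 / (len(light_rec.sequence) / 1000.0),
        ),
    )
    for rec, w in zip(background, bg_weights):
        weights[rec.id] = float(w)
    return HybridomaTruth(
        heavy_transcript=heavy_rec,
        light_transcript=light_rec,
        heavy_cds=heavy_cds,
        light_cds=light_cds,
        heavy_isotype=config.heavy_isotype,
        light_isotype=config.light_isotype,
        background_transcripts=background,
        expression_weights=weights,
    )


_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)
_ENCODE = np.full(256, 0, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i


def _apply_errors(
    seqs: list[str], read_len: int, error_rate: float, rng: np.random.Generator
) -> list[str]:
    if not seqs:
        return seqs
    codes = _ENCODE[
        np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    ].reshape(len(seqs), read_len)
    mask = rng.random(codes.shape) < error_rate
    shift = rng.integers(1, 4, size=codes.shape, dtype=np.uint8)
    codes = np.where(mask, (codes + shift) % 4, codes)
    blob = _DECODE[codes].tobytes().decode("ascii")
    return [blob[i * read_len : (i + 1) * read_len] for i in range(len(seqs))]


def generate_read_pairs(
    truth: HybridomaTruth, config: SimulationConfig
) -> list[ReadPair]:
    """Draw paired-end fragments from the weighted transcriptome.

    mate1 is the fragment 5' prefix on the transcript strand; mate2 is
    the reverse complement of the fragment 3' suffix.  Fragment lengths
    are normal (clamped to [read_len, transcript length]); substitution
    errors are i.i.d. per base; qualities are constant 'I' (Q40).
    Deterministic for a fixed config seed.
    """
    rng = np.random.default_rng(config.seed)
    transcripts = truth.all_transcripts()
    weights = np.array(
        [truth.expression_weights[t.id] for t in transcripts], dtype=float
    )
    weights = weights / weights.sum()
    n = config.n_pairs
    tidx = rng.choice(len(transcripts), size=n, p=weights)
    flen = np.rint(
        rng.normal(config.fragment_len_mean, config.fragment_len_sd, size=n)
    ).astype(int)
    flen = np.maximum(flen, config.read_len)
    tlens = np.array([len(t.sequence) for t in transcripts])[tidx]
    clamped = int(np.sum(flen > tlens))
    if clamped:
        # fragments longer than their transcript are shortened to fit
        flen = np.minimum(flen, tlens)
    starts = np.floor(rng.random(n) * (tlens - flen + 1)).astype(int)
    mate1: list[str] = []
    mate2: list[str] = []
    L = config.read_len
    for i in range(n):
        frag = transcripts[tidx[i]].sequence[starts[i] : starts[i] + flen[i]]
        mate1.append(frag[:L])
        mate2.append(reverse_complement(frag[-L:]))
    mate1 = _apply_errors(mate1, L, config.error_rate, rng)
    mate2 = _apply_errors(mate2, L, config.error_rate, rng)
    qual = "I" * L
    return [
        ReadPair(id=f"frag_{i + 1:07d}", seq1=mate1[i], seq2=mate2[i],
                 qual1=qual, qual2=qual)
        for i in range(n)
    ]


def save_truth(truth: HybridomaTruth, fasta_path, json_path) -> None:
    """Serialize the transcriptome FASTA and the truth JSON."""
    write_fasta(truth.all_transcripts(), fasta_path)
    payload = {
        "heavy_id": truth.heavy_transcript.id,
        "light_id": truth.light_transcript.id,
        "heavy_cds": truth.heavy_cds,
        "light_cds": truth.light_cds,
        "heavy_isotype": truth.heavy_isotype,
        "light_isotype": truth.light_isotype,
        "expression_weights": truth.expression_weights,
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=1)


def simulate_reads(truth: HybridomaTruth, config: SimulationConfig, path1, path2) -> None:
    """Generate reads and write them as (optionally gzipped) FASTQ mates."""
    write_fastq_pairs(generate_read_pairs(truth, config), path1, path2)
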