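# Methods

## Overview

`hybriseq` reconstructs immunoglobulin heavy- and light-chain coding
sequences from hybridoma mRNA-seq by exploiting a single biological
fact: in a hybridoma the two immunoglobulin transcripts dominate the
transcriptome. Under that condition a de novo assembly of even a few
tens of thousands of read pairs contains a single deeply covered contig
per chain, and each contig can be recognized purely by literal
containment of a short constant-region anchor sequence.

## Signature anchors

The unit of recognition is a 20–30 bp nucleotide *signature* unique to
one constant-region gene. The built-in catalogs cover 7 rat entries
(IgG1/IgG2a/IgG2b/IgG2c heavy subclasses, two lambda types, kappa) and
10 mouse entries (five IgG subclasses, four lambda types, kappa); user
catalogs load from TSV. Matching is exact and two-stranded: assembled
contigs have arbitrary orientation, and substitution errors in reads are
expected to be resolved by the assembly consensus rather than by fuzzy
matching. Catalog validation enforces length bounds, the DNA alphabet,
and mutual non-nesting (no signature a substring of another), since a
nested anchor could never be attributed unambiguously.

Contigs hit by signatures from more than one chain family are reported
as ambiguous and excluded from extraction with a warning — a
conservative choice; well-formed assemblies of real hybridoma data
should not produce such contigs.

## Assembly

The assembler is a minimal canonical-k-mer unitig assembler intended for
the dominant-transcript regime, not a general-purpose transcriptome
assembler:

- k-mers (odd k, 3–31; default 25 for 50-bp reads, 31 recommended for
  100-bp reads) are packed 2 bits/base into 64-bit integers; counting is
  strand-insensitive via the canonical (lexicographically smaller)
  orientation. The upper bound k ≤ 31 follows from the packing; k must
  be odd so no k-mer is its own reverse complement.
- `min_count` (default 1) drops rare k-mers before graph construction.
  The default keeps singletons because the saturation experiment
  assembles samples as small as 5000 pairs, where true coverage is thin.
- Contigs are maximal non-branching paths (unitigs), emitted in
  canonical orientation and lexicographic order, so output is
  byte-deterministic. Unitigs of one graph share no k-mer, hence no
  contig is a substring of another on either strand.

### Error pruning

With `min_count=1`, every substitution error survives counting and
appears as a short side branch: a *tip* when the error lies near a read
end, a rejoining *bubble branch* when it lies mid-read. Both fragment
the deeply covered immunoglobulin unitig at their attachment points, so
both are pruned, iteratively, under three joint conditions:

1. the branch is attached to the rest of the graph at one or both ends;
2. its sequence is shorter than `max(3k, read_len + k)` — the longest
   artifact chain a single erroneous read can spawn is one read length;
3. some sibling branch at an attachment point has at least 8× its mean
   k-mer coverage.

The coverage-dominance condition (3) is what makes pruning safe:
genuine branching structure at comparable coverage (e.g. a shared repeat
between two real transcripts) is never removed, and genuine
transcript-terminal segments — which a coverage-blind tip rule would
delete whenever an error branch attaches within a couple of k of a
transcript end — are protected by their high coverage. The 8× ratio
sits comfortably between error-branch coverage (~1–2×) and the ≥ 13×
per-k-mer coverage the immunoglobulin transcripts have even at the
lowest depth of interest; it is deliberately not exposed as a tuning
knob. No bubble *phasing* is attempted: the weaker branch is discarded,
which is correct when one branch is an error and a documented
limitation when a clone genuinely carries two isoforms.

Pruning operates on an incrementally maintained node graph (degrees and
unitig successors updated locally after each removal), so the graph is
built and walked once rather than per round.

## CDS extraction

Candidate contigs must carry a single-family signature and be strictly
longer than 1200 nt (heavy) or 600 nt (light) — thresholds applied to
the contig, with strict inequality. Note that at exactly 1201/601 nt
the length gate passes but no qualifying ORF can exist (a 400-aa ORF
plus stop needs 1203 nt), so the amino-acid floor is the binding
constraint near the boundary.

Extraction orients the contig so the signature reads forward, then
scans all three forward frames for ORFs (first ATG after each in-frame
stop, through the stop). Among ORFs that fully contain the signature
span and encode at least 400 aa (heavy) or 200 aa (light), the longest
wins; ties break toward the smaller start coordinate. The CDS includes
the terminal stop codon; the reported protein excludes the '*'. With
this convention a 1395-nt heavy CDS yields a 464-aa protein whose
constant region, located by alignment, spans residues 133–464. The
isotype/subclass is simply the subclass of the anchoring signature.

When no ORF qualifies, the error carries the longest ORF found, which
makes "contig present but truncated" diagnosable. When several contigs
of one chain qualify, all are reported and the longest is flagged
primary.

### V/C delineation

`align_constant_region` performs a semi-global protein alignment
(match 2, mismatch −1, gap −5 to open — charged on the first gap
residue — and −1 to extend; end gaps free) of the chain protein
against a user-supplied constant-region protein. The V region is
everything before the first aligned residue; identity is computed over
aligned columns only. The scoring values are pragmatic defaults for
near-identical constant regions, not tuned quantities; the test suite
pins the implementation to an independent dynamic-programming oracle on
short sequences.

## Quantification

The premise check uses k-mer plurality assignment: each read pair is
assigned to the transcript matching the most of its canonical k-mers
(k-mers shared between transcripts vote for each); ties and zero-match
pairs are unassigned, i.e. dropped rather than fractionally allocated.
FPKM = count / ((length/1000) · (assigned/10⁶)). This is a deliberate,
documented surrogate for probabilistic quantifiers: it supports the
*ranking* claim (immunoglobulin transcripts at ranks 1–2, FPKM > 10⁴)
on data where transcripts share little sequence, and is not suitable
for isoform-level estimates.

## Saturation experiment

To estimate the read depth needed for reliable recovery, the CDSs
identified from the full data set are frozen as reference sequences;
then for each depth d and replicate r the pipeline subsamples d pairs
(uniformly, without replacement, seed = base seed + r, so any replicate
reproduces in isolation), reassembles, reruns identification, and
scores success only on exact string equality of a candidate CDS with
the reference — a truncated or single-substituted CDS is a failure.
Depths are counted in read *pairs* (fragments), the natural unit of
paired-end subsampling; this halves the nominal "read" counts and is
stated here prominently for comparability.

Default grid: 5k, 10k, 30k, 50k, 100k, 500k, 1M pairs × 25 replicates.
The packaged experiments use a 100k-pair simulated clone so that depths
up to 50k remain true subsamples; on those conditions the light chain
(645-nt CDS) saturates at 100% by ~10k pairs and the heavy chain
(1395-nt CDS) by ~30k, with failures below that driven by coverage
gaps, matching the intuition that the longer chain needs more depth.

## The simulator

`simulate` generates the study conditions the method assumes; it is the
package's test bed, not a general RNA-seq simulator.

- **Ig transcripts**: 5'UTR (40–120 nt) + CDS + 3'UTR (50–200 nt). The
  CDS is ATG + random stop-free V-region codons (heavy 132 incl. the
  start, light 107) + a synthetic constant region (random stop-free
  codons, heavy 332, light 107) with the true catalog signature embedded
  in frame at a fixed offset + stop. Defaults give a 1395-nt/464-aa
  heavy and 645-nt/214-aa light chain; the light V-region length is
  configurable (e.g. 127 codons for a 705-nt CDS). Constant regions are
  random rather than database sequences because the identification
  method keys only on the anchor; a real constant-region protein can
  still be supplied for V/C delineation.
- **5'UTRs are upstream-closed**: resampled until no in-frame ATG
  precedes the planted start without an intervening stop. Otherwise the
  longest-ORF rule would — correctly — call a longer CDS than the
  planted one in a noticeable fraction of seeds. Real 5'UTRs share this
  property (the annotated start is the first usable one).
- **Uniqueness guarantees**: each planted signature occurs exactly once
  across the whole transcriptome (both strands); background transcripts
  (default 500, lengths uniform 400–4000 nt) are resampled until
  signature-free.
- **Expression**: the two Ig transcripts receive fixed fragment shares
  (4% each by default, putting their true FPKM at ~25k and ~47k);
  background shares are log-normal(μ=2, σ=1.5) normalized to the
  remainder, with each background transcript's true FPKM capped at half
  the smaller Ig FPKM. The cap encodes the defining expression feature
  of a hybridoma — the Ig pair outranks everything — which the raw
  log-normal tail would otherwise violate in a few percent of seeds.
- **Reads**: fragments drawn by expression weight; lengths
  normal(250, 25) clamped to [read length, transcript length]; mate 1 is
  the fragment prefix, mate 2 the reverse complement of the suffix;
  i.i.d. substitutions at 0.1% by default (a substituted base always
  changes); constant 'I' qualities. Everything is deterministic per
  seed.

What the simulator does **not** model — real V(D)J alleles and somatic
hypermutation, quality decay along reads, indels, PCR duplicates,
strand bias, homologous background genes — bounds what passing tests
show: they demonstrate the pipeline's logic and its behavior under
coverage and substitution noise, not robustness to every artifact of
real libraries. In particular, real data may contain transcripts
homologous to the Ig constant region (e.g. the fusion partner's sterile
transcripts), which the uniqueness-by-construction guarantee excludes.

## Numerical and degenerate-input choices

- All nucleotide input is uppercased; RNA 'U' is rejected (reads are
  DNA-space); FASTQ is Phred+33 only, with a heuristic rejection of
  Phred+64-looking quality strings; gzip is sniffed from magic bytes.
- k-mers containing N are skipped everywhere.
- Empty inputs yield empty outputs (empty FASTA, empty contig list,
  header-only report); malformed inputs raise typed errors naming the
  offending record or line.
- Tie-breaks are total and documented: unitig traversal order by node
  index, contig order lexicographic, ORF ties by start coordinate,
  expression ties by transcript id.

## Problem sizes used in the packaged experiments

The bundled tests and the acceptance script run on a 100k-pair
simulated clone with 500 background transcripts, a depth grid of
5k–50k pairs and 25 replicates per depth — sizes chosen so the full
suite completes in minutes on a single CPU while every depth remains a
genuine subsample. The same code paths scale to the tens of millions
of reads of a real mRNA-seq run; only the k-mer dictionaries grow.

## Known limitations

- One dominant clone per sample: mixed hybridoma cultures or biclonal
  lines produce competing contigs that the primary-flag heuristic does
  not disambiguate.
- No isoform or allele phasing; the stronger branch wins at every
  pruned bubble.
- The quantifier's plurality assignment is biased against transcripts
  with substantial shared sequence.
- Exact-match signatures fail if a clone's constant region is mutated
  inside the anchor itself (rare, but then the contig must be found via
  a user-supplied catalog).
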