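"""Exception hierarchy for the hybriseq pipeline."""


class HybriseqError(Exception):
    """Base class for all hybriseq errors."""


class FastaParseError(HybriseqError):
    """Malformed FASTA input (bad header, empty sequence, stray data)."""


class FastqParseError(HybriseqError):
    """Malformed FASTQ input (truncated 4-line block, bad separator)."""


class FastqPairingError(HybriseqError):
    """Mate files with unequal record counts."""


class AlphabetError(HybriseqError):
    """Sequence contains characters outside the expected alphabet."""


class FrameError(HybriseqError):
    """Coding sequence length not divisible by 3."""


class TranslationError(HybriseqError):
    """Codon cannot be translated (e.g. contains N)."""


class CatalogError(HybriseqError):
    """Unknown species, duplicate ids, or invalid signature catalog."""


class ParameterError(HybriseqError):
    """Invalid algorithm parameter (e.g. k larger than read length)."""


class NoValidOrfError(HybriseqError):
    """No open reading frame satisfies the chain's constraints.

    Carries the longest ORF found (may be None) for diagnostics.
    """

    def __init__(self, message, longest_orf=None):
        super().__init__(message)
        self.longest_orf = longest_orf


class ReferenceCdsError(HybriseqError):
    """The full-data run yielded no reference CDS; saturation cannot proceed."""


class ReportError(HybriseqError):
    """Invalid report input (e.g. duplicate contig ids)."""
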