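"""Read-depth saturation analysis for immunoglobulin CDS recovery.

How many read pairs does the assembly-and-filter pipeline need before it
reliably reconstructs the complete heavy- and light-chain CDSs?  The
experiment: define the CDSs recovered from the *full* data set as the
reference ("correct") sequences, then repeatedly subsample the reads to
each target depth, reassemble, rerun the CDS identification, and score
a replicate as successful only if some candidate CDS string-equals the
reference exactly — a truncated or mutated CDS counts as failure.

Depths are counted in read *pairs* (fragments), the native unit of
paired-end subsampling.  Per-replicate seeds are derived as
``config.seed + replicate`` so any single replicate can be reproduced
in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .assembler import assemble, subsample_pairs
from .errors import ReferenceCdsError
from .igfilter import CdsRecord, FilterParams, find_cds_records
from .seqio import ReadPair
from .signatures import HEAVY, Signature

logger = logging.getLogger(__name__)

DEFAULT_DEPTHS = (5000, 10000, 30000, 50000, 100000, 500000, 1000000)


@dataclass
class SaturationConfig:
    """Depth grid, replication, and parameter bundles for the sweep."""

    depths: tuple[int, ...] = DEFAULT_DEPTHS
    replicates: int = 25
    seed: int = 0
    k: int = 25
    min_count: int = 1
    min_contig_len: int = 100
    filter_params: FilterParams = field(default_factory=FilterParams)

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.depths):
            raise ValueError("depths must be positive")
        if list(self.depths) != sorted(self.depths):
            raise ValueError("depths must be sorted ascending")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class SuccessRateTable:
    """Per-depth, per-gene success counts from the subsampling sweep."""

    frame: pd.DataFrame  # columns: depth, gene, successes, replicates, success_rate

    def rate(self, depth: int, gene: str) -> float:
        sel = self.frame[(self.frame.depth == depth) & (self.frame.gene == gene)]
        return float(sel.success_rate.iloc[0])

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def _split_by_gene(records: Sequence[CdsRecord]) -> dict[str, list[CdsRecord]]:
    out: dict[str, list[CdsRecord]] = {"heavy": [], "light": []}
    for rec in records:
        out["heavy" if rec.chain == HEAVY else "light"].append(rec)
    return out


def define_reference_cds(
    all_pairs: Sequence[ReadPair],
    catalog: Mapping[str, Signature],
    config: SaturationConfig | None = None,
) -> tuple[str, str]:
    """Reference (heavy, light) CDS strings from the full-data pipeline.

    The primary (longest) CDS per gene is taken; failure to recover
    either gene aborts the experiment.
    """
    config = config or SaturationConfig()
    contigs = assemble(
        all_pairs,
        k=config.k,
        min_count=config.min_count,
        min_contig_len=config.min_contig_len,
    )
    records = find_cds_records(contigs, catalog, config.filter_params)
    by_gene = _split_by_gene(records)
    missing = [g for g, recs in by_gene.items() if not recs]
    if missing:
        raise ReferenceCdsError(
            f"full-data assembly recovered no {'/'.join(missing)} CDS; "
            "cannot define reference sequences"
        )
    return tuple(
        max(by_gene[g], key=lambda r: len(r.cds)).cds for g in ("heavy", "light")
    )


def is_success(
    candidates: Sequence[CdsRecord], reference_cds: str, gene: str
) -> bool:
    """True iff some candidate CDS of ``gene`` equals the reference exactly."""
    want_heavy = gene == "heavy"
    return any(
        rec.cds == reference_cds
        for rec in candidates
        if (rec.chain == HEAVY) == want_heavy
    )


def run_saturation(
    pairs: Sequence[ReadPair],
    config: SaturationConfig,
    catalog: Mapping[str, Signature],
    reference: tuple[str, str] | None = None,
) -> SuccessRateTable:
    """Subsample/assemble/identify at each depth; tabulate success rates.

    Per-replicate failures (including assembly or extraction errors)
    count as unsuccessful and never abort the sweep.
    """
    if reference is None:
        reference = define_reference_cds(pairs, catalog, config)
    ref_heavy, ref_light = reference
    rows = []
    for depth in config.depths:
        successes = {"heavy": 0, "light": 0}
        for rep in range(config.replicates):
            sub = subsample_pairs(pairs, depth, seed=config.seed + rep)
            try:
                contigs = assemble(
                    sub,
                    k=config.k,
                    min_count=config.min_count,
                    min_contig_len=config.min_contig_len,
                )
                records = find_cds_records(contigs, catalog, config.filter_params)
            except Exception:  # pragma: no cover - counted as failure
                logger.exception(
                    "replicate %d at depth %d failed", rep, depth
                )
                records = []
            if is_success(records, ref_heavy, "heavy"):
                successes["heavy"] += 1
            if is_success(records, ref_light, "light"):
                successes["light"] += 1
        for gene in ("heavy", "light"):
            rows.append(
                {
                    "depth": depth,
                    "gene": gene,
                    "successes": successes[gene],
                    "replicates": config.replicates,
                    "success_rate": 100.0 * successes[gene] / config.replicates,
                }
            )
    return SuccessRateTable(frame=pd.DataFrame(rows))


def plot_saturation(table: SuccessRateTable, path) -> None:
    """Depth-vs-success-rate curves, one panel per gene (optional extra)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    genes = ["heavy", "light"]
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=True)
    for ax, gene in zip(axes, genes):
        sub = table.frame[table.frame.gene == gene]
        ax.plot(sub.depth, sub.success_rate, marker="o")
        ax.set_xscale("log")
        ax.set_xlabel("subsampled read pairs")
        ax.set_title(f"{gene} chain")
        ax.set_ylim(-5, 105)
    axes[0].set_ylabel("success rate (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
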