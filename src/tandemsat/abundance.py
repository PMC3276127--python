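"""Dataset coverage and per-repeat genome-proportion arithmetic.

Proportions are read-count based: a repeat family's share of the genome is
estimated as its cluster's read count over the dataset total. Reports use
half-up rounding (1 decimal for percents, 2 for coverage); raw values are
kept unrounded internally. A base-pair-weighted alternative is available
because count-based estimates can understate repeat content when coverage is
low and biased against repeats.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .errors import InputError
from .simgen import Read


def round_half_up(value: float, decimals: int = 0) -> float:
    """Round with ties away from zero (half-up), as in printed reports."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class DatasetSummary:
    """Shotgun dataset totals and the implied genome coverage."""

    n_reads: int
    mean_len_bp: float
    total_mb: float
    genome_size_mb: float
    coverage_x: float

    @property
    def coverage_x_reported(self) -> float:
        return round_half_up(self.coverage_x, 2)


def summarize_dataset(
    n_reads: int | None = None,
    total_bp: float | None = None,
    *,
    genome_size_mb: float,
    reads: list[Read] | None = None,
) -> DatasetSummary:
    """Dataset summary from either (n_reads, total_bp) or a read list.

    coverage_x = total sequenced Mb / genome size Mb.
    """
    if genome_size_mb <= 0:
        raise InputError("genome_size_mb must be > 0")
    if reads is not None:
        n_reads = len(reads)
        total_bp = sum(len(r.seq) for r in reads)
    if not n_reads or total_bp is None or total_bp <= 0:
        raise InputError("dataset contains no reads")
    total_mb = total_bp / 1e6
    return DatasetSummary(
        n_reads=n_reads,
        mean_len_bp=total_bp / n_reads,
        total_mb=total_mb,
        genome_size_mb=genome_size_mb,
        coverage_x=total_mb / genome_size_mb,
    )


def genome_proportion(cluster_n_reads: int, total_reads: int) -> float:
    """Percent of the genome attributed to a repeat family by read count.

    Returns the unrounded percent; reports round half-up to 1 decimal.
    """
    if total_reads == 0:
        raise InputError("total_reads must be > 0")
    if not 0 < cluster_n_reads <= total_reads:
        raise InputError("cluster_n_reads must lie in (0, total_reads]")
    return 100.0 * cluster_n_reads / total_reads


def genome_proportion_bp(
    cluster_total_bp: float, dataset_total_bp: float
) -> float:
    """Base-pair-weighted alternative to the count-based proportion."""
    if dataset_total_bp <= 0:
        raise InputError("dataset_total_bp must be > 0")
    if not 0 < cluster_total_bp <= dataset_total_bp:
        raise InputError("cluster_total_bp out of range")
    return 100.0 * cluster_total_bp / dataset_total_bp
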