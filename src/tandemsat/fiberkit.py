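"""Fiber-FISH signal calibration and size-category statistics.

Stretched-DNA fiber signals measured in micrometres convert to physical DNA
lengths through a stretch factor (default 3.0 kb per um, within the commonly
cited 2.9-3.3 kb/um range for extended fibers). Signals from different loci
are grouped into size categories by splitting the sorted lengths at the
largest adjacent gaps, and each category is summarized as mean +/- standard
error of the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .abundance import round_half_up
from .errors import ConfigError, InputError


@dataclass
class FiberMeasurement:
    """One fiber-FISH signal length in micrometres, with its probe and the
    ordered probe context observed at the chromosome end (e.g. TEL,CL34,CL14)."""

    id: str
    length_um: float
    probe: str = ""
    end_context: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.length_um <= 0:
            raise InputError("length_um must be > 0")


@dataclass
class SizeCategory:
    """A group of fibers of similar length: n, mean and SE (sd/sqrt(n))."""

    member_ids: list[str]
    n: int
    mean_um: float
    se_um: float


@dataclass
class StretchFactor:
    """kb of DNA per micrometre of stretched fiber."""

    kb_per_um: float = 3.0

    def __post_init__(self) -> None:
        if self.kb_per_um <= 0:
            raise ConfigError("kb_per_um must be > 0")


def um_to_kb(length_um: float, factor: StretchFactor | float = 3.0) -> float:
    """Convert a fiber length in um to kb via the stretch factor.

    Reports round half-up: kb to the nearest integer kb, Mb to the nearest
    integer Mb.
    """
    if length_um <= 0:
        raise InputError("length_um must be > 0")
    kb_per_um = factor.kb_per_um if isinstance(factor, StretchFactor) else factor
    if kb_per_um <= 0:
        raise ConfigError("stretch factor must be > 0")
    return length_um * kb_per_um


def kb_reported(kb: float) -> int:
    return int(round_half_up(kb, 0))


def mb_reported(kb: float) -> int:
    return int(round_half_up(kb / 1000.0, 0))


def locus_fraction(length_kb: float, genome_size_mb: float = 840.0) -> float:
    """Percent of the genome one locus of length_kb accounts for.

    Returns the unrounded percent; reports round half-up to 1 decimal.
    """
    if length_kb <= 0 or genome_size_mb <= 0:
        raise InputError("length_kb and genome_size_mb must be > 0")
    return 100.0 * length_kb / (1000.0 * genome_size_mb)


def _ss_partition_boundaries(lengths: np.ndarray, n_groups: int) -> list[int]:
    """Exact minimum within-group sum-of-squares ordered partition (DP)."""
    n = len(lengths)
    pre = np.concatenate([[0.0], np.cumsum(lengths)])
    pre2 = np.concatenate([[0.0], np.cumsum(lengths**2)])

    def cost(i: int, j: int) -> float:  # [i, j)
        s, s2, m = pre[j] - pre[i], pre2[j] - pre2[i], j - i
        return s2 - s * s / m

    best = np.full((n_groups + 1, n + 1), np.inf)
    back = np.zeros((n_groups + 1, n + 1), dtype=int)
    best[0, 0] = 0.0
    for c in range(1, n_groups + 1):
        for j in range(c, n + 1):
            for i in range(c - 1, j):
                val = best[c - 1, i] + cost(i, j)
                if val < best[c, j]:
                    best[c, j], back[c, j] = val, i
    boundaries, j = [], n
    for c in range(n_groups, 1, -1):
        j = back[c, j]
        boundaries.append(j)
    return sorted(boundaries)


def group_sizes(
    measurements: list[FiberMeasurement], n_groups: int, *, method: str = "gap"
) -> list[SizeCategory]:
    """Partition fiber lengths into n_groups size categories.

    The default ``gap`` method sorts lengths ascending and splits at the
    n_groups - 1 largest adjacent gaps (ties broken toward the leftmost gap):
    deterministic, order-free, and exact on well-separated data. The
    ``centroid`` method instead takes the exact minimum within-group
    sum-of-squares ordered partition. Categories are returned ordered by mean.
    """
    if n_groups < 1:
        raise ConfigError("n_groups must be >= 1")
    if method not in ("gap", "centroid"):
        raise ConfigError(f"unknown grouping method {method!r}")
    if n_groups > len(measurements):
        raise InputError("n_groups exceeds the number of measurements")
    order = sorted(measurements, key=lambda m: (m.length_um, m.id))
    lengths = np.array([m.length_um for m in order])
    if n_groups == 1:
        boundaries: list[int] = []
    elif method == "centroid":
        boundaries = _ss_partition_boundaries(lengths, n_groups)
    else:
        gaps = np.diff(lengths)
        # argsort on (-gap, index): largest gaps first, leftmost on ties
        ranked = sorted(range(len(gaps)), key=lambda i: (-gaps[i], i))
        boundaries = sorted(i + 1 for i in ranked[: n_groups - 1])
    groups = np.split(np.arange(len(order)), boundaries)
    categories = []
    for idx in groups:
        members = [order[i] for i in idx]
        vals = lengths[idx]
        se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        categories.append(
            SizeCategory(
                member_ids=[m.id for m in members],
                n=len(members),
                mean_um=float(vals.mean()),
                se_um=se,
            )
        )
    categories.sort(key=lambda c: c.mean_um)
    return categories
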