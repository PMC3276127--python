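"""Alignment-free reconstruction of tandem-repeat monomer consensi.

Satellite monomers are recovered from raw reads by oligomer-frequency
analysis: count every k-mer (k = 17 or 20) on both strands of the cluster's
reads, greedily walk between overlapping high-frequency k-mers (minimum seed
frequency 1e-4, extension threshold 10% of the current terminal k-mer's
frequency), and detect circularity — a fragment whose terminal (k-1)-mer
re-occurs at its start is a tandem monomer whose length is the cycle length.

The monomer is reported in a canonical rotation (lexicographic minimum over
all rotations of both strands) so reconstructions are orientation- and
phase-free. A positional base-frequency logo and major variant positions are
then obtained by aligning reads back onto a linearized multi-copy monomer.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from ._seq import revcomp
from .errors import InputError
from .readcluster import _best_alignment, _alignment_stats
from .simgen import Read

_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


@dataclass
class KmerTable:
    """Occurrence counts of all k-mers over both strands of a read set."""

    k: int
    counts: Counter
    total: int

    def frequency(self, kmer: str) -> float:
        return self.counts.get(kmer, 0) / self.total


@dataclass
class Fragment:
    """A greedily reconstructed high-frequency sequence fragment.

    support[i] is the frequency of the k-mer starting at position i, so
    len(support) = len(seq) - k + 1.
    """

    seq: str
    support: list[float]


@dataclass
class MonomerConsensus:
    """A circular tandem-repeat monomer in canonical rotation.

    logo is an (L, 4) matrix of per-position A/C/G/T frequencies (columns sum
    to 1); variants lists (position 1-based, prevailing base, variant base,
    variant frequency) for positions with a major second allele.
    """

    monomer: str
    length_bp: int
    circular: bool
    logo: np.ndarray | None = None
    variants: list[tuple[int, str, str, float]] = field(default_factory=list)


def kmer_frequencies(reads: list[Read], k: int) -> KmerTable:
    """Count every k-mer occurrence in every read and its reverse complement.

    k-mers containing N are skipped. total is the grand sum of counted
    occurrences, so frequency() is an occurrence fraction over both strands.
    """
    if not 2 <= k <= 31:
        raise InputError("k must be within [2, 31]")
    counts: Counter = Counter()
    for read in reads:
        for seq in (read.seq, revcomp(read.seq)):
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" not in kmer:
                    counts[kmer] += 1
    if not counts:
        raise InputError(f"no read reaches length k = {k}")
    return KmerTable(k=k, counts=counts, total=sum(counts.values()))


def reconstruct_fragments(
    table: KmerTable,
    seed_min_freq: float = 0.0001,
    extension_threshold: float = 0.10,
) -> list[Fragment]:
    """Greedy walk between overlapping high-frequency k-mers.

    Repeatedly: seed on the most frequent unused k-mer with frequency >=
    seed_min_freq; extend rightward to the most frequent of the four k-mers
    overlapping the terminal k-mer by k-1 bases, stopping when that k-mer's
    frequency drops below extension_threshold times the current terminal
    k-mer's frequency or when it was already used within the fragment (a
    wrap, i.e. a completed tandem cycle); extend leftward symmetrically;
    mark the fragment's k-mers used. Fragments are returned in descending
    order of seed frequency.
    """
    if not 0.0 < seed_min_freq < 1.0 or not 0.0 < extension_threshold < 1.0:
        raise InputError("thresholds must lie in (0, 1)")
    if table.total == 0 or not table.counts:
        raise InputError("empty k-mer table")
    k = table.k
    counts = table.counts
    # deterministic seed order: count descending, then lexicographic
    seed_order = sorted(counts, key=lambda m: (-counts[m], m))
    min_count = seed_min_freq * table.total
    used: set[str] = set()
    fragments: list[Fragment] = []

    def _extend(chain: list[str], in_fragment: set[str], rightward: bool) -> None:
        while True:
            terminal = chain[-1] if rightward else chain[0]
            if rightward:
                cands = [terminal[1:] + b for b in "ACGT"]
            else:
                cands = [b + terminal[:-1] for b in "ACGT"]
            cands = [c for c in cands if c in counts]
            if not cands:
                return
            best = max(cands, key=lambda m: (counts[m], m))
            if counts[best] < extension_threshold * counts[terminal]:
                return
            if best in in_fragment:
                return
            in_fragment.add(best)
            if rightward:
                chain.append(best)
            else:
                chain.insert(0, best)

    for seed in seed_order:
        if seed in used or counts[seed] < min_count:
            continue
        chain = [seed]
        in_fragment = {seed}
        _extend(chain, in_fragment, rightward=True)
        _extend(chain, in_fragment, rightward=False)
        used |= in_fragment
        seq = chain[0] + "".join(m[-1] for m in chain[1:])
        support = [counts[m] / table.total for m in chain]
        fragments.append(Fragment(seq=seq, support=support))
    return fragments


def canonical_rotation(monomer: str) -> str:
    """Lexicographically smallest rotation over both strands of a circular
    monomer, making reconstructions phase- and orientation-free."""
    candidates = []
    for s in (monomer, revcomp(monomer)):
        candidates.extend(s[i:] + s[:i] for i in range(len(s)))
    return min(candidates)


def circularize(fragment: Fragment, k: int) -> MonomerConsensus | None:
    """Detect a tandem wrap and emit the monomer in canonical rotation.

    A fragment circularizes when its terminal (k-1)-mer exactly re-occurs at
    its start; the monomer is the fragment with that duplicated overlap
    removed. Returns None for non-circular fragments.
    """
    seq = fragment.seq
    if len(seq) < k:
        raise InputError("fragment shorter than k")
    overlap = k - 1
    if len(seq) <= overlap or seq[-overlap:] != seq[:overlap]:
        return None
    monomer = canonical_rotation(seq[: len(seq) - overlap])
    return MonomerConsensus(monomer=monomer, length_bp=len(monomer), circular=True)


def tandem_period(seq: str, k: int) -> int | None:
    """Modal distance between successive occurrences of repeated k-mers.

    Estimates the tandem period of a sequence; returns None when fewer than
    3 distinct k-mers recur (no usable periodicity signal).
    """
    if len(seq) < 2 * k:
        raise InputError("sequence shorter than 2k")
    positions: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        positions.setdefault(seq[i : i + k], []).append(i)
    distances: Counter = Counter()
    n_repeated = 0
    for pos in positions.values():
        if len(pos) < 2:
            continue
        n_repeated += 1
        for a, b in zip(pos, pos[1:]):
            distances[b - a] += 1
    if n_repeated < 3:
        return None
    # modal distance; ties broken toward the smallest period
    return min(distances, key=lambda d: (-distances[d], d))


def positional_logo(
    reads: list[Read],
    monomer: MonomerConsensus,
    *,
    min_identity_pct: float = 70.0,
    variant_min_freq: float = 0.20,
) -> MonomerConsensus:
    """Per-position base frequencies and major variants of a monomer.

    Each read (better of the two orientations) is locally aligned to a
    three-copy linearization of the monomer; aligned bases are accumulated at
    monomer positions modulo the monomer length and columns normalized to
    frequencies. Positions where the second most frequent base exceeds
    variant_min_freq are reported as variants. Columns never covered by any
    read fall back to the monomer base at frequency 1.
    """
    if not monomer.circular:
        raise InputError("monomer must be circular")
    if not reads:
        raise InputError("no reads supplied")
    L = monomer.length_bp
    # enough tandem copies that a read of any phase aligns full-length
    longest = max(len(r.seq) for r in reads)
    ref = monomer.monomer * max(3, longest // L + 2)
    counts = np.zeros((L, 4), dtype=float)
    n_aligned = 0
    for read in reads:
        best = None
        for seq in (read.seq, revcomp(read.seq)):
            aln = _best_alignment(ref, seq)
            if aln is not None and (best is None or aln.score > best[0].score):
                best = (aln, seq)
        if best is None:
            continue
        aln, seq = best
        identities, columns, _, _ = _alignment_stats(aln)
        if columns == 0 or 100.0 * identities / columns < min_identity_pct:
            continue
        n_aligned += 1
        t_blocks, q_blocks = aln.aligned
        for (t0, t1), (q0, q1) in zip(t_blocks, q_blocks):
            for off in range(t1 - t0):
                base = seq[q0 + off]
                if base in _BASE_INDEX:
                    counts[(t0 + off) % L, _BASE_INDEX[base]] += 1.0
    if n_aligned == 0:
        raise InputError("no read aligns to the monomer above the identity gate")

    logo = np.zeros_like(counts)
    variants: list[tuple[int, str, str, float]] = []
    bases = "ACGT"
    for pos in range(L):
        col = counts[pos]
        tot = col.sum()
        if tot == 0:
            logo[pos, _BASE_INDEX[monomer.monomer[pos]]] = 1.0
            continue
        logo[pos] = col / tot
        order = np.argsort(-logo[pos], kind="stable")
        top, second = order[0], order[1]
        if logo[pos, second] > variant_min_freq:
            variants.append(
                (pos + 1, bases[top], bases[second], float(logo[pos, second]))
            )
    return MonomerConsensus(
        monomer=monomer.monomer,
        length_bp=L,
        circular=True,
        logo=logo,
        variants=variants,
    )
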