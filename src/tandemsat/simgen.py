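"""Synthetic genomes with subtelomeric satellite arrays and 454-like shotgun reads.

Emulates the statistical structure that the downstream discovery pipeline
assumes: a low-coverage (~0.5x) single-end read set over a genome carrying
long tandem arrays of unrelated monomers (a well-homogenized ~182 bp class
and a more variable ~339 bp class), with chromosome ends ordered
telomere -> distal array -> proximal array and junctions that are direct,
mixed, or contain a short unknown insert.

Every generator is a pure function of its inputs and a seed, and emits a
machine-checkable ground-truth table (0-based half-open coordinates,
strand '+'/'-') alongside the sequence.

The copy-homogenization model is a star phylogeny: each array copy is mutated
independently from a master monomer, optionally partitioned into subfamilies
that each derive their own master first. This is the simplest model that
reproduces the contrast between a well-homogenized family (no subfamilies,
low divergence) and a variable one (several subfamilies).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import revcomp, validate_nucleotides
from .errors import ConfigError, InputError

_BASES = np.array(list("ACGT"))

#: minimum simulated read length, matching the shortest informative 454 reads
MIN_READ_LEN = 50

TRUTH_COLUMNS = ["label", "start", "end", "strand", "copy_index", "n_mutations"]


@dataclass
class ArraySpec:
    """Specification of one tandem satellite array.

    divergence_rate is substitutions per base per copy relative to the master
    monomer (star phylogeny); indel_rate is insertions+deletions per base per
    copy; n_subfamilies > 1 first derives that many subfamily masters from the
    array master (at divergence_rate) and assigns copies to them round-robin.
    """

    label: str
    monomer_length_bp: int
    n_copies: int
    divergence_rate: float = 0.0
    indel_rate: float = 0.0
    n_subfamilies: int = 1

    def __post_init__(self) -> None:
        if self.monomer_length_bp < 10:
            raise ConfigError("monomer_length_bp must be >= 10")
        if self.n_copies < 1:
            raise ConfigError("n_copies must be >= 1")
        if not 0.0 <= self.divergence_rate <= 0.3:
            raise ConfigError("divergence_rate must be within [0, 0.3]")
        if self.indel_rate < 0:
            raise ConfigError("indel_rate must be >= 0")
        if self.n_subfamilies < 1:
            raise ConfigError("n_subfamilies must be >= 1")


@dataclass
class SimConfig:
    """Simulation parameters for a shotgun run over a synthetic genome.

    Defaults mirror the dataset the pipeline was designed around: mean read
    length 361 bp and 0.53x genome coverage, plant telomeric unit TTTAGGG,
    chromosome ends ordered telomere, distal array (B), proximal array (A).
    """

    seed: int
    genome_size_bp: int
    read_mean_len_bp: int = 361
    read_len_sd_bp: int = 60
    coverage_x: float = 0.53
    per_base_error_rate: float = 0.0
    array_specs: list[ArraySpec] = field(default_factory=list)
    telomere_unit: str = "TTTAGGG"
    telomere_n_units: int = 25
    gc_fraction: float = 0.4
    chromosome_end_order: tuple[str, ...] = ("telomere", "arrayB", "arrayA")

    def __post_init__(self) -> None:
        if self.coverage_x <= 0:
            raise ConfigError("coverage_x must be > 0")
        if not 0.0 <= self.per_base_error_rate < 1.0:
            raise ConfigError("per_base_error_rate must be in [0, 1)")
        total_array = sum(
            s.monomer_length_bp * s.n_copies for s in self.array_specs
        )
        if self.genome_size_bp < total_array:
            raise ConfigError(
                "genome_size_bp smaller than the summed array lengths"
            )
        if not 0.0 < self.gc_fraction < 1.0:
            raise ConfigError("gc_fraction must be in (0, 1)")


@dataclass
class Read:
    """A nucleotide read; truth records (source_label, start, end, strand)
    as a 0-based half-open interval on its source when simulated."""

    id: str
    seq: str
    truth: tuple[str, int, int, str] | None = None

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.seq)


def _random_dna(length: int, gc_fraction: float, rng: np.random.Generator) -> str:
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    return "".join(rng.choice(_BASES, size=length, p=[at, gc, gc, at]))


def make_monomer(length_bp: int, gc_fraction: float, seed: int) -> str:
    """Draw a random monomer sequence of exactly length_bp at the given GC.

    Deterministic for a fixed seed; the building block for planted arrays.
    """
    if length_bp < 10:
        raise ConfigError("length_bp must be >= 10")
    if not 0.0 < gc_fraction < 1.0:
        raise ConfigError("gc_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    return _random_dna(length_bp, gc_fraction, rng)


def make_background(length_bp: int, gc_fraction: float, seed: int) -> str:
    """Random single-copy background sequence (non-repetitive flank)."""
    if length_bp < 0:
        raise ConfigError("length_bp must be >= 0")
    rng = np.random.default_rng(seed)
    return _random_dna(length_bp, gc_fraction, rng)


def _mutate(
    seq: str,
    sub_rate: float,
    indel_rate: float,
    rng: np.random.Generator,
) -> tuple[str, int]:
    """Apply i.i.d. substitutions and indels; returns (sequence, n_mutations)."""
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    n_mut = 0
    if sub_rate > 0:
        mask = rng.random(arr.size) < sub_rate
        idx = np.nonzero(mask)[0]
        for i in idx:
            choices = [b for b in "ACGT" if b != arr[i]]
            arr[i] = choices[rng.integers(3)]
        n_mut += idx.size
    out = arr.tolist()
    if indel_rate > 0:
        result: list[str] = []
        for ch in out:
            r = rng.random()
            if r < indel_rate / 2.0:  # deletion
                n_mut += 1
                continue
            if r < indel_rate:  # insertion before the base
                result.append(str(_BASES[rng.integers(4)]))
                n_mut += 1
            result.append(ch)
        out = result
    return "".join(out), n_mut


def build_array(
    monomer: str, spec: ArraySpec, seed: int
) -> tuple[str, pd.DataFrame]:
    """Concatenate n_copies independently mutated copies of a master monomer.

    Returns the array sequence and a truth table with one row per copy
    (label, start, end, strand, copy_index, n_mutations). With indel_rate = 0
    the array length is exactly n_copies * monomer_length.
    """
    if len(monomer) != spec.monomer_length_bp:
        raise ConfigError(
            f"monomer length {len(monomer)} != spec.monomer_length_bp "
            f"{spec.monomer_length_bp}"
        )
    validate_nucleotides(monomer, context="monomer")
    rng = np.random.default_rng(seed)

    if spec.n_subfamilies > 1:
        masters = [
            _mutate(monomer, spec.divergence_rate, 0.0, rng)[0]
            for _ in range(spec.n_subfamilies)
        ]
    else:
        masters = [monomer]

    parts: list[str] = []
    rows: list[dict] = []
    pos = 0
    for i in range(spec.n_copies):
        master = masters[i % len(masters)]
        copy, n_mut = _mutate(master, spec.divergence_rate, spec.indel_rate, rng)
        parts.append(copy)
        rows.append(
            {
                "label": spec.label,
                "start": pos,
                "end": pos + len(copy),
                "strand": "+",
                "copy_index": i,
                "n_mutations": n_mut,
            }
        )
        pos += len(copy)
    return "".join(parts), pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def build_chromosome_end(
    config: SimConfig,
    arrayA: str,
    arrayB: str,
    junction_style: str,
    insert_len_bp: int = 30,
    seed: int = 0,
    *,
    label_a: str = "arrayA",
    label_b: str = "arrayB",
    max_trim_bp: int = 120,
) -> tuple[str, pd.DataFrame]:
    """Assemble one chromosome end: telomere run, array B, junction, array A.

    junction_style:
      * ``direct``  - truncated terminal monomers joined with no extra bases;
      * ``mixed``   - 1-3 alternating sub-monomer fragments of each array
        interleaved at the boundary;
      * ``insert``  - insert_len_bp of random non-repeat sequence at the
        boundary (labelled UNKNOWN in the truth table).

    The truth segments are contiguous, non-overlapping and cover the whole
    emitted sequence (0-based half-open).
    """
    if junction_style not in ("direct", "mixed", "insert"):
        raise ConfigError(f"unknown junction_style {junction_style!r}")
    if insert_len_bp < 0:
        raise ConfigError("insert_len_bp must be >= 0")
    rng = np.random.default_rng(seed)

    tel = config.telomere_unit * config.telomere_n_units
    trim_b = int(rng.integers(1, max_trim_bp + 1))
    trim_a = int(rng.integers(1, max_trim_bp + 1))
    b_part = arrayB[: len(arrayB) - trim_b]
    a_part = arrayA[trim_a:]

    segments: list[tuple[str, str]] = [("TEL", tel), (label_b, b_part)]
    if junction_style == "mixed":
        n_frag = int(rng.integers(1, 4))
        for _ in range(n_frag):
            for label, src in ((label_a, arrayA), (label_b, arrayB)):
                flen = int(rng.integers(40, 91))
                start = int(rng.integers(0, max(1, len(src) - flen)))
                segments.append((label, src[start : start + flen]))
    elif junction_style == "insert":
        segments.append(
            ("UNKNOWN", _random_dna(insert_len_bp, config.gc_fraction, rng))
        )
    segments.append((label_a, a_part))

    parts: list[str] = []
    rows: list[dict] = []
    pos = 0
    for i, (label, s) in enumerate(segments):
        parts.append(s)
        rows.append(
            {
                "label": label,
                "start": pos,
                "end": pos + len(s),
                "strand": "+",
                "copy_index": i,
                "n_mutations": 0,
            }
        )
        pos += len(s)
    return "".join(parts), pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def simulate_reads(
    genome: str, config: SimConfig, seed: int | None = None
) -> list[Read]:
    """Simulate unstranded single-end shotgun reads over a genome.

    The read count is Poisson with mean coverage_x * len(genome) /
    read_mean_len_bp; lengths follow a truncated normal (min MIN_READ_LEN,
    max the genome length); start positions are uniform; strands uniform;
    substitution errors are i.i.d. at per_base_error_rate. Truth fields give
    the genomic interval and strand of each read.
    """
    if len(genome) < MIN_READ_LEN:
        raise InputError(
            f"genome shorter than the minimum read length ({MIN_READ_LEN} bp)"
        )
    validate_nucleotides(genome, context="genome")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    g = len(genome)
    expected = config.coverage_x * g / config.read_mean_len_bp
    n_reads = int(rng.poisson(expected))

    reads: list[Read] = []
    for i in range(n_reads):
        while True:
            length = int(
                round(rng.normal(config.read_mean_len_bp, config.read_len_sd_bp))
            )
            if MIN_READ_LEN <= length <= g:
                break
        start = int(rng.integers(0, g - length + 1))
        end = start + length
        strand = "+" if rng.random() < 0.5 else "-"
        seq = genome[start:end]
        if strand == "-":
            seq = revcomp(seq)
        if config.per_base_error_rate > 0:
            seq, _ = _mutate(seq, config.per_base_error_rate, 0.0, rng)
        reads.append(
            Read(id=f"read{i:06d}", seq=seq, truth=("genome", start, end, strand))
        )
    return reads


def label_read(read: Read, truth: pd.DataFrame, min_overlap_frac: float = 0.5) -> str:
    """Majority-overlap truth label for a simulated read.

    Returns the truth-segment label covering the largest part of the read's
    source interval, or 'mixed'/'none' when no single label reaches
    min_overlap_frac of the read length.
    """
    if read.truth is None:
        raise InputError("read carries no truth record")
    _, start, end, _ = read.truth
    best_label, best_ov = "none", 0
    for row in truth.itertuples():
        ov = min(end, row.end) - max(start, row.start)
        if ov > best_ov:
            best_ov, best_label = ov, row.label
    if best_ov < min_overlap_frac * (end - start):
        return "mixed" if best_ov > 0 else "none"
    return best_label


def simulate_junction_clone(
    monomerA: str,
    monomerB: str,
    style: str,
    seed: int,
    *,
    insert_len_bp: int = 30,
    divergence: float = 0.0,
    gc_fraction: float = 0.4,
    label_a: str = "CL14",
    label_b: str = "CL34",
) -> tuple[str, str, int | None]:
    """Generate one junction-clone sequence spanning an array-array boundary.

    Mirrors the three observed junction patterns: a direct connection at
    arbitrary monomer phases, a mixture of alternating sub-monomer fragments
    of both repeats, or a short unknown insert between truncated monomers.
    Returns (sequence, expected junction type, expected insert length).

    For the insert style the insert's boundary bases are forced to differ
    from the flanking arrays' tandem continuations: an insert whose first
    base happens to extend the distal array is, as ground truth, a shorter
    insert next to a longer array, so the planted length would otherwise be
    ill-defined.
    """
    if style not in ("direct", "mixed", "insert"):
        raise ConfigError(f"unknown junction style {style!r}")
    rng = np.random.default_rng(seed)

    def _side(monomer: str) -> tuple[str, str, str]:
        """A tandem slice plus the bases just after and just before it."""
        tandem = monomer * 4
        span = int(rng.integers(150, 401))
        phase = int(rng.integers(0, len(monomer)))
        after = tandem[phase + span]
        before = tandem[phase - 1]
        return tandem[phase : phase + span], after, before

    b_side, b_after, _ = _side(monomerB)
    a_side, _, a_before = _side(monomerA)

    parts = [b_side]
    expected_insert: int | None = None
    if style == "mixed":
        n_frag = int(rng.integers(1, 4))
        for _ in range(n_frag):
            for src in (monomerA, monomerB):
                flen = int(rng.integers(40, 91))
                phase = int(rng.integers(0, len(src)))
                parts.append((src * 2)[phase : phase + flen])
        expected_type = "mixed"
    elif style == "insert":
        ins = list(_random_dna(insert_len_bp, gc_fraction, rng))
        if ins[0] == b_after:  # keep the breakpoint identifiable
            ins[0] = "ACGT"[("ACGT".index(b_after) + 1) % 4]
        if ins[-1] == a_before:
            ins[-1] = "ACGT"[("ACGT".index(a_before) + 1) % 4]
        parts.append("".join(ins))
        expected_type = "insert_containing"
        expected_insert = insert_len_bp
    else:
        expected_type = "direct"
    parts.append(a_side)

    clone = "".join(parts)
    if divergence > 0:
        clone, _ = _mutate(clone, divergence, 0.0, rng)
    return clone, expected_type, expected_insert
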