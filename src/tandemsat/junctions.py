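"""Segmentation and classification of array-junction clone sequences.

A junction clone spans the boundary between two satellite arrays or between
an array and the telomere. Each clone is tiled greedily by the
highest-identity local matches to the two monomer consensi (on a three-copy
linearization, coordinates modulo the monomer length) and by telomeric-unit
runs; residual internal gaps of at least min_insert_len become UNKNOWN
segments. The resulting segmentation is classified as a direct connection,
a mixture of fragments of both repeats, an insert-containing junction, or a
single-repeat (non-junction) clone.

Coordinates are 0-based half-open internally; report writers convert monomer
coordinates to 1-based on the monomer rotation supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

from ._seq import revcomp, validate_nucleotides
from .consensus import MonomerConsensus
from .errors import InputError
from .readcluster import _alignment_stats

TEL_UNIT = "TTTAGGG"


def _make_junction_aligner() -> Align.PairwiseAligner:
    # Stricter scoring than read clustering (match 1, mismatch -3, gap
    # open -5, extend -2): breakpoint coordinates must be tight, so
    # extending an alignment into unrelated flanking sequence has to be
    # score-negative even over a lucky stretch of chance matches.
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1.0
    aligner.mismatch_score = -3.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -2.0
    return aligner


_JUNCTION_ALIGNER = _make_junction_aligner()


def _best_alignment(target: str, query: str):
    alignments = _JUNCTION_ALIGNER.align(target, query)
    if len(alignments) == 0 or alignments.score <= 0:
        return None
    return alignments[0]


@dataclass
class JunctionSegment:
    """A labelled interval of a junction clone.

    ref_start/ref_end are positions on the circular monomer (None for TEL
    and UNKNOWN segments); identity_pct is the local-alignment identity of
    the segment against its reference.
    """

    q_start: int
    q_end: int
    label: str
    ref_start: int | None = None
    ref_end: int | None = None
    identity_pct: float = 0.0
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.q_start >= self.q_end:
            raise InputError("segment must have q_start < q_end")

    @property
    def length(self) -> int:
        return self.q_end - self.q_start


@dataclass
class JunctionCall:
    """Segmentation of one junction clone and its junction-type verdict."""

    query_id: str
    segments: list[JunctionSegment]
    junction_type: str
    insert_len_bp: int | None = None


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def scan_telomere(
    query: str,
    unit: str = TEL_UNIT,
    *,
    min_copies: int = 2,
    max_mismatch_per_copy: int = 1,
) -> list[JunctionSegment]:
    """Maximal tandem runs of the telomeric unit on either strand.

    A run is at least min_copies consecutive unit-length windows, each
    matching the unit with at most max_mismatch_per_copy substitutions.
    """
    if not query:
        raise InputError("empty query")
    validate_nucleotides(query, context="query")
    n = len(unit)
    segments: list[JunctionSegment] = []
    for strand, u in (("+", unit), ("-", revcomp(unit))):
        p = 0
        while p <= len(query) - n:
            copies = 0
            mismatches = 0
            while True:
                window = query[p + copies * n : p + (copies + 1) * n]
                if len(window) < n:
                    break
                mm = _hamming(window, u)
                if mm > max_mismatch_per_copy:
                    break
                copies += 1
                mismatches += mm
            if copies >= min_copies:
                length = copies * n
                segments.append(
                    JunctionSegment(
                        q_start=p,
                        q_end=p + length,
                        label="TEL",
                        identity_pct=100.0 * (length - mismatches) / length,
                        strand=strand,
                    )
                )
                p += length
            else:
                p += 1
    # drop runs fully contained in a longer one (other phase or strand)
    segments.sort(key=lambda s: (s.q_start, -s.q_end))
    kept: list[JunctionSegment] = []
    for seg in segments:
        if kept and seg.q_start >= kept[-1].q_start and seg.q_end <= kept[-1].q_end:
            continue
        kept.append(seg)
    return kept


def _best_circular_hit(
    sub: str,
    ref: str,
    monomer_len: int,
    min_identity_pct: float,
    min_len_bp: int,
) -> tuple[int, int, int, int, float, str] | None:
    """Best local alignment of a (sub)query against a 3-copy monomer
    linearization, both strands; returns (q0, q1, ref0, ref1, identity,
    strand) with query coords on the forward subquery, or None below the
    identity/length filters."""
    best = None
    for strand, seq in (("+", sub), ("-", revcomp(sub))):
        aln = _best_alignment(ref, seq)
        if aln is not None and (best is None or aln.score > best[0].score):
            best = (aln, strand)
    if best is None:
        return None
    aln, strand = best
    identities, columns, _, _ = _alignment_stats(aln)
    identity = 100.0 * identities / columns
    t_blocks, q_blocks = aln.aligned
    t0, t1 = int(t_blocks[0][0]), int(t_blocks[-1][1])
    q0, q1 = int(q_blocks[0][0]), int(q_blocks[-1][1])
    if strand == "-":
        q0, q1 = len(sub) - q1, len(sub) - q0
    if columns < min_len_bp or identity < min_identity_pct or q1 - q0 < min_len_bp:
        return None
    ref0 = t0 % monomer_len
    ref1 = ((t1 - 1) % monomer_len) + 1
    return q0, q1, ref0, ref1, identity, strand


def align_circular(
    query: str,
    monomer: MonomerConsensus,
    *,
    label: str = "REPEAT",
    min_identity_pct: float = 60.0,
    min_len_bp: int = 25,
) -> list[JunctionSegment]:
    """Non-overlapping local alignments of a query against a circular monomer.

    The query (both strands) is aligned to a three-copy linearization of the
    monomer; the best hit is recorded and the flanking unaligned intervals
    are re-aligned recursively. Hits below min_identity_pct or min_len_bp
    are discarded. Reference coordinates are modulo the monomer length.
    """
    if not monomer.circular:
        raise InputError("monomer must be circular")
    validate_nucleotides(query, context="query")
    L = monomer.length_bp
    # enough tandem copies that a query of any phase fits entirely
    ref = monomer.monomer * max(3, len(query) // L + 2)
    segments: list[JunctionSegment] = []
    stack = [(0, len(query))]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < min_len_bp:
            continue
        hit = _best_circular_hit(
            query[lo:hi], ref, L, min_identity_pct, min_len_bp
        )
        if hit is None:
            continue
        q0, q1, ref0, ref1, identity, strand = hit
        segments.append(
            JunctionSegment(
                q_start=lo + q0,
                q_end=lo + q1,
                label=label,
                ref_start=ref0,
                ref_end=ref1,
                identity_pct=identity,
                strand=strand,
            )
        )
        stack.append((lo, lo + q0))
        stack.append((lo + q1, hi))
    segments.sort(key=lambda s: s.q_start)
    return segments


def _best_tel_candidate(
    sub: str, unit: str, offset: int
) -> JunctionSegment | None:
    runs = scan_telomere(sub, unit)
    if not runs:
        return None
    best = max(runs, key=lambda s: (s.length, s.identity_pct, -s.q_start))
    return JunctionSegment(
        q_start=offset + best.q_start,
        q_end=offset + best.q_end,
        label="TEL",
        identity_pct=best.identity_pct,
        strand=best.strand,
    )


def classify_junction(
    query: str,
    monomerA: MonomerConsensus,
    monomerB: MonomerConsensus,
    unit: str = TEL_UNIT,
    *,
    labels: tuple[str, str] = ("CL14", "CL34"),
    min_identity_pct: float = 60.0,
    min_len_bp: int = 25,
    min_insert_len: int = 10,
    query_id: str = "query",
) -> JunctionCall:
    """Tile a junction clone by its best matches and classify the junction.

    Greedy non-overlapping tiling: within each still-unassigned interval the
    highest-identity candidate among telomere runs and local hits to either
    monomer is assigned, and the flanks are revisited. Internal residual
    gaps >= min_insert_len become UNKNOWN segments (smaller residuals are
    boundary slack). Verdicts: 'insert_containing' when an internal UNKNOWN
    exists; 'mixed' when three or more repeat segments alternate; 'direct'
    when exactly two repeat segments abut; 'single_repeat' for one label;
    'unresolved' when less than half the clone is tiled by any label.
    """
    if len(query) < 50:
        raise InputError("junction clone shorter than 50 bp")
    validate_nucleotides(query, context="query")
    label_a, label_b = labels
    # enough tandem copies that a segment of any phase fits entirely
    refs = [
        (label, m.monomer * max(3, len(query) // m.length_bp + 2), m.length_bp)
        for label, m in ((label_a, monomerA), (label_b, monomerB))
    ]

    segments: list[JunctionSegment] = []
    stack = [(0, len(query))]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < min(min_len_bp, 2 * len(unit)):
            continue
        sub = query[lo:hi]
        candidates: list[JunctionSegment] = []
        tel = _best_tel_candidate(sub, unit, lo)
        if tel is not None:
            candidates.append(tel)
        for label, ref, L in refs:
            hit = _best_circular_hit(sub, ref, L, min_identity_pct, min_len_bp)
            if hit is not None:
                q0, q1, ref0, ref1, identity, strand = hit
                candidates.append(
                    JunctionSegment(
                        q_start=lo + q0,
                        q_end=lo + q1,
                        label=label,
                        ref_start=ref0,
                        ref_end=ref1,
                        identity_pct=identity,
                        strand=strand,
                    )
                )
        if not candidates:
            continue
        best = max(
            candidates, key=lambda s: (s.identity_pct, s.length, s.label)
        )
        segments.append(best)
        stack.append((lo, best.q_start))
        stack.append((best.q_end, hi))

    segments.sort(key=lambda s: s.q_start)

    # merge adjacent same-label segments separated by sub-insert gaps
    merged: list[JunctionSegment] = []
    for seg in segments:
        if (
            merged
            and seg.label == merged[-1].label
            and seg.strand == merged[-1].strand
            and seg.q_start - merged[-1].q_end < min_insert_len
        ):
            prev = merged[-1]
            total = prev.length + seg.length
            merged[-1] = JunctionSegment(
                q_start=prev.q_start,
                q_end=seg.q_end,
                label=prev.label,
                ref_start=prev.ref_start,
                ref_end=seg.ref_end,
                identity_pct=(
                    prev.identity_pct * prev.length
                    + seg.identity_pct * seg.length
                )
                / total,
                strand=prev.strand,
            )
        else:
            merged.append(seg)

    # residual internal gaps become UNKNOWN segments
    tiled: list[JunctionSegment] = []
    for prev, nxt in zip(merged, merged[1:]):
        tiled.append(prev)
        gap = nxt.q_start - prev.q_end
        if gap >= min_insert_len:
            tiled.append(
                JunctionSegment(
                    q_start=prev.q_end, q_end=nxt.q_start, label="UNKNOWN"
                )
            )
    if merged:
        tiled.append(merged[-1])

    labelled = [s for s in tiled if s.label != "UNKNOWN"]
    unknown = [s for s in tiled if s.label == "UNKNOWN"]
    covered = sum(s.length for s in labelled)
    if covered < 0.5 * len(query):
        return JunctionCall(
            query_id=query_id,
            segments=tiled,
            junction_type="unresolved",
            insert_len_bp=None,
        )
    if unknown:
        insert_len = max(s.length for s in unknown)
        return JunctionCall(
            query_id=query_id,
            segments=tiled,
            junction_type="insert_containing",
            insert_len_bp=insert_len,
        )
    n_labels = len(labelled)
    if n_labels == 1:
        jtype = "single_repeat"
    elif n_labels == 2:
        jtype = "direct"
    else:
        jtype = "mixed"
    return JunctionCall(
        query_id=query_id, segments=tiled, junction_type=jtype, insert_len_bp=None
    )


def render_junction(call: JunctionCall, query_len: int, width: int = 72) -> str:
    """Plain-text diagram of a junction call, one ruled line per clone.

    Monomer coordinates in the per-segment lines are 1-based on the monomer
    rotation the call was made against.
    """
    scale = width / max(query_len, 1)
    track = ["."] * width
    glyph = {"TEL": "t", "UNKNOWN": "?"}
    for seg in call.segments:  # one letter per repeat label, a, b, ...
        if seg.label not in glyph:
            glyph[seg.label] = chr(ord("a") + len(glyph) - 2)
    lines = [f"{call.query_id}  [{call.junction_type}]"]
    for seg in call.segments:
        a = min(int(seg.q_start * scale), width - 1)
        b = max(min(int(seg.q_end * scale), width), a + 1)
        ch = glyph[seg.label]
        for i in range(a, b):
            track[i] = ch
        coords = (
            f" ref {seg.ref_start + 1}-{seg.ref_end} ({seg.strand})"
            if seg.ref_start is not None
            else ""
        )
        lines.append(
            f"  {seg.label:<8} {seg.q_start}-{seg.q_end}"
            f" ({seg.identity_pct:.1f}% id){coords}"
        )
    lines.insert(1, "  " + "".join(track))
    return "\n".join(lines) + "\n"
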