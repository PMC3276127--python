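"""Similarity-graph clustering of shotgun reads into repeat families.

All-vs-all pairwise local alignment builds an undirected read graph: an edge
joins two reads when their best local alignment (either orientation) reaches
90% identity over at least 55% of the longer read. Connected components of
that graph are the repeat-family clusters, and a cluster's read count over
the dataset total estimates the family's genome proportion.

Alignment is exact dynamic programming (Smith-Waterman via Biopython's
PairwiseAligner); a shared-canonical-k-mer prefilter may skip pairs that
cannot plausibly reach the thresholds, and must agree with the exhaustive
all-vs-all evaluation on small instances.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
from Bio import Align

from ._seq import canonical_kmer, revcomp, validate_nucleotides
from .errors import InputError
from .simgen import Read

#: minimum alignment columns to report a similarity hit (suppresses micro-hits)
MIN_ALIGN_COLUMNS = 30


@dataclass(frozen=True)
class SimilarityHit:
    """Best local alignment between two reads.

    identity_pct counts matches over all alignment columns (gap columns in
    the denominator); longer_cov_frac is the aligned span on the longer read
    divided by the longer read's length; strand is 'same' or 'opposite'.
    """

    read_i: str
    read_j: str
    identity_pct: float
    longer_cov_frac: float
    strand: str


@dataclass
class ReadGraph:
    """Undirected simple graph: nodes are read ids, edges are hits that
    passed both clustering thresholds."""

    nodes: list[str]
    hits: list[SimilarityHit]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for h in self.hits:
            g.add_edge(
                h.read_i,
                h.read_j,
                identity_pct=h.identity_pct,
                longer_cov_frac=h.longer_cov_frac,
                strand=h.strand,
            )
        return g


@dataclass
class Cluster:
    """A connected component of the read graph: one repeat family."""

    id: str
    read_ids: list[str]
    n_reads: int
    proportion_pct: float


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def _best_alignment(target: str, query: str):
    """Best local alignment, or None when no positive-scoring cell exists."""
    alignments = _ALIGNER.align(target, query)
    if len(alignments) == 0 or alignments.score <= 0:
        return None
    return alignments[0]


def _alignment_stats(aln) -> tuple[int, int, int, int]:
    """(identities, columns, target_span, query_span) of a local alignment."""
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    t_blocks, q_blocks = aln.aligned
    t_span = int(t_blocks[-1][1] - t_blocks[0][0])
    q_span = int(q_blocks[-1][1] - q_blocks[0][0])
    return int(counts.identities), int(columns), t_span, q_span


def pairwise_similarity(
    a: Read, b: Read, min_columns: int = MIN_ALIGN_COLUMNS
) -> SimilarityHit | None:
    """Best local alignment between two reads, considering both orientations.

    Returns None when no alignment of at least min_columns columns exists.
    """
    if not a.seq or not b.seq:
        raise InputError("empty read sequence")
    validate_nucleotides(a.seq, context=f"read {a.id}")
    validate_nucleotides(b.seq, context=f"read {b.id}")

    best = None
    for strand, query in (("same", b.seq), ("opposite", revcomp(b.seq))):
        aln = _best_alignment(a.seq, query)
        if aln is None:
            continue
        if best is None or aln.score > best[0].score:
            best = (aln, strand)
    if best is None:
        return None
    aln, strand = best
    identities, columns, t_span, q_span = _alignment_stats(aln)
    if columns < min_columns:
        return None
    # the "longer" read is picked symmetrically: by length, then sequence
    a_is_longer = (len(a.seq), a.seq) >= (len(b.seq), b.seq)
    longer_len = len(a.seq) if a_is_longer else len(b.seq)
    longer_span = t_span if a_is_longer else q_span
    return SimilarityHit(
        read_i=a.id,
        read_j=b.id,
        identity_pct=100.0 * identities / columns,
        longer_cov_frac=longer_span / longer_len,
        strand=strand,
    )


def _kmer_set(seq: str, k: int) -> frozenset[str]:
    return frozenset(
        canonical_kmer(seq[i : i + k])
        for i in range(len(seq) - k + 1)
        if "N" not in seq[i : i + k]
    )


def build_graph(
    reads: list[Read],
    identity_cutoff_pct: float = 90.0,
    coverage_cutoff_frac: float = 0.55,
    *,
    prefilter: bool = True,
    prefilter_k: int = 11,
    min_columns: int = MIN_ALIGN_COLUMNS,
) -> ReadGraph:
    """All-vs-all similarity graph thresholded at identity and coverage.

    An edge is present iff identity_pct >= identity_cutoff_pct AND
    longer_cov_frac >= coverage_cutoff_frac. With prefilter=True, pairs
    sharing no canonical prefilter_k-mer are skipped before alignment;
    prefilter=False performs the exhaustive evaluation.
    """
    if len(reads) < 2:
        raise InputError("need at least 2 reads to build a graph")
    ids = [r.id for r in reads]
    if len(set(ids)) != len(ids):
        raise InputError("duplicate read ids")

    kmer_sets = (
        {r.id: _kmer_set(r.seq, prefilter_k) for r in reads} if prefilter else None
    )
    # Score lower bound for a qualifying edge: identity I over coverage C of
    # the longer read L gives >= C*L alignment columns, each non-match column
    # (<= (1-I) of them) costing at most 2, so score >= (3I - 2) * C * L.
    # Exact (never drops a true edge) whenever I > 2/3.
    identity_frac = identity_cutoff_pct / 100.0
    score_bound_coef = (
        (3.0 * identity_frac - 2.0) * coverage_cutoff_frac
        if identity_frac > 2.0 / 3.0
        else None
    )
    hits: list[SimilarityHit] = []
    for a, b in combinations(reads, 2):
        if kmer_sets is not None and kmer_sets[a.id].isdisjoint(kmer_sets[b.id]):
            continue
        if score_bound_coef is not None:
            bound = score_bound_coef * max(len(a.seq), len(b.seq))
            best_score = max(
                _ALIGNER.score(a.seq, b.seq),
                _ALIGNER.score(a.seq, revcomp(b.seq)),
            )
            if best_score < bound:
                continue
        hit = pairwise_similarity(a, b, min_columns=min_columns)
        if (
            hit is not None
            and hit.identity_pct >= identity_cutoff_pct
            and hit.longer_cov_frac >= coverage_cutoff_frac
        ):
            hits.append(hit)
    return ReadGraph(nodes=ids, hits=hits)


def cluster_graph(graph: ReadGraph, total_reads: int) -> list[Cluster]:
    """Connected components of the read graph as repeat-family clusters.

    Singletons are excluded. Clusters are sorted by size descending, ties
    broken by the lexicographically smallest member read id, and labelled
    CL1, CL2, ... in that order. proportion_pct = 100 * n / total_reads.
    """
    if total_reads < len(graph.nodes):
        raise InputError("total_reads smaller than the number of graph nodes")
    g = graph.to_networkx()
    components = [sorted(c) for c in nx.connected_components(g) if len(c) > 1]
    components.sort(key=lambda c: (-len(c), c[0]))
    return [
        Cluster(
            id=f"CL{i + 1}",
            read_ids=comp,
            n_reads=len(comp),
            proportion_pct=100.0 * len(comp) / total_reads,
        )
        for i, comp in enumerate(components)
    ]
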