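"""End-to-end wiring: reads -> clusters -> monomer consensi -> report.

run_discovery is the library entry point used by the CLI, the demo and the
reproduction script: it clusters reads by pairwise similarity, reconstructs a
circular monomer consensus for each large cluster by k-mer-frequency
analysis, and attaches read-count genome proportions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from .abundance import genome_proportion, round_half_up, summarize_dataset
from .config import PipelineConfig
from .consensus import (
    MonomerConsensus,
    circularize,
    kmer_frequencies,
    reconstruct_fragments,
)
from .readcluster import Cluster, build_graph, cluster_graph
from .simgen import (
    ArraySpec,
    Read,
    SimConfig,
    build_array,
    make_background,
    make_monomer,
    simulate_reads,
)


@dataclass
class ClusterResult:
    """One repeat-family cluster with its reconstructed monomer (if any)."""

    cluster: Cluster
    monomer: MonomerConsensus | None


@dataclass
class DiscoveryResult:
    clusters: list[ClusterResult]
    n_reads_total: int


def consensus_for_reads(
    reads: list[Read],
    k: int,
    seed_min_freq: float = 0.0001,
    extension_threshold: float = 0.10,
) -> MonomerConsensus | None:
    """Reconstruct the monomer of one cluster; None when nothing circularizes."""
    table = kmer_frequencies(reads, k)
    fragments = reconstruct_fragments(
        table, seed_min_freq=seed_min_freq, extension_threshold=extension_threshold
    )
    for frag in fragments:
        if len(frag.seq) < k + 1:
            continue
        monomer = circularize(frag, k)
        if monomer is not None:
            return monomer
    return None


def run_discovery(
    reads: list[Read],
    *,
    k: int = 17,
    identity_cutoff_pct: float = 90.0,
    coverage_cutoff_frac: float = 0.55,
    seed_min_freq: float = 0.0001,
    extension_threshold: float = 0.10,
    min_cluster_reads: int = 5,
) -> DiscoveryResult:
    """Cluster reads and reconstruct a circular monomer per major cluster."""
    graph = build_graph(
        reads,
        identity_cutoff_pct=identity_cutoff_pct,
        coverage_cutoff_frac=coverage_cutoff_frac,
    )
    clusters = cluster_graph(graph, total_reads=len(reads))
    by_id = {r.id: r for r in reads}
    results: list[ClusterResult] = []
    for cl in clusters:
        monomer = None
        if cl.n_reads >= min_cluster_reads:
            member_reads = [by_id[i] for i in cl.read_ids]
            monomer = consensus_for_reads(
                member_reads,
                k,
                seed_min_freq=seed_min_freq,
                extension_threshold=extension_threshold,
            )
        results.append(ClusterResult(cluster=cl, monomer=monomer))
    return DiscoveryResult(clusters=results, n_reads_total=len(reads))


def demo_genome(
    seed: int,
    *,
    monomer_lengths: tuple[int, int] = (182, 339),
    n_copies: tuple[int, int] = (80, 60),
    background_bp: int = 30_000,
    divergence: float = 0.02,
) -> tuple[str, list[str]]:
    """Toy genome with two unrelated planted arrays separated by background.

    Returns the genome and the two planted master monomers.
    """
    monomers = [
        make_monomer(length, 0.4, seed * 10 + i)
        for i, length in enumerate(monomer_lengths)
    ]
    arrays = []
    for i, (monomer, n) in enumerate(zip(monomers, n_copies)):
        spec = ArraySpec(
            label=f"array{i}",
            monomer_length_bp=len(monomer),
            n_copies=n,
            divergence_rate=divergence,
        )
        arrays.append(build_array(monomer, spec, seed * 10 + 5 + i)[0])
    bg = make_background(background_bp, 0.4, seed * 10 + 9)
    third = background_bp // 3
    genome = bg[:third] + arrays[0] + bg[third : 2 * third] + arrays[1] + bg[2 * third :]
    return genome, monomers


def monomer_length_replicate(
    monomer_length: int,
    k: int,
    seed: int,
    *,
    n_copies: int = 110,
    divergence: float = 0.02,
    error_rate: float = 0.005,
    background_bp: int = 40_000,
    coverage: float = 0.53,
) -> int | None:
    """One seeded replicate of the monomer-length recovery experiment.

    Plants a tandem array of a random monomer of the given length inside
    single-copy background, simulates ~0.5x shotgun reads, clusters them, and
    reconstructs the largest cluster's monomer by k-mer consensus. Returns
    the recovered monomer length in bp, or None when nothing circularizes.
    """
    monomer = make_monomer(monomer_length, 0.4, seed)
    spec = ArraySpec(
        label="array",
        monomer_length_bp=monomer_length,
        n_copies=n_copies,
        divergence_rate=divergence,
    )
    array, _ = build_array(monomer, spec, seed + 1)
    bg = make_background(background_bp, 0.4, seed + 2)
    half = background_bp // 2
    genome = bg[:half] + array + bg[half:]
    sim = SimConfig(
        seed=seed + 3,
        genome_size_bp=len(genome),
        coverage_x=coverage,
        per_base_error_rate=error_rate,
    )
    reads = simulate_reads(genome, sim)
    result = run_discovery(reads, k=k)
    if not result.clusters or result.clusters[0].monomer is None:
        return None
    return result.clusters[0].monomer.length_bp


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate the demo genome, run discovery, and assemble a JSON-able report.

    Deterministic for a fixed config and seed: rerunning yields byte-identical
    serialized reports.
    """
    genome, _ = demo_genome(config.seed)
    sim = SimConfig(
        seed=config.seed,
        genome_size_bp=len(genome),
        per_base_error_rate=0.005,
    )
    reads = simulate_reads(genome, sim)
    result = run_discovery(
        reads,
        k=config.k,
        identity_cutoff_pct=config.identity_cutoff_pct,
        coverage_cutoff_frac=config.coverage_cutoff_frac,
        seed_min_freq=config.seed_min_freq,
        extension_threshold=config.extension_threshold,
    )
    summary = summarize_dataset(
        reads=reads, genome_size_mb=len(genome) / 1e6
    )
    report = {
        "dataset": {
            "n_reads": summary.n_reads,
            "mean_len_bp": round_half_up(summary.mean_len_bp, 1),
            "total_mb": round_half_up(summary.total_mb, 3),
            "genome_size_mb": round_half_up(summary.genome_size_mb, 3),
            "coverage_x": summary.coverage_x_reported,
        },
        "clusters": [
            {
                "id": cr.cluster.id,
                "n_reads": cr.cluster.n_reads,
                "proportion_pct": round_half_up(
                    genome_proportion(cr.cluster.n_reads, result.n_reads_total), 1
                ),
                "monomer_length_bp": cr.monomer.length_bp if cr.monomer else None,
                "monomer": cr.monomer.monomer if cr.monomer else None,
            }
            for cr in result.clusters
        ],
    }
    return report


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True) + "\n"
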