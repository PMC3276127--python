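# Methods

`tandemsat` implements a de novo satellite-repeat discovery and
characterization pipeline for low-coverage shotgun data, together with a
synthetic-data generator that emulates the genomic structures the pipeline
assumes. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic data do and do not demonstrate.

## Read clustering (`readcluster`)

Repeat families are found as clusters of mutually overlapping reads. Every
read pair is compared by exact Smith–Waterman local alignment (Biopython's
`PairwiseAligner`; match +1, mismatch −1, gap open −2, extend −1), taking the
better of the two orientations of the second read. Identity is matches over
all alignment columns — gap columns count in the denominator — and coverage
is the aligned span on the longer read divided by that read's length. An
edge joins two reads when identity ≥ 90% and coverage ≥ 55% (both
configurable); hits shorter than 30 alignment columns are never reported,
which suppresses spurious micro-hits. Clusters are the connected components
of the resulting graph, sorted by size (ties broken by the smallest member
read id) and labelled CL1, CL2, …; singletons are not clusters.

Two exact accelerations skip hopeless pairs before the full alignment:

* a shared-canonical-11-mer prefilter (pairs of unrelated random reads
  rarely share an 11-mer; overlapping reads at ≥ 90% identity essentially
  always do);
* a score prescreen: a qualifying edge with identity I > ⅔ over coverage C
  of the longer read L implies at least C·L alignment columns of which at
  most (1−I) are non-matches costing at most 2 each, so its local alignment
  score is at least (3I−2)·C·L. Pairs whose best orientation scores below
  that bound cannot form an edge. `aligner.score` is about twice as fast as
  a full traceback.

Both are validated against the exhaustive all-vs-all definition in the test
suite. Components rather than community detection: "mutually overlapping
reads" is read minimally; a community-detection switch would slot in at
`cluster_graph` but is out of scope.

## Monomer consensus by k-mer frequency (`consensus`)

Satellite monomers are reconstructed without alignment or assembly. All
k-mers (default k = 17; 20 for longer, more variable monomers) are counted
over both strands of a cluster's reads. Reconstruction is a greedy walk:

1. seed on the most frequent unused k-mer with frequency ≥ 10⁻⁴ of the
   grand total;
2. extend right to the most frequent of the four k-mers overlapping the
   terminal k-mer by k−1 bases; stop when that frequency falls below 10% of
   the **current terminal** k-mer's frequency (a locally scale-free rule)
   or when the candidate was already used inside this fragment — the latter
   is exactly what happens when a tandem cycle closes;
3. extend left symmetrically; mark the fragment's k-mers used; repeat.

A fragment whose terminal (k−1)-mer exactly re-occurs at its start is
circular: removing the duplicated overlap yields the monomer, whose length
is the cycle length. With k between 17 and 20, chance (k−1)-mer collisions
are negligible at these scales, so exact wrap detection is safe. Monomers
are reported in a canonical rotation — the lexicographic minimum over all
rotations of both strands — making reconstructions phase- and
orientation-free; reported coordinates are 1-based on that rotation. The
canonical rotation is computed by explicit minimization over all 2L
rotations (L ≤ a few hundred; no need for Booth's algorithm).

Why the expected depth supports this: a planted array of ~100 copies read
at 0.53× coverage gives each monomer-phase k-mer on the order of 50–100
occurrences per strand, while any particular substitution (divergence 2%
per copy, spread over three alternative bases) or sequencing-error k-mer
appears roughly once — far below both the seed floor and the 10% extension
threshold, so the greedy walk follows the master cycle.

Per-position base frequencies (the sequence logo) and major variants come
from aligning each cluster read (better orientation, ≥ 70% identity gate)
onto a tandem linearization of the monomer and accumulating base counts at
positions modulo the monomer length. The linearization uses
max(3, ⌊query/L⌋ + 2) copies: a fixed 3-copy reference cannot hold a query
longer than about two monomer lengths at an arbitrary phase, which would
truncate alignments. Columns never covered fall back to the monomer base at
frequency 1 so every column sums to exactly 1. A variant is reported where
the second most frequent base exceeds 0.20 — "major" variants only; the
threshold is configurable and deliberately conservative.

`tandem_period` estimates periodicity directly as the modal distance
between successive occurrences of repeated k-mers (ties toward the smaller
period; None below 3 recurring k-mers), useful for screening clusters for
tandem structure before running the full reconstruction.

## Abundance (`abundance`)

Genome proportion of a repeat family = 100 × cluster read count / total
read count. This is count-based by definition; a base-pair-weighted variant
is provided because count-based estimates can understate repeat content
when low-coverage sequencing is biased against repeats (fiber-FISH derived
locus sizes run higher than read-count estimates). Coverage = total
sequenced Mb / genome size Mb. Reports round half-up: 1 decimal for
percents, 2 for coverage; raw values stay unrounded internally.

## Junction classification (`junctions`)

Junction clones are segmented by greedy highest-identity tiling. Within
each still-unassigned interval, the candidates are (a) telomeric-unit runs
(≥ 2 tandem copies of TTTAGGG on either strand, ≤ 1 substitution per copy)
and (b) the best local alignment to a tandem linearization of each monomer
(both strands, coordinates modulo the monomer length, discarding hits below
60% identity or 25 bp). The best candidate is assigned and the flanking
intervals revisited, so segments can never overlap. Internal residual gaps
of ≥ 10 bp become UNKNOWN segments; smaller residuals are boundary slack.

Junction alignment uses stricter scoring than read clustering: match +1,
mismatch −3, gap open −5, extend −2 (BLASTN-like). Breakpoint coordinates
must be tight: with mismatch −1 a maximal local alignment profitably
extends 15+ bp into adjacent random sequence whenever a lucky stretch of
chance matches is net-positive, which visibly erodes planted inserts. With
mismatch −3 such extensions are score-negative.

Verdicts: `insert_containing` if an internal UNKNOWN exists (insert length
= the gap length); `mixed` if ≥ 3 repeat segments alternate; `direct` if
exactly two repeat segments abut; `single_repeat` for one label;
`unresolved` when less than half the clone is tiled.

## Fiber-FISH calibration (`fiberkit`)

Micrometre signal lengths convert to DNA lengths via a stretch factor,
default 3.0 kb/μm. That default is the only round value consistent with the
reference calibration pair 322 μm ↔ 966 kb; common literature values span
2.9–3.3 kb/μm and the factor is configurable. Note an arithmetic tension in
the reference values themselves: 1031 μm × 3.0 = 3093 kb is 0.368% of an
840 Mb genome, which rounds to 0.4% under half-up rounding, not the 0.3%
usually quoted for that locus. The package reports the computed value and
leaves the discrepancy to the user.

Size categories come from sorting lengths and splitting at the n−1 largest
adjacent gaps (ties toward the leftmost gap): deterministic, order-free,
and exact when categories are well separated. Each category reports n,
mean, and SE = sample sd/√n (SE 0 for singletons). An exact minimum
within-group sum-of-squares ordered partition is available as
`method="centroid"`. Known limitation: when within-category spread is
comparable to between-category gaps (as implied by the larger reference
SEs once converted to per-measurement sds), no ordered 1-D partition rule
recovers the reference 4/20/5/5/4 grouping reliably — largest-gap manages
roughly two thirds of simulated datasets and even the optimal
sum-of-squares partition about four fifths — although the true categories
almost always remain order-separable. That grouping was evidently made on
better-separated real data than an i.i.d. normal resimulation from its
summary statistics implies.

## Synthetic data (`simgen`)

The generator emulates the statistical structure the pipeline assumes, at
desk scale:

* **Arrays.** A master monomer (uniform random sequence at 40% GC — typical
  for AT-rich plant satellite neighbourhoods) is copied n times; each copy
  is independently mutated from the master (star phylogeny) at
  `divergence_rate` substitutions/base, optionally with indels, optionally
  partitioned into subfamilies that derive their own masters first. The
  star phylogeny is the simplest model that reproduces the contrast between
  a well-homogenized family and a variable, subfamily-structured one; it
  does not model concerted-evolution gradients along the array.
* **Chromosome ends.** telomere run → distal array → junction → proximal
  array. Junction styles: `direct` (truncated terminal monomers, trim
  seeded and capped at 120 bp), `mixed` (1–3 alternating sub-monomer
  fragments of 40–90 bp from each array), `insert` (a run of random
  sequence, default 30 bp). Truth tables (0-based half-open, TSV) tile the
  emitted sequence exactly.
* **Reads.** Read count ~ Poisson(coverage × genome / mean length); lengths
  truncated normal (mean 361 bp, sd 60 bp, minimum 50 bp) — only the mean
  is pinned by the reference dataset, so the dispersion is a qualitative
  match to 454 data; positions uniform; strands uniform; i.i.d.
  substitution errors.
  No homopolymer error model, no quality realism, no paired ends.

Everything is a pure function of (inputs, seed), so acceptance runs are
reproducible byte for byte.

## Problem sizes used in tests and reproduction runs

The recovery experiments plant one array of 110 copies (182 bp → ~20 kb;
339 bp → ~37 kb) inside 40 kb of background, simulate 0.53× coverage
(~90–115 reads), and run the full cluster → consensus path; 20 seeded
replicates per monomer length. These sizes keep each replicate at a few
seconds while preserving the quantities that matter for the method: ~50×
effective k-mer depth over the monomer and ~30–50 reads in the array
cluster. What passing shows: the pipeline's thresholds and greedy rules
recover exact monomer lengths and high-identity consensi under realistic
divergence (2%) and error (0.5%) at 0.5× coverage. What it does not show:
behaviour on megabase-scale read sets (the all-vs-all aligner is quadratic
and deliberately not engineered for 10⁶ reads), on 454 homopolymer error
profiles, or on satellite families with internal higher-order structure.

## Defaults

| parameter | default | meaning |
| --- | --- | --- |
| identity_cutoff_pct | 90 | minimum pairwise identity for a graph edge |
| coverage_cutoff_frac | 0.55 | minimum aligned fraction of the longer read |
| k | 17 | k-mer length for consensus (20 for the longer monomer class) |
| seed_min_freq | 1e-4 | minimum k-mer frequency to seed a fragment |
| extension_threshold | 0.10 | next/current k-mer frequency ratio to continue |
| variant_min_freq | 0.20 | second-base frequency to report a logo variant |
| min_insert_len | 10 bp | smallest residual gap called UNKNOWN |
| telomere unit | TTTAGGG | plant telomeric repeat |
| stretch factor | 3.0 kb/μm | fiber-FISH length calibration |
| genome size | 840 Mb | reference genome size for fractions |
| read length | 361 ± 60 bp | simulated shotgun read length law |
| coverage | 0.53× | simulated dataset depth |
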