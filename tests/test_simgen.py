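"""Synthetic-genome and read generators: determinism, truth tables, coverage."""

import numpy as np
import pytest
from Bio import Align
from hypothesis import given, settings
from hypothesis import strategies as st

from tandemsat import (
    ArraySpec,
    ConfigError,
    InputError,
    SimConfig,
    build_array,
    build_chromosome_end,
    label_read,
    make_background,
    make_monomer,
    simulate_junction_clone,
    simulate_reads,
)
from tandemsat._seq import revcomp


def global_identity(a: str, b: str) -> float:
    """Independent full-DP (Needleman-Wunsch) identity oracle."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -1.0
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    return counts.identities / (counts.identities + counts.mismatches + counts.gaps)


class TestMakeMonomer:
    @pytest.mark.parametrize("length", [182, 339, 10])
    def test_exact_length(self, length):
        assert len(make_monomer(length, 0.4, 1)) == length

    def test_deterministic_for_fixed_seed(self):
        assert make_monomer(339, 0.4, 1) == make_monomer(339, 0.4, 1)
        assert make_monomer(339, 0.4, 1) != make_monomer(339, 0.4, 2)

    def test_length_below_minimum_rejected(self):
        with pytest.raises(ConfigError):
            make_monomer(9, 0.5, 7)

    def test_gc_fraction_out_of_range_rejected(self):
        with pytest.raises(ConfigError):
            make_monomer(100, 1.0, 1)


class TestBuildArray:
    def test_zero_divergence_array_is_exact_repeat(self):
        monomer = make_monomer(182, 0.4, 5)
        spec = ArraySpec(label="A", monomer_length_bp=182, n_copies=100)
        array, truth = build_array(monomer, spec, 6)
        assert len(array) == 18_200
        assert all(
            array[i : i + 182] == monomer for i in range(0, 18_200, 182)
        )
        assert len(truth) == 100
        assert truth["n_mutations"].sum() == 0

    def test_single_copy_equals_one_monomer(self):
        monomer = make_monomer(50, 0.5, 3)
        spec = ArraySpec(label="A", monomer_length_bp=50, n_copies=1)
        array, truth = build_array(monomer, spec, 4)
        assert len(array) == 50
        assert len(truth) == 1

    def test_divergence_gives_expected_copy_identity(self):
        """Mean DP-alignment identity of copies vs the master ~ 1 - divergence."""
        monomer = make_monomer(339, 0.4, 7)
        spec = ArraySpec(
            label="B", monomer_length_bp=339, n_copies=50, divergence_rate=0.05
        )
        array, truth = build_array(monomer, spec, 8)
        identities = [
            global_identity(array[row.start : row.end], monomer)
            for row in truth.itertuples()
        ]
        assert abs(float(np.mean(identities)) - 0.95) < 0.01

    def test_truth_table_tiles_array(self):
        monomer = make_monomer(100, 0.4, 9)
        spec = ArraySpec(
            label="A", monomer_length_bp=100, n_copies=20,
            divergence_rate=0.03, indel_rate=0.01,
        )
        array, truth = build_array(monomer, spec, 10)
        assert truth["start"].iloc[0] == 0
        assert truth["end"].iloc[-1] == len(array)
        assert (truth["start"].values[1:] == truth["end"].values[:-1]).all()

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(
        length=st.integers(10, 60),
        n_copies=st.integers(1, 20),
        divergence=st.floats(0.0, 0.3),
        seed=st.integers(0, 10_000),
    )
    def test_length_exact_without_indels(self, length, n_copies, divergence, seed):
        monomer = make_monomer(length, 0.5, seed)
        spec = ArraySpec(
            label="A", monomer_length_bp=length, n_copies=n_copies,
            divergence_rate=divergence,
        )
        array, _ = build_array(monomer, spec, seed + 1)
        assert len(array) == length * n_copies


class TestBuildChromosomeEnd:
    def _config(self, n_units=25):
        return SimConfig(seed=0, genome_size_bp=10**6, telomere_n_units=n_units)

    def _arrays(self):
        ma = make_monomer(182, 0.4, 1)
        mb = make_monomer(339, 0.4, 2)
        arr_a, _ = build_array(
            ma, ArraySpec(label="A", monomer_length_bp=182, n_copies=20), 3
        )
        arr_b, _ = build_array(
            mb, ArraySpec(label="B", monomer_length_bp=339, n_copies=10), 4
        )
        return arr_a, arr_b

    def test_insert_style_places_exact_unknown_segment(self):
        arr_a, arr_b = self._arrays()
        _, truth = build_chromosome_end(
            self._config(), arr_a, arr_b, "insert", insert_len_bp=30, seed=5
        )
        unknown = truth[truth["label"] == "UNKNOWN"]
        assert len(unknown) == 1
        row = unknown.iloc[0]
        assert row.end - row.start == 30
        labels = list(truth["label"])
        i = labels.index("UNKNOWN")
        assert labels[i - 1] == "arrayB" and labels[i + 1] == "arrayA"

    def test_direct_style_abuts_arrays_with_no_unknown(self):
        arr_a, arr_b = self._arrays()
        _, truth = build_chromosome_end(
            self._config(), arr_a, arr_b, "direct", seed=6
        )
        assert "UNKNOWN" not in set(truth["label"])
        b_end = truth[truth["label"] == "arrayB"]["end"].iloc[0]
        a_start = truth[truth["label"] == "arrayA"]["start"].iloc[0]
        assert b_end == a_start

    def test_telomere_run_length_is_units_times_seven(self):
        arr_a, arr_b = self._arrays()
        seq, truth = build_chromosome_end(
            self._config(n_units=20), arr_a, arr_b, "direct", seed=7
        )
        first = truth.iloc[0]
        assert first.label == "TEL"
        assert first.start == 0 and first.end == 20 * 7
        assert seq[:140] == "TTTAGGG" * 20

    @pytest.mark.parametrize("style", ["direct", "mixed", "insert"])
    def test_truth_segments_tile_sequence(self, style):
        arr_a, arr_b = self._arrays()
        seq, truth = build_chromosome_end(
            self._config(), arr_a, arr_b, style, seed=8
        )
        assert truth["start"].iloc[0] == 0
        assert truth["end"].iloc[-1] == len(seq)
        assert (truth["start"].values[1:] == truth["end"].values[:-1]).all()

    def test_unknown_style_rejected(self):
        arr_a, arr_b = self._arrays()
        with pytest.raises(ConfigError):
            build_chromosome_end(self._config(), arr_a, arr_b, "bogus", seed=9)


class TestSimulateReads:
    def test_read_count_matches_coverage(self):
        genome = make_background(1_000_000, 0.4, 11)
        config = SimConfig(seed=12, genome_size_bp=len(genome))
        reads = simulate_reads(genome, config)
        expected = 0.53 * 1_000_000 / 361  # 1468.1
        assert abs(len(reads) - expected) <= 3 * np.sqrt(expected)

    def test_zero_error_reads_are_exact_substrings(self):
        genome = make_background(20_000, 0.4, 13)
        config = SimConfig(seed=14, genome_size_bp=len(genome))
        reads = simulate_reads(genome, config)
        rc = revcomp(genome)
        assert reads, "no reads simulated"
        for read in reads:
            assert read.seq in genome or read.seq in rc

    def test_truth_interval_matches_sequence(self):
        genome = make_background(20_000, 0.4, 15)
        config = SimConfig(seed=16, genome_size_bp=len(genome))
        for read in simulate_reads(genome, config):
            _, start, end, strand = read.truth
            expected = genome[start:end]
            if strand == "-":
                expected = revcomp(expected)
            assert read.seq == expected

    def test_deterministic_for_fixed_seed(self):
        genome = make_background(20_000, 0.4, 17)
        config = SimConfig(
            seed=18, genome_size_bp=len(genome), per_base_error_rate=0.01
        )
        r1 = simulate_reads(genome, config)
        r2 = simulate_reads(genome, config)
        assert [(r.id, r.seq, r.truth) for r in r1] == [
            (r.id, r.seq, r.truth) for r in r2
        ]

    def test_genome_shorter_than_min_read_rejected(self):
        with pytest.raises(InputError):
            simulate_reads("ACGT" * 10, SimConfig(seed=1, genome_size_bp=40))

    def test_coverage_conserved_over_seeds(self):
        """Mean realized coverage over 20 seeds is within 3 SE of the target."""
        genome = make_background(100_000, 0.4, 19)
        ratios = []
        for seed in range(20):
            config = SimConfig(seed=seed, genome_size_bp=len(genome))
            reads = simulate_reads(genome, config)
            ratios.append(sum(len(r.seq) for r in reads) / len(genome))
        mean = float(np.mean(ratios))
        se = float(np.std(ratios, ddof=1) / np.sqrt(len(ratios)))
        assert abs(mean - 0.53) <= 3 * se

    def test_label_read_recovers_source_segment(self):
        monomer = make_monomer(100, 0.4, 20)
        array, _ = build_array(
            monomer, ArraySpec(label="sat", monomer_length_bp=100, n_copies=50), 21
        )
        bg = make_background(5_000, 0.4, 22)
        genome = bg + array
        import pandas as pd

        truth = pd.DataFrame(
            [
                {"label": "background", "start": 0, "end": 5000},
                {"label": "sat", "start": 5000, "end": len(genome)},
            ]
        )
        config = SimConfig(seed=23, genome_size_bp=len(genome), coverage_x=1.0)
        reads = simulate_reads(genome, config)
        for read in reads:
            _, start, end, _ = read.truth
            mid = (start + end) / 2
            expected = "background" if mid < 5000 else "sat"
            got = label_read(read, truth)
            if got != "mixed":
                assert got == expected


class TestJunctionClones:
    @pytest.mark.parametrize(
        "style,expected_type",
        [
            ("direct", "direct"),
            ("mixed", "mixed"),
            ("insert", "insert_containing"),
        ],
    )
    def test_styles_report_expected_type(self, style, expected_type):
        ma = make_monomer(182, 0.4, 30)
        mb = make_monomer(339, 0.4, 31)
        clone, etype, insert = simulate_junction_clone(ma, mb, style, seed=32)
        assert etype == expected_type
        assert len(clone) >= 300
        if style == "insert":
            assert insert == 30
        else:
            assert insert is None

    def test_unknown_style_rejected(self):
        ma = make_monomer(182, 0.4, 33)
        mb = make_monomer(339, 0.4, 34)
        with pytest.raises(ConfigError):
            simulate_junction_clone(ma, mb, "weird", seed=35)
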