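"""Shared fixtures: a planted two-array read set used across modules."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from tandemsat import ArraySpec, Read, build_array, make_background, make_monomer
from tandemsat._seq import revcomp
from tandemsat.simgen import _mutate


@dataclass
class PlantedInstance:
    reads: list[Read]
    labels: dict[str, str]  # read id -> arrayA / arrayB / background
    monomer_a: str  # 182 bp master
    monomer_b: str  # 339 bp master


def _sample_reads(
    source: str,
    n: int,
    label: str,
    prefix: str,
    rng: np.random.Generator,
    error_rate: float = 0.005,
) -> tuple[list[Read], dict[str, str]]:
    reads, labels = [], {}
    for i in range(n):
        length = int(rng.integers(120, 181))
        start = int(rng.integers(0, len(source) - length + 1))
        seq = source[start : start + length]
        if rng.random() < 0.5:
            seq = revcomp(seq)
        if error_rate > 0:
            seq, _ = _mutate(seq, error_rate, 0.0, rng)
        rid = f"{prefix}{i:03d}"
        reads.append(Read(id=rid, seq=seq))
        labels[rid] = label
    return reads, labels


@pytest.fixture(scope="session")
def planted_instance() -> PlantedInstance:
    """50 reads each from a 182 bp array, a 339 bp array, and single-copy
    background, with truth labels. Built once per session."""
    rng = np.random.default_rng(20240)
    mono_a = make_monomer(182, 0.4, 100)
    mono_b = make_monomer(339, 0.4, 101)
    arr_a, _ = build_array(
        mono_a,
        ArraySpec(label="arrayA", monomer_length_bp=182, n_copies=60,
                  divergence_rate=0.02),
        102,
    )
    arr_b, _ = build_array(
        mono_b,
        ArraySpec(label="arrayB", monomer_length_bp=339, n_copies=40,
                  divergence_rate=0.02),
        103,
    )
    bg = make_background(40_000, 0.4, 104)
    reads: list[Read] = []
    labels: dict[str, str] = {}
    for source, label, prefix in (
        (arr_a, "arrayA", "a"),
        (arr_b, "arrayB", "b"),
        (bg, "background", "g"),
    ):
        r, l = _sample_reads(source, 50, label, prefix, rng)
        reads.extend(r)
        labels.update(l)
    return PlantedInstance(
        reads=reads, labels=labels, monomer_a=mono_a, monomer_b=mono_b
    )
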