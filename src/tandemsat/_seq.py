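"""Small sequence utilities shared across modules."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
VALID_CHARS = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case A/C/G/T/N sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_nucleotides(seq: str, *, context: str = "sequence") -> None:
    """Raise InputError when seq contains characters outside {A,C,G,T,N}."""
    from .errors import InputError

    bad = set(seq) - VALID_CHARS
    if bad:
        raise InputError(
            f"{context} contains non-nucleotide characters: {sorted(bad)!r}"
        )


def canonical_kmer(kmer: str) -> str:
    """The lexicographically smaller of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc
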