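"""Small DNA-string primitives shared across the pipeline.

All sequence handling in ampsel is substitution-only: amplicon alleles are
identified by exact merged-read length, so indel-tolerant matching would
corrupt the length semantics. Hamming distance with an early-exit budget is
therefore the only comparison primitive needed, and it is deliberately the
only one provided.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_dna(seq: str) -> bool:
    """True iff ``seq`` is non-empty and drawn from {A,C,G,T}."""
    return bool(seq) and set(seq) <= DNA_ALPHABET


def hamming(a: str, b: str, limit: int | None = None) -> int:
    """Substitutions between equal-length strings, early-exiting past ``limit``.

    Returns a value > ``limit`` (not the exact distance) once the budget is
    exceeded, which is all callers need for accept/reject decisions.
    """
    if len(a) != len(b):
        raise ValueError(f"hamming requires equal lengths ({len(a)} vs {len(b)})")
    if a == b:
        return 0
    d = 0
    if limit is None:
        for x, y in zip(a, b):
            if x != y:
                d += 1
        return d
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return d
    return d
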