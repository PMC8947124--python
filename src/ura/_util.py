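"""Shared low-level sequence helpers."""

from __future__ import annotations

_RC_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


def canonical(seq: str) -> str:
    """Lexicographic minimum of a sequence and its reverse complement.

    Uniqueness and read lookup are strand-agnostic: a read and its reverse
    complement are the same observation, so both are keyed by this form.
    """
    rc = seq.translate(_RC_TABLE)[::-1]
    return seq if seq <= rc else rc
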