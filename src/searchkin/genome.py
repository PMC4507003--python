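"""Synthetic genome sequences with planted motif instances."""

from __future__ import annotations

from typing import Sequence

import numpy as np
from Bio.Seq import Seq

#: Canonical 19-bp tetO operator recognized by TetR.
TETO_MOTIF = "TCCCTATCAGTGATAGAGA"

_BASES = np.array(list("ACGT"))


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def generate_genome(
    length_bp: int,
    gc: float = 0.5,
    planted: Sequence[tuple[str, int, str]] = (),
    seed: int = 0,
) -> str:
    """Random genome with i.i.d. bases at GC fraction ``gc``.

    ``planted`` lists (sequence, 0-based position, strand); minus-strand
    entries are written as their reverse complement on the plus strand.
    Planted sites must fit within the genome and must not overlap.
    """
    if not 0 <= gc <= 1:
        raise ValueError("gc must be in [0, 1]")
    if length_bp < 1:
        raise ValueError("length_bp must be >= 1")
    occupied: list[tuple[int, int]] = []
    for seq, pos, strand in planted:
        if strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {strand!r}")
        end = pos + len(seq)
        if pos < 0 or end > length_bp:
            raise ValueError(f"planted site at {pos} does not fit in genome of {length_bp} bp")
        for s, e in occupied:
            if pos < e and s < end:
                raise ValueError(f"planted sites overlap at position {pos}")
        occupied.append((pos, end))

    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(_BASES, size=length_bp, p=p)
    for seq, pos, strand in planted:
        ins = seq if strand == "+" else reverse_complement(seq)
        arr[pos : pos + len(ins)] = list(ins.upper())
    return "".join(arr)
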