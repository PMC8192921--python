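"""Position-incidence descriptors of a nucleotide sequence.

All positions are 1-based.  Base order everywhere is the fixed alphabet
order A, C, G, T.

* ``frequency_vector`` — per-base occurrence counts (sums to n).
* ``aapiv`` — per-base sums of occurrence positions (sums to n(n+1)/2).
* ``raapiv`` — the same on the reversed sequence.
* ``prim`` — 4x4 matrix whose (p, q) entry aggregates the positions of
  base q relative to the first occurrence of base p.
* ``rprim`` — PRIM of the reversed sequence.

The PRIM aggregate is, by default, the *signed* sum
``sum_j (pos_j(q) - firstpos(p))``; an absolute-value convention is
available via ``convention="absolute"``.  If base p never occurs its row
is zero (no first occurrence exists); if base q never occurs the entry is
an empty sum, hence zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequence_io import ALPHABET, NucleotideSequence

PRIM_CONVENTIONS = ("signed", "absolute")


@dataclass(frozen=True)
class IncidenceMatrix:
    """4x4 base-to-base relative-position matrix (PRIM or RPRIM)."""

    entries: np.ndarray
    kind: str  # "PRIM" | "RPRIM"


@dataclass(frozen=True)
class FrequencyVector:
    counts: np.ndarray  # A, C, G, T occurrence counts


@dataclass(frozen=True)
class PositionSumVector:
    sums: np.ndarray  # A, C, G, T position sums
    direction: str  # "forward" | "reverse"


def _positions(seq: NucleotideSequence) -> dict[str, np.ndarray]:
    """1-based occurrence positions of each base."""
    arr = np.frombuffer(seq.bases.encode("ascii"), dtype=np.uint8)
    return {b: np.flatnonzero(arr == ord(b)) + 1 for b in ALPHABET}


def frequency_vector(seq: NucleotideSequence) -> FrequencyVector:
    counts = np.array([seq.bases.count(b) for b in ALPHABET], dtype=np.int64)
    return FrequencyVector(counts=counts)


def aapiv(seq: NucleotideSequence) -> PositionSumVector:
    pos = _positions(seq)
    sums = np.array([pos[b].sum() for b in ALPHABET], dtype=np.int64)
    return PositionSumVector(sums=sums, direction="forward")


def raapiv(seq: NucleotideSequence) -> PositionSumVector:
    forward = aapiv(seq.reverse())
    return PositionSumVector(sums=forward.sums, direction="reverse")


def prim(seq: NucleotideSequence, convention: str = "signed") -> IncidenceMatrix:
    if convention not in PRIM_CONVENTIONS:
        raise ValueError(
            f"unknown PRIM convention {convention!r}; expected one of {PRIM_CONVENTIONS}"
        )
    pos = _positions(seq)
    entries = np.zeros((4, 4), dtype=np.int64)
    for i, p in enumerate(ALPHABET):
        if pos[p].size == 0:
            continue  # absent base: row stays zero
        first = pos[p][0]
        for j, q in enumerate(ALPHABET):
            rel = pos[q] - first
            entries[i, j] = np.abs(rel).sum() if convention == "absolute" else rel.sum()
    return IncidenceMatrix(entries=entries, kind="PRIM")


def rprim(seq: NucleotideSequence, convention: str = "signed") -> IncidenceMatrix:
    base = prim(seq.reverse(), convention=convention)
    return IncidenceMatrix(entries=base.entries, kind="RPRIM")
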