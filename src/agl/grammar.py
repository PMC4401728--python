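"""Nested and cross-serial dependency grammars over the syllable lexicon.

A well-formed sequence is A1..An followed by the paired B syllables, with
the B-part in reversed pair order (nested, a mirror language — context-free)
or in identical pair order (cross-serial, a copy language — mildly
context-sensitive).  This module provides the constructor, the membership
recognizer, and the dependency-structure/distance bookkeeping that the
memory-cost argument (distance = number of intervening elements) rests on.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from .errors import CategoryError, DuplicatePairError, SequenceError
from .lexicon import Lexicon


class DependencyType(Enum):
    """The two dependency grammars under study."""

    NESTED = "nested"
    CROSS_SERIAL = "cross_serial"

    @property
    def chomsky_level(self) -> str:
        return ("context-free" if self is DependencyType.NESTED
                else "mildly context-sensitive")

    @property
    def other(self) -> "DependencyType":
        return (DependencyType.CROSS_SERIAL if self is DependencyType.NESTED
                else DependencyType.NESTED)

    @classmethod
    def parse(cls, name: str) -> "DependencyType":
        key = name.strip().lower().replace("-", "_")
        aliases = {"nested": cls.NESTED, "cross_serial": cls.CROSS_SERIAL,
                   "cross": cls.CROSS_SERIAL, "crossserial": cls.CROSS_SERIAL}
        try:
            return aliases[key]
        except KeyError:
            raise ValueError(f"unknown dependency type {name!r}") from None


@dataclass(frozen=True)
class DependencyStructure:
    """Link positions and intervening distances for an n-pair sequence.

    ``links[i]`` is the 0-based ``(a_position, b_position)`` of link i+1,
    links reported outermost-first (nested) / leftmost-first (cross-serial)
    to match the conventional subscripts A1..An.  ``distances[i]`` counts
    the elements strictly between the two linked positions.
    """

    n_pairs: int
    dependency: DependencyType
    links: tuple[tuple[int, int], ...]
    distances: tuple[int, ...]
    has_dummy: bool = False


def dependency_structure(n_pairs: int, dep: DependencyType,
                         dummy: bool = False) -> DependencyStructure:
    """Compute link positions and intervening distances.

    For nested dependencies link i connects positions (i-1, 2n-i), giving
    distance 2(n-i): the outermost link spans the whole sequence, the
    innermost pair is adjacent.  For cross-serial dependencies link i
    connects (i-1, n+i-1), a constant distance of n-1.  With ``dummy=True``
    a single filler occupies the midpoint, shifting every B position right
    by one and adding one to every distance.
    """
    if n_pairs < 1:
        raise SequenceError(f"n_pairs must be >= 1, got {n_pairs}")
    n = n_pairs
    pad = 1 if dummy else 0
    links, dists = [], []
    for i in range(1, n + 1):
        if dep is DependencyType.NESTED:
            a, b = i - 1, 2 * n - i + pad
        else:
            a, b = i - 1, n + i - 1 + pad
        links.append((a, b))
        dists.append(b - a - 1)
    return DependencyStructure(n, dep, tuple(links), tuple(dists), dummy)


def arrange_b_part(a_sequence: Sequence[str], dep: DependencyType,
                   lexicon: Lexicon) -> tuple[str, ...]:
    """Extend an A-part to the full 2n-syllable sequence under ``dep``.

    The B-part is the paired B syllables in reversed (nested) or identical
    (cross-serial) pair order.  Raises CategoryError for non-A input and
    DuplicatePairError if a pair is reused within the sequence.
    """
    pair_ids = []
    for text in a_sequence:
        s = lexicon.lookup(text)
        if s.category != "A":
            raise CategoryError(f"{text!r} is category {s.category}, expected A")
        pair_ids.append(s.pair_id)
    if len(set(pair_ids)) != len(pair_ids):
        raise DuplicatePairError(f"duplicate pair in A-part {tuple(a_sequence)}")
    b_order = reversed(pair_ids) if dep is DependencyType.NESTED else pair_ids
    return tuple(a_sequence) + tuple(lexicon.b_of(p) for p in b_order)


def is_member(sequence: Sequence[str], dep: DependencyType, lexicon: Lexicon,
              dummy: str | None = None) -> bool:
    """Membership test: all-A first half, all-B second half, pair order
    matching ``dep``.

    Structural defects (odd length, unknown syllable, misplaced dummy) raise
    rather than return False: they mean the input is not a candidate string
    at all.  With ``dummy`` set, the sequence must carry exactly one dummy
    syllable at its midpoint, which is stripped before the core check.
    """
    seq = list(sequence)
    if dummy is not None:
        mid = len(seq) // 2
        if len(seq) % 2 == 0 or seq[mid] != dummy or seq.count(dummy) != 1:
            raise SequenceError("dummy mode requires odd length with the dummy at the midpoint")
        seq = seq[:mid] + seq[mid + 1:]
    if not seq or len(seq) % 2:
        raise SequenceError(f"sequence length must be even and positive, got {len(seq)}")
    entries = [lexicon.lookup(t) for t in seq]
    n = len(seq) // 2
    if any(e.category != "A" for e in entries[:n]):
        return False
    if any(e.category != "B" for e in entries[n:]):
        return False
    a_ids = [e.pair_id for e in entries[:n]]
    b_ids = [e.pair_id for e in entries[n:]]
    expected = a_ids[::-1] if dep is DependencyType.NESTED else a_ids
    return b_ids == expected


def insert_dummy(sequence: Sequence[str], dep: DependencyType,
                 dummy_syllable: str, lexicon: Lexicon) -> tuple[str, ...]:
    """Insert a filler syllable between the A-part and the B-part.

    The input must be a member of ``dep``; the result (e.g.
    A1 A2 A3 D B3 B2 B1) increases every dependency's intervening distance
    by one and removes the nested grammar's adjacent innermost pair.
    """
    if not is_member(sequence, dep, lexicon):
        raise SequenceError("can only insert a dummy into a grammatical sequence")
    mid = len(sequence) // 2
    return tuple(sequence[:mid]) + (dummy_syllable,) + tuple(sequence[mid:])
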