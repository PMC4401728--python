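"""The 20-pair syllable lexicon used to realize the artificial languages.

Each pair couples one category-A syllable (vowel 'e' or 'i') with one
category-B syllable (vowel 'o' or 'u'); A syllables fill the first half of a
stimulus sequence and their paired B syllables the second half.  Pair
identity is an explicit table lookup, never recomputed from shared onset
letters: several entries share a first letter ('sted', 'sek', 'schip'), so
an onset rule would misclassify.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from .errors import UnknownSyllableError

A_VOWELS = frozenset("ei")
B_VOWELS = frozenset("ou")
_VOWELS = frozenset("aeiou")

#: The default stimulus material: (class A, class B), in table order.
DEFAULT_PAIRS: tuple[tuple[str, str], ...] = (
    ("del", "dol"),
    ("sted", "stod"),
    ("bem", "bom"),
    ("jelz", "jolz"),
    ("pfes", "pfos"),
    ("schip", "schop"),
    ("riw", "row"),
    ("fid", "fod"),
    ("hiz", "hoz"),
    ("zib", "zob"),
    ("lef", "luf"),
    ("sek", "suk"),
    ("kem", "kum"),
    ("pegs", "pugs"),
    ("wel", "wul"),
    ("tix", "tux"),
    ("miv", "muv"),
    ("nist", "nust"),
    ("xim", "xum"),
    ("gid", "gud"),
)


@dataclass(frozen=True)
class Syllable:
    """One lexicon entry: its string, A/B category, pair id, and vowel."""

    text: str
    category: str  # "A" or "B"
    pair_id: int   # 1-based table row

    @property
    def vowel(self) -> str:
        for ch in self.text:
            if ch in _VOWELS:
                return ch
        raise ValueError(f"syllable {self.text!r} has no vowel")


class Lexicon:
    """Ordered collection of (A, B) syllable pairs with lookup by string.

    Parameters
    ----------
    pairs
        Iterable of ``(a_text, b_text)`` tuples.  Defaults to the embedded
        20-pair table.
    """

    def __init__(self, pairs: Iterable[tuple[str, str]] | None = None):
        raw = tuple(tuple(p) for p in (pairs if pairs is not None else DEFAULT_PAIRS))
        self._syllables: dict[str, Syllable] = {}
        self._pairs: list[tuple[Syllable, Syllable]] = []
        for i, (a_text, b_text) in enumerate(raw, start=1):
            a = Syllable(a_text, "A", i)
            b = Syllable(b_text, "B", i)
            for s in (a, b):
                if s.text in self._syllables:
                    raise ValueError(f"duplicate syllable {s.text!r}")
                if s.category == "A" and s.vowel not in A_VOWELS:
                    raise ValueError(f"A syllable {s.text!r} violates the vowel rule")
                if s.category == "B" and s.vowel not in B_VOWELS:
                    raise ValueError(f"B syllable {s.text!r} violates the vowel rule")
                self._syllables[s.text] = s
            self._pairs.append((a, b))

    def __len__(self) -> int:
        return len(self._pairs)

    def __contains__(self, text: str) -> bool:
        return text in self._syllables

    def __iter__(self) -> Iterator[tuple[Syllable, Syllable]]:
        return iter(self._pairs)

    @property
    def pair_ids(self) -> tuple[int, ...]:
        return tuple(range(1, len(self._pairs) + 1))

    def lookup(self, text: str) -> Syllable:
        try:
            return self._syllables[text]
        except KeyError:
            raise UnknownSyllableError(text) from None

    def category(self, text: str) -> str:
        """A/B category of a syllable, by table lookup."""
        return self.lookup(text).category

    def pair_id(self, text: str) -> int:
        return self.lookup(text).pair_id

    def pair(self, pair_id: int) -> tuple[Syllable, Syllable]:
        return self._pairs[pair_id - 1]

    def a_of(self, pair_id: int) -> str:
        return self._pairs[pair_id - 1][0].text

    def b_of(self, pair_id: int) -> str:
        return self._pairs[pair_id - 1][1].text

    def partner(self, text: str) -> str:
        """The other member of a syllable's pair."""
        s = self.lookup(text)
        a, b = self._pairs[s.pair_id - 1]
        return b.text if s.category == "A" else a.text

    # -- CSV round trip ----------------------------------------------------

    def to_csv(self, path: str | Path | None = None) -> str:
        """Serialize as CSV (pair_id, class_a, class_b); return the text."""
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(["pair_id", "class_a", "class_b"])
        for i, (a, b) in enumerate(self._pairs, start=1):
            writer.writerow([i, a.text, b.text])
        text = buf.getvalue()
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_csv(cls, source: str | Path) -> "Lexicon":
        """Load a lexicon from a CSV file path or CSV text."""
        text = source if isinstance(source, str) and "\n" in source else Path(source).read_text(encoding="utf-8")
        rows = list(csv.reader(io.StringIO(text)))
        if not rows or rows[0] != ["pair_id", "class_a", "class_b"]:
            raise ValueError("lexicon CSV must have header pair_id,class_a,class_b")
        return cls((r[1], r[2]) for r in rows[1:] if r)


def load_lexicon() -> Lexicon:
    """Return the embedded default 20-pair lexicon."""
    return Lexicon()


def classify_syllable(text: str, lexicon: Lexicon) -> str:
    """A/B category of ``text``; raises UnknownSyllableError if absent."""
    return lexicon.category(text)
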