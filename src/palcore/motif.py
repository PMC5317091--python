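"""Degenerate nucleotide patterns with case-annotated conservation.

A pattern is a string over ``{A, C, G, T, N}`` in which case carries
meaning: uppercase marks a highly conserved position, lowercase a weakly
conserved one.  ``N``/``n`` is a wildcard matching any base.  Matching is
case-insensitive; case is only an annotation layer.

The mismatch model is ungapped Hamming distance evaluated at non-wildcard
positions.  An ``N`` in the *genome* window at a non-wildcard pattern
position counts as a mismatch, so masked or ambiguous genome stretches can
never produce spurious exact hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

_ALPHABET = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: The 18-nt palindrome core scanned throughout this package: four wildcard
#: positions (1, 9, 10, 18) around two conserved 7-bp inverted arms.
PALINDROME_CORE = "nAACCGTTnnAACGGTTn"

#: The full case-annotated consensus of the repeat family the core derives
#: from (lowercase = weakly conserved flanking/central positions).
REPEAT_CONSENSUS = "aAACCGTTgaAACGGTTt"

#: Generalized Rex repressor operator consensus (NADH/NAD+ redox sensor).
REX_CONSENSUS = "TTGTGAANNNNTTCACAA"


def complement(base: str) -> str:
    """Watson-Crick complement of a single base (case preserved)."""
    return base.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DegeneratePattern:
    """A degenerate, case-annotated nucleotide pattern.

    Parameters
    ----------
    text
        Pattern string over ``{A,C,G,T,N}``, case-insensitively.  Case is
        preserved: uppercase marks highly conserved positions.

    Attributes
    ----------
    wildcard_positions
        1-based positions holding ``N``/``n``.
    conserved_positions
        1-based positions that are uppercase and not wildcards.
    """

    text: str

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("pattern must be non-empty")
        for i, ch in enumerate(self.text, start=1):
            if ch.upper() not in _ALPHABET:
                raise ValueError(
                    f"invalid pattern character {ch!r} at position {i}"
                )

    @property
    def length(self) -> int:
        return len(self.text)

    @cached_property
    def upper(self) -> str:
        return self.text.upper()

    @cached_property
    def wildcard_positions(self) -> frozenset[int]:
        return frozenset(
            i for i, ch in enumerate(self.upper, start=1) if ch == "N"
        )

    @cached_property
    def conserved_positions(self) -> frozenset[int]:
        return frozenset(
            i
            for i, ch in enumerate(self.text, start=1)
            if ch.isupper() and ch != "N"
        )

    @cached_property
    def is_self_reverse_complementary(self) -> bool:
        """True when the pattern equals its own reverse complement
        (case-insensitively) — a degenerate palindrome."""
        return self.upper == revcomp(self.upper)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.length

    def __str__(self) -> str:
        return self.text


def parse_pattern(text: str) -> DegeneratePattern:
    """Parse a pattern string, validating the alphabet.

    Raises
    ------
    ValueError
        If the string is empty or contains a character outside
        ``{A,C,G,T,N}`` (case-insensitive); the error names the offending
        1-based position.
    """
    return DegeneratePattern(text)


def mismatch_count(pattern: DegeneratePattern | str, window: str) -> int:
    """Hamming distance between a pattern and an equal-length window.

    Wildcard pattern positions are skipped; everywhere else the window
    base must equal the pattern base (case-insensitive).  A window ``N``
    at a non-wildcard position counts as a mismatch.
    """
    if isinstance(pattern, str):
        pattern = DegeneratePattern(pattern)
    if len(window) != pattern.length:
        raise ValueError(
            f"window length {len(window)} != pattern length {pattern.length}"
        )
    pu = pattern.upper
    wu = window.upper()
    return sum(
        1 for p, w in zip(pu, wu) if p != "N" and (w != p or w == "N")
    )


def reverse_complement(pattern: DegeneratePattern) -> DegeneratePattern:
    """Reverse complement of a pattern, carrying the case annotation with
    the positions it belongs to (an involution)."""
    return DegeneratePattern(revcomp(pattern.text))


def palindromic_positions(pattern: DegeneratePattern) -> frozenset[int]:
    """1-based non-wildcard positions i whose base complements the base at
    the mirror position w+1-i.  Wildcard mirrors never qualify."""
    w = pattern.length
    pu = pattern.upper
    out = set()
    for i in range(1, w + 1):
        a, b = pu[i - 1], pu[w - i]
        if a != "N" and b != "N" and a == complement(b):
            out.add(i)
    return frozenset(out)


def conserved_palindromic_count(pattern: DegeneratePattern) -> int:
    """Number of positions that are both palindromic and highly conserved
    (uppercase)."""
    return len(palindromic_positions(pattern) & pattern.conserved_positions)
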