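"""Two-symbol event sequences and their probability estimates.

The test of uncertainty reduction asks whether observing event A makes a
later event B more likely than its base rate: it compares the lag-k
conditional probability P(B_{+k} | A) with the marginal P(B).  This module
parses an ordered sequence of A/B tokens and estimates those probabilities
by counting.

Conventions
-----------
* Positions are 1-based in documentation and error messages.
* Marginal probabilities use the full sequence length n.
* An occurrence of A within the final k positions has no successor at
  lag k and is excluded from the antecedent count, so
  ``count_a_then_b <= count_a`` holds structurally.
* Only two-symbol alphabets are accepted; the test is defined for two
  complementary events.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .errors import (
    DegenerateSequenceError,
    LagError,
    ParseError,
    SequenceLengthError,
)

__all__ = [
    "EventSequence",
    "EventProbabilities",
    "parse_event_sequence",
    "read_event_file",
    "write_event_file",
    "estimate_probabilities",
]

_SEPARATORS = re.compile(r"[\s,;]+")


@dataclass(frozen=True)
class EventSequence:
    """An ordered realization of two complementary events.

    ``tokens`` is the observed sequence; every token equals ``symbol_a``
    or ``symbol_b``.  ``n`` is the sequence length.
    """

    tokens: tuple[str, ...]
    symbol_a: str = "A"
    symbol_b: str = "B"

    def __post_init__(self) -> None:
        if self.symbol_a == self.symbol_b:
            raise ParseError("the two event symbols must differ")
        if len(self.tokens) < 2:
            raise SequenceLengthError(
                f"an event sequence needs at least 2 tokens, got {len(self.tokens)}"
            )
        alphabet = {self.symbol_a, self.symbol_b}
        for pos, tok in enumerate(self.tokens, start=1):
            if tok not in alphabet:
                raise ParseError(
                    f"unknown symbol {tok!r} at position {pos} "
                    f"(alphabet is {{{self.symbol_a!r}, {self.symbol_b!r}}})"
                )

    @property
    def n(self) -> int:
        return len(self.tokens)

    def relabeled(self) -> "EventSequence":
        """Swap the roles of the two symbols (A <-> B)."""
        return EventSequence(
            tokens=self.tokens,
            symbol_a=self.symbol_b,
            symbol_b=self.symbol_a,
        )

    def __str__(self) -> str:
        return " ".join(self.tokens)


@dataclass(frozen=True)
class EventProbabilities:
    """Counting estimates behind the uncertainty-reduction statistic.

    Attributes
    ----------
    p_a, p_b
        Marginal occurrence probabilities, estimated over all n positions.
    p_b_given_a_lag
        P(B_{+k} | A): among positions i <= n-k holding A, the fraction
        whose position i+k holds B.
    count_a
        Eligible antecedents (occurrences of A at positions 1..n-k).
    count_a_then_b
        Those antecedents followed by B at lag k.
    n, k
        Sequence length and lag.
    """

    p_a: float
    p_b: float
    p_b_given_a_lag: float
    count_a: int
    count_a_then_b: int
    n: int
    k: int


def parse_event_sequence(
    text: str,
    symbol_a: str = "A",
    symbol_b: str = "B",
) -> EventSequence:
    """Parse a token stream into an :class:`EventSequence`.

    Tokens are separated by whitespace, commas or semicolons; lines whose
    first non-blank character is ``#`` are comments.  Order is preserved
    exactly.  An unknown symbol raises :class:`ParseError` naming its
    1-based position; fewer than 2 tokens raises
    :class:`SequenceLengthError`.
    """
    tokens: list[str] = []
    for line in text.splitlines() or [text]:
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        tokens.extend(t for t in _SEPARATORS.split(stripped) if t)
    return EventSequence(tuple(tokens), symbol_a=symbol_a, symbol_b=symbol_b)


def read_event_file(path: str | Path, symbol_a: str = "A", symbol_b: str = "B") -> EventSequence:
    """Read an event file: plain text or single-column CSV of tokens."""
    return parse_event_sequence(Path(path).read_text(), symbol_a=symbol_a, symbol_b=symbol_b)


def write_event_file(seq: EventSequence, path: str | Path) -> None:
    """Write a sequence in the plain-text event file format (round-trips)."""
    Path(path).write_text(" ".join(seq.tokens) + "\n")


def estimate_probabilities(seq: EventSequence, k: int = 1) -> EventProbabilities:
    """Estimate marginal and lag-k conditional probabilities by counting.

    Raises
    ------
    LagError
        If not ``1 <= k <= n - 1``.
    DegenerateSequenceError
        If no position in ``1..n-k`` holds A, leaving P(B_{+k}|A)
        undefined.
    """
    n = seq.n
    if not 1 <= k <= n - 1:
        raise LagError(f"lag must satisfy 1 <= k <= n-1 = {n - 1}, got k={k}")
    a, b = seq.symbol_a, seq.symbol_b
    n_a = sum(1 for t in seq.tokens if t == a)
    n_b = n - n_a
    count_a = 0
    count_a_then_b = 0
    for i in range(n - k):  # 0-based i; antecedent positions 1..n-k
        if seq.tokens[i] == a:
            count_a += 1
            if seq.tokens[i + k] == b:
                count_a_then_b += 1
    if count_a == 0:
        raise DegenerateSequenceError(
            f"no occurrence of {a!r} among positions 1..{n - k}; "
            f"P(B_+{k}|A) is undefined"
        )
    return EventProbabilities(
        p_a=n_a / n,
        p_b=n_b / n,
        p_b_given_a_lag=count_a_then_b / count_a,
        count_a=count_a,
        count_a_then_b=count_a_then_b,
        n=n,
        k=k,
    )
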