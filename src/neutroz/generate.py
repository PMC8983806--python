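"""Synthetic event-sequence generation and the packaged worked example.

The generator produces two-symbol sequences with a lag-k Markov coupling:
the symbol at position i+k is B with probability ``p_b_given_a`` whenever
position i holds A, and otherwise follows the baseline marginal (A with
probability ``p_a``).  This is the simplest dependence structure matching
the alternative hypothesis of the uncertainty-reduction test; setting
``p_b_given_a = 1 - p_a`` removes the coupling entirely and yields an
i.i.d. sequence, the null case.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from .errors import ValidationError
from .events import EventSequence, parse_event_sequence

__all__ = ["covid19_sequence", "generate_fixture"]


def covid19_sequence() -> EventSequence:
    """The packaged 12-token Covid-19 worked-example sequence.

    Event A is a reduction in Covid-19 deaths, event B an increase in
    vaccinations; the analysis asks whether A reduces uncertainty about a
    B one step later.
    """
    text = resources.files("neutroz").joinpath("data/covid19_sequence.txt").read_text()
    return parse_event_sequence(text)


def generate_fixture(
    n: int,
    p_a: float = 0.5,
    p_b_given_a: float = 0.5,
    k: int = 1,
    seed: int | None = None,
) -> EventSequence:
    """Generate a seeded lag-k coupled event sequence of length ``n``.

    Positions 1..k are drawn from the baseline (A with probability
    ``p_a``).  Each later position i+k is B with probability
    ``p_b_given_a`` if position i holds A, else baseline.  The empirical
    P(B_{+k}|A) converges to ``p_b_given_a`` as n grows.
    """
    if not 0.0 < p_a < 1.0 or not 0.0 < p_b_given_a < 1.0:
        raise ValidationError(
            f"probabilities must lie strictly in (0,1); got p_a={p_a}, p_b_given_a={p_b_given_a}"
        )
    if k < 1:
        raise ValidationError(f"lag must be >= 1, got k={k}")
    if n < k + 1:
        raise ValidationError(f"need n >= k+1 = {k + 1}, got n={n}")
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    p_b_baseline = 1.0 - p_a
    tokens: list[str] = []
    for i in range(n):
        if i >= k and tokens[i - k] == "A":
            p_b = p_b_given_a
        else:
            p_b = p_b_baseline
        tokens.append("B" if u[i] < p_b else "A")
    return EventSequence(tuple(tokens))
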