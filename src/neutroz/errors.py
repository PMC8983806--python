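"""Exception hierarchy shared across the package.

All library errors derive from :class:`NeutrozError` so callers (and the
CLI) can catch one type and turn it into a diagnostic.
"""


class NeutrozError(ValueError):
    """Base class for all neutroz validation and parse errors."""


class ParseError(NeutrozError):
    """A token stream or grid file could not be parsed."""


class SequenceLengthError(NeutrozError):
    """An event sequence is too short for the requested analysis."""


class LagError(NeutrozError):
    """The lag k is outside 1 <= k <= n - 1."""


class DegenerateSequenceError(NeutrozError):
    """No eligible antecedent: the lag-k conditional probability is undefined."""


class DegenerateProbabilityError(NeutrozError):
    """A marginal probability of 0 or 1 makes the Z denominator vanish."""


class ValidationError(NeutrozError):
    """A configuration value is outside its admissible range."""
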