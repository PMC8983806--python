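"""Neutrosophic scalar quantities.

A neutrosophic quantity extends a classical scalar with an indeterminate
part: ``X_N = X_L + X_U * I`` where ``X_L`` is the determinate (classical)
component, ``X_U`` the coefficient of indeterminacy, and ``I`` ranges over
a measure-of-indeterminacy interval ``[I_L, I_U]``.  Evaluating the form at
the two ends of the interval yields the interval representation
``X_N in [X_L + X_U*I_L, X_L + X_U*I_U]``.  With ``I = [0, 0]`` the
quantity collapses to its classical value.

This module stores the *form* (determinate part, coefficient, indeterminacy
interval) and derives the interval, because the test statistic and the
indeterminacy sweep are defined on the form.  Constructors from either
representation are provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

from .errors import ValidationError

__all__ = ["IndeterminacyInterval", "NeutrosophicValue"]


@dataclass(frozen=True)
class IndeterminacyInterval:
    """A measure-of-indeterminacy interval ``[lower, upper]``.

    Both ends are nonnegative and ``lower <= upper``.  ``[0, 0]``
    represents the classical (fully determinate) case.  Values above 1 are
    permitted: the indeterminacy is a scale factor, not a probability.
    """

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.lower < 0 or self.upper < 0:
            raise ValidationError(
                f"indeterminacy endpoints must be >= 0, got [{self.lower}, {self.upper}]"
            )
        if self.lower > self.upper:
            raise ValidationError(
                f"indeterminacy interval requires lower <= upper, got [{self.lower}, {self.upper}]"
            )

    @property
    def is_zero(self) -> bool:
        return self.lower == 0.0 and self.upper == 0.0

    @classmethod
    def classical(cls) -> "IndeterminacyInterval":
        return cls(0.0, 0.0)

    def __iter__(self):
        yield self.lower
        yield self.upper

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.lower:g}, {self.upper:g}]"


@dataclass(frozen=True)
class NeutrosophicValue:
    """A scalar in neutrosophic form ``determinate + coeff * I``.

    Parameters
    ----------
    determinate
        The determinate (classical, lower) part, e.g. ``A_L``.  May be
        negative: a Z statistic can point either way.
    coeff
        The coefficient multiplying the indeterminacy, e.g. ``A_U``.
    indeterminacy
        The interval the indeterminacy ``I`` ranges over.
    """

    determinate: float
    coeff: float
    indeterminacy: IndeterminacyInterval

    def endpoints(self) -> tuple[float, float]:
        """Evaluate the form at both ends of the indeterminacy interval.

        Returns ``(determinate + coeff*I_L, determinate + coeff*I_U)``,
        normalized so the first element never exceeds the second (a
        negative coefficient flips the orientation).
        """
        a = self.determinate + self.coeff * self.indeterminacy.lower
        b = self.determinate + self.coeff * self.indeterminacy.upper
        return (a, b) if a <= b else (b, a)

    def is_classical(self) -> bool:
        """True iff the indeterminacy interval is exactly ``[0, 0]``."""
        return self.indeterminacy.is_zero

    @classmethod
    def from_endpoints(
        cls,
        lower: float,
        upper: float,
        indeterminacy: IndeterminacyInterval,
    ) -> "NeutrosophicValue":
        """Build the form from an interval ``[lower, upper]``.

        The coefficient is chosen so the form evaluates back to the given
        endpoints over ``indeterminacy``.  A degenerate indeterminacy
        interval only admits a degenerate value interval.
        """
        if lower > upper:
            raise ValidationError(f"interval requires lower <= upper, got [{lower}, {upper}]")
        span = indeterminacy.upper - indeterminacy.lower
        if span == 0.0:
            if lower != upper:
                raise ValidationError(
                    "a degenerate indeterminacy interval cannot carry a non-degenerate value interval"
                )
            return cls(lower, 0.0, indeterminacy)
        coeff = (upper - lower) / span
        determinate = lower - coeff * indeterminacy.lower
        return cls(determinate, coeff, indeterminacy)

    def to_dict(self) -> dict[str, Any]:
        return {
            "determinate": self.determinate,
            "coeff": self.coeff,
            "I": [self.indeterminacy.lower, self.indeterminacy.upper],
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "NeutrosophicValue":
        lo, hi = d["I"]
        return cls(float(d["determinate"]), float(d["coeff"]), IndeterminacyInterval(lo, hi))

    def __str__(self) -> str:
        return (
            f"{self.determinate:g} + {self.coeff:g}*I; "
            f"I in {self.indeterminacy}"
        )
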