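"""The neutrosophic Z-test for reduction of uncertainty.

The classical statistic compares the lag-k conditional probability of B
after A with the marginal probability of B::

    Z = ( P(B_{+k}|A) - P(B) ) / sqrt( P(B)[1-P(B)][1-P(A)] / ((n-k) P(A)) )

Large positive values mean observing A sharply reduces uncertainty about a
later B.  The neutrosophic extension scales the statistic by (1 + I_ZN)
with the measure of indeterminacy I_ZN ranging over an interval
[I_ZL, I_ZU], giving an interval-valued statistic [Z_L, Z_U].  With
I_ZN = [0, 0] the test reduces exactly to the classical Z-test for
uncertainty events.

Two rounding modes are offered.  ``exact`` (the default) carries full
floating-point precision.  ``paper`` reproduces desk arithmetic commonly
used when the statistic is computed by hand from values printed to two
decimals: the conditional probability and the square-root denominator are
rounded to 2 decimals before dividing, the quotient is rounded to 2
decimals, and scaled endpoints are reported to 2 decimals.  The two modes
differ in the third decimal for typical inputs; ``paper`` exists so that
published worked examples can be verified digit-for-digit.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal

from scipy.stats import norm

from .core import IndeterminacyInterval
from .errors import DegenerateProbabilityError, ValidationError
from .events import EventProbabilities

__all__ = [
    "RoundingMode",
    "NeutrosophicZResult",
    "TestDecision",
    "Verdict",
    "z_statistic_endpoint",
    "z_statistic_neutrosophic",
    "critical_value",
    "decide",
]


class RoundingMode(str, enum.Enum):
    EXACT = "exact"
    PAPER = "paper"


class Verdict(str, enum.Enum):
    REJECT = "reject"
    ACCEPT = "accept"
    INDETERMINATE = "indeterminate"


def _round2(x: float) -> float:
    """Half-up rounding to 2 decimals, as done in desk arithmetic."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _truncate2(x: float) -> float:
    """Truncation (toward zero) to 2 decimals.

    Published sweep tables report the scaled endpoint (1+I)*Z with its
    trailing digits dropped rather than rounded (2.20*1.04 = 2.288 appears
    as 2.28), so the paper rounding mode truncates here.
    """
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_DOWN))


def _scale_endpoint(determinate: float, indet: float, mode: RoundingMode) -> float:
    """Evaluate (1 + I) * Z at one end of the indeterminacy interval."""
    if mode is RoundingMode.PAPER:
        scaled = Decimal(repr(determinate)) * (1 + Decimal(repr(indet)))
        return float(scaled.quantize(Decimal("0.01"), rounding=ROUND_DOWN))
    return determinate * (1.0 + indet)


@dataclass(frozen=True)
class NeutrosophicZResult:
    """Interval-valued statistic [Z_L, Z_U] with its neutrosophic form.

    ``determinate`` is the classical statistic (the lower-endpoint data's
    Z), which is also the coefficient of the indeterminate part in the
    factored form ``Z_N = Z + Z*I_ZN``.  In exact mode
    ``z_lower = determinate*(1+I_ZL)`` and ``z_upper`` is the upper-data
    statistic times ``(1+I_ZU)``; with I = [0,0] both endpoints equal the
    determinate part.
    """

    z_lower: float
    z_upper: float
    determinate: float
    indeterminacy: IndeterminacyInterval
    form_text: str
    rounding_mode: RoundingMode

    def to_dict(self) -> dict:
        return {
            "z_lower": self.z_lower,
            "z_upper": self.z_upper,
            "determinate": self.determinate,
            "I": [self.indeterminacy.lower, self.indeterminacy.upper],
            "form": self.form_text,
            "rounding_mode": self.rounding_mode.value,
        }


@dataclass(frozen=True)
class TestDecision:
    """Outcome of comparing [Z_L, Z_U] with the critical value.

    ``reject`` requires both endpoints above the critical value,
    ``accept`` neither; an interval straddling the critical value yields
    the third, ``indeterminate``, verdict.
    """

    alpha: float
    critical_value: float
    reject_lower: bool
    reject_upper: bool
    verdict: Verdict

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "critical_value": self.critical_value,
            "reject_lower": self.reject_lower,
            "reject_upper": self.reject_upper,
            "verdict": self.verdict.value,
        }


def _validate_probs(p: EventProbabilities) -> None:
    if not 0.0 < p.p_a < 1.0 or not 0.0 < p.p_b < 1.0:
        raise DegenerateProbabilityError(
            f"marginal probabilities must lie strictly in (0,1); "
            f"got P(A)={p.p_a}, P(B)={p.p_b} (zero-variance denominator)"
        )


def z_statistic_endpoint(
    probs: EventProbabilities,
    n: int | None = None,
    k: int | None = None,
    rounding_mode: RoundingMode | str = RoundingMode.EXACT,
) -> float:
    """The classical statistic at one data endpoint.

    ``n`` and ``k`` default to the values recorded in ``probs``; the
    denominator uses ``n - k`` directly.
    """
    mode = RoundingMode(rounding_mode)
    _validate_probs(probs)
    n = probs.n if n is None else n
    k = probs.k if k is None else k
    if n <= k:
        raise ValidationError(f"need n > k, got n={n}, k={k}")
    p_a, p_b = probs.p_a, probs.p_b
    p_cond = probs.p_b_given_a_lag
    denom = math.sqrt(p_b * (1.0 - p_b) * (1.0 - p_a) / ((n - k) * p_a))
    if mode is RoundingMode.PAPER:
        p_cond = _round2(p_cond)
        denom = _round2(denom)
        if denom == 0.0:
            raise DegenerateProbabilityError("denominator rounds to 0.00 in paper mode")
        return _round2((p_cond - p_b) / denom)
    return (p_cond - p_b) / denom


def z_statistic_neutrosophic(
    probs_lower: EventProbabilities,
    probs_upper: EventProbabilities | None = None,
    i_z: IndeterminacyInterval = IndeterminacyInterval(0.0, 0.0),
    rounding_mode: RoundingMode | str = RoundingMode.EXACT,
    form: str = "factored",
) -> NeutrosophicZResult:
    """Interval-valued statistic [Z_L, Z_U] under indeterminacy ``i_z``.

    Each endpoint statistic is computed from its own data (``probs_upper``
    defaults to ``probs_lower``, the common case of point-valued data).
    Two algebraic forms of the neutrosophic statistic exist:

    * ``factored`` (default): each endpoint scaled by its own factor,
      ``Z_L = T_L*(1+I_ZL)``, ``Z_U = T_U*(1+I_ZU)`` — the form used in
      worked examples and sweeps;
    * ``additive``: the form ``T_L + T_U*I_ZN`` evaluated at the interval
      ends, ``Z_L = T_L + T_U*I_ZL``, ``Z_U = T_L + T_U*I_ZU``.

    The two coincide whenever the endpoint data coincide.
    """
    mode = RoundingMode(rounding_mode)
    if form not in ("factored", "additive"):
        raise ValidationError(f"form must be 'factored' or 'additive', got {form!r}")
    if probs_upper is None:
        probs_upper = probs_lower
    t_lower = z_statistic_endpoint(probs_lower, rounding_mode=mode)
    if probs_upper is probs_lower:
        t_upper = t_lower
    else:
        t_upper = z_statistic_endpoint(probs_upper, rounding_mode=mode)

    if form == "factored":
        z_lo = _scale_endpoint(t_lower, i_z.lower, mode)
        z_hi = _scale_endpoint(t_upper, i_z.upper, mode)
    else:
        z_lo = t_lower + t_upper * i_z.lower
        z_hi = t_lower + t_upper * i_z.upper
        if mode is RoundingMode.PAPER:
            z_lo, z_hi = _truncate2(z_lo), _truncate2(z_hi)

    if mode is RoundingMode.PAPER:
        coeff_txt = f"{t_lower:.2f} + {t_upper:.2f}*I_ZN"
    else:
        coeff_txt = f"{t_lower:g} + {t_upper:g}*I_ZN"
    form_text = f"{coeff_txt}; I_ZN in [{i_z.lower:g}, {i_z.upper:g}]"

    return NeutrosophicZResult(
        z_lower=z_lo,
        z_upper=z_hi,
        determinate=t_lower,
        indeterminacy=i_z,
        form_text=form_text,
        rounding_mode=mode,
    )


def critical_value(alpha: float) -> float:
    """Standard-normal quantile at 1 - alpha/2.

    The test is upper-tailed in substance (reject for large Z), but the
    customary critical value 1.96 at alpha = 0.05 is the two-sided
    quantile; this function follows that convention.  Callers may pass an
    explicit critical value to :func:`decide` to override it.
    """
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha must lie in (0, 1), got {alpha}")
    return float(norm.ppf(1.0 - alpha / 2.0))


def decide(
    z: NeutrosophicZResult,
    alpha: float = 0.05,
    critical: float | None = None,
) -> TestDecision:
    """Compare each endpoint of [Z_L, Z_U] with the critical value.

    The null hypothesis (no reduction in uncertainty) is rejected when
    both endpoints exceed the critical value and retained when neither
    does; a straddling interval — where the truth of the rejection itself
    depends on the indeterminacy — yields ``indeterminate``.
    """
    crit = critical_value(alpha) if critical is None else critical
    lo, hi = min(z.z_lower, z.z_upper), max(z.z_lower, z.z_upper)
    reject_lower = lo > crit
    reject_upper = hi > crit
    if reject_lower and reject_upper:
        verdict = Verdict.REJECT
    elif not reject_lower and not reject_upper:
        verdict = Verdict.ACCEPT
    else:
        verdict = Verdict.INDETERMINATE
    return TestDecision(
        alpha=alpha,
        critical_value=crit,
        reject_lower=reject_lower,
        reject_upper=reject_upper,
        verdict=verdict,
    )
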