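"""Indeterminacy sweeps and Monte-Carlo power comparison.

Two studies accompany the interval-valued Z-test:

* a deterministic *sweep* that recomputes [Z_L, Z_U] and the verdict over
  a grid of indeterminacy intervals, showing how the gap between the
  statistic and the critical value widens as the indeterminacy grows;
* a seeded Monte-Carlo *power study* comparing the classical test with the
  indeterminacy-scaled test under an explicit generative model: statistics
  are drawn from Normal(effect_mean, 1) under the alternative, the
  classical test rejects when z > z_crit, and the scaled test rejects when
  (1 + I_U) * z > z_crit.  The two tests are evaluated on common random
  draws, shared across the whole indeterminacy grid, so the dominance of
  the scaled test (every classical rejection is also a scaled rejection
  when the effect is positive) holds draw-for-draw rather than only in
  expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal

import numpy as np

from .core import IndeterminacyInterval, NeutrosophicValue
from .errors import ValidationError
from .events import EventProbabilities
from .ztest import (
    RoundingMode,
    Verdict,
    critical_value,
    decide,
    z_statistic_neutrosophic,
)

__all__ = [
    "SweepRow",
    "PowerConfig",
    "PowerRow",
    "DEFAULT_SWEEP_GRID",
    "indeterminacy_sweep",
    "sample_neutrosophic_normal",
    "power_study",
]


def _default_grid() -> tuple[IndeterminacyInterval, ...]:
    # 0 to 0.20 in steps of 0.01, then 0.3 to 1.0 in steps of 0.1, then 2.
    uppers = [Decimal(i) / 100 for i in range(21)]
    uppers += [Decimal(i) / 10 for i in range(3, 11)]
    uppers += [Decimal(2)]
    return tuple(IndeterminacyInterval(0.0, float(u)) for u in uppers)


#: The 30-interval grid [0, I_U] customarily tabulated: I_U from 0 to 0.20
#: in steps of 0.01, 0.3 to 1.0 in steps of 0.1, and 2.
DEFAULT_SWEEP_GRID: tuple[IndeterminacyInterval, ...] = _default_grid()


@dataclass(frozen=True)
class SweepRow:
    indeterminacy: IndeterminacyInterval
    z_lower: float
    z_upper: float
    verdict: Verdict


@dataclass(frozen=True)
class PowerConfig:
    """Configuration of the Monte-Carlo power comparison.

    ``effect_mean`` is the mean of the sampled statistic under the
    alternative hypothesis (the classical mean is 0 under the null);
    ``indeterminacy_grid`` lists the intervals whose upper ends scale the
    proposed test's statistic; ``replicates`` draws are shared across the
    grid and between the two tests.
    """

    effect_mean: float
    indeterminacy_grid: tuple[IndeterminacyInterval, ...] = field(
        default_factory=lambda: tuple(
            IndeterminacyInterval(0.0, u)
            for u in (0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.75, 1.0)
        )
    )
    replicates: int = 100
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValidationError(f"replicates must be >= 1, got {self.replicates}")
        if not self.indeterminacy_grid:
            raise ValidationError("indeterminacy_grid must be nonempty")


@dataclass(frozen=True)
class PowerRow:
    indeterminacy_upper: float
    power_existing: float
    power_proposed: float
    replicates: int


def indeterminacy_sweep(
    probs: EventProbabilities,
    grid: tuple[IndeterminacyInterval, ...] = DEFAULT_SWEEP_GRID,
    alpha: float = 0.05,
    rounding_mode: RoundingMode | str = RoundingMode.EXACT,
    critical: float | None = None,
) -> list[SweepRow]:
    """Recompute [Z_L, Z_U] and the verdict for each grid interval.

    Rows preserve grid order.  The data (and hence the determinate
    statistic) are fixed; only the indeterminacy varies, so in exact mode
    Z_U/Z_L - 1 = I_ZU along a [0, I_U] grid.
    """
    if not grid:
        raise ValidationError("sweep grid must be nonempty")
    rows: list[SweepRow] = []
    for interval in grid:
        z = z_statistic_neutrosophic(probs, i_z=interval, rounding_mode=rounding_mode)
        d = decide(z, alpha=alpha, critical=critical)
        rows.append(SweepRow(interval, z.z_lower, z.z_upper, d.verdict))
    return rows


def sample_neutrosophic_normal(
    mu: NeutrosophicValue,
    sigma: float = 1.0,
    size: int = 100,
    seed: int | None = None,
) -> np.ndarray:
    """Draw interval values from a neutrosophic normal distribution.

    The neutrosophic mean ``mu = mu_L + mu_U * I`` spans the interval
    ``[m_lo, m_hi] = mu.endpoints()``.  Each draw shifts a single classical
    deviate z_i ~ Normal(0, sigma) by both mean endpoints, returning rows
    ``[m_lo + z_i, m_hi + z_i]`` — the two endpoints are fully coupled,
    sharing one source of randomness.  With a classical ``mu`` the
    intervals collapse to points.

    Returns an array of shape ``(size, 2)``.
    """
    if sigma <= 0:
        raise ValidationError(f"sigma must be > 0, got {sigma}")
    if size < 1:
        raise ValidationError(f"size must be >= 1, got {size}")
    rng = np.random.default_rng(seed)
    z = rng.normal(0.0, sigma, size)
    m_lo, m_hi = mu.endpoints()
    return np.column_stack([m_lo + z, m_hi + z])


def power_study(config: PowerConfig) -> list[PowerRow]:
    """Empirical power of the classical and indeterminacy-scaled tests.

    For each grid interval I, over the shared draws
    z_i ~ Normal(effect_mean, 1):

    * ``power_existing``  = fraction with z_i > z_crit(alpha);
    * ``power_proposed``  = fraction with (1 + I_U) * z_i > z_crit(alpha).

    Identical seeds give identical tables.
    """
    crit = critical_value(config.alpha)
    rng = np.random.default_rng(config.seed)
    z = rng.normal(config.effect_mean, 1.0, config.replicates)
    power_existing = float(np.mean(z > crit))
    rows: list[PowerRow] = []
    for interval in config.indeterminacy_grid:
        power_proposed = float(np.mean((1.0 + interval.upper) * z > crit))
        rows.append(
            PowerRow(
                indeterminacy_upper=interval.upper,
                power_existing=power_existing,
                power_proposed=power_proposed,
                replicates=config.replicates,
            )
        )
    return rows
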