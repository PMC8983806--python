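# Methods

## Model

The test concerns an ordered realization of two complementary events A and
B (a two-symbol sequence of length *n*).  The question is whether
observing A *reduces the uncertainty* of a B occurring *k* positions
later, i.e. whether the lag-*k* conditional probability P(B₊ₖ|A) exceeds
the marginal P(B).  The classical statistic standardizes that difference:

    Z = ( P(B₊ₖ|A) − P(B) ) / sqrt( P(B)[1−P(B)][1−P(A)] / ((n−k)·P(A)) )

and is referred to a standard-normal critical value.  The implicit
assumptions are those of the classical test: the plug-in probabilities are
treated as stable across the sequence (stationarity), and n−k is large
enough for the normal approximation to be usable.  At the n = 12 of the
packaged worked example the normal approximation is rough; the example's
role is illustrative, and the type-I simulation (below) probes calibration
at a more realistic n = 200.

Neutrosophic statistics attaches to every quantity a determinate part and
an indeterminate part scaled by a measure of indeterminacy I ranging over
an interval: X_N = X_L + X_U·I, I ∈ [I_L, I_U].  The package stores this
*form* (determinate part, coefficient, interval) and derives the interval
representation by evaluating it at the interval ends; constructors from
either representation exist, and the derived interval is normalized to
lower ≤ upper (a negative coefficient flips orientation).  I = [0, 0]
recovers classical statistics; I may exceed 1 (it is a scale factor, not a
probability).

Applied to the statistic, Z_N = (1 + I_ZN)·Z with I_ZN ∈ [I_ZL, I_ZU]
yields the interval [Z_L, Z_U] = [Z·(1+I_ZL), Z·(1+I_ZU)].  Two algebraic
forms exist when the two data endpoints differ (genuinely interval-valued
data): a *factored* form scaling each endpoint statistic by its own
(1+I), and an *additive* form T_L + T_U·I_ZN evaluated at the interval
ends.  They coincide whenever the endpoint data coincide — the only case
exercised by the worked example — so the factored form is the default and
the additive form is kept as an explicit option rather than reconciled.

## Decision rule

H₀ (no reduction in uncertainty) is rejected when **both** endpoints of
[Z_L, Z_U] exceed the critical value and retained when neither does.  An
interval that straddles the critical value gets the third verdict,
`indeterminate`: whether to reject then depends on the realized
indeterminacy, and forcing a binary answer would discard exactly the
information the interval was built to carry.  The straddling case never
arises in the packaged example (every tabulated interval rejects).

The critical value is the standard-normal quantile at 1 − α/2 (1.96 at
α = 0.05).  The test is upper-tailed in substance — large positive Z means
uncertainty reduction — but the customary reference value is the
two-sided quantile, so that convention is followed; callers may pass an
explicit critical value instead.

## Estimation conventions

* Marginals use the full length: P(A) = #A/n.
* Antecedent eligibility: positions 1..n−k are eligible antecedents; an A
  in the final k positions has no lag-k successor and is excluded from the
  denominator, which makes count(A→B) ≤ count(A) structural.
* The statistic's denominator uses n−k verbatim, not the eligible
  antecedent count.
* Degenerate inputs raise errors instead of returning infinities: a
  marginal of 0 or 1 (zero-variance denominator), no eligible antecedent
  (undefined conditional), lag outside 1..n−1, alphabets other than two
  symbols.

## Rounding modes

`exact` (default) carries full floating-point precision; on the packaged
sequence Z = 2.2111 (and 2.1890 if the conditional probability is first
rounded to 0.83).  `paper` reproduces two-decimal desk arithmetic so that
published worked examples can be verified digit-for-digit: the conditional
probability and the square-root denominator are rounded (half-up) to two
decimals before dividing and the quotient rounded to two decimals
(0.83 → 0.33/0.15 = 2.20), while the scaled endpoints (1+I_U)·Z are
**truncated** toward zero to two decimals.  Truncation, not rounding, is
what published sweep tables of this statistic use (2.20·1.04 = 2.288 is
printed as 2.28, 2.20·1.09 = 2.398 as 2.39); the two conventions agree on
every other quantity in the worked example.  `paper` mode exists for
verification only and should not be used for inference.

## Simulations

**Indeterminacy sweep.**  Deterministic: recomputes [Z_L, Z_U] and the
verdict over a grid of indeterminacy intervals (default: [0, I_U] for I_U
= 0…0.20 step 0.01, 0.3…1.0 step 0.1, and 2 — thirty intervals).  Since
the data are fixed, exact mode obeys Z_U/Z_L − 1 = I_ZU identically; the
sweep shows how the margin over the critical value widens with the
indeterminacy while the verdict stays put.

**Power comparison.**  The published comparison of the classical and
indeterminacy-scaled tests does not pin down a generative model (what
makes H₀ false, or how the neutrosophic mean enters the rejection rule),
and its 100-replicate powers are non-monotone in I_U — consistent with
Monte-Carlo noise.  This package therefore states its own explicit model
and reproduces the qualitative claim, not tabulated cells: statistics are
drawn z_i ~ Normal(δ, 1) with effect mean δ > 0 under the alternative;
the classical test rejects when z_i > z_crit(α) and the scaled test when
(1 + I_U)·z_i > z_crit(α).  The two tests — and all grid rows — share the
same seeded draws (common random numbers), so the dominance
power_proposed ≥ power_existing and the monotonicity of power_proposed in
I_U hold draw-for-draw, not merely in expectation.  Default replicates:
100, matching the customary table size; calibration checks in the tests
use 10⁵.  The neutrosophic normal sampler represents each interval draw by
shifting a single classical deviate by the two mean endpoints (fully
coupled endpoints); independent endpoint noise was rejected as an
unmotivated extra assumption.

## Synthetic sequence generator

`generate_fixture(n, p_a, p_b_given_a, k, seed)` draws a two-symbol
sequence with a lag-k Markov coupling: position i+k is B with probability
`p_b_given_a` when position i holds A, and otherwise follows the baseline
marginal (A with probability `p_a`).  This is the simplest mechanism
matching the test's alternative hypothesis; setting `p_b_given_a = 1−p_a`
removes the coupling and yields an i.i.d. sequence (the null).  It
emulates stationary dependence at a single known lag only — real event
records may carry trends, multiple lags, or regime changes — so passing
tests demonstrate correctness of the machinery and calibration under the
stated model, not robustness to such features.  Test problem sizes
(sequences of 200 tokens for the 500-run type-I check, 4,000–5,000 for
coupling recovery, 10⁵ replicates for power calibration) were chosen so
binomial standard errors are small relative to the asserted tolerances.

## Known limitations

* The measure of indeterminacy I_ZN is an input, not something estimated
  from data; the package propagates it but cannot tell you its value.
* The interval decision rule is conservative in the straddling case: it
  reports `indeterminate` rather than quantifying how much of the
  indeterminacy interval rejects.
* No p-values are computed; the procedure is compare-to-critical by
  construction.
* Only two-symbol alphabets are supported; multi-state records must be
  dichotomized by the user.
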