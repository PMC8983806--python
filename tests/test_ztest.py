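"""Classical and interval-valued statistics, critical values, verdicts."""

import math

import pytest
from hypothesis import given, strategies as st

from neutroz import (
    DegenerateProbabilityError,
    EventProbabilities,
    IndeterminacyInterval,
    Verdict,
    critical_value,
    decide,
    z_statistic_endpoint,
    z_statistic_neutrosophic,
)


def make_probs(p_a, p_b, p_cond, n, k):
    return EventProbabilities(
        p_a=p_a, p_b=p_b, p_b_given_a_lag=p_cond,
        count_a=0, count_a_then_b=0, n=n, k=k,
    )


class TestEndpointStatistic:
    def test_paper_mode_reproduces_desk_arithmetic(self, paper_probs):
        """0.83 over the 2-dp denominator 0.15 gives exactly 2.20."""
        assert z_statistic_endpoint(paper_probs, rounding_mode="paper") == 2.20

    def test_exact_mode_full_precision(self, paper_probs):
        # (5/6 - 1/2) / sqrt(0.125 / 5.5)
        assert z_statistic_endpoint(paper_probs) == pytest.approx(2.2111, abs=5e-5)

    def test_exact_mode_with_prerounded_conditional(self):
        """Feeding the 2-dp conditional 0.83 into exact arithmetic: 2.1890."""
        p = make_probs(0.5, 0.5, 0.83, 12, 1)
        assert z_statistic_endpoint(p) == pytest.approx(2.1890, abs=5e-5)

    @pytest.mark.parametrize("n,k", [(12, 1), (50, 3), (1000, 10)])
    def test_zero_numerator(self, n, k):
        p = make_probs(0.4, 0.6, 0.6, n, k)
        assert z_statistic_endpoint(p) == 0.0

    def test_degenerate_probabilities_raise(self):
        with pytest.raises(DegenerateProbabilityError):
            z_statistic_endpoint(make_probs(1.0, 0.0, 1.0, 10, 1))

    @given(c=st.floats(min_value=0.1, max_value=100))
    def test_sample_size_scaling(self, c):
        """Scaling n-k by c scales the statistic by sqrt(c), probabilities fixed."""
        base = make_probs(0.5, 0.5, 5 / 6, 12, 1)
        z1 = z_statistic_endpoint(base)
        z2 = z_statistic_endpoint(base, n=1 + round(11 * c), k=1)
        expected = z1 * math.sqrt(round(11 * c) / 11)
        assert z2 == pytest.approx(expected, rel=1e-12)

    @given(
        p_a=st.floats(min_value=0.05, max_value=0.95),
        p_b=st.floats(min_value=0.05, max_value=0.95),
        p_cond=st.floats(min_value=0.0, max_value=1.0),
    )
    def test_sign_tracks_uncertainty_reduction(self, p_a, p_b, p_cond):
        z = z_statistic_endpoint(make_probs(p_a, p_b, p_cond, 30, 1))
        if p_cond > p_b:
            assert z > 0
        elif p_cond < p_b:
            assert z < 0
        else:
            assert z == 0


class TestNeutrosophicStatistic:
    def test_worked_example_interval(self, paper_probs):
        z = z_statistic_neutrosophic(
            paper_probs, i_z=IndeterminacyInterval(0, 0.1), rounding_mode="paper"
        )
        assert (z.z_lower, z.z_upper) == (2.20, 2.42)
        assert z.form_text == "2.20 + 2.20*I_ZN; I_ZN in [0, 0.1]"

    @pytest.mark.parametrize(
        "upper, expected_hi", [(0.0, 2.20), (1.0, 4.40), (2.0, 6.60)]
    )
    def test_sweep_endpoints_paper_mode(self, paper_probs, upper, expected_hi):
        z = z_statistic_neutrosophic(
            paper_probs, i_z=IndeterminacyInterval(0, upper), rounding_mode="paper"
        )
        assert (z.z_lower, z.z_upper) == (2.20, expected_hi)

    def test_classical_reduction(self, paper_probs):
        """I = [0,0] in exact mode gives the classical statistic at both ends."""
        z = z_statistic_neutrosophic(paper_probs)
        classical = z_statistic_endpoint(paper_probs)
        assert z.z_lower == z.z_upper == z.determinate == classical

    @given(
        i_l=st.floats(min_value=0, max_value=3),
        span=st.floats(min_value=0, max_value=3),
    )
    def test_upper_endpoint_linear_in_indeterminacy(self, paper_probs, i_l, span):
        """Exact mode: Z_U = determinate * (1 + I_ZU) — slope is the determinate part."""
        i = IndeterminacyInterval(i_l, i_l + span)
        z = z_statistic_neutrosophic(paper_probs, i_z=i)
        assert z.z_upper == pytest.approx(z.determinate * (1 + i.upper), rel=1e-12)
        assert z.z_lower == pytest.approx(z.determinate * (1 + i.lower), rel=1e-12)

    def test_additive_and_factored_forms_agree_on_shared_data(self, paper_probs):
        i = IndeterminacyInterval(0.0, 0.4)
        zf = z_statistic_neutrosophic(paper_probs, i_z=i, form="factored")
        za = z_statistic_neutrosophic(paper_probs, i_z=i, form="additive")
        assert za.z_lower == pytest.approx(zf.z_lower, rel=1e-12)
        assert za.z_upper == pytest.approx(zf.z_upper, rel=1e-12)

    def test_forms_differ_with_distinct_endpoint_data(self):
        lo = make_probs(0.5, 0.5, 0.7, 30, 1)
        hi = make_probs(0.5, 0.5, 0.9, 30, 1)
        i = IndeterminacyInterval(0.2, 0.5)
        t_lo = z_statistic_endpoint(lo)
        t_hi = z_statistic_endpoint(hi)
        zf = z_statistic_neutrosophic(lo, hi, i_z=i, form="factored")
        za = z_statistic_neutrosophic(lo, hi, i_z=i, form="additive")
        assert zf.z_lower == pytest.approx(t_lo * 1.2, rel=1e-12)
        assert zf.z_upper == pytest.approx(t_hi * 1.5, rel=1e-12)
        assert za.z_lower == pytest.approx(t_lo + t_hi * 0.2, rel=1e-12)
        assert za.z_upper == pytest.approx(t_lo + t_hi * 0.5, rel=1e-12)
        assert za.z_upper != pytest.approx(zf.z_upper, rel=1e-6)


class TestDecisionRule:
    def test_standard_critical_value(self):
        assert critical_value(0.05) == pytest.approx(1.96, abs=5e-3)

    def test_quantile_convention(self):
        assert critical_value(0.3173) == pytest.approx(1.00, abs=5e-3)
        assert critical_value(0.999999) == pytest.approx(0.0, abs=1e-4)

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.1, 1.5])
    def test_alpha_out_of_range(self, alpha):
        with pytest.raises(Exception):
            critical_value(alpha)

    @pytest.mark.parametrize(
        "lo, hi, expected",
        [
            (2.20, 2.42, Verdict.REJECT),
            (0.5, 1.0, Verdict.ACCEPT),
            (1.5, 2.5, Verdict.INDETERMINATE),
        ],
    )
    def test_three_way_verdict(self, lo, hi, expected, paper_probs):
        z = z_statistic_neutrosophic(paper_probs)
        z = type(z)(
            z_lower=lo, z_upper=hi, determinate=lo,
            indeterminacy=z.indeterminacy, form_text=z.form_text,
            rounding_mode=z.rounding_mode,
        )
        d = decide(z, alpha=0.05)
        assert d.verdict is expected
        assert d.reject_lower == (lo > d.critical_value)
        assert d.reject_upper == (hi > d.critical_value)

    def test_explicit_critical_override(self, paper_probs):
        z = z_statistic_neutrosophic(paper_probs, rounding_mode="paper")
        assert decide(z, critical=2.5).verdict is Verdict.ACCEPT
        assert decide(z, critical=1.0).verdict is Verdict.REJECT
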