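import pytest
from hypothesis import settings

from neutroz import covid19_sequence, estimate_probabilities

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def paper_seq():
    """The packaged 12-token Covid-19 worked-example sequence."""
    return covid19_sequence()


@pytest.fixture(scope="session")
def paper_probs(paper_seq):
    return estimate_probabilities(paper_seq, k=1)


def naive_lag_probabilities(tokens, k, symbol_a="A", symbol_b="B"):
    """Brute-force oracle: enumerate every (i, i+k) pair with a double loop.

    Returns (count_a, count_a_then_b) counting antecedent positions i with
    1 <= i <= n-k (1-based) holding symbol_a, and among those the ones
    whose position i+k holds symbol_b.
    """
    n = len(tokens)
    count_a = 0
    count_ab = 0
    for i in range(n):
        for j in range(n):
            if j - i == k and tokens[i] == symbol_a:
                count_a += 1
                if tokens[j] == symbol_b:
                    count_ab += 1
    return count_a, count_ab
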