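import random

import pytest

from costruct import load_params


@pytest.fixture(scope="session")
def params():
    return load_params()


@pytest.fixture()
def rng():
    return random.Random(20240901)


def random_seq(rng, n):
    return "".join(rng.choice("ACGU") for _ in range(n))


def random_structure(rng, n, p_open=0.4):
    """A random valid (non-crossing) pair list for a length-n sequence."""
    pairs = []

    def rec(i, j):
        while i < j - 3:
            if rng.random() < p_open:
                span = rng.randint(4, j - i)
                pairs.append((i, i + span))
                rec(i + 1, i + span - 1)
                i = i + span + 1
            else:
                i += 1

    rec(1, n)
    return sorted(pairs)
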