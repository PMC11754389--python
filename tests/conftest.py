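"""Shared fixtures: the running example antidictionary and random-instance
generators used by the oracle-equivalence suites."""

import random

import pytest

from stringsan import Alphabet, MvrsInstance, normalize_pattern_set


@pytest.fixture(scope="session")
def ab() -> Alphabet:
    return Alphabet.from_string("ab")


@pytest.fixture(scope="session")
def example_patterns(ab):
    """The running example: S = {bbbb, abba, aaba} over {a, b}, k = 4."""
    return normalize_pattern_set(["bbbb", "abba", "aaba"], ab)


def random_pattern_set(rng: random.Random, alphabet: Alphabet,
                       max_patterns: int = 4, max_len: int = 4):
    """A small random antidictionary (possibly empty), normalized."""
    n = rng.randint(0, max_patterns)
    raw = [
        "".join(rng.choice(alphabet.letters) for _ in range(rng.randint(1, max_len)))
        for _ in range(n)
    ]
    return normalize_pattern_set(raw, alphabet)


def random_mvrs_instance(rng: random.Random, sigma: int = 2,
                         max_context: int = 5) -> MvrsInstance:
    alphabet = Alphabet.from_string("abc"[:sigma])
    u = "".join(rng.choice(alphabet.letters)
                for _ in range(rng.randint(0, max_context)))
    v = "".join(rng.choice(alphabet.letters)
                for _ in range(rng.randint(0, max_context)))
    patterns = random_pattern_set(rng, alphabet)
    return MvrsInstance(u=u, v=v, patterns=patterns, alphabet=alphabet)


def random_string(rng: random.Random, alphabet: Alphabet, max_len: int) -> str:
    return "".join(rng.choice(alphabet.letters)
                   for _ in range(rng.randint(0, max_len)))
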