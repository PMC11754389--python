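"""Unit and property tests for partial (TFS) and full (SFSS/GFSS)
sanitization."""

import itertools
import random

import pytest

from stringsan import (
    Alphabet,
    SanitizeFailure,
    assert_fully_sanitized,
    gfss,
    kgram_sequence,
    normalize_pattern_set,
    sfss,
    tfs,
)
from stringsan.errors import BadK


def is_subsequence(short, long):
    it = iter(long)
    return all(any(x == y for y in it) for x in short)


def surviving_grams(w, k, patterns):
    return kgram_sequence(w, k, drop=set(patterns.patterns))


def random_sanitize_instance(rng, sigma=2, max_w=60, ks=(2, 3, 4)):
    alphabet = Alphabet.from_string("abcd"[:sigma])
    k = rng.choice(ks)
    w = "".join(rng.choice(alphabet.letters)
                for _ in range(rng.randint(0, max_w)))
    pool = ["".join(p) for p in itertools.product(alphabet.letters, repeat=k)]
    pats = normalize_pattern_set(rng.sample(pool, rng.randint(0, min(4, len(pool)))),
                                 alphabet)
    return w, k, pats, alphabet


class TestTfs:
    def test_worked_example(self, ab, example_patterns):
        x = tfs("abbbbaaabaa", 4, example_patterns)
        assert x.text == "abbbaaab#abaa"
        assert x.segments == ("abbbaaab", "abaa")
        assert x.d == 1

    def test_pattern_free_input_is_unchanged(self, ab, example_patterns):
        assert tfs("abab", 4, example_patterns).text == "abab"

    def test_fully_forbidden_input_vanishes(self, ab):
        pats = normalize_pattern_set(["bbbb"], ab)
        x = tfs("bbbb", 4, pats)
        assert x.text == "" and x.d == 0

    def test_short_input_vanishes(self, ab, example_patterns):
        assert tfs("ab", 4, example_patterns).text == ""

    def test_bad_k(self, ab, example_patterns):
        with pytest.raises(BadK):
            tfs("abab", 1, normalize_pattern_set(["a"], ab))
        with pytest.raises(BadK):
            tfs("abab", 3, example_patterns)  # patterns have length 4

    def test_gram_sequence_preserved_exactly(self):
        """The k-gram sequence over the original alphabet of the partial
        string equals the non-forbidden k-gram sequence of the input, the
        length bound |x| <= |w| + d*k holds and every segment has length at
        least k."""
        rng = random.Random(101)
        for _ in range(150):
            w, k, pats, _ = random_sanitize_instance(rng, sigma=rng.choice([2, 3]))
            x = tfs(w, k, pats)
            expected = surviving_grams(w, k, pats)
            got = [g for seg in x.segments for g in kgram_sequence(seg, k)]
            assert got == expected
            assert len(x.text) <= len(w) + x.d * k
            assert all(len(seg) >= k for seg in x.segments)
            assert x.d <= sum(
                1 for i in range(len(w) - k + 1) if w[i:i + k] in pats
            )


class TestSfss:
    def test_worked_example(self, ab, example_patterns):
        assert sfss("abbbbaaabaa", 4, example_patterns) == "abbbaaabbbabaa"

    def test_pattern_free_input_is_unchanged(self, ab, example_patterns):
        assert sfss("ababab", 4, example_patterns) == "ababab"

    def test_repeated_overlapping_occurrences(self):
        # CAAAAAC with AAA forbidden: both surviving 3-grams CAA and AAC
        # chain through the 2-overlap AA, so the optimum needs no new
        # letters beyond one C.
        alpha = Alphabet.from_string("AC")
        pats = normalize_pattern_set(["AAA"], alpha)
        y = sfss("CAAAAAC", 3, pats)
        assert y == "CAAC"
        assert assert_fully_sanitized(y, 3, pats).ok
        assert is_subsequence(surviving_grams("CAAAAAC", 3, pats),
                              kgram_sequence(y, 3))

    def test_subsequence_constraint(self):
        """The surviving k-gram sequence of w is a subsequence of that of
        the fully sanitized output, which itself contains no forbidden
        pattern and no '#'."""
        rng = random.Random(211)
        for _ in range(150):
            w, k, pats, alphabet = random_sanitize_instance(
                rng, sigma=rng.choice([2, 3, 4])
            )
            y = sfss(w, k, pats, alphabet=alphabet)
            if isinstance(y, SanitizeFailure):
                continue
            assert assert_fully_sanitized(y, k, pats).ok
            assert is_subsequence(surviving_grams(w, k, pats),
                                  kgram_sequence(y, k))

    def test_minimality_on_tiny_instances(self):
        """No strictly shorter fully sanitized string satisfies the
        k-gram-subsequence constraint (exhaustive search over all shorter
        strings)."""
        rng = random.Random(307)
        alphabet = Alphabet.from_string("ab")
        checked = 0
        while checked < 60:
            w, k, pats, _ = random_sanitize_instance(
                rng, sigma=2, max_w=10, ks=(2, 3)
            )
            y = sfss(w, k, pats, alphabet=alphabet)
            if isinstance(y, SanitizeFailure) or len(y) > 13:
                continue
            checked += 1
            target = surviving_grams(w, k, pats)
            for n in range(len(y)):
                for cand in itertools.product("ab", repeat=n):
                    c = "".join(cand)
                    if not assert_fully_sanitized(c, k, pats).ok:
                        continue
                    assert not is_subsequence(target, kgram_sequence(c, k)), (
                        w, k, pats.patterns, y, c
                    )

    def test_failure_is_reported_with_gap_index(self):
        # w = abab with S = {ba}: the partial string is ab#ab and the gap
        # needs a walk from 'b' back to 'a' that never crosses the
        # forbidden bigram ba — impossible.
        alphabet = Alphabet.from_string("ab")
        pats = normalize_pattern_set(["ba"], alphabet)
        res = sfss("abab", 2, pats, alphabet=alphabet)
        assert isinstance(res, SanitizeFailure)
        assert res.gap_index == 0 and res.reason == "NO_PATH"

    def test_per_gap_antidictionaries(self, ab, example_patterns):
        x_d = tfs("abbbbaaabaa", 4, example_patterns).d
        y = sfss(
            "abbbbaaabaa", 4, example_patterns,
            gap_antidictionaries=[example_patterns] * x_d,
        )
        assert y == "abbbaaabbbabaa"


class TestGfss:
    @pytest.mark.parametrize(
        "w, k, pats, sigma, expected",
        [
            ("CAAAAAC", 3, ["AAA"], "AC", "CAAC"),
            ("abbbbaaabaa", 4, ["bbbb", "aaba", "abba"], "ab", "abbbaaab"),
            ("ababab", 4, ["bbbb", "aaba", "abba"], "ab", "ababab"),
        ],
    )
    def test_examples(self, w, k, pats, sigma, expected):
        alphabet = Alphabet.from_string(sigma)
        assert gfss(w, k, normalize_pattern_set(pats, alphabet)) == expected

    def test_always_safe_and_never_longer(self):
        rng = random.Random(401)
        for _ in range(200):
            w, k, pats, _ = random_sanitize_instance(rng, sigma=rng.choice([2, 3]))
            y = gfss(w, k, pats)
            assert assert_fully_sanitized(y, k, pats).ok
            assert len(y) <= len(w)


class TestVerifier:
    def test_clean_output(self, ab, example_patterns):
        assert assert_fully_sanitized("abbbaaabbbabaa", 4, example_patterns).ok

    def test_pattern_violation_with_position(self, ab):
        pats = normalize_pattern_set(["bbbb"], ab)
        rep = assert_fully_sanitized("abbbb", 4, pats)
        assert not rep.ok and rep.violations == (("bbbb", 2),)

    def test_hash_violation(self, ab):
        rep = assert_fully_sanitized("ab#a", 2, normalize_pattern_set([], ab))
        assert not rep.ok and rep.violations == (("#", 3),)

    def test_overlapping_occurrences_all_reported(self, ab):
        pats = normalize_pattern_set(["aa"], ab)
        rep = assert_fully_sanitized("aaa", 2, pats)
        assert rep.violations == (("aa", 1), ("aa", 2))
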