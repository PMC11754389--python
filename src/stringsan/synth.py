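"""Synthetic string collections with planted cluster structure.

Collections are generated the way clustering benchmarks for sequence data
are usually built: ``K`` seed strings (by default uniformly random over the
alphabet, length 2000) each found a cluster of ``L`` strings consisting of
the seed plus ``L - 1`` noisy copies, where a copy is obtained by applying
``e`` random edit operations (substitution, insertion, deletion, each
equally likely, positions and letters uniform).  The relative noise level
is ``δ = e / |Q|`` with ``|Q|`` the seed length, so every copy is at edit
distance at most ``e`` from its seed.

Forbidden-pattern sets are sampled either uniformly from the full k-gram
space ``Σ^k`` at a rate ``R = |S_k| / |Σ|^k`` (stress-testing dense
antidictionaries) or uniformly from the distinct k-grams actually occurring
in a dataset (guaranteeing every pattern has occurrences to sanitize).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .automaton import Alphabet, PatternSet, normalize_pattern_set
from .errors import EmptyString, NotEnoughPatterns


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic collection.

    ``edits`` is the number of random edit operations applied per noisy
    copy (noise level ``δ = edits / seed_length``); ``fraction`` is the
    share ``R`` of all k-grams declared forbidden.
    """

    alphabet: Alphabet
    K: int
    L: int
    edits: int
    k: int
    seed_length: int = 2000
    fraction: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1 or self.L < 1:
            raise ValueError("K and L must be positive")
        if self.edits < 0:
            raise ValueError("edit count must be non-negative")
        if not 0 < self.fraction <= 1:
            raise ValueError("forbidden fraction must be in (0, 1]")

    @property
    def delta(self) -> float:
        return self.edits / self.seed_length


def random_string(length: int, alphabet: Alphabet, rng: np.random.Generator) -> str:
    idx = rng.integers(0, len(alphabet), size=length)
    return "".join(alphabet.letters[i] for i in idx)


def apply_random_edits(Q: str, e: int, alphabet: Alphabet, rng: np.random.Generator) -> str:
    """Apply ``e`` uniformly chosen edit operations to ``Q`` in sequence.

    Substitutions replace a uniform position with a uniform *different*
    letter; insertions put a uniform letter at a uniform slot; deletions
    drop a uniform position.  The result is at edit distance at most ``e``
    from ``Q`` (operations may cancel).  Raises :class:`EmptyString` if a
    deletion is drawn on an empty string.
    """
    s = list(Q)
    letters = alphabet.letters
    for _ in range(e):
        op = int(rng.integers(0, 3))
        if op == 0:  # substitution
            if not s:
                raise EmptyString("cannot substitute in an empty string")
            pos = int(rng.integers(0, len(s)))
            others = [c for c in letters if c != s[pos]]
            s[pos] = others[int(rng.integers(0, len(others)))]
        elif op == 1:  # insertion
            pos = int(rng.integers(0, len(s) + 1))
            s.insert(pos, letters[int(rng.integers(0, len(letters)))])
        else:  # deletion
            if not s:
                raise EmptyString("deletions exhausted the string")
            pos = int(rng.integers(0, len(s)))
            del s[pos]
    return "".join(s)


def generate_cluster_collection(
    spec: SyntheticSpec, seeds: list[str] | None = None
) -> tuple[list[str], list[int]]:
    """Generate ``K * L`` strings with planted labels.

    ``seeds`` may supply the K cluster seeds (e.g. real sequences);
    otherwise they are uniformly random of length ``spec.seed_length``.
    Each cluster holds its seed followed by ``L - 1`` noisy copies; labels
    record the cluster of origin.
    """
    rng = np.random.default_rng(spec.rng_seed)
    if seeds is None:
        seeds = [
            random_string(spec.seed_length, spec.alphabet, rng) for _ in range(spec.K)
        ]
    elif len(seeds) != spec.K:
        raise ValueError(f"expected {spec.K} seeds, got {len(seeds)}")
    strings: list[str] = []
    labels: list[int] = []
    for c, Q in enumerate(seeds):
        strings.append(Q)
        labels.append(c)
        for _ in range(spec.L - 1):
            strings.append(apply_random_edits(Q, spec.edits, spec.alphabet, rng))
            labels.append(c)
    return strings, labels


def _decode(code: int, k: int, alphabet: Alphabet) -> str:
    letters = []
    for _ in range(k):
        code, r = divmod(code, len(alphabet))
        letters.append(alphabet.letters[r])
    return "".join(reversed(letters))


def sample_forbidden_patterns(
    mode: str,
    alphabet: Alphabet,
    k: int,
    rng: np.random.Generator,
    fraction: float | None = None,
    count: int | None = None,
    dataset: list[str] | None = None,
) -> PatternSet:
    """Sample an antidictionary of length-k patterns without replacement.

    ``mode='space'`` draws from all of ``Σ^k``; the size is ``count`` or
    ``round(fraction * |Σ|^k)``.  ``mode='occurring'`` draws ``count``
    patterns from the distinct k-grams present in ``dataset``.  Raises
    :class:`NotEnoughPatterns` if the pool is too small.
    """
    if mode == "space":
        pool_size = len(alphabet) ** k
        if count is None:
            if fraction is None:
                raise ValueError("mode='space' needs fraction or count")
            count = round(fraction * pool_size)
        if count > pool_size:
            raise NotEnoughPatterns(f"requested {count} of {pool_size} k-grams")
        codes = rng.choice(pool_size, size=count, replace=False)
        patterns = [_decode(int(c), k, alphabet) for c in codes]
    elif mode == "occurring":
        if dataset is None or count is None:
            raise ValueError("mode='occurring' needs dataset and count")
        pool = sorted({s[i : i + k] for s in dataset for i in range(len(s) - k + 1)})
        if count > len(pool):
            raise NotEnoughPatterns(
                f"requested {count} patterns but only {len(pool)} k-grams occur"
            )
        idx = rng.choice(len(pool), size=count, replace=False)
        patterns = [pool[int(i)] for i in idx]
    else:
        raise ValueError(f"unknown sampling mode {mode!r}")
    return normalize_pattern_set(patterns, alphabet)


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance by the standard dynamic program (used to
    validate the edit-noise generator and for reporting; quadratic, so only
    for short-to-moderate strings)."""
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(
                min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
            )
        prev = cur
    return prev[-1]
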