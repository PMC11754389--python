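"""Partial and full sanitization of a private string.

Given a string ``w`` and an antidictionary ``S_k`` of forbidden length-k
patterns, sanitization must produce a string in which no forbidden pattern
occurs while preserving as much of ``w``'s sequential structure as
possible.  The structure that all methods here preserve is the ordered
sequence of *non-forbidden* k-grams of ``w``.

Three routes are provided:

* :func:`tfs` — partial sanitization: the unique shortest string whose
  k-gram sequence over the original alphabet equals that of ``w``, using
  the reserved marker ``'#'`` to separate segments where forbidden
  occurrences were cut out.
* :func:`sfss` — full sanitization: the shortest string over the original
  alphabet whose k-gram sequence contains that of ``w`` as a subsequence.
  Each ``#`` gap of the partial string is resolved independently by a
  shortest missing-value replacement between the length-(k-1) contexts
  flanking the gap.
* :func:`gfss` — a greedy full-sanitization baseline that simply refuses to
  append any letter that would complete a forbidden pattern.  It is fast
  and always safe, but may drop k-grams and so distort similarity much more
  than :func:`sfss` (dramatically so for small alphabets or dense
  antidictionaries).
"""

from __future__ import annotations

from dataclasses import dataclass

from .automaton import (
    MISSING,
    Alphabet,
    PatternSet,
    PrefixAutomaton,
    build_prefix_automaton,
)
from .errors import BadK
from .mvrs import MvrsInstance, solve_mvrs


@dataclass(frozen=True)
class PartialString:
    """A partially sanitized string ``x0 # x1 # ... # xd``.

    Every segment has length at least ``k`` and is free of forbidden
    patterns; ``d`` (the number of ``#`` markers) never exceeds the number
    of forbidden-pattern occurrences in the input.
    """

    segments: tuple[str, ...]
    k: int

    @property
    def d(self) -> int:
        return max(0, len(self.segments) - 1)

    @property
    def text(self) -> str:
        return MISSING.join(self.segments)


@dataclass(frozen=True)
class SanitizeFailure:
    """Full sanitization failed: some gap admits no replacement."""

    gap_index: int
    reason: str | None = None


@dataclass(frozen=True)
class SanitizationReport:
    ok: bool
    violations: tuple[tuple[str, int], ...]


def _check_k(k: int, patterns: PatternSet) -> None:
    if k <= 1:
        raise BadK(f"window length must exceed 1, got {k}")
    if len(patterns) and patterns.uniform_k != k:
        raise BadK(f"all patterns must have length exactly {k}")


def tfs(w: str, k: int, patterns: PatternSet) -> PartialString:
    """Shortest partial sanitization of ``w``.

    Scans the k-grams of ``w`` left to right, skipping forbidden ones.  A
    surviving k-gram either *extends* the current output (when the output
    already ends with its (k-1)-prefix, one letter suffices) or *restarts*
    a fresh segment after a ``#``.  Each step appends exactly one new
    k-gram, so the k-gram sequence of the result equals the non-forbidden
    k-gram sequence of ``w``; the result is the unique shortest string with
    that property.

    For ``|w| < k`` the k-gram sequence is empty and the result is the
    empty string.
    """
    _check_k(k, patterns)
    segments: list[str] = []
    current = ""
    for i in range(len(w) - k + 1):
        g = w[i : i + k]
        if g in patterns:
            continue
        if current.endswith(g[:-1]) and current:
            current += g[-1]
        else:
            if current:
                segments.append(current)
            current = g
    if current:
        segments.append(current)
    return PartialString(segments=tuple(segments), k=k)


def sfss(
    w: str,
    k: int,
    patterns: PatternSet,
    alphabet: Alphabet | None = None,
    automaton: PrefixAutomaton | None = None,
    gap_antidictionaries: list[PatternSet] | None = None,
) -> str | SanitizeFailure:
    """Shortest full sanitization of ``w``.

    Computes the partial string ``x0 # x1 # ... # xd`` and replaces each
    gap ``# `` by solving a shortest missing-value replacement between
    ``u`` = the length-(k-1) suffix of the left segment and ``v`` = the
    length-(k-1) prefix of the right segment.  Because every segment has
    length at least ``k``, gaps do not interact and each can be resolved
    independently and optimally.

    ``alphabet`` defaults to the letters appearing in ``w`` or in the
    patterns.  A prebuilt ``automaton`` for ``patterns`` may be supplied to
    amortize construction over a collection.  ``gap_antidictionaries``
    optionally replaces the antidictionary for each gap individually (one
    entry per gap).

    Returns the sanitized string, or a :class:`SanitizeFailure` naming the
    first gap with no feasible replacement.
    """
    _check_k(k, patterns)
    x = tfs(w, k, patterns)
    if not x.segments:
        return ""
    if alphabet is None:
        alphabet = Alphabet.from_strings([w, *patterns.patterns])
    if gap_antidictionaries is not None and len(gap_antidictionaries) != x.d:
        raise ValueError(
            f"expected {x.d} per-gap antidictionaries, got {len(gap_antidictionaries)}"
        )

    shared = automaton
    y = x.segments[0]
    for gap in range(x.d):
        right = x.segments[gap + 1]
        u = y[-(k - 1) :]
        v = right[: k - 1]
        if gap_antidictionaries is not None:
            gap_patterns = gap_antidictionaries[gap]
            gap_automaton = build_prefix_automaton(gap_patterns, alphabet)
        else:
            gap_patterns = patterns
            if shared is None:
                shared = build_prefix_automaton(patterns, alphabet)
            gap_automaton = shared
        res = solve_mvrs(
            MvrsInstance(u=u, v=v, patterns=gap_patterns, alphabet=alphabet),
            automaton=gap_automaton,
        )
        if not res.solved:
            return SanitizeFailure(gap_index=gap, reason=res.fail_reason)
        y = y + res.x[k - 1 :] + right[k - 1 :]
    return y


def gfss(w: str, k: int, patterns: PatternSet) -> str:
    """Greedy full sanitization: append each letter of ``w`` unless the
    resulting length-k suffix is forbidden, in which case skip it.

    Always fully sanitized and never longer than ``w``, but the surviving
    k-gram sequence of ``w`` need not survive as a subsequence.
    """
    _check_k(k, patterns)
    members = patterns._members
    out: list[str] = []
    for c in w:
        out.append(c)
        if len(out) >= k and "".join(out[-k:]) in members:
            out.pop()
    return "".join(out)


def assert_fully_sanitized(
    y: str, k: int, patterns: PatternSet
) -> SanitizationReport:
    """Verify full sanitization: no forbidden pattern and no ``'#'``.

    Violations are reported as ``(pattern, position)`` with 1-based
    positions; overlapping occurrences are all listed.
    """
    violations: list[tuple[str, int]] = []
    for i, c in enumerate(y):
        if c == MISSING:
            violations.append((MISSING, i + 1))
    for p in patterns:
        start = y.find(p)
        while start != -1:
            violations.append((p, start + 1))
            start = y.find(p, start + 1)
    violations.sort(key=lambda t: (t[1], t[0]))
    return SanitizationReport(ok=not violations, violations=tuple(violations))
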