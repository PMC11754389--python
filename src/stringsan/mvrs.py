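"""Shortest missing-value replacement between two contexts.

The problem: given a left context ``u``, a right context ``v`` and an
antidictionary ``S``, find a shortest string ``x`` that has ``u`` as a
prefix and ``v`` as a suffix and contains no pattern of ``S`` — the string
that can stand in for ``u·#·v`` when the missing value ``#`` must be
resolved into real letters.

Two regimes cover all solutions:

* ``|x| <= |u| + |v|``: a nonempty suffix of ``u`` coincides with a prefix
  of ``v``.  We spell ``u`` through the avoidance automaton and, at each
  prefix length reached at a sink state, test whether the remaining suffix
  of ``u`` is a prefix of ``v``; the first success corresponds to the
  longest overlap and hence the shortest ``x``.
* ``|x| > |u| + |v|``: breadth-first search over the automaton from the
  state reached after spelling ``u`` (the *source*) to the nearest state
  that can safely be followed by ``v`` (a *sink*).  The BFS expands letters
  in alphabet-rank order and keeps first-discovery parents, so the returned
  middle string is the lexicographically smallest among the shortest.

``FAIL`` is a value, not an exception: either a pattern already occurs in a
context (``PATTERN_IN_CONTEXT``) or no sink is reachable (``NO_PATH``).
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass

from .automaton import (
    FORBIDDEN,
    Alphabet,
    PatternSet,
    PrefixAutomaton,
    build_prefix_automaton,
)
from .errors import OracleBudgetExceeded

SOLVED = "SOLVED"
FAIL = "FAIL"

PATTERN_IN_CONTEXT = "PATTERN_IN_CONTEXT"
NO_PATH = "NO_PATH"


@dataclass(frozen=True)
class MvrsInstance:
    """One missing-value replacement task: ``u # v`` under antidictionary S."""

    u: str
    v: str
    patterns: PatternSet
    alphabet: Alphabet

    def __post_init__(self) -> None:
        self.alphabet.validate(self.u, what="left context")
        self.alphabet.validate(self.v, what="right context")


@dataclass(frozen=True)
class MvrsResult:
    status: str  # SOLVED | FAIL
    x: str | None = None
    middle: str | None = None
    overlap_used: int | None = None
    fail_reason: str | None = None

    @property
    def solved(self) -> bool:
        return self.status == SOLVED


def suffix_prefix_overlaps(u: str, v: str) -> list[int]:
    """All lengths ``l >= 1`` such that the length-``l`` suffix of ``u``
    equals the length-``l`` prefix of ``v``, in decreasing order."""
    return [
        l
        for l in range(min(len(u), len(v)), 0, -1)
        if u[len(u) - l :] == v[:l]
    ]


def solve_mvrs(
    inst: MvrsInstance, automaton: PrefixAutomaton | None = None
) -> MvrsResult:
    """Solve one replacement instance exactly.

    An optional prebuilt ``automaton`` (for ``inst.patterns`` over
    ``inst.alphabet``) lets callers amortize construction over many
    instances sharing the same antidictionary.
    """
    u, v = inst.u, inst.v
    A = automaton if automaton is not None else build_prefix_automaton(
        inst.patterns, inst.alphabet
    )

    if A.contains_pattern(u) or A.contains_pattern(v):
        return MvrsResult(status=FAIL, fail_reason=PATTERN_IN_CONTEXT)

    # Spell u from the root; states[i] is the state after i letters of u.
    # No transition can be FORBIDDEN because u is pattern-free.
    path = [0]
    q = 0
    for c in u:
        q = A.goto[q][A.alphabet.rank(c)]
        path.append(q)

    # Case 1: overlapping solutions, longest overlap (shortest x) first.
    for i in range(len(u) + 1):
        l = len(u) - i
        if not 1 <= l <= len(v):
            continue
        if u[i:] == v[:l] and A.is_sink(path[i], v):
            return MvrsResult(status=SOLVED, x=u[:i] + v, middle="", overlap_used=l)

    # Case 2: BFS from the source to the nearest sink; letters expand in
    # rank order so the first path found is the lexicographically smallest
    # shortest one.
    source = path[-1]
    prev: dict[int, tuple[int, str]] = {source: (-1, "")}
    queue = deque([source])
    while queue:
        s = queue.popleft()
        if A.is_sink(s, v):
            letters = []
            t = s
            while t != source:
                t, c = prev[t]
                letters.append(c)
            h = "".join(reversed(letters))
            return MvrsResult(status=SOLVED, x=u + h + v, middle=h)
        row = A.goto[s]
        for r, c in enumerate(inst.alphabet.letters):
            t = row[r]
            if t != FORBIDDEN and t not in prev:
                prev[t] = (s, c)
                queue.append(t)

    return MvrsResult(status=FAIL, fail_reason=NO_PATH)


def brute_force_mvrs(
    inst: MvrsInstance, max_len: int, budget: int = 2_000_000
) -> MvrsResult:
    """Exhaustive-search oracle: enumerate candidate strings by increasing
    length, then lexicographically by letter rank, and return the first
    feasible one.  Only practical for tiny alphabets and short outputs;
    raises :class:`OracleBudgetExceeded` past ``budget`` candidates."""
    u, v = inst.u, inst.v
    pats = inst.patterns.patterns
    checked = 0

    def feasible(x: str) -> bool:
        return not any(p in x for p in pats)

    for n in range(max(len(u), len(v)), max_len + 1):
        if n <= len(u) + len(v):
            # The overlap determines x completely.
            l = len(u) + len(v) - n
            if u[len(u) - l :] != v[:l]:
                continue
            x = u + v[l:]
            checked += 1
            if feasible(x):
                return MvrsResult(
                    status=SOLVED, x=x, middle="", overlap_used=l if l else None
                )
        else:
            m = n - len(u) - len(v)
            for mid in itertools.product(inst.alphabet.letters, repeat=m):
                checked += 1
                if checked > budget:
                    raise OracleBudgetExceeded(
                        f"enumeration exceeded {budget} candidates"
                    )
                x = u + "".join(mid) + v
                if feasible(x):
                    return MvrsResult(status=SOLVED, x=x, middle="".join(mid))
    return MvrsResult(status=FAIL, fail_reason=NO_PATH)
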