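"""Avoidance automaton over dangerous strings.

Given a finite antidictionary ``S`` of forbidden patterns over an alphabet
``Σ``, the *dangerous* strings are the empty string together with every
proper prefix of a pattern in ``S``.  They are exactly the strings that can
still be safely extended, and they form the state set of a deterministic
automaton whose complete transition function sends a state ``q`` and a
letter ``α`` to the longest dangerous suffix of ``q·α`` — or to the
reserved ``FORBIDDEN`` value when ``q·α`` ends with a full pattern.  The
construction is the classic trie-plus-failure-links one (the failure link
of a state is its longest proper dangerous suffix), built breadth-first so
that every transition is resolved in constant time.

Walking the automaton with the letters of a string ``s`` therefore decides,
online, whether ``s`` contains a forbidden pattern, and the reached state
summarises everything about ``s`` that matters for future extensions.

The antidictionary is assumed *anti-factorial* (no pattern is a proper
substring of another); :func:`normalize_pattern_set` reduces any raw set to
this form.  The missing-value marker ``'#'`` is reserved and can never be an
alphabet member.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import (
    AlphabetViolation,
    EmptyPattern,
    InfeasibleContext,
    UnknownLetter,
)

#: Reserved missing-value marker; never a member of any Alphabet.
MISSING = "#"

#: Sentinel transition target: following this edge would complete a pattern.
FORBIDDEN = -1

# Internal trie-edge sentinels.
_S_PRIME = -2  # edge into the merged forbidden node
_NO_EDGE = -3


@dataclass(frozen=True)
class Alphabet:
    """An ordered alphabet of single-character symbols.

    The position of a letter in ``letters`` is its *rank*; ranks are used to
    index dense transition tables and to break ties deterministically
    (smaller rank wins).
    """

    letters: tuple[str, ...]
    _rank: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.letters:
            raise AlphabetViolation("alphabet must be nonempty")
        for a in self.letters:
            if not isinstance(a, str) or len(a) != 1:
                raise AlphabetViolation(f"letters must be single characters, got {a!r}")
            if a == MISSING:
                raise AlphabetViolation("'#' is reserved for missing values")
        if len(set(self.letters)) != len(self.letters):
            raise AlphabetViolation("alphabet letters must be distinct")
        object.__setattr__(self, "_rank", {a: i for i, a in enumerate(self.letters)})

    @classmethod
    def from_string(cls, letters: str) -> "Alphabet":
        return cls(tuple(letters))

    @classmethod
    def from_strings(cls, strings) -> "Alphabet":
        """Smallest alphabet covering every letter of the given strings,
        in sorted letter order."""
        return cls(tuple(sorted(set().union(*(set(s) for s in strings)) or {"a"})))

    def rank(self, letter: str) -> int:
        try:
            return self._rank[letter]
        except KeyError:
            raise UnknownLetter(f"letter {letter!r} is not in the alphabet") from None

    def __contains__(self, letter: str) -> bool:
        return letter in self._rank

    def __len__(self) -> int:
        return len(self.letters)

    def __iter__(self):
        return iter(self.letters)

    def validate(self, s: str, what: str = "string") -> None:
        for c in s:
            if c not in self._rank:
                raise AlphabetViolation(f"{what} contains {c!r}, not in the alphabet")


@dataclass(frozen=True)
class PatternSet:
    """A normalized antidictionary: deduplicated, anti-factorial, nonempty
    patterns, stored in (length, lexicographic) order."""

    patterns: tuple[str, ...]
    total_length: int
    uniform_k: int | None

    def __contains__(self, s: str) -> bool:
        return s in self._members

    def __len__(self) -> int:
        return len(self.patterns)

    def __iter__(self):
        return iter(self.patterns)

    @property
    def _members(self) -> frozenset[str]:
        return self.__dict__.setdefault("_members_cache", frozenset(self.patterns))

    @classmethod
    def empty(cls) -> "PatternSet":
        return cls(patterns=(), total_length=0, uniform_k=None)


def normalize_pattern_set(raw_patterns, alphabet: Alphabet) -> PatternSet:
    """Deduplicate and reduce a raw pattern collection to anti-factorial form.

    A pattern that contains another pattern as a proper substring is
    redundant — avoiding the shorter one already avoids the longer — and is
    dropped.  Raises :class:`EmptyPattern` for an empty pattern and
    :class:`AlphabetViolation` for letters outside ``alphabet``.
    """
    seen: set[str] = set()
    for p in raw_patterns:
        if p == "":
            raise EmptyPattern("forbidden patterns must be nonempty")
        alphabet.validate(p, what=f"pattern {p!r}")
        seen.add(p)

    lengths = {len(p) for p in seen}
    if len(lengths) <= 1:
        kept = seen  # equal-length patterns cannot contain one another
    else:
        by_len = sorted(seen, key=len)
        kept = set()
        for p in by_len:
            if not any(q in p for q in kept if len(q) < len(p)):
                kept.add(p)

    ordered = tuple(sorted(kept, key=lambda s: (len(s), s)))
    uniform = len(ordered[0]) if ordered and len(lengths) == 1 else None
    return PatternSet(
        patterns=ordered,
        total_length=sum(len(p) for p in ordered),
        uniform_k=uniform,
    )


@dataclass
class PrefixAutomaton:
    """The avoidance automaton ``G(D, E)``.

    ``states[i]`` is the dangerous string of state ``i`` (state 0 is the
    empty string), ``goto`` is the complete transition table indexed by
    (state, letter rank) with ``FORBIDDEN`` marking transitions that would
    complete a pattern, ``fail`` maps each state to its longest proper
    dangerous suffix, and ``depth`` is the string length of each state.
    ``_trie`` keeps the raw trie edges (with ``_S_PRIME`` marking edges into
    the merged forbidden node) for boundary-pattern queries.
    """

    alphabet: Alphabet
    states: list[str]
    goto: list[list[int]]
    fail: list[int]
    depth: list[int]
    _trie: list[list[int]] = field(repr=False)
    _index: dict[str, int] = field(repr=False)

    def __len__(self) -> int:
        return len(self.states)

    def state_of(self, s: str) -> int:
        """State id of a dangerous string."""
        return self._index[s]

    def run(self, start: int, s: str) -> int:
        """Follow the letters of ``s`` from ``start``; return the reached
        state, or ``FORBIDDEN`` as soon as a pattern would be completed."""
        q = start
        for c in s:
            q = self.goto[q][self.alphabet.rank(c)]
            if q == FORBIDDEN:
                return FORBIDDEN
        return q

    def contains_pattern(self, s: str) -> bool:
        """Whether some pattern of the antidictionary occurs in ``s``."""
        return self.run(0, s) == FORBIDDEN

    def is_sink(self, state: int, v: str) -> bool:
        """Whether ``state·v`` is free of forbidden patterns.

        Precondition: no pattern occurs inside ``v`` itself.  A pattern in
        ``state·v`` must then straddle the boundary, i.e. equal ``t·p`` for
        some dangerous suffix ``t`` of the state's string and nonempty
        prefix ``p`` of ``v``.  The dangerous suffixes of a state are
        exactly its failure chain, so we walk the raw trie from each chain
        element along ``v`` and test whether a pattern node is reached.
        """
        rank = self.alphabet.rank
        trie = self._trie
        q = state
        while True:
            node = q
            for c in v:
                nxt = trie[node][rank(c)]
                if nxt == _S_PRIME:
                    return False
                if nxt == _NO_EDGE:
                    break
                node = nxt
            if q == 0:
                return True
            q = self.fail[q]


def build_prefix_automaton(patterns: PatternSet, alphabet: Alphabet) -> PrefixAutomaton:
    """Build the avoidance automaton for a normalized antidictionary.

    The trie of the patterns is built first; its leaves (the patterns
    themselves — anti-factoriality guarantees every pattern node is a leaf)
    are conceptually merged into one forbidden node.  Failure links and the
    complete transition table are then filled in breadth-first order via::

        f(w)      = goto(f(parent(w)), last letter of w)
        goto(w,α) = wα           if wα is a trie node
                  = goto(f(w),α) otherwise

    with transitions into the forbidden node recorded as ``FORBIDDEN``.
    """
    sigma = len(alphabet)
    rank = alphabet.rank

    # Trie over dangerous strings; pattern nodes collapse into _S_PRIME.
    states: list[str] = [""]
    depth: list[int] = [0]
    trie: list[list[int]] = [[_NO_EDGE] * sigma]
    index: dict[str, int] = {"": 0}
    parent: list[tuple[int, int]] = [(-1, -1)]  # (parent state, letter rank)

    for p in patterns.patterns:
        node = 0
        for i, c in enumerate(p):
            r = rank(c)
            if i == len(p) - 1:
                trie[node][r] = _S_PRIME
                break
            nxt = trie[node][r]
            if nxt == _NO_EDGE:
                s = p[: i + 1]
                nxt = len(states)
                states.append(s)
                depth.append(i + 1)
                trie.append([_NO_EDGE] * sigma)
                index[s] = nxt
                parent.append((node, r))
                trie[node][r] = nxt
            node = nxt

    fail = [0] * len(states)
    goto = [row[:] for row in trie]

    order = sorted(range(len(states)), key=depth.__getitem__)
    for q in order:
        if depth[q] > 1:
            pq, r = parent[q]
            fail[q] = goto[fail[pq]][r]
        for r in range(sigma):
            t = trie[q][r]
            if t == _S_PRIME:
                goto[q][r] = FORBIDDEN
            elif t == _NO_EDGE:
                goto[q][r] = goto[fail[q]][r] if q != 0 else 0

    return PrefixAutomaton(
        alphabet=alphabet,
        states=states,
        goto=goto,
        fail=fail,
        depth=depth,
        _trie=trie,
        _index=index,
    )


def run(automaton: PrefixAutomaton, start: int, s: str) -> int:
    """Module-level alias for :meth:`PrefixAutomaton.run`."""
    return automaton.run(start, s)


def compute_non_sinks(
    automaton: PrefixAutomaton, patterns: PatternSet, v: str
) -> set[str]:
    """Dangerous strings ``q`` such that ``q·v`` contains a forbidden pattern.

    These are exactly the states at which a completion may *not* stop before
    appending the right context ``v``.  Every state whose string ``q``
    splits some pattern as ``q' · p`` — with ``q'`` a dangerous suffix of
    ``q`` and ``p`` a nonempty prefix of ``v`` — is a non-sink; note that
    the set is closed under extension along failure links (a state is
    dangerous for ``v`` whenever any of its dangerous suffixes is).

    Raises :class:`InfeasibleContext` if a pattern occurs inside ``v``.
    """
    automaton.alphabet.validate(v, what="right context")
    if automaton.contains_pattern(v):
        raise InfeasibleContext("a forbidden pattern occurs in the right context")
    return {
        automaton.states[q]
        for q in range(len(automaton.states))
        if not automaton.is_sink(q, v)
    }
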