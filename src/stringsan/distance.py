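"""LIS-based k-gram distance between strings.

For a string ``x``, ``S_k(x)`` is the left-to-right sequence of its
length-k substrings.  Listing, for each k-gram of ``x`` in order, all of
its (1-based) occurrence positions in another string ``y`` and
concatenating the lists yields the sequence ``Occ_y(S_k(x))``; the length
of its longest strictly increasing subsequence, ``LIS_k(x, y)``, counts
how many k-grams of ``x`` can be matched in ``y`` in a compatible order.
The (asymmetric) directed quantities combine into the symmetric distance

    L_k(x, y) = |x| + |y| - 2(k-1) - LIS_k(x, y) - LIS_k(y, x)

which is non-negative, zero on identical strings and symmetric, but
satisfies neither the triangle inequality nor the semimetric axiom
(distinct strings can be at distance zero).  It serves as a cheap proxy
for edit distance when comparing many long strings pairwise.
"""

from __future__ import annotations

from bisect import bisect_left
from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .errors import BadK


def kgram_sequence(x: str, k: int, drop: "set[str] | None" = None) -> list[str]:
    """The k-grams of ``x`` in order of occurrence; with ``drop`` given,
    members of it (e.g. a forbidden-pattern set) are omitted."""
    if k < 1:
        raise BadK(f"window length must be positive, got {k}")
    grams = [x[i : i + k] for i in range(len(x) - k + 1)]
    if drop is not None:
        grams = [g for g in grams if g not in drop]
    return grams


def occ_concatenation(x: str, y: str, k: int) -> list[int]:
    """Concatenated occurrence-position lists (1-based) of each k-gram of
    ``x`` within ``y``, in k-gram order; empty lists contribute nothing."""
    positions: dict[str, list[int]] = defaultdict(list)
    for j in range(len(y) - k + 1):
        positions[y[j : j + k]].append(j + 1)
    out: list[int] = []
    for g in kgram_sequence(x, k):
        out.extend(positions.get(g, ()))
    return out


def lis_length(seq) -> int:
    """Length of a longest strictly increasing subsequence (patience
    sorting, O(h log h))."""
    tails: list[int] = []
    for v in seq:
        i = bisect_left(tails, v)
        if i == len(tails):
            tails.append(v)
        else:
            tails[i] = v
    return len(tails)


def lis_k(x: str, y: str, k: int) -> int:
    """Directed LIS similarity of ``x`` into ``y``; not symmetric."""
    return lis_length(occ_concatenation(x, y, k))


def l_k(x: str, y: str, k: int) -> int:
    """The symmetric LIS-based k-gram distance (see module docstring)."""
    if k > min(len(x), len(y)):
        raise BadK(
            f"window length {k} exceeds a string length "
            f"({len(x)}, {len(y)}); the distance is undefined"
        )
    return len(x) + len(y) - 2 * (k - 1) - lis_k(x, y, k) - lis_k(y, x, k)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances with zero diagonal."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def distance_matrix(collection, k: int) -> DistanceMatrix:
    """Pairwise L_k distances of a string collection.

    Raises :class:`BadK`, naming the offending index, if any string is
    shorter than ``k``.
    """
    strings = list(collection)
    for i, s in enumerate(strings):
        if len(s) < k:
            raise BadK(f"string at index {i} is shorter than k={k}")
    n = len(strings)
    values = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            d = l_k(strings[i], strings[j], k)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(values=values)
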