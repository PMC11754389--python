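# stringsan

Missing-value replacement and full sanitization of strings under
forbidden-pattern constraints, with an LIS-based k-gram distance and
medoid clustering of sanitized collections.

## The problem

Sequential datasets — DNA reads, location traces, text modeled as strings —
routinely contain missing values (written `#`), whether from imprecise
measurement or because confidential substrings were deliberately deleted.
Before such strings can be analyzed they must be completed with *valid*
letters: the completion has to respect the context around the gap and must
not introduce any pattern from a user-supplied *antidictionary* `S` of
forbidden strings (implausible artifacts, or the very sensitive patterns
the deletion was meant to hide). `stringsan` treats this as a combinatorial
optimization problem and solves it exactly:

* **MVRS** (missing-value replacement): given a left context `u`, right
  context `v` and antidictionary `S`, find a *shortest* string `x` with
  prefix `u`, suffix `v` and no occurrence of any `s ∈ S` — or report FAIL.
  The solver builds a deterministic automaton whose states are the
  *dangerous* strings (ε and the proper prefixes of patterns), with
  Aho–Corasick-style failure links and a complete transition function
  `δ(q, α)` = longest dangerous suffix of `q·α` (or FORBIDDEN when a
  pattern would be completed). After a suffix/prefix-overlap check, a BFS
  from the state reached by spelling `u` to the nearest state that can
  safely precede `v` yields the optimum in
  `O(|u| + |v| + ‖S‖·|Σ|)` time. For fixed-length patterns this is
  equivalent to shortest-path search in the complete de Bruijn graph of
  order `k` with forbidden edges removed — without ever building the
  `Θ(|Σ|^k)`-size graph.
* **Full sanitization (SFSS)**: given `w` and a set `S_k ⊂ Σ^k`, produce
  the shortest string `y` over the *original* alphabet such that no
  forbidden pattern occurs in `y` and the sequence of non-forbidden
  k-grams of `w` survives, in order, as a subsequence of that of `y`.
  The partial sanitization `x₀#x₁#…#x_d` (TFS) is computed first; each
  `#` gap is then resolved by an MVRS instance between the length-(k−1)
  contexts flanking it. A greedy deletion baseline (GFSS) and a
  sanitization verifier are included.
* **Distance and clustering**: the LIS-based k-gram distance
  `𝓛_k(x,y) = |x| + |y| − 2(k−1) − LIS_k(x,y) − LIS_k(y,x)`,
  where `LIS_k(x,y)` is the longest strictly increasing subsequence of the
  concatenated occurrence lists of `x`'s k-grams in `y`; PAM K-medoids on
  the resulting matrix; NMI, a pair-counting adjusted Rand index, and an
  LIS-based cluster-compactness score.
* **Synthetic benchmarks**: collections with planted clusters (K seeds,
  L strings each at ≤ e random edits, noise `δ = e/|Q|`) and antidictionaries
  sampled from `Σ^k` at a rate `𝓡 = |S_k|/|Σ^k|` or from occurring k-grams.

## Worked example

```python
>>> from stringsan import *
>>> ab = Alphabet.from_string("ab")
>>> S = normalize_pattern_set(["bbbb", "aaba", "abba"], ab)
>>> solve_mvrs(MvrsInstance(u="aab", v="aba", patterns=S, alphabet=ab)).x
'aabbbaba'
>>> tfs("abbbbaaabaa", 4, S).text       # partial sanitization
'abbbaaab#abaa'
>>> sfss("abbbbaaabaa", 4, S)           # full sanitization
'abbbaaabbbabaa'
>>> gfss("abbbbaaabaa", 4, S)           # greedy baseline loses a k-gram
'abbbaaab'
>>> occ_concatenation("abbbbaaabaa", "abbbaaabbbabaa", 4)
[1, 7, 2, 8, 3, 4, 5, 11]
>>> lis_k("abbbbaaabaa", "abbbaaabbbabaa", 4)
6
>>> l_k("aaabaaab", "abaaaaaa", 4)
6
```

The replacement `aabbbaba` fills `aab#aba` with `bb` — the fewest new
letters that avoid all three forbidden 4-grams. The full sanitization
`abbbaaabbbabaa` keeps all six surviving 4-grams of the input (it is at
edit distance 4 from it), while the greedy baseline drops the final
`abaa`. The distance values combine the two directed LIS scores: for the
first pair both directions score 6, so
`l_k("abbbbaaabaa", "abbbaaabbbabaa", 4)` returns
`11 + 14 − 2·3 − 6 − 6 = 7`.

A command-line interface mirrors the library
(`stringsan mvrs|sanitize|distmat|cluster|evaluate|evaluate-lis|simulate|pipeline`);
`stringsan pipeline` chains sanitization, distance computation and
clustering and emits a JSON report with NMI/ARI scores.

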