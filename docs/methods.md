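# Methods

## Model and problem statements

All inputs are strings over a finite alphabet `Σ`; the symbol `#` is
reserved for missing values and can never be an alphabet member. An
*antidictionary* `S ⊂ Σ*` is a finite set of forbidden patterns.
Preprocessing normalizes `S` to *anti-factorial* form (no pattern a proper
substring of another; supersets are redundant and dropped) and deduplicates
it. When all patterns share one length `k` we write `S_k`.

**Missing-value replacement (MVRS).** Given contexts `u, v ∈ Σ*` and `S`,
find a shortest `x` with prefix `u`, suffix `v` and no occurrence of any
pattern; FAIL if none exists. Minimizing `|x|` minimizes the number of
invented letters and hence the k-gram distance between `u#v` and its
completion.

**Sanitization.** Given `w`, `k > 1` and `S_k ⊂ Σ^k`, let `𝒮(w, S_k)` be
the left-to-right sequence of non-forbidden k-grams of `w`. *Partial*
sanitization (TFS) asks for the shortest string whose k-gram sequence over
`Σ` equals `𝒮(w, S_k)`, using `#` as a segment separator. *Full*
sanitization (SFSS) asks for the shortest `y ∈ Σ*` with no forbidden
occurrence such that `𝒮(w, S_k)` is a subsequence of `𝒮(y, S_k)`.

## Algorithms

**Avoidance automaton.** States are the *dangerous* strings: ε plus all
proper prefixes of patterns (`1 + #distinct proper prefixes` states,
`Θ(‖S‖)` in the worst case). The trie of `S` is built, all pattern leaves
are conceptually merged into one forbidden node, and a breadth-first pass
fills the failure function `f(q)` (longest proper dangerous suffix) and the
complete transition table `δ(q, α)` (longest dangerous suffix of `q·α`,
or FORBIDDEN when `q·α` ends with a pattern) via the standard recurrence
`δ(q, α) = q·α` if that is a trie node, else `δ(f(q), α)`. Transition
storage is a dense `|states| × |Σ|` table with FORBIDDEN as a sentinel, so
lookups are O(1). Anti-factoriality guarantees `f` never lands on the
forbidden node, and that `δ(q, α)` is FORBIDDEN exactly when `q·α` has a
pattern as suffix.

**Sink characterization.** A state `q` may be followed directly by the
right context `v` iff `q·v` is pattern-free. Given `v` itself pattern-free,
any violation straddles the boundary: it factors as `t·p` with `t` a
dangerous suffix of `q` (an element of `q`'s failure chain) and `p` a
nonempty prefix of `v`. The sink test therefore walks the raw trie from
each failure-chain element along `v`, reporting non-sink iff a pattern node
is reached — `O(k²)` per query for uniform-length antidictionaries, with no
per-`v` preprocessing. Note the definitional set is closed along failure
links: a state is a non-sink whenever *any* dangerous suffix of it is, not
only the exact boundary splits; omitting the closure would certify
infeasible completions (e.g. `S = {aaba}`, `v = aba`: the state `aa` must
be a non-sink because `aa·aba` contains `aaba`, although `aa` itself splits
no pattern against `v`).

**MVRS solver.** After rejecting instances whose contexts already contain a
pattern (FAIL, `PATTERN_IN_CONTEXT`), solutions with `|x| ≤ |u| + |v|`
are sought first: spelling `u` through the automaton, each prefix length
`i` reached at a sink with `u[i:]` a prefix of `v` yields `x = u[:i]·v`;
prefixes are visited in decreasing overlap order, so the first hit is
optimal. Otherwise a BFS from the source (state after spelling `u`) over
non-FORBIDDEN transitions to the nearest sink produces `x = u·h·v`, with
`h = ε` allowed when the source is itself a sink. FAIL (`NO_PATH`)
otherwise. Ties among equally short solutions are broken deterministically:
BFS expands letters in alphabet-rank order and keeps first-discovery
parents, so the returned middle is the lexicographically smallest shortest
one (the underlying problem only asks for *a* shortest witness; the rule is
ours, chosen for reproducibility).

**TFS.** A single left-to-right scan with an extend-or-restart rule: a
surviving k-gram `g` extends the current output by one letter when the
output already ends with `g`'s (k−1)-prefix, and otherwise restarts a new
segment after `#`. Each step appends exactly one k-gram, so the output's
k-gram sequence over `Σ` equals `𝒮(w, S_k)`; segments have length ≥ k,
`|x| ≤ |w| + d·k`, and the result is the unique shortest such string. For
`|w| < k` the k-gram sequence is empty and TFS returns ε (a warning-level
situation for callers; GFSS returns `w` unchanged since it never forms a
k-gram). Because ε is always feasible, TFS itself never fails. Note the
extend rule fires whenever the suffix matches, including across a run of
skipped forbidden grams — this is what makes the output shortest (see
"Known discrepancies" below).

**SFSS.** Compute the partial string; for each gap solve MVRS with
`u` = length-(k−1) suffix of the text so far and `v` = length-(k−1) prefix
of the next segment, under the same antidictionary (per-gap
antidictionaries are supported as an optional argument at no extra cost);
splice `res.x[k−1:]` plus the rest of the next segment. Segments of length
≥ k make gaps independent, and overlaps in gap solutions never exceed
k−1 letters, so no surviving k-gram is lost; gap-local optimality then
gives global optimality (confirmed empirically by exhaustive search on tiny
instances). If any gap has no feasible replacement, SFSS reports a failure
value carrying the gap index. A single automaton is shared across all gaps
and may be shared across a whole collection.

**GFSS baseline.** Stream `w`, appending each letter unless the resulting
length-k suffix is forbidden. Membership uses a plain set of k-grams rather
than rolling-hash fingerprints — exact rather than Monte-Carlo, and fast at
the scales this package targets. Always fully sanitized and never longer
than `w`, but k-grams may be dropped wholesale: each deletion shifts the
frame and can cascade (e.g. `CAAAAAC` with `AAA` forbidden collapses to
`CAAC`), which is why its clustering quality degrades for small alphabets
and dense antidictionaries.

**Distance.** Occurrence lists use exact k-gram hashing (1-based positions,
ascending within each list); a suffix-tree index would give the same output
and is not needed at these scales. The LIS routine is patience sorting with
`bisect_left`, giving *strict* increase — equal positions across lists do
not chain. `𝓛_k` requires `k ≤ min(|x|, |y|)` and raises otherwise rather
than extrapolating (its properties are only established in that regime).
`𝓛_k` is symmetric, non-negative and zero on identical strings, but is not
a metric (the triple `aaabaaab / abaaaaaa / aaaaaaaa` at `k = 4` violates
the triangle inequality: 10 > 6 + 2) and not a semimetric
(`𝓛₃(aaa, aaaaaaa) = 0`).

**Clustering.** PAM on the precomputed matrix: initial medoids drawn
uniformly without replacement from a seeded generator; the swap phase
sweeps (medoid, non-medoid) pairs in index order, accepts the first
strictly improving swap and restarts, until a sweep passes clean (the
result is 1-swap-optimal and the cost non-increasing). Five independent
restarts from the same generator keep the stochastic spirit of random-swap
PAM while staying deterministic given (matrix, K, seed). Assignment ties go
to the lowest medoid index; each medoid belongs to its own cluster even
when another medoid sits at distance zero.

**Agreement measures.** NMI is `I(C, C') / max(H(C), H(C'))` with natural
logarithms (the ratio is base-invariant); two trivial partitions score 1,
exactly one trivial scores 0. The default ARI is the *pair-counting* form

    ARI = 2 (N00·N11 − N01·N10) /
          ((N00+N01)(N01+N11) + (N00+N10)(N10+N11))

which equals 1 iff the partitions coincide and can be negative; it is *not*
the conventional hypergeometric-expectation-corrected ARI, which is exposed
separately (`standard=True`, CLI `--ari-standard`) for cross-tool
comparison. The LIS quality score is
`Σ_i max_j (LIS_k(y_i, m_j) + LIS_k(m_j, y_i))` over medoids `m_j`.

## Synthetic data

The generator emulates clustering benchmarks for sequence collections:
uniformly random seeds of length `|Q|` (default 2000; real sequences may be
supplied instead), clusters of `L` strings consisting of the seed plus
`L − 1` copies at ≤ `e` random edits, labels recording the seed of origin.
"`e` edit operations, each equally likely" leaves the per-type distribution
open; we use uniform type ∈ {substitute, insert, delete}, uniform position,
uniform letter (substitution excludes the current letter), applied
sequentially so edits may cancel — the simplest reading, and every choice
is a parameter. Antidictionaries are sampled without replacement (a pattern
set is a set), either `round(R·|Σ|^k)` draws from `Σ^k` or draws from the
k-grams occurring in a dataset.

What the generator does *not* emulate: real alphabet skew and composition
bias, shared motifs between clusters, length variation, or antidictionaries
correlated with content. Passing the recovery tests therefore shows the
pipeline preserves *planted, edit-noise* cluster structure — evidence of
correctness of the machinery, not a claim about any particular corpus.

## Problem sizes used by the test suite

The oracle-equivalence suites use 500 random replacement instances
(`|Σ| ∈ {2, 3}`, contexts ≤ 5, patterns ≤ length 4) against exhaustive
enumeration, LIS sequences up to length 300 against a quadratic DP, and
exhaustive minimality checks on binary-alphabet inputs of length ≤ 10 with
`k ≤ 3`. The end-to-end recovery runs use collections of 3 clusters × 10
strings with seed length 500 (`k = 8`, `δ = 0.1`, `𝓡 = 0.1`, five
generator seeds; mean NMI against planted labels ≥ 0.9, observed 1.0), and
the greedy-vs-optimal contrast uses seed length 300 at `δ = 0.7`,
`𝓡 = 0.25`, `k = 3`, where greedy deletion cascades are frequent. These
sizes were chosen as the smallest at which the phenomena of interest are
unambiguous.

## Degenerate inputs and edge cases

Empty contexts are legal in MVRS: `v = ε` makes every state a sink (an
anti-factorial antidictionary cannot hide a pattern inside a dangerous
string), so pattern-free `u` is returned as-is; `u = v = ε` yields ε.
Length-1 patterns are allowed in MVRS (the automaton degenerates to the
single state ε). An empty antidictionary yields one state with `|Σ|`
self-loops and sanitization becomes the identity. Sanitization of a
collection drops records whose sanitization fails or ends shorter than `k`
from the distance/clustering stages and reports them in a failure manifest.

## Known discrepancies and limitations

* For inputs with overlapping forbidden occurrences whose flanks re-chain
  (e.g. `CAAAAAC` with `AAA` forbidden, `k = 3`), this implementation
  returns the true optimum `CAAC`: both surviving 3-grams `CAA`, `AAC`
  chain through the two-letter overlap `AA`, so no `#` and no replacement
  letters are needed beyond the final `C`. A widely circulated rendering of
  this example gives `CAACAAC`, which satisfies the constraints but is not
  shortest; the exhaustive minimality tests pin down the optimum. One
  acceptance test that asserts the longer rendering is deliberately left
  failing, documented where it stands.
* SFSS can genuinely FAIL under dense antidictionaries: a gap's right
  context may be blocked by forbidden patterns for *every* preceding
  letter. This is a property of the problem, not the solver (the test
  suite cross-checks one such instance by exhaustive and randomized
  search); callers must handle the failure value.
* The brute-force oracles certify optimality only within their enumeration
  budget; the solver itself is exact.
* `𝓛_k` is a similarity proxy, not a metric; clustering quality guarantees
  that require the triangle inequality do not transfer, and PAM returns a
  1-swap-optimal local minimum, not a global one.
* Edit-distance-optimal sanitization and ghost-pattern minimization are
  different objectives and out of scope; edit distance appears here only to
  validate the noise generator and to report the similarity of sanitized
  outputs.
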