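# Methods

## Model and conventions

A target system is a multiset of non-empty strings over a declared basic set
of indivisible blocks (single characters by default; multi-character blocks
are allowed).  Members are "not connected": no block ever spans two member
strings, which the implementation enforces structurally by keeping one pool
piece per member instance instead of concatenating them with a sentinel.

Costs are counted in lifts: a merge of *n* blocks costs *n − 1* (it is a
chain of *n − 1* pairwise concatenations, so merge arity never matters to
the optimum), and taking a target instance out of the multiset costs 1.
Consequences fixed by this accounting and asserted throughout the tests:

- the size-index of a single basic block is 1 (its one take-out lift);
- levels start at 1 for basic blocks; a product sits one level above its
  highest constituent;
- a member whose instances are all obtained by replication appears in the
  ladderpath with multiplicity `count − 1 + (uses as a constituent)`;
  a member with residual multiplicity 0 is deleted from the multiset
  (it may still be drawn in the laddergraph, annotated "(0)").

For multi-character basic sets, strings are mapped to token sequences by a
minimum-token-count dynamic program (ties resolved longest-block-first, left
to right), and both the per-letter conservation law and the repeat search
operate at token granularity.  The package does not branch over alternative
minimal tokenizations, and for pathological basic sets in which one basic
block spells the concatenation of others the search result is a valid but
not necessarily minimal ladderpath; with prefix-free or single-character
basic sets (every case exercised here) this does not arise.

## Length formula and validation

The length of a ladderpath J for target X is computed directly from the
multiset as `|J| = S(X) − Σᵢ mᵢ (S(i) − 1)`, summed over all ladderons
(basic blocks have S = 1 and drop out), and the order-index is the sum
itself.  `validate_ladderpath` checks, in order: structural sanity
(multiplicities ≥ 1, unique blocks, basic ⟺ level 1); existence of a
witness segmentation of every non-basic ladderon into strictly lower blocks
with a constituent exactly one level below; token conservation (for every
basic token, target occurrences = Σᵢ mᵢ·nᵢₐ over all ladderons); and joint
realizability — a backtracking assignment of one segmentation per generated
block such that every block is used exactly `m + generated − taken out`
times.  On success one witness generation path is returned and replaying it
reproduces the validated multiset exactly.  Conservation alone is necessary
but not sufficient, which is why the realizability step exists; its
backtracking is capped (50 000 nodes per enumeration) and raises rather than
guessing if the cap is hit.

Path simulation follows the replication convention: multiplicities may go
negative in transit, and take-outs do not require a positive count — only
that the instance is a known (basic or generated) block and a target member.
A merge whose output already exists in the multiset is rejected.

## Search

Both searches run one slicing engine over a pool of token pieces.  Forced
moves (applied to fixpoint): drop single-token pieces; remove any non-pending
piece equal to a committed ladderon (a replication, saving S − 1 lifts);
deduplicate identical pieces, committing the block as a new ladderon with one
*pending* copy left in the pool so its internal structure is decomposed in
turn.  Branching moves: factor a new repeat out of two disjoint occurrences,
or excise one occurrence of an already-committed ladderon.  The ladderpath
length is the total size-index minus the accumulated savings; multiplicities,
constituent sets and levels are reconstructed from the recorded
removal/use events, and the emitted ladderpath always satisfies conservation
and `λ + ω = S` (asserted over every fixture and 500 random cases).

**Exact search** is a depth-first enumeration of all such slicing schemes
with memoization on canonical states (sorted piece multiset plus the still-
relevant committed blocks) and branch-and-bound pruning.  The bound is the
count of "coverable" digram positions: every removable chunk has at least
two occurrences (or matches a committed block), so each of its digrams does
too, and disjoint chunks inside a run of r + 1 tokens save at most r lifts —
hence the count of positions whose digram occurs twice in the pool or inside
a committed block is an admissible upper bound on further savings (see the
bound's docstring and the oracle cross-check test).  `optimal=True` is set
only when the state space was exhausted; if the node budget (default
2 × 10⁶ states) runs out, the heuristic result is returned flagged
`optimal=False`.  Exact mode refuses inputs above `max_exact_size` (default
40 tokens) unless forced — never a silent fallback.  Ties between equally
short ladderpaths are resolved by the deterministic move ordering
(first-found optimum), so repeated runs return the identical canonical
result; we do not additionally canonicalize to the lexicographically
smallest co-optimal multiset, which would require enumerating all optima.
Highly degenerate inputs (unary strings beyond ~24 tokens, where the problem
degenerates to an addition-chain search) explode combinatorially and are
better served by the heuristic.

**Heuristic search** implements the longest-repeat bias: repeatedly excise
replications of committed ladderons and factor the longest token repeat with
at least two disjoint occurrences (leftmost-greedy; ties by occurrence
count, then lexicographically smallest), recursing into the kept copy.  The
longest repeat is found by binary search on length (a disjoint pair of
length-k occurrences implies one at k − 1), keeping the greedy usable at
thousands of tokens (a 1 000-token binary string decomposes in ~0.2 s).
The heuristic is deterministic and always reports `optimal=False`; on every
input where both run, its length is bounded below by the exact length and
above by the size-index (property-tested).

## Oracle

`ladderpath.oracle.enumerate_min_length` is an independent brute force used
only by tests: candidate ladderons are all length-≥ 2 subsequences with two
pairwise disjoint occurrences; for every candidate subset, the cheapest
consistent assignment is the per-block minimum-token segmentation DP, and
the cost is the number of segmentation boundaries plus one take-out per
instance.  It returns the global minimum and the number of distinct
canonical shortest multisets in reduced form (every committed ladderon used
at least twice; a block used once is indistinguishable, after zero-
multiplicity deletion, from inlining it).  Limits default to 9 total tokens
and 4 letters.  Exact search and oracle agree on 500 seeded random cases in
the acceptance suite and more in the unit tests.

## Synthetic generators

`random_string(n, k, seed)` draws i.i.d. uniform letters over a declared
k-letter alphabet — the "totally random" foil whose order-index is near
zero.  `planted_hierarchy` grows a block by concatenating it `reuse_factor`
times for `depth` rounds and records the planted path cost
`(base length − 1) + depth·(reuse_factor − 1) + 1`, a certified upper bound
on λ of the expansion; the bound is tight for pure doublings (verified
against the oracle) and both generators are seed-deterministic.  Note that
pure-power grammars with different (depth, reuse) splits can expand to the
same string, in which case only the planted costs differ, not λ.  What these
generators do not emulate: natural-sequence composition biases, noisy or
partial repeats, and alphabet non-uniformity — so green tests certify the
algebra and the search, not performance claims about real genomes or
corpora.

## A note on the Y′ example

For the 34-letter signal Y analysed over the basic set of its repeated units
{T, R, H, K, EF, MU, BCD} (18 tokens), the well-known decomposition
{…// TEF, BCDEF} has length 16 by the length formula, and the tests assert
that value for that multiset.  It is not minimal, however: deleting the
non-repeated letters creates a new token repeat EF·H·K (in the full signal
the second occurrence is interrupted by a J), and factoring EFHK together
with BCDEF yields a valid ladderpath of length 15 — found by both searches,
certified optimal by the exhaustive one, and easy to check by hand
(EF+H+K = EFHK: 2 lifts; BCD+EF = BCDEF: 1; the twelve-block merge of the
signal: 11; take-out: 1).  The package reports the computed minimum.

## Defaults that matter

| parameter | default | unit | why |
|---|---|---|---|
| `SearchConfig.max_exact_size` | 40 | tokens | exact state space is manageable below this for non-degenerate alphabets; refusal is explicit |
| `SearchConfig.node_budget` | 2 000 000 | states | caps worst-case exact runs; exhaustion falls back to the heuristic, flagged |
| `OracleLimit.max_total_length` | 9 | tokens | subset enumeration stays ≤ ~2¹⁸ configurations |
| `OracleLimit.max_alphabet` | 4 | letters | keeps candidate counts small |
| validation node cap | 50 000 | nodes | realizability backtracking on hand-sized multisets |

Problem sizes used in the shipped tests and acceptance script — strings of
16–34 letters, a 39-letter five-member system, 500 random strings of ≤ 9
letters, one 1 000-token heuristic run — were chosen so the whole suite
certifies the integer algebra exactly in a couple of seconds.
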