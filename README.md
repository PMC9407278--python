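# ladderpath

Hierarchical repeat decomposition of strings, in the spirit of assembly
theory: how cheaply can a target string — or a whole multiset of strings — be
built from a declared set of basic blocks when anything already built can be
reused for free?

The package is for people who want a syntactic, single-instance measure of
complexity: exobiologists scoring a received signal, origin-of-life
researchers comparing construction costs of sequence inventories, linguists
or bioinformaticians quantifying how much of a string is hierarchical reuse
rather than fresh information.

## The model

A **generation-operation** takes blocks from a partially ordered multiset,
concatenates them, and puts the product back one level above its highest
constituent; writing *n* blocks together costs *n − 1* **lifts**, and the
final take-out of each target instance costs one lift.  Distilling a
generation path (delete zero-multiplicity blocks, take absolute
multiplicities) yields its **ladderpath** *J*: a partially ordered multiset of
**ladderons** — the blocks that were reused — written, e.g. for
X = ABCDBCDBCDCDEFEF,

```
J_X = {A, B, C, D, E, F // CD, EF // BCD(2)}
```

Three indices, all in lifts, summarize a target X:

- **size-index** `S(X)` — length of the shortest *trivial* ladderpath
  (spell everything out in basic blocks: the minimal token count);
- **ladderpath-index** `λ(X)` — length of the shortest ladderpath, the
  minimal construction cost, computed here by exhaustive factoring with
  branch-and-bound (`exact_shortest`) or a longest-repeat-first greedy
  (`heuristic_shortest`);
- **order-index** `ω(X) = S(X) − λ(X)` — the lifts saved by reuse, i.e. how
  hierarchically organized the target is.

The length of any ladderpath can be read off its multiset directly:
`|J| = S(X) − Σᵢ mᵢ·(S(i) − 1)` over its ladderons *i* with multiplicities
*mᵢ*, and the identity `λ + ω = S` holds for every target.  λ and ω are two
distinct axes of complexity: a random string maximizes λ (hard to reproduce,
nothing reused), a highly repetitive one maximizes ω.

Finding λ exactly is at least as hard as an NP-complete problem (it is a
close relative of the smallest-grammar and addition-chain problems), so the
exact search is guarded by a size limit and a node budget; the heuristic
scales to thousands of tokens.

## Worked example

`X.txt` contains the single line `ABCDBCDBCDCDEFEF`:

```
$ ladderpath compute --mode exact --targets X.txt
{
  "schema_version": "1.0",
  ...
  "targets": [
    {
      "target_id": "X",
      "size": 16,
      "lambda": 10,
      "omega": 6,
      "optimal": true,
      "ladderpath": "{A, B, C, D, E, F // CD, EF // BCD(2)}",
      "elapsed_sec": 0.004
    }
  ]
}
```

Reading: spelling X letter-by-letter costs 16 lifts (its size-index); the
shortest construction instead builds CD, reuses it inside BCD, writes BCD
once and replicates it twice, for 10 lifts total (λ); the 6 saved lifts are
the order-index ω.  `optimal: true` certifies the exact search exhausted the
state space.

Multisets of strings work the same way — lines may carry a tab-separated
count, FASTA input accumulates duplicate sequences, and repeats are shared
across members but never span them:

```
$ ladderpath compute --targets Q.txt --out tsv
target_id  size  lambda  omega  optimal
Q          39    17      22     True
```

Other entry points: `--graph out.dot` writes the laddergraph (the
transitively reduced constituent DAG) in DOT format; `ladderpath validate
J.pom --targets X.txt` checks a user-supplied multiset against the
definition (segmentability, level placement, per-letter conservation,
realizability by an actual generation path) and reports its length.  The
same functionality is available as a library:

```python
from ladderpath import BasicSet, TargetSystem, exact_shortest

target = TargetSystem("ABCDBCDBCDCDEFEF", BasicSet("ABCDEF"))
result = exact_shortest(target)
result.summary          # IndexSummary(size_index=16, ladderpath_index=10, order_index=6)
```

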