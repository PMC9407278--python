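"""Brute-force reference for shortest ladderpaths of tiny targets.

Deliberately independent of :mod:`ladderpath.search` (different formulation,
no shared code), so agreement between the two is evidence rather than
tautology.  The enumeration works over *ladderon type subsets*: every
candidate ladderon is a token subsequence with at least two pairwise disjoint
occurrences across the target instances; for each subset the cheapest
assignment of segmentations is a per-block minimum-token dynamic program
(the cost of a ladderpath is the number of segmentation boundaries plus one
take-out lift per target instance, which is exactly the partially-ordered-
multiset length formula summed the other way around).
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass

from .core import BasicSet, LadderpathError, TargetSystem

__all__ = ["OracleLimit", "OracleLimitError", "enumerate_min_length"]

TokenTuple = tuple[str, ...]


class OracleLimitError(LadderpathError):
    """The input exceeds the oracle's enumeration limits."""


@dataclass(frozen=True)
class OracleLimit:
    max_total_length: int = 9
    max_alphabet: int = 4
    max_candidates: int = 18


def _has_disjoint_pair(spans: list[tuple[int, int]], counts: list[int], k: int) -> bool:
    """spans: (member index, start); counts: instance count per member."""
    for (m1, s1), (m2, s2) in itertools.combinations(spans, 2):
        if m1 != m2 or abs(s1 - s2) >= k:
            return True
    return any(counts[m] >= 2 for m, _ in spans)


def _min_tokens_dp(block: TokenTuple, parts: list[TokenTuple]) -> int | None:
    n = len(block)
    best: list[float] = [float("inf")] * (n + 1)
    best[0] = 0
    for i in range(n):
        if best[i] == float("inf"):
            continue
        for p in parts:
            j = i + len(p)
            if j <= n and block[i:j] == p:
                best[j] = min(best[j], best[i] + 1)
    return None if best[n] == float("inf") else int(best[n])


def _all_optimal_segs(
    block: TokenTuple, parts: list[TokenTuple], cap: int = 20_000
) -> list[tuple[TokenTuple, ...]]:
    n = len(block)
    best: list[float] = [float("inf")] * (n + 1)
    best[n] = 0
    for i in range(n - 1, -1, -1):
        for p in parts:
            j = i + len(p)
            if j <= n and block[i:j] == p and best[j] + 1 < best[i]:
                best[i] = best[j] + 1
    out: list[tuple[TokenTuple, ...]] = []

    def rec(i: int, acc: list[TokenTuple]) -> None:
        if len(out) > cap:
            raise OracleLimitError("too many optimal segmentations")
        if i == n:
            out.append(tuple(acc))
            return
        for p in parts:
            j = i + len(p)
            if j <= n and block[i:j] == p and best[j] + 1 == best[i]:
                acc.append(p)
                rec(j, acc)
                acc.pop()

    rec(0, [])
    return out


def enumerate_min_length(
    target: TargetSystem,
    basic: BasicSet | None = None,
    lim: OracleLimit | None = None,
) -> tuple[int, int]:
    """Exhaustive minimum ladderpath length and the number of distinct
    canonical shortest ladderpaths (in reduced form: every committed ladderon
    actually reused).  Only for tiny targets; raises
    :class:`OracleLimitError` beyond the limits."""
    basic = basic or target.basic_set
    lim = lim or OracleLimit()
    member_tokens = {m: basic.tokenize(m) for m in target.members}
    total = sum(c * len(member_tokens[m]) for m, c in target.members.items())
    alphabet = {t for toks in member_tokens.values() for t in toks}
    if total > lim.max_total_length:
        raise OracleLimitError(
            f"total token length {total} exceeds the oracle limit {lim.max_total_length}"
        )
    if len(alphabet) > lim.max_alphabet:
        raise OracleLimitError(
            f"alphabet size {len(alphabet)} exceeds the oracle limit {lim.max_alphabet}"
        )
    if total == 0:
        return 0, 1

    members = sorted(target.members)
    counts = [target.members[m] for m in members]
    tuples = [member_tokens[m] for m in members]
    n_instances = sum(counts)

    # candidate ladderons: length >= 2 subsequences with two disjoint
    # occurrences somewhere among the instances
    spans: dict[TokenTuple, list[tuple[int, int]]] = {}
    for mi, toks in enumerate(tuples):
        n = len(toks)
        for length in range(2, n + 1):
            for start in range(n - length + 1):
                s = toks[start : start + length]
                spans.setdefault(s, []).append((mi, start))
    member_set = set(tuples)
    candidates = sorted(
        s
        for s, sp in spans.items()
        if s not in member_set
        and basic.min_tokens("".join(s)) >= 2
        and _has_disjoint_pair(sp, counts, len(s))
    )
    if len(candidates) > lim.max_candidates:
        raise OracleLimitError(
            f"{len(candidates)} candidate ladderons exceed the oracle limit"
        )

    basic_parts = [(b,) for b in sorted(basic.blocks)]
    non_basic_members = sorted(
        {t for t in tuples if basic.min_tokens("".join(t)) >= 2}
    )

    def cost_of(subset: tuple[TokenTuple, ...]) -> int | None:
        builds = sorted(set(subset) | set(non_basic_members), key=lambda t: (len(t), t))
        available = list(builds)
        cost = n_instances
        for b in builds:
            parts = basic_parts + [p for p in available if len(p) < len(b)]
            mt = _min_tokens_dp(b, parts)
            if mt is None:
                return None
            cost += mt - 1
        return cost

    best = None
    best_subsets: list[tuple[TokenTuple, ...]] = []
    for r in range(len(candidates) + 1):
        for subset in itertools.combinations(candidates, r):
            c = cost_of(subset)
            if c is None:
                continue
            if best is None or c < best:
                best = c
                best_subsets = [subset]
            elif c == best:
                best_subsets.append(subset)
    assert best is not None

    # count distinct canonical ladderpaths attaining the minimum
    from .notation import serialize_pom
    from .core import Ladderpath

    canon: set[str] = set()
    for subset in best_subsets:
        builds = sorted(set(subset) | set(non_basic_members), key=lambda t: (len(t), t))
        per_build: list[list[tuple[TokenTuple, ...]]] = []
        for b in builds:
            parts = basic_parts + [p for p in builds if p != b and len(p) < len(b)]
            per_build.append(_all_optimal_segs(b, parts))
        for combo in itertools.product(*per_build):
            uses: Counter[TokenTuple] = Counter()
            for seg in combo:
                uses.update(seg)
            # reduced form: every non-member ladderon reused at least twice
            ok = True
            mult: dict[TokenTuple, int] = {}
            seg_of = dict(zip(builds, combo))
            for t in builds:
                c_t = target.members.get("".join(t), 0)
                m_t = uses[t] + c_t - 1
                if t in subset and uses[t] < 2:
                    ok = False
                    break
                if m_t < 0:
                    ok = False
                    break
                mult[t] = m_t
            if not ok:
                continue
            levels: dict[TokenTuple, int] = {}

            def level(t: TokenTuple) -> int:
                if len(t) == 1:
                    return 1
                if t not in levels:
                    levels[t] = 1 + max(level(p) for p in seg_of[t])
                return levels[t]

            blocks: dict[str, tuple[int, int]] = {}
            for t in builds:
                if mult[t] >= 1:
                    blocks["".join(t)] = (mult[t], level(t))
            for bt in {p for seg in combo for p in seg if len(p) == 1}:
                m_b = uses[bt] + target.members.get("".join(bt), 0)
                if m_b >= 1:
                    blocks["".join(bt)] = (m_b, 1)
            for m, c in target.members.items():
                toks = member_tokens[m]
                if len(toks) == 1 and toks not in uses:
                    blocks[m] = (c + uses[toks], 1)
            lp = Ladderpath.from_blocks(blocks, basic, target)
            canon.add(serialize_pom(lp))
    return best, len(canon)
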