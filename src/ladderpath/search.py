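"""Shortest (exact) and short (heuristic) ladderpath search.

Both searches run the same *slicing* engine over a pool of token pieces:

* the pool starts as one piece per target instance (duplicate instances are
  deduplicated immediately — replication is free up to the take-out lift);
* *factoring* a repeated subsequence ``s`` excises occurrences of ``s`` from
  the pieces that host them, commits ``s`` as a new ladderon and leaves one
  pending copy in the pool so that the internal structure of ``s`` can be
  decomposed in turn;
* occurrences of an already-committed ladderon are excised one at a time;
* pieces with no further repeats are cut into basic tokens.

Every removed copy of a block of size-index S saves exactly S − 1 lifts over
spelling it out from basic blocks, so the search maximizes the total savings;
the ladderpath length is the size-index minus the savings.  The exact search
branches over every factoring decision with memoization on canonical pool
states and an admissible repeat-coverage bound; the heuristic greedily takes
the longest repeat (most occurrences, then lexicographically smallest) and
never backtracks.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

from .core import (
    BasicSet,
    IndexSummary,
    Ladderpath,
    LadderpathError,
    TargetSystem,
    size_index,
)

__all__ = [
    "SearchConfig",
    "SearchResult",
    "SizeGuardError",
    "exact_shortest",
    "heuristic_shortest",
    "shortest",
]

logger = logging.getLogger(__name__)

TokenTuple = tuple[str, ...]


class SizeGuardError(LadderpathError):
    """Exact search refused: the input exceeds the configured size guard."""


class _BudgetExceeded(Exception):
    pass


@dataclass(frozen=True)
class SearchConfig:
    """Search settings.

    ``max_exact_size`` caps the total token count admitted to exact search
    unless ``force_exact`` is set (the refusal is explicit, never a silent
    fallback).  ``node_budget`` caps the number of explored states; if it is
    exhausted the best complete decomposition found so far is returned with
    ``optimal=False``.  ``seed`` is reserved: both algorithms are
    deterministic.
    """

    mode: str = "exact"
    max_exact_size: int = 40
    node_budget: int = 2_000_000
    tie_break: str = "first-found"
    seed: int = 0
    force_exact: bool = False

    def __post_init__(self) -> None:
        if self.max_exact_size < 1 or self.node_budget < 1:
            raise ValueError("budgets must be positive")


@dataclass(frozen=True)
class SearchResult:
    ladderpath: Ladderpath
    summary: IndexSummary
    optimal: bool


# a pool piece: the token subsequence still to decompose, the block whose
# construction it belongs to, and whether it is the designated pending copy
# of a committed ladderon (pending copies are built, never removed whole)
@dataclass(frozen=True)
class _Piece:
    tokens: TokenTuple
    build: TokenTuple
    pending: bool = False


class _Engine:
    """Shared slicing machinery: occurrence finding, move application,
    savings/parts bookkeeping and ladderpath reconstruction."""

    def __init__(self, target: TargetSystem, basic: BasicSet):
        self.target = target
        self.basic = basic
        self._sdp: dict[TokenTuple, int] = {}
        self._single_char = all(len(b) == 1 for b in basic.blocks)

    def sdp(self, tokens: TokenTuple) -> int:
        """Size-index of the block spelled by ``tokens``."""
        if self._single_char:
            return len(tokens)
        v = self._sdp.get(tokens)
        if v is None:
            v = self.basic.min_tokens("".join(tokens))
            self._sdp[tokens] = v
        return v

    # -- initial state ------------------------------------------------

    def initial(self) -> tuple[list[_Piece], set[TokenTuple], int, list[tuple]]:
        pieces: list[_Piece] = []
        events: list[tuple] = []
        for member, count in self.target.members.items():
            tw = self.basic.tokenize(member)
            if len(tw) == 1:
                # a basic member: its instances come straight from the
                # reservoir of basic blocks, one take-out lift each
                events.append(("basic_member", tw, count))
                continue
            for _ in range(count):
                pieces.append(_Piece(tw, tw))
        committed: set[TokenTuple] = set()
        pieces, savings, more = self._normalize(pieces, committed)
        events.extend(more)
        return pieces, committed, savings, events

    # -- normalization (forced moves) -----------------------------------

    def _normalize(
        self, pieces: list[_Piece], committed: set[TokenTuple]
    ) -> tuple[list[_Piece], int, list[tuple]]:
        """Apply all forced moves: drop single-token pieces, remove
        replications of committed ladderons, deduplicate identical pieces.
        Mutates ``committed``; returns (pieces, savings, events)."""
        savings = 0
        events: list[tuple] = []
        changed = True
        while changed:
            changed = False
            kept: list[_Piece] = []
            for p in pieces:
                if len(p.tokens) == 1:
                    events.append(("use", p.build, p.tokens))
                    changed = True
                elif not p.pending and p.tokens in committed:
                    savings += self.sdp(p.tokens) - 1
                    events.append(("copy", p.tokens))
                    if p.build != p.tokens:
                        events.append(("use", p.build, p.tokens))
                    changed = True
                else:
                    kept.append(p)
            pieces = kept
            groups: dict[TokenTuple, list[int]] = defaultdict(list)
            for i, p in enumerate(pieces):
                if not p.pending:
                    groups[p.tokens].append(i)
            dup = next(
                (t for t, idxs in groups.items() if len(idxs) >= 2 and self.sdp(t) >= 2),
                None,
            )
            if dup is not None:
                idxs = set(groups[dup])
                kept = [p for i, p in enumerate(pieces) if i not in idxs]
                for i in sorted(idxs):
                    p = pieces[i]
                    if p.build != dup:
                        events.append(("use", p.build, dup))
                n = len(idxs)
                savings += (n - 1) * (self.sdp(dup) - 1)
                for _ in range(n - 1):
                    events.append(("copy", dup))
                committed.add(dup)
                kept.append(_Piece(dup, dup, pending=True))
                pieces = kept
                changed = True
        pieces.sort(key=lambda p: (p.tokens, p.build, p.pending))
        return pieces, savings, events

    # -- occurrence scanning --------------------------------------------

    @staticmethod
    def _occurrences(piece: TokenTuple, s: TokenTuple) -> list[int]:
        n, k = len(piece), len(s)
        return [i for i in range(n - k + 1) if piece[i : i + k] == s]

    def _subtuple_occurrences(
        self, pieces: Sequence[_Piece]
    ) -> dict[TokenTuple, list[tuple[int, int]]]:
        """All subsequences of length ≥ 2 → list of (piece index, start)."""
        occ: dict[TokenTuple, list[tuple[int, int]]] = defaultdict(list)
        for pi, p in enumerate(pieces):
            n = len(p.tokens)
            for length in range(2, n + 1):
                for start in range(n - length + 1):
                    occ[p.tokens[start : start + length]].append((pi, start))
        return occ

    @staticmethod
    def _disjoint(a: tuple[int, int], b: tuple[int, int], k: int) -> bool:
        if a[0] != b[0]:
            return True
        return abs(a[1] - b[1]) >= k

    # -- move application -------------------------------------------------

    def _excise(
        self, pieces: list[_Piece], spans: list[tuple[int, int, int]]
    ) -> list[_Piece]:
        """Remove (piece index, start, length) spans; spans within one piece
        must be disjoint.  Returns the new piece list (fragments inherit the
        host's build and are never pending)."""
        by_piece: dict[int, list[tuple[int, int]]] = defaultdict(list)
        for pi, start, length in spans:
            by_piece[pi].append((start, length))
        out: list[_Piece] = []
        for pi, p in enumerate(pieces):
            if pi not in by_piece:
                out.append(p)
                continue
            cuts = sorted(by_piece[pi])
            pos = 0
            for start, length in cuts:
                if start > pos:
                    out.append(_Piece(p.tokens[pos:start], p.build))
                pos = start + length
            if pos < len(p.tokens):
                out.append(_Piece(p.tokens[pos:], p.build))
        return out

    def apply_factor(
        self,
        pieces: list[_Piece],
        committed: set[TokenTuple],
        s: TokenTuple,
        occs: list[tuple[int, int]],
    ) -> tuple[list[_Piece], int, list[tuple]]:
        """Factor a new ladderon ``s`` out of ≥2 disjoint occurrences: all are
        excised, one pending copy enters the pool, the others count as
        replications.  Mutates ``committed``; returns (pieces, savings, events)."""
        events: list[tuple] = []
        k = len(s)
        for pi, start in occs:
            host = pieces[pi]
            whole = start == 0 and k == len(host.tokens)
            if not (whole and host.build == s):
                events.append(("use", host.build, s))
        n = len(occs)
        savings = (n - 1) * (self.sdp(s) - 1)
        for _ in range(n - 1):
            events.append(("copy", s))
        pieces = self._excise(pieces, [(pi, st, k) for pi, st in occs])
        committed.add(s)
        pieces.append(_Piece(s, s, pending=True))
        pieces, extra, more = self._normalize(pieces, committed)
        return pieces, savings + extra, events + more

    def apply_known(
        self,
        pieces: list[_Piece],
        committed: set[TokenTuple],
        t: TokenTuple,
        occ: tuple[int, int],
    ) -> tuple[list[_Piece], int, list[tuple]]:
        """Excise one occurrence of an already-committed ladderon."""
        pi, start = occ
        events: list[tuple] = [("use", pieces[pi].build, t), ("copy", t)]
        savings = self.sdp(t) - 1
        pieces = self._excise(pieces, [(pi, start, len(t))])
        pieces, extra, more = self._normalize(pieces, committed)
        return pieces, savings + extra, events + more

    def terminal_events(self, pieces: Sequence[_Piece]) -> list[tuple]:
        events: list[tuple] = []
        for p in pieces:
            for tok in p.tokens:
                events.append(("use", p.build, (tok,)))
        return events

    # -- reconstruction -----------------------------------------------------

    def build_ladderpath(self, events: Iterable[tuple]) -> Ladderpath:
        m: Counter[TokenTuple] = Counter()
        parts: dict[TokenTuple, Counter] = defaultdict(Counter)
        basic_m: Counter[TokenTuple] = Counter()
        for ev in events:
            if ev[0] == "copy":
                m[ev[1]] += 1
            elif ev[0] == "use":
                _, build, part = ev
                parts[build][part] += 1
                if len(part) == 1:
                    basic_m[part] += 1
            else:  # basic_member
                _, t, count = ev
                basic_m[t] += count

        levels: dict[TokenTuple, int] = {}

        def level(t: TokenTuple) -> int:
            if len(t) == 1:
                return 1
            v = levels.get(t)
            if v is None:
                v = 1 + max(level(p) for p in parts[t])
                levels[t] = v
            return v

        blocks: dict[str, tuple[int, int]] = {}
        for t, count in m.items():
            if count >= 1 and len(t) > 1:
                blocks["".join(t)] = (count, level(t))
        for t, count in basic_m.items():
            if count >= 1:
                blocks["".join(t)] = (count, 1)
        return Ladderpath.from_blocks(blocks, self.basic, self.target)

    def result(self, savings: int, events: list[tuple], optimal: bool) -> SearchResult:
        s = size_index(self.target, self.basic)
        lp = self.build_ladderpath(events)
        summary = IndexSummary(s, s - savings, savings)
        return SearchResult(lp, summary, optimal)


# ---------------------------------------------------------------------------
# heuristic search: longest repeat first
# ---------------------------------------------------------------------------


def _greedy_disjoint(occs: list[tuple[int, int]], k: int) -> list[tuple[int, int]]:
    """Leftmost-greedy maximal set of pairwise disjoint occurrences."""
    chosen: list[tuple[int, int]] = []
    last: dict[int, int] = {}
    for pi, start in sorted(occs):
        if pi not in last or start >= last[pi]:
            chosen.append((pi, start))
            last[pi] = start + k
    return chosen


def _repeats_of_length(
    pieces: Sequence[_Piece], k: int
) -> dict[TokenTuple, list[tuple[int, int]]]:
    """Length-k subsequences with >= 2 disjoint occurrences (greedy count)."""
    occ: dict[TokenTuple, list[tuple[int, int]]] = defaultdict(list)
    for pi, p in enumerate(pieces):
        toks = p.tokens
        for start in range(len(toks) - k + 1):
            occ[toks[start : start + k]].append((pi, start))
    out: dict[TokenTuple, list[tuple[int, int]]] = {}
    for s, occs in occ.items():
        if len(occs) < 2:
            continue
        chosen = _greedy_disjoint(occs, k)
        if len(chosen) >= 2:
            out[s] = chosen
    return out


def _longest_repeats(
    pieces: Sequence[_Piece],
) -> dict[TokenTuple, list[tuple[int, int]]]:
    """The repeats of maximal token length, found by binary search.

    Monotone because the (k-1)-prefixes of a disjoint pair of length-k
    occurrences are themselves a disjoint pair.
    """
    hi = max((len(p.tokens) for p in pieces), default=0)
    if hi < 2:
        return {}
    lo, best = 2, {}
    while lo <= hi:
        mid = (lo + hi) // 2
        found = _repeats_of_length(pieces, mid)
        if found:
            best = found
            lo = mid + 1
        else:
            hi = mid - 1
    return best


def heuristic_shortest(
    target: TargetSystem,
    basic: BasicSet | None = None,
    cfg: SearchConfig | None = None,
) -> SearchResult:
    """Short (not guaranteed shortest) ladderpath via the longest-repeat bias.

    Repeatedly deduplicates identical blocks, then factors the longest token
    subsequence with at least two disjoint occurrences (ties: more
    occurrences, then lexicographically smallest), keeping one occurrence as
    a new ladderon whose inside is decomposed recursively.  Deterministic;
    always flagged non-optimal.
    """
    basic = basic or target.basic_set
    eng = _Engine(target, basic)
    pieces, committed, savings, events = eng.initial()
    while True:
        best_key = None
        best_action = None
        # replications of committed ladderons still occurring inside pieces
        # (whole-piece matches were removed by normalization and the pending
        # copy itself is never an occurrence to excise)
        for s in sorted(committed):
            if eng.sdp(s) < 2:
                continue
            usable = [
                (pi, st)
                for pi, p in enumerate(pieces)
                if not (p.pending and p.tokens == s)
                for st in eng._occurrences(p.tokens, s)
            ]
            if not usable:
                continue
            chosen = _greedy_disjoint(usable, len(s))
            key = (len(s), len(chosen), tuple(-ord(c) for c in "".join(s)))
            if best_key is None or key > best_key:
                best_key = key
                best_action = ("known", s, chosen)
        # longest new repeats; step down in length if every repeat at the
        # maximal length is already committed or saves nothing (the latter
        # can happen with multi-character basic sets)
        longest = _longest_repeats(pieces)
        k_max = max((len(s) for s in longest), default=0)
        for k in range(k_max, 1, -1):
            found = longest if k == k_max else _repeats_of_length(pieces, k)
            useful = {
                s: chosen
                for s, chosen in found.items()
                if s not in committed and eng.sdp(s) >= 2
            }
            if useful:
                for s, chosen in useful.items():
                    key = (len(s), len(chosen), tuple(-ord(c) for c in "".join(s)))
                    if best_key is None or key > best_key:
                        best_key = key
                        best_action = ("new", s, chosen)
                break
        if best_action is None:
            break
        kind, s, chosen = best_action
        if kind == "new":
            pieces, sv, evs = eng.apply_factor(pieces, committed, s, chosen)
        else:
            sv, evs = 0, []
            for occ in chosen:
                # occurrences shift as pieces are excised: redo one at a time
                occs_now = [
                    (pi, st)
                    for pi, p in enumerate(pieces)
                    for st in eng._occurrences(p.tokens, s)
                    if not (p.pending and p.tokens == s)
                ]
                if not occs_now:
                    break
                pieces, sv1, evs1 = eng.apply_known(pieces, committed, s, occs_now[0])
                sv += sv1
                evs += evs1
        savings += sv
        events += evs
    events += eng.terminal_events(pieces)
    return eng.result(savings, events, optimal=False)


# ---------------------------------------------------------------------------
# exact search: branch and bound over all factorings
# ---------------------------------------------------------------------------


class _ExactSolver:
    def __init__(self, eng: _Engine, node_budget: int):
        self.eng = eng
        self.node_budget = node_budget
        self.nodes = 0
        self.memo: dict[tuple, int] = {}

    # admissible upper bound on further savings: every removable chunk sits
    # inside a run of "coverable" digrams (digrams occurring at least twice
    # across the pool, or occurring inside a committed ladderon), and disjoint
    # chunks within a run of r+1 tokens save at most r lifts in total
    def _bound(self, pieces: Sequence[_Piece], committed: set[TokenTuple]) -> int:
        digram_count: Counter[TokenTuple] = Counter()
        for p in pieces:
            toks = p.tokens
            for i in range(len(toks) - 1):
                digram_count[toks[i : i + 2]] += 1
        covered: set[TokenTuple] = set()
        for t in committed:
            for i in range(len(t) - 1):
                covered.add(t[i : i + 2])
        total = 0
        for p in pieces:
            toks = p.tokens
            for i in range(len(toks) - 1):
                d = toks[i : i + 2]
                if digram_count[d] >= 2 or d in covered:
                    total += 1
        return total

    def _relevant(self, pieces: Sequence[_Piece], committed: set[TokenTuple]) -> frozenset:
        rel = set()
        for t in committed:
            k = len(t)
            for p in pieces:
                if any(p.tokens[i : i + k] == t for i in range(len(p.tokens) - k + 1)):
                    rel.add(t)
                    break
        return frozenset(rel)

    def _key(self, pieces: Sequence[_Piece], committed: set[TokenTuple]) -> tuple:
        return (
            tuple(sorted(p.tokens for p in pieces)),
            self._relevant(pieces, committed),
        )

    def _moves(
        self, pieces: list[_Piece], committed: set[TokenTuple]
    ) -> list[tuple]:
        eng = self.eng
        moves: list[tuple] = []
        occ_map = eng._subtuple_occurrences(pieces)
        for s in sorted(occ_map, key=lambda t: (-len(t), t)):
            if eng.sdp(s) < 2:
                continue
            occs = occ_map[s]
            if s in committed:
                for occ in occs:
                    p = pieces[occ[0]]
                    if p.pending and p.tokens == s:
                        continue
                    moves.append(("known", s, occ))
            else:
                k = len(s)
                for a in range(len(occs)):
                    for b in range(a + 1, len(occs)):
                        if eng._disjoint(occs[a], occs[b], k):
                            moves.append(("new", s, (occs[a], occs[b])))
        return moves

    def _apply(
        self, pieces: list[_Piece], committed: set[TokenTuple], move: tuple
    ) -> tuple[list[_Piece], set[TokenTuple], int, list[tuple]]:
        committed2 = set(committed)
        if move[0] == "new":
            s, (o1, o2) = move[1], move[2]
            p2, sv, evs = self.eng.apply_factor(list(pieces), committed2, s, [o1, o2])
        else:
            s, occ = move[1], move[2]
            p2, sv, evs = self.eng.apply_known(list(pieces), committed2, s, occ)
        return p2, committed2, sv, evs

    def best_savings(self, pieces: list[_Piece], committed: set[TokenTuple]) -> int:
        key = self._key(pieces, committed)
        hit = self.memo.get(key)
        if hit is not None:
            return hit
        self.nodes += 1
        if self.nodes > self.node_budget:
            raise _BudgetExceeded()
        best = 0
        if self._bound(pieces, committed) > 0:
            for move in self._moves(pieces, committed):
                p2, c2, sv, _ = self._apply(pieces, committed, move)
                if sv + self._bound(p2, c2) <= best:
                    continue
                total = sv + self.best_savings(p2, c2)
                if total > best:
                    best = total
        self.memo[key] = best
        return best

    def walk(
        self, pieces: list[_Piece], committed: set[TokenTuple]
    ) -> list[tuple]:
        """Replay one optimal line, collecting reconstruction events."""
        events: list[tuple] = []
        while True:
            value = self.best_savings(pieces, committed)
            if value == 0:
                events += self.eng.terminal_events(pieces)
                return events
            for move in self._moves(pieces, committed):
                p2, c2, sv, evs = self._apply(pieces, committed, move)
                if sv + self.best_savings(p2, c2) == value:
                    events += evs
                    pieces, committed = p2, c2
                    break
            else:  # pragma: no cover - would indicate an inconsistent memo
                raise LadderpathError("optimal line reconstruction failed")


def exact_shortest(
    target: TargetSystem,
    basic: BasicSet | None = None,
    cfg: SearchConfig | None = None,
) -> SearchResult:
    """Globally shortest ladderpath by exhaustive factoring with pruning.

    Enumerates every deterministic slicing scheme — deduplicate identical
    blocks, factor a repeated subsequence out of a pair of disjoint
    occurrences, excise replications of committed ladderons — with
    memoization on canonical pool states, branch-and-bound pruning and a
    node budget.  ``optimal=True`` only when the state space was exhausted;
    on budget exhaustion the longest-repeat heuristic result is returned
    with ``optimal=False``.
    """
    basic = basic or target.basic_set
    cfg = cfg or SearchConfig()
    eng = _Engine(target, basic)
    if target.is_empty:
        return eng.result(0, [], optimal=True)
    total_tokens = sum(
        c * len(basic.tokenize(m)) for m, c in target.members.items()
    )
    if total_tokens > cfg.max_exact_size and not cfg.force_exact:
        raise SizeGuardError(
            f"exact search refused: {total_tokens} tokens exceed the guard of "
            f"{cfg.max_exact_size}; use heuristic mode or force_exact"
        )
    pieces, committed, savings0, events0 = eng.initial()
    solver = _ExactSolver(eng, cfg.node_budget)
    try:
        extra = solver.best_savings(pieces, committed)
        events = events0 + solver.walk(pieces, committed)
        logger.debug("exact search explored %d states", solver.nodes)
        return eng.result(savings0 + extra, events, optimal=True)
    except _BudgetExceeded:
        logger.warning(
            "exact search node budget (%d) exhausted after %d states; "
            "falling back to the heuristic result",
            cfg.node_budget,
            solver.nodes,
        )
        res = heuristic_shortest(target, basic, cfg)
        return replace(res, optimal=False)


def shortest(
    target: TargetSystem,
    basic: BasicSet | None = None,
    cfg: SearchConfig | None = None,
) -> SearchResult:
    """Dispatch on ``cfg.mode`` (exact by default)."""
    cfg = cfg or SearchConfig()
    if cfg.mode == "exact":
        return exact_shortest(target, basic, cfg)
    if cfg.mode == "heuristic":
        return heuristic_shortest(target, basic, cfg)
    raise ValueError(f"unknown search mode {cfg.mode!r}")
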