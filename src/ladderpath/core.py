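"""Domain types and index algebra for ladderpath decompositions.

A *ladderpath* describes how a target string (or a multiset of strings, a
*target system*) can be assembled from a user-declared *basic set* of
indivisible blocks by repeatedly concatenating blocks, reusing anything that
has already been built.  The partially ordered multiset of reused blocks
(*ladderons*) carries three integer indices, all measured in *lifts* (one
pairwise concatenation, or one final take-out, each cost one lift):

``size_index``       S — length of the shortest trivial ladderpath, i.e. the
                     minimum number of basic tokens needed to spell out every
                     target instance;
``ladderpath_length``
                     |J| = S − Σ_i m_i (S(i) − 1) over the ladderons i of a
                     given ladderpath J (multiplicity m_i, size-index S(i));
``order_index_of``   ω = Σ_i m_i (S(i) − 1), the lifts saved by reuse.

The identity λ + ω = S holds for every target, where λ is the length of a
shortest ladderpath (computed by :mod:`ladderpath.search`).
"""

from __future__ import annotations

import itertools
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "LadderpathError",
    "TokenizationError",
    "SimulationError",
    "BasicSet",
    "TargetSystem",
    "Ladderon",
    "Ladderpath",
    "GenerationOp",
    "GenerationPath",
    "IndexSummary",
    "SimulationResult",
    "ConservationEntry",
    "ConservationReport",
    "ValidationResult",
    "size_index",
    "ladderpath_length",
    "order_index_of",
    "conservation_check",
    "validate_ladderpath",
    "simulate_path",
    "path_to_ladderpath",
    "witness_segmentation",
    "read_targets_lines",
    "read_targets_fasta",
    "read_basic_set",
]


class LadderpathError(Exception):
    """Base class for all errors raised by this package."""


class TokenizationError(LadderpathError):
    """A string cannot be segmented into blocks of the basic set."""

    def __init__(self, member: str, position: int, basic: "BasicSet"):
        self.member = member
        self.position = position
        super().__init__(
            f"{member!r} is not tokenizable over the basic set: no basic block "
            f"covers position {position} ({member[position:position + 8]!r}...)"
        )


class SimulationError(LadderpathError):
    """A generation path does not replay."""


class BasicSet:
    """The user-declared alphabet of indivisible building blocks.

    Blocks may be single characters (the common case) or longer strings
    (e.g. ``"BCD"``); they sit at level 1 of every ladderpath and have
    size-index 1 by definition.
    """

    __slots__ = ("blocks", "_by_length", "_max_len")

    def __init__(self, blocks: Iterable[str]):
        blocks = frozenset(blocks)
        if not blocks:
            raise ValueError("the basic set must not be empty")
        if "" in blocks:
            raise ValueError("the empty string cannot be a basic block")
        self.blocks = blocks
        # longest-first, then lexicographic: the deterministic preference
        # order used when reconstructing witness segmentations
        self._by_length = tuple(sorted(blocks, key=lambda b: (-len(b), b)))
        self._max_len = max(len(b) for b in blocks)

    @classmethod
    def from_targets(cls, strings: Iterable[str]) -> "BasicSet":
        """Default basic set: the single characters observed in the targets."""
        chars = set(itertools.chain.from_iterable(strings))
        if not chars:
            raise ValueError("cannot infer a basic set from empty input")
        return cls(chars)

    def __contains__(self, block: object) -> bool:
        return block in self.blocks

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.blocks))

    def __len__(self) -> int:
        return len(self.blocks)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, BasicSet) and self.blocks == other.blocks

    def __hash__(self) -> int:
        return hash(self.blocks)

    def __repr__(self) -> str:
        return f"BasicSet({sorted(self.blocks)!r})"

    def _min_token_table(self, s: str) -> list[float]:
        """g[i] = minimum tokens needed to cover s[i:] (inf if impossible)."""
        n = len(s)
        inf = float("inf")
        g: list[float] = [inf] * (n + 1)
        g[n] = 0
        for i in range(n - 1, -1, -1):
            best = inf
            for b in self._by_length:
                j = i + len(b)
                if j <= n and g[j] + 1 < best and s.startswith(b, i):
                    best = g[j] + 1
            g[i] = best
        return g

    def min_tokens(self, s: str) -> int:
        """Size-index of a single block string: its minimum token count."""
        if s == "":
            return 0
        g = self._min_token_table(s)
        if g[0] == float("inf"):
            raise TokenizationError(s, self._first_uncoverable(s), self)
        return int(g[0])

    def tokenize(self, s: str) -> tuple[str, ...]:
        """Canonical minimal tokenization (ties: longest block first)."""
        if s == "":
            return ()
        g = self._min_token_table(s)
        if g[0] == float("inf"):
            raise TokenizationError(s, self._first_uncoverable(s), self)
        out: list[str] = []
        i = 0
        n = len(s)
        while i < n:
            for b in self._by_length:
                j = i + len(b)
                if j <= n and s.startswith(b, i) and g[i] == g[j] + 1:
                    out.append(b)
                    i = j
                    break
        return tuple(out)

    def _first_uncoverable(self, s: str) -> int:
        """Leftmost reachable position from which no basic block matches."""
        n = len(s)
        reachable = {0}
        frontier = [0]
        stuck: list[int] = []
        while frontier:
            i = frontier.pop()
            matched = False
            for b in self._by_length:
                if s.startswith(b, i) and i + len(b) <= n:
                    matched = True
                    j = i + len(b)
                    if j < n and j not in reachable:
                        reachable.add(j)
                        frontier.append(j)
            if not matched and i < n:
                stuck.append(i)
        return min(stuck) if stuck else n - 1


class TargetSystem:
    """A multiset of target strings with per-string counts.

    The members are treated jointly (repeats may be shared between members)
    but are *not connected*: no block ever spans two member strings.  A single
    target string is simply the size-1 case.
    """

    __slots__ = ("members", "basic_set", "_tokens")

    def __init__(
        self,
        members: Mapping[str, int] | Iterable[str] | str,
        basic_set: BasicSet | None = None,
    ):
        if isinstance(members, str):
            members = {members: 1}
        if not isinstance(members, Mapping):
            members = dict(Counter(members))
        cleaned: dict[str, int] = {}
        for m in sorted(members):
            c = members[m]
            if not m:
                raise ValueError("target members must be non-empty strings")
            if not isinstance(c, int) or c < 1:
                raise ValueError(f"count for {m!r} must be a positive integer, got {c!r}")
            cleaned[m] = c
        if basic_set is None:
            if not cleaned:
                raise ValueError("cannot infer a basic set for an empty target system")
            basic_set = BasicSet.from_targets(cleaned)
        self.members: dict[str, int] = cleaned
        self.basic_set = basic_set
        # construction-time rejection of untokenizable members
        self._tokens: dict[str, tuple[str, ...]] = {
            m: basic_set.tokenize(m) for m in cleaned
        }

    @classmethod
    def empty(cls, basic_set: BasicSet) -> "TargetSystem":
        return cls({}, basic_set)

    def tokenized(self) -> dict[str, tuple[str, ...]]:
        return dict(self._tokens)

    @property
    def total_instances(self) -> int:
        return sum(self.members.values())

    @property
    def is_empty(self) -> bool:
        return not self.members

    def with_extra_copy(self, member: str) -> "TargetSystem":
        """A new system with one more instance of an existing member."""
        if member not in self.members:
            raise KeyError(member)
        members = dict(self.members)
        members[member] += 1
        return TargetSystem(members, self.basic_set)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, TargetSystem)
            and self.members == other.members
            and self.basic_set == other.basic_set
        )

    def __repr__(self) -> str:
        return f"TargetSystem({self.members!r})"


@dataclass(frozen=True)
class Ladderon:
    """A block of a ladderpath: reused ``multiplicity`` times, basic iff level 1."""

    block: str
    multiplicity: int
    level: int

    def __post_init__(self) -> None:
        if not self.block:
            raise ValueError("a ladderon block must be a non-empty string")
        if self.multiplicity < 1:
            raise ValueError(
                f"multiplicity of {self.block!r} must be >= 1 "
                "(zero-multiplicity blocks are deleted from ladderpaths)"
            )
        if self.level < 1:
            raise ValueError("levels start at 1")


class Ladderpath:
    """A partially ordered multiset of ladderons for a target system.

    ``levels[k]`` maps block → multiplicity at level k+1.  Basic blocks sit at
    level 1; every non-basic ladderon must be a concatenation of blocks drawn
    from strictly lower levels.  The target block itself appears only if its
    residual multiplicity is positive (i.e. some instances were obtained by
    replication).
    """

    def __init__(
        self,
        levels: Sequence[Mapping[str, int]],
        basic_set: BasicSet,
        target: TargetSystem,
    ):
        entries: list[Ladderon] = []
        for lvl, group in enumerate(levels, start=1):
            for block in sorted(group):
                entries.append(Ladderon(block, group[block], lvl))
        self.entries: tuple[Ladderon, ...] = tuple(entries)
        self.basic_set = basic_set
        self.target = target

    @classmethod
    def from_blocks(
        cls,
        blocks: Mapping[str, tuple[int, int]],
        basic_set: BasicSet,
        target: TargetSystem,
    ) -> "Ladderpath":
        """Build from a mapping block → (multiplicity, level)."""
        if not blocks:
            return cls([], basic_set, target)
        depth = max(lvl for _, lvl in blocks.values())
        levels: list[dict[str, int]] = [{} for _ in range(depth)]
        for block, (m, lvl) in blocks.items():
            levels[lvl - 1][block] = m
        return cls(levels, basic_set, target)

    @property
    def levels(self) -> list[dict[str, int]]:
        if not self.entries:
            return []
        depth = max(e.level for e in self.entries)
        out: list[dict[str, int]] = [{} for _ in range(depth)]
        for e in self.entries:
            out[e.level - 1][e.block] = e.multiplicity
        return out

    @property
    def ladderons(self) -> dict[str, Ladderon]:
        """Block → ladderon; requires unique blocks (true for valid ladderpaths)."""
        out = {e.block: e for e in self.entries}
        if len(out) != len(self.entries):
            raise LadderpathError("duplicate blocks in ladderpath")
        return out

    def non_basic(self) -> list[Ladderon]:
        return [e for e in self.entries if e.block not in self.basic_set]

    @property
    def is_trivial(self) -> bool:
        return all(e.block in self.basic_set for e in self.entries)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Ladderpath)
            and set(self.entries) == set(other.entries)
            and self.basic_set == other.basic_set
        )

    def __repr__(self) -> str:
        from .notation import serialize_pom

        return f"Ladderpath({serialize_pom(self)})"


@dataclass(frozen=True)
class IndexSummary:
    """The three indices of a target, in lifts: S = λ + ω."""

    size_index: int
    ladderpath_index: int
    order_index: int

    def __post_init__(self) -> None:
        if self.size_index != self.ladderpath_index + self.order_index:
            raise ValueError(
                f"S = λ + ω violated: {self.size_index} != "
                f"{self.ladderpath_index} + {self.order_index}"
            )
        if min(self.size_index, self.ladderpath_index, self.order_index) < 0:
            raise ValueError("indices are non-negative")


# ---------------------------------------------------------------------------
# index algebra
# ---------------------------------------------------------------------------


def size_index(target: TargetSystem | str, basic_set: BasicSet | None = None) -> int:
    """Length of the shortest trivial ladderpath, in lifts.

    Equals the minimum basic-token count summed over all target instances
    (for single-character basic sets: the total letter count).  Each instance
    also accounts for its one take-out lift, which is why a single basic
    block has size-index 1 rather than 0.
    """
    if isinstance(target, str):
        target = TargetSystem(target, basic_set)
    basic = basic_set or target.basic_set
    return sum(c * basic.min_tokens(m) for m, c in target.members.items())


def ladderpath_length(lp: Ladderpath) -> int:
    """Length |J| of a ladderpath, in lifts: S(target) − Σ m_i (S(i) − 1).

    Basic ladderons have size-index 1 and contribute nothing; the sum runs
    over all ladderons, so no case split is needed.
    """
    basic = lp.basic_set
    s = size_index(lp.target, basic)
    saved = sum(e.multiplicity * (basic.min_tokens(e.block) - 1) for e in lp.entries)
    return s - saved


def order_index_of(lp: Ladderpath) -> int:
    """ω = Σ m_i (S(i) − 1): the lifts saved by reuse (identically S − |J|)."""
    basic = lp.basic_set
    return sum(e.multiplicity * (basic.min_tokens(e.block) - 1) for e in lp.entries)


@dataclass(frozen=True)
class ConservationEntry:
    token: str
    target_count: int
    ladderpath_count: int

    @property
    def ok(self) -> bool:
        return self.target_count == self.ladderpath_count


@dataclass(frozen=True)
class ConservationReport:
    entries: dict[str, ConservationEntry]

    @property
    def passed(self) -> bool:
        return all(e.ok for e in self.entries.values())

    def failures(self) -> list[ConservationEntry]:
        return [e for e in self.entries.values() if not e.ok]


def conservation_check(lp: Ladderpath) -> ConservationReport:
    """Per-token material balance between the target and the ladderpath.

    For every basic token a, the number of occurrences of a across all target
    instances must equal Σ_i m_i · n_{i,a} over *all* ladderons i (basic and
    non-basic), where n_{i,a} counts token a in ladderon i.  For
    single-character basic sets this is the letter-count conservation law;
    for multi-character basic sets the balance is checked at the granularity
    of basic-block tokens of the canonical minimal tokenization.
    """
    basic = lp.basic_set
    lhs: Counter[str] = Counter()
    for m, c in lp.target.members.items():
        for tok in basic.tokenize(m):
            lhs[tok] += c
    rhs: Counter[str] = Counter()
    for e in lp.entries:
        for tok in basic.tokenize(e.block):
            rhs[tok] += e.multiplicity
    entries = {
        tok: ConservationEntry(tok, lhs.get(tok, 0), rhs.get(tok, 0))
        for tok in sorted(set(lhs) | set(rhs))
    }
    return ConservationReport(entries)


# ---------------------------------------------------------------------------
# generation paths
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenerationOp:
    """One generation-operation.

    ``merge``: concatenate ``inputs`` (≥2 blocks, in order) into ``output``,
    placed one level above the highest constituent; costs ``len(inputs) − 1``
    lifts.  ``takeout``: remove the listed target instances from the multiset
    without putting anything back; costs one lift per instance.
    """

    kind: str
    inputs: tuple[str, ...]
    output: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("merge", "takeout"):
            raise ValueError(f"unknown operation kind {self.kind!r}")
        if self.kind == "merge":
            if len(self.inputs) < 2:
                raise ValueError("a merge takes at least two blocks")
            if self.output is None or "".join(self.inputs) != self.output:
                raise ValueError(
                    f"merge inputs {self.inputs!r} do not concatenate to {self.output!r}"
                )
        else:
            if not self.inputs:
                raise ValueError("a take-out removes at least one instance")
            if self.output is not None:
                raise ValueError("a take-out has no output")

    @property
    def cost(self) -> int:
        return len(self.inputs) - 1 if self.kind == "merge" else len(self.inputs)

    @classmethod
    def merge(cls, *inputs: str) -> "GenerationOp":
        return cls("merge", tuple(inputs), "".join(inputs))

    @classmethod
    def takeout(cls, *instances: str) -> "GenerationOp":
        return cls("takeout", tuple(instances))


@dataclass(frozen=True)
class GenerationPath:
    """An ordered sequence of generation-operations ending in take-outs."""

    ops: tuple[GenerationOp, ...]
    basic_set: BasicSet
    target: TargetSystem

    def __post_init__(self) -> None:
        object.__setattr__(self, "ops", tuple(self.ops))

    @property
    def length(self) -> int:
        return sum(op.cost for op in self.ops)


@dataclass
class SimulationResult:
    """Final signed multiset after replaying a generation path."""

    multiset: dict[str, int]
    levels: dict[str, int]
    takeouts: Counter
    op_costs: list[int]

    @property
    def length(self) -> int:
        return sum(self.op_costs)


def simulate_path(path: GenerationPath) -> SimulationResult:
    """Replay the multiset bookkeeping of a generation path.

    Multiplicities may go negative in transit (blocks can be taken even when
    absent, under the replication assumption); take-outs likewise only
    require the instance to be a known block that is a target member.  A
    merge whose output is already present in the set — including as a basic
    block — is rejected, as is a merge using a block that is neither basic
    nor previously generated.
    """
    counts: dict[str, int] = {b: 0 for b in path.basic_set}
    levels: dict[str, int] = {b: 1 for b in path.basic_set}
    takeouts: Counter[str] = Counter()
    op_costs: list[int] = []
    for k, op in enumerate(path.ops):
        if op.kind == "merge":
            if op.output in counts:
                raise SimulationError(
                    f"op {k}: the newly-generated blocks must not be present in "
                    f"the set ({op.output!r} already exists)"
                )
            for b in op.inputs:
                if b not in counts:
                    raise SimulationError(
                        f"op {k}: input {b!r} is neither basic nor previously generated"
                    )
                counts[b] -= 1
            counts[op.output] = 1
            levels[op.output] = 1 + max(levels[b] for b in op.inputs)
        else:
            for inst in op.inputs:
                if inst not in counts:
                    raise SimulationError(
                        f"op {k}: cannot take out {inst!r}: never generated and not basic"
                    )
                if inst not in path.target.members:
                    raise SimulationError(
                        f"op {k}: {inst!r} is not a member of the target system"
                    )
                counts[inst] -= 1
                takeouts[inst] += 1
        op_costs.append(op.cost)
    return SimulationResult(counts, levels, takeouts, op_costs)


def path_to_ladderpath(path: GenerationPath) -> Ladderpath:
    """Distill a generation path into its ladderpath.

    Deletes all blocks with zero residual multiplicity, takes absolute values
    of the rest and preserves the partial order (levels).  Requires that the
    path took out every target instance exactly.
    """
    sim = simulate_path(path)
    if dict(sim.takeouts) != dict(path.target.members):
        raise SimulationError(
            f"path does not take out exactly the target instances: "
            f"took {dict(sim.takeouts)!r}, target is {path.target.members!r}"
        )
    blocks = {
        b: (abs(c), sim.levels[b]) for b, c in sim.multiset.items() if c != 0
    }
    return Ladderpath.from_blocks(blocks, path.basic_set, path.target)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def witness_segmentation(
    block: str, parts: Sequence[str]
) -> tuple[str, ...] | None:
    """First segmentation of ``block`` into ``parts``, found in left-to-right,
    longest-part-first order (deterministic); None if none exists."""
    ordered = sorted(set(parts), key=lambda p: (-len(p), p))

    def rec(i: int) -> tuple[str, ...] | None:
        if i == len(block):
            return ()
        for p in ordered:
            if block.startswith(p, i):
                rest = rec(i + len(p))
                if rest is not None:
                    return (p,) + rest
        return None

    return rec(0)


@dataclass
class ValidationResult:
    valid: bool
    problems: list[str]
    witness: GenerationPath | None = None

    def __bool__(self) -> bool:
        return self.valid


def _enumerate_segmentations(
    block: str,
    parts: Sequence[str],
    budget: Mapping[str, int] | None,
    require_any_of: frozenset[str] | None,
    cap: int = 50_000,
) -> Iterator[tuple[str, ...]]:
    """All segmentations of ``block`` into ``parts``, optionally limited by a
    per-part use budget and required to contain at least one part from
    ``require_any_of``.  Deterministic longest-first order."""
    ordered = sorted(set(parts), key=lambda p: (-len(p), p))
    n = len(block)
    counter = [0]

    def rec(i: int, used: Counter, seen_required: bool) -> Iterator[tuple[str, ...]]:
        counter[0] += 1
        if counter[0] > cap:
            raise LadderpathError("witness search exceeded its node cap")
        if i == n:
            if require_any_of is None or seen_required:
                yield ()
            return
        for p in ordered:
            if not block.startswith(p, i):
                continue
            if budget is not None and used[p] + 1 > budget.get(p, 0):
                continue
            used[p] += 1
            for rest in rec(
                i + len(p), used, seen_required or (require_any_of is not None and p in require_any_of)
            ):
                yield (p,) + rest
            used[p] -= 1

    return rec(0, Counter(), False)


def validate_ladderpath(lp: Ladderpath) -> ValidationResult:
    """Check a ladderpath against its definition and build one witness path.

    Valid iff (a) every non-basic ladderon admits a segmentation into blocks
    of strictly lower levels whose highest constituent sits exactly one level
    below; (b) token conservation holds; (c) all multiplicities are ≥ 1 and
    blocks are unique; and (d) the multiplicities are jointly realizable by
    a generation path, one witness of which is returned.
    """
    problems: list[str] = []
    basic = lp.basic_set
    target = lp.target

    # (c) structural checks
    seen: set[str] = set()
    for e in lp.entries:
        if e.block in seen:
            problems.append(f"duplicate block across levels: {e.block!r}")
        seen.add(e.block)
        if e.multiplicity < 1:
            problems.append(f"non-positive multiplicity for {e.block!r}")
        is_basic = e.block in basic
        if is_basic and e.level != 1:
            problems.append(f"basic block {e.block!r} not at level 1")
        if not is_basic and e.level == 1:
            problems.append(f"non-basic block {e.block!r} at level 1")
    if problems:
        return ValidationResult(False, problems)

    ladderons = {e.block: e for e in lp.entries}
    try:
        for e in lp.entries:
            basic.tokenize(e.block)
    except TokenizationError as err:
        return ValidationResult(False, [str(err)])

    # (a) per-ladderon witness segmentation with level consistency
    for e in lp.entries:
        if e.block in basic:
            continue
        lower = [x.block for x in lp.entries if x.level < e.level]
        one_below = frozenset(
            x.block for x in lp.entries if x.level == e.level - 1
        )
        found = False
        try:
            for _ in _enumerate_segmentations(e.block, lower, None, one_below):
                found = True
                break
        except LadderpathError as err:
            return ValidationResult(False, [str(err)])
        if not found:
            problems.append(
                f"{e.block!r} (level {e.level}) has no segmentation into "
                f"strictly lower blocks with a constituent at level {e.level - 1}"
            )
    if problems:
        return ValidationResult(False, problems)

    # (b) conservation
    report = conservation_check(lp)
    if not report.passed:
        for f in report.failures():
            problems.append(
                f"conservation fails for token {f.token!r}: target has "
                f"{f.target_count}, ladderpath supplies {f.ladderpath_count}"
            )
        return ValidationResult(False, problems)

    # (d) joint realizability: assign one segmentation per generated block so
    # that every block is used exactly the number of times its multiplicity
    # dictates (uses = m + generated − taken out).
    builds: list[tuple[str, list[str], frozenset[str] | None]] = []
    uses_req: dict[str, int] = {}
    for e in lp.entries:
        gen = 0 if e.block in basic else 1
        c = target.members.get(e.block, 0)
        req = e.multiplicity + gen - c
        if req < 0:
            return ValidationResult(
                False,
                [
                    f"multiplicity of {e.block!r} is lower than its take-out "
                    f"count allows"
                ],
            )
        uses_req[e.block] = req
        if gen:
            lower = [x.block for x in lp.entries if x.level < e.level]
            one_below = frozenset(
                x.block for x in lp.entries if x.level == e.level - 1
            )
            builds.append((e.block, lower, one_below))
    for m, c in target.members.items():
        if m in ladderons:
            continue
        if m in basic:
            return ValidationResult(
                False, [f"basic member {m!r} with take-outs missing from the ladderpath"]
            )
        if c > 1:
            return ValidationResult(
                False,
                [
                    f"member {m!r} has {c} instances but no residual "
                    f"multiplicity in the ladderpath"
                ],
            )
        builds.append((m, [x.block for x in lp.entries], None))
    # ladderon builds in level order, then residual-free members
    builds.sort(key=lambda b: (ladderons[b[0]].level if b[0] in ladderons else 10**9, b[0]))

    segs: dict[str, tuple[str, ...]] = {}
    remaining = dict(uses_req)

    def assign(k: int) -> bool:
        if k == len(builds):
            return all(v == 0 for v in remaining.values())
        block, lower, one_below = builds[k]
        try:
            options = _enumerate_segmentations(block, lower, remaining, one_below)
            for seg in options:
                for p in seg:
                    remaining[p] -= 1
                segs[block] = seg
                if assign(k + 1):
                    return True
                del segs[block]
                for p in seg:
                    remaining[p] += 1
        except LadderpathError:
            raise
        return False

    try:
        ok = assign(0)
    except LadderpathError as err:
        return ValidationResult(False, [str(err)])
    if not ok:
        return ValidationResult(
            False,
            ["multiplicities are not realizable by any generation path"],
        )

    ops = [GenerationOp.merge(*segs[b]) for b, _, _ in builds]
    instances: list[str] = []
    for m, c in target.members.items():
        instances.extend([m] * c)
    if instances:
        ops.append(GenerationOp.takeout(*instances))
    witness = GenerationPath(tuple(ops), basic, target)
    return ValidationResult(True, [], witness)


# ---------------------------------------------------------------------------
# target readers
# ---------------------------------------------------------------------------


def read_targets_lines(path: str | Path, basic_set: BasicSet | None = None) -> TargetSystem:
    """Read targets from a lines file: ``STRING[<TAB>count]`` per line.

    Repeated strings accumulate their counts.  Blank lines and lines starting
    with ``#`` are skipped.  An empty file yields an empty target system,
    which requires an explicit basic set.
    """
    members: Counter[str] = Counter()
    for raw in Path(path).read_text().splitlines():
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if "\t" in line:
            s, count_s = line.split("\t", 1)
            members[s] += int(count_s.strip())
        else:
            members[line] += 1
    if not members:
        if basic_set is None:
            basic_set = BasicSet({"A"})
        return TargetSystem.empty(basic_set)
    return TargetSystem(dict(members), basic_set)


def read_targets_fasta(path: str | Path, basic_set: BasicSet | None = None) -> TargetSystem:
    """Read targets from a FASTA file; duplicate sequences accumulate counts."""
    from Bio import SeqIO

    members: Counter[str] = Counter()
    for record in SeqIO.parse(str(path), "fasta"):
        members[str(record.seq)] += 1
    if not members:
        if basic_set is None:
            basic_set = BasicSet({"A"})
        return TargetSystem.empty(basic_set)
    return TargetSystem(dict(members), basic_set)


def read_basic_set(path: str | Path) -> BasicSet:
    """Read a basic set: one block per line (blank lines skipped)."""
    blocks = [l for l in Path(path).read_text().splitlines() if l.strip()]
    return BasicSet(blocks)
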