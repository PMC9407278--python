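"""Fixtures and synthetic inputs: worked examples, random strings and
planted hierarchies with a known construction cost."""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np

from .core import BasicSet, GenerationOp, GenerationPath, IndexSummary, TargetSystem

__all__ = [
    "Fixture",
    "PlantedGrammar",
    "worked_examples",
    "example_paths",
    "random_string",
    "planted_hierarchy",
]

_ALPHABET = string.ascii_uppercase + string.ascii_lowercase


@dataclass(frozen=True)
class Fixture:
    """A worked example: target, basic set and its reference index values."""

    name: str
    target: TargetSystem
    basic: BasicSet
    expected: IndexSummary
    exact_feasible: bool  # exact search comfortably fits the size guard


def worked_examples() -> dict[str, Fixture]:
    """The five worked examples used throughout the documentation and the
    acceptance suite, with their known (S, λ, ω) values in lifts.

    ``X`` is the structured 16-letter string, ``W`` a repeat-free string of
    the same length (maximal λ, zero ω), ``Q`` a five-member target system,
    ``Y`` a 34-letter signal decomposed over single letters, and ``Y'`` the
    same signal restricted to its repeated units, analysed over the
    multi-character basic set {T, R, H, K, EF, MU, BCD}.
    """
    out: dict[str, Fixture] = {}

    basic_af = BasicSet("ABCDEF")
    x = TargetSystem("ABCDBCDBCDCDEFEF", basic_af)
    out["X"] = Fixture("X", x, basic_af, IndexSummary(16, 10, 6), True)

    w = TargetSystem("ABCDEFCFEDCBFDBA", basic_af)
    out["W"] = Fixture("W", w, basic_af, IndexSummary(16, 16, 0), True)

    basic_ae = BasicSet("ABCDE")
    q = TargetSystem(
        {"ABDEDBED": 2, "ABDED": 1, "ABDABD": 1, "CAB": 2, "ED": 3}, basic_ae
    )
    out["Q"] = Fixture("Q", q, basic_ae, IndexSummary(39, 17, 22), True)

    y_str = "TBCDEFRBCDEFTEFHKREFHJKLMUVTEFPSMU"
    basic_y = BasicSet.from_targets([y_str])
    y = TargetSystem(y_str, basic_y)
    out["Y"] = Fixture("Y", y, basic_y, IndexSummary(34, 25, 9), False)

    basic_yp = BasicSet({"T", "R", "H", "K", "EF", "MU", "BCD"})
    yp = TargetSystem("TBCDEFRBCDEFTEFHKREFHKMUTEFMU", basic_yp)
    out["Yprime"] = Fixture("Yprime", yp, basic_yp, IndexSummary(18, 16, 2), True)

    return out


def example_paths() -> dict[str, GenerationPath]:
    """Explicit generation paths for the worked targets X and Q.

    Ex1 realizes the shortest ladderpath of X (length 10); Ex2 and Ex3 are
    two different paths of length 13 that distill to one and the same
    ladderpath; Ex4 realizes the shortest ladderpath of the system Q
    (length 17, final nine-instance take-out included).
    """
    fx = worked_examples()
    x, q = fx["X"], fx["Q"]
    merge, takeout = GenerationOp.merge, GenerationOp.takeout
    paths = {
        "Ex1": [
            merge("C", "D"),
            merge("B", "CD"),
            merge("E", "F"),
            merge("A", "BCD", "BCD", "BCD", "CD", "EF", "EF"),
            takeout("ABCDBCDBCDCDEFEF"),
        ],
        "Ex2": [
            merge("D", "B", "C"),
            merge("E", "F"),
            merge("A", "B", "C"),
            merge("DBC", "DBC"),
            merge("C", "D"),
            merge("ABC", "DBCDBC", "D", "CD", "EF", "EF"),
            takeout("ABCDBCDBCDCDEFEF"),
        ],
        "Ex3": [
            merge("D", "B", "C"),
            merge("E", "F"),
            merge("A", "B", "C", "DBC", "DBC", "D", "C", "D", "EF", "EF"),
            takeout("ABCDBCDBCDCDEFEF"),
        ],
        "Ex4": [
            merge("A", "B"),
            merge("C", "AB"),
            merge("AB", "D"),
            merge("ABD", "ABD"),
            merge("E", "D"),
            merge("ABD", "ED"),
            merge("ABDED", "B", "ED"),
            takeout(
                "ABDEDBED", "ABDEDBED", "ABDED", "ABDABD", "CAB", "CAB",
                "ED", "ED", "ED",
            ),
        ],
    }
    out = {}
    for name, ops in paths.items():
        fixture = q if name == "Ex4" else x
        out[name] = GenerationPath(tuple(ops), fixture.basic, fixture.target)
    return out


def random_string(n: int, k: int, seed: int) -> TargetSystem:
    """A single uniform i.i.d. random string of length ``n`` over a declared
    ``k``-letter alphabet — the "totally random sequence" foil with λ close
    to S.  Reproducible under ``seed``."""
    if n < 1 or k < 1:
        raise ValueError("need n >= 1 and k >= 1")
    if k > len(_ALPHABET):
        raise ValueError(f"alphabet size capped at {len(_ALPHABET)}")
    rng = np.random.default_rng(seed)
    alphabet = _ALPHABET[:k]
    s = "".join(alphabet[i] for i in rng.integers(0, k, size=n))
    return TargetSystem(s, BasicSet(alphabet))


@dataclass(frozen=True)
class PlantedGrammar:
    """A bottom-up composition with a known-cost generation path.

    Starting from a ``base`` word over ``alphabet``, each of ``depth`` rounds
    concatenates the previous block ``reuse_factor`` times.  The recorded
    ``planted_cost`` is the length of the planted path — base assembly plus
    ``reuse_factor − 1`` lifts per round plus the final take-out — and is an
    upper bound on the exact ladderpath-index of the expanded string.
    """

    seed: int
    alphabet: str
    depth: int
    reuse_factor: int
    derivation: tuple[tuple[str, tuple[str, ...]], ...]
    planted_cost: int
    target: TargetSystem


def planted_hierarchy(
    alphabet: str,
    depth: int,
    reuse_factor: int,
    seed: int = 0,
    base: str | None = None,
    base_length: int = 2,
) -> PlantedGrammar:
    if depth < 1 or reuse_factor < 2:
        raise ValueError("need depth >= 1 and reuse_factor >= 2")
    rng = np.random.default_rng(seed)
    if base is None:
        base = "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=base_length))
    derivation: list[tuple[str, tuple[str, ...]]] = [(base, tuple(base))]
    block = base
    cost = len(base) - 1
    for _ in range(depth):
        nxt = block * reuse_factor
        derivation.append((nxt, (block,) * reuse_factor))
        cost += reuse_factor - 1
        block = nxt
    cost += 1  # take-out
    target = TargetSystem(block, BasicSet(alphabet))
    return PlantedGrammar(
        seed, alphabet, depth, reuse_factor, tuple(derivation), cost, target
    )
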