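"""Partially-ordered-multiset notation and laddergraph export.

The canonical text form joins levels with ``" // "`` (an ASCII stand-in for
the double-slash level separator; the original ``⫽`` is accepted on input),
lists blocks within a level comma-separated in lexicographic order, and omits
the multiplicity suffix ``(m)`` when m = 1::

    {A, B, C, D, E, F // CD, EF // BCD(2)}

Blocks containing commas, parentheses, braces, slashes, quotes or whitespace
are double-quoted with backslash escaping, so arbitrary alphabets round-trip.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import networkx as nx

from .core import BasicSet, Ladderpath, LadderpathError, TargetSystem, witness_segmentation

__all__ = [
    "PomParseError",
    "parse_pom",
    "serialize_pom",
    "export_laddergraph",
    "write_targets_lines",
    "write_targets_fasta",
]

_NEEDS_QUOTING = set(',(){}/"⫽ \t\n')


class PomParseError(LadderpathError):
    def __init__(self, message: str, position: int):
        self.position = position
        super().__init__(f"{message} (at character {position})")


def _escape_block(block: str) -> str:
    if any(ch in _NEEDS_QUOTING for ch in block):
        return '"' + block.replace("\\", "\\\\").replace('"', '\\"') + '"'
    return block


def serialize_pom(lp: Ladderpath) -> str:
    """Deterministic canonical notation: levels ascending, blocks sorted."""
    groups = []
    for group in lp.levels:
        items = []
        for block in sorted(group):
            m = group[block]
            items.append(_escape_block(block) + (f"({m})" if m != 1 else ""))
        groups.append(", ".join(items))
    return "{" + " // ".join(groups) + "}"


class _PomScanner:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def error(self, msg: str) -> PomParseError:
        return PomParseError(msg, self.pos)

    def skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos] in " \t\n":
            self.pos += 1

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def at_separator(self) -> bool:
        return self.text.startswith("//", self.pos) or self.text.startswith("⫽", self.pos)

    def eat_separator(self) -> None:
        self.pos += 2 if self.text.startswith("//", self.pos) else 1

    def read_block(self) -> str:
        self.skip_ws()
        if self.peek() == '"':
            self.pos += 1
            out = []
            while True:
                if self.pos >= len(self.text):
                    raise self.error("unterminated quoted block")
                ch = self.text[self.pos]
                if ch == "\\":
                    if self.pos + 1 >= len(self.text):
                        raise self.error("dangling escape")
                    out.append(self.text[self.pos + 1])
                    self.pos += 2
                elif ch == '"':
                    self.pos += 1
                    return "".join(out)
                else:
                    out.append(ch)
                    self.pos += 1
        out = []
        while self.pos < len(self.text):
            ch = self.text[self.pos]
            if ch in ",(}" or ch in " \t\n" or self.at_separator():
                break
            out.append(ch)
            self.pos += 1
        return "".join(out)

    def read_multiplicity(self) -> int:
        if self.peek() != "(":
            return 1
        start = self.pos
        self.pos += 1
        digits = []
        while self.peek().isdigit() or self.peek() == "-":
            digits.append(self.peek())
            self.pos += 1
        if self.peek() != ")":
            self.pos = start
            raise self.error("malformed multiplicity")
        self.pos += 1
        try:
            m = int("".join(digits))
        except ValueError:
            self.pos = start
            raise self.error("malformed multiplicity") from None
        if m < 1:
            self.pos = start
            raise self.error(f"non-positive multiplicity {m}")
        return m


def parse_pom(text: str, basic: BasicSet, target: TargetSystem) -> Ladderpath:
    """Parse canonical (or ``⫽``-separated) notation into a Ladderpath.

    Structural errors — malformed items, duplicate blocks, non-positive
    multiplicities — are rejected with the character position; semantic
    validation is deferred to :func:`ladderpath.core.validate_ladderpath`.
    """
    sc = _PomScanner(text)
    sc.skip_ws()
    if sc.peek() != "{":
        raise sc.error("expected '{'")
    sc.pos += 1
    levels: list[dict[str, int]] = []
    current: dict[str, int] = {}
    seen: set[str] = set()
    sc.skip_ws()
    if sc.peek() == "}":
        sc.pos += 1
        return Ladderpath([], basic, target)
    while True:
        sc.skip_ws()
        block = sc.read_block()
        if not block:
            raise sc.error("empty block")
        m = sc.read_multiplicity()
        if block in seen:
            raise sc.error(f"duplicate block {block!r}")
        seen.add(block)
        current[block] = m
        sc.skip_ws()
        if sc.peek() == ",":
            sc.pos += 1
            continue
        if sc.at_separator():
            sc.eat_separator()
            levels.append(current)
            current = {}
            continue
        if sc.peek() == "}":
            sc.pos += 1
            levels.append(current)
            break
        raise sc.error("expected ',', '//' or '}'")
    return Ladderpath(levels, basic, target)


# ---------------------------------------------------------------------------
# laddergraph
# ---------------------------------------------------------------------------


def laddergraph(lp: Ladderpath) -> nx.DiGraph:
    """The constituent DAG after transitive reduction.

    Nodes are the ladderpath blocks plus the target members; an edge i → j
    means block i is a constituent of block j under the deterministic witness
    segmentation, with edges implied by longer chains removed.  Node
    attributes: ``level`` (members absent from the ladderpath get level 0,
    meaning "top"), ``multiplicity``, ``basic``, ``target_count``.
    """
    entries = {e.block: e for e in lp.entries}
    g = nx.DiGraph()
    for e in lp.entries:
        g.add_node(
            e.block,
            level=e.level,
            multiplicity=e.multiplicity,
            basic=e.block in lp.basic_set,
            target_count=lp.target.members.get(e.block, 0),
        )
    for m, c in lp.target.members.items():
        if m not in entries:
            g.add_node(m, level=0, multiplicity=0, basic=m in lp.basic_set, target_count=c)
    for block in list(g.nodes):
        if g.nodes[block]["basic"]:
            continue
        if block in entries:
            lower = [e.block for e in lp.entries if e.level < entries[block].level]
        else:
            lower = [e.block for e in lp.entries]
        seg = witness_segmentation(block, lower)
        if seg is None:
            raise LadderpathError(
                f"cannot draw laddergraph: no witness segmentation for {block!r}"
            )
        for part in set(seg):
            g.add_edge(part, block)
    reduced = nx.transitive_reduction(g)
    reduced.add_nodes_from(g.nodes(data=True))
    return reduced


def _dot_quote(s: str) -> str:
    return '"' + s.replace("\\", "\\\\").replace('"', '\\"') + '"'


def export_laddergraph(lp: Ladderpath) -> str:
    """Render the laddergraph as a DOT digraph.

    Follows the drawing conventions of the partially-ordered-multiset view:
    edges incident to basic blocks are dimmed, the constituent relation is
    transitively reduced, multiplicities are written behind the block, target
    members carry a ``[×n]`` prefix and, when their residual multiplicity is
    zero, a grey fill and a ``(0)`` suffix.
    """
    g = laddergraph(lp)
    lines = ["digraph laddergraph {", "  rankdir=BT;", "  node [shape=box];"]
    for node, data in sorted(g.nodes(data=True)):
        label = node
        if data["multiplicity"] > 1:
            label += f"({data['multiplicity']})"
        elif data["multiplicity"] == 0:
            label += "(0)"
        attrs = []
        if data["target_count"]:
            label = f"[×{data['target_count']}] " + label
            attrs.append("style=filled")
            attrs.append('fillcolor="grey90"')
        attrs.insert(0, f"label={_dot_quote(label)}")
        lines.append(f"  {_dot_quote(node)} [{', '.join(attrs)}];")
    by_level: dict[int, list[str]] = {}
    for node, data in g.nodes(data=True):
        by_level.setdefault(data["level"], []).append(node)
    for level in sorted(by_level):
        if level == 0:
            continue
        group = "; ".join(_dot_quote(n) for n in sorted(by_level[level]))
        lines.append(f"  {{ rank=same; {group}; }}")
    if 0 in by_level:
        group = "; ".join(_dot_quote(n) for n in sorted(by_level[0]))
        lines.append(f"  {{ rank=same; {group}; }}")
    for u, v in sorted(g.edges):
        if g.nodes[u]["basic"]:
            lines.append(f"  {_dot_quote(u)} -> {_dot_quote(v)} [color=grey, style=dashed];")
        else:
            lines.append(f"  {_dot_quote(u)} -> {_dot_quote(v)};")
    lines.append("}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# target writers (round-trip counterparts of the core readers)
# ---------------------------------------------------------------------------


def write_targets_lines(target: TargetSystem, path: str | Path) -> None:
    lines = [f"{m}\t{c}" if c != 1 else m for m, c in target.members.items()]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_targets_fasta(target: TargetSystem, path: str | Path) -> None:
    chunks = []
    i = 0
    for m, c in target.members.items():
        for _ in range(c):
            chunks.append(f">seq{i}\n{m}\n")
            i += 1
    Path(path).write_text("".join(chunks))
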