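"""Boolean logic-network data model and text I/O.

A :class:`BooleanNetwork` holds an ordered node list, one Boolean update rule
per non-input node, and an optional set of *pins* — nodes whose state is held
at a fixed value regardless of their rule.  Pins model both loss-/gain-of-
function mutations (pin 0 / pin 1) and therapeutic control interventions.

Rules are written in a BoolNet-style text dialect, one line per regulated
node::

    TARGET, EXPRESSION      # expression over parent node names
    # comment lines start with '#'
    @pin NODE VALUE         # optional pin overrides

Expressions support ``&``/``AND``, ``|``/``OR``, ``!``/``NOT``, parentheses
and the literals ``0``/``1``.  Identifiers are ``[A-Za-z0-9_]+`` and
case-sensitive.  Nodes that never appear as a rule target are external
inputs: they hold whatever value the initial state gives them (unless
pinned).

Internally every rule is compiled to a truth table over its parents, which
makes logical equivalence decidable by enumeration and the synchronous
update a table lookup.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

_IDENT_RE = re.compile(r"[A-Za-z0-9_]+")

MAX_PARENTS_DEFAULT = 16


class BnetParseError(ValueError):
    """Raised for malformed logic-rule documents; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


# ---------------------------------------------------------------------------
# Expression AST and parser
# ---------------------------------------------------------------------------

class _Tok:
    __slots__ = ("kind", "text")

    def __init__(self, kind: str, text: str):
        self.kind = kind
        self.text = text


def _tokenize(expr: str, line: int) -> list[_Tok]:
    toks: list[_Tok] = []
    i = 0
    while i < len(expr):
        c = expr[i]
        if c.isspace():
            i += 1
            continue
        if c == "(":
            toks.append(_Tok("lpar", c)); i += 1
        elif c == ")":
            toks.append(_Tok("rpar", c)); i += 1
        elif c == "!":
            toks.append(_Tok("not", c)); i += 1
        elif c == "&":
            toks.append(_Tok("and", c)); i += 1
        elif c == "|":
            toks.append(_Tok("or", c)); i += 1
        else:
            m = _IDENT_RE.match(expr, i)
            if not m:
                raise BnetParseError(f"unexpected character {c!r} in expression", line)
            word = m.group(0)
            i = m.end()
            upper = word.upper()
            if upper == "AND":
                toks.append(_Tok("and", word))
            elif upper == "OR":
                toks.append(_Tok("or", word))
            elif upper == "NOT":
                toks.append(_Tok("not", word))
            elif word == "0" or word == "1":
                toks.append(_Tok("const", word))
            else:
                toks.append(_Tok("ident", word))
    return toks


class _Parser:
    """Recursive-descent parser: OR < AND < NOT < atom."""

    def __init__(self, toks: list[_Tok], line: int):
        self.toks = toks
        self.pos = 0
        self.line = line

    def _peek(self) -> _Tok | None:
        return self.toks[self.pos] if self.pos < len(self.toks) else None

    def _next(self) -> _Tok:
        tok = self._peek()
        if tok is None:
            raise BnetParseError("unexpected end of expression", self.line)
        self.pos += 1
        return tok

    def parse(self) -> tuple:
        node = self._or()
        if self._peek() is not None:
            raise BnetParseError(
                f"trailing token {self._peek().text!r} in expression", self.line)
        return node

    def _or(self) -> tuple:
        left = self._and()
        while (tok := self._peek()) is not None and tok.kind == "or":
            self._next()
            left = ("or", left, self._and())
        return left

    def _and(self) -> tuple:
        left = self._not()
        while (tok := self._peek()) is not None and tok.kind == "and":
            self._next()
            left = ("and", left, self._not())
        return left

    def _not(self) -> tuple:
        tok = self._peek()
        if tok is not None and tok.kind == "not":
            self._next()
            return ("not", self._not())
        return self._atom()

    def _atom(self) -> tuple:
        tok = self._next()
        if tok.kind == "lpar":
            inner = self._or()
            closing = self._next()
            if closing.kind != "rpar":
                raise BnetParseError("expected ')'", self.line)
            return inner
        if tok.kind == "const":
            return ("const", int(tok.text))
        if tok.kind == "ident":
            return ("var", tok.text)
        raise BnetParseError(f"unexpected token {tok.text!r}", self.line)


def _expr_vars(ast: tuple) -> list[str]:
    """Variables referenced by an expression AST, in first-appearance order."""
    out: list[str] = []
    seen: set[str] = set()

    def walk(node: tuple) -> None:
        if node[0] == "var":
            if node[1] not in seen:
                seen.add(node[1])
                out.append(node[1])
        elif node[0] == "not":
            walk(node[1])
        elif node[0] in ("and", "or"):
            walk(node[1])
            walk(node[2])

    walk(ast)
    return out


def _eval_expr(ast: tuple, env: dict[str, int]) -> int:
    op = ast[0]
    if op == "const":
        return ast[1]
    if op == "var":
        return env[ast[1]]
    if op == "not":
        return 1 - _eval_expr(ast[1], env)
    if op == "and":
        return _eval_expr(ast[1], env) & _eval_expr(ast[2], env)
    if op == "or":
        return _eval_expr(ast[1], env) | _eval_expr(ast[2], env)
    raise AssertionError(op)


def compile_rule(ast: tuple, parents: list[str]) -> np.ndarray:
    """Truth table over ``parents``: entry ``i`` is the rule value when parent
    ``j`` holds bit ``j`` of ``i`` (parent 0 = least significant bit)."""
    k = len(parents)
    table = np.empty(1 << k, dtype=np.uint8)
    for idx in range(1 << k):
        env = {p: (idx >> j) & 1 for j, p in enumerate(parents)}
        table[idx] = _eval_expr(ast, env)
    return table


# ---------------------------------------------------------------------------
# Core types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Rule:
    """A compiled update rule: parent node names, truth table, source text."""

    parents: tuple[str, ...]
    table: np.ndarray          # uint8, length 2**len(parents)
    expression: str            # original textual form (for serialization)

    def __eq__(self, other) -> bool:  # table equality, not identity
        return (isinstance(other, Rule)
                and self.parents == other.parents
                and np.array_equal(self.table, other.table))

    def __hash__(self) -> int:
        return hash((self.parents, self.table.tobytes()))


class BooleanNetwork:
    """An ordered collection of nodes with Boolean update rules and pins.

    Parameters
    ----------
    node_names:
        Ordered, unique node identifiers.
    rules:
        Mapping from regulated node name to its :class:`Rule`.  Nodes absent
        from this mapping are external inputs.
    pins:
        Partial mapping node -> 0/1 of state overrides.  A pinned node keeps
        its pin value at every synchronous update, ignoring its rule.
    """

    def __init__(self, node_names: list[str], rules: dict[str, Rule],
                 pins: dict[str, int] | None = None,
                 max_parents: int = MAX_PARENTS_DEFAULT):
        if len(set(node_names)) != len(node_names):
            raise ValueError("duplicate node names")
        self.node_names: list[str] = list(node_names)
        self.index: dict[str, int] = {n: i for i, n in enumerate(node_names)}
        for target, rule in rules.items():
            if target not in self.index:
                raise ValueError(f"rule target {target!r} is not a declared node")
            if len(rule.parents) > max_parents:
                raise ValueError(
                    f"node {target!r} has {len(rule.parents)} parents "
                    f"(> max_parents={max_parents})")
            for p in rule.parents:
                if p not in self.index:
                    raise ValueError(
                        f"rule for {target!r} references undeclared node {p!r}")
        self.rules: dict[str, Rule] = dict(rules)
        self.input_nodes: list[str] = [n for n in node_names if n not in rules]
        self.pins: dict[str, int] = {}
        for node, val in (pins or {}).items():
            if node not in self.index:
                raise ValueError(f"pinned node {node!r} is not a declared node")
            if val not in (0, 1):
                raise ValueError(f"pin value for {node!r} must be 0 or 1")
            self.pins[node] = int(val)
        # Precompute arrays used by the simulator.
        self._compile_arrays()

    # -- derived, simulator-facing layout ---------------------------------
    def _compile_arrays(self) -> None:
        n = len(self.node_names)
        self.n_nodes = n
        self.parent_idx: list[np.ndarray] = []
        self.tables: list[np.ndarray] = []
        self.has_rule = np.zeros(n, dtype=bool)
        for i, name in enumerate(self.node_names):
            rule = self.rules.get(name)
            if rule is None:
                self.parent_idx.append(np.empty(0, dtype=np.intp))
                self.tables.append(np.empty(0, dtype=np.uint8))
            else:
                self.has_rule[i] = True
                self.parent_idx.append(
                    np.array([self.index[p] for p in rule.parents], dtype=np.intp))
                self.tables.append(rule.table)
        self.pin_idx = np.array(
            [self.index[nm] for nm in self.node_names if nm in self.pins],
            dtype=np.intp)
        self.pin_val = np.array(
            [self.pins[nm] for nm in self.node_names if nm in self.pins],
            dtype=np.uint8)
        self.free_idx = np.array(
            [i for i, nm in enumerate(self.node_names) if nm not in self.pins],
            dtype=np.intp)

    # -- pinning -----------------------------------------------------------
    def with_pins(self, pins: dict[str, int], *, replace: bool = False) -> "BooleanNetwork":
        """Return a copy with extra pins merged in (later pin wins)."""
        merged = {} if replace else dict(self.pins)
        for node, val in pins.items():
            if node in merged and merged[node] != val:
                warnings.warn(
                    f"pin conflict on {node!r}: {merged[node]} -> {val} (later wins)",
                    stacklevel=2)
            merged[node] = val
        return BooleanNetwork(self.node_names, self.rules, merged)

    def without_pins(self) -> "BooleanNetwork":
        return BooleanNetwork(self.node_names, self.rules, {})

    # -- misc ---------------------------------------------------------------
    @property
    def n_links(self) -> int:
        """Number of distinct regulator -> target dependencies."""
        return sum(len(r.parents) for r in self.rules.values())

    def equivalent(self, other: "BooleanNetwork") -> bool:
        """Same nodes, same truth tables, same pins (parent order may differ)."""
        if self.node_names != other.node_names or self.pins != other.pins:
            return False
        if set(self.rules) != set(other.rules):
            return False
        for target, rule in self.rules.items():
            orule = other.rules[target]
            pars = sorted(set(rule.parents) | set(orule.parents))
            if len(pars) > 20:
                raise ValueError("equivalence check limited to <= 20 parents")
            for idx in range(1 << len(pars)):
                env = {p: (idx >> j) & 1 for j, p in enumerate(pars)}
                a = rule.table[sum(env[p] << j for j, p in enumerate(rule.parents))]
                b = orule.table[sum(env[p] << j for j, p in enumerate(orule.parents))]
                if a != b:
                    return False
        return True

    def __repr__(self) -> str:
        return (f"BooleanNetwork(n_nodes={self.n_nodes}, n_links={self.n_links}, "
                f"inputs={len(self.input_nodes)}, pins={len(self.pins)})")


# ---------------------------------------------------------------------------
# Mutation profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Mutation:
    node: str
    value: int
    label: str = ""


@dataclass
class MutationProfile:
    """Ordered driver-mutation list; stage *k* pins the first *k* entries.

    The canonical colorectal sequence is APC:0 (loss), KRAS:1 (gain),
    PTEN:0, TP53:0 — adenoma through carcinoma.
    """

    mutations: list[Mutation] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.mutations)

    def __iter__(self):
        return iter(self.mutations)

    def stage_labels(self) -> list[str]:
        out = ["baseline"]
        for k in range(1, len(self.mutations) + 1):
            out.append("+".join(m.label or m.node for m in self.mutations[:k]))
        return out


def apply_mutations(network: BooleanNetwork, profile: MutationProfile,
                    stage: int) -> BooleanNetwork:
    """Pin the first ``stage`` mutations of ``profile`` onto a copy of
    ``network``.  The original network is untouched."""
    if not 0 <= stage <= len(profile):
        raise ValueError(f"stage must be in [0, {len(profile)}], got {stage}")
    seen: dict[str, int] = {}
    for mut in profile.mutations[:stage]:
        if mut.node not in network.index:
            raise ValueError(f"mutation on unknown node {mut.node!r}")
        if mut.node in seen and seen[mut.node] != mut.value:
            raise ValueError(f"conflicting simultaneous pins on {mut.node!r}")
        seen[mut.node] = mut.value
    if stage == 0:
        return network.with_pins({})
    return network.with_pins(seen)


# ---------------------------------------------------------------------------
# .bnet parsing / serialization
# ---------------------------------------------------------------------------

def parse_bnet(text: str, max_parents: int = MAX_PARENTS_DEFAULT) -> BooleanNetwork:
    """Parse a logic-rule document into a :class:`BooleanNetwork`.

    Node order is: rule targets in file order, then inputs (nodes referenced
    but never defined) in first-reference order.
    """
    targets: list[str] = []
    exprs: dict[str, tuple] = {}
    expr_text: dict[str, str] = {}
    pins: dict[str, int] = {}
    referenced: list[str] = []
    ref_seen: set[str] = set()
    any_content = False

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        any_content = True
        if line.startswith("@pin"):
            parts = line.split()
            if len(parts) != 3 or parts[2] not in ("0", "1"):
                raise BnetParseError("expected '@pin NODE 0|1'", lineno)
            pins[parts[1]] = int(parts[2])
            continue
        if "," not in line:
            raise BnetParseError("expected 'TARGET, EXPRESSION'", lineno)
        target, expr_src = line.split(",", 1)
        target = target.strip()
        if not _IDENT_RE.fullmatch(target):
            raise BnetParseError(f"invalid target identifier {target!r}", lineno)
        if target in exprs:
            raise BnetParseError(f"duplicate target {target!r}", lineno)
        toks = _tokenize(expr_src, lineno)
        if not toks:
            raise BnetParseError("empty expression", lineno)
        ast = _Parser(toks, lineno).parse()
        targets.append(target)
        exprs[target] = ast
        expr_text[target] = expr_src.strip()
        for v in _expr_vars(ast):
            if v not in ref_seen:
                ref_seen.add(v)
                referenced.append(v)

    if not any_content:
        raise BnetParseError("empty document")

    node_names = list(targets)
    declared = set(targets)
    for v in referenced:
        if v not in declared:
            declared.add(v)
            node_names.append(v)

    rules: dict[str, Rule] = {}
    for target in targets:
        ast = exprs[target]
        parents = tuple(_expr_vars(ast))
        rules[target] = Rule(parents=parents,
                             table=compile_rule(ast, list(parents)),
                             expression=expr_text[target])

    for node in pins:
        if node not in declared:
            raise BnetParseError(f"@pin references undeclared node {node!r}")

    return BooleanNetwork(node_names, rules, pins, max_parents=max_parents)


def serialize_bnet(network: BooleanNetwork) -> str:
    """Render a network back to the logic-rule dialect.

    Rules are emitted from their stored expressions; pins go into a trailing
    ``@pin`` section (pins are runtime overrides, never rewritten into the
    logic).  Input nodes with no incoming rule and no reference inside any
    rule would be lost on re-parse, so they are declared via a self-loop
    comment-free identity rule only if truly orphaned — in practice inputs
    are always referenced by some rule.
    """
    lines: list[str] = []
    referenced: set[str] = set()
    for name in network.node_names:
        rule = network.rules.get(name)
        if rule is not None:
            lines.append(f"{name}, {rule.expression}")
            referenced.update(rule.parents)
    for name in network.input_nodes:
        if name not in referenced:
            # orphan input: keep it alive with an identity rule on itself
            logger.warning("orphan input %s serialized as identity self-loop", name)
            lines.append(f"{name}, {name}")
    for name in network.node_names:
        if name in network.pins:
            lines.append(f"@pin {name} {network.pins[name]}")
    return "\n".join(lines) + "\n"
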