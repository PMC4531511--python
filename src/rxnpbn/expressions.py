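"""Boolean expression trees used as update-rule right-hand sides.

Expressions are immutable trees over AND / OR / NOT / literal / constant
nodes.  Literals name network nodes (components, elemental states or
reactions).  The constructors :func:`land`, :func:`lor` and :func:`lnot`
perform light simplification (flattening, constant absorption) so that
generated rules print in the compact form the bipartite construction
implies, without attempting full logic minimisation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

import numpy as np

__all__ = [
    "BoolExpr",
    "Lit",
    "Not",
    "And",
    "Or",
    "TRUE",
    "FALSE",
    "lit",
    "lnot",
    "land",
    "lor",
    "truth_table",
    "equivalent",
]


class BoolExpr:
    """Base class for Boolean expression nodes."""

    __slots__ = ()

    # -- evaluation ---------------------------------------------------
    def evaluate(self, env: Mapping[str, bool]) -> bool:
        raise NotImplementedError

    def literals(self) -> frozenset[str]:
        """Names of all literals appearing in the expression."""
        raise NotImplementedError

    def compile(self, index: Mapping[str, int]) -> Callable[[np.ndarray], np.ndarray]:
        """Compile to a vectorised evaluator.

        The returned callable maps a Boolean state array of shape
        ``(..., n_nodes)`` (last axis indexed by ``index``) to a Boolean
        array of shape ``(...,)``.
        """
        raise NotImplementedError

    # -- rendering ----------------------------------------------------
    def to_text(self, style: str = "math") -> str:
        """Render the expression.

        Styles: ``math`` (∧ ∨ ¬), ``booleannet`` (``and or not``),
        ``boolnet`` (``& | !``).
        """
        ops = _STYLES[style]
        return self._render(ops, top=True)

    def _render(self, ops: dict, top: bool) -> str:
        raise NotImplementedError

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_text()


_STYLES = {
    "math": {"and": " ∧ ", "or": " ∨ ", "not": "¬", "true": "TRUE", "false": "FALSE"},
    "booleannet": {"and": " and ", "or": " or ", "not": "not ", "true": "True", "false": "False"},
    "boolnet": {"and": " & ", "or": " | ", "not": "!", "true": "1", "false": "0"},
}


@dataclass(frozen=True, slots=True)
class _Const(BoolExpr):
    value: bool

    def evaluate(self, env):
        return self.value

    def literals(self):
        return frozenset()

    def compile(self, index):
        value = self.value

        def _eval(state: np.ndarray) -> np.ndarray:
            return np.full(state.shape[:-1], value, dtype=bool)

        return _eval

    def _render(self, ops, top):
        return ops["true"] if self.value else ops["false"]


TRUE = _Const(True)
FALSE = _Const(False)


@dataclass(frozen=True, slots=True)
class Lit(BoolExpr):
    name: str

    def evaluate(self, env):
        return bool(env[self.name])

    def literals(self):
        return frozenset((self.name,))

    def compile(self, index):
        i = index[self.name]

        def _eval(state: np.ndarray) -> np.ndarray:
            return state[..., i]

        return _eval

    def _render(self, ops, top):
        return self.name


@dataclass(frozen=True, slots=True)
class Not(BoolExpr):
    operand: BoolExpr

    def evaluate(self, env):
        return not self.operand.evaluate(env)

    def literals(self):
        return self.operand.literals()

    def compile(self, index):
        f = self.operand.compile(index)

        def _eval(state: np.ndarray) -> np.ndarray:
            return ~f(state)

        return _eval

    def _render(self, ops, top):
        inner = self.operand._render(ops, top=False)
        if isinstance(self.operand, (And, Or)):
            inner = f"({inner})"
        return ops["not"] + inner


@dataclass(frozen=True, slots=True)
class And(BoolExpr):
    operands: tuple[BoolExpr, ...]

    def evaluate(self, env):
        return all(op.evaluate(env) for op in self.operands)

    def literals(self):
        return frozenset().union(*(op.literals() for op in self.operands))

    def compile(self, index):
        fns = [op.compile(index) for op in self.operands]

        def _eval(state: np.ndarray) -> np.ndarray:
            out = fns[0](state)
            for f in fns[1:]:
                out = out & f(state)
            return out

        return _eval

    def _render(self, ops, top):
        parts = [
            f"({op._render(ops, top=False)})" if isinstance(op, Or) else op._render(ops, top=False)
            for op in self.operands
        ]
        return ops["and"].join(parts)


@dataclass(frozen=True, slots=True)
class Or(BoolExpr):
    operands: tuple[BoolExpr, ...]

    def evaluate(self, env):
        return any(op.evaluate(env) for op in self.operands)

    def literals(self):
        return frozenset().union(*(op.literals() for op in self.operands))

    def compile(self, index):
        fns = [op.compile(index) for op in self.operands]

        def _eval(state: np.ndarray) -> np.ndarray:
            out = fns[0](state)
            for f in fns[1:]:
                out = out | f(state)
            return out

        return _eval

    def _render(self, ops, top):
        parts = [
            f"({op._render(ops, top=False)})" if isinstance(op, And) else op._render(ops, top=False)
            for op in self.operands
        ]
        return ops["or"].join(parts)


def lit(name: str) -> Lit:
    return Lit(name)


def lnot(x: BoolExpr) -> BoolExpr:
    if x is TRUE:
        return FALSE
    if x is FALSE:
        return TRUE
    if isinstance(x, Not):
        return x.operand
    return Not(x)


def _flatten(xs: Iterable[BoolExpr], cls) -> list[BoolExpr]:
    out: list[BoolExpr] = []
    for x in xs:
        if isinstance(x, cls):
            out.extend(x.operands)
        else:
            out.append(x)
    return out


def land(*xs: BoolExpr) -> BoolExpr:
    ops = [x for x in _flatten(xs, And) if x is not TRUE]
    if any(x is FALSE for x in ops):
        return FALSE
    # keep first occurrence, drop exact duplicates
    seen: list[BoolExpr] = []
    for x in ops:
        if x not in seen:
            seen.append(x)
    if not seen:
        return TRUE
    if len(seen) == 1:
        return seen[0]
    return And(tuple(seen))


def lor(*xs: BoolExpr) -> BoolExpr:
    ops = [x for x in _flatten(xs, Or) if x is not FALSE]
    if any(x is TRUE for x in ops):
        return TRUE
    seen: list[BoolExpr] = []
    for x in ops:
        if x not in seen:
            seen.append(x)
    if not seen:
        return FALSE
    if len(seen) == 1:
        return seen[0]
    return Or(tuple(seen))


def truth_table(expr: BoolExpr, names: Iterable[str] | None = None) -> tuple[bool, ...]:
    """Exhaustive evaluation over all assignments of ``names``.

    ``names`` defaults to the expression's own literals (sorted); passing
    an explicit superset lets two expressions be tabulated on a common
    domain.
    """
    names = sorted(expr.literals()) if names is None else list(names)
    rows = []
    for bits in itertools.product((False, True), repeat=len(names)):
        rows.append(expr.evaluate(dict(zip(names, bits))))
    return tuple(rows)


def equivalent(a: BoolExpr, b: BoolExpr) -> bool:
    """Logical equivalence by exhaustive truth table over the union of literals."""
    names = sorted(a.literals() | b.literals())
    return truth_table(a, names) == truth_table(b, names)
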