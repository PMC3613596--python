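"""Ground atoms, composite descriptions, and three-valued evaluation.

The smallest unit of situation knowledge is an *atom*: an attribute/value
pair such as ``indigestion = present``.  Atoms combine under ``and``, ``or``
and ``not`` into *descriptions*, which are evaluated against a belief set
under strong Kleene semantics.  Under the default open-world assumption an
atom absent from the belief set evaluates ``unknown``; a closed-world flag
turns absence into falsity (negation as failure), which goal conditions
("does not currently hold") rely on.

Terms beginning with ``?`` are variables; a description containing
variables is a *pattern* and must be instantiated before evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional, Union

TRUE = "true"
FALSE = "false"
UNKNOWN = "unknown"

_KLEENE_RANK = {FALSE: 0, UNKNOWN: 1, TRUE: 2}
_KLEENE_BY_RANK = {v: k for k, v in _KLEENE_RANK.items()}


def is_variable(term: str) -> bool:
    return isinstance(term, str) and term.startswith("?")


@dataclass(frozen=True)
class Atom:
    """A ground (or pattern) attribute/value assertion."""

    attr: str
    value: str
    negated: bool = False

    def positive(self) -> "Atom":
        return Atom(self.attr, self.value, False)

    def negate(self) -> "Atom":
        return Atom(self.attr, self.value, not self.negated)

    def __str__(self) -> str:
        sign = "not " if self.negated else ""
        return f"{sign}{self.attr}={self.value}"


@dataclass(frozen=True)
class And:
    children: tuple = ()


@dataclass(frozen=True)
class Or:
    children: tuple = ()


@dataclass(frozen=True)
class Not:
    child: "Description" = None


Description = Union[Atom, And, Or, Not]
Binding = Mapping[str, str]


class NonGroundError(ValueError):
    """Raised when a pattern is evaluated without full instantiation."""


def atoms_of(d: Description) -> Iterator[Atom]:
    if isinstance(d, Atom):
        yield d
    elif isinstance(d, (And, Or)):
        for c in d.children:
            yield from atoms_of(c)
    elif isinstance(d, Not):
        yield from atoms_of(d.child)
    else:  # pragma: no cover - defensive
        raise TypeError(f"not a description: {d!r}")


def variables(d: Description) -> set:
    out = set()
    for a in atoms_of(d):
        for term in (a.attr, a.value):
            if is_variable(term):
                out.add(term)
    return out


def is_ground(d: Description) -> bool:
    return not variables(d)


def substitute(d: Description, binding: Binding) -> Description:
    if isinstance(d, Atom):
        attr = binding.get(d.attr, d.attr) if is_variable(d.attr) else d.attr
        value = binding.get(d.value, d.value) if is_variable(d.value) else d.value
        return Atom(attr, value, d.negated)
    if isinstance(d, And):
        return And(tuple(substitute(c, binding) for c in d.children))
    if isinstance(d, Or):
        return Or(tuple(substitute(c, binding) for c in d.children))
    if isinstance(d, Not):
        return Not(substitute(d.child, binding))
    raise TypeError(f"not a description: {d!r}")


def _eval_atom(a: Atom, beliefs, closed_world: bool) -> str:
    base = UNKNOWN
    if a.positive() in beliefs:
        base = TRUE
    elif a.positive().negate() in beliefs:
        base = FALSE
    elif closed_world:
        base = FALSE
    if a.negated:
        return {TRUE: FALSE, FALSE: TRUE, UNKNOWN: UNKNOWN}[base]
    return base


def holds(d: Description, beliefs, closed_world: bool = False) -> str:
    """Three-valued evaluation of a ground description against a belief set.

    ``beliefs`` is a set of ground atoms (positive atoms believed true,
    negated atoms believed false).  The empty conjunction is vacuously
    ``true`` and the empty disjunction ``false``.
    """
    if not is_ground(d):
        raise NonGroundError(f"description contains variables: {sorted(variables(d))}")
    if isinstance(d, Atom):
        return _eval_atom(d, beliefs, closed_world)
    if isinstance(d, And):
        if not d.children:
            return TRUE
        rank = min(_KLEENE_RANK[holds(c, beliefs, closed_world)] for c in d.children)
        return _KLEENE_BY_RANK[rank]
    if isinstance(d, Or):
        if not d.children:
            return FALSE
        rank = max(_KLEENE_RANK[holds(c, beliefs, closed_world)] for c in d.children)
        return _KLEENE_BY_RANK[rank]
    if isinstance(d, Not):
        v = holds(d.child, beliefs, closed_world)
        return {TRUE: FALSE, FALSE: TRUE, UNKNOWN: UNKNOWN}[v]
    raise TypeError(f"not a description: {d!r}")


def match_atom(pattern: Atom, ground: Atom, binding: Optional[Binding] = None):
    """Unify a pattern atom against a ground atom; return the extended
    binding or None.  Beliefs are ground, so no occurs-check is needed."""
    if pattern.negated != ground.negated:
        return None
    env = dict(binding or {})
    for p, g in ((pattern.attr, ground.attr), (pattern.value, ground.value)):
        if is_variable(p):
            if p in env:
                if env[p] != g:
                    return None
            else:
                env[p] = g
        elif p != g:
            return None
    return env


def match_bindings(patterns, beliefs, binding: Optional[Binding] = None) -> Iterator[dict]:
    """Enumerate all bindings under which every positive pattern atom in
    ``patterns`` unifies with some belief atom (backtracking search)."""
    patterns = list(patterns)
    if not patterns:
        yield dict(binding or {})
        return
    first, rest = patterns[0], patterns[1:]
    for b in sorted(beliefs, key=str):
        env = match_atom(first, b, binding)
        if env is not None:
            yield from match_bindings(rest, beliefs, env)


# ---------------------------------------------------------------------------
# Serialization to/from plain YAML-friendly structures
# ---------------------------------------------------------------------------

def parse_description(obj) -> Description:
    """Parse the KB file encoding of a description.

    Atoms are two-element lists ``[attr, value]`` or ``{atom: [attr, value]}``;
    connectives are ``{all: [...]}``, ``{any: [...]}`` and ``{not: ...}``.
    """
    if isinstance(obj, (list, tuple)):
        if len(obj) != 2 or not all(isinstance(t, str) for t in obj):
            raise ValueError(f"atom must be a [attr, value] pair of strings: {obj!r}")
        return Atom(obj[0], obj[1])
    if isinstance(obj, dict):
        if len(obj) != 1:
            raise ValueError(f"description node must have exactly one key: {obj!r}")
        (key, val), = obj.items()
        if key == "atom":
            return parse_description(val)
        if key == "all":
            return And(tuple(parse_description(c) for c in val))
        if key == "any":
            return Or(tuple(parse_description(c) for c in val))
        if key == "not":
            return Not(parse_description(val))
        raise ValueError(f"unknown description connective: {key!r}")
    raise ValueError(f"cannot parse description from {obj!r}")


def description_to_obj(d: Description):
    if isinstance(d, Atom):
        if d.negated:
            return {"not": [d.attr, d.value]}
        return [d.attr, d.value]
    if isinstance(d, And):
        return {"all": [description_to_obj(c) for c in d.children]}
    if isinstance(d, Or):
        return {"any": [description_to_obj(c) for c in d.children]}
    if isinstance(d, Not):
        return {"not": description_to_obj(d.child)}
    raise TypeError(f"not a description: {d!r}")
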