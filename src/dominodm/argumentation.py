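"""Argument schemas, defeasible undercutting, and aggregation.

Preference over decision candidates is established by instantiating
declarative *argument schemas* into pro/con arguments, resolving defeat
among them (an argument is defeated iff attacked by an undefeated
undercutter — the grounded, skeptical labelling), and aggregating the
surviving reasons.  The default aggregator is the Bentham rule: a
candidate's merit is the summed strength of its undefeated pro arguments
minus the summed strength of its undefeated con arguments.

Rebuttal (pro and con arguments on the same candidate) is *not* defeat:
both sides count in the arithmetic.  Undercut cycles are left undefeated
and flagged undecided, as grounded semantics leaves them unresolved.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

from .descriptions import Atom, is_variable
from . import ontology as onto_mod


class ConfigurationError(ValueError):
    pass


@dataclass
class ArgumentSchema:
    """A declarative pattern yielding one argument per satisfied
    instantiation.

    ``condition`` is a conjunction of clauses, each a single-key dict:

    - ``{"relation": [subject, name, object]}`` — an ontology relation
      assertion (subject inheritance included); terms may be variables;
    - ``{"property": [concept, name]}`` or ``[concept, name, value]`` —
      an inherited property assertion;
    - ``{"belief": [attr, value]}`` — a ground atom currently believed;
    - ``{"goal_target": term}`` — the deciding goal lists ``term`` among
      its target conditions.

    The variables ``?candidate`` and ``?goal`` are pre-bound to the
    candidate payload and the goal name.
    """

    id: str
    polarity: str                      # pro | con | undercut
    condition: Tuple[dict, ...] = ()
    strength: float = 1.0
    undercuts: Optional[str] = None    # schema id the undercutter attacks
    askable: Tuple[str, ...] = ()      # belief attrs an agent may enquire about


@dataclass
class Argument:
    id: int
    target: object                     # candidate payload id, or Argument id
    target_kind: str                   # candidate | argument
    polarity: str
    schema_id: str
    grounds: Tuple = ()                # (binding items, supporting belief atoms)
    strength: float = 1.0
    defeated: bool = False
    undecided: bool = False
    candidate: Optional[str] = None    # candidate whose case this argument joins


@dataclass(frozen=True)
class Merit:
    candidate: str
    value: float
    aggregator: str = "bentham"


# ---------------------------------------------------------------------------
# Schema instantiation
# ---------------------------------------------------------------------------

def _resolve(term, env):
    if is_variable(term):
        return env.get(term)
    return term


def _clause_bindings(clause: dict, env: dict, beliefs, onto, goal_targets):
    """Enumerate extended bindings satisfying one clause."""
    (kind, spec), = clause.items()
    if kind == "relation":
        subj, rel, obj = spec
        if onto is None:
            return
        if rel not in onto.relation_vocab:
            raise ConfigurationError(f"schema clause references undeclared "
                                     f"relation {rel!r}")
        s0, o0 = _resolve(subj, env), _resolve(obj, env)
        for ra in onto.relations:
            if ra.relation != rel:
                continue
            subj_ok = (s0 is None and is_variable(subj)) or ra.subject == s0 or (
                s0 is not None and ra.subject != s0 and s0 in onto.concepts
                and onto_mod.is_a(s0, ra.subject, onto))
            if not subj_ok:
                continue
            if o0 is not None and ra.object != o0:
                continue
            out = dict(env)
            if is_variable(subj) and s0 is None:
                out[subj] = ra.subject
            if is_variable(obj) and o0 is None:
                out[obj] = ra.object
            yield out
    elif kind == "property":
        concept, name = spec[0], spec[1]
        want_value = spec[2] if len(spec) > 2 else None
        c0 = _resolve(concept, env)
        if c0 is None or onto is None or c0 not in onto.concepts:
            return
        for prop in onto_mod.inherited_properties(c0, onto):
            if prop.name != name:
                continue
            if want_value is not None and prop.value != _resolve(want_value, env):
                continue
            yield dict(env)
    elif kind == "belief":
        attr, value = spec
        pattern = Atom(attr, value)
        for b in sorted(beliefs, key=str):
            from .descriptions import match_atom
            new = match_atom(pattern, b, env)
            if new is not None:
                yield new
    elif kind == "goal_target":
        t0 = _resolve(spec, env)
        if t0 is None and is_variable(spec):
            for t in goal_targets:
                out = dict(env)
                out[spec] = t
                yield out
        elif t0 in goal_targets:
            yield dict(env)
    else:
        raise ConfigurationError(f"unknown schema clause kind {kind!r}")


def _schema_bindings(schema, env, beliefs, onto, goal_targets):
    envs = [env]
    for clause in schema.condition:
        nxt = []
        for e in envs:
            nxt.extend(_clause_bindings(clause, e, beliefs, onto, goal_targets))
        envs = nxt
        if not envs:
            return []
    # deduplicate
    seen, out = set(), []
    for e in envs:
        key = tuple(sorted(e.items()))
        if key not in seen:
            seen.add(key)
            out.append(e)
    return out


def _grounds_atoms(schema, env, beliefs):
    atoms = []
    for clause in schema.condition:
        (kind, spec), = clause.items()
        if kind == "belief":
            a = Atom(_resolve(spec[0], env) or spec[0],
                     _resolve(spec[1], env) or spec[1])
            if a in beliefs:
                atoms.append(a)
    return tuple(atoms)


def construct_arguments(candidates: Sequence, goal, beliefs, onto,
                        schemas: Sequence[ArgumentSchema],
                        start_id: int = 1) -> List[Argument]:
    """One argument per satisfied schema instantiation.

    ``candidates`` are objects with ``payload`` (or plain payload strings);
    ``goal`` supplies ``name`` and ``targets`` (may be None).  Pro/con
    schemas target candidates; undercut schemas run in a second pass over
    the constructed arguments, attacking instantiations of the schema they
    name.
    """
    goal_name = getattr(goal, "name", None) if goal is not None else None
    goal_targets = tuple(getattr(goal, "targets", ()) or ()) if goal is not None else ()
    payloads = [getattr(c, "payload", c) for c in candidates]

    args: List[Argument] = []
    next_id = start_id
    for schema in schemas:
        if schema.polarity == "undercut":
            continue
        for payload in payloads:
            env0 = {"?candidate": payload}
            if goal_name is not None:
                env0["?goal"] = goal_name
            for env in _schema_bindings(schema, env0, beliefs, onto, goal_targets):
                args.append(Argument(
                    id=next_id, target=payload, target_kind="candidate",
                    polarity=schema.polarity, schema_id=schema.id,
                    grounds=(tuple(sorted(env.items())),
                             _grounds_atoms(schema, env, beliefs)),
                    strength=schema.strength, candidate=payload))
                next_id += 1
    for schema in schemas:
        if schema.polarity != "undercut":
            continue
        for target_arg in list(args):
            if target_arg.schema_id != schema.undercuts:
                continue
            env0 = {"?candidate": target_arg.candidate}
            if goal_name is not None:
                env0["?goal"] = goal_name
            for env in _schema_bindings(schema, env0, beliefs, onto, goal_targets):
                args.append(Argument(
                    id=next_id, target=target_arg.id, target_kind="argument",
                    polarity="undercut", schema_id=schema.id,
                    grounds=(tuple(sorted(env.items())),
                             _grounds_atoms(schema, env, beliefs)),
                    strength=schema.strength, candidate=target_arg.candidate))
                next_id += 1
    return args


# ---------------------------------------------------------------------------
# Defeat and aggregation
# ---------------------------------------------------------------------------

def resolve_defeat(arguments: Sequence[Argument]) -> List[Argument]:
    """Grounded labelling of the undercut graph, computed iteratively to
    fixpoint.  IN: all attackers OUT.  OUT: some attacker IN.  Arguments
    left unlabelled (undercut cycles) stay undefeated but are flagged
    ``undecided``."""
    by_id = {a.id: a for a in arguments}
    attackers: Dict[int, List[int]] = {a.id: [] for a in arguments}
    for a in arguments:
        if a.target_kind == "argument" and a.target in by_id:
            attackers[a.target].append(a.id)

    label: Dict[int, str] = {}
    changed = True
    while changed:
        changed = False
        for a in arguments:
            if a.id in label:
                continue
            att = attackers[a.id]
            if all(label.get(x) == "out" for x in att):
                label[a.id] = "in"
                changed = True
            elif any(label.get(x) == "in" for x in att):
                label[a.id] = "out"
                changed = True
    for a in arguments:
        a.defeated = label.get(a.id) == "out"
        a.undecided = a.id not in label
    return list(arguments)


def bentham(candidates: Sequence[str], arguments: Sequence[Argument]) -> Dict[str, float]:
    """Sum of undefeated pro strengths minus undefeated con strengths."""
    merits = {c: 0.0 for c in candidates}
    for a in arguments:
        if a.defeated or a.target_kind != "candidate":
            continue
        if a.target not in merits:
            continue
        if a.polarity == "pro":
            merits[a.target] += a.strength
        elif a.polarity == "con":
            merits[a.target] -= a.strength
    return merits


def make_frequency_weighted(counters: Dict[tuple, int], context: str,
                            weight: float = 1.0) -> Callable:
    """Bentham plus a learned-frequency bonus: each past commitment to a
    candidate in this context adds ``weight`` to its merit."""
    def agg(candidates, arguments):
        merits = bentham(candidates, arguments)
        for c in merits:
            merits[c] += weight * counters.get((context, c), 0)
        return merits
    return agg


AGGREGATORS: Dict[str, Callable] = {"bentham": bentham, "weighted": bentham}


def aggregate(candidates: Sequence[str], arguments: Sequence[Argument],
              aggregator="bentham") -> List[Merit]:
    """Merit per candidate under the named (or callable) aggregator.
    Defeat must already be resolved; defeated arguments contribute
    nothing."""
    if callable(aggregator):
        fn, name = aggregator, getattr(aggregator, "__name__", "custom")
    else:
        try:
            fn, name = AGGREGATORS[aggregator], aggregator
        except KeyError:
            raise ConfigurationError(f"unknown aggregator {aggregator!r}") from None
    merits = fn(list(candidates), arguments)
    return [Merit(c, merits[c], name) for c in candidates]


def prefer(candidates: Sequence[str], merits: Sequence[Merit],
           tie_break: str = "random",
           rng: Optional[random.Random] = None,
           priorities: Optional[Dict[str, int]] = None) -> List[str]:
    """Total preference order: descending merit, ties broken by policy.

    Policies: ``random`` (seeded generator — the default, matching choice
    among equally supported options), ``lexicographic`` (payload id), and
    ``priority`` (declared priority map, highest first).
    """
    value = {m.candidate: m.value for m in merits}
    groups: Dict[float, List[str]] = {}
    for c in candidates:
        groups.setdefault(value.get(c, 0.0), []).append(c)
    ordered: List[str] = []
    for v in sorted(groups, reverse=True):
        tie = list(groups[v])
        if len(tie) > 1:
            if tie_break == "random":
                if rng is None:
                    rng = random.Random(0)
                rng.shuffle(tie)
            elif tie_break == "lexicographic":
                tie.sort()
            elif tie_break == "priority":
                tie.sort(key=lambda c: (-(priorities or {}).get(c, 0), c))
            elif tie_break is None:
                tie.sort()   # stable order; caller detects the tie for impasse
            else:
                raise ConfigurationError(f"unknown tie-break policy {tie_break!r}")
        ordered.extend(tie)
    return ordered
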