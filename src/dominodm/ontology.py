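"""The knowledge level: concepts, inheritance, relations, rules, models.

Knowledge is organised as a ladder of increasingly rich structures: terms
are assigned to concepts in an is-a network (a DAG, so multiple
inheritance is allowed); concepts carry property assertions and take part
in named relations (``causes``, ``exacerbates``, ``effective_for``, ...);
descriptions over attribute/value atoms combine into rules; and rules and
descriptions condense into scenario and task models.

Property shadowing follows specific-over-general practice: a property
declared on a descendant overrides a same-named property declared on an
ancestor.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx

from .descriptions import (
    And,
    Atom,
    Description,
    holds,
    is_variable,
    match_bindings,
    substitute,
    variables,
    TRUE,
)


class ResolutionError(KeyError):
    """An identifier does not resolve to a declared element."""

    def __init__(self, kind: str, ident: str):
        super().__init__(f"unknown {kind}: {ident!r}")
        self.kind = kind
        self.ident = ident


@dataclass(frozen=True)
class PropertyAssertion:
    name: str
    value: Optional[str] = None


@dataclass
class Concept:
    id: str
    label: str = ""
    parents: Tuple[str, ...] = ()
    properties: Tuple[PropertyAssertion, ...] = ()

    def __post_init__(self):
        if not self.label:
            self.label = self.id


@dataclass(frozen=True)
class RelationAssertion:
    subject: str
    relation: str
    object: str


@dataclass
class GoalTemplate:
    """Consequent of a goal-kind rule: the goal to raise when it fires."""

    name: str
    condition: Description
    stakes: str = "routine"          # routine | high
    priority: int = 0
    parent: Optional[str] = None     # name of the parent goal, if a sub-goal
    targets: Tuple[str, ...] = ()    # condition terms a decision must serve
    kind: str = "achieve"            # achieve | decide


@dataclass
class Rule:
    id: str
    kind: str                         # belief | goal | candidate | expectation
    antecedent: Description
    consequents: Tuple = ()           # descriptions, GoalTemplates, or payload ids
    closed_world: bool = False        # negation-as-failure for this rule
    provenance: str = "authored"      # authored | learned
    for_goal: Optional[str] = None    # candidate rules: goal name they index


@dataclass
class ScenarioModel:
    id: str
    label: str = ""
    situation: Description = field(default_factory=And)
    goals: Tuple[str, ...] = ()
    provenance: str = "authored"


@dataclass
class TaskModel:
    id: str
    label: str = ""
    serves_goal: str = ""
    plan_template: str = ""


@dataclass
class Ontology:
    """A complete knowledge base: every section cross-validated."""

    concepts: Dict[str, Concept] = field(default_factory=dict)
    relation_vocab: Set[str] = field(default_factory=set)
    relations: List[RelationAssertion] = field(default_factory=list)
    rules: List[Rule] = field(default_factory=list)
    schemas: List = field(default_factory=list)       # ArgumentSchema objects
    scenarios: List[ScenarioModel] = field(default_factory=list)
    tasks: List[TaskModel] = field(default_factory=list)
    plans: Dict[str, dict] = field(default_factory=dict)   # plan templates
    agents: Dict[str, dict] = field(default_factory=dict)  # network section

    def concept(self, cid: str) -> Concept:
        try:
            return self.concepts[cid]
        except KeyError:
            raise ResolutionError("concept", cid) from None

    def rules_of_kind(self, kind: str) -> List[Rule]:
        return [r for r in self.rules if r.kind == kind]

    def merged_with(self, other: "Ontology") -> "Ontology":
        """Union of a shared KB with a specialist partition (ids must not
        collide across concept/rule sections)."""
        out = Ontology(
            concepts=dict(self.concepts),
            relation_vocab=set(self.relation_vocab) | set(other.relation_vocab),
            relations=list(self.relations) + list(other.relations),
            rules=list(self.rules) + list(other.rules),
            schemas=list(self.schemas) + list(other.schemas),
            scenarios=list(self.scenarios) + list(other.scenarios),
            tasks=list(self.tasks) + list(other.tasks),
            plans={**self.plans, **other.plans},
            agents={**self.agents, **other.agents},
        )
        for cid, c in other.concepts.items():
            out.concepts[cid] = c
        return out


# ---------------------------------------------------------------------------
# Inheritance reasoning
# ---------------------------------------------------------------------------

def ancestors(a: str, onto: Ontology) -> Set[str]:
    """Strict ancestors of ``a`` in the is-a DAG (deduplicated)."""
    onto.concept(a)
    seen: Set[str] = set()
    queue = deque(onto.concept(a).parents)
    while queue:
        p = queue.popleft()
        if p in seen:
            continue
        seen.add(p)
        queue.extend(onto.concept(p).parents)
    return seen


def is_a(a: str, b: str, onto: Ontology) -> bool:
    """True iff ``b`` is in the reflexive-transitive is-a closure of ``a``."""
    onto.concept(a)
    onto.concept(b)
    return a == b or b in ancestors(a, onto)


def inherited_properties(a: str, onto: Ontology) -> Set[PropertyAssertion]:
    """Own properties plus those inherited from all ancestors, with
    same-named properties shadowed specific-over-general (breadth-first,
    declared parent order breaks ties between equally specific ancestors)."""
    onto.concept(a)
    out: Dict[str, PropertyAssertion] = {}
    seen: Set[str] = set()
    frontier = [a]
    while frontier:
        nxt: List[str] = []
        for cid in frontier:
            if cid in seen:
                continue
            seen.add(cid)
            for prop in onto.concept(cid).properties:
                out.setdefault(prop.name, prop)
            nxt.extend(onto.concept(cid).parents)
        frontier = nxt
    return set(out.values())


def related(a: str, relation: str, onto: Ontology,
            include_inherited: bool = False) -> Set[str]:
    """Objects of ``relation`` assertions on ``a`` (and, when requested, on
    all its ancestors)."""
    onto.concept(a)
    if relation not in onto.relation_vocab:
        raise ResolutionError("relation", relation)
    subjects = {a} | (ancestors(a, onto) if include_inherited else set())
    return {r.object for r in onto.relations
            if r.relation == relation and r.subject in subjects}


# ---------------------------------------------------------------------------
# Rule application
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RuleFiring:
    rule_id: str
    binding: Tuple[Tuple[str, str], ...]
    consequent: object               # instantiated Description / GoalTemplate / payload

    def binding_dict(self) -> dict:
        return dict(self.binding)


def _positive_pattern_atoms(d: Description) -> List[Atom]:
    """Atoms usable as generators for variable bindings: positive atoms not
    under negation.  Variables appearing only under negation must be bound
    by a positive atom."""
    from .descriptions import Not, Or

    out: List[Atom] = []

    def walk(node, negated):
        if isinstance(node, Atom):
            if not negated and not node.negated:
                out.append(node)
        elif isinstance(node, (And, Or)):
            for c in node.children:
                walk(c, negated)
        elif isinstance(node, Not):
            walk(node.child, not negated)

    walk(d, False)
    return out


def _instantiate_consequent(cons, binding: dict):
    if isinstance(cons, (Atom, And)) or hasattr(cons, "children") or hasattr(cons, "child"):
        return substitute(cons, binding)
    if isinstance(cons, GoalTemplate):
        name = cons.name
        for var, val in binding.items():
            name = name.replace(var, val)
        return GoalTemplate(
            name=name,
            condition=substitute(cons.condition, binding),
            stakes=cons.stakes,
            priority=cons.priority,
            parent=cons.parent,
            targets=tuple(binding.get(t, t) for t in cons.targets),
            kind=cons.kind,
        )
    if isinstance(cons, str):
        return binding.get(cons, cons) if is_variable(cons) else cons
    return cons


def applicable_rules(beliefs, kind: str, onto: Ontology) -> List[RuleFiring]:
    """All instantiated consequents of ``kind``-rules whose antecedent holds
    true under the current ground beliefs, with their bindings.

    Bindings are enumerated by unifying the antecedent's positive atoms
    against belief atoms, then filtered through three-valued evaluation of
    the fully instantiated antecedent.
    """
    firings: List[RuleFiring] = []
    for rule in onto.rules_of_kind(kind):
        patterns = [p for p in _positive_pattern_atoms(rule.antecedent)
                    if variables(p)]
        seen_bindings = set()
        for env in match_bindings(patterns, beliefs):
            key = tuple(sorted(env.items()))
            if key in seen_bindings:
                continue
            seen_bindings.add(key)
            inst = substitute(rule.antecedent, env)
            if variables(inst):
                continue
            if holds(inst, beliefs, rule.closed_world) != TRUE:
                continue
            for cons in rule.consequents:
                firings.append(RuleFiring(rule.id, key, _instantiate_consequent(cons, env)))
    return firings


# ---------------------------------------------------------------------------
# Integrity validation
# ---------------------------------------------------------------------------

def validate(onto: Ontology) -> List[str]:
    """Referential-integrity check across every section; returns one message
    per violation, each naming the offending element."""
    errors: List[str] = []

    # concept graph
    g = nx.DiGraph()
    g.add_nodes_from(onto.concepts)
    for cid, c in onto.concepts.items():
        for p in c.parents:
            if p not in onto.concepts:
                errors.append(f"concept {cid!r}: unknown parent {p!r}")
            else:
                g.add_edge(cid, p)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        names = " -> ".join(str(u) for u, _ in cycle) + f" -> {cycle[0][0]}"
        errors.append(f"is-a cycle: {names}")

    for r in onto.relations:
        if r.relation not in onto.relation_vocab:
            errors.append(f"relation assertion ({r.subject}, {r.relation}, {r.object}): "
                          f"undeclared relation {r.relation!r}")
        for end, cid in (("subject", r.subject), ("object", r.object)):
            if cid not in onto.concepts:
                errors.append(f"relation assertion ({r.subject}, {r.relation}, "
                              f"{r.object}): unknown {end} {cid!r}")

    seen_rule_ids = set()
    for rule in onto.rules:
        if rule.id in seen_rule_ids:
            errors.append(f"rule {rule.id!r}: duplicate id")
        seen_rule_ids.add(rule.id)
        if rule.kind not in {"belief", "goal", "candidate", "expectation"}:
            errors.append(f"rule {rule.id!r}: unknown kind {rule.kind!r}")
        ante_vars = variables(rule.antecedent)
        for cons in rule.consequents:
            cvars = set()
            if isinstance(cons, (Atom, And)) or hasattr(cons, "child"):
                cvars = variables(cons)
            elif isinstance(cons, GoalTemplate):
                cvars = variables(cons.condition)
                cvars |= {t for t in cons.targets if is_variable(t)}
            elif isinstance(cons, str) and is_variable(cons):
                cvars = {cons}
            unbound = cvars - ante_vars
            if unbound:
                errors.append(f"rule {rule.id!r}: consequent variables "
                              f"{sorted(unbound)} unbound in antecedent")

    for schema in onto.schemas:
        for clause in getattr(schema, "condition", ()):
            if "relation" in clause:
                rel = clause["relation"][1]
                if rel not in onto.relation_vocab:
                    errors.append(f"schema {schema.id!r}: undeclared relation {rel!r}")
        if schema.polarity not in {"pro", "con", "undercut"}:
            errors.append(f"schema {schema.id!r}: unknown polarity {schema.polarity!r}")
        if schema.polarity == "undercut" and not schema.undercuts:
            errors.append(f"schema {schema.id!r}: undercut schema must name a "
                          f"target schema")

    for t in onto.tasks:
        if t.plan_template and t.plan_template not in onto.plans:
            errors.append(f"task model {t.id!r}: unknown plan template "
                          f"{t.plan_template!r}")

    return errors
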