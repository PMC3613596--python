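"""Knowledge-base file loading, validation and serialization.

A KB is a single YAML document with top-level sections ``concepts``,
``relations``, ``rules``, ``schemas``, ``scenarios``, ``tasks``, ``plans``
and ``agents`` (all optional), plus a ``format_version``.  Loading is
atomic: the document is parsed and cross-validated in full, and any
structural or integrity problem raises :class:`KBLoadError` carrying one
element-path-anchored message per violation — no partial ontology is ever
returned.

Agent entries may carry a ``partition`` holding the same sections; it is
parsed into a specialist :class:`Ontology` that is merged with the shared
KB when the agent is built.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Optional, Union

import yaml

from .argumentation import ArgumentSchema
from .descriptions import And, description_to_obj, parse_description
from .ontology import (
    Concept,
    GoalTemplate,
    Ontology,
    PropertyAssertion,
    RelationAssertion,
    Rule,
    ScenarioModel,
    TaskModel,
    validate,
)

FORMAT_VERSION = 1


class KBLoadError(ValueError):
    def __init__(self, errors: List[str]):
        self.errors = list(errors)
        super().__init__("KB load failed:\n" + "\n".join(f"  - {e}" for e in errors))


class _Collector:
    def __init__(self):
        self.errors: List[str] = []

    def add(self, path: str, message: str):
        self.errors.append(f"{path}: {message}")


def _parse_concepts(section, col, path) -> dict:
    out = {}
    for i, spec in enumerate(section or []):
        p = f"{path}[{i}]"
        if not isinstance(spec, dict) or "id" not in spec:
            col.add(p, "concept needs an 'id'")
            continue
        props = []
        for j, prop in enumerate(spec.get("properties") or []):
            if isinstance(prop, str):
                props.append(PropertyAssertion(prop))
            elif isinstance(prop, dict) and "name" in prop:
                props.append(PropertyAssertion(prop["name"], prop.get("value")))
            else:
                col.add(f"{p}.properties[{j}]", f"bad property {prop!r}")
        cid = spec["id"]
        if cid in out:
            col.add(p, f"duplicate concept id {cid!r}")
        out[cid] = Concept(id=cid, label=spec.get("label", cid),
                           parents=tuple(spec.get("parents") or ()),
                           properties=tuple(props))
    return out


def _parse_rules(section, col, path) -> list:
    rules = []
    for i, spec in enumerate(section or []):
        p = f"{path}[{i}]"
        if not isinstance(spec, dict) or "id" not in spec:
            col.add(p, "rule needs an 'id'")
            continue
        kind = spec.get("kind", "belief")
        try:
            ante = parse_description(spec.get("when", {"all": []}))
        except ValueError as e:
            col.add(f"{p}.when", str(e))
            continue
        consequents: list = []
        if kind in {"belief", "expectation"}:
            for j, c in enumerate(spec.get("then") or []):
                try:
                    consequents.append(parse_description(c))
                except ValueError as e:
                    col.add(f"{p}.then[{j}]", str(e))
        elif kind == "goal":
            goal_specs = spec.get("goals") or ([spec["goal"]] if "goal" in spec else [])
            if not goal_specs:
                col.add(p, "goal rule needs 'goal' or 'goals'")
            for j, g in enumerate(goal_specs):
                try:
                    consequents.append(GoalTemplate(
                        name=g["name"],
                        condition=parse_description(g.get("condition",
                                                          {"all": []})),
                        stakes=g.get("stakes", "routine"),
                        priority=int(g.get("priority", 0)),
                        parent=g.get("parent"),
                        targets=tuple(g.get("targets") or ()),
                        kind=g.get("kind", "achieve")))
                except (KeyError, ValueError) as e:
                    col.add(f"{p}.goals[{j}]", f"bad goal template: {e}")
        elif kind == "candidate":
            consequents = list(spec.get("options") or [])
            if not consequents:
                col.add(p, "candidate rule needs 'options'")
        else:
            col.add(p, f"unknown rule kind {kind!r}")
        rules.append(Rule(id=spec["id"], kind=kind, antecedent=ante,
                          consequents=tuple(consequents),
                          closed_world=bool(spec.get("closed_world", False)),
                          provenance=spec.get("provenance", "authored"),
                          for_goal=spec.get("for_goal")))
    return rules


def _parse_schemas(section, col, path) -> list:
    out = []
    for i, spec in enumerate(section or []):
        p = f"{path}[{i}]"
        if not isinstance(spec, dict) or "id" not in spec:
            col.add(p, "schema needs an 'id'")
            continue
        condition = []
        for j, clause in enumerate(spec.get("condition") or []):
            if not isinstance(clause, dict) or len(clause) != 1:
                col.add(f"{p}.condition[{j}]", f"clause must be a single-key "
                                               f"mapping: {clause!r}")
                continue
            condition.append(clause)
        out.append(ArgumentSchema(
            id=spec["id"], polarity=spec.get("polarity", "pro"),
            condition=tuple(condition),
            strength=float(spec.get("strength", 1.0)),
            undercuts=spec.get("undercuts"),
            askable=tuple(spec.get("askable") or ())))
    return out


def _parse_ontology(doc: dict, col: _Collector, path: str = "") -> Ontology:
    pfx = f"{path}." if path else ""
    onto = Ontology()
    onto.concepts = _parse_concepts(doc.get("concepts"), col, f"{pfx}concepts")
    rel = doc.get("relations") or {}
    onto.relation_vocab = set(rel.get("vocabulary") or ())
    for i, a in enumerate(rel.get("assertions") or []):
        p = f"{pfx}relations.assertions[{i}]"
        if not (isinstance(a, (list, tuple)) and len(a) == 3):
            col.add(p, f"assertion must be [subject, relation, object]: {a!r}")
            continue
        onto.relations.append(RelationAssertion(*a))
    onto.rules = _parse_rules(doc.get("rules"), col, f"{pfx}rules")
    onto.schemas = _parse_schemas(doc.get("schemas"), col, f"{pfx}schemas")
    for i, s in enumerate(doc.get("scenarios") or []):
        p = f"{pfx}scenarios[{i}]"
        try:
            onto.scenarios.append(ScenarioModel(
                id=s["id"], label=s.get("label", ""),
                situation=parse_description(s.get("situation", {"all": []})),
                goals=tuple(s.get("goals") or ()),
                provenance=s.get("provenance", "authored")))
        except (KeyError, ValueError) as e:
            col.add(p, f"bad scenario model: {e}")
    for i, t in enumerate(doc.get("tasks") or []):
        p = f"{pfx}tasks[{i}]"
        try:
            onto.tasks.append(TaskModel(
                id=t["id"], label=t.get("label", ""),
                serves_goal=t.get("serves_goal", ""),
                plan_template=t.get("plan_template", "")))
        except (KeyError, TypeError) as e:
            col.add(p, f"bad task model: {e}")
    onto.plans = dict(doc.get("plans") or {})
    agents = {}
    for agent_id, spec in (doc.get("agents") or {}).items():
        spec = dict(spec or {})
        if "partition" in spec and isinstance(spec["partition"], dict):
            spec["partition"] = _parse_ontology(
                spec["partition"], col, f"{pfx}agents.{agent_id}.partition")
        agents[agent_id] = spec
    onto.agents = agents
    return onto


def load_kb(path: Union[str, Path]) -> Ontology:
    """Load and fully validate a KB file; total or fails atomically."""
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as e:
        raise KBLoadError([f"{path.name}: YAML parse error: {e}"]) from None
    if not isinstance(doc, dict):
        raise KBLoadError([f"{path.name}: document must be a mapping"])
    col = _Collector()
    version = doc.get("format_version")
    if version != FORMAT_VERSION:
        col.add("format_version",
                f"expected {FORMAT_VERSION}, found {version!r}")
    onto = _parse_ontology(doc, col)
    if col.errors:
        raise KBLoadError(col.errors)
    integrity = validate(onto)
    for spec in onto.agents.values():
        part = spec.get("partition")
        if isinstance(part, Ontology):
            merged = onto.merged_with(part)
            integrity.extend(validate(merged))
    if integrity:
        raise KBLoadError(sorted(set(integrity)))
    return onto


# ---------------------------------------------------------------------------
# Serialization (round-trips through load_kb)
# ---------------------------------------------------------------------------

def _rule_to_obj(rule: Rule) -> dict:
    out = {"id": rule.id, "kind": rule.kind,
           "when": description_to_obj(rule.antecedent)}
    if rule.kind in {"belief", "expectation"}:
        out["then"] = [description_to_obj(c) for c in rule.consequents]
    elif rule.kind == "goal":
        out["goals"] = [{
            "name": g.name, "condition": description_to_obj(g.condition),
            "stakes": g.stakes, "priority": g.priority,
            **({"parent": g.parent} if g.parent else {}),
            **({"targets": list(g.targets)} if g.targets else {}),
            "kind": g.kind} for g in rule.consequents]
    elif rule.kind == "candidate":
        out["options"] = list(rule.consequents)
    if rule.closed_world:
        out["closed_world"] = True
    if rule.provenance != "authored":
        out["provenance"] = rule.provenance
    if rule.for_goal:
        out["for_goal"] = rule.for_goal
    return out


def serialize_kb(onto: Ontology) -> dict:
    doc: dict = {"format_version": FORMAT_VERSION}
    doc["concepts"] = [{
        "id": c.id, "label": c.label, "parents": list(c.parents),
        "properties": [
            p.name if p.value is None else {"name": p.name, "value": p.value}
            for p in c.properties]}
        for c in onto.concepts.values()]
    doc["relations"] = {
        "vocabulary": sorted(onto.relation_vocab),
        "assertions": [[r.subject, r.relation, r.object]
                       for r in onto.relations]}
    doc["rules"] = [_rule_to_obj(r) for r in onto.rules]
    doc["schemas"] = [{
        "id": s.id, "polarity": s.polarity,
        "condition": [dict(c) for c in s.condition],
        "strength": s.strength,
        **({"undercuts": s.undercuts} if s.undercuts else {}),
        **({"askable": list(s.askable)} if s.askable else {})}
        for s in onto.schemas]
    doc["scenarios"] = [{
        "id": s.id, "label": s.label,
        "situation": description_to_obj(s.situation),
        "goals": list(s.goals), "provenance": s.provenance}
        for s in onto.scenarios]
    doc["tasks"] = [{"id": t.id, "label": t.label,
                     "serves_goal": t.serves_goal,
                     "plan_template": t.plan_template} for t in onto.tasks]
    doc["plans"] = onto.plans
    agents = {}
    for aid, spec in onto.agents.items():
        spec = dict(spec)
        if isinstance(spec.get("partition"), Ontology):
            part = serialize_kb(spec["partition"])
            part.pop("format_version")
            spec["partition"] = part
        agents[aid] = spec
    doc["agents"] = agents
    return doc


def save_kb(onto: Ontology, path: Union[str, Path]) -> None:
    Path(path).write_text(yaml.safe_dump(serialize_kb(onto), sort_keys=False))
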