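"""The agent kernel: ten typed cognitive operations and the
decision cycle that sequences them.

The cycle follows the domino lifecycle: observations update beliefs
(``s1``), monitoring checks expectations (``s9``), beliefs raise goals and
sub-goals (``s2``), each decision goal flows through candidate generation,
argument construction, aggregation and commitment (``s3``–``s6``), adopted
plans are enacted and their enabled actions executed (``s7``/``s8``), and
completed decisions feed learning (``s10``).  Operation ordering within a
cycle is a design choice — one decision goal is processed per cycle,
highest priority first, FIFO among equals.

Commitments come in two modes (accept a belief / adopt a plan) and two
firmness grades.  A commitment is firm when the top merit strictly exceeds
the runner-up and no pending enquiry or consultation could still yield a
schema-relevant belief; for high-stakes goals with a declared consultation
source the commitment is provisional and an information-seeking goal is
raised instead.

All randomness (tie-breaks) draws from a single seeded generator owned by
the kernel, so a fixed (knowledge base, scenario, seed) triple yields an
identical trace.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .descriptions import And, Atom, Description, holds, variables, TRUE, FALSE
from .memory import (
    Belief,
    Expectation,
    Goal,
    Justification,
    Observation,
    WorkingMemory,
)
from .argumentation import (
    Argument,
    Merit,
    aggregate,
    construct_arguments,
    make_frequency_weighted,
    prefer,
    resolve_defeat,
)
from .ontology import (
    GoalTemplate,
    Ontology,
    ScenarioModel,
    applicable_rules,
)


class KernelError(RuntimeError):
    pass


@dataclass
class Candidate:
    id: int
    goal_item: int
    kind: str                      # hypothesis | action_option
    payload: str
    origin: str = "retrieved"      # retrieved | constructed


@dataclass
class Commitment:
    id: int
    mode: str                      # accept | adopt
    candidate: str                 # payload
    goal_item: int
    firmness: str                  # provisional | firm


@dataclass
class Task:
    id: str
    kind: str                      # enquiry | decision | action | subplan
    after: Tuple[str, ...] = ()
    preconditions: Optional[Description] = None
    material: Tuple[str, ...] = () # material resources required
    effects: Tuple[Atom, ...] = ()
    performative: Optional[dict] = None   # communication acts
    status: str = "pending"        # pending | enabled | done | postponed | discarded
    retries: int = 0
    subtasks: Tuple[str, ...] = ()


@dataclass
class Plan:
    id: str
    goal_item: Optional[int]
    tasks: Dict[str, Task] = field(default_factory=dict)

    def done(self) -> bool:
        return all(t.status in {"done", "discarded"} for t in self.tasks.values())


def enabled_tasks(plan: Plan, beliefs, closed_world: bool = False) -> List[Task]:
    """Tasks whose completion dependencies are all done and whose logical
    preconditions hold true.  Completed sub-plans fold back: a subplan task
    is done once every subtask is done."""
    for t in plan.tasks.values():
        if t.kind == "subplan" and t.status not in {"done", "discarded"}:
            if t.subtasks and all(plan.tasks[s].status == "done" for s in t.subtasks):
                t.status = "done"
    out = []
    for t in plan.tasks.values():
        if t.status not in {"pending", "postponed", "enabled"}:
            continue
        if any(plan.tasks[p].status != "done" for p in t.after):
            continue
        if t.preconditions is not None and holds(t.preconditions, beliefs,
                                                 closed_world) != TRUE:
            continue
        out.append(t)
    return sorted(out, key=lambda t: t.id)


def plan_from_template(plan_id: str, template: dict,
                       goal_item: Optional[int] = None) -> Plan:
    from .descriptions import parse_description
    tasks: Dict[str, Task] = {}
    for tid, spec in (template.get("tasks") or {}).items():
        spec = spec or {}
        pre = spec.get("preconditions")
        tasks[tid] = Task(
            id=tid, kind=spec.get("kind", "action"),
            after=tuple(spec.get("after", ())),
            preconditions=parse_description(pre) if pre is not None else None,
            material=tuple(spec.get("material", ())),
            effects=tuple(Atom(a, v) for a, v in spec.get("effects", ())),
            performative=spec.get("performative"),
            subtasks=tuple(spec.get("subtasks", ())))
    return Plan(id=plan_id, goal_item=goal_item, tasks=tasks)


@dataclass
class DecisionState:
    """Per-goal record of the s3–s6 pipeline."""

    goal_item: int
    candidates: List[Candidate] = field(default_factory=list)
    arguments: List[Argument] = field(default_factory=list)
    external_arguments: List[Argument] = field(default_factory=list)
    merits: List[Merit] = field(default_factory=list)
    order: List[str] = field(default_factory=list)
    commitment: Optional[Commitment] = None
    consulted: Set[str] = field(default_factory=set)
    awaiting: Optional[str] = None      # consultation source we wait on
    impasse: bool = False
    pending_external: List[dict] = field(default_factory=list)

    def all_arguments(self) -> List[Argument]:
        return list(self.arguments) + list(self.external_arguments)


class AgentKernel:
    """A single decision-making agent over an ontology-backed working
    memory."""

    def __init__(self, agent_id: str, onto: Ontology, seed: int = 0,
                 aggregator: str = "bentham", tie_break: str = "random",
                 consult_sources: Sequence[str] = (),
                 use_frequency_weighting: bool = False,
                 max_derivation_rounds: int = 100):
        self.id = agent_id
        self.onto = onto
        self.memory = WorkingMemory()
        self.rng = random.Random(seed)
        self.aggregator = aggregator
        self.tie_break = tie_break
        self.consult_sources = list(consult_sources)
        self.use_frequency_weighting = use_frequency_weighting
        self.max_derivation_rounds = max_derivation_rounds
        self.decisions: Dict[int, DecisionState] = {}
        self.plans: Dict[str, Plan] = {}
        self.counters: Dict[tuple, int] = {}
        self.episodes: List[ScenarioModel] = []
        self.trace: List[dict] = []
        self.outbox: List = []
        self._arg_id = 1
        self._fresh_firm: List[Tuple[Goal, Commitment]] = []
        self.candidate_strategies: List = []

    # -- trace ------------------------------------------------------------

    def _record(self, op: str, consumed=(), produced=(), **detail):
        self.trace.append({
            "cycle": self.memory.clock, "agent": self.id, "op": op,
            "consumed": sorted(int(i) for i in consumed),
            "produced": sorted(int(i) for i in produced),
            "detail": detail})

    # -- helpers ----------------------------------------------------------

    def _supports_for(self, description: Description) -> frozenset:
        from .ontology import _positive_pattern_atoms
        ids = set()
        for atom in _positive_pattern_atoms(description):
            if atom.attr.startswith("goal:"):
                for it in self.memory.active_goals():
                    if it.content.name == atom.attr[len("goal:"):]:
                        ids.add(it.id)
            else:
                item = self.memory.atom_item(atom)
                if item is not None:
                    ids.add(item)
        return frozenset(ids)

    def _goal_atoms(self) -> Set[Atom]:
        return {Atom(f"goal:{it.content.name}", "active")
                for it in self.memory.active_goals()}

    # -- S1: belief maintenance -------------------------------------------

    def s1_maintain_beliefs(self, observations: Iterable = ()) -> List[int]:
        """Ingest observations and propagate beliefs to the derivation
        fixpoint.  Terminates on cyclic rule bases because an already
        active duplicate is never re-asserted; a round guard catches
        runaway rule interactions."""
        produced: List[int] = []
        for obs in observations:
            atom, source = obs if isinstance(obs, tuple) else (obs, "environment")
            iid = self.memory.assert_item(
                Observation(atom, source, self.memory.clock),
                Justification("observation"))
            produced.append(iid)
        rounds = 0
        while True:
            rounds += 1
            if rounds > self.max_derivation_rounds:
                raise KernelError(
                    f"belief derivation exceeded {self.max_derivation_rounds} "
                    f"rounds; check belief rules for a productive cycle")
            beliefs = self.memory.belief_atoms()
            new = []
            for firing in applicable_rules(beliefs, "belief", self.onto):
                cons = firing.consequent
                if not isinstance(cons, Atom):
                    continue
                if cons in beliefs or cons.negate() in beliefs:
                    continue
                new.append((cons, firing))
            if not new:
                break
            for atom, firing in new:
                if atom in self.memory.belief_atoms():
                    continue
                rule = next(r for r in self.onto.rules if r.id == firing.rule_id)
                inst = None
                try:
                    from .descriptions import substitute
                    inst = substitute(rule.antecedent, firing.binding_dict())
                except Exception:
                    inst = rule.antecedent
                supports = self._supports_for(inst)
                if not supports:
                    supports = frozenset()
                just = Justification("inference" if supports else "assumption",
                                     supports, rule_id=firing.rule_id)
                iid = self.memory.assert_item(Belief(atom), just)
                produced.append(iid)
        if produced:
            self._record("s1", produced=produced)
        return produced

    # -- S9: monitoring ----------------------------------------------------

    def s9_monitor(self, observations: Iterable[Atom] = ()) -> List[int]:
        """Match observations against active expectations; a mismatch
        asserts an expectation-violation belief justified by both sides,
        matched expectations close."""
        produced: List[int] = []
        obs_atoms = [o[0] if isinstance(o, tuple) else o for o in observations]
        for exp_item in self.memory.active_items(Expectation):
            exp = exp_item.content
            lo, hi = exp.window
            if not (lo <= self.memory.clock <= hi):
                continue
            for atom in obs_atoms:
                if atom == exp.predicted:
                    self.memory.retract(exp_item.id, cascade=False)
                    self._record("s9", consumed=[exp_item.id], outcome="met")
                    break
                if atom.attr == exp.predicted.attr and atom.value != exp.predicted.value:
                    obs_id = self.memory.atom_item(atom)
                    supports = {exp_item.id} | ({obs_id} if obs_id else set())
                    vid = self.memory.assert_item(
                        Belief(Atom("expectation_violated", exp.predicted.attr)),
                        Justification("inference", frozenset(supports)))
                    produced.append(vid)
                    self.memory.retract(exp_item.id, cascade=False)
                    self._record("s9", consumed=sorted(supports),
                                 produced=[vid], outcome="violated")
                    break
        return produced

    # -- S2: raising goals --------------------------------------------------

    def s2_raise_goals(self) -> List[int]:
        """Fire goal-kind rules over beliefs and active goals (goals lead
        to sub-goals); duplicates suppressed, conditions that already hold
        are not raised."""
        produced: List[int] = []
        changed = True
        while changed:
            changed = False
            beliefs = self.memory.belief_atoms() | self._goal_atoms()
            existing = {it.content.name for it in self.memory.active_items(Goal)
                        if it.content.status != "dropped"}
            for firing in applicable_rules(beliefs, "goal", self.onto):
                tpl = firing.consequent
                if not isinstance(tpl, GoalTemplate):
                    continue
                if tpl.name in existing:
                    continue
                if not variables(tpl.condition) and \
                        holds(tpl.condition, self.memory.belief_atoms()) == TRUE:
                    continue
                parent_id = None
                if tpl.parent:
                    for it in self.memory.active_goals():
                        if it.content.name == tpl.parent:
                            parent_id = it.id
                rule = next(r for r in self.onto.rules if r.id == firing.rule_id)
                from .descriptions import substitute
                supports = self._supports_for(
                    substitute(rule.antecedent, firing.binding_dict()))
                goal = Goal(name=tpl.name, condition=tpl.condition,
                            parent=parent_id, priority=tpl.priority,
                            stakes=tpl.stakes, status="active",
                            targets=tpl.targets, kind=tpl.kind)
                gid = self.memory.assert_item(
                    goal, Justification("inference" if supports else "assumption",
                                        supports, rule_id=firing.rule_id,
                                        goal_id=parent_id))
                produced.append(gid)
                existing.add(tpl.name)
                changed = True
        if produced:
            self._record("s2", produced=produced)
        return produced

    # -- S3: generate candidates --------------------------------------------

    def s3_generate_candidates(self, goal_item: int) -> List[Candidate]:
        """Knowledge-base retrieval of options indexed under the goal, plus
        any registered constructive strategies.  An empty result logs an
        impasse."""
        goal = self.memory.items[goal_item].content
        ds = self.decisions.setdefault(goal_item, DecisionState(goal_item))
        payloads: List[Tuple[str, str, Optional[str]]] = []
        for rule in self.onto.rules_of_kind("candidate"):
            if rule.for_goal and rule.for_goal != goal.name:
                continue
            beliefs = self.memory.belief_atoms() | self._goal_atoms()
            if holds(rule.antecedent, beliefs, rule.closed_world) != TRUE:
                continue
            for cons in rule.consequents:
                if isinstance(cons, str):
                    payloads.append((cons, "retrieved", rule.id))
        for strategy in self.candidate_strategies:
            for p in strategy(goal):
                payloads.append((p, "constructed", None))
        seen = set()
        ds.candidates = []
        kind = "hypothesis" if goal.kind == "decide_belief" else "action_option"
        for n, (p, origin, rid) in enumerate(payloads):
            if p in seen:
                continue
            seen.add(p)
            cand = Candidate(id=n + 1, goal_item=goal_item, kind=kind,
                             payload=p, origin=origin)
            ds.candidates.append(cand)
            self.memory.assert_item(
                cand, Justification("inference", frozenset({goal_item}),
                                    rule_id=rid, goal_id=goal_item))
        if not ds.candidates:
            ds.impasse = True
            self._record("s3", consumed=[goal_item], impasse=True, goal=goal.name)
        else:
            self._record("s3", consumed=[goal_item], goal=goal.name,
                         candidates=[c.payload for c in ds.candidates])
        return ds.candidates

    # -- S4/S5: arguments, merit, preference ---------------------------------

    def s4_construct_reasons(self, goal_item: int) -> List[Argument]:
        goal = self.memory.items[goal_item].content
        ds = self.decisions[goal_item]
        ds.arguments = construct_arguments(
            ds.candidates, goal, self.memory.belief_atoms(), self.onto,
            self.onto.schemas, start_id=self._arg_id)
        if ds.arguments:
            self._arg_id = max(a.id for a in ds.arguments) + 1
        self._record("s4", consumed=[goal_item],
                     arguments=[(a.schema_id, a.polarity, str(a.target))
                                for a in ds.arguments])
        return ds.arguments

    def s5_aggregate(self, goal_item: int) -> List[str]:
        goal = self.memory.items[goal_item].content
        ds = self.decisions[goal_item]
        all_args = resolve_defeat(ds.all_arguments())
        payloads = [c.payload for c in ds.candidates]
        agg = self.aggregator
        if self.use_frequency_weighting:
            agg = make_frequency_weighted(self.counters, goal.name)
        ds.merits = aggregate(payloads, all_args, agg)
        ds.order = prefer(payloads, ds.merits, self.tie_break, self.rng)
        self._record("s5", consumed=[goal_item],
                     merits={m.candidate: m.value for m in ds.merits},
                     order=list(ds.order))
        return ds.order

    # -- S6: commitment -------------------------------------------------------

    def s6_commit(self, goal_item: int) -> Optional[Commitment]:
        goal = self.memory.items[goal_item].content
        ds = self.decisions[goal_item]
        if not ds.order:
            ds.impasse = True
            self._record("s6", consumed=[goal_item], impasse="no candidates")
            return None
        top = ds.order[0]
        value = {m.candidate: m.value for m in ds.merits}
        strict = len(ds.order) == 1 or value[top] > value[ds.order[1]]
        if not strict and self.tie_break is None:
            ds.impasse = True
            self._record("s6", consumed=[goal_item], impasse="tie")
            return None
        pending = [s for s in self.consult_sources if s not in ds.consulted]
        firm = strict and not (goal.stakes == "high" and pending)
        mode = "accept" if goal.kind == "decide_belief" else "adopt"
        commitment = Commitment(id=goal_item, mode=mode, candidate=top,
                                goal_item=goal_item,
                                firmness="firm" if firm else "provisional")
        ds.commitment = commitment
        cid = self.memory.assert_item(
            commitment, Justification("commitment", frozenset({goal_item}),
                                      goal_id=goal_item))
        self._record("s6", consumed=[goal_item], produced=[cid],
                     candidate=top, firmness=commitment.firmness, mode=mode)
        if firm:
            self.memory.assert_item(
                Belief(Atom(f"decided:{goal.name}", top)),
                Justification("commitment", frozenset({cid})))
            if mode == "accept":
                self.memory.assert_item(
                    Belief(Atom(f"accepted:{goal.name}", top), "confirmed"),
                    Justification("commitment", frozenset({cid})))
            from .descriptions import atoms_of
            if all(not a.negated for a in atoms_of(goal.condition)):
                for atom in atoms_of(goal.condition):
                    self.memory.assert_item(
                        Belief(atom), Justification("commitment",
                                                    frozenset({cid})))
            if mode == "adopt":
                for tm in self.onto.tasks:
                    if tm.serves_goal == goal.name and tm.plan_template in self.onto.plans:
                        plan = plan_from_template(
                            f"{tm.plan_template}:{goal_item}",
                            self.onto.plans[tm.plan_template], goal_item)
                        self.plans[plan.id] = plan
            self._fresh_firm.append((goal, commitment))
        elif goal.stakes == "high" and pending:
            source = pending[0]
            ds.awaiting = source
            consult_name = f"consult:{source}:{goal.name}"
            if not any(it.content.name == consult_name
                       for it in self.memory.active_items(Goal)):
                cg = Goal(name=consult_name,
                          condition=Atom(f"consulted:{source}:{goal.name}", "true"),
                          parent=goal_item, priority=goal.priority + 1,
                          stakes="routine", status="active", kind="consult")
                self.memory.assert_item(
                    cg, Justification("inference", frozenset({cid}),
                                      goal_id=goal_item))
                self._record("s6", consumed=[goal_item],
                             raised_consult=consult_name)
        return commitment

    # -- S7/S8: plan enactment and action --------------------------------------

    def s7_enact(self, plan: Plan) -> List[Task]:
        """Tasks whose dependencies are complete and preconditions hold;
        failed preconditions postpone (and eventually discard) the task."""
        goal_ok = plan.goal_item is None or (
            self.memory.items[plan.goal_item].status == "active")
        if not goal_ok:
            return []
        enabled = enabled_tasks(plan, self.memory.belief_atoms())
        for t in enabled:
            t.status = "enabled"
        if enabled:
            self._record("s7", enabled=[t.id for t in enabled], plan=plan.id)
        return enabled

    def s8_execute(self, task: Task, environment=None) -> List[Atom]:
        """Execute an enabled atomic action: apply the environment
        transition, assert expectations from declared effects, or postpone
        on an unsatisfied material precondition."""
        if task.material and environment is not None:
            missing = [m for m in task.material
                       if not environment.has_resource(m)]
            if missing:
                task.retries += 1
                task.status = "discarded" if task.retries > 3 else "postponed"
                self._record("s8", task=task.id, postponed=missing,
                             status=task.status)
                return []
        if task.performative is not None:
            self.outbox.append(task.performative)
            task.status = "done"
            self._record("s8", task=task.id, message=True)
            return []
        observations: List[Atom] = []
        if environment is not None and hasattr(environment, "apply"):
            observations = list(environment.apply(task))
        task.status = "done"
        produced = []
        for eff in task.effects:
            eid = self.memory.assert_item(
                Expectation(eff, origin=0,
                            window=(self.memory.clock, self.memory.clock + 2)),
                Justification("commitment", frozenset()))
            produced.append(eid)
        self._record("s8", task=task.id, produced=produced,
                     observations=[str(a) for a in observations])
        return observations

    # -- S10: learning -----------------------------------------------------------

    def s10_learn(self) -> List[ScenarioModel]:
        """On decision termination: append an episodic scenario model
        (the goal plus the belief set held at commitment) and increment
        the (context, decision) frequency counter."""
        episodes = []
        for goal, commitment in self._fresh_firm:
            atoms = tuple(sorted(self.memory.belief_atoms(), key=str))
            episode = ScenarioModel(
                id=f"episode:{self.id}:{len(self.episodes) + 1}",
                label=f"{goal.name} -> {commitment.candidate}",
                situation=And(atoms), goals=(goal.name,),
                provenance="learned")
            self.onto.scenarios.append(episode)
            self.episodes.append(episode)
            episodes.append(episode)
            key = (goal.name, commitment.candidate)
            self.counters[key] = self.counters.get(key, 0) + 1
            self._record("s10", episode=episode.id,
                         counter=[goal.name, commitment.candidate,
                                  self.counters[key]])
        self._fresh_firm = []
        return episodes

    # -- the cycle ----------------------------------------------------------------

    def _next_decision_goal(self) -> Optional[int]:
        """Highest-priority active decide-goal still needing a firm
        commitment and not awaiting a consultation reply."""
        best = None
        for it in self.memory.active_goals():
            g = it.content
            if g.kind not in {"decide", "decide_belief"}:
                continue
            ds = self.decisions.get(it.id)
            if ds is not None:
                if ds.commitment is not None and ds.commitment.firmness == "firm":
                    continue
                if ds.awaiting is not None or ds.impasse:
                    continue
            if best is None or g.priority > best[0] or (
                    g.priority == best[0] and it.id < best[1]):
                if best is None or g.priority > best[0]:
                    best = (g.priority, it.id)
        return best[1] if best else None

    def run_decision(self, goal_item: int) -> Optional[Commitment]:
        """The s3–s6 pipeline for one goal."""
        ds = self.decisions.get(goal_item)
        if ds is None or not ds.candidates:
            self.s3_generate_candidates(goal_item)
            ds = self.decisions[goal_item]
            if not ds.candidates:
                return None
        self.s4_construct_reasons(goal_item)
        self.s5_aggregate(goal_item)
        return self.s6_commit(goal_item)

    def step(self, observations: Iterable = (), environment=None) -> bool:
        """One kernel cycle; returns True if any work was done."""
        start_trace = len(self.trace)
        n_items = len(self.memory.items)
        self.s1_maintain_beliefs(observations)
        self.s9_monitor(observations)
        self.s1_maintain_beliefs(())   # propagate violation beliefs
        self.memory.check_goal_termination()
        self.s2_raise_goals()
        goal_item = self._next_decision_goal()
        if goal_item is not None:
            self.run_decision(goal_item)
        for plan in list(self.plans.values()):
            if plan.done():
                continue
            for task in self.s7_enact(plan):
                self.s8_execute(task, environment)
        if self._fresh_firm:
            self.s10_learn()
        worked = len(self.trace) > start_trace or len(self.memory.items) > n_items
        self.memory.clock += 1
        return worked

    def run_cycle(self, environment=None, max_cycles: int = 50) -> List[dict]:
        """Run to quiescence (no enabled work) or ``max_cycles``; returns
        the trace.  Identical (kb, scenario, seed) yields an identical
        trace."""
        for _ in range(max_cycles):
            obs = list(environment.observe(self.memory.clock)) \
                if environment is not None else []
            worked = self.step(obs, environment)
            if not worked and not obs:
                break
        else:
            self._record("cycle", incomplete=True)
        return self.trace
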