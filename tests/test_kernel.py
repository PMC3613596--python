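"""The kernel operations: belief-propagation fixpoints against a naive
iteration oracle, goal raising, commitment policy, plan enactment against
a brute-force dependency oracle, and learning counters."""

import random

import pytest

from dominodm.descriptions import And, Atom, holds, TRUE
from dominodm.kernel import (
    AgentKernel,
    KernelError,
    Plan,
    Task,
    enabled_tasks,
    plan_from_template,
)
from dominodm.memory import Belief, Expectation, Goal, Justification
from dominodm.ontology import GoalTemplate, Ontology, Rule
from dominodm.scenarios.random_fixtures import random_rule_base
from dominodm.scenarios.mi import build_chronic_pain_fixture


def naive_fixpoint(rules, facts):
    """Repeat-until-no-change application of ground rules (independent of
    the kernel's derivation machinery)."""
    derived = set(facts)
    while True:
        new = set()
        for rule in rules:
            if all(c in derived for c in rule.antecedent.children):
                for cons in rule.consequents:
                    if cons not in derived:
                        new.add(cons)
        if not new:
            return derived
        derived |= new


class TestS1:
    def test_mi_inference_chain(self):
        onto = Ontology()
        onto.rules = [
            Rule("r1", "belief", Atom("complaint", "chest_pain"),
                 (Atom("possible", "heart_attack"),)),
            Rule("r2", "belief", And((Atom("possible", "heart_attack"),)),
                 (Atom("possible", "mi"),)),
        ]
        k = AgentKernel("c", onto)
        k.s1_maintain_beliefs([Atom("complaint", "chest_pain")])
        beliefs = k.memory.belief_atoms()
        assert Atom("possible", "heart_attack") in beliefs
        assert Atom("possible", "mi") in beliefs

    def test_no_applicable_rules_leaves_memory_unchanged(self):
        k = AgentKernel("c", Ontology())
        k.s1_maintain_beliefs([Atom("a", "x")])
        n = len(k.memory.items)
        assert k.s1_maintain_beliefs([]) == []
        assert len(k.memory.items) == n

    def test_idempotent_without_new_observations(self):
        onto = random_rule_base(random.Random(1), n_rules=6)
        k = AgentKernel("c", onto)
        k.s1_maintain_beliefs([Atom("a0", "v0"), Atom("a1", "v1")])
        before = k.memory.belief_atoms()
        assert k.s1_maintain_beliefs([]) == []
        assert k.memory.belief_atoms() == before

    def test_matches_naive_fixpoint_oracle_on_random_rule_bases(self):
        for seed in range(40):
            rng = random.Random(seed)
            onto = random_rule_base(rng, n_rules=rng.randint(2, 10))
            facts = {Atom(f"a{rng.randrange(4)}", f"v{rng.randrange(3)}")
                     for _ in range(rng.randint(0, 4))}
            k = AgentKernel("c", onto)
            k.s1_maintain_beliefs(sorted(facts, key=str))
            assert k.memory.belief_atoms() == naive_fixpoint(onto.rules,
                                                             facts)

    def test_cyclic_rule_bases_terminate(self):
        onto = Ontology()
        onto.rules = [
            Rule("r1", "belief", Atom("a", "x"), (Atom("b", "y"),)),
            Rule("r2", "belief", Atom("b", "y"), (Atom("a", "x"),)),
        ]
        k = AgentKernel("c", onto)
        k.s1_maintain_beliefs([Atom("a", "x")])
        assert Atom("b", "y") in k.memory.belief_atoms()


class TestS2:
    def test_chronic_pain_raises_two_decision_goals(self):
        k = AgentKernel("c", build_chronic_pain_fixture())
        k.s1_maintain_beliefs([Atom("complaint", "severe_chronic_pain")])
        new = k.s2_raise_goals()
        names = {k.memory.items[i].content.name for i in new}
        assert names == {"decide_most_plausible_cause",
                         "decide_most_preferred_treatment"}

    def test_goal_chains_to_subgoals_in_one_pass(self):
        onto = Ontology()
        onto.rules = [
            Rule("g1", "goal", Atom("fire", "burning"),
                 (GoalTemplate("put_out_fire", Atom("fire", "out")),)),
            Rule("g2", "goal", Atom("goal:put_out_fire", "active"),
                 (GoalTemplate("get_to_fire", Atom("location", "at_fire"),
                               parent="put_out_fire"),)),
        ]
        k = AgentKernel("c", onto)
        k.s1_maintain_beliefs([Atom("fire", "burning")])
        k.s2_raise_goals()
        names = {it.content.name for it in k.memory.active_goals()}
        assert names == {"put_out_fire", "get_to_fire"}
        sub = next(it for it in k.memory.active_goals()
                   if it.content.name == "get_to_fire")
        parent = next(it for it in k.memory.active_goals()
                      if it.content.name == "put_out_fire")
        assert sub.content.parent == parent.id

    def test_duplicates_suppressed_and_satisfied_conditions_skipped(self):
        onto = Ontology()
        onto.rules = [Rule("g1", "goal", Atom("a", "x"),
                           (GoalTemplate("g", Atom("b", "y")),))]
        k = AgentKernel("c", onto)
        k.s1_maintain_beliefs([Atom("a", "x")])
        assert len(k.s2_raise_goals()) == 1
        assert k.s2_raise_goals() == []
        # a goal whose condition already holds is never raised
        k2 = AgentKernel("c2", onto)
        k2.s1_maintain_beliefs([Atom("a", "x"), Atom("b", "y")])
        assert k2.s2_raise_goals() == []

    def test_no_matching_rules_raise_nothing(self):
        k = AgentKernel("c", Ontology())
        k.s1_maintain_beliefs([Atom("a", "x")])
        assert k.s2_raise_goals() == []


def _decision_kernel(options, stakes="routine", consult=(), schemas=()):
    onto = Ontology()
    onto.rules = [
        Rule("g", "goal", Atom("need", "choice"),
             (GoalTemplate("choose", Atom("choice", "made"), stakes=stakes,
                           kind="decide"),)),
        Rule("c", "candidate", And(), consequents=tuple(options),
             for_goal="choose"),
    ]
    onto.schemas = list(schemas)
    k = AgentKernel("c", onto, seed=3, consult_sources=list(consult))
    k.s1_maintain_beliefs([Atom("need", "choice")])
    k.s2_raise_goals()
    return k


class TestDecisionPipeline:
    def test_empty_candidates_is_an_impasse(self):
        k = _decision_kernel([])
        goal_item = k._next_decision_goal()
        k.run_decision(goal_item)
        assert k.decisions[goal_item].impasse
        assert any(r["op"] == "s3" and r["detail"].get("impasse")
                   for r in k.trace)

    def test_single_candidate_routine_stakes_commits_firm(self):
        k = _decision_kernel(["only"])
        c = k.run_decision(k._next_decision_goal())
        assert c.firmness == "firm" and c.candidate == "only"

    def test_high_stakes_with_consult_source_commits_provisional(self):
        k = _decision_kernel(["a", "b"], stakes="high", consult=["expert"])
        from dominodm.argumentation import ArgumentSchema
        k.onto.schemas = [ArgumentSchema(
            id="pro_a", polarity="pro",
            condition=({"belief": ["likes", "?candidate"]},))]
        k.s1_maintain_beliefs([Atom("likes", "a")])
        goal_item = k._next_decision_goal()
        c = k.run_decision(goal_item)
        assert c.firmness == "provisional"
        names = {it.content.name for it in k.memory.active_goals()}
        assert "consult:expert:choose" in names

    def test_consultation_completion_firms_the_commitment(self):
        k = _decision_kernel(["a", "b"], stakes="high", consult=["expert"])
        from dominodm.argumentation import ArgumentSchema
        k.onto.schemas = [ArgumentSchema(
            id="pro_a", polarity="pro",
            condition=({"belief": ["likes", "?candidate"]},))]
        k.s1_maintain_beliefs([Atom("likes", "a")])
        goal_item = k._next_decision_goal()
        k.run_decision(goal_item)
        ds = k.decisions[goal_item]
        ds.consulted.add("expert")
        ds.awaiting = None
        c = k.run_decision(goal_item)
        assert c.firmness == "firm"

    def test_tie_with_disabled_tie_break_is_an_impasse(self):
        k = _decision_kernel(["a", "b"])
        k.tie_break = None
        goal_item = k._next_decision_goal()
        assert k.run_decision(goal_item) is None
        assert k.decisions[goal_item].impasse

    def test_firm_commitment_marks_goal_achieved(self):
        k = _decision_kernel(["only"])
        goal_item = k._next_decision_goal()
        k.run_decision(goal_item)
        assert holds(Atom("choice", "made"), k.memory.belief_atoms()) == TRUE
        k.memory.check_goal_termination()
        assert k.memory.items[goal_item].content.status == "achieved"


class TestS7S8:
    def test_soap_network_gating(self):
        soap = {"tasks": {
            "subjective": {"kind": "enquiry"},
            "objective": {"kind": "enquiry"},
            "assess": {"kind": "decision", "after": ["subjective",
                                                     "objective"]},
            "plan": {"kind": "action", "after": ["assess"]}}}
        p = plan_from_template("soap", soap)
        assert {t.id for t in enabled_tasks(p, set())} == \
            {"subjective", "objective"}
        p.tasks["subjective"].status = "done"
        assert {t.id for t in enabled_tasks(p, set())} == {"objective"}
        p.tasks["objective"].status = "done"
        assert {t.id for t in enabled_tasks(p, set())} == {"assess"}

    def test_empty_plan_enables_nothing(self):
        assert enabled_tasks(Plan("p", None), set()) == []

    def test_matches_brute_force_predecessor_oracle_on_random_networks(self):
        rng = random.Random(77)
        for _ in range(50):
            n = rng.randint(1, 8)
            tasks = {}
            for i in range(n):
                after = tuple(f"t{j}" for j in range(i)
                              if rng.random() < 0.3)
                tasks[f"t{i}"] = Task(id=f"t{i}", kind="action", after=after)
            plan = Plan("p", None, tasks)
            for t in tasks.values():
                if rng.random() < 0.4:
                    t.status = "done"
            got = {t.id for t in enabled_tasks(plan, set())}
            want = {t.id for t in tasks.values()
                    if t.status not in {"done", "discarded"}
                    and all(tasks[p_].status == "done" for p_ in t.after)}
            assert got == want

    def test_precondition_gates_enablement(self):
        tasks = {"act": Task(id="act", kind="action",
                             preconditions=Atom("ready", "yes"))}
        plan = Plan("p", None, tasks)
        assert enabled_tasks(plan, set()) == []
        assert [t.id for t in
                enabled_tasks(plan, {Atom("ready", "yes")})] == ["act"]

    def test_subplan_folds_back_when_subtasks_complete(self):
        tasks = {
            "sub": Task(id="sub", kind="subplan", subtasks=("a", "b")),
            "a": Task(id="a", kind="action", status="done"),
            "b": Task(id="b", kind="action", status="done"),
            "next": Task(id="next", kind="action", after=("sub",)),
        }
        plan = Plan("p", None, tasks)
        enabled = {t.id for t in enabled_tasks(plan, set())}
        assert tasks["sub"].status == "done"
        assert "next" in enabled

    def test_missing_material_precondition_postpones(self):
        class Env:
            def has_resource(self, r):
                return False

        k = AgentKernel("c", Ontology())
        task = Task(id="x", kind="action", material=("scalpel",))
        assert k.s8_execute(task, Env()) == []
        assert task.status == "postponed"

    def test_execution_asserts_effect_expectations(self):
        k = AgentKernel("c", Ontology())
        task = Task(id="x", kind="action", effects=(Atom("feedback",
                                                         "positive"),))
        k.s8_execute(task)
        exps = k.memory.active_items(Expectation)
        assert len(exps) == 1
        assert exps[0].content.predicted == Atom("feedback", "positive")


class TestS9:
    def test_violation_asserts_belief_supported_by_both_sides(self):
        k = AgentKernel("c", Ontology())
        origin = k.memory.assert_item(Belief(Atom("rule", "color")),
                                      Justification("axiom"))
        k.memory.assert_item(
            Expectation(Atom("feedback", "positive"), origin),
            Justification("commitment", frozenset({origin})))
        k.s1_maintain_beliefs([Atom("feedback", "negative")])
        k.s9_monitor([Atom("feedback", "negative")])
        assert Atom("expectation_violated", "feedback") in \
            k.memory.belief_atoms()

    def test_met_expectation_closes_silently(self):
        k = AgentKernel("c", Ontology())
        origin = k.memory.assert_item(Belief(Atom("rule", "color")),
                                      Justification("axiom"))
        eid = k.memory.assert_item(
            Expectation(Atom("feedback", "positive"), origin),
            Justification("commitment", frozenset({origin})))
        k.s1_maintain_beliefs([Atom("feedback", "positive")])
        k.s9_monitor([Atom("feedback", "positive")])
        assert k.memory.items[eid].status == "retracted"
        assert Atom("expectation_violated", "feedback") not in \
            k.memory.belief_atoms()

    def test_no_expectations_means_no_violations(self):
        k = AgentKernel("c", Ontology())
        assert k.s9_monitor([Atom("feedback", "negative")]) == []


class TestS10:
    def test_firm_commitment_writes_episode_and_counter(self):
        k = _decision_kernel(["only"])
        k.run_decision(k._next_decision_goal())
        episodes = k.s10_learn()
        assert len(episodes) == 1
        assert episodes[0].provenance == "learned"
        assert k.counters[("choose", "only")] == 1
        assert episodes[0] in k.onto.scenarios

    def test_repeated_scenarios_increment_the_counter(self):
        counters = {}
        for _ in range(2):
            k = _decision_kernel(["only"])
            k.counters = counters
            k.run_decision(k._next_decision_goal())
            k.s10_learn()
        assert counters[("choose", "only")] == 2


class TestRunCycle:
    def test_empty_environment_quiesces_immediately(self):
        k = AgentKernel("c", Ontology())
        trace = k.run_cycle(max_cycles=10)
        assert trace == []
        assert k.memory.clock <= 2

    def test_fixed_seed_gives_identical_traces(self):
        def run():
            k = _decision_kernel(["a", "b", "c"])
            k.run_decision(k._next_decision_goal())
            return k.trace
        assert run() == run()

    def test_derivation_guard_reports_runaway_rules(self):
        onto = Ontology()
        # a productive ladder that exceeds the round guard
        onto.rules = [Rule(f"r{i}", "belief", Atom("n", str(i)),
                           (Atom("n", str(i + 1)),)) for i in range(30)]
        k = AgentKernel("c", onto, max_derivation_rounds=5)
        with pytest.raises(KernelError):
            k.s1_maintain_beliefs([Atom("n", "0")])
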