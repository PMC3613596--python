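"""Defeat resolution against exhaustive grounded-labelling oracles,
Bentham aggregation against a tally oracle, and preference-order
properties."""

import itertools
import random

import pytest

from dominodm.argumentation import (
    Argument,
    ArgumentSchema,
    ConfigurationError,
    Merit,
    aggregate,
    construct_arguments,
    make_frequency_weighted,
    prefer,
    resolve_defeat,
)
from dominodm.descriptions import Atom
from dominodm.ontology import Concept, Ontology, RelationAssertion


def arg(i, target, polarity="pro", target_kind="candidate", strength=1.0):
    return Argument(id=i, target=target, target_kind=target_kind,
                    polarity=polarity, schema_id=f"s{i}", strength=strength,
                    candidate=target if target_kind == "candidate" else None)


def undercut(i, target_arg_id):
    return arg(i, target_arg_id, polarity="undercut", target_kind="argument")


# ---------------------------------------------------------------------------
# Grounded labelling oracles
# ---------------------------------------------------------------------------

def grounded_by_enumeration(attack_edges, nodes):
    """The grounded labelling is the complete labelling with the fewest
    IN arguments; enumerate all legal labellings to find it."""
    attackers = {n: [a for a, b in attack_edges if b == n] for n in nodes}
    best = None
    for assignment in itertools.product(["in", "out", "undec"],
                                        repeat=len(nodes)):
        label = dict(zip(nodes, assignment))
        legal = True
        for n in nodes:
            att = attackers[n]
            if label[n] == "in" and not all(label[a] == "out" for a in att):
                legal = False
            elif label[n] == "out" and not any(label[a] == "in" for a in att):
                legal = False
            elif label[n] == "undec" and (
                    all(label[a] == "out" for a in att)
                    or any(label[a] == "in" for a in att)):
                legal = False
            if not legal:
                break
        if legal:
            n_in = sum(1 for v in label.values() if v == "in")
            if best is None or n_in < best[0]:
                best = (n_in, label)
    return best[1]


def grounded_on_dag(attack_edges, nodes):
    """Topological-order labelling — valid on acyclic attack graphs."""
    attackers = {n: [a for a, b in attack_edges if b == n] for n in nodes}
    label = {}
    remaining = set(nodes)
    while remaining:
        for n in sorted(remaining):
            if all(a in label for a in attackers[n]):
                label[n] = "out" if any(label[a] == "in"
                                        for a in attackers[n]) else "in"
                remaining.discard(n)
                break
    return label


class TestResolveDefeat:
    def test_undercut_flips_preference_between_two_candidates(self):
        """R1 favors A, R2 favors B, R3 undermines R1: B wins."""
        r1, r2 = arg(1, "A"), arg(2, "B")
        r3 = undercut(3, 1)
        args = resolve_defeat([r1, r2, r3])
        assert r1.defeated and not r2.defeated and not r3.defeated
        merits = aggregate(["A", "B"], args)
        order = prefer(["A", "B"], merits, "lexicographic")
        assert order[0] == "B"

    def test_no_undercuts_leaves_everything_undefeated(self):
        args = resolve_defeat([arg(1, "A"), arg(2, "B", "con")])
        assert not any(a.defeated for a in args)

    def test_defeated_undercutter_does_not_defeat(self):
        a1 = arg(1, "A")
        u2, u3 = undercut(2, 1), undercut(3, 2)
        resolve_defeat([a1, u2, u3])
        assert not a1.defeated and u2.defeated and not u3.defeated

    def test_cycles_left_undefeated_and_flagged(self):
        u1, u2 = undercut(1, 2), undercut(2, 1)
        resolve_defeat([u1, u2])
        assert not u1.defeated and not u2.defeated
        assert u1.undecided and u2.undecided

    def test_matches_enumeration_oracle_on_random_graphs(self):
        rng = random.Random(21)
        for _ in range(120):
            n = rng.randint(1, 7)
            nodes = list(range(1, n + 1))
            edges = [(a, b) for a in nodes for b in nodes
                     if a != b and rng.random() < 0.25]
            args = {i: arg(i, "C") for i in nodes}
            for a, b in edges:
                args[a].polarity, args[a].target_kind = "undercut", "argument"
                args[a].target = b
            # multi-attack nodes: keep only last edge per attacker
            attack = {}
            for a, b in edges:
                attack[a] = b
            arglist = []
            for i in nodes:
                if i in attack:
                    arglist.append(undercut(i, attack[i]))
                else:
                    arglist.append(arg(i, "C"))
            resolve_defeat(arglist)
            want = grounded_by_enumeration(sorted(attack.items()), nodes)
            for a in arglist:
                assert a.defeated == (want[a.id] == "out")
                assert a.undecided == (want[a.id] == "undec")

    def test_matches_topological_oracle_on_random_dags(self):
        rng = random.Random(34)
        for _ in range(200):
            n = rng.randint(1, 12)
            nodes = list(range(1, n + 1))
            # edges point from later to earlier ids: acyclic
            attack = {}
            for a in nodes:
                targets = [b for b in nodes if b < a]
                if targets and rng.random() < 0.5:
                    attack[a] = rng.choice(targets)
            arglist = [undercut(i, attack[i]) if i in attack else arg(i, "C")
                       for i in nodes]
            resolve_defeat(arglist)
            want = grounded_on_dag(sorted(attack.items()), nodes)
            for a in arglist:
                assert a.defeated == (want[a.id] == "out")


class TestAggregate:
    def test_worked_counts_two_versus_one(self):
        args = resolve_defeat([arg(1, "target1"), arg(2, "target1"),
                               arg(3, "target2")])
        merits = {m.candidate: m.value
                  for m in aggregate(["target1", "target2"], args)}
        assert merits == {"target1": 2.0, "target2": 1.0}

    def test_candidate_with_no_arguments_scores_zero(self):
        merits = aggregate(["lonely"], [])
        assert merits[0].value == 0.0

    def test_matches_tally_oracle_on_random_multisets(self):
        rng = random.Random(55)
        for _ in range(250):
            cands = [f"c{i}" for i in range(rng.randint(1, 4))]
            args = []
            for i in range(rng.randint(0, 12)):
                a = arg(i + 1, rng.choice(cands),
                        rng.choice(["pro", "con"]),
                        strength=rng.choice([0.5, 1.0, 2.0]))
                a.defeated = rng.random() < 0.3
                args.append(a)
            merits = {m.candidate: m.value for m in aggregate(cands, args)}
            for c in cands:
                want = sum(a.strength for a in args
                           if a.target == c and not a.defeated
                           and a.polarity == "pro") - \
                    sum(a.strength for a in args
                        if a.target == c and not a.defeated
                        and a.polarity == "con")
                assert merits[c] == pytest.approx(want)

    def test_defeated_arguments_are_inert(self):
        """Deleting a defeated argument never changes any merit."""
        rng = random.Random(70)
        for _ in range(100):
            cands = ["a", "b"]
            args = [arg(i + 1, rng.choice(cands),
                        rng.choice(["pro", "con"])) for i in range(8)]
            for a in args:
                a.defeated = rng.random() < 0.4
            with_all = {m.candidate: m.value for m in aggregate(cands, args)}
            kept = [a for a in args if not a.defeated]
            without = {m.candidate: m.value for m in aggregate(cands, kept)}
            assert with_all == without

    def test_merit_is_additive_over_argument_sets(self):
        rng = random.Random(71)
        cands = ["a", "b"]
        s1 = [arg(i, rng.choice(cands), rng.choice(["pro", "con"]))
              for i in range(1, 5)]
        s2 = [arg(i, rng.choice(cands), rng.choice(["pro", "con"]))
              for i in range(5, 9)]
        m1 = {m.candidate: m.value for m in aggregate(cands, s1)}
        m2 = {m.candidate: m.value for m in aggregate(cands, s2)}
        m12 = {m.candidate: m.value for m in aggregate(cands, s1 + s2)}
        for c in cands:
            assert m12[c] == pytest.approx(m1[c] + m2[c])

    def test_frequency_weighting_adds_learned_bonus(self):
        counters = {("ctx", "a"): 3}
        fw = make_frequency_weighted(counters, "ctx")
        merits = {m.candidate: m.value for m in aggregate(["a", "b"], [], fw)}
        assert merits == {"a": 3.0, "b": 0.0}

    def test_unknown_aggregator_rejected(self):
        with pytest.raises(ConfigurationError):
            aggregate(["a"], [], "nonsense")


class TestPrefer:
    def test_descending_merit(self):
        merits = [Merit("t1", 2), Merit("t2", 1)]
        assert prefer(["t1", "t2"], merits, "lexicographic")[0] == "t1"

    def test_equal_merits_shuffle_deterministically_per_seed(self):
        merits = [Merit(c, 1.0) for c in "abcd"]
        orders = {tuple(prefer(list("abcd"), merits, "random",
                               random.Random(9))) for _ in range(5)}
        assert len(orders) == 1

    def test_total_order_consistent_with_merits(self):
        rng = random.Random(88)
        for _ in range(250):
            cands = [f"c{i}" for i in range(rng.randint(1, 6))]
            merits = [Merit(c, rng.choice([0, 1, 1, 2, 3])) for c in cands]
            order = prefer(cands, merits, "random", rng)
            assert sorted(order) == sorted(cands)
            value = {m.candidate: m.value for m in merits}
            # pairwise-sort oracle: every pair respects merit dominance
            for a, b in itertools.combinations(cands, 2):
                ia, ib = order.index(a), order.index(b)
                if value[a] > value[b]:
                    assert ia < ib
                elif value[b] > value[a]:
                    assert ib < ia

    def test_adding_a_pro_argument_never_lowers_rank(self):
        rng = random.Random(91)
        for _ in range(100):
            cands = ["a", "b", "c"]
            args = [arg(i + 1, rng.choice(cands),
                        rng.choice(["pro", "con"])) for i in range(6)]
            resolve_defeat(args)
            target = rng.choice(cands)
            before = prefer(cands, aggregate(cands, args), "lexicographic")
            boosted = args + [arg(99, target, "pro")]
            resolve_defeat(boosted)
            after = prefer(cands, aggregate(cands, boosted), "lexicographic")
            assert after.index(target) <= before.index(target)


class TestConstructArguments:
    def _mini_onto(self):
        onto = Ontology()
        for cid in ["drug", "aspirin", "gastritis"]:
            onto.concepts[cid] = Concept(cid)
        onto.concepts["aspirin"] = Concept("aspirin", parents=("drug",))
        onto.relation_vocab = {"exacerbates"}
        onto.relations = [RelationAssertion("aspirin", "exacerbates",
                                            "gastritis")]
        onto.schemas = [ArgumentSchema(
            id="exacerbation_con", polarity="con", strength=1.0,
            condition=({"relation": ["?candidate", "exacerbates",
                                     "?condition"]},
                       {"belief": ["has_condition", "?condition"]}))]
        return onto

    def test_exacerbation_schema_yields_con_against_aspirin(self):
        onto = self._mini_onto()
        beliefs = {Atom("has_condition", "gastritis")}
        args = construct_arguments(["aspirin", "clopidogrel"], None,
                                   beliefs, onto, onto.schemas)
        assert len(args) == 1
        assert args[0].polarity == "con" and args[0].target == "aspirin"
        assert Atom("has_condition", "gastritis") in args[0].grounds[1]

    def test_no_argument_without_the_patient_fact(self):
        onto = self._mini_onto()
        args = construct_arguments(["aspirin"], None, set(), onto,
                                   onto.schemas)
        assert args == []

    def test_empty_schema_set_yields_nothing(self):
        onto = self._mini_onto()
        args = construct_arguments(["aspirin"], None,
                                   {Atom("has_condition", "gastritis")},
                                   onto, [])
        assert args == []

    def test_undercut_schema_attacks_instantiated_argument(self):
        onto = self._mini_onto()
        onto.schemas.append(ArgumentSchema(
            id="doubt_exacerbation", polarity="undercut",
            undercuts="exacerbation_con",
            condition=({"belief": ["evidence", "weak"]},)))
        beliefs = {Atom("has_condition", "gastritis"),
                   Atom("evidence", "weak")}
        args = construct_arguments(["aspirin"], None, beliefs, onto,
                                   onto.schemas)
        kinds = {(a.schema_id, a.target_kind) for a in args}
        assert ("exacerbation_con", "candidate") in kinds
        assert ("doubt_exacerbation", "argument") in kinds
        resolve_defeat(args)
        con = next(a for a in args if a.schema_id == "exacerbation_con")
        assert con.defeated

    def test_undeclared_relation_is_a_configuration_error(self):
        onto = self._mini_onto()
        onto.schemas = [ArgumentSchema(
            id="bad", polarity="pro",
            condition=({"relation": ["?candidate", "cures", "?x"]},))]
        with pytest.raises(ConfigurationError):
            construct_arguments(["aspirin"], None, set(), onto, onto.schemas)
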