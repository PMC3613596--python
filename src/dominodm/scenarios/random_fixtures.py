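"""Seeded random fixtures for property-based tests: concept DAGs,
relation tables, ground and variable rule bases, and WCST decks.

Generation is constructive — every fixture passes integrity validation by
construction — and fully determined by the seed."""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import List

from ..descriptions import And, Atom
from ..ontology import (
    Concept,
    Ontology,
    PropertyAssertion,
    RelationAssertion,
    Rule,
)
from .wcst import WcstCard, shuffled_deck


@dataclass
class RandomFixture:
    ontology: Ontology
    atoms: List[Atom] = field(default_factory=list)
    deck: List[WcstCard] = field(default_factory=list)


def random_dag_ontology(rng: random.Random, n_concepts: int = 30,
                        n_relations: int = 20,
                        max_parents: int = 2) -> Ontology:
    """A random is-a DAG (edges only point to earlier concepts, so
    acyclicity is structural) with random properties and relation
    assertions."""
    onto = Ontology()
    prop_pool = [f"prop{i}" for i in range(6)]
    for i in range(n_concepts):
        cid = f"c{i}"
        n_par = rng.randint(0, min(max_parents, i))
        parents = tuple(rng.sample([f"c{j}" for j in range(i)], n_par))
        props = tuple(PropertyAssertion(p, rng.choice(["x", "y", None]))
                      for p in rng.sample(prop_pool, rng.randint(0, 2)))
        onto.concepts[cid] = Concept(id=cid, parents=parents, properties=props)
    onto.relation_vocab = {"rel0", "rel1", "rel2"}
    ids = list(onto.concepts)
    for _ in range(n_relations):
        onto.relations.append(RelationAssertion(
            rng.choice(ids), rng.choice(sorted(onto.relation_vocab)),
            rng.choice(ids)))
    return onto


def atom_pool(n_attrs: int = 4, n_values: int = 3) -> List[Atom]:
    return [Atom(f"a{i}", f"v{j}")
            for i in range(n_attrs) for j in range(n_values)]


def random_rule_base(rng: random.Random, n_rules: int = 8,
                     n_attrs: int = 4, n_values: int = 3,
                     with_variables: bool = False) -> Ontology:
    """Random belief rules over a small atom vocabulary; the consequent
    alphabet overlaps the antecedent alphabet so chains and cycles occur."""
    onto = Ontology()
    pool = atom_pool(n_attrs, n_values)
    for i in range(n_rules):
        if with_variables and rng.random() < 0.4:
            attr_a = f"a{rng.randrange(n_attrs)}"
            attr_b = f"a{rng.randrange(n_attrs)}"
            ante = And((Atom(attr_a, "?x"),))
            cons = (Atom(attr_b, "?x"),)
        else:
            n_ante = rng.randint(1, 2)
            ante = And(tuple(rng.sample(pool, n_ante)))
            cons = (rng.choice(pool),)
        onto.rules.append(Rule(id=f"r{i}", kind="belief",
                               antecedent=ante, consequents=cons))
    return onto


def generate_random_fixture(seed: int, n_concepts: int = 30,
                            n_relations: int = 20, n_rules: int = 8,
                            n_trials: int = 64) -> RandomFixture:
    """A complete random fixture: DAG ontology carrying a random rule
    base, the atom vocabulary, and a shuffled WCST deck.  Same seed, same
    fixture."""
    if min(n_concepts, n_relations, n_rules, n_trials) < 0:
        raise ValueError("sizes must be non-negative")
    rng = random.Random(seed)
    onto = random_dag_ontology(rng, n_concepts, n_relations)
    rules = random_rule_base(rng, n_rules)
    onto.rules = rules.rules
    deck = shuffled_deck(n_trials, rng) if n_trials else []
    return RandomFixture(ontology=onto, atoms=atom_pool(), deck=deck)
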