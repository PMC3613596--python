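import random

import pytest

from dominodm.descriptions import Atom
from dominodm.ontology import (
    Concept,
    Ontology,
    PropertyAssertion,
    RelationAssertion,
)


@pytest.fixture
def ulcer_ontology():
    """The gastric-ulcer fragment of the clinical knowledge ladder:
    gastric ulcer is-a peptic ulcer is-a disease is-a abnormal state, with
    has_symptoms declared on disease and causal relations at two levels of
    generality."""
    onto = Ontology()
    for cid, parents, props in [
        ("abnormal_state", (), ()),
        ("disease", ("abnormal_state",), (PropertyAssertion("has_symptoms"),)),
        ("peptic_ulcer", ("disease",), ()),
        ("gastric_ulcer", ("peptic_ulcer",), ()),
        ("hematemesis", (), ()),
        ("pain_after_meals", (), ()),
    ]:
        onto.concepts[cid] = Concept(id=cid, parents=parents, properties=props)
    onto.relation_vocab = {"causes"}
    onto.relations = [
        RelationAssertion("gastric_ulcer", "causes", "hematemesis"),
        RelationAssertion("peptic_ulcer", "causes", "pain_after_meals"),
    ]
    return onto


@pytest.fixture(scope="session")
def mi_outcome():
    """One full run of the three-agent consultation, shared across tests
    (the network is deterministic under a fixed seed)."""
    from dominodm.scenarios.mi import run_mi_scenario
    return run_mi_scenario(seed=7)


@pytest.fixture
def rng():
    return random.Random(12345)
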