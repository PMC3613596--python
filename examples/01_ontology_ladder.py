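"""Climbing the knowledge ladder: concepts, inheritance, relations,
rules.

Builds the gastric-ulcer fragment of a clinical knowledge base and shows
how class membership, property inheritance and causal relations combine
with rules to turn raw findings into diagnostic possibilities.
"""

from dominodm import (
    Atom,
    Concept,
    Ontology,
    PropertyAssertion,
    RelationAssertion,
    Rule,
    applicable_rules,
    inherited_properties,
    is_a,
    related,
)
from dominodm.descriptions import And

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
onto.rules = [
    Rule("r1", "belief", Atom("indigestion", "present"),
         (Atom("possible_diagnosis", "peptic_ulcer"),)),
    Rule("r2", "belief",
         And((Atom("indigestion", "present"), Atom("patient", "elderly"))),
         (Atom("possible_diagnosis", "gastric_ulcer"),)),
]

print("gastric_ulcer is a kind of peptic_ulcer:",
      is_a("gastric_ulcer", "peptic_ulcer", onto))
print("inherited properties of gastric_ulcer:",
      sorted(p.name for p in inherited_properties("gastric_ulcer", onto)))
print("symptoms caused (with inheritance):",
      sorted(related("gastric_ulcer", "causes", onto,
                     include_inherited=True)))

beliefs = {Atom("indigestion", "present"), Atom("patient", "elderly")}
firings = applicable_rules(beliefs, "belief", onto)
print("rule consequents from {indigestion=present, patient=elderly}:")
for f in firings:
    print("  ", f.rule_id, "->", f.consequent)

# The subclass inherits has_symptoms from 'disease' two levels up, pulls
# in symptoms asserted on its more general kind, and the elderly-patient
# rule sharpens the diagnosis from peptic to gastric ulcer.
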