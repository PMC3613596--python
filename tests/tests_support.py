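"""Independent oracles shared by the unit and acceptance suites.  Each
reimplements the checked computation by a different route than the
package (naive iteration, topological labelling, from-scratch
recomputation)."""

from dominodm.memory import Observation


def naive_ground_fixpoint(rules, facts):
    """Repeat-until-no-change application of ground conjunction rules."""
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


def grounded_on_dag(attack_edges, nodes):
    """Grounded labelling by topological evaluation (acyclic attacks):
    IN iff every attacker is OUT."""
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


def founded_oracle(wm):
    """From-scratch recomputation of the well-founded active set."""
    founded = set()
    while True:
        grew = False
        for item in wm.items.values():
            if item.id in founded or item.explicitly_retracted:
                continue
            ok = isinstance(item.content, Observation)
            for j in item.justifications:
                if j.kind in {"observation", "axiom", "assumption"}:
                    ok = True
                elif not j.supports and j.kind not in {"inference",
                                                       "communication"}:
                    ok = True
                elif j.supports and j.supports <= founded:
                    ok = True
            if ok:
                founded.add(item.id)
                grew = True
        if not grew:
            return founded
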