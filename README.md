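# dominodm

An executable kernel for **dynamic decision-making**: the decision
lifecycle of a cognitive agent — from the observations that make a
decision necessary, through goal raising, option generation and
argumentation-based preference, to commitment, plan enactment,
monitoring and learning — implemented as a small, fully deterministic
Python library.

It is written for computational cognitive modellers who want an
executable counterpart of BDI-style ("belief–desire–intention") agent
theory, and for decision-engineering work where the rationale for every
recommendation must be articulable: every working-memory item carries a
justification chain bottoming out at observations, and every run
serializes to a replayable trace.

## The model

The agent state is a justification-tagged **working memory** over an
ontology (a concept DAG with inheritance, named relations, rules and
scenario/task models).  Each cycle applies ten typed operations:

| op  | operation            | contract (inputs ⊢ outputs) |
|-----|----------------------|------------------------------|
| s1  | belief maintenance   | Observation × Ontology ⊢ Belief (recursively: Belief × Ontology ⊢ Belief) |
| s2  | raising goals        | Belief × Ontology ⊢ Goal; Goal × Ontology ⊢ Goal |
| s3  | generate options     | Goal × Belief × Ontology ⊢ Candidate |
| s4  | construct reasons    | Candidate × Goal × Belief × Ontology ⊢ Candidate × Reason |
| s5  | aggregate reasons    | Goal × Candidate × Reason ⊢ Candidate × Merit |
| s6  | commitment           | Candidate × Merit ⊢ Belief (accept) / Goal × Plan (adopt) |
| s7  | plan enactment       | Goal × Belief × Plan ⊢ Goal × Plan |
| s8  | action               | Plan × Precondition ⊢ Action |
| s9  | monitoring           | Goal × Observation × Ontology ⊢ Belief |
| s10 | learning             | Belief × Ontology ⊢ Scenario; Goal × Belief × Ontology ⊢ Task |

Preference (s4–s5) is argumentation-based: declarative schemas
instantiate into pro/con **reasons**; an *undercutter* attacks another
reason's veracity, and defeat is resolved by the grounded (skeptical)
labelling — a reason is defeated iff attacked by an undefeated
undercutter.  Merit is then the **Bentham rule**

```
merit(c) = Σ strength(undefeated pros for c) − Σ strength(undefeated cons against c)
```

and preference is the descending-merit total order (seeded tie-breaks).
Commitments are *provisional* (reversible — the default for high-stakes
goals with an unconsulted specialist) or *firm*; firm adoption triggers
episodic learning and (context, decision) frequency counters that can
weight future aggregation.

Agents form networks over a FIFO **switchboard**, exchanging performative
messages (`inform`, `request`, `query`, `challenge`, `explain`, ...) so
that joint decisions can be argued out: advice that conflicts with the
receiver's preference is challenged, the explanation's arguments are
incorporated with communication justifications, and defeat + aggregation
re-run.

Two scenarios ship as executable fixtures:

- the **Wisconsin Card Sorting Test** (WCST), with two placement
  strategies and two lesion toggles that dissociate *perseverative*
  errors (monitoring disabled) from *set-loss* errors (retention
  failure);
- a three-agent **clinical consultation** on drug treatment for a
  suspected myocardial infarction (records agent, cardiology lead,
  drug-safety specialist).

## A worked example

```sh
$ dominodm run --kb src/dominodm/fixtures/mi.yaml --seed 42
cardio: endpoint clopidogrel (firm), 14 arguments constructed
safety: no commitment, 9 arguments constructed
rounds: 10, messages: 9
```

The cardiology lead first prefers aspirin (merit 4 = two efficacy pros +
availability + price, vs 3 for clopidogrel) but only provisionally,
because the stakes are high and a safety specialist is declared.  The
specialist learns from the records agent that the patient has gastritis,
which aspirin exacerbates (a con of strength 2), advises clopidogrel, and
— when challenged — explains its arguments.  Incorporating the con drops
aspirin to merit 2, so the lead commits **firm to clopidogrel**.

The card-sorting analogue, from Python:

```python
>>> from dominodm.scenarios.wcst import worked_example_decision
>>> d = worked_example_decision()
>>> len(d["candidates"]), len(d["arguments"])
(4, 3)
>>> {m.candidate: m.value for m in d["merits"]}
{'target1': 2.0, 'target2': 1.0, 'target3': 0.0, 'target4': 0.0}
```

One green diamond matches target 1 on shape and number and target 2 on
color: two reasons beat one, so the card goes under target 1.  A full
lesion battery:

```sh
$ dominodm wcst --trials 128 --lesion monitoring --seed 1
trials: 128, correct: 37, switches: 1
errors: perseverative 89, set-loss 0, other 2
```

`examples/` contains one short narrative script per capability
(ontology ladder, undercutting, WCST trial and lesions, the
consultation, task networks, trace replay).

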