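# Methods

This note records the model the package implements, the choices made
where the design was genuinely open, and what the shipped scenarios do
and do not establish.

## Knowledge representation

The ontology is deliberately minimal: a concept DAG with is-a links
(multiple inheritance allowed; traversal deduplicates), property
assertions, a declared relation vocabulary with subject-side
inheritance, rules, argument schemas, and scenario/task models.  It is
the smallest formalism that carries the package's scenarios; it is not a
description logic — satisfiability, classification and OWL/SNOMED import
are out of scope.

Situation knowledge is attribute/value atoms.  Descriptions combine
atoms under and/or/not and are evaluated with strong Kleene three-valued
semantics.  The default is open-world: an atom absent from the belief
set is *unknown*.  A per-rule closed-world flag enables
negation-as-failure, which goal conditions ("does not currently hold")
need.  Rule variables are written `?name`; matching is plain unification
against ground belief atoms, so no occurs-check is required.

Property conflicts resolve specific-over-general: a property declared on
a descendant shadows a same-named ancestor property, with declared
parent order breaking ties between equally specific ancestors.

## Working memory and reason maintenance

Every cognitive state is an item tagged with one or more justifications
(observation, inference, commitment, communication, assumption, axiom).
The active set is kept equal to the least fixpoint of derivation from
active observations and axioms: after any assertion or retraction the
well-founded set is recomputed from scratch (memories here are small —
hundreds of items — so the O(n²) recomputation is simpler and safer than
incremental bookkeeping).  Retraction therefore cascades exactly, and
re-asserting an item with identical support restores the pre-retraction
active set, because cascaded dependents are revived by the fixpoint.

Consistency policy (the model requires one; none is forced by the
theory): when an atom conflicts with an active negation,
observation-backed items outrank inference-backed ones, and between two
observations the more recent wins.  Confidence is ordinal
({confirmed, provisional, doubted}); quantitative belief strength is out
of scope.

## The decision cycle

Operation ordering within a cycle is a design choice: perceive → s1 (to
quiescence) → s9 → goal termination check → s2 → one decision goal
through s3–s6 (highest priority first, FIFO among equals) → s7/s8 →
s10 on termination.  s1 terminates on cyclic rule bases because an
already-active duplicate is never re-asserted; a configurable round
guard (default 100) converts genuinely productive runaway rule ladders
into a diagnostic error.

**Commitment rule.** The theory's condition — commit when further
information cannot change the preference, weighing the cost of
information against the cost of error — has no cost model here, so it is
operationalized as: commit *firm* when the top merit strictly exceeds
the runner-up and no declared information source is pending; for
high-stakes goals each declared consultation source must have been
consulted once before a firm commitment, and until then the commitment
is provisional and an information-seeking goal is raised.  This is a
stand-in, not a claim about the right cost model.

Impasses (no candidates, or a top-merit tie with tie-breaking disabled)
are logged and the goal suspended; no subgoaling machinery is attempted.

All randomness — tie-breaks, the initial sorting-rule pick — draws from
one seeded generator per agent, so a fixed (knowledge base, scenario,
seed) triple reproduces a bit-identical trace.  Replay re-executes the
run and verifies each stored record digest.

## Argumentation

Defeat uses the grounded (skeptical) labelling of the undercut graph,
computed by fixpoint iteration: IN iff all attackers OUT, OUT iff some
attacker IN; members of undercut cycles stay undefeated but are flagged
undecided.  Grounded semantics is chosen because the underlying
pattern this module exists to capture — one reason silencing another —
is exactly its base case; the preferred/stable semantics zoo is out of
scope.  Rebuttal (pro and con on one candidate) is *not* defeat: both
sides enter the Bentham arithmetic.

Schema strengths default to 1 and are configurable per schema.  The
consultation fixture sets the exacerbation con-schema's strength to 2 —
a safety consideration outweighing a price convenience — which is what
makes the lead's preference flip deterministic after the explanation is
incorporated; with uniform strengths the merits would tie.

Aggregators are pluggable (name → callable registry).  Shipped:
`bentham` and a frequency-weighted variant that adds a learned
(context, decision) counter bonus.  Probabilistic and expected-utility
aggregation are interface stubs only.

## The consultation scenario

The case knowledge base encodes only the assertions the scenario
narrative states: two (then three) drugs effective for analgesia and
clot prevention, availability and price properties, and the
aspirin-exacerbates-gastritis relation held by the safety specialist's
partition.  The lead's pipeline yields merits aspirin 4 / clopidogrel 3;
after the explained con (strength 2) the merits are 2 / 3.  The lead
challenges advice exactly when it conflicts with its own current
preference, and incorporating an explanation re-runs defeat and
aggregation only (a from-scratch recomputation over the merged argument
set provably gives the same result, which a test asserts) rather than
re-running the whole pipeline.  Whether the incorporated commitment
should instead re-open candidate generation is undetermined by the
scenario; re-aggregation is the narrower reading.

The records agent is a pure responder with no decision pipeline.  Agent
turn order within a round is registration order; serializing the
conceptually concurrent agents does not change quiescence outcomes, and
makes runs deterministic.

## The card-sorting scenario

The standard deck is the 64-card product of numbers 1–4, shapes
{triangle, star, cross, circle} and colors {red, green, yellow, blue};
sessions draw shuffled concatenated packs.  Targets are the standard
1-red-triangle / 2-green-stars / 3-yellow-crosses / 4-blue-circles, so
each feature value maps to a unique target.  The worked single-trial
example uses a one-green-diamond card (diamond admitted only there)
against targets built to share shape+number (target 1) and color
(target 2) with it, reproducing the 2-vs-1 merit count.  The criterion
switches color → form → number cyclically after `switch_after`
(default 6) consecutive correct placements; the figure is configurable
since only "a series of correct choices" is specified.

The rule strategy maintains a viable-rule set with argument strengths.
Positive feedback strengthens (+1) viable rules matching the chosen
target and eliminates the rest.  *Monitoring* processes the failure of
the expected positive outcome: on negative feedback the viable rules
matching the chosen target (always including the applied rule) are
eliminated.  Gating all negative-feedback processing on the monitoring
toggle is the modelled lesion: with monitoring off the agent still
converges on the first criterion through positive feedback alone, then
perseveres indefinitely after the switch.  Retention failure deletes the
maintained rule state (viable set and strengths) with the configured
per-trial probability before the trial.  The location strategy carries
no state across trials.

**Error scoring.** Perseverative: an error whose placement matches the
immediately previous criterion, after at least one switch.  Set-loss: an
error after ≥ 3 consecutive correct with no intervening switch *and* no
single sorting rule consistent with the entire run plus the error — if
one rule explains every placement including the error, the subject
maintained a coherent (merely wrong) set, typically a wrong rule
sustained by ambiguous cards, and the error is scored "other".  Without
the consistency condition such exploration episodes are misscored as
set loss, which would blur the lesion dissociation the categories exist
to measure.  The run-length threshold of 3 follows common scoring
practice and is a choice, not a theoretical commitment.  Categories are
disjoint with perseverative precedence.

"Reaches criterion after a switch" is checked for switches with at
least 15 subsequent trials (a trailing block can be cut off by the end
of the deck).

## Scenario batteries and what they show

The lesion battery uses 20 seeds × 128 trials with `switch_after` 6 and
retention-failure probability 0.05 — sizes chosen so each mechanism's
signature is unambiguous while a full battery runs in well under a
minute.  Across seeds: monitoring-off strictly increases perseverative
errors with set-loss unchanged; retention failure produces set-loss
errors with monitoring intact; the intact agent re-reaches criterion
after every switch.

The synthetic fixtures (random concept DAGs built parents-backward so
acyclicity is structural, random ground/variable rule bases, shuffled
decks) exercise the inference machinery, not realistic knowledge: they
contain no property correlations, no deep hierarchies, and rule bases
far smaller than a clinical KB.  Passing the property suites shows the
operations meet their contracts (against independent oracles:
enumeration, naive fixpoints, topological labellings, from-scratch
recomputation), not that the knowledge engineering of any real domain
would be easy or that human WCST statistics are fit — fitting patient
group data is explicitly out of scope.

## Known limitations

- No assumption-based truth maintenance or revision over quantified
  formulas; consistency is atom-level.
- Plan repair is postpone/discard with a retry count; no re-planning.
- Learning is episodic recording plus frequency counting; no
  generalization over episodes is attempted.
- The dialog protocol covers the inform/challenge/explain triangle plus
  protocol-opening acts; negotiation and persuasion protocols are not
  modelled.
- KB validation reports element-path anchors (e.g.
  `agents.safety.partition.rules[0]`), not file line numbers.
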