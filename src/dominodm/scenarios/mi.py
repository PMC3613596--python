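"""Clinical scenario fixtures: the myocardial-infarction consultation
case and the chronic-pain goal-raising example.

The MI case is shipped as a KB file and reproduces the full four-phase
joint decision: (1) the cardiology lead infers a possible MI from the
announced chest pain, raises management sub-goals, retrieves two drugs,
prefers aspirin on price and commits provisionally; (2) the drug-safety
specialist, asked to confirm, generates three options, learns from the
records agent that the patient has gastritis — which aspirin exacerbates
— and advises clopidogrel; (3) the lead challenges, the specialist
explains its arguments, the lead incorporates the con-argument against
aspirin and its preference flips, so it commits firm to clopidogrel;
(4) an episodic record is stored and the (context, decision) frequency
counter increments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Tuple

from ..descriptions import Atom
from ..ontology import GoalTemplate, Ontology, Rule
from ..agents import NetworkTrace, Switchboard, build_network, run_network
from ..kb import load_kb


def mi_fixture_path() -> Path:
    """Filesystem path of the shipped MI knowledge-base file."""
    return Path(resources.files("dominodm") / "fixtures" / "mi.yaml")


@dataclass
class MiCaseFile:
    """The Phase 1-2 assertions of the consultation case."""

    patient_facts: List[Atom]
    drugs: List[str]
    relations: List[Tuple[str, str, str]]
    schemas: List[str]


@dataclass
class MiFixture:
    ontology: Ontology
    case: MiCaseFile
    network: Dict[str, dict]


def build_mi_fixture() -> MiFixture:
    """Load the shipped case KB and derive the case-file summary."""
    onto = load_kb(mi_fixture_path())
    records = onto.agents["records"]
    safety_part = onto.agents["safety"]["partition"]
    merged = onto.merged_with(safety_part)
    case = MiCaseFile(
        patient_facts=[Atom(a, v) for a, v in records["case"]],
        drugs=[c for c in merged.concepts
               if "drug" in merged.concepts[c].parents],
        relations=[(r.subject, r.relation, r.object) for r in merged.relations],
        schemas=[s.id for s in merged.schemas])
    return MiFixture(ontology=onto, case=case, network=onto.agents)


@dataclass
class MiOutcome:
    """Decision endpoints extracted from a full network run."""

    trace: NetworkTrace
    phase1_candidate: Optional[str] = None
    phase1_firmness: Optional[str] = None
    pre_explanation_preference: Optional[str] = None
    final_candidate: Optional[str] = None
    final_firmness: Optional[str] = None
    lead_candidates: List[str] = field(default_factory=list)
    specialist_candidates: List[str] = field(default_factory=list)
    specialist_preference: Optional[str] = None
    episodes: int = 0
    counters: Dict[tuple, int] = field(default_factory=dict)


def run_mi_scenario(seed: int = 0, max_rounds: int = 30) -> MiOutcome:
    """Run the three-agent network to quiescence and summarize the
    decision endpoints."""
    fixture = build_mi_fixture()
    sb = build_network(fixture.ontology, seed=seed)
    trace = run_network(sb, max_rounds=max_rounds)
    outcome = MiOutcome(trace=trace)

    lead = sb.agents["cardio"]
    specialist = sb.agents["safety"]

    commits = [r for r in lead.kernel.trace
               if r["op"] == "s6" and "candidate" in r["detail"]]
    if commits:
        outcome.phase1_candidate = commits[0]["detail"]["candidate"]
        outcome.phase1_firmness = commits[0]["detail"]["firmness"]
        outcome.pre_explanation_preference = commits[0]["detail"]["candidate"]
        outcome.final_candidate = commits[-1]["detail"]["candidate"]
        outcome.final_firmness = commits[-1]["detail"]["firmness"]

    for r in lead.kernel.trace:
        if r["op"] == "s3" and r["detail"].get("candidates"):
            outcome.lead_candidates = r["detail"]["candidates"]
            break
    for r in specialist.kernel.trace:
        if r["op"] == "s3" and r["detail"].get("candidates"):
            outcome.specialist_candidates = r["detail"]["candidates"]
            break
    informs = [m for m in trace.messages
               if m["sender"] == "safety" and m["performative"] == "inform"]
    for ds in specialist.kernel.decisions.values():
        if ds.order:
            outcome.specialist_preference = ds.order[0]
    outcome.episodes = len(lead.kernel.episodes)
    outcome.counters = dict(lead.kernel.counters)
    return outcome


# ---------------------------------------------------------------------------
# The chronic-pain goal-raising example
# ---------------------------------------------------------------------------

def build_chronic_pain_fixture() -> Ontology:
    """A minimal KB whose single goal rule raises two goals from the
    presentation of severe chronic pain: decide the most plausible cause,
    and decide the most preferred treatment."""
    from ..descriptions import And
    onto = Ontology()
    onto.rules.append(Rule(
        id="g_chronic_pain", kind="goal",
        antecedent=Atom("complaint", "severe_chronic_pain"),
        consequents=(
            GoalTemplate(name="decide_most_plausible_cause",
                         condition=Atom("cause", "decided"),
                         kind="decide", priority=1),
            GoalTemplate(name="decide_most_preferred_treatment",
                         condition=Atom("treatment", "decided"),
                         kind="decide", priority=1),
        )))
    return onto
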