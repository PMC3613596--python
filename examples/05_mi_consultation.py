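"""The three-agent treatment consultation, end to end.

A records agent announces an elderly patient with chest pain.  The
cardiology lead infers a possible myocardial infarction, weighs two
drugs, provisionally prefers aspirin (cheapest of the effective,
available options) and consults a drug-safety specialist.  The
specialist discovers the patient's gastritis — which aspirin exacerbates
— and advises clopidogrel; challenged, it explains its arguments, and
the lead's preference flips, ending in a firm commitment.
"""

from dominodm.scenarios.mi import run_mi_scenario

outcome = run_mi_scenario(seed=1)

print("dialog:")
for m in outcome.trace.messages:
    print(f"  round {m['round']}: {m['sender']} -> {m['receiver']}: "
          f"{m['performative']}")

print("lead's candidate drugs:", outcome.lead_candidates)
print("phase 1 commitment:", outcome.phase1_candidate,
      f"({outcome.phase1_firmness})")
print("specialist's options:", outcome.specialist_candidates)
print("specialist's preference:", outcome.specialist_preference)
print("final commitment:", outcome.final_candidate,
      f"({outcome.final_firmness})")
print("episodic records learned:", outcome.episodes)
print("decision frequency counters:", outcome.counters)

# The provisional/firm distinction carries the safety logic: a
# high-stakes decision stays reversible until the declared specialist
# has been consulted and any conflict argued out.
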