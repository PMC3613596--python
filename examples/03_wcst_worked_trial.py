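"""One card-sorting trial, argued out loud.

The to-be-sorted card is one green diamond.  The location strategy
treats the four target positions as options; feature matches supply the
lines of reasoning: shape and number both point at target 1, color
points at target 2.
"""

from dominodm.scenarios.wcst import (
    WORKED_CARD,
    WORKED_TARGETS,
    worked_example_decision,
)

print("card:", WORKED_CARD)
for i, t in enumerate(WORKED_TARGETS, start=1):
    print(f"  target {i}: {t}")

decision = worked_example_decision()
print("placement options:", decision["candidates"])
print("lines of reasoning:")
for a in decision["arguments"]:
    print(f"  {a.schema_id} -> {a.target}")
print("merits:", {m.candidate: m.value for m in decision["merits"]})
print("preference:", decision["order"])

# Two reasons for target 1 versus one for target 2 gives Bentham merits
# 2 vs 1, so the subject places the card under target 1.
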