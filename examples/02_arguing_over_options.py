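"""Reasons, undercuts and the Bentham rule.

A reason R1 favors option A and a reason R2 favors option B; a third
reason R3 undermines R1's veracity.  Under grounded defeat semantics R1
is defeated, so summing the surviving pros and cons prefers B.
"""

from dominodm import Argument, aggregate, prefer, resolve_defeat

r1 = Argument(id=1, target="A", target_kind="candidate", polarity="pro",
              schema_id="R1", candidate="A")
r2 = Argument(id=2, target="B", target_kind="candidate", polarity="pro",
              schema_id="R2", candidate="B")
r3 = Argument(id=3, target=1, target_kind="argument", polarity="undercut",
              schema_id="R3")

args = resolve_defeat([r1, r2, r3])
for a in args:
    print(f"{a.schema_id}: {'defeated' if a.defeated else 'stands'}")

merits = aggregate(["A", "B"], args)
print("merits:", {m.candidate: m.value for m in merits})
print("preference:", prefer(["A", "B"], merits, "lexicographic"))

# R3 silences R1 without touching B's case, so the Bentham difference is
# A: 0, B: 1 — all other things being equal, B is preferred to A.
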