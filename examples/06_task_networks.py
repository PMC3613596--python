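"""Plan enactment over a clinical task network.

The SOAP pattern (Subjective, Objective, Assessment, Plan): two
enquiries may run in either order, but the assessment decision is gated
until both have completed, and the treatment action until the decision.
"""

from dominodm import enabled_tasks, plan_from_template

soap = {"tasks": {
    "subjective": {"kind": "enquiry"},
    "objective": {"kind": "enquiry"},
    "assess": {"kind": "decision", "after": ["subjective", "objective"]},
    "treat": {"kind": "action", "after": ["assess"]},
}}

plan = plan_from_template("soap", soap)

def show(step):
    enabled = [t.id for t in enabled_tasks(plan, set())]
    print(f"{step}: enabled tasks = {enabled}")

show("at the start")
plan.tasks["subjective"].status = "done"
show("subjective history taken")
plan.tasks["objective"].status = "done"
show("objective findings recorded")
plan.tasks["assess"].status = "done"
show("assessment decided")

# Arrows are completion dependencies: a task becomes enabled exactly
# when every predecessor is done and its preconditions hold.
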