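"""Dissociating the classic card-sorting error categories.

Runs three 128-trial sessions from one seed: an intact agent, one with
monitoring disabled (negative feedback never processed), and one with a
5% per-trial chance of losing the maintained rule.  The intact agent
recovers after every criterion switch; the monitoring lesion produces
perseveration; retention failure produces set-loss errors.
"""

from dominodm.scenarios.wcst import (
    LesionConfig,
    classify_errors,
    run_wcst,
    switch_recoveries,
)

SEED, TRIALS = 27, 128

for label, config in [
    ("intact", LesionConfig()),
    ("monitoring off", LesionConfig(monitoring=False)),
    ("retention failure 0.05", LesionConfig(retention_failure=0.05)),
]:
    state = run_wcst(config, n_trials=TRIALS, seed=SEED)
    errors = classify_errors(state)
    correct = sum(1 for t in state.trial_log if t.positive)
    recovered = switch_recoveries(state)
    print(f"{label}: {correct}/{TRIALS} correct, "
          f"{state.n_switches} criterion switches, errors {errors}, "
          f"recovered after {sum(recovered)}/{len(recovered)} switches")

# Perseverative errors follow the previously correct criterion after a
# switch; set-loss errors break a run of correct sorts with no rule that
# could explain the whole run.  Each lesion moves exactly one count.
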