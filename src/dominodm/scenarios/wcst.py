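"""The Wisconsin Card Sorting Test as a dynamic decision environment.

Cards show one to four shapes (triangles, stars, crosses or circles)
printed in red, green, yellow or blue; the subject places each card under
one of four targets and receives positive feedback iff the card matches
the chosen target on the experimenter's hidden criterion (color, form or
number).  After ``switch_after`` consecutive correct placements the
criterion switches without warning.

Two placement strategies are modelled:

- the *location* strategy treats the four target locations as decision
  options and argues from feature matches (one pro argument per matching
  feature); no knowledge is carried across trials;
- the *rule* strategy treats the sorting rules themselves as decision
  options, maintains a set of still-viable rules with argument strengths,
  anticipates positive feedback once a single rule remains, and learns
  from feedback: on positive feedback arguments for matching rules gain
  strength (+1) and non-matching rules are eliminated; a violated
  positive-feedback expectation (monitoring) eliminates the applied rule.

Two lesion toggles dissociate the classic error categories: disabling
monitoring leaves expectation violations unprocessed, producing
perseveration (sorting by a previously correct rule under sustained
negative feedback); a per-trial retention-failure probability deletes the
maintained rule belief, producing set-loss errors after runs of correct
sorts.

The worked single-trial example uses a one-green-diamond card (diamond is
admitted solely for this fixture) against targets chosen so that target 1
shares shape and number with the card and target 2 shares color.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

from ..argumentation import Argument, Merit, aggregate, prefer, resolve_defeat

SHAPES = ("triangle", "star", "cross", "circle")
EXTENDED_SHAPES = SHAPES + ("diamond",)   # worked example only
COLORS = ("red", "green", "yellow", "blue")
NUMBERS = (1, 2, 3, 4)
CRITERIA = ("color", "form", "number")


@dataclass(frozen=True)
class WcstCard:
    number: int
    shape: str
    color: str

    def __post_init__(self):
        if self.number not in NUMBERS:
            raise ValueError(f"number must be 1-4, got {self.number}")
        if self.shape not in EXTENDED_SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.color not in COLORS:
            raise ValueError(f"unknown color {self.color!r}")

    def feature(self, criterion: str):
        if criterion == "color":
            return self.color
        if criterion == "form":
            return self.shape
        if criterion == "number":
            return self.number
        raise ValueError(f"unknown criterion {criterion!r}")


def wcst_fixture_path():
    """Filesystem path of the shipped scenario configuration."""
    from importlib import resources
    from pathlib import Path
    return Path(resources.files("dominodm") / "fixtures" / "wcst.yaml")


def load_wcst_config() -> dict:
    """Parse the shipped configuration into cards and parameters."""
    import yaml
    doc = yaml.safe_load(wcst_fixture_path().read_text())
    return {
        "criteria": tuple(doc["criteria"]),
        "switch_after": int(doc["switch_after"]),
        "targets": tuple(WcstCard(n, s, c) for n, s, c in doc["targets"]),
        "worked_card": WcstCard(*doc["worked_example"]["card"]),
        "worked_targets": tuple(
            WcstCard(n, s, c) for n, s, c in doc["worked_example"]["targets"]),
    }


_CONFIG = load_wcst_config()
STANDARD_TARGETS: Tuple[WcstCard, ...] = _CONFIG["targets"]

# Worked-example fixture: one green diamond; target 1 shares shape and
# number, target 2 shares color, targets 3-4 share nothing.
WORKED_CARD = _CONFIG["worked_card"]
WORKED_TARGETS: Tuple[WcstCard, ...] = _CONFIG["worked_targets"]
DEFAULT_SWITCH_AFTER: int = _CONFIG["switch_after"]


def standard_deck() -> List[WcstCard]:
    """The 64 distinct cards (4 numbers x 4 shapes x 4 colors)."""
    return [WcstCard(n, s, c)
            for n, s, c in itertools.product(NUMBERS, SHAPES, COLORS)]


def shuffled_deck(n_trials: int, rng: random.Random) -> List[WcstCard]:
    """Concatenated shuffled 64-card packs, cut to ``n_trials``."""
    deck: List[WcstCard] = []
    while len(deck) < n_trials:
        pack = standard_deck()
        rng.shuffle(pack)
        deck.extend(pack)
    return deck[:n_trials]


@dataclass
class LesionConfig:
    monitoring: bool = True
    retention_failure: float = 0.0     # per-trial probability of rule loss
    strategy: str = "rule"             # rule | location
    aspiration: str = "general"        # general | specific

    def __post_init__(self):
        if not 0.0 <= self.retention_failure <= 1.0:
            raise ValueError("retention_failure must be in [0, 1]")
        if self.strategy not in {"rule", "location"}:
            raise ValueError(f"unknown strategy {self.strategy!r}")


@dataclass
class WcstState:
    targets: Tuple[WcstCard, ...] = STANDARD_TARGETS
    deck: List[WcstCard] = field(default_factory=list)
    criterion: str = "color"
    consecutive_correct: int = 0
    switch_after: int = 6
    n_switches: int = 0
    prev_criterion: Optional[str] = None
    trial_log: List["TrialRecord"] = field(default_factory=list)


@dataclass
class TrialRecord:
    index: int
    card: WcstCard
    criterion: str
    placement: int
    positive: bool
    rule_used: Optional[str] = None
    prev_criterion: Optional[str] = None
    n_switches_before: int = 0
    consecutive_before: int = 0
    forgot: bool = False
    switched_after: bool = False


def _next_criterion(criterion: str) -> str:
    return CRITERIA[(CRITERIA.index(criterion) + 1) % len(CRITERIA)]


def wcst_feedback(placement: int, card: WcstCard, state: WcstState) -> bool:
    """Experimenter feedback: positive iff the card matches the chosen
    target on the current criterion.  Applies counter and criterion-switch
    bookkeeping (the criterion switches, without warning, exactly when the
    consecutive-correct counter reaches ``switch_after``)."""
    if not 1 <= placement <= len(state.targets):
        raise ValueError(f"placement must be 1-{len(state.targets)}, "
                         f"got {placement}")
    target = state.targets[placement - 1]
    positive = card.feature(state.criterion) == target.feature(state.criterion)
    if positive:
        state.consecutive_correct += 1
        if state.consecutive_correct >= state.switch_after:
            state.prev_criterion = state.criterion
            state.criterion = _next_criterion(state.criterion)
            state.n_switches += 1
            state.consecutive_correct = 0
    else:
        state.consecutive_correct = 0
    return positive


# ---------------------------------------------------------------------------
# Per-trial decision-making
# ---------------------------------------------------------------------------

def placement_candidates(targets: Sequence[WcstCard]) -> List[str]:
    """The location strategy's options: the four target positions."""
    return [f"target{i}" for i in range(1, len(targets) + 1)]


def rule_strategy_candidates() -> List[str]:
    """The sophisticated strategy's options: the sorting rules
    themselves."""
    return list(CRITERIA)


def location_arguments(card: WcstCard,
                       targets: Sequence[WcstCard]) -> List[Argument]:
    """One pro argument per feature the card shares with a target (the
    three possible lines of reasoning: shape, number, color)."""
    args: List[Argument] = []
    next_id = 1
    for criterion in ("form", "number", "color"):
        for i, target in enumerate(targets, start=1):
            if card.feature(criterion) == target.feature(criterion):
                payload = f"target{i}"
                args.append(Argument(
                    id=next_id, target=payload, target_kind="candidate",
                    polarity="pro", schema_id=f"match_{criterion}",
                    strength=1.0, candidate=payload))
                next_id += 1
    return args


def location_decision(card: WcstCard, targets: Sequence[WcstCard],
                      rng: random.Random) -> dict:
    """Run the location strategy's s3-s5 pipeline for one card."""
    candidates = placement_candidates(targets)
    arguments = resolve_defeat(location_arguments(card, targets))
    merits = aggregate(candidates, arguments)
    order = prefer(candidates, merits, "random", rng)
    return {"candidates": candidates, "arguments": arguments,
            "merits": merits, "order": order}


def worked_example_decision(rng: Optional[random.Random] = None) -> dict:
    """The single worked trial: one green diamond against the worked
    targets, yielding four placement options, three arguments and merits
    2 (target 1) vs 1 (target 2)."""
    return location_decision(WORKED_CARD, WORKED_TARGETS,
                             rng or random.Random(0))


def _rule_decision(viable: Set[str], strengths: Dict[str, float],
                   rng: random.Random) -> Tuple[str, dict]:
    candidates = sorted(viable)
    args = [Argument(id=i + 1, target=c, target_kind="candidate",
                     polarity="pro", schema_id="rule_support",
                     strength=strengths[c], candidate=c)
            for i, c in enumerate(candidates)]
    resolve_defeat(args)
    merits = aggregate(candidates, args)
    order = prefer(candidates, merits, "random", rng)
    return order[0], {"merits": merits, "order": order}


def _placement_for_rule(card: WcstCard, rule: str,
                        targets: Sequence[WcstCard]) -> int:
    for i, target in enumerate(targets, start=1):
        if card.feature(rule) == target.feature(rule):
            return i
    raise ValueError(f"no target matches card {card} on {rule}")


def run_wcst(lesion: LesionConfig, deck: Optional[Sequence[WcstCard]] = None,
             switch_after: int = 6, n_trials: int = 64,
             seed: int = 0, initial_criterion: str = "color") -> WcstState:
    """Run a full WCST session and return the state with its trial log.

    Per trial: (seeded) retention failure may delete the maintained rule
    belief; candidate generation per strategy; argument construction,
    aggregation and commitment; placement; feedback; expectation
    monitoring; feedback-driven argument-strength update.
    """
    rng = random.Random(seed)
    state = WcstState(criterion=initial_criterion, switch_after=switch_after)
    state.deck = list(deck) if deck is not None else shuffled_deck(n_trials, rng)
    state.deck = state.deck[:n_trials]

    viable: Set[str] = set(CRITERIA)
    strengths: Dict[str, float] = {c: 1.0 for c in CRITERIA}

    for index, card in enumerate(state.deck):
        forgot = False
        if lesion.strategy == "rule" and lesion.retention_failure > 0:
            if rng.random() < lesion.retention_failure:
                viable = set(CRITERIA)
                strengths = {c: 1.0 for c in CRITERIA}
                forgot = True

        prev_criterion = state.prev_criterion
        n_switches_before = state.n_switches
        consecutive_before = state.consecutive_correct
        criterion = state.criterion

        if lesion.strategy == "location":
            decision = location_decision(card, state.targets, rng)
            placement = int(decision["order"][0][len("target"):])
            rule_used = None
            expect_positive = False
        else:
            rule_used, _ = _rule_decision(viable, strengths, rng)
            placement = _placement_for_rule(card, rule_used, state.targets)
            expect_positive = viable == {rule_used}

        positive = wcst_feedback(placement, card, state)

        if lesion.strategy == "rule":
            chosen_target = state.targets[placement - 1]
            if positive:
                # assimilate positive feedback: matching rules strengthen,
                # non-matching rules are eliminated
                for r in sorted(viable):
                    if card.feature(r) == chosen_target.feature(r):
                        strengths[r] += 1.0
                    else:
                        viable.discard(r)
            elif lesion.monitoring:
                # the expected positive outcome did not arrive: the
                # criterion cannot be a rule that matched the chosen
                # target (in particular the applied rule is wrong)
                for r in sorted(viable):
                    if card.feature(r) == chosen_target.feature(r):
                        viable.discard(r)
                        strengths[r] = 1.0
            if not viable:
                viable = set(CRITERIA) - {rule_used}
                strengths = {c: 1.0 for c in CRITERIA}

        state.trial_log.append(TrialRecord(
            index=index, card=card, criterion=criterion, placement=placement,
            positive=positive, rule_used=rule_used,
            prev_criterion=prev_criterion,
            n_switches_before=n_switches_before,
            consecutive_before=consecutive_before, forgot=forgot,
            switched_after=state.n_switches > n_switches_before))
    return state


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def _consistent_rule_exists(state: WcstState, trials: Sequence[TrialRecord]) -> bool:
    """True if one sorting rule explains every placement in ``trials``."""
    for rule in CRITERIA:
        ok = True
        for t in trials:
            target = state.targets[t.placement - 1]
            if t.card.feature(rule) != target.feature(rule):
                ok = False
                break
        if ok:
            return True
    return False


def classify_errors(state: WcstState) -> Dict[str, int]:
    """Error categories over a completed trial log.

    - *perseverative*: an error whose placement matches the immediately
      previous criterion, occurring after a switch;
    - *set-loss*: an error following at least three consecutive correct
      trials with no intervening switch, where the behavior suggests the
      maintained rule was spontaneously lost — no single sorting rule
      explains the run of correct placements together with the error
      placement.  (If one rule explains them all, the subject maintained
      a consistent — merely wrong — set, so the error is not a loss of
      set.)
    - *other*: everything else.  Categories are disjoint; perseverative
      takes precedence.
    """
    counts = {"perseverative": 0, "set_loss": 0, "other": 0}
    for t in state.trial_log:
        if t.positive:
            continue
        target = state.targets[t.placement - 1]
        persev = (t.n_switches_before > 0 and t.prev_criterion is not None
                  and t.card.feature(t.prev_criterion)
                  == target.feature(t.prev_criterion))
        if persev:
            counts["perseverative"] += 1
        elif t.consecutive_before >= 3:
            run_start = t.index - t.consecutive_before
            window = state.trial_log[run_start:t.index + 1]
            if _consistent_rule_exists(state, window):
                counts["other"] += 1
            else:
                counts["set_loss"] += 1
        else:
            counts["other"] += 1
    return counts


def switch_recoveries(state: WcstState, margin: int = 15) -> List[bool]:
    """For each criterion switch with at least ``margin`` subsequent
    trials, whether the agent reached criterion (``switch_after``
    consecutive correct, i.e. another switch) afterwards."""
    switch_trials = [t.index for t in state.trial_log if t.switched_after]
    n_trials = len(state.trial_log)
    out = []
    for k, s in enumerate(switch_trials):
        if n_trials - (s + 1) < margin:
            continue
        out.append(any(s2 > s for s2 in switch_trials[k + 1:])
                   or _reaches_run(state, s))
    return out


def _reaches_run(state: WcstState, after: int) -> bool:
    run = 0
    for t in state.trial_log[after + 1:]:
        run = run + 1 if t.positive else 0
        if run >= state.switch_after:
            return True
    return False
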