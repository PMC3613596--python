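"""Justification-tagged working memory with reason maintenance.

Every cognitive state (belief, goal, candidate, argument, commitment,
expectation, ...) is held as a :class:`WorkingMemoryItem` tagged with the
grounds for holding it.  The active set is kept *well-founded*: an active
non-observation, non-axiom item must have at least one justification all
of whose supports are themselves active, and chains bottom out at
observations or axioms.  Retraction therefore cascades automatically —
after any mutation the well-founded set is recomputed from scratch, so the
active set always equals the least fixpoint of derivation from active
observations and axioms.

Consistency policy for conflicting ground atoms (an atom and its
negation): observation-supported items outrank inference-supported ones,
and between two observations the more recent wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Set, Tuple

from .descriptions import (
    Atom,
    Description,
    holds,
    match_atom,
    match_bindings,
    variables,
    TRUE,
)

SELF_FOUNDED_KINDS = {"observation", "axiom", "assumption"}


@dataclass(frozen=True)
class Justification:
    kind: str                          # observation | inference | commitment |
                                       # communication | assumption | axiom
    supports: frozenset = frozenset()  # ids of supporting items
    rule_id: Optional[str] = None
    schema_id: Optional[str] = None
    goal_id: Optional[int] = None

    def __post_init__(self):
        if self.kind in {"inference", "communication"} and not self.supports:
            if self.kind == "inference":
                raise ValueError("inference justification needs non-empty supports")


@dataclass(frozen=True)
class Observation:
    description: Atom
    source: str = "environment"        # environment | message
    cycle: int = 0


@dataclass(frozen=True)
class Belief:
    description: Description
    confidence: Optional[str] = None   # confirmed | provisional | doubted


@dataclass
class Goal:
    name: str
    condition: Description
    parent: Optional[int] = None       # parent goal item id
    priority: int = 0
    stakes: str = "routine"
    status: str = "raised"             # raised | active | achieved | dropped
    targets: Tuple[str, ...] = ()
    kind: str = "achieve"              # achieve | decide


@dataclass(frozen=True)
class Expectation:
    predicted: Atom
    origin: int                        # commitment or action item id
    window: Tuple[int, int] = (0, 1 << 30)


class UnknownItemError(KeyError):
    pass


@dataclass
class WorkingMemoryItem:
    id: int
    content: object
    justifications: List[Justification]
    status: str = "active"             # active | retracted
    asserted_at: int = 0
    retracted_at: Optional[int] = None
    explicitly_retracted: bool = False


def _content_key(content) -> tuple:
    """Exact-duplicate key used to merge re-assertions."""
    if isinstance(content, Goal):
        return ("goal", content.name)
    if isinstance(content, Belief):
        return ("belief", content.description)
    if isinstance(content, Observation):
        return ("observation", content.description, content.source)
    if isinstance(content, Expectation):
        return ("expectation", content.predicted, content.origin)
    return ("other", id(content))


def _atom_of(content) -> Optional[Atom]:
    if isinstance(content, Observation):
        return content.description
    if isinstance(content, Belief) and isinstance(content.description, Atom):
        return content.description
    return None


class WorkingMemory:
    """Per-agent store of current cognitive states."""

    def __init__(self):
        self.items: Dict[int, WorkingMemoryItem] = {}
        self._next_id = 1
        self.clock = 0

    # -- core mutation ----------------------------------------------------

    def assert_item(self, content, justification: Justification) -> int:
        """Add (or revive) an item; exact duplicates merge justifications.

        Conflicting ground atoms are resolved by the consistency policy and
        the well-founded active set is then recomputed.
        """
        for sid in justification.supports:
            if sid not in self.items:
                raise UnknownItemError(f"dangling support id {sid}")
        key = _content_key(content)
        target = None
        for item in self.items.values():
            if _content_key(item.content) == key:
                target = item
                break
        if target is not None:
            if justification not in target.justifications:
                target.justifications.append(justification)
            target.explicitly_retracted = False
            if target.status != "active":
                target.status = "active"
                target.asserted_at = self.clock
                target.retracted_at = None
        else:
            target = WorkingMemoryItem(
                id=self._next_id, content=content,
                justifications=[justification], asserted_at=self.clock)
            self._next_id += 1
            self.items[target.id] = target
        self._resolve_conflicts(target)
        self._recompute_foundation()
        return target.id

    def retract(self, item_id: int, cascade: bool = True) -> Set[int]:
        """Explicitly retract an item; returns all ids retracted (including
        dependents that lost their last support when cascading)."""
        if item_id not in self.items:
            raise UnknownItemError(f"unknown item id {item_id}")
        before = {i for i, it in self.items.items() if it.status == "active"}
        item = self.items[item_id]
        item.explicitly_retracted = True
        item.status = "retracted"
        item.retracted_at = self.clock
        if cascade:
            self._recompute_foundation()
        after = {i for i, it in self.items.items() if it.status == "active"}
        return before - after

    def _resolve_conflicts(self, new_item: WorkingMemoryItem) -> None:
        atom = _atom_of(new_item.content)
        if atom is None:
            return
        neg = atom.negate()
        for other in list(self.items.values()):
            if other.id == new_item.id or other.status != "active":
                continue
            if _atom_of(other.content) == neg:
                loser = self._conflict_loser(new_item, other)
                loser.explicitly_retracted = True
                loser.status = "retracted"
                loser.retracted_at = self.clock

    def _conflict_loser(self, a: WorkingMemoryItem, b: WorkingMemoryItem):
        def obs_backed(it):
            return any(j.kind == "observation" for j in it.justifications) or \
                isinstance(it.content, Observation)
        a_obs, b_obs = obs_backed(a), obs_backed(b)
        if a_obs and not b_obs:
            return b
        if b_obs and not a_obs:
            return a
        # same class: most recent assertion wins
        return b if a.asserted_at >= b.asserted_at else a

    def _recompute_foundation(self) -> None:
        """Active set := least fixpoint of support from observations/axioms."""
        founded: Set[int] = set()
        changed = True
        while changed:
            changed = False
            for item in self.items.values():
                if item.id in founded or item.explicitly_retracted:
                    continue
                ok = False
                if isinstance(item.content, Observation):
                    ok = True
                for j in item.justifications:
                    if j.kind in SELF_FOUNDED_KINDS:
                        ok = True
                    elif not j.supports and j.kind not in {"inference",
                                                           "communication"}:
                        # e.g. a commitment justification with no recorded
                        # supports stands on its own
                        ok = True
                    elif j.supports and j.supports <= founded:
                        ok = True
                if ok:
                    founded.add(item.id)
                    changed = True
        for item in self.items.values():
            if item.explicitly_retracted:
                continue
            if item.id in founded:
                if item.status != "active":
                    item.status = "active"
                    item.retracted_at = None
            else:
                if item.status == "active":
                    item.status = "retracted"
                    item.retracted_at = self.clock

    # -- queries ----------------------------------------------------------

    def active_items(self, content_type=None) -> List[WorkingMemoryItem]:
        out = [it for it in self.items.values() if it.status == "active"]
        if content_type is not None:
            out = [it for it in out if isinstance(it.content, content_type)]
        return sorted(out, key=lambda it: it.id)

    def belief_atoms(self) -> Set[Atom]:
        """Ground atoms currently held true (observations plus atomic
        beliefs)."""
        atoms: Set[Atom] = set()
        for it in self.active_items():
            a = _atom_of(it.content)
            if a is not None:
                atoms.add(a)
        return atoms

    def atom_item(self, atom: Atom) -> Optional[int]:
        """Id of an active item asserting the given ground atom."""
        for it in self.active_items():
            if _atom_of(it.content) == atom:
                return it.id
        return None

    def query(self, pattern: Atom, content_type=None):
        """All active items whose atomic content unifies with ``pattern``;
        yields (item, binding) pairs."""
        out = []
        for it in self.active_items(content_type):
            a = _atom_of(it.content)
            if a is None:
                continue
            env = match_atom(pattern, a)
            if env is not None:
                out.append((it, env))
        return out

    def active_goals(self) -> List[WorkingMemoryItem]:
        return [it for it in self.active_items(Goal)
                if it.content.status in {"raised", "active"}]

    def check_goal_termination(self, closed_world: bool = False) -> Set[int]:
        """Mark every active goal whose condition now holds true as
        achieved; achieved goals are terminal."""
        achieved: Set[int] = set()
        beliefs = self.belief_atoms()
        for it in self.active_goals():
            if holds(it.content.condition, beliefs, closed_world) == TRUE:
                it.content.status = "achieved"
                achieved.add(it.id)
        return achieved

    def snapshot(self) -> List[dict]:
        """Serializable view of every item, for the trace stream."""
        out = []
        for it in sorted(self.items.values(), key=lambda x: x.id):
            out.append({
                "id": it.id,
                "content": repr(it.content),
                "status": it.status,
                "asserted_at": it.asserted_at,
                "retracted_at": it.retracted_at,
                "justifications": [
                    {"kind": j.kind, "supports": sorted(j.supports),
                     "rule": j.rule_id, "schema": j.schema_id}
                    for j in it.justifications],
            })
        return out
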