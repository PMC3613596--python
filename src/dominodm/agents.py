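"""Multi-agent shell: switchboard-routed performative messaging and
dialog-based joint decision-making.

Agents share a common knowledge base plus a specialist partition each, and
communicate exclusively through a switchboard that delivers queued
messages first-in-first-out, exactly once per round.  Communication acts
carry standard performatives (inform, request, query, explain, instruct,
challenge, accept, reject).

Three roles are provided:

- a *records* agent: a pure responder that answers ``query`` performatives
  from its case table and may announce presenting facts to the lead;
- a *lead* agent: runs the full decision kernel; on a high-stakes decision
  it raises a consultation goal, opens an inform dialog with the declared
  specialist, and challenges advice that conflicts with its own current
  preference (eliciting the specialist's rationale);
- a *specialist* agent: answers confirmation requests by running its own
  decision pipeline over its specialist knowledge, querying the records
  agent for any askable patient facts its argument schemas need, and
  replying with its preferred option; a challenge is answered with an
  ``explain`` carrying its undefeated argument set.

Received explanations are incorporated by asserting the arguments with a
communication justification and re-running defeat resolution and
aggregation — preference may flip as a result, after which the lead can
commit firm.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .descriptions import Atom
from .memory import Belief, Goal, Justification, Observation
from .argumentation import Argument, resolve_defeat
from .kernel import AgentKernel
from .ontology import Ontology

PERFORMATIVES = {"inform", "request", "query", "explain", "instruct",
                 "challenge", "accept", "reject"}


class MessagingError(ValueError):
    pass


@dataclass
class Message:
    sender: str
    receiver: str
    performative: str
    content: dict = field(default_factory=dict)
    dialog: str = ""
    seq: int = 0

    def to_record(self) -> dict:
        return {"sender": self.sender, "receiver": self.receiver,
                "performative": self.performative, "dialog": self.dialog,
                "seq": self.seq, "content": _digest(self.content)}


def _digest(content) -> str:
    import hashlib
    import json
    return hashlib.sha256(
        json.dumps(content, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


@dataclass
class DialogPlan:
    """Nominal ordered communication acts of a dialog protocol.  Acts run
    in sequence but the dialog can be interrupted by an incoming
    communication (the lead's challenge policy interrupts after advice
    that conflicts with its own preference)."""

    id: str
    acts: Tuple[str, ...] = ()
    interruption_policy: str = "challenge_on_conflict"
    completion_condition: str = ""


CONSULT_PLAN = DialogPlan(
    id="consult_inform",
    acts=("request:open", "await:accept", "request:confirm", "await:inform"),
    completion_condition="consulted")


class Switchboard:
    """FIFO message router: every sent message is delivered exactly once
    within a round."""

    def __init__(self):
        self.agents: Dict[str, object] = {}
        self.queue: List[Message] = []
        self.send_log: List[Message] = []
        self.delivery_log: List[Message] = []
        self._seq: Dict[str, int] = {}

    def register(self, agent) -> None:
        self.agents[agent.id] = agent

    def send(self, message: Message) -> Message:
        if message.sender == message.receiver:
            raise MessagingError("message to self rejected")
        if message.receiver not in self.agents:
            raise MessagingError(f"unregistered receiver {message.receiver!r}")
        if message.performative not in PERFORMATIVES:
            raise MessagingError(f"unknown performative {message.performative!r}")
        self._seq[message.dialog] = self._seq.get(message.dialog, 0) + 1
        message.seq = self._seq[message.dialog]
        self.queue.append(message)
        self.send_log.append(message)
        return message

    def dispatch(self) -> List[Message]:
        """Deliver every queued message in send order."""
        delivered = []
        while self.queue:
            msg = self.queue.pop(0)
            self.agents[msg.receiver].inbox.append(msg)
            self.delivery_log.append(msg)
            delivered.append(msg)
        return delivered


# ---------------------------------------------------------------------------
# Agent shells
# ---------------------------------------------------------------------------

class RecordsAgent:
    """Pure responder: answers ``query`` performatives from a case table;
    no decision pipeline."""

    def __init__(self, agent_id: str, case: Sequence[Atom],
                 announce: Sequence[Atom] = (), announce_to: str = ""):
        self.id = agent_id
        self.case = list(case)
        self.announce = list(announce)
        self.announce_to = announce_to
        self.inbox: List[Message] = []
        self._announced = False

    def step(self, round_no: int) -> List[Message]:
        out: List[Message] = []
        if not self._announced and self.announce and self.announce_to:
            out.append(Message(self.id, self.announce_to, "inform",
                               {"atoms": [[a.attr, a.value] for a in self.announce]},
                               dialog=f"{self.id}:announce"))
            self._announced = True
        for msg in self.inbox:
            if msg.performative == "query":
                attr = msg.content.get("attr")
                matches = [[a.attr, a.value] for a in self.case if a.attr == attr]
                out.append(Message(self.id, msg.sender, "inform",
                                   {"atoms": matches, "attr": attr},
                                   dialog=msg.dialog))
            else:
                out.append(Message(self.id, msg.sender, "reject",
                                   {"reason": f"unsupported performative "
                                              f"{msg.performative}"},
                                   dialog=msg.dialog))
        self.inbox = []
        return out


def serialize_arguments(arguments: Iterable[Argument]) -> List[dict]:
    """Candidate-targeting undefeated arguments in wire form (rationale
    export for explain performatives)."""
    out = []
    for a in arguments:
        if a.defeated or a.target_kind != "candidate":
            continue
        out.append({"schema": a.schema_id, "polarity": a.polarity,
                    "target": a.target, "strength": a.strength,
                    "grounds": [[g.attr, g.value] for g in a.grounds[1]]
                    if len(a.grounds) > 1 else []})
    return out


def incorporate_explanation(kernel: AgentKernel, goal_item: int,
                            arguments: Sequence[dict]) -> List[str]:
    """Assert communicated arguments and re-run defeat + aggregation for
    the open decision; returns the updated preference order.  Arguments
    referencing unknown candidates are held pending."""
    ds = kernel.decisions[goal_item]
    payloads = {c.payload for c in ds.candidates}
    pending = ds.pending_external
    for spec in arguments:
        if spec["target"] not in payloads:
            pending.append(spec)
            continue
        # an argument already held (constructed or previously communicated)
        # merges rather than double-counting
        if any(e.schema_id == spec["schema"] and e.target == spec["target"]
               for e in ds.all_arguments()):
            continue
        arg = Argument(
            id=kernel._arg_id, target=spec["target"], target_kind="candidate",
            polarity=spec["polarity"], schema_id=spec["schema"],
            grounds=((), tuple(Atom(a, v) for a, v in spec.get("grounds", []))),
            strength=spec.get("strength", 1.0), candidate=spec["target"])
        kernel._arg_id += 1
        ds.external_arguments.append(arg)
        kernel.memory.assert_item(
            arg, Justification("communication",
                               frozenset({goal_item}), schema_id=spec["schema"]))
    ds.pending_external = pending
    if ds.candidates:
        kernel.s5_aggregate(goal_item)
    return ds.order


class KernelAgent:
    """An agent shell around :class:`AgentKernel` with dialog behavior."""

    def __init__(self, agent_id: str, onto: Ontology, role: str,
                 seed: int = 0, consult: Sequence[str] = (),
                 askable: Optional[Dict[str, str]] = None,
                 aggregator: str = "bentham"):
        self.id = agent_id
        self.role = role
        self.kernel = AgentKernel(agent_id, onto, seed=seed,
                                  aggregator=aggregator,
                                  consult_sources=list(consult))
        self.askable = dict(askable or {})
        self.inbox: List[Message] = []
        self.dialog_plan = CONSULT_PLAN
        self._dialogs: Dict[str, dict] = {}
        self._dialog_counter = 0
        self._pending_requests: Dict[str, dict] = {}
        self.message_log: List[dict] = []

    # -- helpers ----------------------------------------------------------

    def _new_dialog(self) -> str:
        self._dialog_counter += 1
        return f"{self.id}:{self._dialog_counter}"

    def _goal_item_named(self, name: str) -> Optional[int]:
        for it in self.kernel.memory.active_items(Goal):
            if it.content.name == name:
                return it.id
        return None

    def _assert_communicated_atoms(self, atoms: Sequence[Sequence[str]],
                                   msg: Message) -> None:
        for attr, value in atoms:
            self.kernel.memory.assert_item(
                Observation(Atom(attr, value), "message",
                            self.kernel.memory.clock),
                Justification("observation"))

    # -- message handling --------------------------------------------------

    def handle_message(self, msg: Message) -> List[Message]:
        self.message_log.append(msg.to_record())
        if msg.performative not in PERFORMATIVES:
            return [Message(self.id, msg.sender, "reject",
                            {"reason": "unknown performative"},
                            dialog=msg.dialog)]
        handler = getattr(self, f"_on_{msg.performative}", None)
        if handler is None:
            return [Message(self.id, msg.sender, "reject",
                            {"reason": f"unsupported performative "
                                       f"{msg.performative}"},
                            dialog=msg.dialog)]
        return handler(msg)

    def _on_inform(self, msg: Message) -> List[Message]:
        out: List[Message] = []
        if "atoms" in msg.content:
            self._assert_communicated_atoms(msg.content["atoms"], msg)
            pending = self._pending_requests.get(msg.dialog)
            if pending is not None and "attr" in msg.content:
                pending["waiting"].discard(msg.content["attr"])
                if not pending["waiting"]:
                    out.extend(self._complete_confirmation(msg.dialog))
        elif "preferred" in msg.content:
            out.extend(self._on_advice(msg))
        return out

    def _on_accept(self, msg: Message) -> List[Message]:
        state = self._dialogs.get(msg.dialog)
        if state is None or state["state"] != "opening":
            return []
        state["state"] = "awaiting_advice"
        goal_item = state["goal_item"]
        ds = self.kernel.decisions[goal_item]
        goal = self.kernel.memory.items[goal_item].content
        return [Message(self.id, msg.sender, "request",
                        {"act": "confirm",
                         "candidate": ds.order[0] if ds.order else None,
                         "goal": {"name": goal.name,
                                  "targets": list(goal.targets)}},
                        dialog=msg.dialog)]

    def _on_advice(self, msg: Message) -> List[Message]:
        """Advice received during a consultation: accept it if it matches
        our preference, otherwise challenge (the lead's interruption
        policy)."""
        state = self._dialogs.get(msg.dialog)
        if state is None:
            return []
        preferred = msg.content["preferred"]
        goal_item = state["goal_item"]
        ds = self.kernel.decisions[goal_item]
        own_top = ds.order[0] if ds.order else None
        if preferred == own_top:
            self._close_consultation(msg.dialog, msg.sender)
            return []
        state["state"] = "awaiting_explanation"
        return [Message(self.id, msg.sender, "challenge",
                        {"candidate": preferred}, dialog=msg.dialog)]

    def _on_explain(self, msg: Message) -> List[Message]:
        state = self._dialogs.get(msg.dialog)
        if state is None:
            return []
        goal_item = state["goal_item"]
        incorporate_explanation(self.kernel, goal_item,
                                msg.content.get("arguments", []))
        self._close_consultation(msg.dialog, msg.sender)
        return []

    def _close_consultation(self, dialog: str, source: str) -> None:
        state = self._dialogs[dialog]
        goal_item = state["goal_item"]
        ds = self.kernel.decisions[goal_item]
        ds.consulted.add(source)
        ds.awaiting = None
        state["state"] = "closed"
        consult_name = f"consult:{source}:" \
                       f"{self.kernel.memory.items[goal_item].content.name}"
        self.kernel.memory.assert_item(
            Belief(Atom(f"consulted:{source}:"
                        f"{self.kernel.memory.items[goal_item].content.name}",
                        "true")),
            Justification("communication", frozenset({goal_item})))
        cg = self._goal_item_named(consult_name)
        if cg is not None:
            self.kernel.memory.items[cg].content.status = "achieved"

    def _on_request(self, msg: Message) -> List[Message]:
        act = msg.content.get("act")
        if act == "open":
            return [Message(self.id, msg.sender, "accept",
                            {"protocol": msg.content.get("protocol", "inform")},
                            dialog=msg.dialog)]
        if act == "confirm":
            return self._on_confirm_request(msg)
        return [Message(self.id, msg.sender, "reject",
                        {"reason": f"unknown request act {act!r}"},
                        dialog=msg.dialog)]

    def _on_confirm_request(self, msg: Message) -> List[Message]:
        """Run our own decision pipeline on the referenced goal; query the
        records agent first for any askable facts our schemas need."""
        spec = msg.content.get("goal", {})
        goal = Goal(name=spec.get("name", "advice"),
                    condition=Atom(f"decided:{spec.get('name', 'advice')}", "*"),
                    targets=tuple(spec.get("targets", ())),
                    status="active", kind="decide")
        goal_item = self.kernel.memory.assert_item(
            goal, Justification("communication", frozenset()))
        self.kernel.s3_generate_candidates(goal_item)
        pending = {"goal_item": goal_item, "requester": msg.sender,
                   "candidate": msg.content.get("candidate"),
                   "waiting": set()}
        beliefs = self.kernel.memory.belief_atoms()
        known = {a.attr for a in beliefs}
        for schema in self.kernel.onto.schemas:
            for clause in schema.condition:
                if "belief" not in clause:
                    continue
                attr = clause["belief"][0]
                if attr in self.askable and attr not in known:
                    pending["waiting"].add(attr)
        self._pending_requests[msg.dialog] = pending
        out: List[Message] = []
        if pending["waiting"]:
            for attr in sorted(pending["waiting"]):
                out.append(Message(self.id, self.askable[attr], "query",
                                   {"attr": attr}, dialog=msg.dialog))
        else:
            out.extend(self._complete_confirmation(msg.dialog))
        return out

    def _complete_confirmation(self, dialog: str) -> List[Message]:
        pending = self._pending_requests[dialog]
        goal_item = pending["goal_item"]
        self.kernel.s4_construct_reasons(goal_item)
        order = self.kernel.s5_aggregate(goal_item)
        pending["done"] = True
        return [Message(self.id, pending["requester"], "inform",
                        {"preferred": order[0] if order else None},
                        dialog=dialog)]

    def _on_challenge(self, msg: Message) -> List[Message]:
        pending = self._pending_requests.get(msg.dialog)
        if pending is None:
            return [Message(self.id, msg.sender, "reject",
                            {"reason": "no open decision to explain"},
                            dialog=msg.dialog)]
        ds = self.kernel.decisions[pending["goal_item"]]
        args = resolve_defeat(ds.all_arguments())
        return [Message(self.id, msg.sender, "explain",
                        {"arguments": serialize_arguments(args)},
                        dialog=msg.dialog)]

    def _on_query(self, msg: Message) -> List[Message]:
        attr = msg.content.get("attr")
        matches = [[a.attr, a.value]
                   for a in self.kernel.memory.belief_atoms()
                   if a.attr == attr]
        return [Message(self.id, msg.sender, "inform",
                        {"atoms": matches, "attr": attr}, dialog=msg.dialog)]

    def _on_reject(self, msg: Message) -> List[Message]:
        return []

    def _on_instruct(self, msg: Message) -> List[Message]:
        if "atoms" in msg.content:
            self._assert_communicated_atoms(msg.content["atoms"], msg)
        return []

    # -- per-round step ----------------------------------------------------

    def _open_consultations(self) -> List[Message]:
        """Open an inform dialog for every consult goal not yet served."""
        out: List[Message] = []
        open_goals = {s["consult_goal"] for s in self._dialogs.values()
                      if s["state"] != "closed"}
        for it in self.kernel.memory.active_goals():
            g = it.content
            if g.kind != "consult" or g.name in open_goals:
                continue
            if any(s["consult_goal"] == g.name for s in self._dialogs.values()):
                continue
            source = g.name.split(":")[1]
            dialog = self._new_dialog()
            self._dialogs[dialog] = {
                "state": "opening", "consult_goal": g.name,
                "source": source, "goal_item": g.parent}
            out.append(Message(self.id, source, "request",
                               {"act": "open", "protocol": "inform"},
                               dialog=dialog))
        return out

    def step(self, round_no: int) -> List[Message]:
        out: List[Message] = []
        inbox, self.inbox = self.inbox, []
        for msg in inbox:
            out.extend(self.handle_message(msg))
        self.kernel.step(())
        if self.role == "lead":
            out.extend(self._open_consultations())
        return out

# ---------------------------------------------------------------------------
# Network construction and execution
# ---------------------------------------------------------------------------

def build_network(shared: Ontology, switchboard: Optional[Switchboard] = None,
                  seed: int = 0, aggregator: str = "bentham") -> Switchboard:
    """Instantiate the agents declared in the KB ``agents`` section (in
    declaration order, which fixes the turn order) on a switchboard."""
    sb = switchboard or Switchboard()
    master = random.Random(seed)
    for agent_id, spec in shared.agents.items():
        role = spec.get("role", "lead")
        agent_seed = master.randrange(2 ** 31)
        if role == "records":
            case = [Atom(a, v) for a, v in spec.get("case", [])]
            announce = [Atom(a, v) for a, v in spec.get("announce", [])]
            agent = RecordsAgent(agent_id, case, announce,
                                 spec.get("announce_to", ""))
        else:
            onto = shared
            partition = spec.get("partition")
            if isinstance(partition, Ontology):
                onto = shared.merged_with(partition)
            agent = KernelAgent(agent_id, onto, role, seed=agent_seed,
                                consult=spec.get("consult", ()),
                                askable=spec.get("askable"),
                                aggregator=aggregator)
        sb.register(agent)
    return sb


@dataclass
class NetworkTrace:
    rounds: int = 0
    messages: List[dict] = field(default_factory=list)
    agent_traces: Dict[str, list] = field(default_factory=dict)
    complete: bool = True

    def records(self) -> List[dict]:
        out = []
        for m in self.messages:
            out.append({"event": "message", **m})
        for agent, tr in sorted(self.agent_traces.items()):
            for rec in tr:
                out.append({"event": "op", **rec})
        return out


def run_network(switchboard: Switchboard, max_rounds: int = 30,
                initial_messages: Sequence[Message] = ()) -> NetworkTrace:
    """Rounds of (each agent steps, messages dispatched) until quiescence
    or ``max_rounds``; deterministic under fixed seeds and registration
    order."""
    trace = NetworkTrace()
    for msg in initial_messages:
        switchboard.send(msg)
    for round_no in range(max_rounds):
        trace.rounds = round_no + 1
        any_out = False
        for agent in switchboard.agents.values():
            for msg in agent.step(round_no):
                switchboard.send(msg)
                any_out = True
        delivered = switchboard.dispatch()
        for m in delivered:
            trace.messages.append({"round": round_no, **m.to_record()})
        if not any_out and not delivered:
            break
    else:
        trace.complete = False
    for agent_id, agent in switchboard.agents.items():
        if isinstance(agent, KernelAgent):
            trace.agent_traces[agent_id] = agent.kernel.trace
    return trace
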