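"""Deterministic trace logging and replay.

Traces are JSONL: a header record carrying the format version, the run
kind, the seed and the run parameters, followed by one record per event
(operation firing, message delivery, or WCST trial), each with a content
digest.  Replay re-executes the run from the same knowledge base, seed
and parameters and checks each regenerated record against the stored
digest, reporting the first divergence; a truncated trace is flagged
incomplete rather than failing.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Union

TRACE_FORMAT_VERSION = 1


class TraceError(ValueError):
    pass


def _digest(record: dict) -> str:
    return hashlib.sha256(
        json.dumps(record, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _wcst_records(state) -> List[dict]:
    out = []
    for t in state.trial_log:
        out.append({
            "event": "trial", "index": t.index,
            "card": [t.card.number, t.card.shape, t.card.color],
            "criterion": t.criterion, "placement": t.placement,
            "positive": t.positive, "rule_used": t.rule_used,
            "prev_criterion": t.prev_criterion,
            "n_switches_before": t.n_switches_before,
            "consecutive_before": t.consecutive_before,
            "forgot": t.forgot, "switched_after": t.switched_after})
    return out


def records_for(run) -> List[dict]:
    """Normalize a run result (NetworkTrace, WcstState, or kernel trace
    list) to a flat record list."""
    from .agents import NetworkTrace
    from .scenarios.wcst import WcstState
    if isinstance(run, NetworkTrace):
        return run.records()
    if isinstance(run, WcstState):
        return _wcst_records(run)
    if isinstance(run, list):
        return [{"event": "op", **r} for r in run]
    raise TraceError(f"cannot serialize run of type {type(run).__name__}")


def write_trace(run, path: Union[str, Path], kind: str, seed: int,
                params: Optional[dict] = None) -> int:
    """Write a run as JSONL; returns the number of event records."""
    records = records_for(run)
    header = {"format_version": TRACE_FORMAT_VERSION, "kind": kind,
              "seed": seed, "params": params or {}, "records": len(records)}
    with open(path, "w") as fh:
        fh.write(json.dumps(header, sort_keys=True) + "\n")
        for rec in records:
            rec = dict(rec)
            rec["digest"] = _digest({k: v for k, v in rec.items()
                                     if k != "digest"})
            fh.write(json.dumps(rec, sort_keys=True, default=str) + "\n")
    return len(records)


def read_trace(path: Union[str, Path]):
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise TraceError("empty trace file")
    header = json.loads(lines[0])
    if header.get("format_version") != TRACE_FORMAT_VERSION:
        raise TraceError(f"unsupported trace format "
                         f"{header.get('format_version')!r}")
    records = [json.loads(ln) for ln in lines[1:] if ln.strip()]
    return header, records


@dataclass
class ReplayReport:
    ok: bool
    incomplete: bool = False
    divergence_index: Optional[int] = None
    detail: str = ""
    checked: int = 0


def _rerun(header: dict, kb_path: Optional[Union[str, Path]]):
    kind = header["kind"]
    seed = header["seed"]
    params = header.get("params", {})
    if kind == "wcst":
        from .scenarios.wcst import LesionConfig, run_wcst
        lesion = LesionConfig(
            monitoring=params.get("monitoring", True),
            retention_failure=params.get("retention_failure", 0.0),
            strategy=params.get("strategy", "rule"))
        return run_wcst(lesion, switch_after=params.get("switch_after", 6),
                        n_trials=params.get("n_trials", 64), seed=seed)
    if kind == "network":
        if kb_path is None:
            raise TraceError("network replay needs the KB file")
        from .agents import build_network, run_network
        from .kb import load_kb
        onto = load_kb(kb_path)
        sb = build_network(onto, seed=seed)
        return run_network(sb, max_rounds=params.get("max_rounds", 30))
    raise TraceError(f"unknown trace kind {kind!r}")


def replay(path: Union[str, Path],
           kb_path: Optional[Union[str, Path]] = None) -> ReplayReport:
    """Re-execute the run described by a trace and verify every stored
    record digest against the regenerated one."""
    header, stored = read_trace(path)
    fresh = records_for(_rerun(header, kb_path))
    for i, rec in enumerate(stored):
        if i >= len(fresh):
            return ReplayReport(ok=False, divergence_index=i,
                                detail="stored trace longer than replay",
                                checked=i)
        want = rec.get("digest")
        got = _digest({k: v for k, v in fresh[i].items() if k != "digest"})
        # stored records round-trip through JSON; compare digests of the
        # JSON-normalized forms
        norm = _digest({k: v for k, v in
                        json.loads(json.dumps(fresh[i], default=str)).items()
                        if k != "digest"})
        if want not in (got, norm):
            return ReplayReport(ok=False, divergence_index=i,
                                detail=f"digest mismatch at record {i}",
                                checked=i)
    incomplete = len(stored) < len(fresh) or \
        int(header.get("records", len(stored))) > len(stored)
    return ReplayReport(ok=True, incomplete=incomplete, checked=len(stored))


def summarize(path: Union[str, Path]) -> dict:
    """Decision endpoints, argument counts, and WCST error categories of a
    stored trace."""
    header, records = read_trace(path)
    out = {"kind": header["kind"], "seed": header["seed"],
           "records": len(records)}
    if header["kind"] == "wcst":
        from .scenarios.wcst import (WcstCard, WcstState, TrialRecord,
                                     classify_errors, STANDARD_TARGETS)
        state = WcstState()
        for r in records:
            n, s, c = r["card"]
            state.trial_log.append(TrialRecord(
                index=r["index"], card=WcstCard(n, s, c),
                criterion=r["criterion"], placement=r["placement"],
                positive=r["positive"], rule_used=r.get("rule_used"),
                prev_criterion=r.get("prev_criterion"),
                n_switches_before=r.get("n_switches_before", 0),
                consecutive_before=r.get("consecutive_before", 0),
                forgot=r.get("forgot", False),
                switched_after=r.get("switched_after", False)))
        out["errors"] = classify_errors(state)
        out["trials"] = len(state.trial_log)
        out["correct"] = sum(1 for t in state.trial_log if t.positive)
        out["switches"] = sum(1 for t in state.trial_log if t.switched_after)
    else:
        commits = [r for r in records
                   if r.get("op") == "s6" and "candidate" in
                   r.get("detail", {})]
        if commits:
            last = commits[-1]
            out["endpoint"] = {"agent": last.get("agent"),
                               "candidate": last["detail"]["candidate"],
                               "firmness": last["detail"]["firmness"]}
        out["arguments"] = sum(len(r["detail"].get("arguments", []))
                               for r in records if r.get("op") == "s4")
        out["messages"] = sum(1 for r in records
                              if r.get("event") == "message")
    return out
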