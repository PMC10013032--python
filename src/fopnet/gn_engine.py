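"""Reduced generalized-net execution engine.

The net is the four-tuple ⟨A, K, X, Φ⟩: A the ordered transitions, K the
token registry, X the initial characteristics tokens carry on entering the
net, and Φ the characteristic hooks that append new records to a token's
history when it moves.  Transitions are triples ⟨inputs, outputs,
condition⟩ with an index-matrix condition (:mod:`fopnet.im_core`); the
standard components this reduction omits (priorities, place capacities,
transition durations) are deliberately absent — every firing takes one tick
and places are unbounded.

Scheduling is synchronous: :func:`step` fires every transition once, in
declared order, then advances the global clock; a token moved (or created)
during tick *t* is frozen until *t + 1*, so no token crosses two
transitions within one tick.  Every state change is mirrored by exactly one
trace event, which makes runs auditable: the conservation ledger
``live(t+1) = live(t) + splits − unite-deaths − stops`` must balance at
every tick of every trace.
"""

from __future__ import annotations

import hashlib
import json
import random
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, NamedTuple

from .im_core import (
    ALWAYS_FALSE,
    ALWAYS_TRUE,
    FiringContext,
    IndexMatrix,
    StructuralError,
    im_evaluate_row,
)

# trace event kinds
TRANSFER = "TRANSFER"
SPLIT = "SPLIT"
UNITE = "UNITE"
STOP = "STOP"
CHARACTERISTIC = "CHARACTERISTIC"
EVENT_KINDS = (TRANSFER, SPLIT, UNITE, STOP, CHARACTERISTIC)

TRACE_SCHEMA = "gn-trace/1"


def canonical_json(obj: Any) -> str:
    """Canonical single-line JSON (sorted keys, compact) for byte-stable traces."""
    return json.dumps(obj, sort_keys=True, separators=(",", ":"), ensure_ascii=True)


@dataclass
class TraceEvent:
    tick: int
    seq: int
    kind: str
    transition_id: str | None
    token_ids: list[str]
    source_place: str | None
    target_place: str | None
    payload: dict

    def to_record(self) -> dict:
        return {
            "kind": self.kind,
            "payload": self.payload,
            "seq": self.seq,
            "source": self.source_place,
            "target": self.target_place,
            "tick": self.tick,
            "token_ids": list(self.token_ids),
            "transition": self.transition_id,
        }


@dataclass
class Token:
    """Mobile information carrier with an append-only characteristic history.

    ``history`` entries are dicts ``{"tick", "label", "data"}`` with
    non-decreasing ticks; ``meta`` holds engine bookkeeping (freeze marks,
    thresholds, provenance sets) that is not part of the formal history.
    """

    id: str
    type_tag: str
    history: list[dict] = field(default_factory=list)
    alive: bool = True
    parent_ids: list[str] = field(default_factory=list)
    place: str | None = None
    meta: dict = field(default_factory=dict)

    def last_characteristic(self) -> dict | None:
        return self.history[-1] if self.history else None


@dataclass
class Place:
    id: str
    role: str = ""
    token_ids: list[str] = field(default_factory=list)


@dataclass
class Transition:
    """Reduced transition ⟨inputs, outputs, condition⟩ plus an optional firing policy.

    Without ``on_fire`` the default policy applies: each eligible resident
    token of each input place moves to the first enabled output column (a
    self-loop column means "stay").  Policies implement richer lifecycles
    (split / unite / stop / characteristic assignment).
    """

    id: str
    inputs: list[str]
    outputs: list[str]
    condition: IndexMatrix
    on_fire: Callable[["GNet", "Transition", int], list[TraceEvent]] | None = None


class NetComponents(NamedTuple):
    """The four top-level components of the reduced net."""

    A: list
    K: dict
    X: dict
    Phi: dict


class GNet:
    """A reduced generalized net with a global tick clock."""

    def __init__(self) -> None:
        self.transitions: list[Transition] = []  # A
        self.tokens: dict[str, Token] = {}  # K
        self.initial_characteristics: dict[str, dict] = {}  # X
        self.characteristic_hooks: dict[str, Callable] = {}  # Φ
        self.places: dict[str, Place] = {}
        self.clock: int = 0
        self.aux: dict = {}  # policy scratch state; not part of the formal net
        self.trace_events: list[TraceEvent] = []
        self.tick_snapshots: list[dict] = []
        self.rng = random.Random(0)
        self._counter = 0
        self._transition_index: dict[str, Transition] = {}

    # -- the four-tuple -------------------------------------------------
    @property
    def A(self) -> list[Transition]:
        return self.transitions

    @property
    def K(self) -> dict[str, Token]:
        return self.tokens

    @property
    def X(self) -> dict[str, dict]:
        return self.initial_characteristics

    @property
    def Phi(self) -> dict[str, Callable]:
        return self.characteristic_hooks

    def as_four_tuple(self) -> NetComponents:
        return NetComponents(self.A, self.K, self.X, self.Phi)

    # -- construction ---------------------------------------------------
    def add_place(self, place_id: str, role: str = "") -> Place:
        if place_id in self.places:
            raise StructuralError(f"duplicate place id {place_id!r}")
        pl = Place(id=place_id, role=role)
        self.places[place_id] = pl
        return pl

    def add_transition(self, transition: Transition) -> Transition:
        if transition.id in self._transition_index:
            raise StructuralError(f"duplicate transition id {transition.id!r}")
        self.transitions.append(transition)
        self._transition_index[transition.id] = transition
        return transition

    def get_transition(self, transition_id: str) -> Transition:
        try:
            return self._transition_index[transition_id]
        except KeyError:
            raise StructuralError(f"unknown transition {transition_id!r}") from None

    def new_token(
        self,
        type_tag: str,
        place_id: str,
        characteristic: dict | None = None,
        label: str | None = None,
        parents: Iterable[str] = (),
        tick: int | None = None,
    ) -> Token:
        """Create a token in ``place_id``; its first characteristic is recorded in X."""
        if place_id not in self.places:
            raise StructuralError(f"unknown place {place_id!r}")
        tok = Token(id=f"{type_tag}-{self._counter}", type_tag=type_tag, parent_ids=list(parents))
        self._counter += 1
        tok.place = place_id
        self.tokens[tok.id] = tok
        self.places[place_id].token_ids.append(tok.id)
        if characteristic is not None:
            t = self.clock if tick is None else tick
            tok.history.append({"tick": t, "label": label, "data": dict(characteristic)})
            self.initial_characteristics[tok.id] = dict(characteristic)
        return tok

    # -- queries --------------------------------------------------------
    def live_token_ids(self) -> list[str]:
        return [tid for tid, tok in self.tokens.items() if tok.alive]

    def is_eligible(self, token: Token, tick: int) -> bool:
        """A token moved or created at tick t may not act again before t+1."""
        moved = token.meta.get("moved_at")
        return token.alive and (moved is None or moved < tick)

    def eligible_tokens(
        self, place_id: str, tick: int, type_tags: tuple[str, ...] | None = None
    ) -> list[Token]:
        out = []
        for tid in list(self.places[place_id].token_ids):
            tok = self.tokens[tid]
            if not self.is_eligible(tok, tick):
                continue
            if type_tags is not None and tok.type_tag not in type_tags:
                continue
            out.append(tok)
        return out

    def state_digest(self) -> str:
        """Digest of formal net state (clock, markings, token records)."""
        snap = self.final_state()
        snap["clock"] = self.clock
        return hashlib.sha256(canonical_json(snap).encode()).hexdigest()

    def final_state(self) -> dict:
        return {
            "places": {pid: list(pl.token_ids) for pid, pl in self.places.items()},
            "tokens": {
                tid: {
                    "alive": tok.alive,
                    "history": tok.history,
                    "parents": list(tok.parent_ids),
                    "place": tok.place,
                    "type": tok.type_tag,
                }
                for tid, tok in self.tokens.items()
            },
        }

    # -- event plumbing -------------------------------------------------
    def _emit(
        self,
        tick: int,
        kind: str,
        transition_id: str | None,
        token_ids: list[str],
        source: str | None,
        target: str | None,
        payload: dict | None = None,
    ) -> TraceEvent:
        ev = TraceEvent(
            tick=tick,
            seq=len(self.trace_events),
            kind=kind,
            transition_id=transition_id,
            token_ids=list(token_ids),
            source_place=source,
            target_place=target,
            payload=payload or {},
        )
        self.trace_events.append(ev)
        return ev

    # -- token lifecycle ------------------------------------------------
    def transfer(
        self, token: Token, src: str, dst: str, tick: int, transition_id: str | None
    ) -> TraceEvent:
        if token.place != src:
            raise StructuralError(f"token {token.id} is not in {src!r}")
        if dst not in self.places:
            raise StructuralError(f"unknown place {dst!r}")
        self.places[src].token_ids.remove(token.id)
        self.places[dst].token_ids.append(token.id)
        token.place = dst
        token.meta["moved_at"] = tick
        return self._emit(tick, TRANSFER, transition_id, [token.id], src, dst)

    def split(
        self,
        token_id: str,
        child_specs: list[tuple[str, dict | None]],
        tick: int,
        transition_id: str | None = None,
        label: str | None = None,
    ) -> tuple[TraceEvent, list[str]]:
        """Split a token: the parent stays put, children appear beside it.

        ``child_specs`` is a list of ``(type_tag, initial characteristic)``;
        children carry parent provenance and are frozen until the next tick.
        """
        parent = self.tokens[token_id]
        if not parent.alive:
            raise StructuralError(f"cannot split dead token {token_id}")
        if not child_specs:
            raise StructuralError("split requires at least one child spec")
        assert parent.place is not None
        child_ids: list[str] = []
        for type_tag, characteristic in child_specs:
            child = self.new_token(
                type_tag,
                parent.place,
                characteristic=characteristic,
                label=label,
                parents=[parent.id],
                tick=tick,
            )
            child.meta["moved_at"] = tick  # produced this tick => frozen until next
            child_ids.append(child.id)
        ev = self._emit(
            tick,
            SPLIT,
            transition_id,
            [parent.id, *child_ids],
            parent.place,
            parent.place,
            {"children": child_ids, "parent": parent.id},
        )
        return ev, child_ids

    def unite(
        self,
        token_ids: list[str],
        host_token_id: str,
        tick: int,
        transition_id: str | None = None,
    ) -> list[TraceEvent]:
        """Merge co-located tokens into the host; the others stop functioning.

        The host survives with the constituents' histories merged by a
        stable tick-ordered merge (equal ticks keep ``token_ids`` order);
        each absorbed token is recorded dead with a STOP event of cause
        ``"unite"``.
        """
        if len(set(token_ids)) < 2:
            raise StructuralError("unite requires at least two distinct tokens")
        if host_token_id not in token_ids:
            raise StructuralError("host must be among the united tokens")
        toks = [self.tokens[tid] for tid in token_ids]
        place = toks[0].place
        for tok in toks:
            if not tok.alive:
                raise StructuralError(f"cannot unite dead token {tok.id}")
            if tok.place != place:
                raise StructuralError(
                    f"tokens are not co-located: {tok.id} in {tok.place!r}, expected {place!r}"
                )
        host = self.tokens[host_token_id]
        merged = [rec for tok in toks for rec in tok.history]
        merged.sort(key=lambda rec: rec["tick"])  # stable: equal ticks keep order
        host.history = merged
        absorbed = [tok for tok in toks if tok.id != host_token_id]
        events = [
            self._emit(
                tick,
                UNITE,
                transition_id,
                [host.id] + [t.id for t in absorbed],
                place,
                place,
                {"host": host.id, "absorbed": [t.id for t in absorbed]},
            )
        ]
        for tok in absorbed:
            assert tok.place is not None
            self.places[tok.place].token_ids.remove(tok.id)
            tok.place = None
            tok.alive = False
            host.parent_ids.append(tok.id)
            events.append(
                self._emit(tick, STOP, transition_id, [tok.id], place, None, {"cause": "unite"})
            )
        return events

    def stop(self, token_id: str, tick: int, transition_id: str | None = None) -> TraceEvent:
        """A token stops functioning (the ◦ of the threshold gate)."""
        tok = self.tokens[token_id]
        if not tok.alive:
            raise StructuralError(f"token {token_id} already stopped")
        src = tok.place
        if src is not None:
            self.places[src].token_ids.remove(tok.id)
        tok.place = None
        tok.alive = False
        return self._emit(tick, STOP, transition_id, [tok.id], src, None, {"cause": "stop"})

    def assign_characteristic(
        self,
        token: Token,
        data: dict,
        tick: int,
        transition_id: str | None = None,
        label: str | None = None,
    ) -> TraceEvent:
        if token.history and token.history[-1]["tick"] > tick:
            raise StructuralError(
                f"characteristic tick {tick} precedes last history tick of {token.id}"
            )
        token.history.append({"tick": tick, "label": label, "data": dict(data)})
        return self._emit(
            tick,
            CHARACTERISTIC,
            transition_id,
            [token.id],
            token.place,
            token.place,
            {"label": label, "data": dict(data)},
        )


# -- module-level operation surface (thin wrappers over GNet methods) ----

def split_token(
    net: GNet, token_id: str, child_specs: list[tuple[str, dict | None]]
) -> list[str]:
    """Split at the current clock tick; returns the child token ids."""
    _, child_ids = net.split(token_id, child_specs, net.clock)
    return child_ids


def unite_tokens(net: GNet, token_ids: list[str], host_token_id: str) -> str:
    """Unite at the current clock tick; returns the surviving (host) id."""
    net.unite(token_ids, host_token_id, net.clock)
    return host_token_id


def validate_net(net: GNet) -> list[str]:
    """Structural validation; returns a list of violations (empty if well-formed)."""
    violations: list[str] = []
    for tr in net.transitions:
        if not tr.inputs:
            violations.append(f"transition {tr.id}: empty input set")
        if not tr.outputs:
            violations.append(f"transition {tr.id}: empty output set")
        for pid in [*tr.inputs, *tr.outputs]:
            if pid not in net.places:
                violations.append(f"transition {tr.id}: unknown place {pid!r}")
        if list(tr.condition.row_labels) != list(tr.inputs):
            violations.append(
                f"transition {tr.id}: condition rows {tr.condition.row_labels} != inputs {tr.inputs}"
            )
        if list(tr.condition.col_labels) != list(tr.outputs):
            violations.append(
                f"transition {tr.id}: condition cols {tr.condition.col_labels} != outputs {tr.outputs}"
            )
    residence: dict[str, list[str]] = {}
    for pid, pl in net.places.items():
        seen_here: set[str] = set()
        for tid in pl.token_ids:
            if tid not in net.tokens:
                violations.append(f"place {pid}: unknown token {tid!r}")
                continue
            if tid in seen_here:
                violations.append(f"place {pid}: token {tid} listed twice")
            seen_here.add(tid)
            residence.setdefault(tid, []).append(pid)
    for tid, tok in net.tokens.items():
        homes = residence.get(tid, [])
        if tok.alive:
            if len(homes) != 1:
                violations.append(
                    f"token {tid}: live token resident in {len(homes)} places {homes}"
                )
            elif tok.place != homes[0]:
                violations.append(f"token {tid}: place field {tok.place!r} != residence {homes[0]!r}")
        elif homes:
            violations.append(f"token {tid}: dead token still resident in {homes}")
        ticks = [rec["tick"] for rec in tok.history]
        if any(b < a for a, b in zip(ticks, ticks[1:])):
            violations.append(f"token {tid}: history ticks not non-decreasing: {ticks}")
    return violations


def default_fire_policy(net: GNet, transition: Transition, tick: int) -> list[TraceEvent]:
    """Move each eligible token to its first enabled output column.

    The residency snapshot is taken at the start of the firing, so tokens
    this firing moves into one of its own (later) input places are not
    re-examined.  A self-loop column that is first-enabled means the token
    stays (no event, no freeze).
    """
    events: list[TraceEvent] = []
    snapshot = [
        (src, tid) for src in transition.inputs for tid in list(net.places[src].token_ids)
    ]
    for src, tid in snapshot:
        tok = net.tokens.get(tid)
        if tok is None or tok.place != src or not net.is_eligible(tok, tick):
            continue
        ctx = FiringContext(token=tok, source_place=src, net=net, tick=tick)
        row = im_evaluate_row(transition.condition, src, ctx)
        target = next((col for col, enabled in row if enabled), None)
        if target is None or target == src:
            continue  # nothing enabled, or explicit stay
        events.append(net.transfer(tok, src, target, tick, transition.id))
        hook = net.characteristic_hooks.get(transition.id)
        if hook is not None:
            data = hook(tok, src, target, net, tick)
            if data is not None:
                events.append(
                    net.assign_characteristic(tok, data, tick, transition.id)
                )
    return events


def fire_transition(net: GNet, transition_id: str, tick: int) -> list[TraceEvent]:
    """Fire one transition at the given tick (must equal the net clock)."""
    transition = net.get_transition(transition_id)
    if tick != net.clock:
        raise StructuralError(
            f"clock mismatch: firing {transition_id} at tick {tick}, net clock is {net.clock}"
        )
    policy = transition.on_fire or default_fire_policy
    return policy(net, transition, tick)


def step(net: GNet) -> list[TraceEvent]:
    """Fire every transition once in declared order, then advance the clock."""
    tick = net.clock
    events: list[TraceEvent] = []
    for transition in net.transitions:
        events.extend(fire_transition(net, transition.id, tick))
    net.tick_snapshots.append({"tick": tick, "live": len(net.live_token_ids())})
    net.clock += 1
    return events


@dataclass
class Trace:
    """Auditable ledger of a run: header, events, per-tick live counts, final state."""

    header: dict
    events: list[TraceEvent]
    tick_snapshots: list[dict]
    final_state: dict

    def to_jsonl(self) -> str:
        lines = [canonical_json({"kind": "HEADER", **self.header})]
        ev_iter = iter(self.events)
        pending = next(ev_iter, None)
        for snap in self.tick_snapshots:
            while pending is not None and pending.tick <= snap["tick"]:
                lines.append(canonical_json(pending.to_record()))
                pending = next(ev_iter, None)
            lines.append(canonical_json({"kind": "TICK", "live": snap["live"], "tick": snap["tick"]}))
        while pending is not None:  # pragma: no cover - events never trail the last tick
            lines.append(canonical_json(pending.to_record()))
            pending = next(ev_iter, None)
        lines.append(canonical_json({"kind": "FINAL", **self.final_state}))
        return "\n".join(lines) + "\n"

    @staticmethod
    def parse_jsonl(text: str) -> list[dict]:
        return [json.loads(line) for line in text.splitlines() if line.strip()]


def run(net: GNet, n_ticks: int, seed: int | None = None) -> Trace:
    """Run the net for ``n_ticks`` synchronous ticks.

    Deterministic: with an identical net specification and seed the
    serialized trace is byte-identical across invocations.  The seed feeds
    the single generator stochastic hooks must draw from; the bundled
    physiological net is itself deterministic given its stimulus train.
    """
    if n_ticks < 0:
        raise StructuralError("n_ticks must be >= 0")
    if seed is not None:
        net.rng = random.Random(int(seed))
    initial_live = len(net.live_token_ids())
    for _ in range(n_ticks):
        step(net)
    header = {
        "initial_live": initial_live,
        "schema": TRACE_SCHEMA,
        "seed": seed,
        "ticks": n_ticks,
    }
    return Trace(
        header=header,
        events=list(net.trace_events),
        tick_snapshots=list(net.tick_snapshots),
        final_state=net.final_state(),
    )


def audit_trace(lines_or_trace: Trace | list[dict]) -> list[str]:
    """Conservation-ledger audit of a serialized trace.

    Checks: dense event sequence numbers, non-decreasing ticks, and at
    every tick boundary ``live = initial + splits − unite-deaths − stops``
    against the recorded per-tick live counts; the final snapshot must
    agree with the last tick.  Returns violations (empty when sound).
    """
    if isinstance(lines_or_trace, Trace):
        lines = Trace.parse_jsonl(lines_or_trace.to_jsonl())
    else:
        lines = lines_or_trace
    violations: list[str] = []
    if not lines or lines[0].get("kind") != "HEADER":
        return ["missing HEADER line"]
    header = lines[0]
    live = int(header.get("initial_live", 0))
    expected_seq = 0
    last_tick = -1
    unite_deaths_tick = 0
    unite_stop_tick = 0
    final: dict | None = None
    for line in lines[1:]:
        kind = line.get("kind")
        if kind == "FINAL":
            final = line
            continue
        tick = int(line.get("tick", -1))
        if kind == "TICK":
            if unite_stop_tick != unite_deaths_tick:
                violations.append(
                    f"tick {tick}: UNITE absorbed {unite_deaths_tick} tokens but "
                    f"{unite_stop_tick} unite-STOPs recorded"
                )
            if line.get("live") != live:
                violations.append(
                    f"tick {tick}: ledger expects {live} live tokens, trace records {line.get('live')}"
                )
                live = int(line.get("live", live))
            unite_deaths_tick = unite_stop_tick = 0
            last_tick = max(last_tick, tick)
            continue
        if kind not in EVENT_KINDS:
            violations.append(f"unknown line kind {kind!r}")
            continue
        if line.get("seq") != expected_seq:
            violations.append(
                f"sequence gap at tick {tick}: expected seq {expected_seq}, found {line.get('seq')}"
            )
            expected_seq = int(line.get("seq", expected_seq))
        expected_seq += 1
        if tick < last_tick:
            violations.append(f"event at tick {tick} after tick {last_tick}")
        last_tick = max(last_tick, tick)
        payload = line.get("payload", {})
        if kind == SPLIT:
            live += len(payload.get("children", []))
        elif kind == UNITE:
            unite_deaths_tick += len(payload.get("absorbed", []))
        elif kind == STOP:
            live -= 1
            if payload.get("cause") == "unite":
                unite_stop_tick += 1
    if final is None:
        violations.append("missing FINAL snapshot")
    else:
        final_live = sum(1 for rec in final.get("tokens", {}).values() if rec.get("alive"))
        if final_live != live:
            violations.append(
                f"final snapshot has {final_live} live tokens, ledger expects {live}"
            )
    return violations
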