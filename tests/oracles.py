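"""Independent reference implementations used as test oracles.

Everything here is deliberately naive: the brute-force firing reference
enumerates (input place, token, output place) triples over an explicit
marking dictionary and never touches the engine's data structures, so it
can adjudicate the engine's routing semantics.
"""

from __future__ import annotations

import random

from fopnet.gn_engine import GNet, TRANSFER, STOP, Transition
from fopnet.im_core import ALWAYS_FALSE, ALWAYS_TRUE, make_index_matrix


def random_net_description(rng: random.Random) -> dict:
    """A small random net: constant true/false conditions, default policy."""
    n_places = rng.randint(2, 8)
    places = [f"p{i}" for i in range(n_places)]
    transitions = []
    for t in range(rng.randint(1, 4)):
        inputs = rng.sample(places, rng.randint(1, min(3, n_places)))
        outputs = rng.sample(places, rng.randint(1, min(3, n_places)))
        cells = {
            (i, o): rng.random() < 0.5 for i in inputs for o in outputs
        }
        transitions.append(
            {"id": f"T{t}", "inputs": inputs, "outputs": outputs, "cells": cells}
        )
    tokens = [f"x{i}" for i in range(rng.randint(0, 6))]
    marking = {pl: [] for pl in places}
    for label in tokens:
        marking[rng.choice(places)].append(label)
    return {"places": places, "transitions": transitions, "marking": marking}


def materialize(desc: dict) -> tuple[GNet, dict[str, str]]:
    """Build an engine net from a description; returns (net, label -> token id)."""
    net = GNet()
    for pl in desc["places"]:
        net.add_place(pl)
    for tr in desc["transitions"]:
        entries = [
            (i, o, ALWAYS_TRUE if enabled else ALWAYS_FALSE)
            for (i, o), enabled in tr["cells"].items()
        ]
        net.add_transition(
            Transition(
                id=tr["id"],
                inputs=list(tr["inputs"]),
                outputs=list(tr["outputs"]),
                condition=make_index_matrix(list(tr["inputs"]), list(tr["outputs"]), entries),
            )
        )
    id_map: dict[str, str] = {}
    for pl in desc["places"]:
        for label in desc["marking"][pl]:
            tok = net.new_token(label, pl)
            id_map[label] = tok.id
    return net, id_map


def reference_fire(marking: dict, transition: dict, frozen: set) -> dict:
    """Brute-force single-firing reference for the default routing policy.

    A residency snapshot is taken first; each non-frozen token moves to the
    first output column (declared order) whose condition cell is true, a
    first-enabled self-loop meaning "stay".  Tokens that move are added to
    ``frozen`` (the engine's moved-this-tick rule).
    """
    marking = {pl: list(toks) for pl, toks in marking.items()}
    snapshot = [(src, tok) for src in transition["inputs"] for tok in marking[src]]
    for src, tok in snapshot:
        if tok in frozen or tok not in marking[src]:
            continue
        target = next(
            (o for o in transition["outputs"] if transition["cells"].get((src, o), False)),
            None,
        )
        if target is None or target == src:
            continue
        marking[src].remove(tok)
        marking[target].append(tok)
        frozen.add(tok)
    return marking


def engine_marking(net: GNet, id_map: dict[str, str]) -> dict:
    """The engine's marking expressed in reference token labels."""
    reverse = {v: k for k, v in id_map.items()}
    return {
        pid: [reverse[tid] for tid in pl.token_ids] for pid, pl in net.places.items()
    }


# --------------------------------------------------------------------------
# trace scans


def exclusivity_violations(net: GNet) -> int:
    """Each impact token processed by a receptor must take exactly one branch.

    A supra-threshold impact transfers to the pass place ``i{k}_2``; a
    sub-threshold one transfers to the loop place ``i{k}_3`` and stops by
    union.  Any impact token with zero or two branch outcomes after being
    examined is a violation.
    """
    branches: dict[str, list[str]] = {}
    for ev in net.trace_events:
        if ev.kind != TRANSFER or not (ev.transition_id or "").startswith("I"):
            continue
        tok = ev.token_ids[0]
        if not tok.startswith("ε-"):
            continue
        assert ev.target_place is not None
        branch = "pass" if ev.target_place.endswith("_2") else "absorb"
        branches.setdefault(tok, []).append(branch)
    violations = sum(1 for b in branches.values() if len(b) != 1)
    # an absorbed token must also have stopped functioning
    stopped = {
        ev.token_ids[0]
        for ev in net.trace_events
        if ev.kind == STOP and ev.token_ids[0].startswith("ε-")
    }
    violations += sum(
        1 for tok, b in branches.items() if b == ["absorb"] and tok not in stopped
    )
    return violations


def same_tick_double_moves(net: GNet) -> list[str]:
    """Token ids transferred twice within one tick via different transitions."""
    seen: dict[tuple[str, int], set[str]] = {}
    out = []
    for ev in net.trace_events:
        if ev.kind != TRANSFER:
            continue
        key = (ev.token_ids[0], ev.tick)
        trs = seen.setdefault(key, set())
        trs.add(ev.transition_id or "")
        if len(trs) > 1:
            out.append(ev.token_ids[0])
    return out
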