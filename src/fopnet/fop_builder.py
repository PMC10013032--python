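"""Factory for the foreign-object stimulus–response net.

The foreign-object principle says a system functions by accepting foreign
objects from its environment and emitting objects back into it.  The net
built here realizes that loop for a system with *m* thresholded receptors,
*n* internal processing components and *p* effectors:

* ``En0``/``En1``/``En2`` are the environment: ``En0`` injects one impact
  token ε per pending stimulus and absorbs the system's total reaction ζ;
  ``En1`` routes each ε to the receptor that registers it; ``En2`` fuses
  effector outputs φ′ into ζ.
* ``I_k`` is the k-th receptor: an ε whose strength exceeds the receptor's
  current threshold (carried by the resident token τ_k) passes inward;
  otherwise it is absorbed by τ_k — registered but not transmitted — and
  stops functioning.  Feedback tokens κ arriving from the system core
  rewrite τ_k's threshold.
* ``S`` is the system core: the resident status token ω absorbs arriving
  registrations (ε) and component responses (σ′), and splits off work
  orders σ to components, reaction orders π to effectors, and threshold
  updates κ to receptors.
* ``S_k``/``O_k`` are the k-th component/effector: a delay line that holds
  arrivals and releases a response (σ′ / φ′) after a configured number of
  ticks.

The net has ``m + n + p + 3`` transitions, ``4m + 3(n + p + 1) + 1`` places
and six declared token types (ε*, ε, ω, φ, τ, κ); σ, σ′, π, φ′ and ζ are
derived in-flight from splits and unions of those six.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .gn_engine import GNet, Token, TraceEvent, Transition
from .im_core import (
    ALWAYS_TRUE,
    FiringContext,
    PredicateRef,
    StructuralError,
    im_evaluate_row,
    make_index_matrix,
)

logger = logging.getLogger("fopnet")

# token type tags
EPS_STAR = "ε*"  # information about the environment (resident in e0)
EPS = "ε"  # information about one impact of the environment on the system
OMEGA = "ω"  # information about the system status (resident in s)
PHI = "φ"  # information about an effector (resident in o_k3)
TAU = "τ"  # receptor threshold carrier (resident in i_k3)
KAPPA = "κ"  # system signal changing a receptor threshold
SIGMA = "σ"  # work order to a system component
SIGMA_P = "σ′"  # component response
PI = "π"  # reaction order to an effector
PHI_P = "φ′"  # effector output
ZETA = "ζ"  # total system reaction

#: the six declared token roles; the derived tags above are split/union products
DECLARED_TOKEN_TYPES = (EPS_STAR, EPS, OMEGA, PHI, TAU, KAPPA)

# canonical characteristic labels
CH_RESULT = "a result of the impact of the system over the environment"
CH_REGISTERED = "an impact is registered by the k-th receptor/sensor, parameters"
CH_NEW_THRESHOLD = "new value of the threshold of the respective receptor/sensor"
CH_REGISTRATION = "registration of the impact, parameters"
CH_PART_REACTION = "reaction of the respective part of the system to the corresponding impact"
CH_MUST_PROCESS = "the current impact must be processed by the respective part of the system"
CH_TO_EFFECTOR = "the prepared by the system reaction must be directed to the respective effector"
CH_RESPONSE = "response to the registered impact, parameters"
CH_EFFECTOR_REACTION = "system reaction for the k-th effector, parameters"
CH_TOTAL_REACTION = "total system reaction, parameters"


@dataclass
class Stimulus:
    """One impact of the environment on the system."""

    tick: int
    modality: str = "default"
    strength: float = 0.0
    payload: dict = field(default_factory=dict)


@dataclass
class AdaptationRule:
    """How receptor thresholds change in response to registered impacts.

    ``kind="multiplicative"`` rescales the threshold by ``gamma`` per
    trigger; ``trigger`` selects which registrations count: sub-threshold
    ones, supra-threshold ones, or any.  ``kind="none"`` disables feedback
    entirely (thresholds stay constant).
    """

    kind: str = "none"  # "none" | "multiplicative"
    gamma: float = 0.8
    trigger: str = "any"  # "any" | "sub" | "supra"

    def validate(self) -> None:
        if self.kind not in ("none", "multiplicative"):
            raise StructuralError(f"unknown adaptation rule {self.kind!r}")
        if self.trigger not in ("any", "sub", "supra"):
            raise StructuralError(f"unknown adaptation trigger {self.trigger!r}")
        if self.kind == "multiplicative" and not (
            math.isfinite(self.gamma) and self.gamma > 0
        ):
            raise StructuralError("multiplicative gamma must be finite and > 0")

    def active(self) -> bool:
        return self.kind != "none"

    def wants(self, relation: str) -> bool:
        """Does a registration of this kind ("sub"/"supra") trigger adaptation?"""
        return self.active() and self.trigger in ("any", relation)

    def propose(self, base: float, n_triggers: int) -> float:
        if self.kind == "multiplicative":
            return base * self.gamma**n_triggers
        return base


@dataclass
class FOPConfig:
    """Parameters of the stimulus–response net.

    ``routing`` maps a stimulus modality to the (1-based) receptor that
    registers it; the key ``"*"`` is a wildcard.  ``component_policy`` and
    ``effector_policy`` map a modality to the component/effector subsets
    that process it ("all" broadcasts).  Delays are in ticks.
    """

    m: int = 1
    n: int = 1
    p: int = 1
    initial_thresholds: list[float] | None = None
    processing_delays: list[int] | None = None
    effector_delays: list[int] | None = None
    routing: dict[str, int] = field(default_factory=lambda: {"*": 1})
    adaptation: AdaptationRule = field(default_factory=AdaptationRule)
    component_policy: str | dict[str, list[int]] = "all"
    effector_policy: str | dict[str, list[int]] = "all"

    def validate(self) -> "FOPConfig":
        for name, value in (("m", self.m), ("n", self.n), ("p", self.p)):
            if not isinstance(value, int) or value < 1:
                raise StructuralError(f"{name} must be an integer >= 1, got {value!r}")
        if self.initial_thresholds is None:
            self.initial_thresholds = [3.0] * self.m
        if self.processing_delays is None:
            self.processing_delays = [1] * self.n
        if self.effector_delays is None:
            self.effector_delays = [1] * self.p
        if len(self.initial_thresholds) != self.m:
            raise StructuralError(
                f"initial_thresholds has {len(self.initial_thresholds)} entries, expected m={self.m}"
            )
        if len(self.processing_delays) != self.n:
            raise StructuralError(
                f"processing_delays has {len(self.processing_delays)} entries, expected n={self.n}"
            )
        if len(self.effector_delays) != self.p:
            raise StructuralError(
                f"effector_delays has {len(self.effector_delays)} entries, expected p={self.p}"
            )
        for theta in self.initial_thresholds:
            if not (math.isfinite(theta) and theta >= 0):
                raise StructuralError(f"thresholds must be finite and >= 0, got {theta!r}")
        for d in [*self.processing_delays, *self.effector_delays]:
            if not isinstance(d, int) or d < 1:
                raise StructuralError(f"delays must be integer ticks >= 1, got {d!r}")
        for mod, k in self.routing.items():
            if not (1 <= k <= self.m):
                raise StructuralError(f"routing[{mod!r}]={k} outside receptor range 1..{self.m}")
        self.adaptation.validate()
        for name, policy, upper in (
            ("component_policy", self.component_policy, self.n),
            ("effector_policy", self.effector_policy, self.p),
        ):
            if policy == "all":
                continue
            if not isinstance(policy, dict):
                raise StructuralError(f'{name} must be "all" or a modality mapping')
            for mod, targets in policy.items():
                for k in targets:
                    if not (1 <= k <= upper):
                        raise StructuralError(
                            f"{name}[{mod!r}] target {k} outside range 1..{upper}"
                        )
        return self


def _route(routing: dict[str, int], modality: str | None) -> int | None:
    if modality in routing:
        return routing[modality]  # type: ignore[index]
    return routing.get("*")


def _policy_targets(policy: str | dict[str, list[int]], modality: str | None, upper: int) -> set[int]:
    if policy == "all":
        return set(range(1, upper + 1))
    assert isinstance(policy, dict)
    if modality in policy:
        return set(policy[modality])  # type: ignore[index]
    return set(policy.get("*", []))


def threshold_update(tau_token: Token, proposed: float) -> float:
    """Install a new threshold on a receptor's τ token.

    The proposed value must be finite and non-negative; the token's
    ``meta["threshold"]`` (consulted by the supra/sub-threshold predicate)
    is updated and the value returned.  History recording is the caller's
    job so the characteristic carries the transition that assigned it.
    """
    if not (isinstance(proposed, (int, float)) and math.isfinite(proposed)):
        raise StructuralError(f"proposed threshold must be finite, got {proposed!r}")
    if proposed < 0:
        raise StructuralError(f"proposed threshold must be >= 0, got {proposed!r}")
    tau_token.meta["threshold"] = float(proposed)
    return float(proposed)


def _fop(net: GNet) -> dict:
    return net.aux["fop"]


def _tau(net: GNet, k: int) -> Token:
    return net.tokens[_fop(net)["tau_ids"][k]]


def _phi(net: GNet, k: int) -> Token:
    return net.tokens[_fop(net)["phi_ids"][k]]


# --------------------------------------------------------------------------
# predicate hooks

def default_hooks(config: FOPConfig) -> dict[str, PredicateRef]:
    """The predicate set gating the net's index matrices.

    Each predicate's description is its plain-language condition; the
    evaluators only read net state (thresholds live on the τ tokens,
    delay bookkeeping on the σ/φ tokens, pending split decisions in the
    core-transition firing context).
    """
    hooks: dict[str, PredicateRef] = {}

    def w01(tok, src, dst, net, tick):
        fop = _fop(net)
        i = fop["next_stimulus"]
        return i < len(fop["stimuli"]) and fop["stimuli"][i].tick <= tick

    hooks["W_0_1"] = PredicateRef(
        "W_0_1", "there is an impact from the environment to the system", w01
    )

    for k in range(1, config.m + 1):
        def w1k1(tok, src, dst, net, tick, k=k):
            return _route(_fop(net)["config"].routing, tok.meta.get("modality")) == k

        hooks[f"W_1_{k}_1"] = PredicateRef(
            f"W_1_{k}_1",
            f"the current impact is registered by the {k}-th receptor/sensor",
            w1k1,
        )

        def w1k2(tok, src, dst, net, tick, k=k):
            # strictly greater-than: equality stays sub-threshold
            return tok.meta.get("strength", 0.0) > _tau(net, k).meta["threshold"]

        def w1k3(tok, src, dst, net, tick, k=k):
            return not w1k2(tok, src, dst, net, tick)

        hooks[f"W_1_{k}_2"] = PredicateRef(
            f"W_1_{k}_2",
            f"the strength of the impact is greater than the threshold of the {k}-th "
            f"receptor/sensor, determined as current characteristic of token τ_{k}",
            w1k2,
        )
        hooks[f"W_1_{k}_3"] = PredicateRef(
            f"W_1_{k}_3", f"negation of W_1_{k}_2", w1k3
        )

    for k in range(1, config.n + 1):
        def vsk(tok, src, dst, net, tick, k=k):
            ctx = _fop(net).get("s_ctx") or {}
            return k in ctx.get("component_targets", ())

        hooks[f"V_s_{k}"] = PredicateRef(
            f"V_s_{k}",
            f"the registered impact must be processed by the {k}-th system component",
            vsk,
        )

        def u3k2(tok, src, dst, net, tick, k=k):
            arrived = tok.meta.get("arrived")
            delay = _fop(net)["config"].processing_delays[k - 1]
            return (
                arrived is not None
                and not tok.meta.get("spent", False)
                and tick - arrived >= delay
            )

        hooks[f"U_3_{k}_2"] = PredicateRef(
            f"U_3_{k}_2",
            f"the {k}-th system component is ready with generated response to the registered impact",
            u3k2,
        )

    for k in range(1, config.p + 1):
        def vok(tok, src, dst, net, tick, k=k):
            ctx = _fop(net).get("s_ctx") or {}
            return k in ctx.get("effector_targets", ())

        hooks[f"V_o_{k}"] = PredicateRef(
            f"V_o_{k}",
            f"a new impact of the system over the environment may occur through the {k}-th effector",
            vok,
        )

        def t3k2(tok, src, dst, net, tick, k=k):
            delay = _fop(net)["config"].effector_delays[k - 1]
            return any(tick - item["arrived"] >= delay for item in tok.meta.get("queue", []))

        hooks[f"T_3_{k}_2"] = PredicateRef(
            f"T_3_{k}_2", f"there is a ready system reaction for the {k}-th effector", t3k2
        )

    for k in range(1, config.m + 1):
        def vik(tok, src, dst, net, tick, k=k):
            fop = _fop(net)
            return fop["config"].adaptation.active() and fop["pending_adapt"][k - 1] > 0

        hooks[f"V_i_{k}"] = PredicateRef(
            f"V_i_{k}",
            f"the value of the threshold of the {k}-th receptor/sensor must be changed",
            vik,
        )

    return hooks


# --------------------------------------------------------------------------
# transition firing policies

def _en0_policy(net: GNet, transition: Transition, tick: int) -> list[TraceEvent]:
    fop = _fop(net)
    events: list[TraceEvent] = []
    eps_star = net.tokens[fop["eps_star_id"]]
    # a returning total-reaction token is absorbed by the environment token
    for tok in net.eligible_tokens("e2", tick, type_tags=(ZETA,)):
        events.append(net.transfer(tok, "e2", "e0", tick, transition.id))
        events.extend(net.unite([eps_star.id, tok.id], eps_star.id, tick, transition.id))
        events.append(
            net.assign_characteristic(
                eps_star,
                {"stimuli": sorted(tok.meta.get("stimulus_ids", ())), "tick": tick},
                tick,
                transition.id,
                label=CH_RESULT,
            )
        )
    # one ε child per stimulus due at this tick; the environment token never leaves e0
    stimuli = fop["stimuli"]
    while fop["next_stimulus"] < len(stimuli) and stimuli[fop["next_stimulus"]].tick <= tick:
        idx = fop["next_stimulus"]
        fop["next_stimulus"] = idx + 1
        st = stimuli[idx]
        ev, (child_id,) = net.split(
            eps_star.id,
            [(EPS, {"stimulus": idx, "modality": st.modality, "strength": st.strength,
                    "stimulus_tick": st.tick})],
            tick,
            transition.id,
            label="information about the impact from the environment to the system",
        )
        child = net.tokens[child_id]
        child.meta.update(
            stimulus_index=idx,
            modality=st.modality,
            strength=float(st.strength),
            stimulus_ids=frozenset({idx}),
            stimulus_tick=st.tick,
        )
        events.append(ev)
        events.append(net.transfer(child, "e0", "e1", tick, transition.id))
    return events


def _en1_policy(net: GNet, transition: Transition, tick: int) -> list[TraceEvent]:
    fop = _fop(net)
    config: FOPConfig = fop["config"]
    events: list[TraceEvent] = []
    for tok in net.eligible_tokens("e1", tick, type_tags=(EPS,)):
        ctx = FiringContext(token=tok, source_place="e1", net=net, tick=tick)
        target = next(
            (col for col, enabled in im_evaluate_row(transition.condition, "e1", ctx) if enabled),
            None,
        )
        if target is None:
            # no drop rule exists for an unmatched stimulus: the token stays put
            if not tok.meta.get("unrouted_warned"):
                tok.meta["unrouted_warned"] = True
                logger.warning(
                    "stimulus %s (modality %r) matches no receptor; token stays in e1",
                    tok.id,
                    tok.meta.get("modality"),
                )
            continue
        events.append(net.transfer(tok, "e1", target, tick, transition.id))
    return events


def _make_i_policy(k: int):
    def policy(net: GNet, transition: Transition, tick: int) -> list[TraceEvent]:
        fop = _fop(net)
        config: FOPConfig = fop["config"]
        events: list[TraceEvent] = []
        tau = _tau(net, k)
        p_in, p_pass, p_hold, p_fb = f"i{k}_1", f"i{k}_2", f"i{k}_3", f"i{k}"
        for tok in net.eligible_tokens(p_in, tick, type_tags=(EPS,)):
            ctx = FiringContext(token=tok, source_place=p_in, net=net, tick=tick)
            row = dict(im_evaluate_row(transition.condition, p_in, ctx))
            supra = row[p_pass]
            theta = tau.meta["threshold"]
            fop["receptor_log"].append(
                {
                    "stimulus": tok.meta.get("stimulus_index"),
                    "tick": tick,
                    "receptor": k,
                    "strength": tok.meta.get("strength", 0.0),
                    "threshold": theta,
                    "passed": supra,
                }
            )
            if supra:
                # passes inward without a new characteristic
                events.append(net.transfer(tok, p_in, p_pass, tick, transition.id))
            else:
                # registered but not transmitted: absorbed by the threshold token
                events.append(net.transfer(tok, p_in, p_hold, tick, transition.id))
                events.extend(net.unite([tau.id, tok.id], tau.id, tick, transition.id))
                events.append(
                    net.assign_characteristic(
                        tau,
                        {
                            "time_moment": tick,
                            "strength": tok.meta.get("strength", 0.0),
                            "relation": "under",
                            "threshold": theta,
                            "stimulus": tok.meta.get("stimulus_index"),
                            "receptor": k,
                        },
                        tick,
                        transition.id,
                        label=CH_REGISTERED,
                    )
                )
                if config.adaptation.wants("sub"):
                    fop["pending_adapt"][k - 1] += 1
        # feedback: a κ token rewrites the receptor threshold
        for tok in net.eligible_tokens(p_fb, tick, type_tags=(KAPPA,)):
            events.append(net.transfer(tok, p_fb, p_hold, tick, transition.id))
            new_theta = threshold_update(tau, tok.meta["new_threshold"])
            events.extend(net.unite([tau.id, tok.id], tau.id, tick, transition.id))
            events.append(
                net.assign_characteristic(
                    tau,
                    {"threshold": new_theta, "receptor": k},
                    tick,
                    transition.id,
                    label=CH_NEW_THRESHOLD,
                )
            )
        # the τ token itself stays in its loop place (reconstructed loop arc)
        return events

    return policy


def _s_policy(net: GNet, transition: Transition, tick: int) -> list[TraceEvent]:
    fop = _fop(net)
    config: FOPConfig = fop["config"]
    events: list[TraceEvent] = []
    omega = net.tokens[fop["omega_id"]]
    impacts: list[dict] = []
    responses: list[dict] = []
    # phase 1: absorb arrivals into the status token
    for k in range(1, config.m + 1):
        for tok in net.eligible_tokens(f"i{k}_2", tick, type_tags=(EPS,)):
            events.append(net.transfer(tok, f"i{k}_2", "s", tick, transition.id))
            events.extend(net.unite([omega.id, tok.id], omega.id, tick, transition.id))
            events.append(
                net.assign_characteristic(
                    omega,
                    {
                        "stimulus": tok.meta.get("stimulus_index"),
                        "modality": tok.meta.get("modality"),
                        "strength": tok.meta.get("strength", 0.0),
                        "receptor": k,
                        "time_moment": tick,
                    },
                    tick,
                    transition.id,
                    label=CH_REGISTRATION,
                )
            )
            impacts.append(
                {
                    "ids": set(tok.meta.get("stimulus_ids", ())),
                    "modality": tok.meta.get("modality"),
                    "receptor": k,
                }
            )
            if config.adaptation.wants("supra"):
                fop["pending_adapt"][k - 1] += 1
    for k in range(1, config.n + 1):
        for tok in net.eligible_tokens(f"s{k}_2", tick, type_tags=(SIGMA_P,)):
            events.append(net.transfer(tok, f"s{k}_2", "s", tick, transition.id))
            events.extend(net.unite([omega.id, tok.id], omega.id, tick, transition.id))
            events.append(
                net.assign_characteristic(
                    omega,
                    {"component": k, "stimuli": sorted(tok.meta.get("stimulus_ids", ()))},
                    tick,
                    transition.id,
                    label=CH_PART_REACTION,
                )
            )
            responses.append(
                {
                    "ids": set(tok.meta.get("stimulus_ids", ())),
                    "modalities": set(tok.meta.get("modalities", ())),
                    "component": k,
                }
            )
    # phase 2: split work orders / reaction orders / threshold updates off ω
    comp_targets: dict[int, dict] = {}
    for imp in impacts:
        for k in _policy_targets(config.component_policy, imp["modality"], config.n):
            entry = comp_targets.setdefault(k, {"ids": set(), "modalities": set()})
            entry["ids"] |= imp["ids"]
            if imp["modality"] is not None:
                entry["modalities"].add(imp["modality"])
    eff_targets: dict[int, dict] = {}
    for resp in responses:
        modalities = resp["modalities"] or {None}
        for modality in modalities:
            for k in _policy_targets(config.effector_policy, modality, config.p):
                entry = eff_targets.setdefault(k, {"ids": set(), "modalities": set()})
                entry["ids"] |= resp["ids"]
                entry["modalities"] |= resp["modalities"]
    fop["s_ctx"] = {
        "component_targets": set(comp_targets),
        "effector_targets": set(eff_targets),
    }
    try:
        ctx = FiringContext(token=omega, source_place="s", net=net, tick=tick)
        row = dict(im_evaluate_row(transition.condition, "s", ctx))
        for k in range(1, config.n + 1):
            if not row[f"s{k}_1"]:
                continue
            entry = comp_targets[k]
            ev, (cid,) = net.split(
                omega.id,
                [(SIGMA, {"component": k, "stimuli": sorted(entry["ids"])})],
                tick,
                transition.id,
                label=CH_MUST_PROCESS,
            )
            child = net.tokens[cid]
            child.meta.update(
                stimulus_ids=frozenset(entry["ids"]), modalities=frozenset(entry["modalities"])
            )
            events.append(ev)
            events.append(net.transfer(child, "s", f"s{k}_1", tick, transition.id))
        for k in range(1, config.p + 1):
            if not row[f"o{k}_1"]:
                continue
            entry = eff_targets[k]
            ev, (cid,) = net.split(
                omega.id,
                [(PI, {"effector": k, "stimuli": sorted(entry["ids"])})],
                tick,
                transition.id,
                label=CH_TO_EFFECTOR,
            )
            child = net.tokens[cid]
            child.meta.update(
                stimulus_ids=frozenset(entry["ids"]), modalities=frozenset(entry["modalities"])
            )
            events.append(ev)
            events.append(net.transfer(child, "s", f"o{k}_1", tick, transition.id))
        for k in range(1, config.m + 1):
            if not row[f"i{k}"]:
                continue
            n_triggers = fop["pending_adapt"][k - 1]
            # propose from the last proposed value so j triggers give θ0·γ^j
            # even while an earlier κ is still in transit
            new_theta = config.adaptation.propose(fop["proposed_threshold"][k - 1], n_triggers)
            fop["proposed_threshold"][k - 1] = new_theta
            fop["pending_adapt"][k - 1] = 0
            ev, (cid,) = net.split(
                omega.id,
                [(KAPPA, {"receptor": k, "threshold": new_theta})],
                tick,
                transition.id,
                label=CH_NEW_THRESHOLD,
            )
            child = net.tokens[cid]
            child.meta["new_threshold"] = new_theta
            events.append(ev)
            events.append(net.transfer(child, "s", f"i{k}", tick, transition.id))
    finally:
        fop["s_ctx"] = None
    return events


def _make_sk_policy(k: int):
    def policy(net: GNet, transition: Transition, tick: int) -> list[TraceEvent]:
        events: list[TraceEvent] = []
        p_in, p_out, p_hold = f"s{k}_1", f"s{k}_2", f"s{k}_3"
        for tok in net.eligible_tokens(p_in, tick, type_tags=(SIGMA,)):
            events.append(net.transfer(tok, p_in, p_hold, tick, transition.id))
            tok.meta["arrived"] = tick
        for tok in net.eligible_tokens(p_hold, tick, type_tags=(SIGMA,)):
            ctx = FiringContext(token=tok, source_place=p_hold, net=net, tick=tick)
            row = dict(im_evaluate_row(transition.condition, p_hold, ctx))
            if not row[p_out]:
                continue
            ev, (cid,) = net.split(
                tok.id,
                [(SIGMA_P, {"component": k, "stimuli": sorted(tok.meta.get("stimulus_ids", ()))})],
                tick,
                transition.id,
                label=CH_RESPONSE,
            )
            child = net.tokens[cid]
            child.meta.update(
                stimulus_ids=tok.meta.get("stimulus_ids", frozenset()),
                modalities=tok.meta.get("modalities", frozenset()),
            )
            events.append(ev)
            events.append(net.transfer(child, p_hold, p_out, tick, transition.id))
            tok.meta["spent"] = True  # each work order yields exactly one response
        return events

    return policy


def _make_o_policy(k: int):
    def policy(net: GNet, transition: Transition, tick: int) -> list[TraceEvent]:
        fop = _fop(net)
        events: list[TraceEvent] = []
        phi = _phi(net, k)
        p_in, p_out, p_hold = f"o{k}_1", f"o{k}_2", f"o{k}_3"
        for tok in net.eligible_tokens(p_in, tick, type_tags=(PI,)):
            events.append(net.transfer(tok, p_in, p_hold, tick, transition.id))
            # the reaction order is absorbed by the effector token (convention
            # mirroring the receptor's τ union; the source prose leaves this
            # arrival unspecified)
            ids = tok.meta.get("stimulus_ids", frozenset())
            modalities = tok.meta.get("modalities", frozenset())
            events.extend(net.unite([phi.id, tok.id], phi.id, tick, transition.id))
            phi.meta.setdefault("queue", []).append(
                {"arrived": tick, "ids": set(ids), "modalities": set(modalities)}
            )
            events.append(
                net.assign_characteristic(
                    phi,
                    {"effector": k, "staged": tick, "stimuli": sorted(ids)},
                    tick,
                    transition.id,
                    label="reaction staged at the k-th effector",
                )
            )
        if net.is_eligible(phi, tick):
            ctx = FiringContext(token=phi, source_place=p_hold, net=net, tick=tick)
            row = dict(im_evaluate_row(transition.condition, p_hold, ctx))
            if row[p_out]:
                delay = fop["config"].effector_delays[k - 1]
                queue = phi.meta.get("queue", [])
                ready_idx = next(
                    i for i, item in enumerate(queue) if tick - item["arrived"] >= delay
                )
                item = queue.pop(ready_idx)
                ev, (cid,) = net.split(
                    phi.id,
                    [(PHI_P, {"effector": k, "stimuli": sorted(item["ids"])})],
                    tick,
                    transition.id,
                    label=CH_EFFECTOR_REACTION,
                )
                child = net.tokens[cid]
                child.meta.update(
                    stimulus_ids=frozenset(item["ids"]),
                    modalities=frozenset(item["modalities"]),
                    effector=k,
                )
                events.append(ev)
                events.append(net.transfer(child, p_hold, p_out, tick, transition.id))
        return events

    return policy


def _en2_policy(net: GNet, transition: Transition, tick: int) -> list[TraceEvent]:
    fop = _fop(net)
    config: FOPConfig = fop["config"]
    events: list[TraceEvent] = []
    arrivals: list[Token] = []
    for k in range(1, config.p + 1):
        arrivals.extend(net.eligible_tokens(f"o{k}_2", tick, type_tags=(PHI_P,)))
    if not arrivals:
        return events
    for tok in arrivals:
        assert tok.place is not None
        events.append(net.transfer(tok, tok.place, "e2", tick, transition.id))
    host = arrivals[0]
    ids: set[int] = set()
    effectors: set[int] = set()
    for tok in arrivals:
        ids |= set(tok.meta.get("stimulus_ids", ()))
        if "effector" in tok.meta:
            effectors.add(tok.meta["effector"])
    if len(arrivals) > 1:
        events.extend(net.unite([t.id for t in arrivals], host.id, tick, transition.id))
    # whatever effector outputs are present fuse into the total reaction;
    # the host token takes on the ζ role (its id keeps the birth tag)
    host.type_tag = ZETA
    host.meta["stimulus_ids"] = frozenset(ids)
    events.append(
        net.assign_characteristic(
            host,
            {"stimuli": sorted(ids), "effectors": sorted(effectors), "tick": tick},
            tick,
            transition.id,
            label=CH_TOTAL_REACTION,
        )
    )
    fop["zeta_events"].append(
        {"tick": tick, "token": host.id, "stimulus_ids": sorted(ids)}
    )
    return events


# --------------------------------------------------------------------------
# the builder

def build_fop_net(config: FOPConfig) -> GNet:
    """Build the stimulus–response net for a validated configuration.

    Resident tokens: ε* in ``e0`` (the environment), ω in ``s`` (system
    status), τ_k in ``i{k}_3`` carrying the k-th receptor threshold, φ_k in
    ``o{k}_3`` for the k-th effector.  Stimuli are attached afterwards with
    :func:`set_stimuli`.
    """
    config.validate()
    hooks = default_hooks(config)
    net = GNet()
    m, n, p = config.m, config.n, config.p

    net.add_place("e0", role="environment")
    net.add_place("e1", role="environment")
    net.add_place("e2", role="environment")
    net.add_place("s", role="system-core")
    for k in range(1, m + 1):
        net.add_place(f"i{k}_1", role="receptor-input")
        net.add_place(f"i{k}_2", role="receptor-pass")
        net.add_place(f"i{k}_3", role="receptor-loop")
        net.add_place(f"i{k}", role="receptor-feedback")
    for k in range(1, n + 1):
        net.add_place(f"s{k}_1", role="component-input")
        net.add_place(f"s{k}_2", role="component-output")
        net.add_place(f"s{k}_3", role="component-loop")
    for k in range(1, p + 1):
        net.add_place(f"o{k}_1", role="effector-input")
        net.add_place(f"o{k}_2", role="effector-output")
        net.add_place(f"o{k}_3", role="effector-loop")

    eps_star = net.new_token(EPS_STAR, "e0", {"environment": "initial"}, label="information about the environment")
    omega = net.new_token(OMEGA, "s", {"status": "initial"}, label="information about the system status")
    tau_ids: dict[int, str] = {}
    for k in range(1, m + 1):
        tau = net.new_token(
            TAU,
            f"i{k}_3",
            {"threshold": config.initial_thresholds[k - 1], "receptor": k},
            label="information about thresholds of the receptors/sensors",
        )
        tau.meta["threshold"] = float(config.initial_thresholds[k - 1])
        tau_ids[k] = tau.id
    phi_ids: dict[int, str] = {}
    for k in range(1, p + 1):
        phi = net.new_token(
            PHI, f"o{k}_3", {"effector": k}, label="information about the effector"
        )
        phi.meta["queue"] = []
        phi_ids[k] = phi.id

    net.aux["fop"] = {
        "config": config,
        "stimuli": [],
        "next_stimulus": 0,
        "pending_adapt": [0] * m,
        "proposed_threshold": [float(t) for t in config.initial_thresholds],
        "eps_star_id": eps_star.id,
        "omega_id": omega.id,
        "tau_ids": tau_ids,
        "phi_ids": phi_ids,
        "receptor_log": [],
        "zeta_events": [],
        "s_ctx": None,
        "declared_token_types": DECLARED_TOKEN_TYPES,
        "hooks": hooks,
    }

    # En0 = ⟨{e0,e2},{e0,e1}⟩ — the loop cell r(e0,e0) is reconstructed from
    # the resident-environment-token reading, not printed in the source
    net.add_transition(
        Transition(
            id="En0",
            inputs=["e0", "e2"],
            outputs=["e0", "e1"],
            condition=make_index_matrix(
                ["e0", "e2"],
                ["e0", "e1"],
                [
                    ("e0", "e1", hooks["W_0_1"]),
                    ("e0", "e0", ALWAYS_TRUE),
                    ("e2", "e0", ALWAYS_TRUE),
                ],
            ),
            on_fire=_en0_policy,
        )
    )
    net.add_transition(
        Transition(
            id="En1",
            inputs=["e1"],
            outputs=[f"i{k}_1" for k in range(1, m + 1)],
            condition=make_index_matrix(
                ["e1"],
                [f"i{k}_1" for k in range(1, m + 1)],
                [("e1", f"i{k}_1", hooks[f"W_1_{k}_1"]) for k in range(1, m + 1)],
            ),
            on_fire=_en1_policy,
        )
    )
    for k in range(1, m + 1):
        # loop cells r(i{k}_3, i{k}_3) and the κ arc r(i{k}, i{k}_3) are
        # reconstructed from the surrounding prose (figure matrix unreadable)
        net.add_transition(
            Transition(
                id=f"I{k}",
                inputs=[f"i{k}_1", f"i{k}_3", f"i{k}"],
                outputs=[f"i{k}_2", f"i{k}_3"],
                condition=make_index_matrix(
                    [f"i{k}_1", f"i{k}_3", f"i{k}"],
                    [f"i{k}_2", f"i{k}_3"],
                    [
                        (f"i{k}_1", f"i{k}_2", hooks[f"W_1_{k}_2"]),
                        (f"i{k}_1", f"i{k}_3", hooks[f"W_1_{k}_3"]),
                        (f"i{k}_3", f"i{k}_3", ALWAYS_TRUE),
                        (f"i{k}", f"i{k}_3", ALWAYS_TRUE),
                    ],
                ),
                on_fire=_make_i_policy(k),
            )
        )
    s_inputs = (
        [f"i{k}_2" for k in range(1, m + 1)]
        + [f"s{k}_2" for k in range(1, n + 1)]
        + ["s"]
    )
    s_outputs = (
        [f"s{k}_1" for k in range(1, n + 1)]
        + [f"o{k}_1" for k in range(1, p + 1)]
        + [f"i{k}" for k in range(1, m + 1)]
        + ["s"]
    )
    s_entries: list[tuple[str, str, PredicateRef]] = []
    for k in range(1, m + 1):
        s_entries.append((f"i{k}_2", "s", ALWAYS_TRUE))
    for k in range(1, n + 1):
        s_entries.append((f"s{k}_2", "s", ALWAYS_TRUE))
    for k in range(1, n + 1):
        s_entries.append(("s", f"s{k}_1", hooks[f"V_s_{k}"]))
    for k in range(1, p + 1):
        s_entries.append(("s", f"o{k}_1", hooks[f"V_o_{k}"]))
    for k in range(1, m + 1):
        s_entries.append(("s", f"i{k}", hooks[f"V_i_{k}"]))
    s_entries.append(("s", "s", ALWAYS_TRUE))  # reconstructed ω loop cell
    net.add_transition(
        Transition(
            id="S",
            inputs=s_inputs,
            outputs=s_outputs,
            condition=make_index_matrix(s_inputs, s_outputs, s_entries),
            on_fire=_s_policy,
        )
    )
    for k in range(1, n + 1):
        net.add_transition(
            Transition(
                id=f"S{k}",
                inputs=[f"s{k}_1", f"s{k}_3"],
                outputs=[f"s{k}_2", f"s{k}_3"],
                condition=make_index_matrix(
                    [f"s{k}_1", f"s{k}_3"],
                    [f"s{k}_2", f"s{k}_3"],
                    [
                        (f"s{k}_1", f"s{k}_3", ALWAYS_TRUE),
                        (f"s{k}_3", f"s{k}_2", hooks[f"U_3_{k}_2"]),
                        (f"s{k}_3", f"s{k}_3", ALWAYS_TRUE),  # reconstructed loop cell
                    ],
                ),
                on_fire=_make_sk_policy(k),
            )
        )
    for k in range(1, p + 1):
        net.add_transition(
            Transition(
                id=f"O{k}",
                inputs=[f"o{k}_1", f"o{k}_3"],
                outputs=[f"o{k}_2", f"o{k}_3"],
                condition=make_index_matrix(
                    [f"o{k}_1", f"o{k}_3"],
                    [f"o{k}_2", f"o{k}_3"],
                    [
                        (f"o{k}_1", f"o{k}_3", ALWAYS_TRUE),
                        (f"o{k}_3", f"o{k}_2", hooks[f"T_3_{k}_2"]),
                        (f"o{k}_3", f"o{k}_3", ALWAYS_TRUE),  # reconstructed loop cell
                    ],
                ),
                on_fire=_make_o_policy(k),
            )
        )
    net.add_transition(
        Transition(
            id="En2",
            inputs=[f"o{k}_2" for k in range(1, p + 1)],
            outputs=["e2"],
            condition=make_index_matrix(
                [f"o{k}_2" for k in range(1, p + 1)],
                ["e2"],
                [(f"o{k}_2", "e2", ALWAYS_TRUE) for k in range(1, p + 1)],
            ),
            on_fire=_en2_policy,
        )
    )
    return net


def set_stimuli(net: GNet, stimuli: list[Stimulus]) -> None:
    """Attach the stimulus train the environment will inject during a run."""
    ticks = [s.tick for s in stimuli]
    if any(b < a for a, b in zip(ticks, ticks[1:])):
        raise StructuralError("stimulus ticks must be non-decreasing")
    if any(t < 0 for t in ticks):
        raise StructuralError("stimulus ticks must be >= 0")
    for s in stimuli:
        if not (math.isfinite(s.strength) and s.strength >= 0):
            raise StructuralError(f"stimulus strength must be finite and >= 0, got {s.strength!r}")
    fop = _fop(net)
    fop["stimuli"] = list(stimuli)
    fop["next_stimulus"] = 0


def structural_counts(net: GNet) -> tuple[int, int, int]:
    """(transitions, places, declared token types), counted by enumeration."""
    fop = _fop(net)
    return (len(net.transitions), len(net.places), len(set(fop["declared_token_types"])))
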