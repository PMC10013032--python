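"""Abstract impact–reaction loop between an environment and a system.

This is the lightweight reference formalization that the executable net
(:mod:`fopnet.fop_builder`) concretizes: an environment E and a system S
exchange reactions at discrete time-moments.  The system's reaction at
time t is R_S = F_E(E, S, t) and the next moment it changes is t' =
τ_E(E, S, t); symmetrically the environment's reaction is R_E = F_S(S, E, t)
with time-advance map τ_S.  The thresholded ("complex") variant passes
every reaction through a magnitude gate: a reaction whose σ-magnitude does
not exceed the receiving threshold π stops functioning — it is recorded as
undelivered and leaves the receiving side's state untouched, exactly the
role the receptor threshold plays in the net model.

Both variants run on the same integer tick scale as the net engine; the
two event streams are merged by timestamp, system-side first on ties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Callable

import pandas as pd

from .im_core import StructuralError

SYSTEM = "system"
ENVIRONMENT = "environment"


@dataclass
class ImpactSpec:
    """Hooks defining one impact–reaction loop.

    ``impact_on_system`` is F_E (the environment acting on the system,
    producing the system reaction R_S); ``impact_on_environment`` is F_S.
    ``next_system_time``/``next_environment_time`` are the time-advance
    maps τ_E/τ_S and must return ticks strictly greater than their input.
    The optional ``apply_*`` hooks update the receiving side's state when a
    reaction is delivered.
    """

    impact_on_system: Callable[[Any, Any, int], float]
    impact_on_environment: Callable[[Any, Any, int], float]
    next_system_time: Callable[[Any, Any, int], int]
    next_environment_time: Callable[[Any, Any, int], int]
    initial_environment: Any = None
    initial_system: Any = None
    apply_to_environment: Callable[[Any, float], Any] | None = None
    apply_to_system: Callable[[Any, float], Any] | None = None


@dataclass
class ThresholdGate:
    """Magnitude gates for the thresholded variant.

    ``sigma_system``/``sigma_environment`` extract the impact magnitude of
    a system-side / environment-side reaction; delivery requires the
    magnitude to be strictly greater than the matching threshold.
    """

    sigma_system: Callable[[float, int], float]
    sigma_environment: Callable[[float, int], float]
    pi_system: float = 0.0
    pi_environment: float = 0.0

    def validate(self) -> None:
        for name, v in (("pi_system", self.pi_system), ("pi_environment", self.pi_environment)):
            if not (math.isfinite(v) and v >= 0):
                raise StructuralError(f"{name} must be finite and >= 0, got {v!r}")


@dataclass
class ScheduleEntry:
    tick: int
    side: str  # SYSTEM or ENVIRONMENT
    value: float
    delivered: bool


@dataclass
class ReactionSchedule:
    entries: list[ScheduleEntry] = field(default_factory=list)
    final_environment: Any = None
    final_system: Any = None

    def delivered(self) -> list[ScheduleEntry]:
        return [e for e in self.entries if e.delivered]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.tick, e.side, e.value, e.delivered) for e in self.entries],
            columns=["tick", "side", "value", "delivered"],
        )

    def to_tsv(self) -> str:
        return self.to_frame().to_csv(sep="\t", index=False)


def _advance(hook: Callable, a: Any, b: Any, t: int, name: str) -> int:
    t_next = hook(a, b, t)
    if not isinstance(t_next, int) or t_next <= t:
        raise StructuralError(f"time must advance: {name}({t}) returned {t_next!r}")
    return t_next


def _simulate(
    spec: ImpactSpec, gate: ThresholdGate | None, t_max: int
) -> ReactionSchedule:
    if t_max < 0:
        raise StructuralError("t_max must be >= 0")
    env, sys_ = spec.initial_environment, spec.initial_system
    schedule = ReactionSchedule()
    next_sys = _advance(spec.next_system_time, env, sys_, 0, "next_system_time")
    next_env = _advance(spec.next_environment_time, sys_, env, 0, "next_environment_time")
    while min(next_sys, next_env) <= t_max:
        # merge the two event streams by timestamp, system side first on ties
        if next_sys <= next_env:
            t = next_sys
            value = float(spec.impact_on_system(env, sys_, t))
            delivered = True
            if gate is not None:
                delivered = gate.sigma_system(value, t) > gate.pi_system
            schedule.entries.append(ScheduleEntry(t, SYSTEM, value, delivered))
            if delivered and spec.apply_to_environment is not None:
                env = spec.apply_to_environment(env, value)
            next_sys = _advance(spec.next_system_time, env, sys_, t, "next_system_time")
        else:
            t = next_env
            value = float(spec.impact_on_environment(sys_, env, t))
            delivered = True
            if gate is not None:
                delivered = gate.sigma_environment(value, t) > gate.pi_environment
            schedule.entries.append(ScheduleEntry(t, ENVIRONMENT, value, delivered))
            if delivered and spec.apply_to_system is not None:
                sys_ = spec.apply_to_system(sys_, value)
            next_env = _advance(
                spec.next_environment_time, sys_, env, t, "next_environment_time"
            )
    schedule.final_environment = env
    schedule.final_system = sys_
    return schedule


def simulate_simplified(spec: ImpactSpec, t_max: int) -> ReactionSchedule:
    """Ungated loop: every reaction is delivered."""
    return _simulate(spec, None, t_max)


def simulate_complex(spec: ImpactSpec, gate: ThresholdGate, t_max: int) -> ReactionSchedule:
    """Thresholded loop: a reaction at or under its π threshold stops.

    An undelivered reaction is recorded with ``delivered=False`` and is
    state-inert — it never perturbs the receiving side, so removing it
    from the schedule changes nothing downstream.
    """
    gate.validate()
    return _simulate(spec, gate, t_max)
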