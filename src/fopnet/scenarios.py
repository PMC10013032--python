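"""Executable physiological scenarios and a seeded stimulus generator.

Three concretizations of the net model ship with the package:

``pain_reflex``
    The acute pin-prick reflex: one supra-threshold stimulus travels
    receptor → spinal processing → muscle effector and produces exactly
    one total-reaction token, nine ticks after the prick under unit
    delays.
``chronic_pain``
    Long-lasting pain lowers the pain threshold: every registered impact
    multiplies the receptor threshold by γ < 1, so a repeated stimulus
    that starts sub-threshold eventually elicits responses
    (hypersensitivity).  With θ0 = 3.0, γ = 0.8 and constant strength
    2.5, the threshold first drops under the stimulus after one trigger
    (3.0·0.8 = 2.4 < 2.5), so the second stimulus is the first to respond.
``exchange``
    Intake/excretion: food, drink and oxygen enter through distinct
    receptors and leave through distinct effectors (excrement, urine,
    carbon dioxide), with a stochastic stimulus train.

All scenario magnitudes are package defaults chosen for legible hand
traces; the narratives they model are qualitative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fop_builder import (
    AdaptationRule,
    FOPConfig,
    Stimulus,
    build_fop_net,
    set_stimuli,
)
from .gn_engine import GNet, Trace, run
from .im_core import StructuralError


@dataclass
class StimulusParams:
    """Parameters of the stochastic stimulus generator.

    ``rate`` is the expected number of stimuli per tick (arrivals are
    Poisson per tick), strengths are uniform within ``strength_bounds``,
    modalities are drawn from the normalized ``modality_weights``.
    """

    rate: float = 0.2
    horizon: int = 50
    strength_bounds: tuple[float, float] = (1.0, 5.0)
    modality_weights: dict[str, float] = field(default_factory=lambda: {"default": 1.0})

    def validate(self) -> None:
        if not self.rate > 0:
            raise StructuralError(f"rate must be > 0, got {self.rate!r}")
        if self.horizon < 0:
            raise StructuralError("horizon must be >= 0")
        lo, hi = self.strength_bounds
        if not lo <= hi:
            raise StructuralError(f"strength bounds must be ordered, got ({lo}, {hi})")
        if lo < 0:
            raise StructuralError("strengths must be >= 0")
        if not self.modality_weights or any(w < 0 for w in self.modality_weights.values()):
            raise StructuralError("modality weights must be non-empty and >= 0")
        if sum(self.modality_weights.values()) <= 0:
            raise StructuralError("modality weights must sum to > 0")


@dataclass
class StimulusTrain:
    stimuli: list[Stimulus]
    seed: int | None
    params: StimulusParams | None


def generate_stimuli(params: StimulusParams, seed: int) -> StimulusTrain:
    """Deterministically generate a stimulus train from (params, seed)."""
    params.validate()
    rng = np.random.default_rng(seed)
    modalities = sorted(params.modality_weights)
    weights = np.array([params.modality_weights[m] for m in modalities], dtype=float)
    weights /= weights.sum()
    lo, hi = params.strength_bounds
    stimuli: list[Stimulus] = []
    for tick in range(params.horizon):
        for _ in range(int(rng.poisson(params.rate))):
            modality = modalities[int(rng.choice(len(modalities), p=weights))]
            strength = float(rng.uniform(lo, hi))
            stimuli.append(Stimulus(tick=tick, modality=modality, strength=strength))
    return StimulusTrain(stimuli=stimuli, seed=seed, params=params)


@dataclass
class ScenarioResult:
    """Outcome of one scenario run, with per-stimulus accounting."""

    net: GNet
    trace: Trace
    stimuli: list[Stimulus]
    response_latencies: list[tuple[int, int]]  # (stimulus index, ζ tick − stimulus tick)
    threshold_trajectories: dict[int, list[tuple[int, float]]]
    undelivered_count: int


def collect_result(net: GNet, stimuli: list[Stimulus], trace: Trace) -> ScenarioResult:
    """Assemble the per-stimulus accounting from a finished run."""
    fop = net.aux["fop"]
    latencies: list[tuple[int, int]] = []
    seen: set[int] = set()
    for zev in fop["zeta_events"]:
        for sid in zev["stimulus_ids"]:
            if sid in seen:
                continue
            seen.add(sid)
            latencies.append((sid, zev["tick"] - stimuli[sid].tick))
    latencies.sort()
    trajectories: dict[int, list[tuple[int, float]]] = {}
    for k, tau_id in fop["tau_ids"].items():
        tau = net.tokens[tau_id]
        traj = [
            (rec["tick"], float(rec["data"]["threshold"]))
            for rec in tau.history
            if "threshold" in rec.get("data", {}) and rec.get("data", {}).get("relation") is None
        ]
        trajectories[k] = traj
    undelivered = sum(1 for rec in fop["receptor_log"] if not rec["passed"])
    return ScenarioResult(
        net=net,
        trace=trace,
        stimuli=list(stimuli),
        response_latencies=latencies,
        threshold_trajectories=trajectories,
        undelivered_count=undelivered,
    )


def _pain_reflex_config(cfg: dict) -> tuple[FOPConfig, list[Stimulus], int]:
    strength = float(cfg.get("strength", 5.0))
    config = FOPConfig(
        m=1,
        n=1,
        p=1,
        initial_thresholds=[float(cfg.get("threshold", 3.0))],
        processing_delays=[int(cfg.get("processing_delay", 1))],
        effector_delays=[int(cfg.get("effector_delay", 1))],
        routing={"*": 1},
        adaptation=AdaptationRule(kind="none"),
    )
    stimuli = [Stimulus(tick=int(cfg.get("stimulus_tick", 0)), modality="pin_prick", strength=strength)]
    ticks = int(cfg.get("ticks", 20))
    return config, stimuli, ticks


def _chronic_pain_config(cfg: dict) -> tuple[FOPConfig, list[Stimulus], int]:
    gamma = float(cfg.get("gamma", 0.8))
    adaptation = AdaptationRule(
        kind=cfg.get("adaptation", "multiplicative"),
        gamma=gamma,
        trigger=cfg.get("trigger", "any"),
    )
    config = FOPConfig(
        m=1,
        n=1,
        p=1,
        initial_thresholds=[float(cfg.get("threshold", 3.0))],
        routing={"*": 1},
        adaptation=adaptation,
    )
    strength = float(cfg.get("strength", 2.5))
    n_stimuli = int(cfg.get("n_stimuli", 5))
    spacing = int(cfg.get("spacing", 8))
    stimuli = [
        Stimulus(tick=i * spacing, modality="pain", strength=strength)
        for i in range(n_stimuli)
    ]
    ticks = int(cfg.get("ticks", n_stimuli * spacing + 15))
    return config, stimuli, ticks


def _exchange_config(cfg: dict) -> tuple[FOPConfig, list[Stimulus], int]:
    config = FOPConfig(
        m=3,
        n=1,
        p=3,
        initial_thresholds=[1.0, 1.0, 1.0],
        routing={"food": 1, "drink": 2, "oxygen": 3},
        component_policy="all",
        # intake modalities leave through distinct channels:
        # food -> excrements (1), drink -> urine (2), oxygen -> CO2 (3)
        effector_policy={"food": [1], "drink": [2], "oxygen": [3]},
        adaptation=AdaptationRule(kind="none"),
    )
    horizon = int(cfg.get("horizon", 30))
    params = StimulusParams(
        rate=float(cfg.get("rate", 0.3)),
        horizon=horizon,
        strength_bounds=(2.0, 5.0),
        modality_weights={"food": 1.0, "drink": 1.0, "oxygen": 1.0},
    )
    train = generate_stimuli(params, int(cfg.get("seed", 0)))
    ticks = int(cfg.get("ticks", horizon + 15))
    return config, train.stimuli, ticks


SCENARIOS = {
    "pain_reflex": _pain_reflex_config,
    "chronic_pain": _chronic_pain_config,
    "exchange": _exchange_config,
}


def run_scenario(name: str, config: dict | None = None) -> ScenarioResult:
    """Run a named scenario; ``config`` overrides its defaults."""
    if name not in SCENARIOS:
        raise StructuralError(
            f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}"
        )
    cfg = dict(config or {})
    fop_config, stimuli, ticks = SCENARIOS[name](cfg)
    net = build_fop_net(fop_config)
    set_stimuli(net, stimuli)
    trace = run(net, ticks, seed=int(cfg.get("seed", 0)))
    return collect_result(net, stimuli, trace)


def summarize(result: ScenarioResult) -> pd.DataFrame:
    """Per-stimulus summary: arrival, threshold seen, registration, response.

    ``registered`` means the stimulus reached a receptor at all;
    ``responded`` that a total-reaction token traceable to it reached the
    environment; ``latency`` is in ticks (NaN when no response).
    """
    receptor_by_stimulus = {
        rec["stimulus"]: rec for rec in result.net.aux["fop"]["receptor_log"]
    }
    latency_by_stimulus = dict(result.response_latencies)
    rows = []
    for idx, st in enumerate(result.stimuli):
        rec = receptor_by_stimulus.get(idx)
        rows.append(
            {
                "stimulus": idx,
                "tick": st.tick,
                "modality": st.modality,
                "strength": st.strength,
                "threshold_at_arrival": rec["threshold"] if rec else float("nan"),
                "registered": "y" if rec else "n",
                "responded": "y" if idx in latency_by_stimulus else "n",
                "latency": latency_by_stimulus.get(idx, float("nan")),
            }
        )
    columns = [
        "stimulus",
        "tick",
        "modality",
        "strength",
        "threshold_at_arrival",
        "registered",
        "responded",
        "latency",
    ]
    return pd.DataFrame(rows, columns=columns)


def threshold_table(result: ScenarioResult) -> pd.DataFrame:
    """Per-receptor threshold trajectory as a long table."""
    rows = [
        {"receptor": k, "tick": tick, "threshold": theta}
        for k, traj in sorted(result.threshold_trajectories.items())
        for tick, theta in traj
    ]
    return pd.DataFrame(rows, columns=["receptor", "tick", "threshold"])
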