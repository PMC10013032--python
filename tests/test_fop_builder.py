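from __future__ import annotations

import itertools
import logging
import math

import pytest

from fopnet.fop_builder import (
    DECLARED_TOKEN_TYPES,
    EPS,
    EPS_STAR,
    KAPPA,
    OMEGA,
    PHI,
    PHI_P,
    SIGMA,
    TAU,
    ZETA,
    AdaptationRule,
    FOPConfig,
    Stimulus,
    build_fop_net,
    default_hooks,
    set_stimuli,
    structural_counts,
    threshold_update,
)
from fopnet.gn_engine import SPLIT, TRANSFER, UNITE, Token, audit_trace, run, validate_net
from fopnet.im_core import StructuralError

from oracles import exclusivity_violations


def _run_fop(config: FOPConfig, stimuli: list[Stimulus], ticks: int, seed: int = 0):
    net = build_fop_net(config)
    set_stimuli(net, stimuli)
    trace = run(net, ticks, seed=seed)
    return net, trace


class TestStructure:
    @pytest.mark.parametrize(
        "m,n,p", list(itertools.product([1, 2, 4], [1, 3], [1, 2]))
    )
    def test_enumerated_counts(self, m, n, p):
        """Transition/place counts by enumeration of the built net.

        The net realizes every printed transition form — En0, En1, the m
        receptors, the core S, the n components, the p effectors, En2 —
        which enumerate to m+n+p+4 transitions; places follow
        4m + 3(n+p+1) + 1 exactly.
        """
        net = build_fop_net(FOPConfig(m=m, n=n, p=p))
        n_trans, n_places, n_types = structural_counts(net)
        assert n_trans == m + n + p + 4
        assert n_places == 4 * m + 3 * (n + p + 1) + 1
        assert n_types == 6

    def test_token_type_count_independent_of_dimensions(self):
        counts = {
            structural_counts(build_fop_net(FOPConfig(m=m, n=n, p=p)))[2]
            for m, n, p in [(1, 1, 1), (2, 3, 1), (4, 4, 4)]
        }
        assert counts == {6}
        assert len(DECLARED_TOKEN_TYPES) == 6

    @pytest.mark.parametrize("m,n,p", [(1, 1, 1), (3, 2, 2), (4, 4, 4)])
    def test_built_net_validates_clean(self, m, n, p):
        assert validate_net(build_fop_net(FOPConfig(m=m, n=n, p=p))) == []

    def test_transition_forms(self):
        net = build_fop_net(FOPConfig(m=2, n=2, p=2))
        en0 = net.get_transition("En0")
        assert (en0.inputs, en0.outputs) == (["e0", "e2"], ["e0", "e1"])
        en1 = net.get_transition("En1")
        assert (en1.inputs, en1.outputs) == (["e1"], ["i1_1", "i2_1"])
        i2 = net.get_transition("I2")
        assert (i2.inputs, i2.outputs) == (["i2_1", "i2_3", "i2"], ["i2_2", "i2_3"])
        s = net.get_transition("S")
        assert s.inputs == ["i1_2", "i2_2", "s1_2", "s2_2", "s"]
        assert s.outputs == ["s1_1", "s2_1", "o1_1", "o2_1", "i1", "i2", "s"]
        en2 = net.get_transition("En2")
        assert (en2.inputs, en2.outputs) == (["o1_2", "o2_2"], ["e2"])

    def test_initial_marking(self, fop111):
        fop = fop111.aux["fop"]
        assert fop111.tokens[fop["eps_star_id"]].place == "e0"
        assert fop111.tokens[fop["omega_id"]].place == "s"
        assert fop111.tokens[fop["tau_ids"][1]].place == "i1_3"
        assert fop111.tokens[fop["phi_ids"][1]].place == "o1_3"

    def test_transition_order_is_declared_schedule(self):
        net = build_fop_net(FOPConfig(m=2, n=2, p=2))
        assert [t.id for t in net.transitions] == [
            "En0", "En1", "I1", "I2", "S", "S1", "S2", "O1", "O2", "En2",
        ]


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            (dict(m=0), "m must be"),
            (dict(initial_thresholds=[1.0, 2.0]), "initial_thresholds"),
            (dict(processing_delays=[0]), "delays must be"),
            (dict(effector_delays=[2, 2]), "effector_delays"),
            (dict(initial_thresholds=[-1.0]), "thresholds must be"),
            (dict(routing={"x": 5}), "outside receptor range"),
            (dict(effector_policy={"x": [9]}), "outside range"),
        ],
    )
    def test_invalid_config_rejected_before_build(self, kwargs, msg):
        with pytest.raises(StructuralError, match=msg):
            build_fop_net(FOPConfig(**kwargs))

    def test_bad_adaptation_rule_rejected(self):
        with pytest.raises(StructuralError, match="adaptation"):
            FOPConfig(adaptation=AdaptationRule(kind="weird")).validate()


class TestThresholdPredicates:
    @pytest.mark.parametrize(
        "strength,expected", [(5.0, True), (3.0, False), (2.9, False), (3.0001, True)]
    )
    def test_supra_threshold_is_strict_greater_than(self, fop111, strength, expected):
        hooks = fop111.aux["fop"]["hooks"]
        tok = Token(id="ε-x", type_tag=EPS)
        tok.meta["strength"] = strength
        assert hooks["W_1_1_2"](tok, "i1_1", "i1_2", fop111, 0) is expected
        assert hooks["W_1_1_3"](tok, "i1_1", "i1_3", fop111, 0) is (not expected)

    def test_every_matrix_predicate_resolves(self):
        config = FOPConfig(m=2, n=2, p=2).validate()
        hooks = default_hooks(config)
        net = build_fop_net(config)
        for tr in net.transitions:
            for (row, col), pred in tr.condition.cells().items():
                assert pred.id in hooks or pred.id in ("ALWAYS_TRUE", "ALWAYS_FALSE")


class TestThresholdUpdate:
    def test_none_rule_keeps_threshold_constant(self):
        net, _ = _run_fop(
            FOPConfig(adaptation=AdaptationRule(kind="none")),
            [Stimulus(tick=t, strength=1.0) for t in (0, 5, 10)],
            25,
        )
        tau = net.tokens[net.aux["fop"]["tau_ids"][1]]
        assert tau.meta["threshold"] == 3.0

    def test_two_triggers_compound_multiplicatively(self):
        """θ0=3.0 with γ=0.8 after two sub-threshold registrations → 1.92."""
        net, _ = _run_fop(
            FOPConfig(adaptation=AdaptationRule(kind="multiplicative", gamma=0.8)),
            [Stimulus(tick=0, strength=1.0), Stimulus(tick=8, strength=1.0)],
            20,
        )
        tau = net.tokens[net.aux["fop"]["tau_ids"][1]]
        assert tau.meta["threshold"] == pytest.approx(3.0 * 0.8**2)

    @pytest.mark.parametrize("bad", [-1.0, float("nan"), float("inf")])
    def test_invalid_proposed_threshold_rejected(self, bad):
        tau = Token(id="τ-x", type_tag=TAU)
        tau.meta["threshold"] = 3.0
        with pytest.raises(StructuralError):
            threshold_update(tau, bad)
        assert tau.meta["threshold"] == 3.0


class TestLifecycle:
    def test_first_transfer_is_environment_emission(self, fop111):
        set_stimuli(fop111, [Stimulus(tick=0, strength=5.0)])
        run(fop111, 1, seed=0)
        transfers = [e for e in fop111.trace_events if e.kind == TRANSFER]
        assert transfers[0].transition_id == "En0"
        assert (transfers[0].source_place, transfers[0].target_place) == ("e0", "e1")

    def test_subthreshold_impact_absorbed_and_registered(self, fop111):
        set_stimuli(fop111, [Stimulus(tick=0, strength=2.0)])
        run(fop111, 15, seed=0)
        fop = fop111.aux["fop"]
        assert fop["zeta_events"] == []
        tau = fop111.tokens[fop["tau_ids"][1]]
        regs = [
            rec for rec in tau.history if rec.get("data", {}).get("relation") == "under"
        ]
        assert len(regs) == 1
        assert {"time_moment", "strength", "relation"} <= set(regs[0]["data"])
        eps = [t for t in fop111.tokens.values() if t.type_tag == EPS]
        assert len(eps) == 1 and not eps[0].alive

    def test_exclusivity_over_mixed_train(self):
        net, _ = _run_fop(
            FOPConfig(m=2, routing={"a": 1, "b": 2}),
            [
                Stimulus(tick=0, modality="a", strength=5.0),
                Stimulus(tick=2, modality="b", strength=1.0),
                Stimulus(tick=4, modality="a", strength=3.0),
                Stimulus(tick=6, modality="b", strength=4.0),
            ],
            25,
        )
        assert exclusivity_violations(net) == 0

    def test_omega_splits_but_never_moves_or_dies(self):
        net, trace = _run_fop(
            FOPConfig(), [Stimulus(tick=0, strength=5.0), Stimulus(tick=5, strength=4.0)], 30
        )
        omega_id = net.aux["fop"]["omega_id"]
        omega = net.tokens[omega_id]
        assert omega.alive and omega.place == "s"
        assert not any(
            e.kind == TRANSFER and e.token_ids[0] == omega_id for e in net.trace_events
        )
        assert any(
            e.kind == SPLIT and e.token_ids[0] == omega_id for e in net.trace_events
        )

    def test_zeta_formed_only_by_en2_from_effector_outputs(self):
        net, _ = _run_fop(FOPConfig(), [Stimulus(tick=0, strength=5.0)], 15)
        zetas = [t for t in net.tokens.values() if t.type_tag == ZETA]
        assert len(zetas) == 1
        zeta = zetas[0]
        assert zeta.id.startswith(f"{PHI_P}-")  # born as an effector output
        arrival = next(
            e
            for e in net.trace_events
            if e.kind == TRANSFER and e.token_ids == [zeta.id] and e.target_place == "e2"
        )
        assert arrival.transition_id == "En2"
        # the environment token subsequently absorbs it
        assert not zeta.alive
        eps_star = net.tokens[net.aux["fop"]["eps_star_id"]]
        assert zeta.id in eps_star.parent_ids
        assert any(
            rec.get("label") == "a result of the impact of the system over the environment"
            for rec in eps_star.history
        )

    def test_kappa_routes_through_feedback_place_to_tau(self):
        net, _ = _run_fop(
            FOPConfig(adaptation=AdaptationRule(kind="multiplicative", gamma=0.8)),
            [Stimulus(tick=0, strength=1.0)],
            12,
        )
        kappas = [t for t in net.tokens.values() if t.type_tag == KAPPA]
        assert len(kappas) == 1
        kid = kappas[0].id
        hops = [
            (e.source_place, e.target_place)
            for e in net.trace_events
            if e.kind == TRANSFER and e.token_ids == [kid]
        ]
        assert hops == [("s", "i1"), ("i1", "i1_3")]
        tau = net.tokens[net.aux["fop"]["tau_ids"][1]]
        assert kid in tau.parent_ids and tau.meta["threshold"] == pytest.approx(2.4)

    def test_processing_delay_shifts_response(self, hand_trace):
        """Each extra delay tick at the component or effector adds one tick."""
        base = hand_trace["zeta_tick"]
        for proc, eff in [(1, 1), (3, 1), (1, 2), (2, 2)]:
            net, _ = _run_fop(
                FOPConfig(processing_delays=[proc], effector_delays=[eff]),
                [Stimulus(tick=0, strength=5.0)],
                20,
            )
            assert net.aux["fop"]["zeta_events"][0]["tick"] == base + (proc - 1) + (eff - 1)

    def test_unmatched_stimulus_stays_with_warning(self, caplog):
        net = build_fop_net(FOPConfig(routing={"known": 1}))
        set_stimuli(net, [Stimulus(tick=0, modality="mystery", strength=5.0)])
        with caplog.at_level(logging.WARNING, logger="fopnet"):
            trace = run(net, 10, seed=0)
        assert any("matches no receptor" in r.message for r in caplog.records)
        eps = [t for t in net.tokens.values() if t.type_tag == EPS]
        assert len(eps) == 1 and eps[0].place == "e1"
        assert net.aux["fop"]["zeta_events"] == []
        assert audit_trace(trace) == []

    def test_multi_effector_outputs_fuse_into_one_reaction(self):
        net, trace = _run_fop(
            FOPConfig(m=1, n=1, p=3, effector_policy="all"),
            [Stimulus(tick=0, strength=5.0)],
            20,
        )
        fop = net.aux["fop"]
        assert len(fop["zeta_events"]) == 1
        unites = [
            e
            for e in net.trace_events
            if e.kind == UNITE and e.transition_id == "En2"
        ]
        assert len(unites) == 1 and len(unites[0].payload["absorbed"]) == 2
        assert audit_trace(trace) == []


def test_stimulus_train_must_be_ordered(fop111):
    with pytest.raises(StructuralError, match="non-decreasing"):
        set_stimuli(fop111, [Stimulus(tick=5, strength=1.0), Stimulus(tick=0, strength=1.0)])
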