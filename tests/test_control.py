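"""Assist-control state machine: phases, triggering, adaptive volume setpoint."""

import pytest

import bagvent as bv
from bagvent.control import (TICK, TRIGGER_REFRACTORY, Controller,
                             ControllerState, Mode, Phase, Trigger,
                             VentSettings, check_trigger,
                             update_volume_setpoint)


def make_settings(**kw):
    return VentSettings(**{"mode": Mode.VC_AC, "rr_set": 20.0, "t_insp": 1.0,
                           "max_volume": 400.0, "trigger_threshold": 3.0, **kw})


class TestCheckTrigger:
    def test_strict_threshold_during_release(self):
        s = make_settings()
        state = ControllerState(phase=Phase.RELEASE, release_start=0.0)
        t = TRIGGER_REFRACTORY + 0.01
        assert check_trigger(2.9, s, state, t) is True
        assert check_trigger(3.0, s, state, t) is False

    def test_not_triggerable_outside_release(self):
        s = make_settings()
        for phase in (Phase.COMPRESS, Phase.HOLD):
            state = ControllerState(phase=phase)
            assert check_trigger(2.0, s, state, 1.0) is False

    def test_refractory_window(self):
        s = make_settings()
        state = ControllerState(phase=Phase.RELEASE, release_start=5.0)
        assert check_trigger(2.0, s, state, 5.0 + TRIGGER_REFRACTORY / 2) is False
        assert check_trigger(2.0, s, state, 5.0 + TRIGGER_REFRACTORY + 0.01) is True


class TestAdaptiveSetpoint:
    def test_stated_rule(self):
        assert update_volume_setpoint(400.0, 400.0, 400.0) == 400.0
        assert update_volume_setpoint(400.0, 400.0, 380.0, gain=0.5) == 410.0

    def test_clamped_to_bag(self):
        assert update_volume_setpoint(740.0, 800.0, 0.0, gain=1.0,
                                      bag_capacity=750.0) == 750.0
        assert update_volume_setpoint(10.0, 1.0, 900.0, gain=1.0) == 0.0

    def test_gain_validation(self):
        with pytest.raises(ValueError):
            update_volume_setpoint(400.0, 400.0, 380.0, gain=0.0)
        with pytest.raises(ValueError):
            update_volume_setpoint(400.0, 400.0, 380.0, gain=1.5)

    @pytest.mark.parametrize("offset", [-80.0, -40.0, 0.0, 40.0, 80.0])
    def test_convergence_within_five_breaths_additive_bias(self, offset):
        """Fixed-point contraction of the breath-to-breath map: with a
        constant plant offset up to 20% of the target, delivered volume
        reaches within 2% of the target in at most 5 breaths at gain 0.5."""
        target = 400.0
        setpoint = target
        delivered = None
        for breath in range(1, 6):
            delivered = setpoint + offset  # plant with additive bias
            setpoint = update_volume_setpoint(setpoint, target, delivered)
        assert abs(delivered - target) / target < 0.02

    @pytest.mark.parametrize("bias", [0.8, 0.9, 1.0, 1.1, 1.2])
    def test_convergence_rate_multiplicative_bias(self, bias):
        """With a multiplicative plant bias b the breath-to-breath error
        contracts by (1 - gain*b) per breath; after 5 breaths the residual
        is 0.2*(1-0.5b)^4 of the target (worst case 2.6% at b=0.8)."""
        target = 400.0
        setpoint = target
        delivered = None
        for breath in range(1, 6):
            delivered = bias * setpoint
            setpoint = update_volume_setpoint(setpoint, target, delivered)
        oracle = abs(1.0 - bias) * (1.0 - 0.5 * bias) ** 4
        assert abs(delivered - target) / target == pytest.approx(oracle, abs=1e-9)
        assert abs(delivered - target) / target <= 0.026


class TestControllerSequencing:
    def feed(self, ctrl, n_ticks, p_aw=10.0, flow=0.0, start_tick=0):
        phases = []
        for k in range(start_tick, start_tick + n_ticks):
            phases.append(ctrl.step(k * TICK, p_aw, flow))
        return phases

    def test_vc_stops_at_setpoint_then_holds_to_t_insp(self):
        """Volume reached mid-stroke: flow stops but the phase holds the
        pressure plateau until the inspiratory time ends."""
        ctrl = Controller(make_settings())
        # 60 L/min -> 10 mL per tick; setpoint 400 mL reached at tick 40
        phases = [ctrl.step(k * TICK, 10.0, 60.0) for k in range(150)]
        assert phases[0] is Phase.COMPRESS
        hold_start = phases.index(Phase.HOLD)
        assert hold_start == pytest.approx(40, abs=1)
        release_start = phases.index(Phase.RELEASE)
        assert release_start == 100  # t_insp = 1.0 s
        assert set(phases[hold_start:release_start]) == {Phase.HOLD}

    def test_timed_breaths_at_set_period(self):
        ctrl = Controller(make_settings(rr_set=20.0))
        self.feed(ctrl, 901, p_aw=10.0, flow=0.0)
        starts = [e.t_start for e in ctrl.events]
        assert starts == pytest.approx([0.0, 3.0, 6.0, 9.0], abs=TICK / 2)
        assert all(e.trigger is Trigger.TIMED for e in ctrl.events)

    def test_max_pressure_halts_compression_for_the_cycle(self):
        ctrl = Controller(make_settings(max_pressure=30.0))
        ctrl.step(0.0, 10.0, 0.0)
        phase = ctrl.step(TICK, 31.0, 90.0)  # pressure spike during COMPRESS
        assert phase is Phase.HOLD
        assert ctrl.state.halted_this_cycle
        assert ctrl.max_pressure_events == [TICK]
        # stays halted for the rest of the cycle even if pressure drops
        assert ctrl.step(2 * TICK, 10.0, 0.0) is Phase.HOLD

    def test_patient_trigger_resets_rate_timer(self):
        ctrl = Controller(make_settings())
        # breath 0 at t=0; release from 1.0 s; effort at 1.5 s
        for k in range(150):
            ctrl.step(k * TICK, 10.0, 60.0)
        phase = ctrl.step(1.50, 2.5, 0.0)
        assert phase is Phase.COMPRESS
        assert ctrl.events[-1].trigger is Trigger.PATIENT
        assert ctrl.events[-1].t_start == pytest.approx(1.50)
        # next TIMED breath is one full period after the patient trigger
        for k in range(151, 460):
            ctrl.step(k * TICK, 10.0, 60.0)
        timed = [e for e in ctrl.events if e.trigger is Trigger.TIMED]
        assert timed[-1].t_start == pytest.approx(1.50 + 3.0, abs=TICK)

    def test_phase_order_is_legal(self):
        """Phases only ever step COMPRESS -> HOLD -> RELEASE -> COMPRESS."""
        ctrl = Controller(make_settings())
        allowed = {(Phase.COMPRESS, Phase.HOLD), (Phase.HOLD, Phase.RELEASE),
                   (Phase.RELEASE, Phase.COMPRESS)}
        prev = ctrl.step(0.0, 10.0, 60.0)
        for k in range(1, 700):
            cur = ctrl.step(k * TICK, 10.0, 60.0)
            if cur is not prev:
                assert (prev, cur) in allowed
            prev = cur

    def test_run_disabled_stays_in_release(self):
        ctrl = Controller(make_settings(run_enable=False))
        phases = self.feed(ctrl, 50, p_aw=1.0)
        assert set(phases) == {Phase.RELEASE}
        assert ctrl.events == []


class TestSettingsValidation:
    def test_t_insp_must_fit_period(self):
        with pytest.raises(ValueError):
            make_settings(rr_set=30.0, t_insp=2.0)

    def test_positive_parameters(self):
        with pytest.raises(ValueError):
            make_settings(rr_set=0.0)
        with pytest.raises(ValueError):
            make_settings(max_volume=-5.0)


def test_assist_control_guarantee(reference_wave, spontaneous_wave):
    """The interval between consecutive breath starts never exceeds the set
    period plus one controller tick, with or without patient effort."""
    for sc, wave in (reference_wave, spontaneous_wave):
        starts = [e.t_start for e in wave.breath_events]
        period = sc.settings.period
        gaps = [b - a for a, b in zip(starts, starts[1:])]
        assert max(gaps) <= period + TICK + 1e-9


def test_efforts_during_release_always_trigger(spontaneous_wave):
    """Every breath in the locked spontaneous scenario is patient-triggered
    (after the first mandatory breath)."""
    _, wave = spontaneous_wave
    triggers = [e.trigger for e in wave.breath_events]
    assert triggers[0] is Trigger.TIMED
    assert triggers[1:].count(Trigger.PATIENT) >= 0.9 * len(triggers[1:])
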