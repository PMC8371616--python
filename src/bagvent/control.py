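"""Assist-control ventilator logic sampled at 100 Hz.

Both modes cycle COMPRESS -> HOLD -> RELEASE.  A breath starts either on
the respiration-rate clock (TIMED) or when patient effort pulls airway
pressure below the trigger threshold during exhalation (PATIENT); a
patient trigger resets the rate clock.

VC-AC: flow from the spirometer is integrated, and bag compression stops
when the integrated volume reaches an adaptive setpoint; the rest of the
inspiratory time is a zero-flow inspiratory pause at maintained pressure.
The setpoint is updated breath-to-breath by a proportional rule,
``setpoint += gain * (set_volume - delivered)``, which removes the
tick-quantization overshoot in a few breaths.

PC-AC: target pressure is set on the mechanical PIP valve; the piston is
held against the valve for the whole inspiratory time, so delivered flow
stays pressure-limited until exhalation.  The volume integrator still runs
(for alarms) but does not stop the stroke.

In both modes the software maximum-pressure check halts compression for
the remainder of the cycle and raises a high-priority alarm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

__all__ = [
    "Mode",
    "Phase",
    "Trigger",
    "VentSettings",
    "ControllerState",
    "BreathEvent",
    "Controller",
    "check_trigger",
    "update_volume_setpoint",
]

#: Controller tick, synchronized to the 100 Hz sensor rate.
TICK = 0.01
#: Patient triggering is ignored for this long after exhalation starts,
#: to avoid re-triggering on the release transient.
TRIGGER_REFRACTORY = 0.2
#: Adaptive volume-setpoint gain ("a fraction of the difference").
ADAPTIVE_GAIN = 0.5


class Mode(str, Enum):
    VC_AC = "VC_AC"
    PC_AC = "PC_AC"


class Phase(str, Enum):
    COMPRESS = "COMPRESS"
    HOLD = "HOLD"
    RELEASE = "RELEASE"


class Trigger(str, Enum):
    TIMED = "TIMED"
    PATIENT = "PATIENT"


@dataclass(frozen=True)
class VentSettings:
    """Ventilator front-panel settings.

    ``trigger_threshold`` is compared against the *absolute* airway-
    pressure gauge reading, not relative to PEEP.  ``max_pressure`` is the
    software maximum-pressure parameter (independent of the mechanical PIP
    valve).  ``peep_min`` is the low-pressure warning threshold.
    """

    mode: Mode = Mode.VC_AC
    rr_set: float = 20.0
    t_insp: float = 1.0
    max_volume: float = 400.0
    max_pressure: float = 40.0
    trigger_threshold: float = 3.0
    peep_min: float = 0.0
    run_enable: bool = True

    def __post_init__(self) -> None:
        if self.rr_set <= 0:
            raise ValueError("rr_set must be > 0")
        if self.t_insp <= 0:
            raise ValueError("t_insp must be > 0")
        if self.t_insp >= 60.0 / self.rr_set:
            raise ValueError(
                f"t_insp {self.t_insp} s must be shorter than the breath "
                f"period {60.0 / self.rr_set:.2f} s"
            )
        if self.max_volume <= 0:
            raise ValueError("max_volume must be > 0")

    @property
    def period(self) -> float:
        """Mandatory breath period 60/rr_set in seconds."""
        return 60.0 / self.rr_set


@dataclass
class BreathEvent:
    t_start: float
    trigger: Trigger
    t_insp_commanded: float


@dataclass
class ControllerState:
    """Per-cycle controller state (phase, timers, integrator, adaptive setpoint)."""

    phase: Phase = Phase.RELEASE
    breath_start: float = 0.0
    release_start: float = 0.0
    integrated_volume: float = 0.0
    delivered_drive: float = 0.0      # drive-delivered mL this breath (bag cap)
    adaptive_setpoint: float = 0.0
    delivered_last: float = 0.0
    halted_this_cycle: bool = False
    started: bool = False
    min_paw_breath: float = float("inf")


def check_trigger(p_aw: float, settings: VentSettings, state: ControllerState,
                  t: float) -> bool:
    """True iff patient effort should start an assisted breath now.

    Strict ``p_aw < trigger_threshold`` on the absolute gauge reading,
    evaluated only during RELEASE and outside the post-release refractory
    window.
    """
    if state.phase is not Phase.RELEASE:
        return False
    if t - state.release_start < TRIGGER_REFRACTORY:
        return False
    return p_aw < settings.trigger_threshold


def update_volume_setpoint(setpoint: float, target: float, delivered: float,
                           gain: float = ADAPTIVE_GAIN,
                           bag_capacity: float = 750.0) -> float:
    """Breath-to-breath proportional update of the VC volume setpoint."""
    if not 0.0 < gain <= 1.0:
        raise ValueError("gain must be in (0, 1]")
    if target <= 0:
        raise ValueError("target must be > 0")
    return min(bag_capacity, max(0.0, setpoint + gain * (target - delivered)))


class Controller:
    """Discrete assist-control state machine, stepped at the 100 Hz tick.

    ``step(t, p_aw, flow_lpm)`` consumes one sensor sample and returns the
    phase command for the plant until the next tick.  Breath-start and
    max-pressure events are appended to ``events``; completed-breath
    summaries (delivered volume, minimum pressure) to ``breaths``.
    """

    def __init__(self, settings: VentSettings, stroke_time: float = 0.5,
                 bag_capacity: float = 750.0):
        self.settings = settings
        self.stroke_time = stroke_time
        self.bag_capacity = bag_capacity
        self.state = ControllerState(adaptive_setpoint=settings.max_volume)
        self.events: list[BreathEvent] = []
        self.max_pressure_events: list[float] = []
        self.breath_volumes: list[float] = []   # delivered mL per completed breath
        self.breath_min_paw: list[float] = []

    # -- internal helpers -------------------------------------------------
    def _start_breath(self, t: float, trigger: Trigger) -> None:
        s = self.state
        if s.started:
            self._finish_breath()
        s.phase = Phase.COMPRESS
        s.breath_start = t
        s.integrated_volume = 0.0
        s.delivered_drive = 0.0
        s.halted_this_cycle = False
        s.started = True
        s.min_paw_breath = float("inf")
        self.events.append(BreathEvent(t, trigger, self.settings.t_insp))

    def _finish_breath(self) -> None:
        s = self.state
        s.delivered_last = s.integrated_volume
        self.breath_volumes.append(s.integrated_volume)
        self.breath_min_paw.append(s.min_paw_breath)
        if self.settings.mode is Mode.VC_AC:
            s.adaptive_setpoint = update_volume_setpoint(
                s.adaptive_setpoint, self.settings.max_volume,
                s.integrated_volume, bag_capacity=self.bag_capacity)

    def _compress_window(self) -> float:
        # VC: the piston stroke; PC: held against the PIP valve for all of Ti.
        if self.settings.mode is Mode.PC_AC:
            return self.settings.t_insp
        return min(self.stroke_time, self.settings.t_insp)

    # -- public -----------------------------------------------------------
    def step(self, t: float, p_aw: float, flow_lpm: float) -> Phase:
        """Advance one tick; returns the commanded phase for [t, t+TICK)."""
        s = self.state
        settings = self.settings
        if not settings.run_enable:
            s.phase = Phase.RELEASE
            return s.phase

        # integrate calibrated inspiratory flow (mL) and track min pressure
        if s.started:
            s.integrated_volume += max(0.0, flow_lpm) / 60.0 * TICK * 1000.0
            s.min_paw_breath = min(s.min_paw_breath, p_aw)

        if not s.started:
            self._start_breath(t, Trigger.TIMED)
            return s.phase

        t_in_breath = t - s.breath_start

        if s.phase is Phase.COMPRESS:
            if p_aw >= settings.max_pressure and not s.halted_this_cycle:
                # software pressure check: halt compression for this cycle
                s.halted_this_cycle = True
                self.max_pressure_events.append(t)
                s.phase = Phase.HOLD
            elif (settings.mode is Mode.VC_AC
                  and s.integrated_volume >= s.adaptive_setpoint):
                s.phase = Phase.HOLD
            elif t_in_breath >= self._compress_window():
                s.phase = Phase.HOLD

        if s.phase is Phase.HOLD and t_in_breath >= settings.t_insp:
            s.phase = Phase.RELEASE
            s.release_start = t

        if s.phase is Phase.RELEASE:
            if check_trigger(p_aw, settings, s, t):
                self._start_breath(t, Trigger.PATIENT)
            elif t_in_breath >= settings.period - TICK / 2:
                self._start_breath(t, Trigger.TIMED)

        return s.phase

    def finalize(self) -> None:
        """Close out the breath in progress at end of simulation."""
        if self.state.started:
            self._finish_breath()
            self.state.started = False
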