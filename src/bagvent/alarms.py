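"""Alarm evaluation with priorities and latching display semantics.

Per-breath conditions (volume in/out of band, end-expiratory pressure
below the PEEP-minimum warning threshold) are evaluated on completed
breaths; per-sample conditions (maximum pressure exceeded, sustained low
pressure, continuing airway pressure) on every controller tick.  An alarm
event stays active until its condition is no longer met; the visual
indication persists for as long as the event is open.

Priorities follow the device's alarm table:

=================  ========================================  ========
code               condition                                 priority
=================  ========================================  ========
POWER_LOST         12 V electrical power lost (injected)     HIGH
MAX_PRESSURE       p_aw exceeded the max-pressure parameter  HIGH
PRESSURE_LOW       patient-circuit pressure low              HIGH
VOLUME_LOW         TV < 250 mL (PC-AC)                       HIGH
VOLUME_LOW         TV < 80% of max volume (VC-AC)            MEDIUM
VOLUME_HIGH        TV > 120% of max volume (VC-AC)           MEDIUM
BATTERY_LOW        9 V standby battery low (injected)        MEDIUM
CONTINUING_PRESSURE p_aw > PEEP + 5 for >= 2 breath periods  HIGH
=================  ========================================  ========
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .control import ControllerState, Mode, Phase, VentSettings

__all__ = [
    "AlarmCode",
    "Priority",
    "AlarmEvent",
    "AlarmManager",
    "evaluate_breath_alarms",
    "evaluate_sample_alarms",
    "write_alarm_log",
]

#: PC-AC low-volume threshold, mL.
PC_VOLUME_LOW_ML = 250.0
#: VC-AC volume band as fractions of the set maximum volume.
VC_VOLUME_LOW_FRAC = 0.80
VC_VOLUME_HIGH_FRAC = 1.20
#: Continuing-airway-pressure condition: p_aw above PEEP by this margin ...
CONTINUING_PRESSURE_MARGIN = 5.0
#: ... for at least this many breath periods.
CONTINUING_PRESSURE_PERIODS = 2.0


class AlarmCode(str, Enum):
    MAX_PRESSURE = "MAX_PRESSURE"
    PRESSURE_LOW = "PRESSURE_LOW"
    VOLUME_LOW = "VOLUME_LOW"
    VOLUME_HIGH = "VOLUME_HIGH"
    POWER_LOST = "POWER_LOST"
    BATTERY_LOW = "BATTERY_LOW"
    CONTINUING_PRESSURE = "CONTINUING_PRESSURE"


class Priority(str, Enum):
    HIGH = "HIGH"
    MEDIUM = "MEDIUM"


def alarm_priority(code: AlarmCode, mode: Mode) -> Priority:
    """Priority of an alarm code, mode-dependent for VOLUME_LOW."""
    if code is AlarmCode.VOLUME_LOW:
        return Priority.HIGH if mode is Mode.PC_AC else Priority.MEDIUM
    if code in (AlarmCode.VOLUME_HIGH, AlarmCode.BATTERY_LOW):
        return Priority.MEDIUM
    return Priority.HIGH


@dataclass
class AlarmEvent:
    code: AlarmCode
    priority: Priority
    t_onset: float
    t_cleared: Optional[float] = None
    message: str = ""

    @property
    def active(self) -> bool:
        return self.t_cleared is None


def evaluate_breath_alarms(tidal_volume, peep_min_measured: float = 0.0,
                           settings: VentSettings = None,
                           t: float = 0.0) -> list[AlarmEvent]:
    """Alarm events raised by one completed breath.

    ``tidal_volume`` is the delivered volume (mL) and
    ``peep_min_measured`` the minimum airway pressure (cmH2O) seen during
    the breath; alternatively pass a ``BreathRecord`` as the first
    argument.
    """
    if hasattr(tidal_volume, "tidal_volume"):  # a BreathRecord
        record = tidal_volume
        tidal_volume = record.tidal_volume
        peep_min_measured = record.peep_min
        t = record.t_start + record.duration
    if settings is None:
        raise TypeError("settings is required")
    out: list[AlarmEvent] = []
    if settings.mode is Mode.PC_AC:
        if tidal_volume < PC_VOLUME_LOW_ML:
            out.append(AlarmEvent(
                AlarmCode.VOLUME_LOW, Priority.HIGH, t,
                message=f"tidal volume {tidal_volume:.0f} mL below {PC_VOLUME_LOW_ML:.0f} mL"))
    else:
        if tidal_volume < VC_VOLUME_LOW_FRAC * settings.max_volume:
            out.append(AlarmEvent(
                AlarmCode.VOLUME_LOW, Priority.MEDIUM, t,
                message=f"tidal volume {tidal_volume:.0f} mL below 80% of "
                        f"{settings.max_volume:.0f} mL"))
        elif tidal_volume > VC_VOLUME_HIGH_FRAC * settings.max_volume:
            out.append(AlarmEvent(
                AlarmCode.VOLUME_HIGH, Priority.MEDIUM, t,
                message=f"tidal volume {tidal_volume:.0f} mL above 120% of "
                        f"{settings.max_volume:.0f} mL"))
    if peep_min_measured < settings.peep_min:
        out.append(AlarmEvent(
            AlarmCode.PRESSURE_LOW, Priority.HIGH, t,
            message=f"end-expiratory pressure {peep_min_measured:.1f} below "
                    f"PEEP minimum {settings.peep_min:.1f}"))
    return out


@dataclass
class AlarmManager:
    """Latching per-sample alarm evaluation over a simulation run.

    Call :meth:`sample` once per controller tick; inject POWER_LOST /
    BATTERY_LOW externally with :meth:`inject` / :meth:`clear_injected`.
    """

    settings: VentSettings
    peep_setting: float = 5.0
    log: list[AlarmEvent] = field(default_factory=list)
    _active: dict = field(default_factory=dict)
    _low_since: Optional[float] = None
    _high_since: Optional[float] = None

    def _set(self, code: AlarmCode, active: bool, t: float, message: str = "") -> None:
        ev = self._active.get(code)
        if active and ev is None:
            ev = AlarmEvent(code, alarm_priority(code, self.settings.mode), t,
                            message=message)
            self._active[code] = ev
            self.log.append(ev)
        elif not active and ev is not None:
            ev.t_cleared = t
            del self._active[code]

    def sample(self, t: float, p_aw: float, phase: Phase,
               max_pressure_hit: bool = False) -> list[AlarmEvent]:
        """Evaluate per-sample conditions at time ``t``; returns newly raised events."""
        n0 = len(self.log)
        self._set(AlarmCode.MAX_PRESSURE, max_pressure_hit, t,
                  "airway pressure exceeded the maximum pressure parameter")

        # sustained low circuit pressure: below the PEEP-minimum warning
        # threshold during exhalation for more than one breath period
        low = phase is Phase.RELEASE and p_aw < self.settings.peep_min
        if low:
            if self._low_since is None:
                self._low_since = t
            sustained = (t - self._low_since) > self.settings.period
        else:
            self._low_since = None
            sustained = False
        self._set(AlarmCode.PRESSURE_LOW, sustained, t,
                  "sustained low patient-circuit pressure")

        # continuing airway pressure: stuck above PEEP + margin
        high = p_aw > self.peep_setting + CONTINUING_PRESSURE_MARGIN
        if high:
            if self._high_since is None:
                self._high_since = t
            continuing = (t - self._high_since) >= (
                CONTINUING_PRESSURE_PERIODS * self.settings.period)
        else:
            self._high_since = None
            continuing = False
        self._set(AlarmCode.CONTINUING_PRESSURE, continuing, t,
                  "continuing airway pressure")
        return self.log[n0:]

    def breath(self, t: float, tidal_volume: float, peep_min_measured: float) -> list[AlarmEvent]:
        """Evaluate per-breath conditions; latches via the active-event table."""
        raised = evaluate_breath_alarms(tidal_volume, peep_min_measured,
                                        self.settings, t)
        raised_codes = {ev.code for ev in raised}
        out = []
        for ev in raised:
            if ev.code not in self._active:
                self._active[ev.code] = ev
                self.log.append(ev)
                out.append(ev)
        for code in (AlarmCode.VOLUME_LOW, AlarmCode.VOLUME_HIGH):
            if code in self._active and code not in raised_codes:
                self._active[code].t_cleared = t
                del self._active[code]
        return out

    def inject(self, code: AlarmCode, t: float, message: str = "") -> AlarmEvent:
        """Inject an external alarm condition (POWER_LOST, BATTERY_LOW)."""
        self._set(code, True, t, message or f"injected {code.value}")
        return self._active[code]

    def clear_injected(self, code: AlarmCode, t: float) -> None:
        self._set(code, False, t)

    @property
    def active(self) -> list[AlarmEvent]:
        return list(self._active.values())


def evaluate_sample_alarms(t: float, p_aw: float, settings: VentSettings,
                           state: ControllerState,
                           manager: Optional[AlarmManager] = None) -> list[AlarmEvent]:
    """Stateless convenience wrapper for one-off per-sample evaluation."""
    mgr = manager or AlarmManager(settings)
    return mgr.sample(t, p_aw, state.phase,
                      max_pressure_hit=p_aw >= settings.max_pressure)


def write_alarm_log(path, events: list[AlarmEvent]) -> None:
    """Write an alarm log CSV (t_onset, t_cleared, code, priority)."""
    import pandas as pd

    pd.DataFrame(
        [{"t_onset": e.t_onset,
          "t_cleared": "" if e.t_cleared is None else e.t_cleared,
          "code": e.code.value, "priority": e.priority.value,
          "message": e.message}
         for e in events]
    ).to_csv(path, index=False)
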