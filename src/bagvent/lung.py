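"""Single-compartment respiratory mechanics with optional spontaneous effort.

The simulated patient is the standard one-compartment model used on bench
lung simulators: a linear compliance ``C`` (mL/cmH2O) in series with a
phase-dependent airway resistance (``r_insp`` for inspiratory flow,
``r_exp`` for expiratory flow, both cmH2O/(L/s)).  Lung volume is
referenced to functional residual capacity (FRC): ``volume = 0`` at the
end of a complete passive exhalation with zero PEEP.  Applied PEEP enters
as an additive baseline pressure, and spontaneous inspiratory effort as a
negative muscle pressure ``p_mus``:

    p_alv = volume / C + PEEP + p_mus
    p_aw  = p_alv + R(q) * q,   R(q) = r_insp if q >= 0 else r_exp

Spontaneous effort follows the half-sinusoidal profile used by active
servo lung simulators: a quarter-sine descent to ``-p_max`` over the
inspiratory fraction of the breath cycle, a quarter-cosine release back to
zero over the release fraction, and zero for the rest of the cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "LungModel",
    "MusclePattern",
    "LungState",
    "LUNG_PRESETS",
    "muscle_pressure",
    "lung_step",
    "airway_pressure",
]


@dataclass(frozen=True)
class LungModel:
    """Linear one-compartment lung.

    Parameters
    ----------
    compliance : float
        Lung compliance in mL/cmH2O.
    r_insp, r_exp : float
        Inspiratory / expiratory resistance in cmH2O/(L/s).
    label : str
        Free-text name of the model.
    """

    compliance: float
    r_insp: float
    r_exp: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.compliance > 0 and self.r_insp > 0 and self.r_exp > 0):
            raise ValueError(
                "compliance, r_insp and r_exp must all be positive "
                f"(got C={self.compliance}, Ri={self.r_insp}, Re={self.r_exp})"
            )

    @property
    def tau_exp(self) -> float:
        """Passive expiratory time constant R_exp * C, in seconds."""
        return self.r_exp * self.compliance / 1000.0


#: Bench lung presets: healthy lung plus three ARDS severities
#: (compliance mL/cmH2O, inspiratory and expiratory resistance cmH2O/(L/s)).
LUNG_PRESETS: dict[str, LungModel] = {
    "NORMAL": LungModel(50.0, 6.0, 6.0, label="Normal"),
    "ARDS1": LungModel(30.0, 6.0, 6.0, label="ARDS 1"),
    "ARDS2": LungModel(30.0, 11.0, 16.0, label="ARDS 2"),
    "ARDS3": LungModel(10.0, 20.0, 20.0, label="ARDS 3"),
}


@dataclass(frozen=True)
class MusclePattern:
    """Half-sinusoidal spontaneous-effort pattern.

    ``rate`` is the patient's own respiratory rate (breaths/min), ``p_max``
    the magnitude of the most negative muscle pressure (cmH2O).  The effort
    ramps down over ``insp_frac`` of the cycle and releases over
    ``release_frac``; defaults 20% / 15% of the cycle.
    """

    rate: float = 0.0
    p_max: float = 0.0
    insp_frac: float = 0.20
    release_frac: float = 0.15
    active: bool = False

    def __post_init__(self) -> None:
        if self.insp_frac + self.release_frac >= 1.0:
            raise ValueError(
                "insp_frac + release_frac must be < 1 "
                f"(got {self.insp_frac} + {self.release_frac})"
            )
        if self.p_max < 0:
            raise ValueError("p_max must be >= 0")
        if self.active and self.rate <= 0:
            raise ValueError("active pattern requires rate > 0")

    @property
    def period(self) -> float:
        """Breath-cycle period 60/rate in seconds (inf when inactive)."""
        return 60.0 / self.rate if self.rate > 0 else math.inf

    def effort_onsets(self, duration: float, t0: float = 0.0) -> list[float]:
        """Effort onset times within ``[t0, duration)`` (empty if passive)."""
        if not self.active:
            return []
        out = []
        t = t0
        while t < duration:
            out.append(t)
            t += self.period
        return out


PASSIVE = MusclePattern()


def muscle_pressure(t_in_cycle: float, pattern: MusclePattern) -> float:
    """Muscle pressure (cmH2O, <= 0) at time ``t_in_cycle`` into the patient cycle.

    Quarter-sine descent on ``[0, Ti)``, quarter-cosine release on
    ``[Ti, Ti+Tr)``, zero afterwards; continuous everywhere with minimum
    exactly ``-p_max`` at ``t = Ti``.
    """
    if not math.isfinite(t_in_cycle):
        raise ValueError("t_in_cycle must be finite")
    if not pattern.active or pattern.p_max == 0.0:
        return 0.0
    period = pattern.period
    ti = pattern.insp_frac * period
    tr = pattern.release_frac * period
    t = t_in_cycle % period
    if t < ti:
        return -pattern.p_max * math.sin(math.pi * t / (2.0 * ti))
    if t < ti + tr:
        return -pattern.p_max * math.cos(math.pi * (t - ti) / (2.0 * tr))
    return 0.0


@dataclass
class LungState:
    """Instantaneous lung state: volume above FRC (mL), pressures (cmH2O), time (s)."""

    volume: float = 0.0
    p_alv: float = 0.0
    p_mus: float = 0.0
    t: float = 0.0
    clamped: bool = False


def alveolar_pressure(volume: float, peep_applied: float, p_mus: float,
                      model: LungModel) -> float:
    return volume / model.compliance + peep_applied + p_mus


def airway_pressure(p_alv: float, q_in: float, model: LungModel) -> float:
    """Airway (patient-circuit) pressure for signed flow ``q_in`` in L/s."""
    r = model.r_insp if q_in >= 0 else model.r_exp
    return p_alv + r * q_in


def lung_step(state: LungState, q_in: float, peep_applied: float, dt: float,
              model: LungModel, pattern: MusclePattern = PASSIVE) -> LungState:
    """Advance the lung one explicit-Euler step of ``dt`` seconds.

    ``q_in`` is the signed flow at the airway opening in L/s (positive into
    the lung), held constant over the step.  Volume that would go negative
    is clamped to zero (the circuit's check valves prevent emptying below
    the FRC baseline) and flagged on the returned state.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if dt > 0.005:
        raise ValueError("dt must be <= 5 ms for a stable explicit step")
    if not (math.isfinite(state.volume) and math.isfinite(q_in)):
        raise ValueError("non-finite lung state or flow")
    t = state.t + dt
    volume = state.volume + q_in * dt * 1000.0
    clamped = False
    if volume < 0.0:
        volume = 0.0
        clamped = True
    p_mus = muscle_pressure(t % pattern.period, pattern) if pattern.active else 0.0
    p_alv = alveolar_pressure(volume, peep_applied, p_mus, model)
    return LungState(volume=volume, p_alv=p_alv, p_mus=p_mus, t=t, clamped=clamped)
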