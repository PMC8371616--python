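"""Closed-loop hybrid simulation: 1 ms plant integration, 10 ms controller.

One simulation couples the single-compartment lung, the bag/valve circuit
and the discrete assist-control logic.  The plant (lung + pneumatics)
integrates with explicit Euler at ``dt_plant`` (default 1 ms); the
controller samples the sensors and issues phase commands at the 100 Hz
sensor rate, held constant between ticks (zero-order hold).  For a fixed
seed the run is bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .alarms import AlarmEvent, AlarmManager
from .circuit import CircuitConfig, SpirometerCal, dp_from_flow, flow_from_dp
from .control import TICK, BreathEvent, Controller, Mode, Phase, VentSettings
from .lung import LungModel, MusclePattern, PASSIVE, muscle_pressure

__all__ = ["Scenario", "Waveform", "run_simulation", "run_suite", "PHASE_CODES"]

PHASE_CODES = {Phase.RELEASE: 0, Phase.COMPRESS: 1, Phase.HOLD: 2}
PHASE_NAMES = {v: k.value for k, v in PHASE_CODES.items()}

#: Breaths discarded before steady-state summaries: the adaptive volume
#: setpoint settles within a few breaths for a passive patient but takes
#: longer when the patient breathes spontaneously.
WARMUP_PASSIVE = 5
WARMUP_SPONTANEOUS = 10


@dataclass(frozen=True)
class Scenario:
    """A complete bench-test configuration."""

    lung: LungModel
    settings: VentSettings
    circuit: CircuitConfig = CircuitConfig()
    muscle: MusclePattern = PASSIVE
    cal: SpirometerCal = SpirometerCal()
    duration: float = 90.0
    dt_plant: float = 0.001
    noise_sigma: float = 0.0
    seed: int = 0
    label: str = "scenario"

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        n_sub = self.dt_plant and round(TICK / self.dt_plant)
        if not n_sub or abs(n_sub * self.dt_plant - TICK) > 1e-12:
            raise ValueError("dt_plant must divide the 10 ms controller tick")

    @property
    def warmup_breaths(self) -> int:
        return WARMUP_SPONTANEOUS if self.muscle.active else WARMUP_PASSIVE

    def effort_onsets(self) -> list[float]:
        return self.muscle.effort_onsets(self.duration)


@dataclass
class Waveform:
    """Recorded time series on the 100 Hz controller grid, plus events."""

    t: np.ndarray
    flow: np.ndarray        # L/min at the airway opening
    p_aw: np.ndarray        # cmH2O
    p_alv: np.ndarray       # cmH2O
    p_mus: np.ndarray       # cmH2O
    volume: np.ndarray      # mL above FRC
    phase: np.ndarray       # int codes, see PHASE_CODES
    breath_events: list[BreathEvent] = field(default_factory=list)
    alarm_events: list[AlarmEvent] = field(default_factory=list)
    scenario: Optional[Scenario] = None
    #: controller-side integrated volume (mL) per completed breath, for
    #: cross-checking the flow-threshold segmentation against the firmware
    breath_volumes: list[float] = field(default_factory=list)

    @property
    def sample_rate(self) -> float:
        return 1.0 / (self.t[1] - self.t[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_s": self.t, "flow_lpm": self.flow, "p_aw_cmh2o": self.p_aw,
            "p_alv_cmh2o": self.p_alv, "p_mus_cmh2o": self.p_mus,
            "volume_ml": self.volume, "phase": self.phase,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Waveform":
        df = pd.read_csv(path)
        required = {"t_s", "flow_lpm", "p_aw_cmh2o"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing waveform columns {sorted(missing)}")
        n = len(df)
        zeros = np.zeros(n)
        return cls(
            t=df["t_s"].to_numpy(float),
            flow=df["flow_lpm"].to_numpy(float),
            p_aw=df["p_aw_cmh2o"].to_numpy(float),
            p_alv=df.get("p_alv_cmh2o", pd.Series(zeros)).to_numpy(float),
            p_mus=df.get("p_mus_cmh2o", pd.Series(zeros)).to_numpy(float),
            volume=df.get("volume_ml", pd.Series(zeros)).to_numpy(float),
            phase=df.get("phase", pd.Series(np.zeros(n, int))).to_numpy(int),
        )

    def resample(self, rate: float = 64.0) -> "Waveform":
        """Linear resample onto a uniform grid at ``rate`` Hz (analysis option)."""
        t_new = np.arange(0.0, self.t[-1] + 1e-12, 1.0 / rate)
        interp = lambda y: np.interp(t_new, self.t, y)
        phase = self.phase[np.minimum(
            np.searchsorted(self.t, t_new, side="right") - 1, len(self.t) - 1)]
        return Waveform(t_new, interp(self.flow), interp(self.p_aw),
                        interp(self.p_alv), interp(self.p_mus),
                        interp(self.volume), phase,
                        self.breath_events, self.alarm_events, self.scenario)


def run_simulation(scenario: Scenario) -> Waveform:
    """Run one closed-loop scenario and return the recorded waveform."""
    lung = scenario.lung
    circ = scenario.circuit
    settings = scenario.settings
    cal = scenario.cal
    dt = scenario.dt_plant
    n_sub = round(TICK / dt)
    n_ticks = int(round(scenario.duration / TICK))

    rng = np.random.default_rng(scenario.seed)
    noisy = scenario.noise_sigma > 0.0

    # muscle-pressure lookup table, one patient cycle at plant resolution
    muscle = scenario.muscle
    if muscle.active and muscle.p_max > 0:
        cycle_n = max(1, round(muscle.period / dt))
        pmus_tab = np.array([muscle_pressure(i * dt, muscle) for i in range(cycle_n)])
    else:
        cycle_n = 1
        pmus_tab = np.zeros(1)

    ctrl = Controller(settings, stroke_time=circ.stroke_time,
                      bag_capacity=circ.bag_capacity)
    mgr = AlarmManager(settings, peep_setting=circ.peep_setting)

    c = lung.compliance
    r_in = lung.r_insp
    r_ex = lung.r_exp
    peep = circ.peep_setting
    pip = circ.pip_setting
    mech_max = circ.mechanical_max
    drive_rate = circ.drive_rate
    bag_cap = circ.bag_capacity
    run_on = settings.run_enable

    n = n_ticks + 1
    rec_flow = np.empty(n)
    rec_paw = np.empty(n)
    rec_palv = np.empty(n)
    rec_pmus = np.empty(n)
    rec_vol = np.empty(n)
    rec_phase = np.empty(n, dtype=np.int8)

    # initial plant state: empty lung at applied PEEP
    volume = 0.0
    p_mus = pmus_tab[0]
    p_alv = volume / c + peep + p_mus
    p_aw = p_alv
    q = 0.0
    rec_flow[0], rec_paw[0], rec_palv[0] = 0.0, p_aw, p_alv
    rec_pmus[0], rec_vol[0], rec_phase[0] = p_mus, volume, PHASE_CODES[Phase.RELEASE]

    n_breaths_done = 0
    step_ms = round(dt * 1e6)  # plant step in microseconds (exact integer time)
    t_us = 0

    for k in range(n_ticks):
        t = k * TICK
        # --- sensor sampling (adds optional Gaussian noise) ---
        dp_true = dp_from_flow(q * 60.0, cal)
        if noisy:
            dp_meas = dp_true + rng.normal(0.0, scenario.noise_sigma)
            paw_meas = p_aw + rng.normal(0.0, scenario.noise_sigma)
        else:
            dp_meas, paw_meas = dp_true, p_aw
        paw_meas = max(-cal.paw_range, min(cal.paw_range, paw_meas))
        flow_meas = flow_from_dp(dp_meas, cal)

        # --- controller tick ---
        n_mp = len(ctrl.max_pressure_events)
        phase = ctrl.step(t, paw_meas, flow_meas)
        halted_now = len(ctrl.max_pressure_events) > n_mp
        mgr.sample(t, paw_meas, phase, max_pressure_hit=halted_now)
        if len(ctrl.breath_volumes) > n_breaths_done:
            mgr.breath(t, ctrl.breath_volumes[-1], ctrl.breath_min_paw[-1])
            n_breaths_done = len(ctrl.breath_volumes)

        # --- plant: n_sub explicit-Euler substeps under the held command ---
        compress = run_on and phase is Phase.COMPRESS
        release = (not run_on) or phase is Phase.RELEASE
        st = ctrl.state
        q_sum = 0.0
        for _ in range(n_sub):
            if compress and st.delivered_drive < bag_cap:
                headroom = (pip - p_alv) / r_in
                q = drive_rate if drive_rate < headroom else (
                    headroom if headroom > 0.0 else 0.0)
                st.delivered_drive += q * dt * 1000.0
            elif release:
                if p_alv > peep:
                    q = -(p_alv - peep) / r_ex
                elif p_alv < 0.0:
                    q = -p_alv / r_in
                else:
                    q = 0.0
            else:  # HOLD (or bag empty): piston held, no flow
                q = 0.0
            q_sum += q
            volume += q * dt * 1000.0
            if volume < 0.0:
                volume = 0.0
            t_us += step_ms
            if muscle.active:
                p_mus = pmus_tab[(t_us // step_ms) % cycle_n]
            p_alv = volume / c + peep + p_mus
            p_aw = p_alv + (r_in if q >= 0.0 else r_ex) * q
            if p_aw > mech_max:
                p_aw = mech_max
        i = k + 1
        # flow channel is the tick-averaged delivered flow (what an
        # anti-aliased 100 Hz acquisition of the continuous flow would see)
        rec_flow[i] = q_sum / n_sub * 60.0
        rec_paw[i] = p_aw
        rec_palv[i] = p_alv
        rec_pmus[i] = p_mus
        rec_vol[i] = volume
        rec_phase[i] = PHASE_CODES[phase]
        if not (math.isfinite(volume) and math.isfinite(p_aw)):
            raise FloatingPointError(
                f"non-finite plant state at t={t:.3f} s in {scenario.label!r}")

    ctrl.finalize()
    t_grid = np.arange(n) * TICK
    # the recorded volume channel is integrated flow, as on the device
    # display ("the flow measured by the spirometer is integrated"); the
    # plant's own lung volume agrees with it to within half a sample
    rec_vol = np.concatenate(
        ([0.0], np.cumsum((rec_flow[1:] + rec_flow[:-1]) / 2.0) * TICK / 60.0 * 1000.0))
    return Waveform(t_grid, rec_flow, rec_paw, rec_palv, rec_pmus, rec_vol,
                    rec_phase, breath_events=ctrl.events,
                    alarm_events=mgr.log, scenario=scenario,
                    breath_volumes=list(ctrl.breath_volumes))


def _dedupe_labels(labels: list[str]) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for lab in labels:
        seen[lab] = seen.get(lab, 0) + 1
        out.append(lab if seen[lab] == 1 else f"{lab}_{seen[lab]}")
    return out


def run_suite(scenarios) -> pd.DataFrame:
    """Run a list of scenarios; one summary row each, failures propagated as rows.

    Duplicate scenario labels are suffixed deterministically (_2, _3, ...).
    """
    from .metrics import segment_breaths, summarize

    scenarios = list(scenarios)
    labels = _dedupe_labels([s.label for s in scenarios])
    rows = []
    for label, sc in zip(labels, scenarios):
        row: dict = {"label": label, "mode": sc.settings.mode.value,
                     "lung": sc.lung.label or "custom"}
        try:
            wave = run_simulation(sc)
            records = segment_breaths(wave)
            steady = records[sc.warmup_breaths:]
            summary = summarize(steady, efforts=sc.effort_onsets() or None)
            row.update(summary.as_dict())
            row["pip_max"] = max((r.pip for r in steady), default=float("nan"))
            row["n_alarms"] = len(wave.alarm_events)
            row["error"] = ""
        except Exception as exc:  # propagate per-scenario failure w/o aborting
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)
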