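"""Patient circuit: drive (piston + self-inflating bag), relief valves, sensors.

The drive compresses a self-inflating resuscitator bag at a piston-set
rate; the bag output is pressure-limited by a mechanical peak-inspiratory-
pressure (PIP) relief valve, and exhalation leaves through the patient
valve's exhaust port into a threshold PEEP valve.  Flow is measured by an
orifice spirometer whose flow is proportional to the square root of the
differential pressure across it; airway pressure by a gauge sensor.

All valves are ideal (instantaneous, no hysteresis): the PIP valve vents
exactly the excess flow needed to keep airway pressure at or below its
setting, and the PEEP valve passes expiratory flow only while alveolar
pressure exceeds the PEEP setting.  A patient inhaling against a disabled
drive draws room air through the bag's inlet-valve path, modeled with the
inspiratory resistance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CircuitConfig",
    "SpirometerCal",
    "SensorSample",
    "drive_flow",
    "pip_limit",
    "expiratory_flow",
    "inlet_flow",
    "flow_from_dp",
    "dp_from_flow",
    "calibrate_spirometer",
    "read_calibration_pairs",
    "write_calibration_pairs",
]

#: Absolute mechanical ceiling (cmH2O) no circuit pressure may exceed.
MECHANICAL_MAX = 60.0


@dataclass(frozen=True)
class CircuitConfig:
    """Mechanical circuit settings.

    ``pip_setting`` is the PIP relief-valve setting (adjustable 20-40
    cmH2O as constructed), ``peep_setting`` the PEEP valve (cmH2O),
    ``bag_capacity`` the deliverable bag volume (mL, 700-800 typical) and
    ``stroke_time`` the full piston down-stroke time (s).
    """

    pip_setting: float = 35.0
    peep_setting: float = 5.0
    bag_capacity: float = 750.0
    stroke_time: float = 0.5
    mechanical_max: float = MECHANICAL_MAX

    def __post_init__(self) -> None:
        if not 20.0 <= self.pip_setting <= 40.0:
            raise ValueError(
                f"pip_setting {self.pip_setting} outside constructed valve range 20-40 cmH2O"
            )
        if self.peep_setting < 0:
            raise ValueError("peep_setting must be >= 0")
        if self.bag_capacity <= 0 or self.stroke_time <= 0:
            raise ValueError("bag_capacity and stroke_time must be positive")

    @property
    def drive_rate(self) -> float:
        """Piston-set bag output in L/s during compression."""
        return self.bag_capacity / 1000.0 / self.stroke_time


@dataclass(frozen=True)
class SpirometerCal:
    """Square-root spirometer calibration: flow = sign(dp) * k * sqrt(|dp|).

    ``k`` in (L/min)/sqrt(cmH2O); ``dp_range`` and ``paw_range`` are the
    sensor full-scale ranges (readings are clipped there); 100 Hz sampling.
    """

    k: float = 60.0
    dp_range: float = 5.0
    paw_range: float = 50.0
    sample_rate: float = 100.0
    rms_residual: float = 0.0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("calibration coefficient k must be > 0")


@dataclass(frozen=True)
class SensorSample:
    """One 100 Hz sensor reading: gauge airway pressure, spirometer dp, derived flow."""

    t: float
    p_aw: float
    dp_spiro: float
    flow: float  # L/min, from flow_from_dp
    clipped: bool = False


def drive_flow(phase: str, cfg: CircuitConfig) -> float:
    """Bag output (L/s) commanded by the drive in a controller phase.

    COMPRESS: the piston squeezes the bag at its needle-valve-set rate
    (``bag_capacity/stroke_time``).  HOLD: the piston is held in place,
    zero flow with pressure maintained.  RELEASE: the piston retracts and
    the drive sources no flow.
    """
    if phase == "COMPRESS":
        return cfg.drive_rate
    if phase in ("HOLD", "RELEASE"):
        return 0.0
    raise ValueError(f"unknown controller phase {phase!r}")


def pip_limit(q_drive: float, p_alv: float, r_insp: float, cfg: CircuitConfig) -> float:
    """Flow actually delivered to the patient after the PIP relief valve.

    The valve vents whatever excess would push airway pressure
    ``p_alv + r_insp*q`` above the PIP setting, so delivered flow is
    ``min(q_drive, max(0, (pip_setting - p_alv)/r_insp))``.
    """
    if r_insp <= 0:
        raise ValueError("r_insp must be > 0")
    if q_drive < 0:
        raise ValueError("q_drive must be >= 0")
    headroom = (cfg.pip_setting - p_alv) / r_insp
    return min(q_drive, max(0.0, headroom))


def expiratory_flow(p_alv: float, r_exp: float, cfg: CircuitConfig) -> float:
    """Signed expiratory flow (L/s, <= 0) through the PEEP valve.

    The threshold valve passes flow only while alveolar pressure exceeds
    the PEEP setting, so exhalation alone can never pull the airway below
    PEEP.
    """
    if r_exp <= 0:
        raise ValueError("r_exp must be > 0")
    return -max(0.0, p_alv - cfg.peep_setting) / r_exp


def inlet_flow(p_alv: float, r_insp: float) -> float:
    """Flow (L/s, >= 0) drawn from room air through the bag inlet-valve path.

    Opens only when the patient's effort pulls alveolar pressure below
    atmospheric; this is what makes breathing through a disabled
    ventilator possible.
    """
    if r_insp <= 0:
        raise ValueError("r_insp must be > 0")
    return max(0.0, -p_alv) / r_insp


def flow_from_dp(dp: float, cal: SpirometerCal) -> float:
    """Flow (L/min) from spirometer differential pressure (cmH2O).

    Readings beyond the sensor range are clipped to ``+-dp_range``.
    """
    if not math.isfinite(dp):
        raise ValueError("dp must be finite")
    dp = max(-cal.dp_range, min(cal.dp_range, dp))
    return math.copysign(cal.k * math.sqrt(abs(dp)), dp)


def dp_from_flow(flow: float, cal: SpirometerCal) -> float:
    """Inverse of :func:`flow_from_dp` for ``|flow| <= k*sqrt(dp_range)``."""
    if not math.isfinite(flow):
        raise ValueError("flow must be finite")
    return math.copysign((flow / cal.k) ** 2, flow)


def calibrate_spirometer(pairs) -> SpirometerCal:
    """Fit the square-root coefficient k from (dp, flow) calibration pairs.

    Least-squares slope of flow against sqrt(dp) through the origin, as in
    a bench sweep against a reference flowmeter.  Requires at least three
    pairs with dp > 0; the RMS fit residual (L/min) is stored on the
    returned calibration.
    """
    pairs = np.asarray(list(pairs), dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        pairs = pairs.reshape(-1, 2)
    dp, flow = pairs[:, 0], pairs[:, 1]
    pos = dp > 0
    if pairs.shape[0] == 1 and pos.all():
        # single-point calibration: k = flow / sqrt(dp)
        k = float(flow[0] / math.sqrt(dp[0]))
        return SpirometerCal(k=k, rms_residual=0.0)
    if pos.sum() < 3:
        raise ValueError("need >= 3 calibration pairs with dp > 0")
    x = np.sqrt(dp[pos])
    y = flow[pos]
    k, *_ = np.linalg.lstsq(x[:, None], y, rcond=None)
    k = float(k[0])
    if k <= 0:
        raise ValueError("degenerate calibration fit (non-positive slope)")
    resid = y - k * x
    return SpirometerCal(k=k, rms_residual=float(np.sqrt(np.mean(resid**2))))


def read_calibration_pairs(path) -> np.ndarray:
    """Read calibration pairs from a 2-column CSV (dp_cmh2o, flow_lpm)."""
    import pandas as pd

    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected 2 columns (dp_cmh2o, flow_lpm)")
    return df.iloc[:, :2].to_numpy(dtype=float)


def write_calibration_pairs(path, pairs) -> None:
    import pandas as pd

    pd.DataFrame(np.asarray(pairs, dtype=float),
                 columns=["dp_cmh2o", "flow_lpm"]).to_csv(path, index=False)
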