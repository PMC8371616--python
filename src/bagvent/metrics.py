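"""Per-breath waveform analytics: segmentation, derived parameters, summaries.

Breaths are segmented from the flow signal alone (threshold crossings with
hysteresis), so the module works equally on simulator output and on
recorded third-party waveforms.  For each breath the derived parameters
are: tidal volume (integral of inspiratory flow), PIP and minimum pressure
(max/min airway pressure), measured inspiratory time (onset to first
expiratory crossing, i.e. including the inspiratory pause), breath
duration, and the expiratory:inspiratory time ratio.  Summaries report
mean and standard deviation over the supplied breaths, plus the fraction
of patient efforts that failed to trigger an assisted breath.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .control import Trigger

__all__ = [
    "BreathRecord",
    "MetricsSummary",
    "segment_breaths",
    "summarize",
    "write_breath_records",
    "write_summary",
]

#: Flow threshold for breath-onset detection (L/min), with re-arm hysteresis.
ONSET_THRESHOLD_LPM = 1.0
HYSTERESIS_LPM = 0.5
#: Expiratory crossing that ends the measured inspiratory time (L/min).
EXP_THRESHOLD_LPM = -1.0
#: A patient effort counts as triggered if a PATIENT breath starts within
#: this window after effort onset (shorter than the shortest breath period
#: tested, 1.5 s at 40 brpm).
EFFORT_MATCH_WINDOW = 0.3


@dataclass
class BreathRecord:
    t_start: float
    duration: float
    tidal_volume: float     # mL
    pip: float              # cmH2O
    peep_min: float         # cmH2O
    t_insp_measured: float  # s, onset to first expiratory crossing
    ie_ratio: float         # expiratory/inspiratory time, dimensionless
    trigger: Optional[Trigger] = None


@dataclass
class MetricsSummary:
    """Mean +- SD of the derived breath parameters over steady-state breaths."""

    n_breaths: int
    tv_mean: float
    tv_sd: float
    pip_mean: float
    pip_sd: float
    peep_mean: float
    peep_sd: float
    rr_mean: float
    rr_sd: float
    ie_mean: float
    ie_sd: float
    missed_fraction: Optional[float] = None

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "n_breaths", "tv_mean", "tv_sd", "pip_mean", "pip_sd",
            "peep_mean", "peep_sd", "rr_mean", "rr_sd", "ie_mean", "ie_sd")}
        d["missed_fraction"] = (
            float("nan") if self.missed_fraction is None else self.missed_fraction)
        return d


def _breath_onsets(t: np.ndarray, flow: np.ndarray) -> list[int]:
    """Indices where inspiratory flow crosses above the onset threshold,
    re-armed only after flow falls back below threshold - hysteresis."""
    onsets = []
    armed = True
    rearm = ONSET_THRESHOLD_LPM - HYSTERESIS_LPM
    for i in range(len(flow)):
        f = flow[i]
        if armed and f >= ONSET_THRESHOLD_LPM:
            onsets.append(i)
            armed = False
        elif not armed and f < rearm:
            armed = True
    return onsets


def segment_breaths(wave, match_events: bool = True) -> list[BreathRecord]:
    """Segment a waveform into breaths and compute the derived parameters.

    The final (incomplete) breath is dropped.  When the waveform carries
    controller breath events and ``match_events`` is true, each record's
    trigger type (TIMED/PATIENT) is taken from the nearest event within
    one breath of the onset; otherwise triggers are left ``None``.
    Returns an empty list (with a warning) when no onsets are found.
    """
    t = np.asarray(wave.t, dtype=float)
    flow = np.asarray(wave.flow, dtype=float)
    p_aw = np.asarray(wave.p_aw, dtype=float)
    onsets = _breath_onsets(t, flow)
    if len(onsets) < 2:
        warnings.warn("no breath onsets found in waveform", stacklevel=2)
        return []

    ev_t, ev_trig = None, None
    events = getattr(wave, "breath_events", None)
    if match_events and events:
        ev_t = np.array([e.t_start for e in events])
        ev_trig = [e.trigger for e in events]

    records: list[BreathRecord] = []
    for i0, i1 in zip(onsets[:-1], onsets[1:]):
        seg_flow = flow[i0:i1]
        seg_t = t[i0:i1]
        duration = t[i1] - t[i0]
        exp_idx = np.nonzero(seg_flow <= EXP_THRESHOLD_LPM)[0]
        if len(exp_idx) == 0:
            # no expiratory crossing: treat whole breath as inspiratory
            ti = duration
            insp_end = len(seg_flow)
        else:
            insp_end = int(exp_idx[0])
            ti = seg_t[insp_end] - seg_t[0]
        # integrate positive flow over the inspiratory window, extended one
        # sample before the crossing so the rising edge is not clipped off
        j0 = max(i0 - 1, 0)
        win_flow = np.clip(flow[j0: i0 + max(insp_end + 1, 2)], 0.0, None) / 60.0
        win_t = t[j0: i0 + max(insp_end + 1, 2)]
        tv = float(np.trapezoid(win_flow, win_t)) * 1000.0
        ie = (duration - ti) / ti if ti > 0 else math.nan
        trigger = None
        if ev_t is not None:
            j = int(np.argmin(np.abs(ev_t - t[i0])))
            if abs(ev_t[j] - t[i0]) <= duration:
                trigger = ev_trig[j]
        records.append(BreathRecord(
            t_start=float(t[i0]), duration=float(duration), tidal_volume=tv,
            pip=float(p_aw[i0:i1].max()), peep_min=float(p_aw[i0:i1].min()),
            t_insp_measured=float(ti), ie_ratio=float(ie), trigger=trigger))
    return records


def summarize(records: Sequence[BreathRecord],
              efforts: Optional[Sequence[float]] = None) -> MetricsSummary:
    """Mean/SD summary of breath records, plus the missed-effort fraction.

    ``efforts`` are patient effort onset times; an effort is missed when
    no PATIENT-triggered breath starts within ``EFFORT_MATCH_WINDOW`` of
    it.  The respiratory rate is 60 over the mean breath duration.
    """
    if not records:
        raise ValueError("cannot summarize an empty breath list")
    arr = lambda attr: np.array([getattr(r, attr) for r in records])
    tv, pip, peep = arr("tidal_volume"), arr("pip"), arr("peep_min")
    dur, ie = arr("duration"), arr("ie_ratio")
    rr = 60.0 / dur

    missed: Optional[float] = None
    if efforts is not None and len(efforts) > 0:
        patient_starts = np.array(
            [r.t_start for r in records if r.trigger is Trigger.PATIENT])
        n_miss = 0
        for e in efforts:
            if patient_starts.size == 0 or not np.any(
                    (patient_starts >= e) &
                    (patient_starts <= e + EFFORT_MATCH_WINDOW)):
                n_miss += 1
        missed = n_miss / len(efforts)

    sd = lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    return MetricsSummary(
        n_breaths=len(records),
        tv_mean=float(tv.mean()), tv_sd=sd(tv),
        pip_mean=float(pip.mean()), pip_sd=sd(pip),
        peep_mean=float(peep.mean()), peep_sd=sd(peep),
        rr_mean=float(60.0 / dur.mean()), rr_sd=sd(rr),
        ie_mean=float(ie.mean()), ie_sd=sd(ie),
        missed_fraction=missed)


def write_breath_records(path, records: Sequence[BreathRecord]) -> None:
    pd.DataFrame([{
        "t_start_s": r.t_start, "duration_s": r.duration,
        "tidal_volume_ml": r.tidal_volume, "pip_cmh2o": r.pip,
        "peep_min_cmh2o": r.peep_min, "t_insp_s": r.t_insp_measured,
        "ie_ratio": r.ie_ratio,
        "trigger": r.trigger.value if r.trigger else "",
    } for r in records]).to_csv(path, index=False)


def write_summary(path, summary: MetricsSummary) -> None:
    """Write a summary as a flat key/value text table."""
    with open(path, "w") as fh:
        for key, val in summary.as_dict().items():
            fh.write(f"{key}\t{val:.6g}\n" if isinstance(val, float)
                     else f"{key}\t{val}\n")
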