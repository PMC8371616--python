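# bagvent

A closed-loop simulator for an acute-shortage mechanical ventilator built
around a piston-compressed self-inflating bag resuscitator. The package
couples a configurable single-compartment patient lung to the ventilator's
assist-control logic and mechanical circuit, and provides the per-breath
waveform analytics used in bench verification of such devices — so the
control logic and its safety envelope (tidal-volume accuracy, pressure
limits, patient triggering, alarms) can be exercised and regression-tested
entirely in software.

It is intended for engineers and researchers working on emergency
ventilator designs, and for anyone studying patient–ventilator interaction
(trigger asynchrony, missed efforts) in a fully reproducible setting.

## The model

**Patient.** A linear one-compartment lung with compliance *C* (mL/cmH₂O)
and phase-dependent resistance *R*ᵢ/*R*ₑ (cmH₂O/(L/s)), referenced to FRC:

```
p_alv = V/C + PEEP + p_mus          p_aw = p_alv + R(q)·q
```

Spontaneous effort `p_mus(t)` is a half-sinusoidal profile: a quarter-sine
descent to −*P*max over the inspiratory fraction of the patient's cycle
(default 20%) and a quarter-cosine release (15%). Four bench presets are
bundled (NORMAL: C=50, R=6/6; three ARDS severities down to C=10, R=20/20).

**Ventilator.** The drive compresses the bag at a piston-set rate
(750 mL / 0.5 s stroke); the output is pressure-limited by a mechanical PIP
relief valve, and exhalation passes through a threshold PEEP valve. The
controller samples pressure and spirometer flow at 100 Hz and cycles
COMPRESS → HOLD → RELEASE:

* **VC-AC** — spirometer flow is integrated and the stroke stops at an
  adaptive volume setpoint, updated breath-to-breath by
  `setpoint += 0.5·(set volume − delivered)`; the rest of the inspiratory
  time is a zero-flow inspiratory pause.
* **PC-AC** — the piston is held against the PIP valve for the whole
  inspiratory time, so delivered volume approaches `C·(PIP − PEEP)`.
* Breaths start on the rate clock (TIMED) or when patient effort pulls
  airway pressure below the absolute trigger threshold during exhalation
  (PATIENT), which resets the clock.
* A software maximum-pressure check halts compression for the cycle;
  volume/pressure alarm conditions are evaluated per breath and per sample
  with HIGH/MEDIUM priorities and latching semantics.

The plant integrates with explicit Euler at 1 ms; controller commands are
held between 10 ms ticks (zero-order hold). Runs are bit-identical for a
fixed seed.

## Worked example

```sh
bagvent run --scenario normal_vcac_400
```

runs the reference scenario — normal lung, VC-AC, set tidal volume 400 mL,
RR 20 brpm, inspiratory time 1.0 s, PEEP 5, PIP valve 35 — and prints the
steady-state summary over 22 breaths (after a 5-breath warm-up):

```
{
  "label": "normal_vcac_400",
  "n_breaths": 22,
  "tv_mean": 400.22727272727354,
  "tv_sd": 7.150969419342493,
  "pip_mean": 22.014615032157693,
  "pip_sd": 0.14292337368680882,
  "peep_mean": 4.974075474609651,
  "peep_sd": 0.0004623079979703596,
  "rr_mean": 20.0,
  "rr_sd": 1.1783018260144473e-14,
  "ie_mean": 1.9999999999999991,
  "ie_sd": 3.1371928395872296e-15
}
```

Delivered volume sits on the 400 mL setpoint (the ±7 mL spread is the
controller's 10 ms volume quantization), peak pressure is ~22 cmH₂O —
well under the 35 cmH₂O valve — end-expiratory pressure equals the set
PEEP, the rate is exactly 20 brpm, and the measured I:E is 1:2.0 for a
1.0 s inspiration in a 3.0 s cycle.

The same can be done from Python:

```python
import bagvent as bv

sc = bv.REFERENCE_SCENARIOS["ards3_pcac"]       # PC-AC on the stiffest lung
wave = bv.run_simulation(sc)                     # 100 Hz Waveform + events
records = bv.segment_breaths(wave)               # per-breath parameters
print(bv.summarize(records[sc.warmup_breaths:]).tv_mean)   # ~248 mL
```

Other entry points: `bagvent suite --grid requirements --report r.csv`
(the bundled 29-scenario lungs × settings grid), `bagvent metrics --in
wave.csv` (analytics on a recorded waveform), `bagvent
calibrate-spirometer --pairs cal.csv` (square-root orifice-flowmeter fit),
`bagvent presets`. Scenario files are flat YAML keyed by the front-panel
parameter names; see `bagvent.scenarios`.

## Layout

| module | contents |
| --- | --- |
| `bagvent.lung` | single-compartment mechanics, effort profile, presets |
| `bagvent.circuit` | drive, PIP/PEEP valves, spirometer + calibration |
| `bagvent.control` | assist-control state machine, triggering, adaptive setpoint |
| `bagvent.alarms` | per-breath/per-sample alarm evaluation, priorities, latching |
| `bagvent.engine` | hybrid simulation loop, `Waveform`, suite runner |
| `bagvent.metrics` | breath segmentation, derived parameters, summaries |
| `bagvent.scenarios` | presets, scenario grids, config parsing/serialization |
| `bagvent.cli` | command-line interface |

See `docs/methods.md` for modeling assumptions, numerical choices and
known limitations.
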