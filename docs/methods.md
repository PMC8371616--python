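# Methods

## Scope and intent

`bagvent` is a software re-creation of the bench-verification setup for a
piston-driven bag-resuscitator ventilator: a servo-lung-style simulated
patient, the ventilator's control logic and mechanical circuit, and the
per-breath analysis pipeline. It is a behavioral model of the control
system and its safety envelope, not a computational-fluid-dynamics or
gas-exchange model.

## Patient model

The patient is the standard linear one-compartment system used on bench
lung simulators: volume `V` (mL above FRC) on a compliance `C`
(mL/cmH2O), in series with a resistance that switches between an
inspiratory and an expiratory value (cmH2O/(L/s)):

    p_alv = V/C + PEEP + p_mus
    p_aw  = p_alv + R(q)·q,   R(q) = r_insp for q >= 0, else r_exp

PEEP enters as an additive baseline: `V = 0` is the end of a complete
passive exhalation at zero PEEP. The four bundled presets (NORMAL 50/6/6,
ARDS1 30/6/6, ARDS2 30/11/16, ARDS3 10/20/20) follow the convention that
resistance is in cmH2O·s/L, so the normal lung's passive expiratory time
constant is `tau = R·C = 0.3 s`. Endotracheal-tube resistance is folded
into these values rather than modeled separately, since no separate tube
parameter is available.

Spontaneous effort is a half-sinusoidal muscle-pressure profile: a
quarter-sine descent from 0 to `-p_max` over the inspiratory fraction of
the patient's cycle (default 20%), a quarter-cosine release back to 0
over the release fraction (default 15%), zero for the rest. The profile
is continuous, with its minimum exactly `-p_max` at the end of the
inspiratory fraction. No patient inspiratory pause or active expiration
is modeled.

## Circuit model

All mechanical elements are ideal:

* **Drive** — a flow source: `bag_capacity / stroke_time` (default
  750 mL / 0.5 s = 1.5 L/s) while the piston descends, zero when held.
  The bag has no elasticity of its own; cumulative delivered volume per
  breath is capped at the bag capacity.
* **PIP relief valve** — vents instantaneously whatever excess flow would
  push `p_alv + r_insp·q` above its setting (constructed range 20–40
  cmH2O), so delivered flow is `min(q_drive, (PIP − p_alv)/r_insp)`.
  A 60 cmH2O mechanical ceiling is enforced as an absolute clamp.
* **PEEP valve** — a threshold check valve passing
  `(p_alv − PEEP)/r_exp` only while alveolar pressure exceeds the PEEP
  setting; intrinsic PEEP emerges naturally when expiratory time is
  short.
* **Inlet path** — patient effort that pulls alveolar pressure below
  atmospheric draws room air through the bag's inlet valve against
  `r_insp`; this is what makes breathing through a disabled ventilator
  possible (and is how the monitoring-only scenario works).
* **Spirometer** — an orifice element: `flow = sign(dp)·k·sqrt(|dp|)`,
  with sensor ranges 5 cmH2O (differential) and 50 cmH2O (gauge),
  sampled at 100 Hz. The coefficient `k` is fitted from calibration
  pairs by a least-squares slope of flow against `sqrt(dp)` through the
  origin. The numeric value of `k` is not critical to the closed loop
  (the round trip dp → flow → dp is exact within sensor range); the
  default k = 60 (L/min)/√cmH2O puts full scale at ~134 L/min,
  comfortably above the ~90 L/min peak flows the drive can produce.
* **Noise** — optional zero-mean Gaussian noise on both sensors with a
  configurable sigma and seed, off by default so the bundled scenarios
  are deterministic.

## Controller

The controller runs at the 100 Hz sensor rate and is total: each tick it
consumes one sample and returns a phase command, held by the plant until
the next tick.

* Phases cycle COMPRESS → HOLD → RELEASE. A breath starts on the rate
  clock (period `60/RR`) or on a patient trigger, which resets the clock.
* **Trigger** — strict `p_aw < threshold` on the absolute gauge reading,
  evaluated only during RELEASE and not within 200 ms of its start. The
  refractory interval prevents re-triggering on the release transient;
  the source device's firmware behavior here is unpublished, so the value
  is this package's choice. Threshold values quoted relative to PEEP are
  converted to absolute at configuration load (PEEP − 2 → 3 at PEEP 5).
* **VC-AC** — integrated (calibrated) flow is compared against an
  adaptive setpoint each tick; compression stops there, or at the stroke
  end, whichever is first, and the breath holds until the inspiratory
  time. The setpoint starts at the set volume and updates per breath by
  `s += g·(V_set − V_delivered)` with gain g = 0.5, clamped to
  [0, bag capacity]. The breath-to-breath error contracts by
  `(1 − g·b)` per breath for plant gain b, so a 20% initial offset is
  inside 2% by the fifth breath; the residual steady-state wobble is the
  one-tick volume quantum (1.5 L/s × 10 ms = 15 mL).
* **PC-AC** — the piston is held against the PIP relief valve for the
  whole inspiratory time, so delivered flow stays pressure-limited and
  volume approaches `C·(PIP − PEEP)` with time constant `r_insp·C`
  (0.2 s for the stiffest preset). The drive-flow operation reports zero
  drive flow in HOLD; in PC-AC the compress window simply extends to the
  full inspiratory time, which is what makes the stiff-lung tidal volume
  approach its quasi-static bound within ~4% — a true 0.5 s stroke
  followed by a sealed hold would stall at ~92% of it. The volume
  integrator still runs (for alarms) but does not stop the stroke.
* **Maximum pressure** — if the gauge reading reaches the software
  maximum-pressure parameter during compression, compression halts for
  the remainder of the cycle and a high-priority alarm is raised in the
  same tick.

## Alarms

Per-breath: volume out of band (PC-AC: < 250 mL, high priority; VC-AC:
< 80% of set volume, medium, or > 120%, medium) and end-expiratory
pressure below the PEEP-minimum warning threshold (high). Per-sample:
maximum pressure (high), sustained low circuit pressure (below the
PEEP-minimum threshold during exhalation for more than one breath
period — high), and continuing airway pressure (above PEEP + 5 cmH2O
for two breath periods — high; the threshold and duration are this
package's reading of the applicable alarm standard, which the source
material defers to without numbers). Power-lost and standby-battery
alarms have no physical model here; they are injectable events that
exercise the priority and latching logic. An event stays active until
its condition is no longer met.

The volume-high condition is defined on tidal volume exceeding 120% of
the set maximum volume (the device's alarm table garbles this row as
"pressure exceeds 120% of maximum volume"; volume is the evident intent).

## Numerics

* Plant: explicit Euler at dt = 1 ms. The shortest mechanical time
  constant in any bundled scenario is 0.2 s, two hundred steps per time
  constant, so Euler is stable and accurate here; halving dt changes
  delivered tidal volume by < 0.5% (tested). dt must divide the 10 ms
  controller tick.
* Internal time is carried as an integer microsecond counter, so breath
  periods are exact (no float drift over long runs); muscle pressure is
  read from a per-cycle lookup table at plant resolution.
* The recorded flow channel is the tick-averaged delivered flow — what an
  anti-aliased 100 Hz acquisition of the continuous signal would see —
  and the recorded volume channel is its running trapezoid integral, as
  on the device display ("volume computed by integrating the flow").
  The plant's internal lung volume agrees with the recorded channel to
  within half a sample interval (≤ 7.5 mL at peak flow). A 64 Hz
  resampling option mirrors the bench acquisition rate.
* Breath segmentation works from the flow signal alone so it applies to
  third-party recordings: onset at an upward crossing of +1 L/min
  (re-armed below +0.5 L/min), inspiratory time from onset to the first
  crossing below −1 L/min — a convention that includes the zero-flow
  inspiratory pause. Tidal volume is the trapezoid integral of positive
  flow over the inspiratory window, extended one sample before the
  crossing so the rising edge is not clipped. Thresholds sit well above
  numerical noise and far below peak flows (~90 L/min).
* Warm-up: summaries exclude the first 5 breaths (passive scenarios) or
  10 (spontaneous), after which the adaptive setpoint has settled.
  Default scenario durations cover warm-up plus 22 steady-state breaths
  (81 s at 20 brpm; 163 s at 10 brpm); the spontaneous reference runs
  210 s so that at least 100 patient efforts are observed.

## Bundled scenario grid

The requirements suite crosses the four lung presets with the
ventilator-settings grid: VC-AC set volumes {250, 300, 400, 500, 600} mL
(20 scenarios) and PC-AC at PIP valve settings {25, 35} cmH2O (8), plus
the spontaneous-trigger reference (29 total), at the fixed points RR 20
brpm, inspiratory time 1.0 s (I:E 1:2), PIP valve 35 cmH2O for VC-AC,
and PEEP 5 (normal lung) or 10 cmH2O (ARDS). The exact scenario roster
used on the physical bench was never published; this grid is the
package's documented reconstruction, and suite-level statistics (e.g.
the highest mean PIP) should be read with that in mind.

## What the simulator does and does not show

Passing tests demonstrate that the control logic meets its specification
against an idealized linear plant: volume accuracy, rate accuracy, I:E
behavior, the pressure envelope, trigger behavior and alarm logic. They
do not validate against real-gas effects, bag elasticity, valve dynamics
and hysteresis, sensor latency, tubing compliance or leaks — none of
which are modeled.

The sharpest known consequence concerns missed patient efforts. With a
spontaneous patient at 30 brpm (−5 cmH2O) against the ventilator at 20
brpm, the physical device missed about 1 effort in 10 because pressure
did not reliably fall below the trigger threshold in the shortened
exhalation. The deterministic simulator instead phase-locks: every
effort lands in exhalation with a ~2.6 cmH2O trigger margin and triggers
~0.13 s after onset, so the measured missed fraction is ~2% (the initial
mandatory breath plus an end-of-run edge). Sweeping the unstated
inspiratory time shows a sharp bifurcation — full lock (~2%) up to
1.3 s, heavy asynchrony (~50%) from 1.4 s — with no deterministic
setting reproducing an intermediate rate: the hardware evidently
operated near this bifurcation, where latencies and noise convert
marginal triggers into intermittent misses. The ideal-valve,
zero-latency trigger path cannot, and the scenario is kept at its
natural fixed point (inspiratory time 1.0 s) rather than repositioned to
chase the hardware number.

## Known limitations

* Single linear compartment; no nonlinear compliance, airway collapse,
  multi-compartment heterogeneity, or gas exchange.
* Ideal valves and flow sources; no supply-pressure dynamics, oxygen
  blending, or HME/filter resistance.
* PC-AC at high compliance is bag-capacity-limited (the drive delivers
  at most 750 mL), which caps deliverable volume rather than pressure.
* The controller volume integrator uses calibrated spirometer flow;
  whether the physical firmware integrates raw or calibrated flow is
  unpublished.
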