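"""Preset catalog, scenario configuration parsing and serialization.

Scenario configs are flat key/value YAML files whose keys follow the
device's front-panel parameter names (snake-cased): ``control_mode``,
``respiration_rate``, ``inspiratory_time``, ``maximum_volume``,
``maximum_pressure``, ``pip``, ``peep``, ``peep_minimum``,
``trigger_threshold`` (absolute) or ``trigger_threshold_rel`` (relative
to PEEP, converted at load time), ``run_enable``; plus lung
(``lung_model`` preset name or ``lung_compliance``/``lung_r_insp``/
``lung_r_exp``), patient effort (``patient_rate``, ``patient_p_max``,
``patient_insp_frac``, ``patient_release_frac``) and run keys
(``duration``, ``seed``, ``noise_sigma``, ``label``, ``bag_capacity``,
``stroke_time``, ``spirometer_k``).

Out-of-range settings load with a warning rather than an error — the
device itself allows them; the recommended ranges are the settings grid
below.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import yaml

from .circuit import CircuitConfig, SpirometerCal
from .control import Mode, VentSettings
from .engine import Scenario
from .lung import LUNG_PRESETS, LungModel, MusclePattern, PASSIVE

__all__ = [
    "SETTINGS_GRID",
    "REFERENCE_SCENARIOS",
    "load_scenario",
    "serialize_scenario",
    "preset_names",
    "requirements_suite",
    "tv_sweep",
    "rr_sweep",
    "ie_table_scenarios",
    "spontaneous_reference",
    "duration_for",
]

#: Recommended ventilator-settings ranges per mode (the bench-test grid).
SETTINGS_GRID = {
    "VC_AC": {
        "respiration_rate": (10, 30),
        "maximum_volume": (250, 600),
        "pip": (15, 35),
        "inspiratory_time": (0.6, 1.5),
        "trigger_threshold_rel": (-5, -2),
        "peep": (5, 20),
    },
    "PC_AC": {
        "respiration_rate": (10, 30),   # device table prints 20-40; required range is 10-30
        "pip": (25, 35),
        "inspiratory_time": (1.0, 1.0),
        "peep": (5, 20),
    },
}

#: Extra steady-state breaths collected after warm-up for a valid summary.
STEADY_BREATHS = 22


def duration_for(rr: float, warmup: int = 5, steady: int = STEADY_BREATHS) -> float:
    """Simulation length covering ``warmup + steady`` breaths at rate ``rr``."""
    return round((warmup + steady) * 60.0 / rr + 1.0)


def _make(lung_name: str, mode: Mode, label: str, *, max_volume: float = 400.0,
          rr: float = 20.0, t_insp: float = 1.0, pip: float = 35.0,
          peep: float = 5.0, trigger: float = 3.0, peep_min: float = 0.0,
          muscle: MusclePattern = PASSIVE, duration: float | None = None,
          run_enable: bool = True, seed: int = 0) -> Scenario:
    lung = LUNG_PRESETS[lung_name]
    warmup = 10 if muscle.active else 5
    if duration is None:
        duration = duration_for(rr, warmup)
    settings = VentSettings(mode=mode, rr_set=rr, t_insp=t_insp,
                            max_volume=max_volume, trigger_threshold=trigger,
                            peep_min=peep_min, run_enable=run_enable)
    circuit = CircuitConfig(pip_setting=pip, peep_setting=peep)
    return Scenario(lung=lung, settings=settings, circuit=circuit,
                    muscle=muscle, duration=duration, seed=seed, label=label)


def spontaneous_reference(duration: float = 210.0, seed: int = 0) -> Scenario:
    """The spontaneous-trigger bench test: active patient at 30 brpm with
    -5 cmH2O maximal effort versus VC-AC at 20 brpm, TV 400 mL, PEEP 5,
    absolute trigger threshold 3 cmH2O (PEEP - 2)."""
    muscle = MusclePattern(rate=30.0, p_max=5.0, insp_frac=0.20,
                           release_frac=0.15, active=True)
    return _make("NORMAL", Mode.VC_AC, "spontaneous_trigger", max_volume=400,
                 rr=20, t_insp=1.0, pip=35, peep=5, trigger=3.0,
                 muscle=muscle, duration=duration, seed=seed)


def _reference_catalog() -> dict[str, Scenario]:
    monitor_muscle = MusclePattern(rate=15.0, p_max=5.0, active=True)
    return {
        "normal_vcac_400": _make("NORMAL", Mode.VC_AC, "normal_vcac_400"),
        "normal_vcac_300": _make("NORMAL", Mode.VC_AC, "normal_vcac_300",
                                 max_volume=300),
        "ards2_vcac_300": _make("ARDS2", Mode.VC_AC, "ards2_vcac_300",
                                max_volume=300, peep=10),
        "ards3_pcac": _make("ARDS3", Mode.PC_AC, "ards3_pcac",
                            pip=35, peep=10),
        "normal_pcac_25": _make("NORMAL", Mode.PC_AC, "normal_pcac_25", pip=25),
        "spontaneous_trigger": spontaneous_reference(),
        "disabled_monitoring": _make(
            "NORMAL", Mode.VC_AC, "disabled_monitoring", peep=0.0,
            peep_min=3.0, muscle=monitor_muscle, duration=60.0,
            run_enable=False),
    }


REFERENCE_SCENARIOS = _reference_catalog()


def preset_names() -> dict[str, list[str]]:
    return {"lungs": list(LUNG_PRESETS), "scenarios": list(REFERENCE_SCENARIOS)}


# ---------------------------------------------------------------------------
# bundled test suites
# ---------------------------------------------------------------------------

def tv_sweep(lung_name: str = "NORMAL",
             volumes=(250, 300, 400, 500, 600), seed: int = 0) -> list[Scenario]:
    """VC-AC set-volume sweep on one lung (RR 20, Ti 1.0, PIP 35)."""
    peep = 5.0 if lung_name == "NORMAL" else 10.0
    trigger = peep - 2.0
    return [_make(lung_name, Mode.VC_AC,
                  f"vcac_{lung_name.lower()}_tv{int(v)}", max_volume=float(v),
                  peep=peep, trigger=trigger, seed=seed)
            for v in volumes]


def rr_sweep(rates=(10, 15, 20, 25, 30), seed: int = 0) -> list[Scenario]:
    """VC-AC respiratory-rate sweep on the normal lung (TV 400, Ti 1.0)."""
    return [_make("NORMAL", Mode.VC_AC, f"vcac_normal_rr{int(rr)}",
                  rr=float(rr), seed=seed) for rr in rates]


def ie_table_scenarios(t_insps=(1.5, 1.0, 0.75, 0.6), seed: int = 0) -> list[Scenario]:
    """Inspiratory-time sweep at RR 20 (TV 400, PEEP 5, PIP 35) for the
    inspiratory-to-expiratory ratio table."""
    return [_make("NORMAL", Mode.VC_AC, f"vcac_normal_ti{ti:g}",
                  t_insp=float(ti), seed=seed) for ti in t_insps]


def requirements_suite(seed: int = 0) -> list[Scenario]:
    """The bundled 29-scenario requirements grid.

    All four lung models crossed with the VC-AC set-volume grid
    {250,300,400,500,600} mL (20 scenarios) and with PC-AC at PIP valve
    settings {25, 35} cmH2O (8), plus the spontaneous-trigger reference
    (1).  Fixed points: RR 20 brpm, Ti 1.0 s (I:E 1:2), PIP valve 35 for
    VC-AC, PEEP 5 for the normal lung and 10 for the ARDS models.
    """
    out: list[Scenario] = []
    for lung_name in LUNG_PRESETS:
        out.extend(tv_sweep(lung_name, seed=seed))
    for lung_name in LUNG_PRESETS:
        peep = 5.0 if lung_name == "NORMAL" else 10.0
        for pip in (25.0, 35.0):
            out.append(_make(lung_name, Mode.PC_AC,
                             f"pcac_{lung_name.lower()}_pip{int(pip)}",
                             pip=pip, peep=peep, trigger=peep - 2.0, seed=seed))
    out.append(spontaneous_reference(seed=seed))
    return out


# ---------------------------------------------------------------------------
# configuration files
# ---------------------------------------------------------------------------

_DEFAULTS = {
    "label": "scenario",
    "run_enable": True,
    "control_mode": "VC_AC",
    "respiration_rate": 20.0,
    "inspiratory_time": 1.0,
    "maximum_volume": 400.0,
    "maximum_pressure": 40.0,
    "pip": 35.0,
    "peep": 5.0,
    "peep_minimum": 0.0,
    "trigger_threshold": 3.0,
    "lung_model": "NORMAL",
    "patient_rate": 0.0,
    "patient_p_max": 0.0,
    "patient_insp_frac": 0.20,
    "patient_release_frac": 0.15,
    "bag_capacity": 750.0,
    "stroke_time": 0.5,
    "spirometer_k": 60.0,
    "duration": 85.0,
    "noise_sigma": 0.0,
    "seed": 0,
}


def _check_ranges(cfg: dict) -> None:
    grid = SETTINGS_GRID[cfg["control_mode"]]
    for key, (lo, hi) in grid.items():
        if key not in cfg or key == "trigger_threshold_rel":
            continue
        val = cfg[key]
        if not lo <= val <= hi:
            warnings.warn(
                f"{key}={val} is outside the recommended range [{lo}, {hi}]",
                stacklevel=3)


def load_scenario(source: Union[str, Path, dict]) -> Scenario:
    """Build a Scenario from a preset name, a config file, or a mapping.

    Unknown preset names raise with the list of available names; an empty
    file yields the all-defaults passive normal-lung scenario.
    """
    if isinstance(source, str) and source in REFERENCE_SCENARIOS:
        return REFERENCE_SCENARIOS[source]
    if isinstance(source, dict):
        user = dict(source)
    else:
        path = Path(source)
        if not path.exists():
            raise KeyError(
                f"unknown preset or missing file {source!r}; available presets: "
                + ", ".join(REFERENCE_SCENARIOS))
        try:
            user = yaml.safe_load(path.read_text()) or {}
        except yaml.YAMLError as exc:
            mark = getattr(exc, "problem_mark", None)
            line = f" at line {mark.line + 1}" if mark else ""
            raise ValueError(f"malformed scenario file {path}{line}: {exc}") from exc
        if not isinstance(user, dict):
            raise ValueError(f"{path}: expected a flat key/value mapping")

    unknown = set(user) - set(_DEFAULTS) - {"trigger_threshold_rel",
                                            "lung_compliance", "lung_r_insp",
                                            "lung_r_exp"}
    if unknown:
        raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
    cfg = {**_DEFAULTS, **user}

    if "trigger_threshold_rel" in user:
        # relative-to-PEEP trigger values are converted to the absolute
        # comparison the firmware performs
        cfg["trigger_threshold"] = cfg["peep"] + float(user["trigger_threshold_rel"])

    if {"lung_compliance", "lung_r_insp", "lung_r_exp"} & set(user):
        lung = LungModel(float(cfg.get("lung_compliance", 50.0)),
                         float(cfg.get("lung_r_insp", 6.0)),
                         float(cfg.get("lung_r_exp", 6.0)), label="custom")
    else:
        name = str(cfg["lung_model"]).upper()
        if name not in LUNG_PRESETS:
            raise KeyError(f"unknown lung model {name!r}; available: "
                           + ", ".join(LUNG_PRESETS))
        lung = LUNG_PRESETS[name]

    _check_ranges(cfg)
    if cfg["run_enable"] and cfg["trigger_threshold"] >= cfg["peep"]:
        warnings.warn(
            f"trigger_threshold {cfg['trigger_threshold']} is not below PEEP "
            f"{cfg['peep']}: the ventilator will self-trigger continuously",
            stacklevel=2)

    muscle = PASSIVE
    if cfg["patient_rate"] and cfg["patient_p_max"]:
        muscle = MusclePattern(rate=float(cfg["patient_rate"]),
                               p_max=float(cfg["patient_p_max"]),
                               insp_frac=float(cfg["patient_insp_frac"]),
                               release_frac=float(cfg["patient_release_frac"]),
                               active=True)

    settings = VentSettings(
        mode=Mode(cfg["control_mode"]), rr_set=float(cfg["respiration_rate"]),
        t_insp=float(cfg["inspiratory_time"]),
        max_volume=float(cfg["maximum_volume"]),
        max_pressure=float(cfg["maximum_pressure"]),
        trigger_threshold=float(cfg["trigger_threshold"]),
        peep_min=float(cfg["peep_minimum"]), run_enable=bool(cfg["run_enable"]))
    circuit = CircuitConfig(pip_setting=float(cfg["pip"]),
                            peep_setting=float(cfg["peep"]),
                            bag_capacity=float(cfg["bag_capacity"]),
                            stroke_time=float(cfg["stroke_time"]))
    return Scenario(lung=lung, settings=settings, circuit=circuit,
                    muscle=muscle, cal=SpirometerCal(k=float(cfg["spirometer_k"])),
                    duration=float(cfg["duration"]),
                    noise_sigma=float(cfg["noise_sigma"]),
                    seed=int(cfg["seed"]), label=str(cfg["label"]))


def serialize_scenario(sc: Scenario) -> str:
    """Serialize a Scenario to flat YAML; ``load_scenario`` round-trips it."""
    lung_preset = next((k for k, v in LUNG_PRESETS.items() if v == sc.lung), None)
    cfg: dict = {
        "label": sc.label,
        "run_enable": sc.settings.run_enable,
        "control_mode": sc.settings.mode.value,
        "respiration_rate": sc.settings.rr_set,
        "inspiratory_time": sc.settings.t_insp,
        "maximum_volume": sc.settings.max_volume,
        "maximum_pressure": sc.settings.max_pressure,
        "pip": sc.circuit.pip_setting,
        "peep": sc.circuit.peep_setting,
        "peep_minimum": sc.settings.peep_min,
        "trigger_threshold": sc.settings.trigger_threshold,
        "bag_capacity": sc.circuit.bag_capacity,
        "stroke_time": sc.circuit.stroke_time,
        "spirometer_k": sc.cal.k,
        "duration": sc.duration,
        "noise_sigma": sc.noise_sigma,
        "seed": sc.seed,
    }
    if lung_preset:
        cfg["lung_model"] = lung_preset
    else:
        cfg.update(lung_compliance=sc.lung.compliance,
                   lung_r_insp=sc.lung.r_insp, lung_r_exp=sc.lung.r_exp)
    if sc.muscle.active:
        cfg.update(patient_rate=sc.muscle.rate, patient_p_max=sc.muscle.p_max,
                   patient_insp_frac=sc.muscle.insp_frac,
                   patient_release_frac=sc.muscle.release_frac)
    buf = io.StringIO()
    yaml.safe_dump(cfg, buf, sort_keys=False)
    return buf.getvalue()
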