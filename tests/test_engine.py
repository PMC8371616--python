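"""Closed-loop simulation engine: determinism, convergence, mode behavior."""

import dataclasses

import numpy as np
import pytest

import bagvent as bv
from bagvent.control import Mode, VentSettings
from bagvent.engine import Scenario, Waveform, run_simulation, run_suite
from bagvent.lung import LUNG_PRESETS, MusclePattern


def short_scenario(**kw):
    base = bv.REFERENCE_SCENARIOS["normal_vcac_400"]
    kw.setdefault("duration", 30.0)
    return dataclasses.replace(base, **kw)


class TestDeterminism:
    def test_bit_identical_reruns(self):
        sc = short_scenario(noise_sigma=0.3, seed=42)
        w1, w2 = run_simulation(sc), run_simulation(sc)
        assert np.array_equal(w1.flow, w2.flow)
        assert np.array_equal(w1.p_aw, w2.p_aw)
        assert np.array_equal(w1.volume, w2.volume)
        assert [e.t_start for e in w1.breath_events] == \
               [e.t_start for e in w2.breath_events]

    def test_seed_changes_noisy_run(self):
        a = run_simulation(short_scenario(noise_sigma=0.3, seed=1, duration=10.0))
        b = run_simulation(short_scenario(noise_sigma=0.3, seed=2, duration=10.0))
        assert not np.array_equal(a.p_aw, b.p_aw)


class TestIntegrationAccuracy:
    def test_halving_dt_changes_tv_by_less_than_half_percent(self):
        sc1 = short_scenario(duration=40.0)
        sc2 = dataclasses.replace(sc1, dt_plant=0.0005)
        tv = []
        for sc in (sc1, sc2):
            wave = run_simulation(sc)
            records = bv.segment_breaths(wave)[sc.warmup_breaths:]
            tv.append(np.mean([r.tidal_volume for r in records]))
        assert abs(tv[0] - tv[1]) / tv[1] < 0.005

    def test_breath_period_equals_set_period(self, reference_wave):
        sc, wave = reference_wave
        starts = [e.t_start for e in wave.breath_events]
        gaps = np.diff(starts)
        assert np.abs(gaps - sc.settings.period).max() <= 0.01 + 1e-9


class TestModeBehavior:
    def test_disabled_drive_passive_patient_is_flat(self):
        sc = short_scenario(duration=10.0)
        sc = dataclasses.replace(
            sc, settings=dataclasses.replace(sc.settings, run_enable=False))
        wave = run_simulation(sc)
        assert np.all(wave.flow == 0.0)
        assert np.allclose(wave.p_aw, sc.circuit.peep_setting)
        assert wave.breath_events == []

    def test_breathing_through_disabled_ventilator(self):
        """An active patient can still draw breaths through the bag inlet
        valve when the drive is off, and doing so raises a high-priority
        low-pressure alarm."""
        sc = bv.REFERENCE_SCENARIOS["disabled_monitoring"]
        wave = run_simulation(sc)
        assert wave.flow.max() > 5.0     # inspiratory flow drawn by effort
        assert wave.flow.min() < -5.0    # and passive exhalation after it
        assert wave.breath_events == []  # the ventilator never cycles
        codes = {(e.code, e.priority) for e in wave.alarm_events}
        assert (bv.AlarmCode.PRESSURE_LOW, bv.Priority.HIGH) in codes

    def test_ards2_same_tv_higher_pip_than_normal(self):
        """The ventilator delivers the same set volume to a stiff lung by
        using more pressure."""
        results = {}
        for lung_name in ("NORMAL", "ARDS2"):
            sc = short_scenario(duration=40.0)
            sc = dataclasses.replace(
                sc, lung=LUNG_PRESETS[lung_name],
                settings=dataclasses.replace(sc.settings, max_volume=300.0),
                label=lung_name)
            wave = run_simulation(sc)
            recs = bv.segment_breaths(wave)[sc.warmup_breaths:]
            s = bv.summarize(recs)
            results[lung_name] = s
        assert results["ARDS2"].tv_mean == pytest.approx(
            results["NORMAL"].tv_mean, rel=0.02)
        assert results["ARDS2"].pip_mean > results["NORMAL"].pip_mean + 5.0

    def test_vc_inspiratory_pause_visible(self, reference_wave):
        """Between the stroke end and the inspiratory time the flow is zero
        while pressure stays high (the inspiratory pause)."""
        _, wave = reference_wave
        # take a steady-state breath starting at 30 s (tick 3000)
        i0 = 3000
        seg_phase = wave.phase[i0 + 1:i0 + 101]   # commands of one breath
        hold = np.nonzero(seg_phase == 2)[0]
        assert len(hold) > 30                     # a substantial pause
        hold_flow = wave.flow[i0 + 2 + hold[1]:i0 + 1 + hold[-1]]
        assert np.allclose(hold_flow, 0.0, atol=1e-9)
        hold_paw = wave.p_aw[i0 + 2 + hold[1]:i0 + 1 + hold[-1]]
        assert hold_paw.min() > 10.0              # plateau pressure held


class TestWaveformContainer:
    def test_volume_channel_is_integrated_flow(self, reference_wave):
        _, wave = reference_wave
        from scipy.integrate import cumulative_trapezoid
        ct = cumulative_trapezoid(wave.flow / 60.0 * 1000.0, wave.t, initial=0.0)
        assert np.abs(ct - wave.volume).max() <= 0.005 * wave.volume.max()

    def test_csv_round_trip(self, tmp_path, reference_wave):
        _, wave = reference_wave
        path = tmp_path / "wave.csv"
        wave.to_csv(path)
        back = Waveform.from_csv(path)
        assert np.allclose(back.flow, wave.flow)
        assert np.allclose(back.p_aw, wave.p_aw)
        assert np.array_equal(back.phase, wave.phase)

    def test_resample_64hz(self, reference_wave):
        _, wave = reference_wave
        low = wave.resample(64.0)
        assert low.t[1] - low.t[0] == pytest.approx(1.0 / 64.0)
        # resampling preserves the tidal volume estimate
        recs = bv.segment_breaths(low)[5:]
        tv = np.mean([r.tidal_volume for r in recs])
        assert tv == pytest.approx(400.0, rel=0.03)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b\n1,2\n")
        with pytest.raises(ValueError):
            Waveform.from_csv(path)


class TestSuiteRunner:
    def test_empty_suite(self):
        table = run_suite([])
        assert len(table) == 0

    def test_duplicate_labels_suffixed(self):
        sc = short_scenario(duration=20.0)
        table = run_suite([sc, sc, sc])
        assert list(table["label"]) == [sc.label, f"{sc.label}_2", f"{sc.label}_3"]

    def test_per_scenario_failure_propagates_without_aborting(self):
        good = short_scenario(duration=20.0)
        bad = dataclasses.replace(good, duration=2.0, label="too_short")
        with pytest.warns(UserWarning):
            table = run_suite([bad, good])
        assert table.loc[table.label == "too_short", "error"].item() != ""
        assert table.loc[table.label == good.label, "error"].item() == ""

    def test_requirement_grid_shape(self, suite_table):
        scenarios, table = suite_table
        assert len(scenarios) == 29
        assert (table["error"] == "").all()


def test_scenario_validation():
    base = bv.REFERENCE_SCENARIOS["normal_vcac_400"]
    with pytest.raises(ValueError):
        dataclasses.replace(base, duration=-1.0)
    with pytest.raises(ValueError):
        dataclasses.replace(base, dt_plant=0.003)  # does not divide the tick
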