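import pytest

import bagvent as bv


@pytest.fixture(scope="session")
def reference_wave():
    """Steady-state VC-AC reference run: normal lung, TV 400, RR 20, PEEP 5."""
    sc = bv.REFERENCE_SCENARIOS["normal_vcac_400"]
    return sc, bv.run_simulation(sc)


@pytest.fixture(scope="session")
def reference_records(reference_wave):
    sc, wave = reference_wave
    records = bv.segment_breaths(wave)
    return sc, wave, records


@pytest.fixture(scope="session")
def spontaneous_wave():
    """Active patient at 30 brpm / -5 cmH2O versus VC-AC at 20 brpm."""
    sc = bv.REFERENCE_SCENARIOS["spontaneous_trigger"]
    return sc, bv.run_simulation(sc)


@pytest.fixture(scope="session")
def suite_table():
    """Per-scenario summary of the bundled 29-scenario requirements grid."""
    scenarios = bv.requirements_suite()
    return scenarios, bv.run_suite(scenarios)
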