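import numpy as np
import pytest

from pilesound import CalibrationChain, PressureSeries, StrikeSceneSpec, synth_scene

FS = 44100.0


@pytest.fixture(scope="session")
def chain() -> CalibrationChain:
    return CalibrationChain(
        hydrophone_sensitivity_v_per_pa=47.7e-6,
        amplifier_gain=1.0,
        adc_fullscale_volts=1.0,
    )


@pytest.fixture
def one_pa_second() -> PressureSeries:
    """1 Pa constant pressure for exactly 1 s: SPL = SEL = 120 dB."""
    return PressureSeries(np.ones(int(FS)), FS)


@pytest.fixture
def sine_1pa_1s() -> PressureSeries:
    """1 Pa amplitude sinusoid, integer cycles in 1 s: level 116.99 dB."""
    t = np.arange(int(FS)) / FS
    return PressureSeries(np.sin(2 * np.pi * 100.0 * t), FS)


@pytest.fixture(scope="session")
def small_scene():
    """A 10-strike scene with quiet ambient; session-scoped for speed."""
    spec = StrikeSceneSpec(
        n_strikes=10,
        inter_strike_s=1.5,
        inter_strike_jitter_s=0.02,
        target_sel_ss_db=183.0,
        sel_jitter_db=1.0,
        ambient_spl_db=130.0,
        seed=42,
    )
    series, truth = synth_scene(spec)
    return spec, series, truth
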