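import numpy as np
import pytest

import imuresp as ir


@pytest.fixture(scope="session")
def params():
    return ir.AlgorithmParams()


@pytest.fixture(scope="session")
def short_subject():
    """A 90 s default-noise synthetic subject (fast, reused across tests)."""
    breathing = ir.BreathingModelConfig(duration=90.0, seed=7)
    gt, node1, node2, reference = ir.simulate_subject(breathing)
    return {
        "breathing": breathing,
        "gt": gt,
        "node1": node1,
        "node2": node2,
        "reference": reference,
    }


@pytest.fixture(scope="session")
def short_record(short_subject):
    return ir.resample_to_grid(
        short_subject["node1"], short_subject["node2"], 100.0
    )


@pytest.fixture(scope="session")
def short_estimate(short_record, params):
    """Fused signal + diagnostics for the 90 s subject."""
    r, diag = ir.estimate_respiration(short_record, params)
    return r, diag


def sine_waveform(amplitude_cm: float, freq_hz: float):
    """A pure-sine displacement 'waveform' usable by simulate_node."""

    class _Sine:
        def displacement(self, t):
            t = np.asarray(t, dtype=float)
            return amplitude_cm * np.sin(2 * np.pi * freq_hz * t)

        def velocity(self, t):
            t = np.asarray(t, dtype=float)
            w = 2 * np.pi * freq_hz
            return amplitude_cm * w * np.cos(w * t)

        def acceleration(self, t):
            t = np.asarray(t, dtype=float)
            w = 2 * np.pi * freq_hz
            return -amplitude_cm * w * w * np.sin(w * t)

    return _Sine()


def ground_truth_with_waveform(waveform, duration: float, period: float, seed=0):
    """Wrap an arbitrary analytic waveform in a GroundTruth container."""
    time = np.arange(int(duration * 100) + 1) / 100.0
    triggers = np.arange(0.0, duration + 1e-9, period)
    return ir.GroundTruth(
        time=time,
        displacement=waveform.displacement(time),
        end_expiration_triggers=triggers,
        cycle_validity=np.ones(triggers.size - 1, dtype=bool),
        waveform=waveform,
        seed=seed,
    )
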