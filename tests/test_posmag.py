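"""Tests of orientation estimation, gravity removal and double integration."""

import numpy as np
import pytest

import imuresp as ir
from imuresp.errors import ConfigurationError
from imuresp.posmag import OrientationState, integrate_highpass, madgwick_update

from conftest import ground_truth_with_waveform, sine_waveform


def rotate_by_quaternion(q, v):
    """World-frame coordinates of a sensor-frame vector (oracle rotation)."""
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    return R @ np.asarray(v, dtype=float)


def make_node2_record(accel_rows, gyro_rows, fs=100.0):
    n = accel_rows.shape[0]
    return ir.ResampledRecord(
        time=np.arange(n) / fs,
        node1_accel_xy=np.zeros((n, 2)),
        node2_accel_xyz=accel_rows,
        node2_gyro_xyz=gyro_rows,
        fs=fs,
    )


def butter_hp_gain(f, f_b):
    """|H| of a 2nd-order Butterworth high-pass (single pass)."""
    x = (f / f_b) ** 2
    return x / np.sqrt(1 + x * x)


class TestMadgwickUpdate:
    def test_level_static_sensor_is_a_fixed_point(self):
        state = OrientationState(np.array([1.0, 0, 0, 0]), beta=0.5)
        for _ in range(100):
            state = madgwick_update(state, [0, 0, 0], [0, 0, 9.81], 0.01)
        assert np.allclose(state.quaternion, [1, 0, 0, 0], atol=1e-12)

    def test_pure_gyro_matches_axis_angle(self):
        # closed-form oracle: constant rate about x for 10 s at 100 Hz
        omega = 0.3
        state = OrientationState(np.array([1.0, 0, 0, 0]), beta=0.0)
        for _ in range(1000):
            state = madgwick_update(state, [omega, 0, 0], [0, 0, 0], 0.01)
        angle = omega * 10.0
        expected = np.array([np.cos(angle / 2), np.sin(angle / 2), 0, 0])
        assert float(np.abs(state.quaternion - expected).max()) < 1e-6
        # recovered rotation angle itself
        est_angle = 2 * np.arctan2(
            np.linalg.norm(state.quaternion[1:]), state.quaternion[0]
        )
        assert abs(est_angle - angle) < 1e-6

    def test_static_tilted_sensor_converges_to_gravity(self):
        # 10 deg tilt about x: accel measured in the sensor frame
        tilt = np.deg2rad(10.0)
        accel = np.array([0.0, np.sin(tilt) * 9.81, np.cos(tilt) * 9.81])
        state = OrientationState(np.array([1.0, 0, 0, 0]), beta=0.1)
        for _ in range(3000):  # 30 s at 100 Hz
            state = madgwick_update(state, [0, 0, 0], accel, 0.01)
        world = rotate_by_quaternion(state.quaternion, accel)
        assert np.allclose(world, [0, 0, 9.81], atol=0.01)

    def test_zero_accel_falls_back_to_gyro_only(self):
        state = OrientationState(np.array([1.0, 0, 0, 0]), beta=0.1)
        out = madgwick_update(state, [0.5, 0, 0], [0, 0, 0], 0.01)
        expected = madgwick_update(
            OrientationState(np.array([1.0, 0, 0, 0]), beta=0.0),
            [0.5, 0, 0],
            [0, 0, 9.81],
            0.01,
        )
        assert np.allclose(out.quaternion, expected.quaternion, atol=1e-12)

    def test_quaternion_stays_normalised(self):
        rng = np.random.default_rng(0)
        state = OrientationState(np.array([1.0, 0, 0, 0]), beta=0.2)
        for _ in range(200):
            state = madgwick_update(
                state, rng.normal(size=3), rng.normal(size=3) + [0, 0, 9.8], 0.01
            )
            assert abs(np.linalg.norm(state.quaternion) - 1) < 1e-9


class TestWorldZAcceleration:
    def test_static_level_sensor_reads_g(self, params):
        n = 2000
        acc = np.tile([0.0, 0.0, 9.81], (n, 1))
        rec = make_node2_record(acc, np.zeros((n, 3)))
        a_z = ir.world_z_acceleration(rec, params)
        assert np.allclose(a_z[500:], 9.81, atol=1e-9)

    def test_static_tilted_sensor_reads_g_not_g_cos_tilt(self, params):
        tilt = np.deg2rad(15.0)
        n = 3000
        acc = np.tile([0.0, np.sin(tilt) * 9.81, np.cos(tilt) * 9.81], (n, 1))
        rec = make_node2_record(acc, np.zeros((n, 3)))
        a_z = ir.world_z_acceleration(rec, params)
        assert a_z[-1] == pytest.approx(9.81, abs=1e-3)
        assert abs(a_z[-1] - 9.81 * np.cos(tilt)) > 0.1

    def test_linear_acceleration_passes_through_untitled(self, params):
        fs, f = 100.0, 0.3
        t = np.arange(0, 30, 1 / fs)
        lin = 0.05 * np.sin(2 * np.pi * f * t)
        acc = np.column_stack([0 * t, 0 * t, 9.81 + lin])
        rec = make_node2_record(acc, np.zeros((t.size, 3)), fs)
        a_z = ir.world_z_acceleration(rec, params)
        assert np.allclose(a_z[500:], 9.81 + lin[500:], atol=2e-3)


class TestRespiratoryAcceleration:
    def test_gravity_removed(self):
        assert np.allclose(ir.respiratory_acceleration(np.full(5, 9.81)), 0.0)

    def test_offset_preserved(self):
        out = ir.respiratory_acceleration(np.full(5, 9.91), g=9.81)
        assert np.allclose(out, 0.1)


class TestIntegrateHighpass:
    def test_zero_in_zero_out(self):
        out = integrate_highpass(np.zeros(1000), 100.0, 0.2)
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_cosine_integral_amplitude_with_filter_response(self):
        # oracle: closed-form antiderivative sin(wt)/w times the
        # forward-backward filter's magnitude response at f
        fs, f, f_b = 100.0, 0.3, 0.2
        t = np.arange(0, 120, 1 / fs)
        w = 2 * np.pi * f
        out = integrate_highpass(np.cos(w * t), fs, f_b)
        edge = int(2 / f_b * fs)
        amp = np.abs(out[edge:-edge]).max()
        expected = butter_hp_gain(f, f_b) ** 2 / w
        assert amp == pytest.approx(expected, rel=0.05)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ConfigurationError):
            integrate_highpass(np.zeros(100), 100.0, 60.0)


class TestPolmagSignal:
    def simulate(self, amplitude_cm, freq, duration=120.0, params=None):
        params = params or ir.AlgorithmParams()
        gt = ground_truth_with_waveform(
            sine_waveform(amplitude_cm, freq), duration, 1 / freq
        )
        sens = ir.SensorModelConfig(
            accel_noise_sd=0.0, gyro_noise_sd=0.0, tilt_gain_node2=0.0
        )
        node2 = ir.simulate_node(gt, "abdomen", sens)
        node1 = ir.simulate_node(gt, "sternum", sens)
        rec = ir.resample_to_grid(node1, node2, params.fs)
        return ir.compute_polmag_signal(rec, params), gt

    def test_sine_displacement_amplitude_recovered(self):
        # two integrate+filtfilt stages each apply |H|^2 at 0.25 Hz
        p, _ = self.simulate(0.5, 0.25)
        core = p.values[3000:-3000]
        expected = 0.5 * butter_hp_gain(0.25, 0.2) ** 4
        assert np.abs(core).max() == pytest.approx(expected, rel=0.10)

    def test_zero_motion_stays_near_zero(self):
        p, _ = self.simulate(1e-9, 0.25, duration=60.0)
        assert np.abs(p.values[1000:-1000]).max() < 0.01

    def test_zero_phase_lag_below_one_sample(self):
        p, gt = self.simulate(0.5, 0.3)
        truth = gt.waveform.displacement(p.time)
        mid = slice(3000, len(p.time) - 3000)
        lags = np.arange(-5, 6)
        corr = [
            float(truth[mid.start + k : mid.stop + k] @ p.values[mid])
            for k in lags
        ]
        assert abs(lags[int(np.argmax(corr))]) <= 1

    def test_amplitude_linearity(self):
        p1, _ = self.simulate(0.5, 0.25)
        p2, _ = self.simulate(1.0, 0.25)
        m1 = np.abs(p1.values[3000:-3000]).max()
        m2 = np.abs(p2.values[3000:-3000]).max()
        assert m2 / m1 == pytest.approx(2.0, rel=0.01)

    def test_highpass_attenuates_below_cutoff(self):
        p_low, _ = self.simulate(0.5, 0.1, duration=200.0)
        p_high, _ = self.simulate(0.5, 0.3)
        ratio_low = np.abs(p_low.values[5000:-5000]).max() / 0.5
        ratio_high = np.abs(p_high.values[3000:-3000]).max() / 0.5
        assert ratio_low < ratio_high

    def test_signal_decays_during_motion_pause(self):
        fs = 100.0

        class PausedSine:
            def __init__(self):
                self.inner = sine_waveform(0.5, 0.25)

            def _mask(self, t):
                t = np.asarray(t, dtype=float)
                return ((t < 60.0) | (t >= 120.0)).astype(float)

            def displacement(self, t):
                return self.inner.displacement(t) * self._mask(t)

            def velocity(self, t):
                return self.inner.velocity(t) * self._mask(t)

            def acceleration(self, t):
                return self.inner.acceleration(t) * self._mask(t)

        gt = ground_truth_with_waveform(PausedSine(), 180.0, 4.0)
        sens = ir.SensorModelConfig(
            accel_noise_sd=0.0, gyro_noise_sd=0.0, tilt_gain_node2=0.0
        )
        rec = ir.resample_to_grid(
            ir.simulate_node(gt, "sternum", sens),
            ir.simulate_node(gt, "abdomen", sens),
            fs,
        )
        p = ir.compute_polmag_signal(rec, ir.AlgorithmParams())
        moving = np.abs(p.values[3000:5500]).max()
        paused = np.abs(p.values[8000:11000]).max()
        assert paused < 0.2 * moving
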