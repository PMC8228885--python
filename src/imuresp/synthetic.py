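"""Synthetic breathing motion and IMU/reference-sensor simulator.

No public recording of the two-node IMU setup exists, so the pipeline is
exercised end-to-end on simulated data.  The generator produces a
ground-truth abdominal displacement waveform (cm, world z-axis, positive
= ventral/up for a supine subject) built from per-cycle asymmetric
raised cosines, and then renders from it

* two IMU nodes (sternum and abdomen) that tilt about the sensor x-axis
  in proportion to the displacement and additionally feel the world-z
  linear acceleration of the breathing motion, sampled at the hardware
  rates (accelerometer ~500 Hz, gyroscope ~400 Hz) with additive white
  Gaussian noise, and
* an optical-marker-like reference signal: the displacement scaled by a
  marker gain, sampled at the reference rate, plus tracking noise, with
  end-expiration trigger timestamps at the cycle troughs and a validity
  flag per trigger-to-trigger interval.

Everything is deterministic given the seed in
:class:`BreathingModelConfig`; node and reference noise streams are
derived from that seed so the whole bundle is reproducible bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .signalio import NodeRecording
from .signals import RespirationSignal

__all__ = [
    "BreathingModelConfig",
    "SensorModelConfig",
    "BreathingWaveform",
    "GroundTruth",
    "generate_breathing",
    "simulate_node",
    "simulate_reference",
    "simulate_subject",
]

#: Sampling rate (Hz) of the dense ground-truth displacement grid.
GROUND_TRUTH_FS = 100.0

# Node roles and their hardware ids.
ROLE_STERNUM = "sternum"
ROLE_ABDOMEN = "abdomen"
_ROLE_IDS = {ROLE_STERNUM: 1, ROLE_ABDOMEN: 2}


@dataclass(frozen=True)
class BreathingModelConfig:
    """Parameters of the ground-truth breathing displacement model.

    Defaults describe a calm adult breather at rest: 4 s cycles (15
    breaths/min) with mild period jitter, 1 cm peak-to-trough abdominal
    excursion (mid-range of typical supine excursions of 0.5-1.7 cm),
    occasional deep breaths, and a slow posture/muscle-tone drift.
    """

    mean_period: float = 4.0  # s
    period_jitter_cv: float = 0.08  # dimensionless cv of per-cycle period
    mean_amplitude: float = 1.0  # cm, peak-to-trough
    amplitude_jitter_cv: float = 0.15  # dimensionless cv of per-cycle amplitude
    asymmetry: float = 0.4  # fraction of the cycle spent in inspiration
    drift_amplitude: float = 0.15  # cm
    drift_period: float = 300.0  # s
    deep_breath_rate: float = 0.5  # events/min
    deep_breath_scale: float = 1.8  # amplitude multiplier of a deep breath
    duration: float = 900.0  # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_period <= 0:
            raise ConfigurationError("mean_period must be positive")
        if self.mean_amplitude <= 0:
            raise ConfigurationError("mean_amplitude must be positive")
        if self.duration <= 0:
            raise ConfigurationError("duration must be positive")
        if not 0.0 < self.asymmetry < 1.0:
            raise ConfigurationError("asymmetry must lie in (0, 1)")
        if self.period_jitter_cv < 0 or self.amplitude_jitter_cv < 0:
            raise ConfigurationError("jitter cv values must be >= 0")
        if self.deep_breath_rate < 0 or self.deep_breath_scale <= 0:
            raise ConfigurationError("invalid deep-breath parameters")
        if self.drift_amplitude < 0 or self.drift_period <= 0:
            raise ConfigurationError("invalid drift parameters")


@dataclass(frozen=True)
class SensorModelConfig:
    """Parameters of the sensor rendering (both IMU nodes and reference).

    Noise standard deviations are order-of-magnitude MEMS datasheet
    values; tilt gains express how many radians of sensor tilt about the
    x-axis one centimetre of breathing displacement produces (large at
    the sternum, small at the abdomen).  The reference emulates an
    optical marker system: sub-millimetre tracking noise at 25 Hz.
    """

    accel_fs: float = 500.0  # Hz
    gyro_fs: float = 400.0  # Hz
    accel_noise_sd: float = 0.003  # m/s^2
    gyro_noise_sd: float = 0.002  # rad/s
    tilt_gain_node1: float = 0.05  # rad/cm (sternum)
    tilt_gain_node2: float = 0.01  # rad/cm (abdomen)
    reference_fs: float = 25.0  # Hz
    reference_noise_sd: float = 0.01  # cm
    reference_gain: float = 1.0  # marker gain (cm of marker per cm of truth)
    gravity: float = 9.81  # m/s^2

    def __post_init__(self) -> None:
        for name in ("accel_fs", "gyro_fs", "reference_fs"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("accel_noise_sd", "gyro_noise_sd", "reference_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.gravity <= 0:
            raise ConfigurationError("gravity must be positive")


class BreathingWaveform:
    """Closed-form piecewise breathing displacement.

    Each cycle ``i`` starts at a trough, rises as a raised cosine to its
    amplitude ``A_i`` over the inspiration fraction ``a`` of the cycle,
    and falls back as a raised cosine over the remaining ``1 - a``.  The
    waveform is C^1, so velocity is continuous and acceleration is
    defined everywhere (with jump discontinuities at segment
    boundaries).  A slow sinusoidal drift is superimposed.

    Displacement is in cm; derivatives are in cm/s and cm/s^2.
    """

    def __init__(
        self,
        boundaries: np.ndarray,
        amplitudes: np.ndarray,
        asymmetry: float,
        drift_amplitude: float = 0.0,
        drift_period: float = 300.0,
    ) -> None:
        boundaries = np.asarray(boundaries, dtype=float)
        amplitudes = np.asarray(amplitudes, dtype=float)
        if boundaries.size != amplitudes.size + 1:
            raise ConfigurationError("need one boundary more than cycles")
        if boundaries.size < 2 or np.any(np.diff(boundaries) <= 0):
            raise ConfigurationError("cycle boundaries must be increasing")
        self.boundaries = boundaries
        self.amplitudes = amplitudes
        self.asymmetry = float(asymmetry)
        self.drift_amplitude = float(drift_amplitude)
        self.drift_period = float(drift_period)

    def _segments(self, t: np.ndarray):
        t = np.asarray(t, dtype=float)
        i = np.clip(
            np.searchsorted(self.boundaries, t, side="right") - 1,
            0,
            self.amplitudes.size - 1,
        )
        tau = t - self.boundaries[i]
        period = np.diff(self.boundaries)[i]
        amp = self.amplitudes[i]
        t_rise = self.asymmetry * period
        t_fall = period - t_rise
        rising = tau < t_rise
        return tau, amp, t_rise, t_fall, rising

    def displacement(self, t: np.ndarray) -> np.ndarray:
        tau, amp, t_rise, t_fall, rising = self._segments(t)
        up = 0.5 * amp * (1.0 - np.cos(np.pi * tau / t_rise))
        down = 0.5 * amp * (1.0 + np.cos(np.pi * (tau - t_rise) / t_fall))
        out = np.where(rising, up, down)
        if self.drift_amplitude:
            out = out + self.drift_amplitude * np.sin(
                2.0 * np.pi * np.asarray(t, dtype=float) / self.drift_period
            )
        return out

    def velocity(self, t: np.ndarray) -> np.ndarray:
        tau, amp, t_rise, t_fall, rising = self._segments(t)
        up = 0.5 * amp * np.pi / t_rise * np.sin(np.pi * tau / t_rise)
        down = -0.5 * amp * np.pi / t_fall * np.sin(
            np.pi * (tau - t_rise) / t_fall
        )
        out = np.where(rising, up, down)
        if self.drift_amplitude:
            w = 2.0 * np.pi / self.drift_period
            out = out + self.drift_amplitude * w * np.cos(
                w * np.asarray(t, dtype=float)
            )
        return out

    def acceleration(self, t: np.ndarray) -> np.ndarray:
        tau, amp, t_rise, t_fall, rising = self._segments(t)
        up = 0.5 * amp * (np.pi / t_rise) ** 2 * np.cos(np.pi * tau / t_rise)
        down = -0.5 * amp * (np.pi / t_fall) ** 2 * np.cos(
            np.pi * (tau - t_rise) / t_fall
        )
        out = np.where(rising, up, down)
        if self.drift_amplitude:
            w = 2.0 * np.pi / self.drift_period
            out = out - self.drift_amplitude * w * w * np.sin(
                w * np.asarray(t, dtype=float)
            )
        return out


@dataclass
class GroundTruth:
    """Ground-truth breathing motion with reference triggers.

    ``displacement`` is the world-z abdominal position in cm sampled on
    ``time`` (a dense uniform grid); ``waveform`` evaluates the same
    motion (and its derivatives) in closed form at arbitrary times.
    ``end_expiration_triggers`` sit at the cycle troughs;
    ``cycle_validity`` holds one flag per trigger-to-trigger interval.
    """

    time: np.ndarray
    displacement: np.ndarray
    end_expiration_triggers: np.ndarray
    cycle_validity: np.ndarray
    waveform: BreathingWaveform
    seed: int = 0

    def __post_init__(self) -> None:
        self.end_expiration_triggers = np.asarray(
            self.end_expiration_triggers, dtype=float
        )
        self.cycle_validity = np.asarray(self.cycle_validity, dtype=bool)
        if np.any(np.diff(self.end_expiration_triggers) <= 0):
            raise ConfigurationError("triggers must be strictly increasing")
        if self.cycle_validity.size != self.end_expiration_triggers.size - 1:
            raise ConfigurationError(
                "need one validity flag per trigger-to-trigger interval"
            )

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])


def _lognormal(rng: np.random.Generator, mean: float, cv: float, n: int):
    """Draw ``n`` lognormal values with the given mean and coefficient of
    variation (degenerate to the constant mean when ``cv == 0``)."""
    if cv == 0.0:
        return np.full(n, mean)
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - 0.5 * sigma2
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n)


def generate_breathing(config: BreathingModelConfig) -> GroundTruth:
    """Generate ground-truth breathing displacement.

    Cycles are drawn one by one until the requested duration is covered:
    per-cycle period and amplitude are lognormal with the configured
    means and coefficients of variation, deep-breath events (Bernoulli
    per cycle at the configured rate) multiply that cycle's amplitude by
    ``deep_breath_scale``, and a slow sinusoidal drift is added on top.
    End-expiration triggers are placed at the cycle troughs.
    """
    rng = np.random.default_rng(config.seed)

    periods: list[float] = []
    amplitudes: list[float] = []
    total = 0.0
    while total < config.duration:
        period = float(_lognormal(rng, config.mean_period, config.period_jitter_cv, 1)[0])
        amp = float(
            _lognormal(rng, config.mean_amplitude, config.amplitude_jitter_cv, 1)[0]
        )
        p_deep = config.deep_breath_rate * period / 60.0
        if rng.random() < p_deep:
            amp *= config.deep_breath_scale
        periods.append(period)
        amplitudes.append(amp)
        total += period

    boundaries = np.concatenate([[0.0], np.cumsum(periods)])
    waveform = BreathingWaveform(
        boundaries,
        np.asarray(amplitudes),
        config.asymmetry,
        config.drift_amplitude,
        config.drift_period,
    )

    n = int(math.floor(config.duration * GROUND_TRUTH_FS)) + 1
    time = np.arange(n) / GROUND_TRUTH_FS
    displacement = waveform.displacement(time)

    triggers = boundaries[boundaries <= config.duration + 1e-9]
    validity = np.ones(triggers.size - 1, dtype=bool)
    return GroundTruth(
        time=time,
        displacement=displacement,
        end_expiration_triggers=triggers,
        cycle_validity=validity,
        waveform=waveform,
        seed=config.seed,
    )


def _node_rng(gt: GroundTruth, stream: int) -> np.random.Generator:
    # Independent, reproducible noise stream per sensor/reference.
    return np.random.default_rng([int(gt.seed) & 0x7FFFFFFF, stream])


def simulate_node(
    gt: GroundTruth, node_role: str, config: SensorModelConfig
) -> NodeRecording:
    """Render one IMU node from the ground truth.

    The node tilts about its x-axis by ``theta(t) = gain * d(t)`` (d in
    cm) and is carried along the world z-axis by the breathing motion,
    so the specific force it measures is the world vector
    ``(0, 0, g + d''(t))`` (d'' converted cm -> m) expressed in the
    sensor frame, i.e. ``(0, sin(theta) f, cos(theta) f)``.  The
    gyroscope sees ``(theta'(t), 0, 0)``.  Each stream is sampled on its
    own grid and corrupted with white Gaussian noise.
    """
    if node_role not in _ROLE_IDS:
        raise ConfigurationError(
            f"unknown node_role {node_role!r}; expected 'sternum' or 'abdomen'"
        )
    node_id = _ROLE_IDS[node_role]
    gain = config.tilt_gain_node1 if node_id == 1 else config.tilt_gain_node2
    duration = gt.duration
    rng = _node_rng(gt, node_id)

    t_acc = np.arange(int(math.floor(duration * config.accel_fs)) + 1) / config.accel_fs
    t_gyr = np.arange(int(math.floor(duration * config.gyro_fs)) + 1) / config.gyro_fs

    disp_acc = gt.waveform.displacement(t_acc)
    theta = gain * disp_acc
    specific_force = config.gravity + 0.01 * gt.waveform.acceleration(t_acc)
    accel = np.column_stack(
        [
            np.zeros_like(t_acc),
            np.sin(theta) * specific_force,
            np.cos(theta) * specific_force,
        ]
    )
    if config.accel_noise_sd > 0:
        accel = accel + rng.normal(0.0, config.accel_noise_sd, accel.shape)

    theta_dot = gain * gt.waveform.velocity(t_gyr)
    gyro = np.column_stack(
        [theta_dot, np.zeros_like(t_gyr), np.zeros_like(t_gyr)]
    )
    if config.gyro_noise_sd > 0:
        gyro = gyro + rng.normal(0.0, config.gyro_noise_sd, gyro.shape)

    return NodeRecording(
        accel_time=t_acc, accel=accel, gyro_time=t_gyr, gyro=gyro, node_id=node_id
    )


def simulate_reference(
    gt: GroundTruth, config: SensorModelConfig
) -> RespirationSignal:
    """Render the optical-marker-like reference respiration signal."""
    rng = _node_rng(gt, 3)
    duration = gt.duration
    t_ref = (
        np.arange(int(math.floor(duration * config.reference_fs)) + 1)
        / config.reference_fs
    )
    values = config.reference_gain * gt.waveform.displacement(t_ref)
    if config.reference_noise_sd > 0:
        values = values + rng.normal(0.0, config.reference_noise_sd, values.shape)
    return RespirationSignal(time=t_ref, values=values, unit="cm", kind="reference")


def simulate_subject(
    breathing: BreathingModelConfig, sensors: SensorModelConfig | None = None
):
    """Convenience wrapper: ground truth plus both nodes and reference.

    Returns ``(gt, node1, node2, reference)``.
    """
    if sensors is None:
        sensors = SensorModelConfig()
    gt = generate_breathing(breathing)
    node1 = simulate_node(gt, ROLE_STERNUM, sensors)
    node2 = simulate_node(gt, ROLE_ABDOMEN, sensors)
    reference = simulate_reference(gt, sensors)
    return gt, node1, node2, reference
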