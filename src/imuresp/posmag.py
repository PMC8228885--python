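"""Polarity-and-magnitude signal: abdomen-node displacement via orientation
estimation and double integration.

The abdomen node rides the largest breathing excursion.  Its six IMU
channels feed a gradient-descent orientation filter (6-axis variant, no
magnetometer): gyro rates propagate the attitude quaternion while a
beta-scaled normalised gradient step pulls the estimated gravity
direction towards the measured accelerometer direction.  Rotating the
measured specific force into the world frame gives the vertical
acceleration a_z; subtracting g leaves the respiratory acceleration,
which is twice integrated (cumulative sum) with a zero-phase
second-order Butterworth high-pass after each integration to suppress
the random walk that integration of sensor noise would otherwise
produce.  The result p(t) is a position estimate in cm whose sign is
physical (positive = up/ventral): it supplies the polarity and the
magnitude that the PCA shape signal lacks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .errors import ConfigurationError, DataError
from .signalio import AlgorithmParams, ResampledRecord
from .signals import RespirationSignal

__all__ = [
    "OrientationState",
    "madgwick_update",
    "orientation_from_accel",
    "world_z_acceleration",
    "respiratory_acceleration",
    "integrate_highpass",
    "compute_polmag_signal",
]


@dataclass
class OrientationState:
    """Attitude quaternion (sensor -> world, scalar first) and filter gain."""

    quaternion: np.ndarray
    beta: float = 0.1

    def __post_init__(self) -> None:
        q = np.asarray(self.quaternion, dtype=float)
        if q.shape != (4,):
            raise ConfigurationError("quaternion must be a 4-vector")
        norm = float(np.linalg.norm(q))
        if norm == 0.0:
            raise ConfigurationError("quaternion must be non-zero")
        self.quaternion = q / norm
        if self.beta < 0:
            raise ConfigurationError("beta must be >= 0")


def _step(q0, q1, q2, q3, gx, gy, gz, ax, ay, az, beta, dt):
    """One orientation-filter step on scalar components.

    Gyro propagation uses the exact quaternion exponential map (right
    multiplication by exp(omega*dt/2)); the accelerometer correction is
    the beta-scaled normalised gradient of the gravity-alignment
    objective.  Returns the renormalised quaternion components.
    """
    wx, wy, wz = gx * dt, gy * dt, gz * dt
    angle = math.sqrt(wx * wx + wy * wy + wz * wz)
    if angle > 1e-12:
        half = 0.5 * angle
        c = math.cos(half)
        s = math.sin(half) / angle
    else:
        c = 1.0
        s = 0.5
    dw, dx, dy, dz = c, wx * s, wy * s, wz * s
    nw = q0 * dw - q1 * dx - q2 * dy - q3 * dz
    nx = q0 * dx + q1 * dw + q2 * dz - q3 * dy
    ny = q0 * dy - q1 * dz + q2 * dw + q3 * dx
    nz = q0 * dz + q1 * dy - q2 * dx + q3 * dw

    if beta > 0.0:
        norm_a = math.sqrt(ax * ax + ay * ay + az * az)
        if norm_a > 0.0:
            axn, ayn, azn = ax / norm_a, ay / norm_a, az / norm_a
            # gravity direction predicted in the sensor frame minus measured
            f1 = 2.0 * (nx * nz - nw * ny) - axn
            f2 = 2.0 * (ny * nz + nw * nx) - ayn
            f3 = 1.0 - 2.0 * (nx * nx + ny * ny) - azn
            g0 = -2.0 * ny * f1 + 2.0 * nx * f2
            g1 = 2.0 * nz * f1 + 2.0 * nw * f2 - 4.0 * nx * f3
            g2 = -2.0 * nw * f1 + 2.0 * nz * f2 - 4.0 * ny * f3
            g3 = 2.0 * nx * f1 + 2.0 * ny * f2
            gn = math.sqrt(g0 * g0 + g1 * g1 + g2 * g2 + g3 * g3)
            if gn > 0.0:
                step = beta * dt / gn
                nw -= step * g0
                nx -= step * g1
                ny -= step * g2
                nz -= step * g3

    inv = 1.0 / math.sqrt(nw * nw + nx * nx + ny * ny + nz * nz)
    return nw * inv, nx * inv, ny * inv, nz * inv


def madgwick_update(
    state: OrientationState, gyro: np.ndarray, accel: np.ndarray, dt: float
) -> OrientationState:
    """Advance the orientation by one sample.

    With a zero-norm accelerometer sample (and ``beta > 0``) the
    gradient step is skipped and the update is gyro-only.
    """
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    gx, gy, gz = (float(v) for v in np.asarray(gyro, dtype=float))
    ax, ay, az = (float(v) for v in np.asarray(accel, dtype=float))
    q = _step(*state.quaternion, gx, gy, gz, ax, ay, az, state.beta, float(dt))
    return OrientationState(quaternion=np.asarray(q), beta=state.beta)


def orientation_from_accel(accel: np.ndarray) -> np.ndarray:
    """Initial attitude from a single (quasi-static) accelerometer sample.

    Returns the quaternion of the rotation taking the measured gravity
    direction onto the world z-axis (roll/pitch from gravity, yaw = 0).
    """
    a = np.asarray(accel, dtype=float)
    norm = float(np.linalg.norm(a))
    if norm == 0.0:
        return np.array([1.0, 0.0, 0.0, 0.0])
    axn, ayn, azn = a / norm
    # axis = a x e_z, angle = angle between a and e_z
    cx, cy = ayn, -axn
    cross = math.sqrt(cx * cx + cy * cy)
    angle = math.atan2(cross, azn)
    if cross < 1e-12:
        if azn > 0:
            return np.array([1.0, 0.0, 0.0, 0.0])
        return np.array([0.0, 1.0, 0.0, 0.0])  # upside down: 180 deg about x
    s = math.sin(0.5 * angle) / cross
    return np.array([math.cos(0.5 * angle), cx * s, cy * s, 0.0])


def world_z_acceleration(rec: ResampledRecord, params: AlgorithmParams) -> np.ndarray:
    """World-frame vertical component of the measured specific force.

    Runs the orientation filter over the node-2 channels (initialised
    from the first accelerometer sample) and rotates each accelerometer
    vector into the world frame.  For a static sensor the output
    converges to g regardless of tilt.
    """
    accel = rec.node2_accel_xyz
    gyro = rec.node2_gyro_xyz
    dt = 1.0 / rec.fs
    beta = params.madgwick_beta
    q0, q1, q2, q3 = orientation_from_accel(accel[0])
    out = np.empty(len(rec))
    ac = accel.tolist()
    gy = gyro.tolist()
    for i in range(len(out)):
        gx_, gy_, gz_ = gy[i]
        ax_, ay_, az_ = ac[i]
        q0, q1, q2, q3 = _step(q0, q1, q2, q3, gx_, gy_, gz_, ax_, ay_, az_, beta, dt)
        # third row of the rotation matrix sensor -> world
        out[i] = (
            2.0 * (q1 * q3 - q0 * q2) * ax_
            + 2.0 * (q2 * q3 + q0 * q1) * ay_
            + (1.0 - 2.0 * (q1 * q1 + q2 * q2)) * az_
        )
    return out


def respiratory_acceleration(a_z: np.ndarray, g: float = 9.81) -> np.ndarray:
    """Vertical acceleration with gravity removed: ``a_resp = a_z - g``."""
    return np.asarray(a_z, dtype=float) - float(g)


def integrate_highpass(x: np.ndarray, fs: float, f_B: float) -> np.ndarray:
    """Cumulative-sum integration followed by a zero-phase high-pass.

    The integral is a cumulative sum weighted by the sample interval
    (first sample starts the sum, i.e. zero initial condition); the
    high-pass is a second-order Butterworth at ``f_B`` applied
    forward-backward (odd-reflection edge padding), so it adds no phase
    but applies its magnitude response twice.
    """
    if f_B >= fs / 2:
        raise ConfigurationError("f_B must be below the Nyquist frequency")
    x = np.asarray(x, dtype=float)
    b, a = butter(2, f_B, btype="highpass", fs=fs)
    pad = 3 * max(len(a), len(b))
    if x.size <= pad:
        raise DataError(
            f"signal of {x.size} samples is shorter than the filter warm-up "
            f"({pad + 1} samples)"
        )
    y = np.cumsum(x) / fs
    return filtfilt(b, a, y)


def compute_polmag_signal(
    rec: ResampledRecord, params: AlgorithmParams
) -> RespirationSignal:
    """Polarity-and-magnitude position estimate p(t) in cm."""
    a_z = world_z_acceleration(rec, params)
    a_resp = respiratory_acceleration(a_z, params.g)
    velocity = integrate_highpass(a_resp, rec.fs, params.f_B)
    position_m = integrate_highpass(velocity, rec.fs, params.f_B)
    return RespirationSignal(
        rec.time, position_m * 100.0, unit="cm", kind="polmag"
    )
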