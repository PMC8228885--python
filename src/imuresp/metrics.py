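"""Breathing-cycle detection and waveform comparison statistics.

Cycle detection is anchored on end-expiration trigger timestamps (from
the reference system): within each trigger-to-trigger window the peak
inspiration time is the time of the largest local maximum of the
signal, falling back to the window argmax when the signal has no
interior local maximum there.  Cycle durations and peak-to-trough
magnitudes follow, and from paired cycle tables the mean absolute
breathing-rate error per minute and the mean absolute amplitude error
quantify agreement between an estimated waveform and the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError
from .shape import moving_average
from .signals import RespirationSignal

__all__ = [
    "CycleTable",
    "ComparisonReport",
    "peak_inspiration_times",
    "cycle_durations",
    "cycle_magnitudes",
    "cycle_table",
    "mae_breathing_rate",
    "mae_amplitude",
    "mean_cycle_magnitude",
    "baseline_correct_reference",
]


@dataclass
class CycleTable:
    """Per-cycle peak times, durations and magnitudes for one signal."""

    peak_times: np.ndarray  # s
    durations: np.ndarray  # s, one per cycle (pairs of consecutive peaks)
    magnitudes: np.ndarray  # cm (or the signal's unit), one per cycle
    source: str = "MMS"  # {"MMS", "reference"}

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        if np.any(np.diff(self.peak_times) <= 0):
            raise DataError("peak times must be strictly increasing")
        if self.durations.size != max(self.peak_times.size - 1, 0):
            raise DataError("need one duration per pair of consecutive peaks")
        if np.any(self.durations <= 0):
            raise DataError("cycle durations must be positive")
        if np.any(self.magnitudes < 0):
            raise DataError("cycle magnitudes must be non-negative")

    @property
    def n_cycles(self) -> int:
        return self.durations.size


@dataclass
class ComparisonReport:
    """Agreement statistics between an estimated signal and the reference."""

    mae_fb: float  # 1/min, mean absolute breathing-rate error per minute
    mms_magn: float  # cm, mean cycle magnitude of the estimate
    ref_magn: float  # cm, mean cycle magnitude of the reference
    mae_amplitude: float  # cm, pointwise mean absolute difference
    n_cycles: int
    q: int | None = None  # polarity of the estimate
    gamma: float | None = None  # calibration constant, if computed
    mae_amplitude_calibrated: float | None = None  # cm, after gamma + drift corr.

    def as_dict(self) -> dict:
        out = {
            "mae_fb": self.mae_fb,
            "mms_magn": self.mms_magn,
            "ref_magn": self.ref_magn,
            "mae_amplitude": self.mae_amplitude,
            "n_cycles": self.n_cycles,
        }
        if self.q is not None:
            out["q"] = self.q
        if self.gamma is not None:
            out["gamma"] = self.gamma
        if self.mae_amplitude_calibrated is not None:
            out["mae_amplitude_calibrated"] = self.mae_amplitude_calibrated
        return out


def peak_inspiration_times(
    signal: RespirationSignal, triggers: np.ndarray
) -> np.ndarray:
    """Peak inspiration time within each trigger-to-trigger window.

    A candidate crest is a sample into which the first discrete
    difference ``r'(t) = r(t+1) - r(t)`` rises and after which it falls
    (``r'(t_{j-1}) > 0`` and ``r'(t_j) <= 0``); the peak time is the
    crest with the largest signal value, or the window argmax when the
    window contains no interior local maximum.
    """
    triggers = np.asarray(triggers, dtype=float)
    if triggers.size < 2:
        raise DataError("need at least two end-expiration triggers")
    if np.any(np.diff(triggers) <= 0):
        raise DataError("triggers must be strictly increasing")
    t = signal.time
    v = signal.values
    if triggers[0] < t[0] - 1e-9 or triggers[-1] > t[-1] + 1e-9:
        raise DataError("triggers fall outside the signal's support")
    dv = np.diff(v)
    cand = np.nonzero((dv[:-1] > 0) & (dv[1:] <= 0))[0] + 1  # crest samples
    peaks = np.empty(triggers.size - 1)
    for i, (ta, tb) in enumerate(zip(triggers[:-1], triggers[1:])):
        lo = int(np.searchsorted(t, ta - 1e-12, side="left"))
        hi = int(np.searchsorted(t, tb + 1e-12, side="right")) - 1
        if hi < lo:
            raise DataError("trigger window contains no samples")
        in_win = cand[(cand >= lo) & (cand <= hi)]
        if in_win.size:
            j = int(in_win[np.argmax(v[in_win])])
        else:
            j = lo + int(np.argmax(v[lo : hi + 1]))
        peaks[i] = t[j]
    return peaks


def cycle_durations(peaks: np.ndarray) -> np.ndarray:
    """Breathing-cycle durations ``d_i = T_{i+1} - T_i`` in seconds."""
    peaks = np.asarray(peaks, dtype=float)
    if peaks.size < 2:
        raise DataError("need at least two peaks to form a cycle")
    return np.diff(peaks)


def cycle_magnitudes(signal: RespirationSignal, peaks: np.ndarray) -> np.ndarray:
    """Peak-to-trough magnitude (max - min) within each cycle."""
    peaks = np.asarray(peaks, dtype=float)
    if peaks.size < 2:
        raise DataError("need at least two peaks to form a cycle")
    t = signal.time
    v = signal.values
    out = np.empty(peaks.size - 1)
    for i, (ta, tb) in enumerate(zip(peaks[:-1], peaks[1:])):
        lo = int(np.searchsorted(t, ta - 1e-12, side="left"))
        hi = int(np.searchsorted(t, tb + 1e-12, side="right")) - 1
        seg = v[lo : hi + 1]
        out[i] = float(seg.max() - seg.min())
    return out


def cycle_table(
    signal: RespirationSignal, triggers: np.ndarray, source: str = "MMS"
) -> CycleTable:
    """Build the full cycle table of a signal from the shared triggers."""
    peaks = peak_inspiration_times(signal, triggers)
    return CycleTable(
        peak_times=peaks,
        durations=cycle_durations(peaks),
        magnitudes=cycle_magnitudes(signal, peaks),
        source=source,
    )


def mae_breathing_rate(
    d_mms: np.ndarray, d_ref: np.ndarray, t_min: float
) -> float:
    """Mean absolute breathing-rate error per minute.

    ``(1 / T_min) * sum_i |d_mms,i - d_ref,i| / d_ref,i`` with ``T_min``
    the measurement duration in minutes; cycles must be paired (built
    from the same trigger windows).
    """
    d_mms = np.asarray(d_mms, dtype=float)
    d_ref = np.asarray(d_ref, dtype=float)
    if d_mms.size != d_ref.size:
        raise DataError("duration lists must be paired (equal length)")
    if t_min <= 0:
        raise DataError("t_min must be positive")
    return float(np.sum(np.abs(d_mms - d_ref) / d_ref) / t_min)


def mae_amplitude(r: RespirationSignal, r_ref: RespirationSignal) -> float:
    """Pointwise mean absolute difference of two signals on one grid."""
    if r.time.size != r_ref.time.size or not np.allclose(
        r.time, r_ref.time, atol=1e-9
    ):
        raise DataError("signals must share the sample grid")
    return float(np.mean(np.abs(r.values - r_ref.values)))


def mean_cycle_magnitude(magnitudes: np.ndarray) -> float:
    """Arithmetic mean of the per-cycle magnitudes."""
    m = np.asarray(magnitudes, dtype=float)
    if m.size == 0:
        raise DataError("empty cycle-magnitude list")
    return float(m.mean())


def baseline_correct_reference(
    reference: RespirationSignal, window: float = 60.0
) -> RespirationSignal:
    """Remove slow drift from a reference signal.

    Subtracts the trailing moving average with the given window length
    (seconds); frequencies well above ``1/window`` pass essentially
    unchanged.
    """
    if reference.duration <= window:
        raise DataError("record must be longer than the baseline window")
    w = max(1, int(round(window * reference.fs)))
    corrected = reference.values - moving_average(reference.values, w)
    return reference.with_values(corrected)
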