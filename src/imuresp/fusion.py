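"""Fusion of the shape and polarity-and-magnitude signals.

The shape signal s(t) has the right waveform but arbitrary units and
sign; the position signal p(t) has physical sign and cm scale but a
poorer waveform.  Fusion re-synchronises the two (the zero-phase
high-pass chain shifts p by an unknown, possibly negative delay with
respect to the causally filtered s), takes the polarity q from the sign
of their mid-record correlation, and rescales the mean-centred shape
signal by the ratio of the signals' moving standard deviations so the
fused signal r(t) carries p's magnitude with s's waveform.  A baseline
term derived from the low-passed shape signal restores the slow trend
that the high-pass filtering removed from p.  An optional subject
constant gamma equates the mean breathing-cycle magnitude with a
reference system's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DataError, DegenerateDataError
from .shape import moving_average
from .signalio import AlgorithmParams
from .signals import RespirationSignal

__all__ = [
    "FusionDiagnostics",
    "estimate_delay",
    "estimate_polarity",
    "moving_stats",
    "shift_samples",
    "fuse_wobc",
    "estimate_baseline",
    "baseline_correct",
    "calibrate",
    "fuse",
]

#: Moving variances below this are treated as numerically zero.
VAR_EPS = 1e-12


@dataclass
class FusionDiagnostics:
    """Intermediate quantities of one fusion run."""

    d: float  # s, delay of p relative to s
    q: int  # polarity, +1 or -1
    gamma: float | None  # calibration constant, if applied
    s_avg: np.ndarray
    s_var: np.ndarray
    p_avg: np.ndarray
    p_var: np.ndarray
    b: np.ndarray  # baseline estimate, cm


def _mid_half(n: int) -> tuple[int, int]:
    # [floor(N/4), floor(3N/4)) — the central half of the record
    return n // 4, (3 * n) // 4


def _lag_range(fs: float, d_max: float) -> np.ndarray:
    k_max = int(round(d_max * fs))
    return np.arange(-k_max, k_max + 1)


def _lag_correlations(s: np.ndarray, p: np.ndarray, ks: np.ndarray) -> np.ndarray:
    n = s.size
    i0, i1 = _mid_half(n)
    seg = s[i0:i1]
    return np.array([float(p[i0 + k : i1 + k] @ seg) for k in ks])


def estimate_delay(
    s: np.ndarray, p: np.ndarray, fs: float, d_max: float = 2.0
) -> float:
    """Delay d maximising the mid-record correlation of s and p.

    Maximises ``|sum_{t in mid half} s(t) p(t + d')|`` over the discrete
    lags ``d' = k / fs`` with ``|d'| <= d_max``.  The magnitude (not the
    raw sum) is maximised because the shape signal's sign is arbitrary:
    an inverted principal component makes the best alignment the most
    *negative* correlation, and chasing the most positive sum instead
    would lock onto a half-period-shifted lag and defeat the polarity
    estimate.  Ties are broken toward the smallest ``|d'|``, then toward
    the negative lag.
    """
    s = np.asarray(s, dtype=float)
    p = np.asarray(p, dtype=float)
    if s.size != p.size:
        raise DataError("s and p must share a grid")
    ks = _lag_range(fs, d_max)
    if s.size <= 4 * ks[-1]:
        raise DataError(
            f"record of {s.size} samples is too short for a delay search "
            f"over +/-{d_max} s (need more than {4 * ks[-1]} samples)"
        )
    corr = np.abs(_lag_correlations(s, p, ks))
    order = np.lexsort((ks, np.abs(ks)))  # |k| ascending, negative first
    best = order[0]
    for idx in order[1:]:
        if corr[idx] > corr[best]:
            best = idx
    return float(ks[best] / fs)


def estimate_polarity(s: np.ndarray, p: np.ndarray, d: float, fs: float) -> int:
    """Sign of the mid-record correlation at lag ``d`` (0 maps to +1)."""
    s = np.asarray(s, dtype=float)
    p = np.asarray(p, dtype=float)
    k = int(round(d * fs))
    i0, i1 = _mid_half(s.size)
    c = float(p[i0 + k : i1 + k] @ s[i0:i1])
    return -1 if c < 0.0 else 1


def moving_stats(x: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Trailing-window mean and population variance by incremental updates.

    The window holds the ``min(w, i + 1)`` most recent samples; samples
    entering and leaving it update the running mean and sum of squared
    deviations with Welford-style add/remove formulas, so each output
    sample costs O(1).
    """
    if int(w) < 2:
        raise ConfigurationError("moving-stats window must be >= 2 samples")
    w = int(w)
    x = np.asarray(x, dtype=float)
    n = x.size
    avg = np.empty(n)
    var = np.empty(n)
    xs = x.tolist()
    mean = 0.0
    m2 = 0.0
    count = 0
    for i in range(n):
        xi = xs[i]
        count += 1
        delta = xi - mean
        mean += delta / count
        m2 += delta * (xi - mean)
        if count > w:
            xo = xs[i - w]
            old_mean = mean
            mean = (count * mean - xo) / (count - 1)
            m2 -= (xo - old_mean) * (xo - mean)
            count -= 1
        if m2 < 0.0:
            m2 = 0.0
        avg[i] = mean
        var[i] = m2 / count
    return avg, var


def shift_samples(x: np.ndarray, k: int) -> np.ndarray:
    """Return ``y[t] = x[t + k]`` with edge samples held."""
    x = np.asarray(x, dtype=float)
    if k == 0:
        return x.copy()
    y = np.empty_like(x)
    if k > 0:
        y[:-k] = x[k:]
        y[-k:] = x[-1]
    else:
        y[-k:] = x[:k]
        y[:-k] = x[0]
    return y


def _scale_factor(s_var: np.ndarray, p_var: np.ndarray) -> np.ndarray:
    """sqrt(p_var/s_var), holding the last valid value where s_var ~ 0."""
    valid = s_var >= VAR_EPS
    if not valid.any():
        raise DegenerateDataError("shape signal has no variance to scale")
    ratio = np.sqrt(p_var / np.where(valid, s_var, 1.0))
    idx = np.where(valid, np.arange(valid.size), 0)
    np.maximum.accumulate(idx, out=idx)
    scale = np.where(valid, ratio, ratio[idx])
    # before the first valid sample the scale is unknown; use zero
    first = int(np.argmax(valid))
    if first > 0:
        scale[:first] = 0.0
    return scale


def fuse_wobc(
    s: np.ndarray, p: np.ndarray, q: int, params: AlgorithmParams
) -> np.ndarray:
    """Fused signal without baseline correction.

    ``r_wobc(t) = q * sqrt(p_var(t) / s_var(t)) * (s(t) - s_avg(t))``
    with the mean over window ``w_avgF1`` and the variances over
    ``w_avgF2``; ``p`` must already be realigned by the estimated delay.
    """
    s = np.asarray(s, dtype=float)
    p = np.asarray(p, dtype=float)
    s_avg, _ = moving_stats(s, params.w_avgF1)
    _, s_var = moving_stats(s, params.w_avgF2)
    _, p_var = moving_stats(p, params.w_avgF2)
    return q * _scale_factor(s_var, p_var) * (s - s_avg)


def estimate_baseline(
    s: np.ndarray, r_wobc: np.ndarray, params: AlgorithmParams
) -> np.ndarray:
    """Baseline drift estimate from the low-passed shape signal.

    ``b(t) = (savg'(t) - mean(s)) * sigma_r / sigma_s`` where savg' is
    the trailing moving average of s over ``w_avgF3`` and sigma_s,
    sigma_r are the global standard deviations of s and r_wobc: a
    zero-centred, low-passed copy of the shape signal rescaled into the
    fused signal's units.
    """
    s = np.asarray(s, dtype=float)
    r_wobc = np.asarray(r_wobc, dtype=float)
    if s.size <= params.w_avgF3:
        raise DataError(
            f"record of {s.size} samples is not longer than the baseline "
            f"window w_avgF3={params.w_avgF3}"
        )
    sigma_s = float(s.std())
    sigma_r = float(r_wobc.std())
    if sigma_r == 0.0 or sigma_s == 0.0:
        raise DegenerateDataError("zero-variance signal in baseline estimation")
    return (moving_average(s, params.w_avgF3) - s.mean()) * (sigma_r / sigma_s)


def baseline_correct(r_wobc: np.ndarray, b: np.ndarray, q: int) -> np.ndarray:
    """Baseline-corrected fused signal: ``r(t) = r_wobc(t) + q b(t)``."""
    return np.asarray(r_wobc, dtype=float) + q * np.asarray(b, dtype=float)


def calibrate(
    signal: RespirationSignal,
    reference_magnitudes: np.ndarray,
    mms_magnitudes: np.ndarray,
) -> tuple[RespirationSignal, float]:
    """Scale a fused signal so mean cycle magnitudes match the reference.

    ``gamma = mean(reference cycle magnitudes) / mean(own cycle
    magnitudes)``; returns ``(gamma * signal, gamma)``.
    """
    ref = np.asarray(reference_magnitudes, dtype=float)
    own = np.asarray(mms_magnitudes, dtype=float)
    if ref.size == 0 or own.size == 0:
        raise DataError("calibration requires non-empty cycle tables")
    own_mean = float(own.mean())
    if own_mean == 0.0:
        raise DegenerateDataError("zero mean cycle magnitude; cannot calibrate")
    gamma = float(ref.mean()) / own_mean
    return signal.with_values(signal.values * gamma), gamma


def fuse(
    s_sig: RespirationSignal,
    p_sig: RespirationSignal,
    params: AlgorithmParams | None = None,
) -> tuple[RespirationSignal, FusionDiagnostics]:
    """Run the full fusion: delay, polarity, scaling, baseline.

    Returns the fused respiration signal r(t) in cm on the shape
    signal's grid, together with the diagnostics (delay, polarity,
    moving statistics, baseline).
    """
    if params is None:
        params = AlgorithmParams()
    s = s_sig.values
    p = p_sig.values
    if s.size != p.size:
        raise DataError("shape and position signals must share a grid")
    d = estimate_delay(s, p, params.fs, params.d_max)
    q = estimate_polarity(s, p, d, params.fs)
    p_al = shift_samples(p, int(round(d * params.fs)))

    s_avg, _ = moving_stats(s, params.w_avgF1)
    _, s_var = moving_stats(s, params.w_avgF2)
    p_avg, _ = moving_stats(p_al, params.w_avgF1)
    _, p_var = moving_stats(p_al, params.w_avgF2)
    r_wobc = q * _scale_factor(s_var, p_var) * (s - s_avg)
    b = estimate_baseline(s, r_wobc, params)
    r = baseline_correct(r_wobc, b, q)
    diag = FusionDiagnostics(
        d=d, q=q, gamma=None, s_avg=s_avg, s_var=s_var, p_avg=p_avg, p_var=p_var, b=b
    )
    fused = RespirationSignal(s_sig.time, r, unit="cm", kind="fused")
    return fused, diag
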