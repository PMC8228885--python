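"""Amplitude-based respiratory gating and data-preservation statistics.

List-mode PET data are binned by the instantaneous value of the
respiration signal: global thresholds at the lower and upper quantiles
of the full record bound the usable amplitude range, which is divided
into equidistant gates.  Samples in cycles the reference system flagged
invalid are rejected outright; samples outside the threshold band are
rejected by amplitude.  Because the thresholds are quantiles, the gate
labels are invariant to multiplying the signal by any positive
constant — calibrated and uncalibrated signals gate identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DataError, DegenerateDataError

__all__ = [
    "GatingConfig",
    "GatingResult",
    "REJECTED_AMPLITUDE",
    "REJECTED_CYCLE",
    "compute_thresholds",
    "sample_validity_mask",
    "assign_gates",
    "export_gate_windows",
]

#: Label for samples whose value falls outside the threshold band.
REJECTED_AMPLITUDE = 0
#: Label for samples inside cycles flagged invalid (or outside all cycles).
REJECTED_CYCLE = -1


@dataclass(frozen=True)
class GatingConfig:
    """Quantile levels and gate count (defaults: 0.2/0.8, 5 gates)."""

    q_low: float = 0.2
    q_high: float = 0.8
    n_gates: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.q_low < self.q_high <= 1.0:
            raise ConfigurationError("need 0 <= q_low < q_high <= 1")
        if self.n_gates < 1:
            raise ConfigurationError("n_gates must be >= 1")


@dataclass
class GatingResult:
    """Thresholds, per-sample gate labels and preservation statistics.

    ``labels`` contains gate numbers ``1..n_gates`` for preserved
    samples, :data:`REJECTED_AMPLITUDE` or :data:`REJECTED_CYCLE`
    otherwise.  ``preserved_fraction[i]`` is the percentage of all
    samples landing in gate ``i + 1``; ``lost_fraction`` is the
    percentage rejected for either reason.
    """

    thr_low: float
    thr_high: float
    gate_edges: np.ndarray
    labels: np.ndarray
    preserved_fraction: np.ndarray  # %, one entry per gate
    lost_fraction: float  # %


def compute_thresholds(
    values: np.ndarray, config: GatingConfig | None = None
) -> tuple[float, float]:
    """Global gating thresholds: empirical quantiles of the full record.

    Linear interpolation of the order statistics.
    """
    if config is None:
        config = GatingConfig()
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise DataError("cannot compute thresholds of an empty signal")
    lo, hi = np.quantile(v, [config.q_low, config.q_high])
    return float(lo), float(hi)


def sample_validity_mask(
    time: np.ndarray, triggers: np.ndarray, validity: np.ndarray
) -> np.ndarray:
    """Broadcast per-cycle validity flags to samples.

    Each trigger-to-trigger interval carries one flag; samples before
    the first trigger or after the last are invalid (no cycle contains
    them).
    """
    time = np.asarray(time, dtype=float)
    triggers = np.asarray(triggers, dtype=float)
    validity = np.asarray(validity, dtype=bool)
    if validity.size != triggers.size - 1:
        raise DataError("need one validity flag per trigger interval")
    mask = np.zeros(time.size, dtype=bool)
    idx = np.searchsorted(triggers, time, side="right") - 1
    in_cycle = (idx >= 0) & (idx < validity.size)
    mask[in_cycle] = validity[idx[in_cycle]]
    # a sample exactly on the last trigger closes the final cycle
    on_last = np.isclose(time, triggers[-1])
    if validity.size:
        mask[on_last] = validity[-1]
    return mask


def assign_gates(
    values: np.ndarray,
    thresholds: tuple[float, float],
    n_gates: int = 5,
    validity_mask: np.ndarray | None = None,
) -> GatingResult:
    """Label every sample with its gate or a rejection cause.

    Gates are equidistant over ``[thr_low, thr_high]``, half-open
    ``[e_i, e_{i+1})`` with the top gate closed.  ``validity_mask``
    marks samples belonging to valid cycles; ``None`` means all valid.
    """
    v = np.asarray(values, dtype=float)
    thr_low, thr_high = (float(x) for x in thresholds)
    if thr_low >= thr_high:
        raise DegenerateDataError(
            "degenerate thresholds (thr_low >= thr_high); constant signal?"
        )
    if n_gates < 1:
        raise ConfigurationError("n_gates must be >= 1")
    if validity_mask is None:
        validity_mask = np.ones(v.size, dtype=bool)
    validity_mask = np.asarray(validity_mask, dtype=bool)
    if validity_mask.size != v.size:
        raise DataError("validity mask must match the signal length")

    edges = np.linspace(thr_low, thr_high, n_gates + 1)
    labels = np.empty(v.size, dtype=int)
    labels.fill(REJECTED_AMPLITUDE)
    in_band = (v >= thr_low) & (v <= thr_high)
    gate = np.searchsorted(edges, v[in_band], side="right")
    gate = np.clip(gate, 1, n_gates)  # top edge closes the last gate
    labels[in_band] = gate
    labels[~validity_mask] = REJECTED_CYCLE

    n = v.size
    preserved = np.array(
        [100.0 * np.count_nonzero(labels == g) / n for g in range(1, n_gates + 1)]
    )
    lost = 100.0 - preserved.sum()
    return GatingResult(
        thr_low=thr_low,
        thr_high=thr_high,
        gate_edges=edges,
        labels=labels,
        preserved_fraction=preserved,
        lost_fraction=float(lost),
    )


def export_gate_windows(
    result: GatingResult, time: np.ndarray
) -> list[tuple[int, float, float]]:
    """Convert label runs into time intervals for list-mode unlisting.

    Returns ``(label, t_start, t_end)`` for every maximal run of equal
    labels, with ``t_start``/``t_end`` the times of the run's first and
    last samples; intervals per gate are disjoint and sorted.
    """
    time = np.asarray(time, dtype=float)
    labels = result.labels
    if labels.size != time.size:
        raise DataError("time grid must match the label array")
    if labels.size == 0:
        return []
    boundaries = np.nonzero(np.diff(labels))[0]
    starts = np.concatenate([[0], boundaries + 1])
    ends = np.concatenate([boundaries, [labels.size - 1]])
    return [
        (int(labels[s]), float(time[s]), float(time[e]))
        for s, e in zip(starts, ends)
    ]
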