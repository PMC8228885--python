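"""One-dimensional respiration waveforms on a sample grid.

A :class:`RespirationSignal` is the common currency of the pipeline: the
shape signal ``s(t)`` (arbitrary units, arbitrary sign), the
polarity-and-magnitude signal ``p(t)`` (cm), the fused signal ``r(t)``
(cm) and the external reference (cm) are all instances of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DataError

#: Allowed values of :attr:`RespirationSignal.kind`.
KINDS = ("shape", "polmag", "fused", "reference")


@dataclass
class RespirationSignal:
    """A sampled 1-D waveform with its time grid and unit metadata.

    Parameters
    ----------
    time:
        Sample times in seconds, strictly increasing.
    values:
        Sample values, same length as ``time``; must be finite.
    unit:
        ``"a.u."`` or ``"cm"``.
    kind:
        One of ``"shape"``, ``"polmag"``, ``"fused"``, ``"reference"``.
    """

    time: np.ndarray
    values: np.ndarray
    unit: str = "a.u."
    kind: str = "shape"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time.ndim != 1 or self.values.ndim != 1:
            raise DataError("time and values must be 1-D arrays")
        if self.time.size != self.values.size:
            raise DataError(
                f"time ({self.time.size}) and values ({self.values.size}) "
                "must have equal length"
            )
        if self.time.size == 0:
            raise DataError("empty signal")
        if self.time.size > 1 and not np.all(np.diff(self.time) > 0):
            raise DataError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise DataError("signal values must be finite")
        if self.kind not in KINDS:
            raise DataError(f"unknown signal kind {self.kind!r}")

    def __len__(self) -> int:
        return self.time.size

    @property
    def duration(self) -> float:
        """Time span covered by the grid, in seconds."""
        return float(self.time[-1] - self.time[0])

    @property
    def fs(self) -> float:
        """Median sampling rate in Hz (exact for uniform grids)."""
        if self.time.size < 2:
            raise DataError("sampling rate undefined for a single sample")
        return 1.0 / float(np.median(np.diff(self.time)))

    def with_values(self, values: np.ndarray, **meta) -> "RespirationSignal":
        """Return a copy carrying new values on the same grid."""
        return replace(self, values=np.asarray(values, dtype=float), **meta)

    def shifted(self, offset: float) -> "RespirationSignal":
        """Return a copy with all timestamps shifted by ``offset`` seconds."""
        return replace(self, time=self.time + float(offset))

    def resampled(self, new_time: np.ndarray) -> "RespirationSignal":
        """Linearly interpolate onto ``new_time`` (no extrapolation beyond
        the support: edge values are held)."""
        new_time = np.asarray(new_time, dtype=float)
        vals = np.interp(new_time, self.time, self.values)
        return replace(self, time=new_time, values=vals)
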