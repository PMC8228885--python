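"""Gated-image quality metrics and line-profile extraction.

Quality of a gated PET reconstruction is summarised from the mean and
standard deviation of tracer uptake (Bq/mL) in two volumes of interest
— myocardium and blood pool:

    CR  = myo_mean / blood_mean          (contrast ratio)
    SNR = myo_mean / blood_sd            (signal-to-noise ratio)
    CV  = myo_sd / myo_mean              (coefficient of variation)
    CNR = (myo_mean - blood_mean) / blood_sd   (contrast-to-noise ratio)

CR and CV are invariant under global intensity scaling; SNR and CNR
scale linearly.  VOI standard deviations are expected as sample (n-1)
standard deviations.  Line profiles over a hot spot are sampled by
trilinear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import DataError, DegenerateDataError

__all__ = ["VoiStats", "ImageQualityMetrics", "image_quality", "extract_profile"]


@dataclass(frozen=True)
class VoiStats:
    """Uptake statistics (Bq/mL) of the two volumes of interest."""

    myocardium_mean: float
    myocardium_sd: float
    bloodpool_mean: float
    bloodpool_sd: float

    def __post_init__(self) -> None:
        if self.myocardium_sd < 0 or self.bloodpool_sd < 0:
            raise DataError("VOI standard deviations must be >= 0")


@dataclass(frozen=True)
class ImageQualityMetrics:
    """The four dimensionless VOI-based quality metrics."""

    cr: float
    snr: float
    cv: float
    cnr: float

    def as_dict(self) -> dict:
        return {"cr": self.cr, "snr": self.snr, "cv": self.cv, "cnr": self.cnr}


def image_quality(v: VoiStats) -> ImageQualityMetrics:
    """Compute CR, SNR, CV and CNR from VOI statistics."""
    if v.myocardium_mean <= 0 or v.bloodpool_mean <= 0:
        raise DegenerateDataError("VOI means must be positive for ratio metrics")
    if v.bloodpool_sd == 0:
        raise DegenerateDataError("blood-pool sd of zero; SNR/CNR undefined")
    return ImageQualityMetrics(
        cr=v.myocardium_mean / v.bloodpool_mean,
        snr=v.myocardium_mean / v.bloodpool_sd,
        cv=v.myocardium_sd / v.myocardium_mean,
        cnr=(v.myocardium_mean - v.bloodpool_mean) / v.bloodpool_sd,
    )


def extract_profile(
    volume: np.ndarray,
    voxel_size: tuple[float, float, float],
    start: tuple[float, float, float],
    end: tuple[float, float, float],
    spacing: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample intensities along a line through a 3-D volume.

    ``start`` and ``end`` are physical coordinates (same units as
    ``voxel_size``, axis order matching the array axes).  Samples are
    trilinear, uniformly spaced at ``spacing`` (default: half the
    smallest voxel dimension).  Returns ``(distances, values)`` with
    distances measured from ``start``.
    """
    vol = np.asarray(volume, dtype=float)
    if vol.ndim != 3:
        raise DataError("volume must be a 3-D array")
    vs = np.asarray(voxel_size, dtype=float)
    if vs.shape != (3,) or np.any(vs <= 0):
        raise DataError("voxel_size must be three positive lengths")
    p0 = np.asarray(start, dtype=float)
    p1 = np.asarray(end, dtype=float)
    extent = (np.array(vol.shape) - 1) * vs
    for name, p in (("start", p0), ("end", p1)):
        if np.any(p < -1e-9) or np.any(p > extent + 1e-9):
            raise DataError(f"{name} point lies outside the volume")
    length = float(np.linalg.norm(p1 - p0))
    if spacing is None:
        spacing = float(vs.min()) / 2.0
    if spacing <= 0:
        raise DataError("spacing must be positive")
    n = max(2, int(np.ceil(length / spacing)) + 1)
    frac = np.linspace(0.0, 1.0, n)
    points = p0[None, :] + frac[:, None] * (p1 - p0)[None, :]
    coords = (points / vs).T  # physical -> voxel-index coordinates
    values = map_coordinates(vol, coords, order=1, mode="nearest")
    return frac * length, values
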