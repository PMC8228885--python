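"""Shape signal: PCA of the sternum node's accelerometer x/y channels.

The thoracic tilt that breathing induces at the sternum projects
gravity onto the sensor's x and y axes.  After a short causal moving
average, the dominant direction of the 2-D (x, y) point cloud is found
by principal component analysis over an initial buffer; projecting the
mean-centred samples onto that first principal direction yields the
*shape signal* s(t) — a clean respiration waveform in arbitrary units
whose sign is arbitrary (polarity is resolved later against the
abdomen-node position signal).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DataError, DegenerateDataError
from .signalio import AlgorithmParams, ResampledRecord
from .signals import RespirationSignal

__all__ = ["PcaBasis", "moving_average", "fit_pca_basis", "compute_shape_signal"]


def moving_average(x: np.ndarray, w: int) -> np.ndarray:
    """Causal (trailing) moving average.

    ``y[i]`` is the mean of the ``min(w, i + 1)`` most recent samples,
    so the output has the input's length and a group delay of about
    ``(w - 1) / 2`` samples in steady state.
    """
    w = int(w)
    if w < 1:
        raise ConfigurationError("moving-average window must be >= 1 sample")
    x = np.asarray(x, dtype=float)
    n = x.size
    c = np.cumsum(x)
    out = np.empty(n)
    head = min(w, n)
    out[:head] = c[:head] / np.arange(1, head + 1)
    if n > w:
        out[w:] = (c[w:] - c[:-w]) / w
    return out


@dataclass(frozen=True)
class PcaBasis:
    """2-D PCA basis: column means and orthonormal principal directions.

    ``components`` rows are the principal directions in descending
    explained-variance order.
    """

    mean: np.ndarray
    components: np.ndarray
    explained_variance: np.ndarray

    def project(self, xy: np.ndarray) -> np.ndarray:
        """First-principal-component score of mean-centred samples."""
        return (np.asarray(xy, dtype=float) - self.mean) @ self.components[0]


def fit_pca_basis(buffer: np.ndarray) -> PcaBasis:
    """Fit a PCA basis to an (N, 2) sample buffer.

    Eigenvectors of the sample covariance, in descending eigenvalue
    order.  A buffer with numerically zero total variance (all points
    coincident) is degenerate.
    """
    b = np.asarray(buffer, dtype=float)
    if b.ndim != 2 or b.shape[1] != 2:
        raise DataError("PCA buffer must be an (N, 2) array")
    if b.shape[0] < 2:
        raise DataError("PCA buffer needs at least two samples")
    mean = b.mean(axis=0)
    centred = b - mean
    cov = centred.T @ centred / (b.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    components = evecs[:, order].T
    scale = max(1.0, float(np.abs(b).max()) ** 2)
    if evals[0] <= 1e-15 * scale:
        raise DegenerateDataError("PCA buffer has zero variance")
    return PcaBasis(mean=mean, components=components, explained_variance=evals)


def _eig2_principal(cxx: float, cyy: float, cxy: float) -> np.ndarray:
    """Unit eigenvector of the larger eigenvalue of [[cxx, cxy], [cxy, cyy]]."""
    angle = 0.5 * math.atan2(2.0 * cxy, cxx - cyy)
    return np.array([math.cos(angle), math.sin(angle)])


def compute_shape_signal(
    rec: ResampledRecord, params: AlgorithmParams, streaming: bool = False
) -> RespirationSignal:
    """Compute the shape signal s(t) from node 1's accelerometer x/y.

    Both channels are moving-average filtered with window ``w_avgS``,
    the PCA basis is fitted to the first ``N_circ`` filtered samples and
    then frozen, and the whole record is projected onto the first
    principal direction.  With ``streaming=True`` the basis is instead
    refitted at every sample from the trailing ``N_circ``-sample window
    (sign-aligned between consecutive fits to avoid polarity flicker);
    the frozen variant is the default and matches the offline use.
    """
    n_circ = params.N_circ
    if len(rec) < n_circ:
        raise DataError(
            f"record has {len(rec)} samples; at least N_circ={n_circ} "
            "are required to fill the PCA buffer"
        )
    ax = moving_average(rec.node1_accel_xy[:, 0], params.w_avgS)
    ay = moving_average(rec.node1_accel_xy[:, 1], params.w_avgS)
    xy = np.column_stack([ax, ay])
    basis = fit_pca_basis(xy[:n_circ])
    if not streaming:
        values = basis.project(xy)
        return RespirationSignal(rec.time, values, unit="a.u.", kind="shape")

    # Streaming mode: rolling mean/covariance over the trailing buffer,
    # closed-form 2x2 eigenvector, continuity-aligned sign.
    n = xy.shape[0]
    values = np.empty(n)
    values[:n_circ] = basis.project(xy[:n_circ])
    direction = basis.components[0].copy()
    sx, sy = ax[:n_circ].sum(), ay[:n_circ].sum()
    sxx = float(ax[:n_circ] @ ax[:n_circ])
    syy = float(ay[:n_circ] @ ay[:n_circ])
    sxy = float(ax[:n_circ] @ ay[:n_circ])
    m = float(n_circ)
    for i in range(n_circ, n):
        xi, yi = ax[i], ay[i]
        xo, yo = ax[i - n_circ], ay[i - n_circ]
        sx += xi - xo
        sy += yi - yo
        sxx += xi * xi - xo * xo
        syy += yi * yi - yo * yo
        sxy += xi * yi - xo * yo
        mx, my = sx / m, sy / m
        cxx = sxx / m - mx * mx
        cyy = syy / m - my * my
        cxy = sxy / m - mx * my
        pc = _eig2_principal(cxx, cyy, cxy)
        if float(pc @ direction) < 0.0:
            pc = -pc
        direction = pc
        values[i] = (xi - mx) * pc[0] + (yi - my) * pc[1]
    return RespirationSignal(rec.time, values, unit="a.u.", kind="shape")
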