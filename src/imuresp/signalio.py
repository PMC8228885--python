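"""Recording I/O, time synchronisation and resampling onto the analysis grid.

The two IMU nodes stream their accelerometer and gyroscope at different
hardware rates with independent timestamps.  Before any respiration
processing, all six channels of interest (node-1 accelerometer x/y,
node-2 accelerometer x/y/z and gyroscope x/y/z) are linearly
interpolated onto one uniform 100 Hz grid covering the common time
support, so every timestamp carries exactly one sample per channel.

Fixture bundles are plain-CSV directories: one file per node (accel and
gyro rows interleaved by timestamp), a reference file, a trigger file
and a YAML echo of the generating configuration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, DataError
from .signals import RespirationSignal

logger = logging.getLogger(__name__)

__all__ = [
    "NodeRecording",
    "ResampledRecord",
    "AlgorithmParams",
    "Bundle",
    "apply_time_offset",
    "resample_to_grid",
    "write_bundle",
    "load_bundle",
]


@dataclass
class NodeRecording:
    """Raw per-node accelerometer + gyroscope streams.

    Each stream has its own strictly increasing timestamps; the three
    channels within a stream share them.  Units: accel m/s^2, gyro rad/s.
    """

    accel_time: np.ndarray
    accel: np.ndarray  # (N, 3)
    gyro_time: np.ndarray
    gyro: np.ndarray  # (M, 3)
    node_id: int = 1

    def __post_init__(self) -> None:
        self.accel_time = np.asarray(self.accel_time, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro_time = np.asarray(self.gyro_time, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        for name, t, x in (
            ("accel", self.accel_time, self.accel),
            ("gyro", self.gyro_time, self.gyro),
        ):
            if x.ndim != 2 or x.shape[1] != 3:
                raise DataError(f"{name} must be an (N, 3) array")
            if t.size != x.shape[0]:
                raise DataError(f"{name} timestamps and samples disagree")
            if t.size > 1 and not np.all(np.diff(t) > 0):
                raise DataError(f"{name} timestamps must be strictly increasing")

    def shifted(self, offset: float) -> "NodeRecording":
        return NodeRecording(
            accel_time=self.accel_time + float(offset),
            accel=self.accel,
            gyro_time=self.gyro_time + float(offset),
            gyro=self.gyro,
            node_id=self.node_id,
        )


@dataclass
class ResampledRecord:
    """Both nodes' channels of interest on one uniform grid at ``fs``."""

    time: np.ndarray
    node1_accel_xy: np.ndarray  # (N, 2)
    node2_accel_xyz: np.ndarray  # (N, 3)
    node2_gyro_xyz: np.ndarray  # (N, 3)
    fs: float

    def __post_init__(self) -> None:
        n = np.asarray(self.time).size
        for name in ("node1_accel_xy", "node2_accel_xyz", "node2_gyro_xyz"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape[0] != n:
                raise DataError(f"{name} length does not match the time grid")
        self.time = np.asarray(self.time, dtype=float)

    def __len__(self) -> int:
        return self.time.size


@dataclass(frozen=True)
class AlgorithmParams:
    """Tunable parameters of the respiration estimation algorithm.

    Window lengths left as ``None`` are derived from ``fs`` with the
    standard factors: ``w_avgS = floor(0.8 fs)``, ``N_circ = floor(60
    fs)``, ``w_avgF1 = floor(10 fs)``, ``w_avgF2 = w_avgF3 = floor(60
    fs)``.  At the default ``fs = 100`` Hz this gives 80, 6000, 1000,
    6000 and 6000 samples.
    """

    fs: float = 100.0  # Hz, common analysis grid
    g: float = 9.81  # m/s^2
    f_B: float = 0.2  # Hz, high-pass cutoff of the integration chain
    d_max: float = 2.0  # s, delay search half-range
    madgwick_beta: float = 0.1  # orientation-filter gain
    w_avgS: int | None = None  # shape-signal moving-average window
    N_circ: int | None = None  # PCA buffer length
    w_avgF1: int | None = None  # fusion moving-average window
    w_avgF2: int | None = None  # fusion moving-variance window
    w_avgF3: int | None = None  # baseline moving-average window

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ConfigurationError("fs must be positive")
        if self.f_B <= 0 or self.f_B >= self.fs / 2:
            raise ConfigurationError("f_B must lie in (0, fs/2)")
        if self.d_max <= 0:
            raise ConfigurationError("d_max must be positive")
        defaults = {
            "w_avgS": int(math.floor(0.8 * self.fs)),
            "N_circ": int(math.floor(60.0 * self.fs)),
            "w_avgF1": int(math.floor(10.0 * self.fs)),
            "w_avgF2": int(math.floor(60.0 * self.fs)),
            "w_avgF3": int(math.floor(60.0 * self.fs)),
        }
        for name, value in defaults.items():
            if getattr(self, name) is None:
                object.__setattr__(self, name, value)
            elif getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1 sample")


def apply_time_offset(obj, offset: float):
    """Shift all timestamps of a recording, signal or trigger array.

    The scanner and the measurement PC run on different clocks; the
    per-recording synchronisation offset is applied with this helper.
    Values are untouched.
    """
    if isinstance(obj, (NodeRecording, RespirationSignal)):
        return obj.shifted(offset)
    arr = np.asarray(obj, dtype=float)
    return arr + float(offset)


def resample_to_grid(
    rec1: NodeRecording, rec2: NodeRecording, fs: float = 100.0
) -> ResampledRecord:
    """Linearly interpolate both nodes onto a uniform grid at ``fs``.

    The grid covers the common time support of all four streams; its
    origin is the first common time rounded up to a multiple of ``1/fs``
    so no channel is ever extrapolated.
    """
    if fs <= 0:
        raise ConfigurationError("fs must be positive")
    streams = [
        (rec1.accel_time, rec1.accel[:, 0]),
        (rec1.accel_time, rec1.accel[:, 1]),
        (rec2.accel_time, rec2.accel[:, 0]),
        (rec2.accel_time, rec2.accel[:, 1]),
        (rec2.accel_time, rec2.accel[:, 2]),
        (rec2.gyro_time, rec2.gyro[:, 0]),
        (rec2.gyro_time, rec2.gyro[:, 1]),
        (rec2.gyro_time, rec2.gyro[:, 2]),
    ]
    t_start = max(t[0] for t, _ in streams)
    t_end = min(t[-1] for t, _ in streams)
    if t_end - t_start < 2.0 / fs:
        raise DataError("streams share less than two grid samples of support")
    first = math.ceil(t_start * fs - 1e-9)
    last = math.floor(t_end * fs + 1e-9)
    grid = np.arange(first, last + 1) / fs
    cols = [np.interp(grid, t, x) for t, x in streams]
    return ResampledRecord(
        time=grid,
        node1_accel_xy=np.column_stack(cols[0:2]),
        node2_accel_xyz=np.column_stack(cols[2:5]),
        node2_gyro_xyz=np.column_stack(cols[5:8]),
        fs=float(fs),
    )


class Bundle(NamedTuple):
    """Contents of a fixture-bundle directory."""

    node1: NodeRecording
    node2: NodeRecording
    reference: RespirationSignal
    triggers: np.ndarray
    validity: np.ndarray
    config: dict | None


def _node_frame(rec: NodeRecording) -> pd.DataFrame:
    acc = pd.DataFrame(
        {
            "t": rec.accel_time,
            "ax": rec.accel[:, 0],
            "ay": rec.accel[:, 1],
            "az": rec.accel[:, 2],
        }
    )
    gyr = pd.DataFrame(
        {
            "t": rec.gyro_time,
            "gx": rec.gyro[:, 0],
            "gy": rec.gyro[:, 1],
            "gz": rec.gyro[:, 2],
        }
    )
    cols = ["t", "ax", "ay", "az", "gx", "gy", "gz"]
    merged = pd.concat([acc, gyr], ignore_index=True).reindex(columns=cols)
    return merged.sort_values("t", kind="stable", ignore_index=True)


def write_bundle(
    path,
    node1: NodeRecording,
    node2: NodeRecording,
    reference: RespirationSignal,
    triggers: np.ndarray,
    validity: np.ndarray,
    config: dict | None = None,
) -> Path:
    """Write a fixture bundle directory (CSV + YAML, UTF-8, '.' decimal)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name, rec in (("node1.csv", node1), ("node2.csv", node2)):
        _node_frame(rec).to_csv(path / name, index=False)
    pd.DataFrame({"t": reference.time, "value": reference.values}).to_csv(
        path / "reference.csv", index=False
    )
    validity = np.asarray(validity, dtype=bool)
    flags = [f"{int(v)}" for v in validity] + [""]
    pd.DataFrame(
        {"t": np.asarray(triggers, dtype=float), "valid_next_cycle": flags}
    ).to_csv(path / "triggers.csv", index=False)
    if config is not None:
        (path / "config.yaml").write_text(
            yaml.safe_dump(config, sort_keys=False), encoding="utf-8"
        )
    return path


def _read_numeric(path: Path, columns: list[str]) -> pd.DataFrame:
    """Read a CSV, dropping (and counting) malformed rows."""
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, on_bad_lines="skip", float_precision="round_trip")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise DataError(f"{path.name}: missing columns {missing}")
    n_raw = len(df)
    for c in columns:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    df = df[np.isfinite(df["t"].to_numpy(dtype=float))]
    rejected = n_raw - len(df)
    if rejected:
        logger.warning("%s: rejected %d malformed row(s)", path.name, rejected)
    return df.reset_index(drop=True)


def _load_node(path: Path, node_id: int) -> NodeRecording:
    df = _read_numeric(path, ["t", "ax", "ay", "az", "gx", "gy", "gz"])
    acc = df.dropna(subset=["ax", "ay", "az"])
    gyr = df.dropna(subset=["gx", "gy", "gz"])
    if acc.empty or gyr.empty:
        raise DataError(f"{path.name}: missing accelerometer or gyroscope rows")
    return NodeRecording(
        accel_time=acc["t"].to_numpy(dtype=float),
        accel=acc[["ax", "ay", "az"]].to_numpy(dtype=float),
        gyro_time=gyr["t"].to_numpy(dtype=float),
        gyro=gyr[["gx", "gy", "gz"]].to_numpy(dtype=float),
        node_id=node_id,
    )


def load_bundle(path) -> Bundle:
    """Load a fixture bundle written by :func:`write_bundle`.

    Malformed rows are rejected with a logged count; missing files raise
    ``FileNotFoundError`` and structural problems raise ``DataError``.
    """
    path = Path(path)
    node1 = _load_node(path / "node1.csv", 1)
    node2 = _load_node(path / "node2.csv", 2)

    ref = _read_numeric(path / "reference.csv", ["t", "value"])
    ref = ref.dropna(subset=["value"])
    if ref.empty:
        raise DataError("reference.csv contains no usable samples")
    reference = RespirationSignal(
        time=ref["t"].to_numpy(dtype=float),
        values=ref["value"].to_numpy(dtype=float),
        unit="cm",
        kind="reference",
    )

    trig = _read_numeric(path / "triggers.csv", ["t"])
    triggers = trig["t"].to_numpy(dtype=float)
    if triggers.size < 2:
        raise DataError("triggers.csv must contain at least two triggers")
    if not np.all(np.diff(triggers) > 0):
        raise DataError("trigger timestamps must be strictly increasing")
    flags = pd.to_numeric(trig["valid_next_cycle"], errors="coerce").to_numpy()
    validity = np.nan_to_num(flags[:-1], nan=1.0).astype(bool)

    config = None
    cfg_path = path / "config.yaml"
    if cfg_path.exists():
        config = yaml.safe_load(cfg_path.read_text(encoding="utf-8"))
    return Bundle(node1, node2, reference, triggers, validity, config)
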