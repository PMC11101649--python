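"""Readers and writers: CSV time series, YAML configs, JSON window reports.

The interchange format is plain CSV with SI units throughout (seconds,
rad/s, rad/s^2, m/s^2, radians).  Measurement files carry one column
block per package (``p0_wx ... p3_az``); ground-truth files carry the
reference-point kinematics plus the angular-acceleration columns; fused
files carry the estimator output.  External data with different column
names can be adapted via the ``column_map`` of :func:`read_measurements`.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .detection import DetectionConfig, ObservationWindow, SignalThresholds, ThresholdSet
from .fusion import FusedSeries, FusionConfig
from .geometry import ClusterGeometry, elemental_rotation
from .simulate import KinematicTruth, MeasurementSeries, NoiseModel

__all__ = [
    "read_measurements",
    "write_measurements",
    "read_truth",
    "write_truth",
    "read_fused",
    "write_fused",
    "load_config",
    "geometry_from_dict",
    "noise_from_dict",
    "write_windows",
    "read_windows",
]

_CHANNELS = ("wx", "wy", "wz", "ax", "ay", "az")


def _validate_time(t: np.ndarray, tol: float = 1e-6) -> None:
    dt = np.diff(t)
    if np.any(dt <= 0):
        row = int(np.nonzero(dt <= 0)[0][0]) + 1
        raise ValueError(f"non-monotonic time at row {row}")
    if len(dt) and float(np.ptp(dt)) > tol:
        raise ValueError("time grid is not uniform within 1e-6 s")


def _check_nan(frame: pd.DataFrame, columns) -> None:
    sub = frame[list(columns)]
    bad = sub.isna().any(axis=1)
    if bad.any():
        row = int(bad.idxmax())
        raise ValueError(f"NaN value at row {row} in columns {list(sub.columns[sub.iloc[row].isna()])}")


def write_measurements(path, series: MeasurementSeries) -> None:
    data = {"t": series.t}
    for i in range(4):
        for c, ch in enumerate(_CHANNELS):
            arr = series.gyro[i][:, c] if c < 3 else series.accel[i][:, c - 3]
            data[f"p{i}_{ch}"] = arr
    pd.DataFrame(data).to_csv(path, index=False)


def read_measurements(
    path, required: tuple[int, ...] = (0, 1, 2, 3), column_map: dict | None = None
) -> MeasurementSeries:
    """Read a per-package recording; missing optional packages become NaN.

    ``required`` lists the packages that must be present (an estimator's
    needs); ``column_map`` renames external column names onto the
    canonical ``t``/``p{i}_{wx..az}`` scheme.
    """
    frame = pd.read_csv(path)
    if column_map:
        frame = frame.rename(columns=column_map)
    if "t" not in frame.columns:
        raise ValueError("missing time column 't'")
    t = frame["t"].to_numpy(dtype=float)
    _check_nan(frame, ["t"])
    _validate_time(t)
    n = len(t)
    gyro = np.full((4, n, 3), np.nan)
    accel = np.full((4, n, 3), np.nan)
    for i in range(4):
        cols = [f"p{i}_{ch}" for ch in _CHANNELS]
        present = [c for c in cols if c in frame.columns]
        if len(present) < len(cols):
            if i in required:
                raise ValueError(
                    f"package {i} required: missing columns "
                    f"{sorted(set(cols) - set(present))}"
                )
            continue
        _check_nan(frame, cols)
        block = frame[cols].to_numpy(dtype=float)
        gyro[i] = block[:, :3]
        accel[i] = block[:, 3:]
    return MeasurementSeries(t, gyro, accel)


def write_truth(path, truth: KinematicTruth) -> None:
    data = {"t": truth.t}
    for c, ch in enumerate(_CHANNELS):
        data[ch] = truth.omega[:, c] if c < 3 else truth.a0[:, c - 3]
    for c, ch in enumerate(("alpha_x", "alpha_y", "alpha_z")):
        data[ch] = truth.alpha[:, c]
    pd.DataFrame(data).to_csv(path, index=False)


def read_truth(path) -> KinematicTruth:
    frame = pd.read_csv(path)
    cols = ["t", *_CHANNELS, "alpha_x", "alpha_y", "alpha_z"]
    missing = sorted(set(cols) - set(frame.columns))
    if missing:
        raise ValueError(f"missing columns {missing}")
    _check_nan(frame, cols)
    t = frame["t"].to_numpy(dtype=float)
    _validate_time(t)
    return KinematicTruth(
        t,
        omega=frame[["wx", "wy", "wz"]].to_numpy(dtype=float),
        alpha=frame[["alpha_x", "alpha_y", "alpha_z"]].to_numpy(dtype=float),
        a0=frame[["ax", "ay", "az"]].to_numpy(dtype=float),
    )


_FUSED_COLS = ["t", "wx", "wy", "wz", "ax_ang", "ay_ang", "az_ang"]


def write_fused(path, fused: FusedSeries) -> None:
    data = dict(zip(_FUSED_COLS, [fused.t, *fused.omega.T, *fused.alpha.T]))
    pd.DataFrame(data).to_csv(path, index=False)


def read_fused(path, estimator: str = "") -> FusedSeries:
    frame = pd.read_csv(path)
    missing = sorted(set(_FUSED_COLS) - set(frame.columns))
    if missing:
        raise ValueError(f"missing columns {missing}")
    _check_nan(frame, _FUSED_COLS)
    t = frame["t"].to_numpy(dtype=float)
    _validate_time(t)
    return FusedSeries(
        t,
        frame[["wx", "wy", "wz"]].to_numpy(dtype=float),
        frame[["ax_ang", "ay_ang", "az_ang"]].to_numpy(dtype=float),
        estimator=estimator,
    )


def _reject_unknown(section: dict, allowed: set, where: str) -> None:
    unknown = sorted(set(section) - allowed)
    if unknown:
        raise ValueError(f"unknown keys in {where}: {unknown}")


def geometry_from_dict(cfg: dict) -> ClusterGeometry:
    _reject_unknown(cfg, {"arm_lengths", "position_offsets", "misalignments"}, "geometry")
    kwargs = {}
    if "arm_lengths" in cfg:
        kwargs["arm_lengths"] = tuple(float(v) for v in cfg["arm_lengths"])
    if "position_offsets" in cfg:
        kwargs["position_offsets"] = np.asarray(cfg["position_offsets"], dtype=float)
    if "misalignments" in cfg:
        mis = np.stack([np.eye(3)] * 4)
        for entry in cfg["misalignments"]:
            _reject_unknown(entry, {"package", "axis", "angle"}, "misalignments entry")
            mis[int(entry["package"])] = elemental_rotation(
                entry["axis"], float(entry["angle"])
            )
        kwargs["misalignments"] = mis
    return ClusterGeometry(**kwargs)


def noise_from_dict(cfg: dict) -> NoiseModel:
    _reject_unknown(cfg, {"gyro_density", "accel_density", "rate", "seed"}, "noise")
    return NoiseModel(**cfg)


def load_config(path) -> dict:
    """Load a run configuration (geometry / noise / fusion / detection).

    Unknown sections or keys are rejected; omitted sections fall back to
    the reference-scenario defaults of the respective dataclasses.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    _reject_unknown(raw, {"geometry", "noise", "fusion", "detection"}, "config")
    out = {}
    if "geometry" in raw:
        out["geometry"] = geometry_from_dict(raw["geometry"])
    if "noise" in raw:
        out["noise"] = noise_from_dict(raw["noise"])
    if "fusion" in raw:
        _reject_unknown(raw["fusion"], {"beta_alpha", "beta_omega"}, "fusion")
        out["fusion"] = FusionConfig(**raw["fusion"])
    if "detection" in raw:
        allowed = {f.name for f in dataclasses.fields(DetectionConfig)}
        _reject_unknown(raw["detection"], allowed, "detection")
        out["detection"] = DetectionConfig(**raw["detection"])
    return out


def write_windows(path, windows: list[ObservationWindow], thresholds: ThresholdSet) -> None:
    payload = {
        "thresholds": {
            "omega": dataclasses.asdict(thresholds.omega),
            "alpha": dataclasses.asdict(thresholds.alpha),
            "stride_frequency": thresholds.stride_frequency,
            "touchdown_rate": thresholds.touchdown_rate,
        },
        "windows": [
            {"t_on": w.t_on, "t_off": w.t_off, "trigger_index": w.trigger_index,
             "flags": w.flags}
            for w in windows
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_windows(path) -> tuple[list[ObservationWindow], ThresholdSet]:
    with open(path) as fh:
        payload = json.load(fh)
    thr = payload["thresholds"]
    thresholds = ThresholdSet(
        omega=SignalThresholds(**thr["omega"]),
        alpha=SignalThresholds(**thr["alpha"]),
        stride_frequency=thr["stride_frequency"],
        touchdown_rate=thr["touchdown_rate"],
    )
    windows = [
        ObservationWindow(w["t_on"], w["t_off"], w.get("trigger_index", -1),
                          w.get("flags", {}))
        for w in payload["windows"]
    ]
    return windows, thresholds


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
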