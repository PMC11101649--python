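"""The cluster processing chain: calibration, 4-way omega and 8-way alpha fusion.

Redundancy is exploited with a sorted weighted mean: the candidate values
for one vector coordinate are sorted, the smallest and largest are treated
as potential outliers, and the fused value is the convex combination

    fused = beta * mean(inner values) + (1 - beta) * mean(outliers),

with ``beta = 0.8`` for the eight angular-acceleration estimates and
``beta = 0.6`` for the four redundant gyroscope readings.  The fused value
is always bounded by the input minimum and maximum, and each output sample
depends only on the input sample at the same instant (no time
differentiation, filtering or phase delay anywhere in the chain).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import ClusterGeometry, enumerate_alpha_estimates
from .simulate import MeasurementSeries

__all__ = [
    "FusionConfig",
    "FusedSeries",
    "Calibration",
    "fuse_scalars",
    "fuse_omega",
    "static_calibration",
    "imc_process",
]


@dataclass(frozen=True)
class FusionConfig:
    beta_alpha: float = 0.8
    beta_omega: float = 0.6

    def __post_init__(self) -> None:
        for name in ("beta_alpha", "beta_omega"):
            b = getattr(self, name)
            if not 0 < b <= 1:
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass
class FusedSeries:
    """Fused angular state in EF, per estimator."""

    t: np.ndarray
    omega: np.ndarray  # (n, 3) rad/s
    alpha: np.ndarray  # (n, 3) rad/s^2
    estimator: str = "IMC"
    meta: dict = field(default_factory=dict)

    @property
    def rate(self) -> float:
        return 1.0 / float(self.t[1] - self.t[0])


@dataclass(frozen=True)
class Calibration:
    """Static offsets subtracted from fused outputs (not raw signals)."""

    omega_offset: np.ndarray  # (3,)
    alpha_offset: np.ndarray  # (3,)

    @classmethod
    def zero(cls) -> "Calibration":
        return cls(np.zeros(3), np.zeros(3))


def _fuse_sorted(values: np.ndarray, beta: float, axis: int = 0) -> np.ndarray:
    """Sorted weighted mean along ``axis`` (stable order; duplicated
    extremes count as the outliers)."""
    srt = np.sort(values, axis=axis)
    n = srt.shape[axis]
    inner = srt.take(range(1, n - 1), axis=axis).mean(axis=axis)
    outer = 0.5 * (srt.take(0, axis=axis) + srt.take(n - 1, axis=axis))
    return beta * inner + (1.0 - beta) * outer


def fuse_scalars(values, beta: float) -> float:
    """Weighted-outlier mean of redundant scalar estimates.

    Sorts ascending, treats the first and last values as outliers and
    combines the inner mean (weight ``beta``) with the outlier mean
    (weight ``1 - beta``).  Requires at least three values.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 3:
        raise ValueError("need at least three scalar values to fuse")
    return float(_fuse_sorted(values, beta))


def fuse_omega(omegas: np.ndarray, beta: float = 0.6) -> np.ndarray:
    """Per-coordinate fusion of the four redundant angular velocities.

    ``omegas`` has shape ``(4, ..., 3)`` with nominal alignment already
    removed; returns ``(..., 3)``.
    """
    omegas = np.asarray(omegas, dtype=float)
    if omegas.shape[0] != 4:
        raise ValueError("expected angular velocities of all four packages")
    return _fuse_sorted(omegas, beta, axis=0)


def static_calibration(
    geometry: ClusterGeometry,
    series: MeasurementSeries,
    cfg: FusionConfig | None = None,
    min_duration: float = 10.0,
) -> Calibration:
    """Offsets from a nominally static recording (about 30 s recommended).

    The static series is run through the full processing chain and the
    per-coordinate means of the fused angular velocity and acceleration
    become the offsets subtracted from all subsequent processed outputs.
    """
    duration = float(series.t[-1] - series.t[0])
    if duration < min_duration:
        warnings.warn(
            f"static calibration series covers only {duration:.1f} s "
            f"(< {min_duration:.0f} s); offsets will be noisy",
            stacklevel=2,
        )
    fused = imc_process(geometry, series, cfg or FusionConfig())
    return Calibration(fused.omega.mean(axis=0), fused.alpha.mean(axis=0))


def imc_process(
    geometry: ClusterGeometry,
    series: MeasurementSeries,
    cfg: FusionConfig | None = None,
    calibration: Calibration | None = None,
) -> FusedSeries:
    """Full differentiation-free processing of a cluster recording.

    Per sample: readings are taken to EF through the nominal alignment,
    the four gyroscope vectors are fused per coordinate, the eight
    root-configuration angular-acceleration estimates are formed with the
    fused angular velocity in their centripetal terms and fused per
    coordinate, and static calibration offsets are subtracted.
    """
    cfg = cfg or FusionConfig()
    # nominal package alignment coincides with EF by construction, so the
    # rotation to EF is the identity; misalignments are unknown mounting
    # errors the estimator cannot correct for
    omega = fuse_omega(series.gyro, cfg.beta_omega)
    alpha8 = enumerate_alpha_estimates(geometry, series.accel, omega)
    alpha = _fuse_sorted(alpha8, cfg.beta_alpha, axis=0)
    if calibration is not None:
        omega = omega - calibration.omega_offset
        alpha = alpha - calibration.alpha_offset
    return FusedSeries(series.t.copy(), omega, alpha, estimator="IMC")
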