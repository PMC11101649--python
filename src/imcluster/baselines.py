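"""Comparison estimators built from subsets of the cluster's raw data.

Replicates earlier direct and indirect angular-acceleration measurement
approaches by disabling redundant sensors of the same recording:

* ``NUMDIFF`` - a single IMU (gyroscope of package 0) with backward-
  difference numerical differentiation; the classical noise-amplifying
  route.
* ``NAP`` - the nine-accelerometer package: accelerometers only, using
  symmetric arm differences in which the centripetal products cancel;
  angular velocity is recoverable only up to a sign ambiguity.
* ``ARS`` - the angular-rate-sensor cube: one gyroscope (package 0) plus
  three accelerometers (packages 0-2); angular acceleration from the
  rigid-body relations with the measured angular velocity.

All baselines run unfiltered, and on noiseless ideal data agree with the
ground truth (and with the cluster estimator) to numerical precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fusion import Calibration, FusedSeries, FusionConfig, imc_process
from .geometry import ClusterGeometry
from .simulate import MeasurementSeries

__all__ = [
    "numdiff_alpha",
    "nap_alpha",
    "nap_omega",
    "ars_alpha",
    "NapOmegaResult",
    "process",
]


def numdiff_alpha(omega: np.ndarray, rate: float) -> np.ndarray:
    """Backward-difference angular acceleration of a gyroscope series.

    ``alpha[k] = (omega[k] - omega[k-1]) * f`` for ``k >= 1``; the first
    sample copies the second (edge convention).  No filtering is applied.
    """
    omega = np.asarray(omega, dtype=float)
    if omega.shape[0] < 2:
        raise ValueError("need at least two samples to differentiate")
    alpha = np.empty_like(omega)
    alpha[1:] = (omega[1:] - omega[:-1]) * rate
    alpha[0] = alpha[1]
    return alpha


_CYCLIC = ((1, 2), (2, 0), (0, 1))


def nap_alpha(accel: np.ndarray, geometry: ClusterGeometry) -> np.ndarray:
    """Accelerometer-only angular acceleration (nine axes, no gyroscopes).

    With the canonical axis-aligned arm layout the symmetric difference

        alpha_k = 1/2 * [ (a_i - a_0).e_j / r_i  -  (a_j - a_0).e_i / r_j ]

    over cyclic axis triples ``(i, j, k)`` cancels the centripetal
    products exactly, so no angular-velocity knowledge is needed.

    ``accel`` is ``(4, n, 3)`` in EF; returns ``(n, 3)``.
    """
    accel = np.asarray(accel, dtype=float)
    if accel.shape[0] != 4:
        raise ValueError("NAP needs accelerometers of all four packages")
    r = geometry.arm_lengths
    d = accel[1:] - accel[0]  # (3, n, 3): arm-package minus root differences
    alpha = np.empty(accel.shape[1:])
    for k in range(3):
        i, j = _CYCLIC[k]
        alpha[:, k] = 0.5 * (d[i][:, j] / r[i] - d[j][:, i] / r[j])
    return alpha


@dataclass
class NapOmegaResult:
    """Accelerometer-only angular velocity with its confidence mask.

    ``low_confidence[k, j]`` is True where component ``j`` at sample ``k``
    is indeterminate (near-zero magnitude or cross products).
    """

    omega: np.ndarray
    low_confidence: np.ndarray


def nap_omega(
    accel: np.ndarray,
    geometry: ClusterGeometry,
    initial_sign: int = 1,
    eps_mag: float = 1e-3,
    eps_prod: float = 1e-6,
) -> NapOmegaResult:
    """Angular velocity from accelerometers alone (sign-ambiguous).

    The diagonal arm relations give ``omega_i^2 - |omega|^2`` and the
    symmetric off-diagonal sums give the products ``omega_i * omega_j``;
    component magnitudes follow algebraically, while signs are resolved by
    temporal continuity (the candidate closest to the previous sample is
    kept; the very first sample takes ``initial_sign`` on its dominant
    component).  Near-zero magnitudes or products leave components
    indeterminate: they are returned as-is with a low-confidence mask
    rather than raising.
    """
    accel = np.asarray(accel, dtype=float)
    if accel.shape[0] != 4:
        raise ValueError("NAP needs accelerometers of all four packages")
    r = geometry.arm_lengths
    n = accel.shape[1]
    d = accel[1:] - accel[0]

    diag = np.stack([d[i][:, i] / r[i] for i in range(3)], axis=1)  # omega_i^2 - |w|^2
    norm_sq = np.clip(-diag.sum(axis=1) / 2.0, 0.0, None)
    mags = np.sqrt(np.clip(diag + norm_sq[:, None], 0.0, None))

    prod = np.empty((n, 3, 3))  # prod[:, i, j] = omega_i * omega_j estimate
    for i in range(3):
        prod[:, i, i] = mags[:, i] ** 2
        for j in range(i + 1, 3):
            p = 0.5 * (d[i][:, j] / r[i] + d[j][:, i] / r[j])
            prod[:, i, j] = p
            prod[:, j, i] = p

    omega = np.zeros((n, 3))
    low_conf = np.zeros((n, 3), dtype=bool)
    prev = None
    for k in range(n):
        m = mags[k]
        dom = int(np.argmax(m))
        v = np.zeros(3)
        v[dom] = m[dom]
        low_conf[k, dom] = m[dom] < eps_mag
        for c in range(3):
            if c == dom:
                continue
            p = prod[k, dom, c]
            sign = np.sign(p) if abs(p) >= eps_prod else 0.0
            if sign == 0.0:
                low_conf[k, c] = True
                sign = 1.0
            v[c] = sign * m[c]
            low_conf[k, c] |= m[c] < eps_mag
        if prev is None:
            if v[dom] * initial_sign < 0:
                v = -v
        elif float(v @ prev) < 0:
            v = -v
        omega[k] = v
        prev = v
    return NapOmegaResult(omega, low_conf)


def ars_alpha(
    gyro0: np.ndarray, accel: np.ndarray, geometry: ClusterGeometry
) -> np.ndarray:
    """Angular acceleration from one gyroscope and three accelerometers.

    Uses packages 0-2 (arms along e1 and e2).  The z coordinate has two
    redundant arm evaluations, averaged with equal weight; x and y each
    have a single available combination.  The measured angular velocity of
    package 0 supplies every centripetal term.

    ``gyro0`` is ``(n, 3)``; ``accel`` is ``(m, n, 3)`` with packages
    0, 1, 2 first (extra packages are ignored).
    """
    gyro0 = np.asarray(gyro0, dtype=float)
    accel = np.asarray(accel, dtype=float)
    if accel.shape[0] < 3:
        raise ValueError("ARS needs accelerometers of packages 0, 1 and 2")
    r1, r2, _ = geometry.arm_lengths
    d1 = accel[1] - accel[0]
    d2 = accel[2] - accel[0]
    wx, wy, wz = gyro0[:, 0], gyro0[:, 1], gyro0[:, 2]
    alpha = np.empty_like(gyro0)
    alpha[:, 0] = d2[:, 2] / r2 - wy * wz
    alpha[:, 1] = -(d1[:, 2] / r1 - wx * wz)
    z_a = d1[:, 1] / r1 - wx * wy
    z_b = -(d2[:, 0] / r2 - wx * wy)
    alpha[:, 2] = 0.5 * (z_a + z_b)
    return alpha


def process(
    geometry: ClusterGeometry,
    series: MeasurementSeries,
    method: str = "imc",
    cfg: FusionConfig | None = None,
    calibration: Calibration | None = None,
) -> FusedSeries:
    """Run one estimator over a recording and return its fused series.

    ``method`` is one of ``imc``, ``nap``, ``ars``, ``numdiff``.
    Calibration offsets, when given, are subtracted from the outputs of
    every method alike.
    """
    method = method.lower()
    if method == "imc":
        return imc_process(geometry, series, cfg, calibration)
    if method == "numdiff":
        omega = series.gyro[0].copy()
        alpha = numdiff_alpha(omega, series.rate)
        label = "NUMDIFF"
    elif method == "nap":
        res = nap_omega(series.accel, geometry)
        omega = res.omega
        alpha = nap_alpha(series.accel, geometry)
        label = "NAP"
    elif method == "ars":
        omega = series.gyro[0].copy()
        alpha = ars_alpha(series.gyro[0], series.accel[:3], geometry)
        label = "ARS"
    else:
        raise ValueError(f"unknown method {method!r}")
    if calibration is not None:
        omega = omega - calibration.omega_offset
        alpha = alpha - calibration.alpha_offset
    out = FusedSeries(series.t.copy(), omega, alpha, estimator=label)
    if method == "nap":
        out.meta["omega_low_confidence"] = res.low_confidence
        out.meta["omega_sign_resolution"] = "temporal-continuity"
    return out
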