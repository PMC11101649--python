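"""Rigid-body vector algebra for the inertial measurement cluster (IMC).

The IMC carries four gyro+accelerometer packages on a rigid base.  For a
rigid body, the linear acceleration of a fixed point ``i`` relates to the
acceleration of a reference point ``0`` through

    a_i = a_0 + alpha x r_i0 + omega x (omega x r_i0),

with ``omega`` the angular velocity and ``alpha`` the angular acceleration
of the body.  Given three linearly independent relative vectors
``g_1, g_2, g_3`` from a chosen root package to the other three packages,
the angular acceleration can be recovered *without any time
differentiation* from the measured point accelerations, by projecting onto
the dual (contravariant) basis ``g^1, g^2, g^3`` defined by
``g_i . g^j = delta_i^j``:

    alpha^k = (1/g) (a_i - a_root - omega x (omega x g_i)) . g_j,

with ``g = (g_1 x g_2) . g_3`` and ``(i, j, k)`` a cyclic index triple, and
``alpha = sum_k alpha^k g_k``.  Because the projection identity
``(alpha x g_i) . g_j = alpha . (g_i x g_j)`` holds for either ordering of
the pair, every coordinate can be evaluated two ways per root
configuration; with four possible roots this yields eight algebraically
independent estimates per sample, which downstream fusion combines.

All vectors are plain ``(..., 3)`` float arrays expressed in the cluster's
orthogonal evaluation frame (EF) unless stated otherwise.  EF is
right-handed; its y axis is the transverse (medio-lateral) axis used for
sagittal-plane trunk rotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DegenerateClusterError",
    "ClusterGeometry",
    "RootConfiguration",
    "dual_basis",
    "rigid_point_accel",
    "root_configuration",
    "alpha_from_configuration",
    "enumerate_alpha_estimates",
    "ESTIMATE_LABELS",
]

#: |scalar triple product| below this (m^3) means the packages are coplanar.
DEGENERACY_TOL = 1e-12

#: Orthonormality tolerance for rotation matrices.
ROTATION_TOL = 1e-10

#: Default arm lengths |r_10|, |r_20|, |r_30| of the physical prototype (m).
DEFAULT_ARM_LENGTHS = (0.1375, 0.175, 0.1)


class DegenerateClusterError(ValueError):
    """Raised when the sensor packages of a root configuration are coplanar."""


def _check_rotation(R: np.ndarray, what: str) -> None:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError(f"{what}: expected a 3x3 matrix, got shape {R.shape}")
    if not np.allclose(R.T @ R, np.eye(3), atol=ROTATION_TOL):
        raise ValueError(f"{what}: matrix is not orthonormal")
    if abs(np.linalg.det(R) - 1.0) > ROTATION_TOL:
        raise ValueError(f"{what}: determinant is not +1 (improper rotation)")


def elemental_rotation(axis: str, angle: float) -> np.ndarray:
    """Rotation matrix about a single EF axis ('x', 'y' or 'z') by ``angle`` rad."""
    c, s = np.cos(angle), np.sin(angle)
    if axis == "x":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)
    if axis == "y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)
    if axis == "z":
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)
    raise ValueError(f"unknown axis {axis!r} (expected 'x', 'y' or 'z')")


@dataclass(frozen=True)
class ClusterGeometry:
    """Nominal and as-built geometry of the four-package cluster.

    The nominal layout places package 0 at the EF origin and packages 1-3
    at the ends of arms collinear with the EF basis vectors:
    ``p1 = r1*e1, p2 = r2*e2, p3 = r3*e3``.  Mounting imperfections are
    carried separately: ``position_offsets[i]`` is the true-minus-nominal
    position of package ``i`` (m, EF) and ``misalignments[i]`` rotates
    package ``i``'s sensing frame relative to EF.  Estimators always use
    the nominal quantities; only the simulator sees the true ones.

    Parameters
    ----------
    arm_lengths
        Norms ``(|r_10|, |r_20|, |r_30|)`` in metres.
    position_offsets
        ``(4, 3)`` array of mounting position errors (m, EF).
    misalignments
        ``(4, 3, 3)`` array of package-frame-to-EF rotation errors.
    """

    arm_lengths: tuple[float, float, float] = DEFAULT_ARM_LENGTHS
    position_offsets: np.ndarray = field(
        default_factory=lambda: np.zeros((4, 3))
    )
    misalignments: np.ndarray = field(
        default_factory=lambda: np.broadcast_to(np.eye(3), (4, 3, 3)).copy()
    )

    def __post_init__(self) -> None:
        if len(self.arm_lengths) != 3 or any(r <= 0 for r in self.arm_lengths):
            raise ValueError("arm_lengths must be three positive norms (m)")
        offsets = np.asarray(self.position_offsets, dtype=float)
        if offsets.shape != (4, 3):
            raise ValueError("position_offsets must have shape (4, 3)")
        if not np.all(np.isfinite(offsets)):
            raise ValueError("position_offsets must be finite")
        mis = np.asarray(self.misalignments, dtype=float)
        if mis.shape != (4, 3, 3):
            raise ValueError("misalignments must have shape (4, 3, 3)")
        for i in range(4):
            _check_rotation(mis[i], f"misalignment of package {i}")
        object.__setattr__(self, "position_offsets", offsets)
        object.__setattr__(self, "misalignments", mis)
        # every root must see three linearly independent relative vectors
        for root in range(4):
            g = self.nominal_positions[[i for i in range(4) if i != root]]
            g = g - self.nominal_positions[root]
            if abs(np.linalg.det(g)) < DEGENERACY_TOL:
                raise DegenerateClusterError(
                    f"coplanar sensor packages for root {root}"
                )

    @property
    def nominal_positions(self) -> np.ndarray:
        """``(4, 3)`` nominal package positions in EF (m)."""
        r1, r2, r3 = self.arm_lengths
        return np.array(
            [[0.0, 0.0, 0.0], [r1, 0.0, 0.0], [0.0, r2, 0.0], [0.0, 0.0, r3]]
        )

    @property
    def true_positions(self) -> np.ndarray:
        """``(4, 3)`` as-built package positions (nominal + offsets)."""
        return self.nominal_positions + self.position_offsets

    def scaled(self, factor: float) -> "ClusterGeometry":
        """Geometry with all arm lengths (and offsets) scaled by ``factor``."""
        return ClusterGeometry(
            arm_lengths=tuple(r * factor for r in self.arm_lengths),
            position_offsets=self.position_offsets * factor,
            misalignments=self.misalignments.copy(),
        )


def dual_basis(
    g1: np.ndarray, g2: np.ndarray, g3: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Contravariant (dual) basis of three linearly independent vectors.

    Returns ``(g^1, g^2, g^3, g)`` with ``g^k = (g_i x g_j) / g`` for cyclic
    ``(i, j, k)`` and ``g = (g_1 x g_2) . g_3``, so that
    ``g_i . g^j = delta_i^j``.

    Raises
    ------
    DegenerateClusterError
        If ``|g|`` is below the coplanarity tolerance.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    g3 = np.asarray(g3, dtype=float)
    g = float(np.cross(g1, g2) @ g3)
    if abs(g) < DEGENERACY_TOL:
        raise DegenerateClusterError("coplanar sensor packages")
    return np.cross(g2, g3) / g, np.cross(g3, g1) / g, np.cross(g1, g2) / g, g


def rigid_point_accel(
    a0: np.ndarray, omega: np.ndarray, alpha: np.ndarray, r: np.ndarray
) -> np.ndarray:
    """Acceleration of the fixed body point at ``r`` from the reference point.

    Implements ``a = a_0 + alpha x r + omega x (omega x r)``; broadcasts
    over leading axes (e.g. time).
    """
    a0 = np.asarray(a0, dtype=float)
    omega = np.asarray(omega, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    r = np.asarray(r, dtype=float)
    return a0 + np.cross(alpha, r) + np.cross(omega, np.cross(omega, r))


@dataclass(frozen=True)
class RootConfiguration:
    """One of the four root choices with its basis and dual basis."""

    root: int
    others: tuple[int, int, int]
    basis: np.ndarray  # (3, 3): rows g_1, g_2, g_3 = r_{others[k], root}
    dual: np.ndarray  # (3, 3): rows g^1, g^2, g^3
    triple_product: float


def root_configuration(positions: np.ndarray, root: int) -> RootConfiguration:
    """Build the root configuration for package ``root`` from ``(4, 3)`` positions."""
    positions = np.asarray(positions, dtype=float)
    others = tuple(i for i in range(4) if i != root)
    basis = positions[list(others)] - positions[root]
    d1, d2, d3, g = dual_basis(*basis)
    try:
        return RootConfiguration(root, others, basis, np.array([d1, d2, d3]), g)
    except DegenerateClusterError as exc:  # pragma: no cover - re-raise w/ root
        raise DegenerateClusterError(f"{exc} (root {root})") from exc


_CYCLIC = ((1, 2), (2, 0), (0, 1))  # (i, j) pair for each k, zero-based


def alpha_from_configuration(
    config: RootConfiguration,
    a_root: np.ndarray,
    a_others: np.ndarray,
    omega: np.ndarray,
    ordering: str = "cyclic",
) -> np.ndarray:
    """Angular acceleration from one root configuration's accelerometers.

    Parameters
    ----------
    config
        Root configuration (basis and dual basis).
    a_root
        ``(..., 3)`` acceleration at the root package, EF.
    a_others
        ``(3, ..., 3)`` accelerations at the non-root packages, ordered
        like ``config.others``.
    omega
        ``(..., 3)`` angular velocity used for the centripetal terms
        (normally the fused value), EF.
    ordering
        ``"cyclic"`` or ``"anticyclic"``; the two orderings project the
        rigid-body relation onto the relative vectors in opposite pair
        order and therefore consume different raw-data combinations.

    Returns
    -------
    ``(..., 3)`` angular acceleration re-expressed in EF Cartesian
    coordinates.
    """
    if ordering not in ("cyclic", "anticyclic"):
        raise ValueError(f"unknown ordering {ordering!r}")
    a_root = np.asarray(a_root, dtype=float)
    a_others = np.asarray(a_others, dtype=float)
    omega = np.asarray(omega, dtype=float)
    basis, g = config.basis, config.triple_product
    comps = []
    for k in range(3):
        i, j = _CYCLIC[k]
        if ordering == "cyclic":
            rhs = a_others[i] - a_root - np.cross(omega, np.cross(omega, basis[i]))
            comps.append((rhs @ basis[j]) / g)
        else:
            rhs = a_others[j] - a_root - np.cross(omega, np.cross(omega, basis[j]))
            comps.append(-(rhs @ basis[i]) / g)
    # alpha = sum_k alpha^k g_k
    comps = np.stack(comps, axis=-1)  # (..., 3) contravariant components
    return comps @ basis


#: Labels of the eight estimates produced by :func:`enumerate_alpha_estimates`.
ESTIMATE_LABELS = tuple(
    (root, ordering) for root in range(4) for ordering in ("cyclic", "anticyclic")
)


def enumerate_alpha_estimates(
    geometry: ClusterGeometry, accel: np.ndarray, omega_fused: np.ndarray
) -> np.ndarray:
    """All eight angular-acceleration estimates from one sample (or series).

    Four root choices times two pair orderings.  The estimator only ever
    sees the *nominal* geometry; mounting errors are unknown to it.

    Parameters
    ----------
    geometry
        Cluster geometry (nominal positions are used).
    accel
        ``(4, ..., 3)`` accelerometer readings expressed in EF.
    omega_fused
        ``(..., 3)`` fused angular velocity.

    Returns
    -------
    ``(8, ..., 3)`` array of estimates ordered like :data:`ESTIMATE_LABELS`.
    """
    accel = np.asarray(accel, dtype=float)
    if accel.shape[0] != 4:
        raise ValueError("accel must stack readings of all four packages")
    positions = geometry.nominal_positions
    estimates = []
    for root, ordering in ESTIMATE_LABELS:
        cfg = root_configuration(positions, root)
        a_others = accel[list(cfg.others)]
        estimates.append(
            alpha_from_configuration(cfg, accel[root], a_others, omega_fused, ordering)
        )
    return np.stack(estimates, axis=0)
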