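"""Balance-recovery performance metrics over an observation window.

The trunk's kinematics are weighted by the subject's trunk moment of
inertia about the transverse principal axis, Theta_yy^(q), giving two
accumulated quantities over the observation window [t_on, t_off]:

    aTAM   = integral Theta_yy |omega_y| dt   (kg m^2 rad/s)
    aRCTAM = integral Theta_yy |alpha_y| dt   (kg m^2 rad/s^2)

the accumulated relative trunk angular momentum and its rate of change.
Negative curve lobes contribute positively (they indicate recovery effort
just as positive ones do), hence the absolute values.  The window length
itself is the time of recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .detection import ObservationWindow

__all__ = [
    "TrunkAnthropometry",
    "RecoveryMetrics",
    "PhaseSummary",
    "trunk_inertia",
    "recovery_metrics",
    "pool_phases",
    "TRUNK_MASS_FRACTION",
]

#: Default trunk mass as a fraction of total body mass (the trunk carries
#: roughly half the body's mass).
TRUNK_MASS_FRACTION = 0.497


@dataclass(frozen=True)
class TrunkAnthropometry:
    """Trunk dimensions (m) and mass (kg).

    Width: acromion-to-acromion (frontal plane); length: averaged C7 to
    left/right spina iliaca posterior; depth: averaged anterior-posterior
    spina iliaca distance.
    """

    width: float
    length: float
    depth: float
    mass: float

    def __post_init__(self) -> None:
        for name in ("width", "length", "depth", "mass"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_body_mass(
        cls, width: float, length: float, depth: float, body_mass: float,
        fraction: float = TRUNK_MASS_FRACTION,
    ) -> "TrunkAnthropometry":
        return cls(width, length, depth, body_mass * fraction)


def trunk_inertia(anthro: TrunkAnthropometry) -> float:
    """Trunk moment of inertia about the transverse axis through the pelvis.

    The trunk is modelled as a homogeneous solid elliptical slab (cylinder
    with elliptical cross-section, semi-axes ``a = depth/2`` sagittal and
    ``b = width/2`` medio-lateral, height ``L = length``), referenced to
    the point q at the midpoint of the slab's base via the parallel-axis
    shift L/2:

        Theta_yy^(q) = m * (a^2/4 + L^2/3)   [kg m^2]
    """
    a = anthro.depth / 2.0
    L = anthro.length
    return anthro.mass * (a * a / 4.0 + L * L / 3.0)


@dataclass(frozen=True)
class RecoveryMetrics:
    time_of_recovery: float  # s
    atam: float  # kg m^2 rad/s
    arctam: float  # kg m^2 rad/s^2
    window: ObservationWindow

    def __post_init__(self) -> None:
        if self.time_of_recovery < 0 or self.atam < 0 or self.arctam < 0:
            raise ValueError("recovery metrics must be non-negative")


def _abs_trapezoid(t: np.ndarray, x: np.ndarray, t0: float, t1: float) -> float:
    """Trapezoid integral of the piecewise-linear interpolant of |x| over
    [t0, t1], with linearly interpolated endpoint values (exactly additive
    under any partition of the interval)."""
    xs = np.abs(np.asarray(x, dtype=float))
    inner = (t > t0) & (t < t1)
    ts = np.concatenate([[t0], t[inner], [t1]])
    vs = np.concatenate([[np.interp(t0, t, xs)], xs[inner], [np.interp(t1, t, xs)]])
    return float(np.trapezoid(vs, ts))


def recovery_metrics(
    window: ObservationWindow,
    t: np.ndarray,
    omega_y: np.ndarray,
    alpha_y: np.ndarray,
    inertia: float,
) -> RecoveryMetrics:
    """Time of recovery, aTAM and aRCTAM over one observation window."""
    t = np.asarray(t, dtype=float)
    if window.t_on < t[0] or window.t_off > t[-1]:
        raise ValueError("observation window lies outside the series")
    if inertia <= 0:
        raise ValueError("inertia must be positive")
    atam = inertia * _abs_trapezoid(t, omega_y, window.t_on, window.t_off)
    arctam = inertia * _abs_trapezoid(t, alpha_y, window.t_on, window.t_off)
    return RecoveryMetrics(window.duration, atam, arctam, window)


@dataclass(frozen=True)
class PhaseSummary:
    """Early / mid / late adaptation-phase means (NaN where no trial)."""

    early: float
    mid: float
    late: float
    missing: tuple[str, ...] = ()


_PHASES = {"early": (1, 2), "mid": (4, 5), "late": (7, 8)}


def pool_phases(trial_values: dict[int, float]) -> PhaseSummary:
    """Pool per-trial metrics of a perturbation series into adaptation phases.

    Trials 1-2 form the early phase, 4-5 mid, 7-8 late (trials 3 and 6
    are washout-adjacent and ignored).  Missing trials are allowed; a
    phase with no valid trial is flagged and reported as NaN.
    """
    out = {}
    missing = []
    for phase, trials in _PHASES.items():
        vals = [trial_values[i] for i in trials if i in trial_values
                and trial_values[i] is not None and not math.isnan(trial_values[i])]
        if vals:
            out[phase] = float(np.mean(vals))
        else:
            out[phase] = float("nan")
            missing.append(phase)
    return PhaseSummary(out["early"], out["mid"], out["late"], tuple(missing))
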