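"""Quantitative signal comparison: RMSE, mean relative deviation, extrema deviation."""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .detection import local_extrema

__all__ = ["rmse", "mean_rel_dev", "extrema_deviation", "RelativeDeviation", "ExtremaDeviation"]


def rmse(proc: np.ndarray, ref: np.ndarray) -> float:
    """Root-mean-square error ``sqrt(sum((proc - ref)^2) / n)``."""
    proc = np.asarray(proc, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if proc.shape != ref.shape:
        raise ValueError("signals must share one time grid")
    if proc.size == 0:
        raise ValueError("need at least one sample")
    return float(np.sqrt(np.mean((proc - ref) ** 2)))


class RelativeDeviation(NamedTuple):
    value: float  # mean |proc - ref| / |ref| over retained samples (fraction)
    n_used: int
    n_masked: int  # samples excluded because |ref| < mask_eps


def mean_rel_dev(
    proc: np.ndarray, ref: np.ndarray, mask_eps: float = 1e-6
) -> RelativeDeviation:
    """Mean relative deviation of ``proc`` with respect to ``ref``.

    Samples where ``|ref| < mask_eps`` are excluded (the ratio is
    undefined at reference zero crossings) and their count is reported.
    The value is a fraction; multiply by 100 to report percent.
    """
    proc = np.asarray(proc, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if proc.shape != ref.shape:
        raise ValueError("signals must share one time grid")
    keep = np.abs(ref) >= mask_eps
    if not np.any(keep):
        raise ValueError("all samples masked: reference is (near) zero throughout")
    value = float(np.mean(np.abs(proc[keep] - ref[keep]) / np.abs(ref[keep])))
    return RelativeDeviation(value, int(keep.sum()), int((~keep).sum()))


class ExtremaDeviation(NamedTuple):
    value: float  # mean relative deviation over matched extremum pairs
    n_pairs: int
    n_unpaired: int


def extrema_deviation(
    t: np.ndarray, proc: np.ndarray, ref: np.ndarray, magnitude_floor: float
) -> ExtremaDeviation:
    """Relative deviation of matched large local extrema.

    Local extrema of the reference with ``|value| > magnitude_floor`` are
    each paired with the nearest-in-time extremum of the processed signal
    of the same sign, within half the median inter-extremum interval; the
    mean of ``|v_proc - v_ref| / |v_ref|`` over the pairs is returned, and
    unpaired reference extrema are counted.
    """
    ref_ext = [e for e in local_extrema(t, ref) if abs(e.value) > magnitude_floor]
    if not ref_ext:
        raise ValueError("no reference extrema exceed the magnitude floor")
    proc_ext = local_extrema(t, proc)
    ref_times = np.array([e.time for e in ref_ext])
    if len(ref_times) > 1:
        window = 0.5 * float(np.median(np.diff(ref_times)))
    else:
        window = float(t[-1] - t[0])
    devs = []
    unpaired = 0
    for e in ref_ext:
        cands = [p for p in proc_ext if p.kind == e.kind and abs(p.time - e.time) <= window]
        if not cands:
            unpaired += 1
            continue
        best = min(cands, key=lambda p: abs(p.time - e.time))
        devs.append(abs(best.value - e.value) / abs(e.value))
    if not devs:
        raise ValueError("no extrema could be paired within the matching window")
    return ExtremaDeviation(float(np.mean(devs)), len(devs), unpaired)
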