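"""Spreading-region volumes and clearance half-life.

The "lightened" (enhanced) region at each time point is the set of voxels
whose signal increment exceeds a noise-scaled threshold; its volume is the
voxel count times the voxel volume (0.125 mm^3 at the protocol's 0.5 mm
isotropic voxels).  The clearance half-life t_1/2 is estimated from the
decline of the total in-brain tracer amount A(t) after its peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import ConcentrationSeries, IncrementSeries

__all__ = [
    "SpreadCurve",
    "HalfLifeResult",
    "spread_volume_timecourse",
    "estimate_half_life",
    "amount_curve",
]


@dataclass
class SpreadCurve:
    """Enhanced-region volume (mm^3) at each acquisition time (h)."""

    times: np.ndarray
    volumes: np.ndarray
    v_max: float
    t_max: float
    threshold_used: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)


@dataclass
class HalfLifeResult:
    """Half-life of the post-peak tracer amount decline.

    For the log-linear method ``t_half = ln 2 / decay_rate`` with the decay
    rate from a least-squares line through log(amount) vs time over the
    post-peak window.  The interpolation method instead returns the time at
    which the amount first falls to half its peak.
    """

    t_half: float  # minutes
    method: str
    fit_window: tuple[int, int]  # [start, stop) indices into the curve
    decay_rate: float  # 1/minute

    def __post_init__(self) -> None:
        if self.t_half <= 0:
            raise ValueError("t_half must be > 0")


def spread_volume_timecourse(
    inc: IncrementSeries,
    k_sigma: float = 3.0,
    abs_threshold: float | None = None,
) -> SpreadCurve:
    """Volume of the enhanced ("lightened") region at each time point.

    A voxel is enhanced when its increment exceeds ``k_sigma`` times the
    series' background noise estimate (or ``abs_threshold``, if given).
    Times are sorted internally, so the maximum is invariant to frame order.
    """
    if abs_threshold is not None:
        thr = float(abs_threshold)
    else:
        if inc.noise_sigma_est <= 0:
            raise ValueError(
                "noise_sigma_est is not positive; supply abs_threshold instead"
            )
        thr = k_sigma * inc.noise_sigma_est
    order = np.argsort(inc.times)
    times = inc.times[order]
    counts = (inc.values[order] > thr).reshape(times.size, -1).sum(axis=1)
    volumes = counts * inc.grid.voxel_volume
    if not np.any(counts > 0):
        warnings.warn("no enhanced voxel at any time point", stacklevel=2)
        v_max, t_max = 0.0, float(times[0])
    else:
        i = int(np.argmax(volumes))
        v_max, t_max = float(volumes[i]), float(times[i])
    return SpreadCurve(
        times=times, volumes=volumes, v_max=v_max, t_max=t_max, threshold_used=thr
    )


def amount_curve(conc: ConcentrationSeries, alpha: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Times (h) and total in-brain tracer amounts (nmol) of a series."""
    return conc.times / 3600.0, conc.total_amounts(alpha=alpha)


def estimate_half_life(
    times_h,
    amounts,
    method: str = "log-linear",
) -> HalfLifeResult:
    """Half-life of a declining amount curve.

    Parameters
    ----------
    times_h
        Sample times in hours (the acquisition schedule).
    amounts
        Total tracer amounts at those times (any consistent unit; the
        estimate is scale-invariant).
    method
        ``"log-linear"`` (default): least-squares line through log(amount)
        over all points from the global maximum onward; ``t_half =
        ln 2 / slope`` (in minutes).  ``"interpolation"``: the elapsed time
        from the peak until the amount first falls to half the peak,
        log-linearly interpolated between samples.

    Both methods agree exactly on a perfect exponential.
    """
    t = np.asarray(times_h, dtype=float) * 60.0  # minutes
    a = np.asarray(amounts, dtype=float)
    if t.shape != a.shape or t.ndim != 1:
        raise ValueError("times and amounts must be matching 1D arrays")
    order = np.argsort(t)
    t, a = t[order], a[order]
    i_peak = int(np.argmax(a))
    post_t, post_a = t[i_peak:], a[i_peak:]
    min_pts = 3 if method == "log-linear" else 2
    if post_t.size < min_pts:
        raise ValueError(f"need >= {min_pts} time points from the peak onward")
    if np.any(post_a <= 0):
        raise ValueError("post-peak amounts must be positive")

    if method == "log-linear":
        slope, _ = np.polyfit(post_t, np.log(post_a), 1)
        if slope >= 0:
            raise ValueError("no measurable clearance: post-peak amounts do not decline")
        rate = -float(slope)
        t_half = float(np.log(2.0) / rate)
    elif method == "interpolation":
        target = post_a[0] / 2.0
        below = np.nonzero(post_a <= target)[0]
        if below.size == 0:
            raise ValueError(
                "no measurable clearance: amount never falls to half its peak"
            )
        j = int(below[0])
        if j == 0:
            t_cross = post_t[0]
        else:
            la0, la1 = np.log(post_a[j - 1]), np.log(post_a[j])
            frac = (np.log(target) - la0) / (la1 - la0)
            t_cross = post_t[j - 1] + frac * (post_t[j] - post_t[j - 1])
        t_half = float(t_cross - post_t[0])
        if t_half <= 0:
            raise ValueError("degenerate curve: peak already at or below half amplitude")
        rate = float(np.log(2.0) / t_half)
    else:
        raise ValueError(f"unknown method {method!r}")
    return HalfLifeResult(
        t_half=t_half,
        method=method,
        fit_window=(i_peak, int(t.size)),
        decay_rate=rate,
    )
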