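"""Preprocessing: rigid registration, baseline subtraction, concentration.

The quantification chain mirrors the acquisition workflow: each dynamic
frame is registered to the pre-injection baseline, the baseline is
subtracted to form signal increments, and increments are inverted through
the signal law to tracer concentration.

Registration is an exhaustive integer-voxel translation search maximising
normalised cross-correlation (NCC) against the baseline — at 0.5 mm voxels
with a head-fixed subject there is no rotation to speak of, and integer
shifts keep the operation exactly testable.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from .core import ConcentrationSeries, ImageSeries, IncrementSeries
from .model import DEFAULT_ALPHA
from .signal import AcquisitionParams, make_signal_law

__all__ = [
    "RegistrationResult",
    "register_series",
    "subtract_baseline",
    "signal_to_concentration",
]

# frames whose relative intensity spread is below this are treated as
# featureless (degenerate for NCC)
_DEGENERATE_REL_STD = 1e-12


@dataclass
class RegistrationResult:
    series: ImageSeries
    shifts: list[tuple[int, int, int]]


def _shift_int(vol: np.ndarray, shift: tuple[int, int, int]) -> np.ndarray:
    """Translate a volume by integer voxels, zero-filling exposed edges."""
    out = np.zeros_like(vol)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, s in enumerate(shift):
        n = vol.shape[ax]
        if abs(s) >= n:
            return out
        if s >= 0:
            dst[ax] = slice(s, n)
            src[ax] = slice(0, n - s)
        else:
            dst[ax] = slice(0, n + s)
            src[ax] = slice(-s, n)
    out[tuple(dst)] = vol[tuple(src)]
    return out


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(a @ b / denom)


def _overlap_slices(shape, shift):
    """Slices of frame (src) and baseline (dst) that overlap after applying
    the candidate correction ``shift`` to the frame."""
    src, dst = [], []
    for ax, s in enumerate(shift):
        n = shape[ax]
        if abs(s) >= n:
            return None
        if s >= 0:
            dst.append(slice(s, n))
            src.append(slice(0, n - s))
        else:
            dst.append(slice(0, n + s))
            src.append(slice(-s, n))
    return tuple(src), tuple(dst)


def _ncc_shifted(frame: np.ndarray, base: np.ndarray, shift) -> float:
    """NCC between frame (moved by ``shift``) and baseline over their valid
    overlap only — zero-filled edges would otherwise dominate the score."""
    sl = _overlap_slices(frame.shape, shift)
    if sl is None:
        return -np.inf
    src, dst = sl
    return _ncc(frame[src], base[dst])


def register_series(series: ImageSeries, max_shift: int = 2) -> RegistrationResult:
    """Rigid integer-voxel registration of every frame to the baseline.

    Searches all translations within ±``max_shift`` voxels per axis and
    keeps the one with the highest NCC against the baseline.  Featureless
    (constant) baselines or frames get a zero shift and a warning.
    ``max_shift=0`` is the identity.
    """
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    shifts: list[tuple[int, int, int]] = []
    if max_shift == 0:
        return RegistrationResult(series=series, shifts=[(0, 0, 0)] * series.n_times)

    base = series.baseline
    base_degenerate = base.std() <= _DEGENERATE_REL_STD * max(abs(base.mean()), 1.0)
    new_frames = np.empty_like(series.frames)
    offsets = range(-max_shift, max_shift + 1)
    for i in range(series.n_times):
        frame = series.frames[i]
        degenerate = base_degenerate or frame.std() <= _DEGENERATE_REL_STD * max(
            abs(frame.mean()), 1.0
        )
        if degenerate:
            warnings.warn(
                f"frame {i}: constant baseline or frame, registration skipped (zero shift)",
                stacklevel=2,
            )
            best = (0, 0, 0)
        else:
            best, best_score = (0, 0, 0), -np.inf
            for cand in itertools.product(offsets, offsets, offsets):
                score = _ncc_shifted(frame, base, cand)
                if score > best_score:
                    best, best_score = cand, score
        shifts.append(best)
        new_frames[i] = _shift_int(frame, best)
    out = ImageSeries(
        grid=series.grid,
        baseline=series.baseline.copy(),
        frames=new_frames,
        times=series.times.copy(),
        subject_id=series.subject_id,
        group=series.group,
        meta={**series.meta, "registration_shifts": shifts},
    )
    return RegistrationResult(series=out, shifts=shifts)


def _corner_blocks(shape: tuple[int, int, int], block: int = 5):
    """Index triples of the eight corner blocks of a volume."""
    b = [min(block, n) for n in shape]
    for cx in (slice(0, b[0]), slice(shape[0] - b[0], shape[0])):
        for cy in (slice(0, b[1]), slice(shape[1] - b[1], shape[1])):
            for cz in (slice(0, b[2]), slice(shape[2] - b[2], shape[2])):
                yield cx, cy, cz


def subtract_baseline(series: ImageSeries, noise_block: int = 5) -> IncrementSeries:
    """Frame-minus-baseline increments plus a background noise estimate.

    The noise scale of the increments is the standard deviation of increment
    values pooled over the eight ``noise_block``-cubed corner blocks of the
    volume — tracer-free by construction in this study geometry.  Negative
    increments are preserved.
    """
    values = series.frames - series.baseline[None]
    corners = np.concatenate(
        [values[(slice(None),) + idx].ravel() for idx in _corner_blocks(series.grid.shape, noise_block)]
    )
    noise_sigma_est = float(corners.std())
    return IncrementSeries(
        grid=series.grid,
        times=series.times.copy(),
        values=values,
        noise_sigma_est=noise_sigma_est,
        meta={**series.meta, "noise_block": noise_block},
    )


def signal_to_concentration(
    inc: IncrementSeries,
    acq: AcquisitionParams,
    alpha: float = DEFAULT_ALPHA,
    law: str = "saturation",
    saturation_fraction: float = 0.90,
) -> ConcentrationSeries:
    """Invert signal increments to ISF concentration (mM).

    Negative increments map to zero concentration.  Increments at or above
    ``saturation_fraction`` of the signal law's supremum sit where the
    inverse map amplifies noise without bound; they are clipped to the
    concentration at that fraction and flagged (``meta["clipped"]`` mask and
    ``meta["clip_fraction"]``) so the fit can exclude them.

    ``meta["conc_noise_floor"]`` carries the increment noise estimate
    expressed in concentration units via the signal law's slope at C = 0 —
    the natural SNR scale for masking downstream.
    """
    if not (0 < saturation_fraction < 1):
        raise ValueError("saturation_fraction must be in (0, 1)")
    sl = make_signal_law(acq, alpha, law)
    sup = sl.increment_sup()
    clip_at = saturation_fraction * sup
    v = np.clip(inc.values, 0.0, None)
    clipped = v >= clip_at
    v = np.minimum(v, clip_at)
    conc = sl.inverse_increment(v)
    conc = np.clip(conc, 0.0, None)
    # Signed companion field for estimation: the same smooth inverse
    # continued through zero (negative increments give negative nominal
    # concentrations).  Zero-clipping would put a positive noise floor under
    # every tracer-free voxel; and because the inverse is convex, applying
    # it to noisy increments adds ~sigma^2/2 * (f^-1)'' per voxel, which
    # integrates to a large phantom tracer amount over a volume — so the
    # delta-method bias is subtracted.  The public concentration field
    # stays non-negative per its physical definition.
    signed = sl.inverse_increment_extended(np.minimum(inc.values, clip_at))
    if inc.noise_sigma_est > 0:
        bias = sl.inverse_noise_bias(np.where(clipped, 0.0, signed), inc.noise_sigma_est)
        signed = np.where(clipped, signed, signed - bias)
    meta = {
        "signed_values": signed,
        "clip_value_conc": float(sl.inverse_increment(clip_at)),
        # raw increments + the law let the fit evaluate its residual in
        # signal space, where the noise actually is additive and symmetric
        "increment_values": inc.values,
        "signal_law_obj": sl,
        **inc.meta,
        "clipped": clipped,
        "clip_fraction": float(clipped.mean()),
        "neg_fraction": float((inc.values < 0).mean()),
        "conc_noise_floor": inc.noise_sigma_est / sl.slope_at_zero(),
        "signal_law": law,
        "alpha": alpha,
    }
    return ConcentrationSeries(
        grid=inc.grid, times=inc.times * 3600.0, values=conc, meta=meta
    )
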