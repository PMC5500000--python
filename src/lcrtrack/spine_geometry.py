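"""Cell spine extraction and curvature mapping.

A spontaneously beating pacemaker cell lying roughly parallel to the x
axis is reduced, per frame, to its "spine": an intensity-weighted
centre-of-mass y-coordinate for every image column.  The weights are
the background-subtracted intensities raised to the power 1.5, which
sharpens the centre of mass toward the bright cytoplasm.  Local
curvature of the spine is conserved under contraction, so the per-frame
curvature profile k(t, x) serves as the substrate for tracking the
contractile motion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .stack_io import ImageStack

__all__ = [
    "BackgroundStats",
    "CurvatureMap",
    "estimate_background",
    "threshold_frame",
    "compute_spine",
    "compute_spines",
    "curvature_map",
    "export_curvature_csv",
]


@dataclass(frozen=True)
class BackgroundStats:
    """Mean ``b`` and population SD ``sigma`` of the background fluorescence."""

    b: float
    sigma: float

    def __post_init__(self) -> None:
        if self.b < 0 or self.sigma < 0:
            raise ValueError("background statistics must be non-negative")


@dataclass
class CurvatureMap:
    """Per-frame, per-column local curvature of the spine.

    ``k`` has shape ``(T, W)`` with NaN where the spine is undefined or
    inside the Savitzky-Golay edge margin.  ``interpolated`` flags
    columns whose spine value was filled by linear interpolation before
    differentiation.
    """

    k: np.ndarray
    sg_window: int
    sg_order: int
    interpolated: np.ndarray


def estimate_background(stack: ImageStack, bg_region: tuple[int, int, int, int]) -> BackgroundStats:
    """Estimate background mean and SD over a user-chosen off-cell rectangle.

    Parameters
    ----------
    bg_region
        ``(x, y, w, h)`` rectangle, required to lie fully inside the
        frame; statistics are pooled over all frames.  The SD is the
        population SD, making small-fixture tests exact.
    """
    x, y, w, h = bg_region
    _, H, W = stack.shape
    if w <= 0 or h <= 0:
        raise ValueError("background region must have positive area")
    if x < 0 or y < 0 or x + w > W or y + h > H:
        raise ValueError("background region lies outside frame bounds")
    values = stack.frames[:, y : y + h, x : x + w]
    return BackgroundStats(b=float(values.mean()), sigma=float(values.std()))


def threshold_frame(frame: np.ndarray, stats: BackgroundStats) -> np.ndarray:
    """Background-subtract a frame, keeping only pixels above b + 3 sigma.

    Returns ``a`` with ``a = i - b`` where ``i > b + 3*sigma`` (strict)
    and 0 elsewhere, so ``a >= 0`` everywhere.
    """
    frame = np.asarray(frame, dtype=np.float64)
    cut = stats.b + 3.0 * stats.sigma
    return np.where(frame > cut, frame - stats.b, 0.0)


def compute_spine(a_frame: np.ndarray) -> np.ndarray:
    """Centre-of-mass spine of one thresholded frame.

    For each column x with any above-threshold signal,
    ``zeta(x) = sum_y y * a^1.5 / sum_y a^1.5``; columns with no signal
    are NaN (undefined).
    """
    a = np.asarray(a_frame, dtype=np.float64)
    H, W = a.shape
    w = a**1.5
    denom = w.sum(axis=0)
    y = np.arange(H, dtype=np.float64)
    num = (y[:, None] * w).sum(axis=0)
    zeta = np.full(W, np.nan)
    ok = denom > 0
    zeta[ok] = num[ok] / denom[ok]
    return zeta


def compute_spines(stack: ImageStack, stats: BackgroundStats) -> np.ndarray:
    """Spine of every frame; shape ``(T, W)`` with NaN where undefined."""
    return np.stack([compute_spine(threshold_frame(f, stats)) for f in stack.frames])


def _fill_interior_nans(zeta: np.ndarray) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Linearly interpolate NaN columns strictly inside the defined span.

    Returns the filled row, a flag array for interpolated columns, and
    the first/last defined column indices.
    """
    defined = np.flatnonzero(np.isfinite(zeta))
    if defined.size == 0:
        raise ValueError("spine undefined for an entire frame")
    lo, hi = int(defined[0]), int(defined[-1])
    filled = zeta.copy()
    flags = np.zeros_like(zeta, dtype=bool)
    span = np.arange(lo, hi + 1)
    nan_inside = span[~np.isfinite(zeta[lo : hi + 1])]
    if nan_inside.size:
        filled[nan_inside] = np.interp(nan_inside, defined, zeta[defined])
        flags[nan_inside] = True
    return filled, flags, lo, hi


def export_curvature_csv(cmap: CurvatureMap, path) -> None:
    """Write the curvature map as a CSV matrix (one row per column x,
    one column per frame t) for visual inspection."""
    np.savetxt(path, cmap.k.T, delimiter=",", fmt="%.6g")


def curvature_map(spines: np.ndarray, sg_window: int = 11, sg_order: int = 3) -> CurvatureMap:
    """Local curvature k(t, x) of the spine via Savitzky-Golay derivatives.

    Per frame, first and second x-derivatives of the (gap-filled) spine
    are estimated with Savitzky-Golay filters over the contiguous
    defined column span, and

        k = zeta_xx / (1 + zeta_x**2)**1.5 .

    Output is interior-only: the half-window at each end of the span is
    NaN rather than extrapolated, which avoids edge artifacts in k.
    """
    if sg_window % 2 != 1 or sg_window < 3:
        raise ValueError("sg_window must be an odd integer >= 3")
    if sg_order >= sg_window:
        raise ValueError("sg_order must be < sg_window")
    spines = np.asarray(spines, dtype=np.float64)
    T, W = spines.shape
    k = np.full((T, W), np.nan)
    interp_flags = np.zeros((T, W), dtype=bool)
    half = sg_window // 2
    for t in range(T):
        filled, flags, lo, hi = _fill_interior_nans(spines[t])
        n = hi - lo + 1
        if n < sg_window:
            raise ValueError(
                f"frame {t}: contiguous defined spine span ({n} columns) shorter than sg_window ({sg_window})"
            )
        seg = filled[lo : hi + 1]
        d1 = savgol_filter(seg, sg_window, sg_order, deriv=1, delta=1.0)
        d2 = savgol_filter(seg, sg_window, sg_order, deriv=2, delta=1.0)
        kk = d2 / (1.0 + d1**2) ** 1.5
        kk[:half] = np.nan
        kk[n - half :] = np.nan
        k[t, lo : hi + 1] = kk
        interp_flags[t] = flags
    return CurvatureMap(k=k, sg_window=sg_window, sg_order=sg_order, interpolated=interp_flags)
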