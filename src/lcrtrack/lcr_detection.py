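"""Per-pixel signal conditioning and per-frame LCR candidate extraction.

The conditioning chain on a stabilized stack is:

1. **Max filter** — per-pixel temporal maximum; the mean of all maxima
   is the cut separating the bright cytoplasm from the dark background,
   and the largest connected component above the cut is the cell mask.
2. **Normalization** — linear rescale of the masked signal to the 0-255
   gray scale: ``F_norm = 255 * (F - F_min) / (F_max - F_min)``.
3. **Transient removal** — subtract the whole-cell average trace
   ``F_a(t)`` from every pixel and clip negatives to zero, isolating
   local releases from the global action-potential-induced transient.
4. **Optional despeckle** — 3x3 median and/or mean filters.
5. **Differential filter** — spatial box average of half-width
   ``search_distance`` followed by the frame-to-frame difference D;
   locations with constant fluorescence (heterogeneous dye loading,
   nuclei) are thereby suppressed.  The SD of D over all cell pixels
   and frames, ``sigma_cell``, is the noise scale for both the
   detection and termination thresholds.

Candidate pixels are those with ``D > sd_detection * sigma_cell`` in
non-suspended frames, plus a single-pass fill of pixels having at least
7 of their 8 neighbors candidate (pixel anomalies inside an event).
Candidates are grouped into 4-connected clusters; a cluster can found a
new event only if it is both large enough (``size_threshold`` pixels)
and bright enough (summed transient-free intensity at least
``intensity_threshold``) — smaller/dimmer clusters may still extend an
existing event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import correlate, median_filter, uniform_filter
from skimage.measure import label as cc_label

from .stack_io import ImageStack, RunConfig

__all__ = [
    "averaging_window",
    "CellMask",
    "ConditionedStack",
    "Cluster",
    "ClusterSet",
    "max_filter_mask",
    "normalize",
    "remove_transient",
    "despeckle",
    "differential_filter",
    "candidacy",
    "find_clusters",
    "condition_stack",
]


@dataclass
class CellMask:
    """Boolean cell-cytoplasm mask with its pixel count."""

    mask: np.ndarray
    area_px: int


@dataclass
class ConditionedStack:
    """All intermediate signals of the conditioning chain.

    Two noise scales are kept, one per signal: ``sigma_cell`` is the SD
    of the differential image D over all cell pixels and frames (the
    scale of the *detection* threshold, which tests D), and
    ``sigma_fnt`` is the SD of the transient-free intensity F_nt over
    the same domain (the scale of the *termination* threshold, which
    tests the event's average intensity).  Each threshold is "a factor
    of the standard deviation of the signal in the cell" measured on
    the signal it actually examines.
    """

    mask: CellMask
    F_norm: np.ndarray
    F_nt: np.ndarray
    F_a: np.ndarray
    D: np.ndarray
    sigma_cell: float
    sigma_fnt: float


@dataclass
class Cluster:
    """One 4-connected candidate component in one frame."""

    pixels: frozenset
    intensity: float
    birth_eligible: bool

    @property
    def size(self) -> int:
        return len(self.pixels)


#: Per-frame collection of clusters.
ClusterSet = list


def averaging_window(search_distance: int, pixel_size_um: float) -> tuple[int, float]:
    """Side length (pixels) and physical area (um^2) of the spatial
    averaging window of the differential filter.

    A search distance ``d`` defines a ``(2d+1) x (2d+1)`` grid with the
    tested pixel at its centre; e.g. the default d = 3 on a camera with
    0.2539 um pixels averages over 7 x 7 x 0.2539^2 ~ 3.16 um^2.
    """
    side = 2 * int(search_distance) + 1
    return side, side * side * pixel_size_um**2


def max_filter_mask(stack: ImageStack) -> CellMask:
    """Segment the cell by thresholding the per-pixel temporal maximum.

    The cut point is the mean of all per-pixel maxima (the background
    being much darker than the cell); the largest 4-connected component
    above the cut is kept, which removes isolated bright speckles.
    """
    mx = stack.frames.max(axis=0)
    cut = float(mx.mean())
    above = mx > cut
    if not above.any():
        raise ValueError("max-filter mask is empty (uniform stack?)")
    lab = cc_label(above, connectivity=1)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    mask = lab == int(counts.argmax())
    return CellMask(mask=mask, area_px=int(mask.sum()))


def normalize(
    stack: ImageStack, mask: CellMask, bounds: tuple[float, float] | None = None
) -> np.ndarray:
    """Rescale so the masked min maps to 0 and the masked max to 255.

    ``bounds`` optionally fixes the (F_min, F_max) anchors instead of
    taking them from the masked data — used when a second region (e.g.
    an off-cell control substack) must be expressed in the same
    intensity units as the cell it is compared against.
    """
    if bounds is None:
        vals = stack.frames[:, mask.mask]
        fmin, fmax = float(vals.min()), float(vals.max())
    else:
        fmin, fmax = bounds
    if fmax <= fmin:
        raise ValueError("cannot normalize a constant signal (F_max == F_min)")
    return 255.0 * (stack.frames - fmin) / (fmax - fmin)


def remove_transient(F_norm: np.ndarray, mask: CellMask) -> tuple[np.ndarray, np.ndarray]:
    """Subtract the whole-cell average trace, clipping negatives to 0.

    Returns ``(F_nt, F_a)`` where ``F_a[t]`` is the mean of F_norm over
    the cell mask at frame t.
    """
    F_a = F_norm[:, mask.mask].mean(axis=1)
    F_nt = np.clip(F_norm - F_a[:, None, None], 0.0, None)
    return F_nt, F_a


def despeckle(frames: np.ndarray, mask: CellMask, median_flag: bool, mean_flag: bool) -> np.ndarray:
    """Optional 3x3 median and/or mean filters, applied within the mask.

    When both are requested the median runs first.  Pixels outside the
    mask are left untouched.
    """
    if not (median_flag or mean_flag):
        return frames
    out = frames.copy()
    for t in range(frames.shape[0]):
        f = out[t]
        if median_flag:
            filt = median_filter(f, size=3, mode="nearest")
            f = np.where(mask.mask, filt, f)
        if mean_flag:
            filt = uniform_filter(f, size=3, mode="nearest")
            f = np.where(mask.mask, filt, f)
        out[t] = f
    return out


def differential_filter(
    F_nt: np.ndarray, mask: CellMask, search_distance: int
) -> tuple[np.ndarray, float]:
    """Spatial box average followed by frame-to-frame differencing.

    ``S(x,y,t)`` is the mean of F_nt over the ``(2d+1) x (2d+1)`` window
    centered on (x, y), intersected with the cell mask (windows are
    truncated at the mask/image boundary so the background never
    dilutes the average).  ``D(x,y,t) = S(t) - S(t-1)`` for t >= 1 and 0
    at t = 0.  ``sigma_cell`` is the population SD of D over all mask
    pixels and frames >= 1.
    """
    if search_distance < 1:
        raise ValueError("search_distance must be >= 1")
    d = int(search_distance)
    size = 2 * d + 1
    m = mask.mask.astype(np.float64)
    area = float(size * size)
    counts = uniform_filter(m, size=size, mode="constant", cval=0.0) * area
    T = F_nt.shape[0]
    S = np.zeros_like(F_nt)
    for t in range(T):
        sums = uniform_filter(F_nt[t] * m, size=size, mode="constant", cval=0.0) * area
        with np.errstate(invalid="ignore", divide="ignore"):
            s = sums / counts
        S[t] = np.where(mask.mask & (counts > 0), s, 0.0)
    D = np.zeros_like(F_nt)
    D[1:] = S[1:] - S[:-1]
    D[:, ~mask.mask] = 0.0
    sigma_cell = float(D[1:, mask.mask].std())
    return D, sigma_cell


_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.intp)


def candidacy(
    D: np.ndarray,
    sigma_cell: float,
    sd_detection: float,
    suspended_frames: set[int] | frozenset[int],
    mask: CellMask,
) -> np.ndarray:
    """Per-frame boolean candidate masks.

    A pixel is a candidate iff ``D > sd_detection * sigma_cell`` and the
    frame is not suspended (transient cut-off); then, in a single
    simultaneous pass, any mask pixel with at least 7 of its 8 neighbors
    candidate is also made candidate.
    """
    thr = sd_detection * sigma_cell
    cand = (D > thr) & mask.mask[None, :, :]
    for t in range(D.shape[0]):
        if t in suspended_frames:
            cand[t] = False
            continue
        nbr = correlate(cand[t].astype(np.intp), _NEIGHBOR_KERNEL, mode="constant", cval=0)
        cand[t] = cand[t] | (mask.mask & (nbr >= 7))
    return cand


def find_clusters(
    candidate_frame: np.ndarray,
    intensity_frame: np.ndarray,
    size_threshold: int,
    intensity_threshold: float,
) -> ClusterSet:
    """Group a frame's candidates into 4-connected clusters.

    A cluster is *birth eligible* (may found a new event) only when its
    pixel count reaches ``size_threshold`` AND its summed intensity over
    ``intensity_frame`` reaches ``intensity_threshold``; failing
    clusters are kept as continuation-only fragments.  The pipeline
    passes the differential image D as ``intensity_frame``: an event is
    born where the signal *changes* fast enough over a large enough
    area, so the brightness test measures the newly appearing signal
    mass rather than the static fluorescence under the cluster.
    """
    clusters: ClusterSet = []
    if not candidate_frame.any():
        return clusters
    lab = cc_label(candidate_frame, connectivity=1)
    for j in range(1, lab.max() + 1):
        ys, xs = np.nonzero(lab == j)
        pixels = frozenset(zip(ys.tolist(), xs.tolist()))
        intensity = float(intensity_frame[ys, xs].sum())
        eligible = len(pixels) >= size_threshold and intensity >= intensity_threshold
        clusters.append(Cluster(pixels=pixels, intensity=intensity, birth_eligible=eligible))
    return clusters


def condition_stack(
    stack: ImageStack,
    config: RunConfig,
    mask: CellMask | None = None,
    norm_bounds: tuple[float, float] | None = None,
) -> ConditionedStack:
    """Run the full conditioning chain on a (stabilized) stack."""
    if mask is None:
        mask = max_filter_mask(stack)
    F_norm = normalize(stack, mask, norm_bounds)
    if config.transients_present:
        F_nt, F_a = remove_transient(F_norm, mask)
    else:
        F_a = F_norm[:, mask.mask].mean(axis=1)
        F_nt = F_norm.copy()
    F_nt = despeckle(F_nt, mask, config.median_filter, config.mean_filter)
    D, sigma_cell = differential_filter(F_nt, mask, config.search_distance)
    sigma_fnt = float(F_nt[:, mask.mask].std())
    return ConditionedStack(
        mask=mask, F_norm=F_norm, F_nt=F_nt, F_a=F_a, D=D,
        sigma_cell=sigma_cell, sigma_fnt=sigma_fnt,
    )
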