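"""Contraction matching and constant-curvature line tracking.

Contractions of a pacemaker cell are stereotyped: one contraction,
marked by the user as a rectangular window on the curvature map, serves
as a template that is matched against the rest of the recording by a
least-difference search.  Horizontal guide lines placed on bands of
constant curvature are then bent inside the template window (a
polyline of per-frame column offsets) and the bend is replayed in every
matched contraction window, yielding tracked lines x = L(t) whose
intersections with the spine provide the moving landmarks used for
stabilization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spine_geometry import CurvatureMap

__all__ = [
    "ContractionTemplate",
    "TrackedLine",
    "match_contractions",
    "track_line",
    "interpolate_lines",
    "spine_points",
]


@dataclass(frozen=True)
class ContractionTemplate:
    """One manually identified contraction: inclusive frame window and column range."""

    frame_window: tuple[int, int]
    column_range: tuple[int, int]

    def __post_init__(self) -> None:
        t0, t1 = self.frame_window
        x0, x1 = self.column_range
        if t1 <= t0:
            raise ValueError("template frame window must span >1 frame")
        if x1 < x0:
            raise ValueError("template column range is empty")


@dataclass
class TrackedLine:
    """A tracked vertical line x = L(t) = baseline_x + offsets[t]."""

    baseline_x: float
    offsets: np.ndarray

    @property
    def L(self) -> np.ndarray:
        return self.baseline_x + self.offsets


def _window_dissimilarity(k: np.ndarray, template: ContractionTemplate) -> np.ndarray:
    """Mean absolute difference between the template block and every
    candidate window start, restricted to the template's column range.

    NaN entries (undefined curvature) are ignored pairwise.
    """
    t0, t1 = template.frame_window
    x0, x1 = template.column_range
    n = t1 - t0 + 1
    T = k.shape[0]
    ref = k[t0 : t1 + 1, x0 : x1 + 1]
    scores = np.empty(T - n + 1)
    for s in range(T - n + 1):
        cand = k[s : s + n, x0 : x1 + 1]
        diff = np.abs(cand - ref)
        scores[s] = np.nanmean(diff) if np.any(np.isfinite(diff)) else np.inf
    return scores


def match_contractions(
    cmap: CurvatureMap, template: ContractionTemplate, match_threshold: float = 20.0
) -> list[tuple[int, int]]:
    """Find all contraction windows matching the template.

    A candidate window start is accepted when its dissimilarity (mean
    absolute curvature difference against the template block) is a local
    minimum and at most ``match_threshold/100`` of the worst candidate
    dissimilarity, so raising the threshold admits more (noisier)
    contractions.  Accepted windows are non-overlapping; among
    overlapping candidates the lowest-dissimilarity one wins.  The
    template's own window always matches (dissimilarity 0).

    Returns inclusive ``(start, end)`` windows sorted by time.
    """
    k = cmap.k
    t0, t1 = template.frame_window
    T = k.shape[0]
    if not (0 <= t0 < t1 < T):
        raise ValueError("template frame window outside stack")
    n = t1 - t0 + 1
    scores = _window_dissimilarity(k, template)
    finite = scores[np.isfinite(scores)]
    if finite.size == 0:
        raise ValueError("curvature map undefined over the template column range")
    max_dissim = float(finite.max())
    cut = (match_threshold / 100.0) * max_dissim

    candidates = []
    for s in range(len(scores)):
        left = scores[s - 1] if s > 0 else np.inf
        right = scores[s + 1] if s + 1 < len(scores) else np.inf
        if scores[s] <= left and scores[s] <= right and scores[s] <= cut:
            candidates.append(s)
    if t0 not in candidates:
        candidates.append(t0)

    # Greedy non-overlap: best (lowest) dissimilarity first; template first on ties.
    order = sorted(candidates, key=lambda s: (scores[s], s != t0, s))
    accepted: list[int] = []
    for s in order:
        if all(s + n <= a or s >= a + n for a in accepted):
            accepted.append(s)
    return sorted((s, s + n - 1) for s in accepted)


def track_line(
    guide_x: float,
    bend: list[tuple[float, float]],
    windows: list[tuple[int, int]],
    template_window: tuple[int, int],
    n_frames: int,
) -> TrackedLine:
    """Replay a template-window bend in every matched contraction window.

    ``bend`` is a polyline of ``(frame_offset, column_offset)`` vertices
    with frame offsets relative to the template window start; offsets
    between vertices are linearly interpolated, and zero outside the
    polyline's frame range.  L(t) equals ``guide_x`` outside all
    windows; inside each window the bend is replayed aligned to the
    window start, relying on the stereotyped shape of contractions.
    """
    t0, t1 = template_window
    win_len = t1 - t0 + 1
    offsets = np.zeros(n_frames)
    if bend:
        bf = np.asarray([v[0] for v in bend], dtype=np.float64)
        bx = np.asarray([v[1] for v in bend], dtype=np.float64)
        if np.any(bf < 0) or np.any(bf > win_len - 1):
            raise ValueError("bend vertices outside template window")
        order = np.argsort(bf)
        bf, bx = bf[order], bx[order]
        for (s, e) in windows:
            rel = np.arange(0, e - s + 1, dtype=np.float64)
            off = np.interp(rel, bf, bx, left=0.0, right=0.0)
            # within the polyline range use interpolation; outside it the
            # guide is straight (offset 0)
            off[(rel < bf[0]) | (rel > bf[-1])] = 0.0
            offsets[s : e + 1] = off
    return TrackedLine(baseline_x=float(guide_x), offsets=offsets)


def interpolate_lines(lines: list[TrackedLine], n_between: int) -> list[TrackedLine]:
    """Insert ``n_between`` linearly interpolated lines between neighbors.

    Lines must be sorted by baseline and must not cross at any frame;
    the first offending frame is reported otherwise.
    """
    if n_between < 0:
        raise ValueError("n_between must be >= 0")
    if len(lines) < 2:
        raise ValueError("need at least two lines to interpolate")
    for a, b in zip(lines, lines[1:]):
        bad = np.flatnonzero(a.L >= b.L)
        if bad.size:
            raise ValueError(f"lines cross or touch at frame {int(bad[0])}")
    if n_between == 0:
        return list(lines)
    out: list[TrackedLine] = []
    for a, b in zip(lines, lines[1:]):
        out.append(a)
        for j in range(1, n_between + 1):
            f = j / (n_between + 1)
            out.append(
                TrackedLine(
                    baseline_x=(1 - f) * a.baseline_x + f * b.baseline_x,
                    offsets=(1 - f) * a.offsets + f * b.offsets,
                )
            )
    out.append(lines[-1])
    return out


def spine_points(lines: list[TrackedLine], spines: np.ndarray) -> np.ndarray:
    """Evaluate each tracked line on the spine, per frame.

    Returns an array of shape ``(T, n_lines, 2)`` of (x, y) points,
    sorted by x within each frame; the spine y-value at a fractional
    column is linearly interpolated between integer columns, both of
    which must be defined.
    """
    spines = np.asarray(spines, dtype=np.float64)
    T = spines.shape[0]
    n = len(lines)
    pts = np.empty((T, n, 2))
    for t in range(T):
        zeta = spines[t]
        xs = np.array([ln.L[t] for ln in lines])
        order = np.argsort(xs)
        for j, idx in enumerate(order):
            x = xs[idx]
            x0 = int(np.floor(x))
            x1 = min(x0 + 1, spines.shape[1] - 1)
            if x0 < 0 or x1 >= spines.shape[1] + 1:
                raise ValueError(f"line position {x} outside frame at t={t}")
            if not (np.isfinite(zeta[x0]) and np.isfinite(zeta[x1])):
                raise ValueError(f"spine undefined at column {x} (frame {t})")
            f = x - x0
            y = (1 - f) * zeta[x0] + f * zeta[x1]
            pts[t, j] = (x, y)
    return pts
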