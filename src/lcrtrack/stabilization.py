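"""Piecewise-affine stabilization over a tracked triangular mesh.

Spine points tracked through the contraction define, per frame, the
base vertices of a strip of isosceles triangles: each adjacent pair of
spine points carries one triangle above and one below the spine (apex
offset purely vertical, +-h), and each pair of neighboring triangles
defines an intervening triangle of opposite orientation.  The topology
is fixed across frames; only the vertex coordinates move.  Every frame
is warped into the reference frame's geometry triangle-by-triangle:
for a reference pixel inside triangle j, the affine map
``M_d . M_r^-1`` (homogeneous vertex matrices of the deformed and
reference triangle) gives the source location in the moving frame,
which is sampled bilinearly (backward warping, so no holes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .spine_geometry import BackgroundStats
from .stack_io import ImageStack

logger = logging.getLogger(__name__)

__all__ = [
    "TriangleMesh",
    "build_mesh",
    "triangle_affine",
    "triangle_label_map",
    "warp_frame",
    "stabilize",
]

_EDGE_EPS = 1e-9


@dataclass
class TriangleMesh:
    """Per-frame vertex coordinates with fixed triangle topology.

    ``vertices`` has shape ``(T, V, 2)`` storing (x, y); ``triangles``
    is ``(n_tri, 3)`` vertex indices, identical for every frame.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    height: float

    @property
    def n_frames(self) -> int:
        return self.vertices.shape[0]


def build_mesh(points: np.ndarray, height: float) -> TriangleMesh:
    """Build the triangle strip over per-frame spine points.

    ``points`` has shape ``(T, n, 2)`` with strictly increasing x per
    frame and ``n >= 2``.  For each adjacent pair (P_i, P_{i+1}) the
    apexes sit at the base midpoint shifted by -h (above) and +h
    (below) in y; intervening triangles connect neighboring apexes
    through the shared spine point.
    """
    points = np.asarray(points, dtype=np.float64)
    if height <= 0:
        raise ValueError("triangle height must be positive")
    if points.ndim != 3 or points.shape[2] != 2:
        raise ValueError("points must have shape (T, n, 2)")
    T, n, _ = points.shape
    if n < 2:
        raise ValueError("need at least 2 spine points per frame")
    if np.any(np.diff(points[:, :, 0], axis=1) <= 0):
        raise ValueError("spine points must have strictly increasing x in every frame")

    mids = 0.5 * (points[:, :-1] + points[:, 1:])  # (T, n-1, 2)
    upper = mids.copy()
    upper[:, :, 1] -= height
    lower = mids.copy()
    lower[:, :, 1] += height
    vertices = np.concatenate([points, upper, lower], axis=1)  # P0..P_{n-1}, A+_0.., A-_0..

    tris: list[tuple[int, int, int]] = []
    up0 = n
    lo0 = n + (n - 1)
    for i in range(n - 1):  # primary triangles on each base
        tris.append((i, i + 1, up0 + i))
        tris.append((i, i + 1, lo0 + i))
    for i in range(n - 2):  # intervening triangles between neighboring apex pairs
        tris.append((up0 + i, up0 + i + 1, i + 1))
        tris.append((lo0 + i, lo0 + i + 1, i + 1))
    return TriangleMesh(vertices=vertices, triangles=np.asarray(tris, dtype=np.intp), height=float(height))


def triangle_affine(ref_tri: np.ndarray, def_tri: np.ndarray) -> np.ndarray:
    """Affine map taking the reference triangle onto the deformed one.

    Returns the 3x3 homogeneous matrix ``M_d . M_r^-1`` where each M
    stacks the triangle's vertices as columns (x; y; 1).  Each
    reference vertex maps exactly onto its deformed counterpart.
    """
    ref_tri = np.asarray(ref_tri, dtype=np.float64)
    def_tri = np.asarray(def_tri, dtype=np.float64)
    Mr = np.vstack([ref_tri.T, np.ones(3)])
    Md = np.vstack([def_tri.T, np.ones(3)])
    det = np.linalg.det(Mr)
    if abs(det) < 1e-12 * max(1.0, np.abs(Mr).max() ** 2):
        raise np.linalg.LinAlgError("reference triangle is degenerate (collinear vertices)")
    return Md @ np.linalg.inv(Mr)


def triangle_label_map(vertices: np.ndarray, triangles: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Assign each pixel centre the index of the triangle containing it.

    Edges are inclusive; a pixel on a shared edge gets the lowest
    containing triangle index (deterministic tie-break).  Pixels outside
    every triangle get -1.
    """
    H, W = shape
    labels = np.full((H, W), -1, dtype=np.intp)
    # iterate highest index first so lower indices overwrite on ties
    for j in range(len(triangles) - 1, -1, -1):
        tri = vertices[triangles[j]]
        xmin = max(int(np.floor(tri[:, 0].min())), 0)
        xmax = min(int(np.ceil(tri[:, 0].max())), W - 1)
        ymin = max(int(np.floor(tri[:, 1].min())), 0)
        ymax = min(int(np.ceil(tri[:, 1].max())), H - 1)
        if xmin > xmax or ymin > ymax:
            continue
        xs, ys = np.meshgrid(np.arange(xmin, xmax + 1), np.arange(ymin, ymax + 1))
        (x1, y1), (x2, y2), (x3, y3) = tri
        den = (y2 - y3) * (x1 - x3) + (x3 - x2) * (y1 - y3)
        if abs(den) < 1e-12:
            continue
        l1 = ((y2 - y3) * (xs - x3) + (x3 - x2) * (ys - y3)) / den
        l2 = ((y3 - y1) * (xs - x3) + (x1 - x3) * (ys - y3)) / den
        l3 = 1.0 - l1 - l2
        inside = (l1 >= -_EDGE_EPS) & (l2 >= -_EDGE_EPS) & (l3 >= -_EDGE_EPS)
        labels[ys[inside], xs[inside]] = j
    return labels


def warp_frame(
    frame: np.ndarray,
    dst_vertices: np.ndarray,
    src_vertices: np.ndarray,
    triangles: np.ndarray,
    fill_value: float = 0.0,
    labels: np.ndarray | None = None,
) -> tuple[np.ndarray, int]:
    """Warp ``frame`` so that ``src`` triangle geometry lands on ``dst``.

    For each output pixel inside a ``dst`` triangle, the corresponding
    location under the per-triangle affine (dst -> src) is sampled from
    ``frame`` with bilinear interpolation, clamped at the frame border
    (clamped samples are counted and returned).  Pixels outside every
    triangle receive ``fill_value``.
    """
    H, W = frame.shape
    if labels is None:
        labels = triangle_label_map(dst_vertices, triangles, (H, W))
    out = np.full((H, W), float(fill_value))
    n_clamped = 0
    for j in range(len(triangles)):
        sel = labels == j
        if not np.any(sel):
            continue
        A = triangle_affine(dst_vertices[triangles[j]], src_vertices[triangles[j]])
        ys, xs = np.nonzero(sel)
        src_x = A[0, 0] * xs + A[0, 1] * ys + A[0, 2]
        src_y = A[1, 0] * xs + A[1, 1] * ys + A[1, 2]
        oob = (src_x < 0) | (src_x > W - 1) | (src_y < 0) | (src_y > H - 1)
        n_clamped += int(np.count_nonzero(oob))
        out[ys, xs] = map_coordinates(frame, [src_y, src_x], order=1, mode="nearest")
    return out, n_clamped


def stabilize(
    stack: ImageStack,
    mesh: TriangleMesh,
    ref_frame: int = 0,
    background: BackgroundStats | float = 0.0,
) -> ImageStack:
    """Warp every frame into the reference frame's mesh geometry.

    Output pixels inside the reference mesh are bilinear samples of the
    moving frame at ``M_d . M_r^-1 (x, y, 1)``; pixels outside the mesh
    are filled with the background mean so the surround is flat.
    Samples mapped outside the source frame are clamped to the border
    and counted in the log.
    """
    T, H, W = stack.shape
    if mesh.n_frames != T:
        raise ValueError("mesh frame count does not match stack")
    if not 0 <= ref_frame < T:
        raise ValueError("ref_frame outside stack")
    fill = background.b if isinstance(background, BackgroundStats) else float(background)
    ref_verts = mesh.vertices[ref_frame]
    labels = triangle_label_map(ref_verts, mesh.triangles, (H, W))
    out = np.empty_like(stack.frames)
    total_clamped = 0
    for t in range(T):
        out[t], n_cl = warp_frame(
            stack.frames[t], ref_verts, mesh.vertices[t], mesh.triangles, fill, labels
        )
        total_clamped += n_cl
    if total_clamped:
        logger.info("stabilize: %d sample(s) clamped to the frame border", total_clamped)
    return ImageStack(out, stack.pixel_size_um, stack.frame_interval_ms)
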