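"""Ground-truthed synthetic movies of a contracting, flashing cell.

The simulator composes, in a stationary reference geometry, an
elongated fluorescent cell on a dark noisy background, a periodic
multiplicative whole-cell transient (the action-potential-induced
Ca2+ rise), and stochastic local release events: isotropic Gaussian
blobs with a short linear rise and an exponential decay whose centroid
may drift (propagation).  Optionally the whole scene is deformed
forward through a known per-frame triangular mesh (periodic
contraction synchronized with the transient), and Gaussian camera
noise plus optional salt-and-pepper speckle is added last.  Everything
the detector is supposed to recover — birth frames, centroid paths,
amplitudes, the deformation mesh — is recorded as ground truth.

The defaults describe the standard study condition used throughout the
test suite: 100 frames of 64 x 256 pixels at 10 ms/frame, two pacemaker
cycles of 50 frames, 10 events per cycle, and event amplitude five
times the camera noise SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stabilization import TriangleMesh, build_mesh, warp_frame
from .stack_io import ImageStack

__all__ = [
    "TruthEvent",
    "SyntheticTruth",
    "DetectionScore",
    "simulate_movie",
    "score_detection",
]


@dataclass
class TruthEvent:
    """One seeded release event."""

    birth_frame: int
    death_frame: int
    centroids: dict[int, tuple[float, float]]  # frame -> (x, y)
    amplitude: float
    radius: float


@dataclass
class SyntheticTruth:
    """Ground truth paired with a simulated stack."""

    events: list[TruthEvent]
    peak_frames: list[int]
    nadir_frames: list[int]
    waveform: np.ndarray
    mesh: TriangleMesh | None
    rest_points: np.ndarray | None
    seed: int


@dataclass
class DetectionScore:
    recall: float
    precision: float
    birth_frame_mae: float
    n_truth: int
    n_detected: int
    n_matched: int


def _rolloff(dist: np.ndarray, flat: float, edge: float) -> np.ndarray:
    """Smoothstep plateau: 1 for dist <= flat, 0 for dist >= flat + edge."""
    u = np.clip((flat + edge - dist) / edge, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _smooth_cell(height: int, width: int, brightness: float) -> tuple[np.ndarray, np.ndarray]:
    """Cell intensity profile and its centerline y_c(x).

    The centerline carries gentle bends (curvature landmarks for the
    tracker).  The cross-section is a flat-topped plateau with short
    smoothstep edges, emulating uniform dye loading of the cytoplasm:
    the detection chain subtracts the whole-cell mean from every pixel,
    so a brightness plateau (rather than a soft dome) is what keeps the
    off-event residual near zero, as in a well-loaded cell.
    """
    x = np.arange(width, dtype=np.float64)
    y = np.arange(height, dtype=np.float64)
    y_c = height / 2.0 + 5.0 * np.sin(2 * np.pi * x / 170.0) + 2.0 * np.sin(2 * np.pi * x / 47.0 + 1.0)
    across = _rolloff(np.abs(y[:, None] - y_c[None, :]), 13.0, 0.8)
    along = _rolloff(np.abs(x - width / 2.0), 0.31 * width, 0.012 * width)
    return brightness * across * along[None, :], y_c


def _transient_waveform(n_frames: int, cycle_period: int, rise_frames: int = 4, decay_tau: float = 10.0) -> np.ndarray:
    """Periodic 0-1 waveform: linear upstroke, exponential decay."""
    phase = np.arange(n_frames) % cycle_period
    w = np.where(
        phase <= rise_frames,
        phase / rise_frames,
        np.exp(-(phase - rise_frames) / decay_tau),
    )
    return w.astype(np.float64)


def simulate_movie(
    n_frames: int = 100,
    height: int = 64,
    width: int = 256,
    pixel_size_um: float = 0.2539,
    frame_interval_ms: float = 10.0,
    background: float = 10.0,
    cell_brightness: float = 100.0,
    cycle_period_frames: int = 50,
    transient_amplitude: float = 1.5,
    n_events_per_cycle: int = 10,
    event_amplitude: float = 20.0,
    event_radius_px: float = 2.5,
    event_rise_frames: int = 2,
    event_decay_tau_frames: float = 3.0,
    propagation_speed_px_per_frame: float = 0.5,
    noise_sd: float = 4.0,
    salt_pepper_fraction: float = 0.0,
    contraction_amplitude: float = 2.0,
    triangle_height: float = 24.0,
    n_spine_points: int = 9,
    transients: bool = True,
    event_times: list[int] | None = None,
    seed: int = 0,
) -> tuple[ImageStack, SyntheticTruth]:
    """Simulate a movie and its ground truth.

    Events are born during diastole (the quiet tail of each cycle) at
    mutually separated positions inside the cell; each rises linearly
    over ``event_rise_frames`` to ``event_amplitude``, decays with time
    constant ``event_decay_tau_frames``, and drifts at
    ``propagation_speed_px_per_frame`` in a random direction.  With
    ``contraction_amplitude > 0`` the composed scene is deformed through
    a per-frame triangle mesh (longitudinal shortening plus a slight
    bend, driven by the transient waveform); the mesh is part of the
    returned truth so stabilization can be tested against it.  The
    whole simulation is reproducible from ``seed``.

    ``event_times`` optionally pins event birth frames explicitly; a
    birth outside diastole while transients are on is an error.
    """
    rng = np.random.default_rng(seed)
    cell, y_c = _smooth_cell(height, width, cell_brightness)
    w = _transient_waveform(n_frames, cycle_period_frames) if transients else np.zeros(n_frames)
    rise = 4
    peak_frames = [c * cycle_period_frames + rise for c in range(n_frames // cycle_period_frames)]
    peak_frames = [p for p in peak_frames if p < n_frames]
    nadir_frames = [max(p - rise, 0) for p in peak_frames]

    # diastolic frames: transient decayed below 5% and before the next upstroke
    if transients:
        diastole = np.flatnonzero(w < 0.05)
        diastole = diastole[(diastole % cycle_period_frames) > rise]
    else:
        diastole = np.arange(1, n_frames)
    if transients and diastole.size == 0:
        raise ValueError("no diastolic frames available for event seeding")

    # ---- seed events ------------------------------------------------
    n_cycles = max(1, n_frames // cycle_period_frames)
    births: list[int]
    if event_times is not None:
        if transients:
            bad = [t for t in event_times if t not in set(diastole.tolist())]
            if bad:
                raise ValueError(f"event birth frames outside diastole: {bad}")
        births = list(event_times)
    else:
        births = []
        for c in range(n_cycles):
            in_cycle = diastole[
                (diastole >= c * cycle_period_frames) & (diastole < (c + 1) * cycle_period_frames)
            ]
            in_cycle = in_cycle[in_cycle < n_frames - 2]
            for _ in range(n_events_per_cycle):
                if in_cycle.size:
                    births.append(int(rng.choice(in_cycle)))

    # events live in the central, uniformly loaded plateau of the cell:
    # in the tapering ends the global-mean subtraction of the detector's
    # decay filter clips sub-pedestal signals, which is a documented
    # insensitivity of the method, not a detection target.  Events of the
    # same cycle coexist and must be well separated; events of different
    # cycles never overlap in time and may reuse locations.
    x_lo, x_hi = 0.22 * width, 0.78 * width
    events: list[TruthEvent] = []
    # per cycle, positions come from a jittered staggered lattice along the
    # plateau, which guarantees the separation by construction (uniform
    # rejection sampling cannot reliably pack this many separated sites)
    slots_by_cycle: dict[int, list[tuple[float, float]]] = {}

    def _cycle_slots(n_slots: int) -> list[tuple[float, float]]:
        """Jittered staggered lattice sites, ordered so that sites that
        will host temporally neighboring events lie far apart: nearly
        concurrent releases at adjacent sites would share one candidate
        contour and be detected as a single propagating event."""
        span = x_hi - x_lo
        xs = x_lo + (np.arange(n_slots) + 0.5) * span / n_slots
        ys_off = np.where(np.arange(n_slots) % 2 == 0, -6.5, 6.5)
        stride = max(n_slots // 3, 1)
        order = sorted(range(n_slots), key=lambda i: (i % stride, i))
        slots = []
        for i in order:
            sx = float(xs[i] + rng.uniform(-1.2, 1.2))
            sy = float(y_c[int(xs[i])] + ys_off[i] + rng.uniform(-1.2, 1.2))
            slots.append((sx, sy))
        return slots

    births.sort()
    for birth in births:
        cyc = birth // cycle_period_frames
        slots = slots_by_cycle.setdefault(cyc, _cycle_slots(max(n_events_per_cycle, 1)))
        ex, ey = slots.pop(0) if slots else (
            float(rng.uniform(x_lo, x_hi)),
            float(y_c[int(width / 2)] + rng.uniform(-7.0, 7.0)),
        )
        theta = float(rng.uniform(0, 2 * np.pi))
        vx = propagation_speed_px_per_frame * np.cos(theta)
        vy = propagation_speed_px_per_frame * np.sin(theta)
        # lifetime: rise + decay down to 5% of peak, cut by next suspension/stack end
        decay_span = int(np.ceil(3.0 * event_decay_tau_frames))
        death = min(birth + event_rise_frames - 1 + decay_span, n_frames - 1)
        if transients:
            upcoming = [p - rise for p in peak_frames if p - rise > birth]
            if upcoming:
                death = min(death, upcoming[0])
        centroids = {}
        for t in range(birth, death + 1):
            centroids[t] = (ex + vx * (t - birth), ey + vy * (t - birth))
        events.append(
            TruthEvent(
                birth_frame=birth,
                death_frame=death,
                centroids=centroids,
                amplitude=event_amplitude,
                radius=event_radius_px,
            )
        )

    # ---- compose reference-geometry frames --------------------------
    frames = np.empty((n_frames, height, width))
    yy, xx = np.mgrid[0:height, 0:width]
    for t in range(n_frames):
        f = background + cell * (1.0 + transient_amplitude * w[t])
        for ev in events:
            if ev.birth_frame <= t <= ev.death_frame:
                tau = t - ev.birth_frame
                if tau < event_rise_frames:
                    amp = ev.amplitude * (tau + 1) / event_rise_frames
                else:
                    amp = ev.amplitude * np.exp(-(tau - (event_rise_frames - 1)) / event_decay_tau_frames)
                cx, cy = ev.centroids[t]
                r2 = (xx - cx) ** 2 + (yy - cy) ** 2
                f = f + amp * np.exp(-r2 / (2.0 * ev.radius**2))
        frames[t] = f

    # ---- contraction: forward piecewise-affine deformation -----------
    mesh = None
    rest_points = None
    if contraction_amplitude > 0:
        xs = np.linspace(0.08 * width, 0.92 * width, n_spine_points)
        rest = np.stack([xs, np.interp(xs, np.arange(width), y_c)], axis=1)
        rest_points = rest
        xc = width / 2.0
        halfspan = xs[-1] - xc
        pts = np.empty((n_frames, n_spine_points, 2))
        for t in range(n_frames):
            c = contraction_amplitude * w[t]
            dx = -c * (xs - xc) / halfspan
            dy = 0.3 * c * np.sin(np.pi * (xs - xs[0]) / (xs[-1] - xs[0]))
            pts[t, :, 0] = xs + dx
            pts[t, :, 1] = rest[:, 1] + dy
        mesh = build_mesh(pts, triangle_height)
        rest_mesh_vertices = build_mesh(rest[None, :, :], triangle_height).vertices[0]
        for t in range(n_frames):
            frames[t], _ = warp_frame(
                frames[t],
                dst_vertices=mesh.vertices[t],
                src_vertices=rest_mesh_vertices,
                triangles=mesh.triangles,
                fill_value=background,
            )

    # ---- camera noise ------------------------------------------------
    if noise_sd > 0:
        frames = frames + rng.normal(0.0, noise_sd, frames.shape)
    if salt_pepper_fraction > 0:
        n_px = frames[0].size
        for t in range(n_frames):
            n_spots = int(salt_pepper_fraction * n_px)
            ys = rng.integers(0, height, n_spots)
            xs_ = rng.integers(0, width, n_spots)
            frames[t, ys, xs_] = rng.choice([0.0, cell_brightness * (1 + transient_amplitude)], n_spots)
    frames = np.clip(frames, 0.0, None)

    stack = ImageStack(frames, pixel_size_um, frame_interval_ms)
    truth = SyntheticTruth(
        events=events,
        peak_frames=peak_frames,
        nadir_frames=nadir_frames,
        waveform=w,
        mesh=mesh,
        rest_points=rest_points,
        seed=seed,
    )
    return stack, truth


def score_detection(
    truth: SyntheticTruth,
    records: list,
    tol_frames: int = 2,
    tol_px: float = 8.0,
) -> DetectionScore:
    """Match detected events to seeded truth and score the detection.

    Matching is greedy one-to-one nearest: a (truth, detected) pair is
    admissible when the birth frames differ by at most ``tol_frames``
    and the detected bounding-box centroid lies within ``tol_px`` of the
    truth centroid averaged over the event's lifetime (the detected
    bounding box spans the whole propagation path, so its centre tracks
    the path middle, not the birth site); admissible pairs are consumed
    best-first (smallest birth difference, then distance).  With no
    detections, precision is 1 by convention (no false claims).
    """
    pairs = []
    for i, tr in enumerate(truth.events):
        cs = np.array(list(tr.centroids.values()))
        tx, ty = cs.mean(axis=0)
        for j, rec in enumerate(records):
            db = abs(rec.birth_from_start_frames - tr.birth_frame)
            if db > tol_frames:
                continue
            cx = 0.5 * (rec.min_x + rec.max_x)
            cy = 0.5 * (rec.min_y + rec.max_y)
            dist = float(np.hypot(cx - tx, cy - ty))
            if dist > tol_px:
                continue
            pairs.append((db, dist, i, j))
    pairs.sort()
    used_t: set[int] = set()
    used_d: set[int] = set()
    birth_err = []
    for db, dist, i, j in pairs:
        if i in used_t or j in used_d:
            continue
        used_t.add(i)
        used_d.add(j)
        birth_err.append(db)
    n_truth = len(truth.events)
    n_det = len(records)
    n_matched = len(used_t)
    recall = n_matched / n_truth if n_truth else 1.0
    precision = n_matched / n_det if n_det else 1.0
    mae = float(np.mean(birth_err)) if birth_err else float("nan")
    return DetectionScore(
        recall=recall,
        precision=precision,
        birth_frame_mae=mae,
        n_truth=n_truth,
        n_detected=n_det,
        n_matched=n_matched,
    )
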