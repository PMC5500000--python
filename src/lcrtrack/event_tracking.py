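"""LCR lifecycle tracking: birth, growth, split, collision, and death.

Events keep their identity frame-to-frame through cluster adjacency: a
candidate cluster that overlaps or touches (4-adjacency) the previous
footprint of exactly one live event extends that event; a cluster
bridging two or more events triggers a collision in which the event
with the largest previous-frame footprint survives and absorbs
everything (ties break to the lower id), while the others are recorded
as dead by collision.  An event whose pixels separate into several
clusters keeps a single identity spanning all of them.  An event that
receives no cluster retains its previous footprint while it decays.

Death has three modes: *stochastic attrition* when the mean
transient-free signal over the event's pixels drops below
``sd_termination * sigma_cell``; *transient* when the whole-cell
transient rises past the cut-off level and detection is suspended (the
event merges into the global signal); and *collision* as above.  Events
still live at the end of the recording stay open (``dead = false``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .lcr_detection import (
    CellMask,
    Cluster,
    ConditionedStack,
    candidacy,
    condition_stack,
    find_clusters,
)
from .stack_io import ImageStack, RunConfig

__all__ = [
    "CycleAnchors",
    "LCREvent",
    "LCRRecord",
    "DetectionResult",
    "cycle_anchors",
    "update_events",
    "check_terminations",
    "finalize",
    "hotspot_map",
    "run_detector",
]


@dataclass
class CycleAnchors:
    """Transient peaks, the nadir preceding each peak, and suspended frames.

    A frame is suspended (the detector stops looking for events) from
    the first frame of a cycle where the whole-cell trace reaches
    ``nadir + cutoff% * (peak - nadir)`` up to and including the peak.
    """

    transient_peak_frames: list[int]
    nadir_frames: list[int]
    suspended_frames: frozenset[int]


@dataclass
class LCREvent:
    """One tracked release event with its per-frame pixel footprint."""

    id: int
    birth_frame: int
    pixels_by_frame: dict[int, frozenset] = field(default_factory=dict)
    death_frame: int | None = None
    death_mode: str = "none"  # none | stochastic_attrition | transient | collision

    @property
    def alive(self) -> bool:
        return self.death_frame is None

    @property
    def path_pixels(self) -> frozenset:
        out: set = set()
        for px in self.pixels_by_frame.values():
            out |= px
        return frozenset(out)


@dataclass
class LCRRecord:
    """Finalized per-event output parameters (one table row)."""

    id: int
    max_x: int
    min_x: int
    max_y: int
    min_y: int
    start_area_px: int
    max_area_px: int
    path_area_px: int
    birth_from_nadir_frames: float
    lcr_cycle_frames: float
    birth_from_start_frames: int
    duration_frames: int
    half_max_amplitude: float
    dead: bool
    dead_by_collision: bool
    dead_by_transient: bool
    dead_by_stochastic_attrition: bool
    trace: dict[int, int] = field(default_factory=dict)


@dataclass
class DetectionResult:
    """Everything the detector produces for one stack."""

    records: list[LCRRecord]
    events: list[LCREvent]
    anchors: CycleAnchors | None
    conditioned: ConditionedStack
    ensemble_trace: np.ndarray
    config: RunConfig


def cycle_anchors(F_a: np.ndarray, transient_cutoff_percent: float) -> CycleAnchors:
    """Locate transient peaks/nadirs on the whole-cell trace and derive
    the suspended-frame set.

    Peaks are local maxima of ``F_a`` above half its global range.  The
    nadir of each cycle is the minimum between the previous peak (or the
    stack start) and the peak.  For each cycle, suspension starts at the
    first frame where ``F_a`` reaches
    ``nadir + (cutoff/100) * (peak - nadir)`` and runs through the peak
    frame, forming one contiguous run per cycle.
    """
    F_a = np.asarray(F_a, dtype=np.float64)
    rng = F_a.max() - F_a.min()
    height = F_a.min() + 0.5 * rng
    peaks, _ = find_peaks(F_a, height=height)
    if F_a[0] >= height and (len(F_a) > 1 and F_a[0] > F_a[1]):
        # a decaying transient truncated at the stack start still anchors a cycle
        peaks = np.concatenate([[0], peaks])
    if peaks.size == 0:
        raise ValueError("no transient peak found on the whole-cell trace")
    peaks = [int(p) for p in peaks]
    nadirs: list[int] = []
    suspended: set[int] = set()
    cutoff = transient_cutoff_percent / 100.0
    for j, p in enumerate(peaks):
        lo = peaks[j - 1] + 1 if j > 0 else 0
        if lo > p:
            lo = p
        seg = F_a[lo : p + 1]
        nadir = lo + int(np.argmin(seg))
        nadirs.append(nadir)
        level = F_a[nadir] + cutoff * (F_a[p] - F_a[nadir])
        run = np.flatnonzero(F_a[nadir : p + 1] >= level)
        if run.size:
            start = nadir + int(run[0])
            suspended.update(range(start, p + 1))
    return CycleAnchors(
        transient_peak_frames=peaks,
        nadir_frames=nadirs,
        suspended_frames=frozenset(suspended),
    )


def _touches(cluster_pixels: frozenset, event_pixels: frozenset) -> bool:
    """Overlap or 4-adjacency between two pixel sets."""
    for (y, x) in cluster_pixels:
        if (y, x) in event_pixels:
            return True
        if (
            (y - 1, x) in event_pixels
            or (y + 1, x) in event_pixels
            or (y, x - 1) in event_pixels
            or (y, x + 1) in event_pixels
        ):
            return True
    return False


def update_events(
    t: int,
    clusters: list[Cluster],
    active: list[LCREvent],
    next_id: int,
) -> tuple[list[LCREvent], int]:
    """Advance all live events to frame ``t`` and create births.

    Association is by overlap/4-adjacency between each cluster and each
    event's frame ``t-1`` footprint.  Clusters and events connected
    through shared associations form groups: a group with one event is
    a continuation (possibly a split — several clusters, one identity);
    a group with several events is a collision resolved in favor of the
    event with the most ``t-1`` pixels (ties to the lower id), which
    absorbs every cluster in the group.  Events with no cluster carry
    their previous footprint forward.  Remaining birth-eligible clusters
    found new events.  Returns ``(new_events, next_id)``.
    """
    prev = {e.id: e.pixels_by_frame[t - 1] for e in active}
    # cluster index -> touching event ids
    links: list[list[int]] = []
    for c in clusters:
        touching = [e.id for e in active if _touches(c.pixels, prev[e.id])]
        links.append(touching)

    # union-find over events via shared clusters
    parent: dict[int, int] = {e.id: e.id for e in active}

    def root(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for touching in links:
        for a, b in zip(touching, touching[1:]):
            parent[root(a)] = root(b)

    groups: dict[int, dict] = {}
    for e in active:
        groups.setdefault(root(e.id), {"events": [], "clusters": []})["events"].append(e)
    for c, touching in zip(clusters, links):
        if touching:
            groups[root(touching[0])]["clusters"].append(c)

    births: list[LCREvent] = []
    for g in groups.values():
        events = g["events"]
        cls = g["clusters"]
        union: set = set()
        for c in cls:
            union |= c.pixels
        survivor = max(events, key=lambda e: (len(prev[e.id]), -e.id))
        for e in events:
            if e is survivor:
                e.pixels_by_frame[t] = frozenset(union) if union else prev[e.id]
            else:
                # dead by collision: final footprint is the pre-collision one
                e.pixels_by_frame[t] = prev[e.id]
                e.death_frame = t
                e.death_mode = "collision"

    for c, touching in zip(clusters, links):
        if not touching and c.birth_eligible:
            ev = LCREvent(id=next_id, birth_frame=t, pixels_by_frame={t: c.pixels})
            next_id += 1
            births.append(ev)
    return births, next_id


def check_terminations(
    active: list[LCREvent],
    F_nt_frame: np.ndarray,
    sigma_fnt: float,
    sd_termination: float,
    anchors: CycleAnchors | None,
    t: int,
) -> None:
    """Apply transient and stochastic-attrition death rules at frame t.

    An event alive when ``t`` enters the suspended set dies by merging
    into the transient; otherwise it dies by stochastic attrition when
    the mean transient-free signal over its current pixels falls below
    ``sd_termination * sigma_fnt``, where ``sigma_fnt`` is the SD of
    the transient-free intensity over the whole cell — the noise scale
    of the signal this test examines.
    """
    suspended = anchors.suspended_frames if anchors is not None else frozenset()
    thr = sd_termination * sigma_fnt
    for e in active:
        if not e.alive:
            continue
        if t in suspended:
            e.death_frame = t
            e.death_mode = "transient"
            continue
        px = e.pixels_by_frame[t]
        ys = [p[0] for p in px]
        xs = [p[1] for p in px]
        if float(F_nt_frame[ys, xs].mean()) < thr:
            e.death_frame = t
            e.death_mode = "stochastic_attrition"


def _nadir_for_birth(anchors: CycleAnchors, birth: int) -> float:
    """Nadir of the cycle (inter-peak interval) containing the birth frame."""
    peaks = anchors.transient_peak_frames
    nadirs = anchors.nadir_frames
    for j, p in enumerate(peaks):
        prev_peak = peaks[j - 1] if j > 0 else -1
        if prev_peak < birth <= p:
            return float(nadirs[j])
    # birth after the last peak: that cycle has no following nadir
    return math.nan


def _preceding_peak(anchors: CycleAnchors, birth: int) -> float:
    peaks = [p for p in anchors.transient_peak_frames if p <= birth]
    return float(peaks[-1]) if peaks else math.nan


def finalize(
    events: list[LCREvent],
    anchors: CycleAnchors | None,
    F_nt: np.ndarray,
    n_frames: int,
) -> tuple[list[LCRRecord], np.ndarray]:
    """Compute the output parameters of every event and the ensemble trace.

    The ensemble trace is the per-frame sum of all individual event
    traces (area in pixels).  ``half_max_amplitude`` is half the
    lifetime maximum of the per-frame peak transient-free intensity over
    the event's pixels, on the 0-255 gray scale.  Cycle-relative timing
    (``birth_from_nadir``, ``lcr_cycle``) is NaN when no transient
    anchors exist (e.g. permeabilized cells).
    """
    records: list[LCRRecord] = []
    ensemble = np.zeros(n_frames)
    for e in sorted(events, key=lambda ev: ev.id):
        frames = sorted(e.pixels_by_frame)
        last = e.death_frame if e.death_frame is not None else frames[-1]
        path = e.path_pixels
        ys = [p[0] for p in path]
        xs = [p[1] for p in path]
        trace = {f: len(e.pixels_by_frame[f]) for f in frames}
        for f, a in trace.items():
            ensemble[f] += a
        amp = 0.0
        for f in frames:
            px = e.pixels_by_frame[f]
            fy = [p[0] for p in px]
            fx = [p[1] for p in px]
            amp = max(amp, float(F_nt[f, fy, fx].max()))
        dead = e.death_frame is not None
        if anchors is not None:
            nadir = _nadir_for_birth(anchors, e.birth_frame)
            birth_from_nadir = e.birth_frame - nadir
            peak = _preceding_peak(anchors, e.birth_frame)
            lcr_cycle = e.birth_frame - peak
        else:
            birth_from_nadir = math.nan
            lcr_cycle = math.nan
        records.append(
            LCRRecord(
                id=e.id,
                max_x=int(max(xs)),
                min_x=int(min(xs)),
                max_y=int(max(ys)),
                min_y=int(min(ys)),
                start_area_px=len(e.pixels_by_frame[e.birth_frame]),
                max_area_px=max(trace.values()),
                path_area_px=len(path),
                birth_from_nadir_frames=birth_from_nadir,
                lcr_cycle_frames=lcr_cycle,
                birth_from_start_frames=e.birth_frame,
                duration_frames=last - e.birth_frame + 1,
                half_max_amplitude=0.5 * amp,
                dead=dead,
                dead_by_collision=e.death_mode == "collision",
                dead_by_transient=e.death_mode == "transient",
                dead_by_stochastic_attrition=e.death_mode == "stochastic_attrition",
                trace=trace,
            )
        )
    return records, ensemble


def hotspot_map(events: list[LCREvent], shape: tuple[int, int]) -> np.ndarray:
    """Per-pixel count of events whose path ever covered the pixel."""
    out = np.zeros(shape, dtype=np.intp)
    for e in events:
        for (y, x) in e.path_pixels:
            out[y, x] += 1
    return out


def run_detector(
    stack: ImageStack,
    config: RunConfig,
    mask: CellMask | None = None,
    norm_bounds: tuple[float, float] | None = None,
) -> DetectionResult:
    """Full detection pipeline on a stabilized stack.

    Conditions the stack, derives cycle anchors from the whole-cell
    trace when transients are present, then per frame extracts candidate
    clusters, advances event identities, and applies the death rules.
    ``norm_bounds`` optionally pins the normalization anchors (see
    :func:`~lcrtrack.lcr_detection.normalize`).
    """
    cond = condition_stack(stack, config, mask, norm_bounds)
    anchors = cycle_anchors(cond.F_a, config.transient_cutoff_percent) if config.transients_present else None
    suspended = anchors.suspended_frames if anchors is not None else frozenset()
    # both thresholds are factors of the SD of the conditioned signal in
    # the cell: a pixel joins a candidate event when its differential
    # signal exceeds sd_detection of that scale, and an event dies when
    # its mean signal falls below sd_termination of it
    cand = candidacy(cond.D, cond.sigma_fnt, config.sd_detection, suspended, cond.mask)

    events: list[LCREvent] = []
    next_id = 0
    T = stack.n_frames
    for t in range(1, T):
        clusters = find_clusters(
            cand[t], cond.D[t], config.size_threshold, config.intensity_threshold
        )
        active = [e for e in events if e.alive and (t - 1) in e.pixels_by_frame]
        births, next_id = update_events(t, clusters, active, next_id)
        events.extend(births)
        live_now = [e for e in events if e.alive and t in e.pixels_by_frame]
        check_terminations(live_now, cond.F_nt[t], cond.sigma_fnt, config.sd_termination, anchors, t)
    records, ensemble = finalize(events, anchors, cond.F_nt, T)
    return DetectionResult(
        records=records,
        events=events,
        anchors=anchors,
        conditioned=cond,
        ensemble_trace=ensemble,
        config=config,
    )
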