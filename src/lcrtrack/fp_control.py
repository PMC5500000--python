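"""False-positive rate estimation from an off-cell control substack.

A control rectangle placed far from the cell contains instrumental
noise but no genuine release events.  Running the identical detection
procedure on that substack (treating the rectangle as the "cell area")
and normalizing event counts by area bounds the spurious detection
rate:

    fp_rate% = 100 * (control_events / control_area) * cell_area / cell_events

The rate is 0 when neither region yields events; a control detection
with zero cell detections yields an infinite rate (the report is then
dominated by noise and the thresholds need retuning).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

from .event_tracking import run_detector
from .lcr_detection import CellMask, max_filter_mask
from .stack_io import ImageStack, RunConfig

__all__ = ["FalsePositiveReport", "false_positive_rate"]


@dataclass
class FalsePositiveReport:
    control_events: int
    cell_events: int
    control_area_px: int
    cell_area_px: int
    fp_rate_percent: float


def false_positive_rate(
    stack: ImageStack,
    control_region: tuple[int, int, int, int],
    config: RunConfig,
) -> FalsePositiveReport:
    """Run the detector on the cell and on an off-cell control region.

    ``control_region`` is an ``(x, y, w, h)`` rectangle that must be
    disjoint from the cell mask.  The control substack is cropped and
    analyzed with the whole rectangle as its "cell area", using the
    identical parameter set *and the cell run's normalization anchors*:
    re-anchoring the 0-255 rescale to the control's own noise floor
    would stretch pure noise to full scale and change what the absolute
    size/intensity thresholds mean, so both regions are expressed in
    the cell's intensity units to make the event counts commensurate.
    Transients are not assumed in the control region (it is off the
    cell, so the whole-cell Ca2+ rise does not reach it).
    """
    x, y, w, h = control_region
    _, H, W = stack.shape
    if w <= 0 or h <= 0:
        raise ValueError("control region must have positive area")
    if x < 0 or y < 0 or x + w > W or y + h > H:
        raise ValueError("control region lies outside frame bounds")

    cell_mask = max_filter_mask(stack)
    if cell_mask.mask[y : y + h, x : x + w].any():
        raise ValueError("control region overlaps the cell mask")

    cell_result = run_detector(stack, config, mask=cell_mask)
    cell_events = len(cell_result.records)
    cell_vals = stack.frames[:, cell_mask.mask]
    norm_bounds = (float(cell_vals.min()), float(cell_vals.max()))

    sub = ImageStack(
        stack.frames[:, y : y + h, x : x + w].copy(),
        stack.pixel_size_um,
        stack.frame_interval_ms,
    )
    control_mask = CellMask(mask=np.ones((h, w), dtype=bool), area_px=h * w)
    control_config = dataclasses.replace(config, transients_present=False)
    control_result = run_detector(sub, control_config, mask=control_mask, norm_bounds=norm_bounds)
    control_events = len(control_result.records)

    if cell_events == 0:
        rate = 0.0 if control_events == 0 else math.inf
    else:
        rate = 100.0 * (control_events / (h * w)) * cell_mask.area_px / cell_events
    return FalsePositiveReport(
        control_events=control_events,
        cell_events=cell_events,
        control_area_px=h * w,
        cell_area_px=cell_mask.area_px,
        fp_rate_percent=rate,
    )
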