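"""Image-stack and tabular I/O, acquisition metadata, and run configuration.

Conventions used throughout the package: 0-based indices everywhere;
``x`` is the column coordinate (increasing rightward), ``y`` the row
coordinate (increasing downward); frames are indexed 0-based in
acquisition order.  Pixel size and frame interval always come from the
run configuration, never from TIFF tags: cameras and binning vary and an
explicit value beats a guessed one.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "ImageStack",
    "RunConfig",
    "EVENT_COLUMNS",
    "read_stack",
    "write_stack",
    "write_event_table",
    "read_event_table",
    "write_config_audit",
]

#: Fixed column set (and order) of the per-event output table.
EVENT_COLUMNS = [
    "id",
    "max_x",
    "min_x",
    "max_y",
    "min_y",
    "start_area_px",
    "max_area_px",
    "path_area_px",
    "birth_from_nadir_frames",
    "lcr_cycle_frames",
    "birth_from_start_frames",
    "duration_frames",
    "half_max_amplitude",
    "dead",
    "dead_by_collision",
    "dead_by_transient",
    "dead_by_stochastic_attrition",
]


@dataclass
class ImageStack:
    """A T x H x W grayscale movie with acquisition metadata.

    Parameters
    ----------
    frames
        Non-negative intensities, shape ``(T, H, W)``, arbitrary units.
    pixel_size_um
        Physical pixel side length in micrometres.
    frame_interval_ms
        Time between consecutive frames in milliseconds.
    """

    frames: np.ndarray
    pixel_size_um: float
    frame_interval_ms: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be T x H x W, got shape {self.frames.shape}")
        t, h, w = self.frames.shape
        if t < 2:
            raise ValueError("stack must have >=2 frames")
        if h < 8 or w < 8:
            raise ValueError("frame dimensions must be >=8 pixels on each side")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("intensities must be finite")
        if self.frames.min() < 0:
            raise ValueError("intensities must be non-negative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.frame_interval_ms <= 0:
            raise ValueError("frame_interval_ms must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape


@dataclass
class RunConfig:
    """All user-settable parameters of the pipeline.

    The detection parameters mirror the fields a user of the original
    interactive tools would set: the spatial averaging half-width of the
    differential filter, detection/termination thresholds in units of
    the cell-wide signal SD, the transient cut-off, the minimum size and
    integrated brightness of a newborn release event, and the optional
    despeckle filters.  Stabilization parameters cover the triangle
    height of the warping mesh, the contraction match threshold, and the
    Savitzky-Golay window/order used for curvature estimation.
    """

    search_distance: int = 3
    sd_detection: float = 1.0
    sd_termination: float = 1.0
    transient_cutoff_percent: float = 20.0
    size_threshold: int = 8
    intensity_threshold: float = 60.0
    median_filter: bool = False
    mean_filter: bool = False
    transients_present: bool = True
    triangle_height: float = 24.0
    match_threshold: float = 20.0
    sg_window: int = 11
    sg_order: int = 3
    pixel_size_um: float = 0.2539
    frame_interval_ms: float = 10.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if int(self.search_distance) != self.search_distance or self.search_distance < 1:
            raise ValueError("search_distance must be an integer >= 1")
        if self.sd_detection <= 0:
            raise ValueError("sd_detection must be positive")
        if self.sd_termination <= 0:
            raise ValueError("sd_termination must be positive")
        if not 0.0 <= self.transient_cutoff_percent <= 100.0:
            raise ValueError("transient_cutoff_percent must lie in [0, 100]")
        if int(self.size_threshold) != self.size_threshold or self.size_threshold < 1:
            raise ValueError("size_threshold must be an integer >= 1 pixel")
        if self.intensity_threshold < 0:
            raise ValueError("intensity_threshold must be non-negative")
        if self.triangle_height <= 0:
            raise ValueError("triangle_height must be positive")
        if self.match_threshold <= 0:
            raise ValueError("match_threshold must be positive")
        if self.sg_window % 2 != 1 or self.sg_window < 3:
            raise ValueError("sg_window must be an odd integer >= 3")
        if self.sg_order < 1 or self.sg_order >= self.sg_window:
            raise ValueError("sg_order must satisfy 1 <= sg_order < sg_window")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.frame_interval_ms <= 0:
            raise ValueError("frame_interval_ms must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def read_stack(path: str | Path, pixel_size_um: float, frame_interval_ms: float) -> ImageStack:
    """Read a multi-page grayscale TIFF into an :class:`ImageStack`.

    Metadata (pixel size, frame interval) is supplied by the caller, not
    read from TIFF tags.  RGB and single-page inputs are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frames = tifffile.imread(str(path))
    frames = np.asarray(frames)
    if frames.ndim == 2:
        raise ValueError("stack must have >=2 frames (single-page TIFF)")
    if frames.ndim != 3:
        raise ValueError(
            f"expected a multi-page grayscale TIFF (T x H x W); got shape {frames.shape} "
            "(RGB or multi-channel input is not supported)"
        )
    return ImageStack(frames.astype(np.float64), pixel_size_um, frame_interval_ms)


def write_stack(stack: ImageStack, path: str | Path, bit_depth: int = 16) -> None:
    """Write a stack as a multi-page TIFF at the declared bit depth.

    Values outside the representable range are clipped; the number of
    clipped samples is logged so that lossy writes are visible.
    """
    if bit_depth == 8:
        dtype, vmax = np.uint8, 255
    elif bit_depth == 16:
        dtype, vmax = np.uint16, 65535
    else:
        raise ValueError("bit_depth must be 8 or 16")
    frames = stack.frames
    n_clipped = int(np.count_nonzero((frames < 0) | (frames > vmax)))
    if n_clipped:
        logger.warning(
            "write_stack: %d sample(s) clipped to [0, %d] for %d-bit output",
            n_clipped,
            vmax,
            bit_depth,
        )
    out = np.clip(np.rint(frames), 0, vmax).astype(dtype)
    tifffile.imwrite(str(path), out, photometric="minisblack")


def _record_row(rec) -> dict:
    get = (lambda k: rec[k]) if isinstance(rec, dict) else (lambda k: getattr(rec, k))
    return {col: get(col) for col in EVENT_COLUMNS}


def write_event_table(records: Sequence, path: str | Path, traces_path: str | Path | None = None) -> None:
    """Write the per-event parameter table (one row per release event).

    ``records`` may be dataclasses or dicts exposing the
    :data:`EVENT_COLUMNS` fields plus, optionally, a ``trace`` mapping
    frame -> area used for the companion size-vs-frame file.  Booleans
    are serialized as ``true``/``false`` literals.  An empty record list
    yields a header-only CSV.
    """
    rows = [_record_row(r) for r in records]
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    for col in ("dead", "dead_by_collision", "dead_by_transient", "dead_by_stochastic_attrition"):
        df[col] = df[col].map(lambda v: "true" if bool(v) else "false")
    df.to_csv(path, index=False)

    if traces_path is not None:
        trace_rows = []
        for rec in records:
            trace = rec["trace"] if isinstance(rec, dict) else getattr(rec, "trace", None)
            rid = rec["id"] if isinstance(rec, dict) else rec.id
            if trace is None:
                continue
            for frame, area in sorted(trace.items()):
                trace_rows.append({"id": rid, "frame": frame, "area_px": area})
        pd.DataFrame(trace_rows, columns=["id", "frame", "area_px"]).to_csv(traces_path, index=False)


def read_event_table(path: str | Path) -> pd.DataFrame:
    """Read back an event table, re-parsing boolean literals."""
    df = pd.read_csv(path)
    for col in ("dead", "dead_by_collision", "dead_by_transient", "dead_by_stochastic_attrition"):
        if col in df.columns and len(df):
            df[col] = df[col].map({"true": True, "false": False, True: True, False: False})
    return df


def write_config_audit(config: RunConfig, out_dir: str | Path, name: str = "resolved_config.yaml") -> Path:
    """Write an audit copy of the fully resolved parameters next to outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / name
    config.to_yaml(path)
    return path
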