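"""Reading canalogram stacks and writing tabular reports.

A canalogram is a time-lapse of fluorescein filling the perilimbal
outflow vessels: one grayscale frame every ``frame_interval_s`` seconds
(30 s over 20 min in the reference acquisition, binned to 580x610).
Stacks arrive either as a multi-page TIFF or as a directory / glob of
same-shaped single images in lexicographic frame order.
"""

from __future__ import annotations

import glob as _glob
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

DEFAULT_FRAME_INTERVAL_S = 30.0


@dataclass
class CanalogramStack:
    """Raw time x row x col fluorescence stack with acquisition metadata.

    Frame ``i`` is at time ``t0_s + i * frame_interval_s``; timestamps are
    synthesized from the fixed cadence, never read from file metadata.
    """

    frames: np.ndarray
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S
    t0_s: float = 0.0
    laterality: str = "OD"
    source: str = ""
    bit_depth: int = 16

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3-D (time, row, col) array")
        if self.frames.shape[0] < 2:
            raise ValueError("a canalogram needs at least 2 frames")
        if self.frames.min() < 0:
            raise ValueError("fluorescence intensities must be non-negative")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.laterality not in ("OD", "OS"):
            raise ValueError("laterality must be 'OD' or 'OS'")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + self.frame_interval_s * np.arange(self.n_frames)

    @property
    def duration_s(self) -> float:
        return float(self.times_s[-1] - self.times_s[0])


def _to_gray(frame: np.ndarray) -> np.ndarray:
    """Average RGB(A) channels; the reference camera was monochrome."""
    if frame.ndim == 3:
        return frame[..., :3].mean(axis=-1)
    return frame


def _read_single(path: str) -> np.ndarray:
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        return _to_gray(tifffile.imread(path))
    import imageio.v3 as iio
    return _to_gray(np.asarray(iio.imread(path)))


def load_stack(path: str | Path, frame_interval_s: float | None = None,
               laterality: str = "OD", t0_s: float = 0.0) -> CanalogramStack:
    """Load a canalogram from a multi-page TIFF, a directory, or a glob.

    Frames are taken in page order (TIFF) or lexicographic filename order
    (series); mixed frame shapes raise ``inconsistent frame geometry``.
    When ``frame_interval_s`` is omitted the reference cadence of 30 s is
    assumed with a logged warning.
    """
    if frame_interval_s is None:
        logger.warning("frame interval not given; assuming %.0f s cadence",
                       DEFAULT_FRAME_INTERVAL_S)
        frame_interval_s = DEFAULT_FRAME_INTERVAL_S

    path = str(path)
    if os.path.isdir(path):
        files = sorted(
            os.path.join(path, f) for f in os.listdir(path)
            if f.lower().endswith((".tif", ".tiff", ".png"))
        )
    elif any(ch in path for ch in "*?["):
        files = sorted(_glob.glob(path))
    else:
        files = None

    if files is not None:
        if len(files) < 2:
            raise ValueError("a canalogram needs at least 2 frames")
        frames = [_read_single(f) for f in files]
        shapes = {f.shape for f in frames}
        if len(shapes) > 1:
            raise ValueError("inconsistent frame geometry: " +
                             ", ".join(sorted(map(str, shapes))))
        arr = np.stack(frames)
        src = path
    else:
        raw = tifffile.imread(path)
        raw = np.asarray(raw)
        if raw.ndim == 2:
            raise ValueError("a canalogram needs at least 2 frames")
        if raw.ndim == 4:  # multi-page RGB
            raw = raw[..., :3].mean(axis=-1)
        arr = raw
        src = path

    bit_depth = 16 if arr.dtype.itemsize > 1 else 8
    return CanalogramStack(frames=arr.astype(np.float64),
                           frame_interval_s=float(frame_interval_s),
                           t0_s=t0_s, laterality=laterality, source=src,
                           bit_depth=bit_depth)


def save_stack(stack: CanalogramStack, path: str | Path) -> None:
    """Write the stack as a multi-page TIFF (uint16)."""
    data = np.clip(np.round(stack.frames), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), data)


def write_report(report, fits, path: str | Path) -> dict[str, Path]:
    """Write the per-macropixel, per-quadrant and per-region CSVs.

    ``report`` is a :class:`~canaloflow.flow.FlowReport`; ``fits`` the
    fit collection from the same stack.  Excluded macropixels appear as
    rows with ``excluded=True`` and empty kinetics fields.  Returns the
    paths written, keyed 'macropixels', 'quadrants', 'regions'.
    """
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)

    fit_df = fits.to_frame()
    mp = report.per_macropixel.merge(
        fit_df[["grid_row", "grid_col", "I_max", "t_half_s", "filling_rate",
                "baseline", "rss", "edf"]],
        on=["grid_row", "grid_col"], how="left")
    mp = mp.rename(columns={"grid_row": "row", "grid_col": "col",
                            "filling_rate": "rate"})
    excl = ~mp["included"].astype(bool)
    mp["excluded"] = excl
    kinetic_cols = ["I_max", "t_half_s", "rate", "baseline",
                    "flow_increment", "flow_ul_min"]
    for c in kinetic_cols:
        if c in mp.columns:
            mp.loc[excl, c] = np.nan
    cols = ["row", "col", "excluded", "quadrant", "clock_hour", "ring",
            "filling", "I_max", "t_half_s", "rate",
            "flow_increment", "flow_ul_min"]
    mp_path = outdir / "macropixels.csv"
    mp[[c for c in cols if c in mp.columns]].to_csv(mp_path, index=False)

    q_path = outdir / "quadrants.csv"
    report.per_quadrant.to_csv(q_path, index=False)

    out = {"macropixels": mp_path, "quadrants": q_path}
    if report.region_table is not None:
        r_path = outdir / "regions.csv"
        report.region_table.to_csv(r_path, index=False)
        out["regions"] = r_path
    return out
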