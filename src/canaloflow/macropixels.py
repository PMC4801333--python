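"""Reduction of full-resolution stacks to a coarse macropixel grid.

Image rows and columns are partitioned into contiguous blocks whose
sizes differ by at most one pixel (the larger blocks come first when the
dimension is not divisible); each macropixel value is the arithmetic
mean of its block, per frame.  The default 32x32 grid yields 1024
macropixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def block_edges(n: int, g: int) -> np.ndarray:
    """Start indices (length g+1, ending at n) of g contiguous blocks of
    size floor(n/g) or ceil(n/g), larger blocks first."""
    if g > n:
        raise ValueError(f"grid dimension {g} exceeds image dimension {n}")
    q, rem = divmod(n, g)
    sizes = np.full(g, q)
    sizes[:rem] += 1
    return np.concatenate([[0], np.cumsum(sizes)])


@dataclass
class MacropixelSeries:
    """time x grid_rows x grid_cols block-mean intensities.

    ``centers_px[r, c]`` is the (row, col) centroid of block (r, c) in
    image-pixel coordinates; ``block_map`` maps each image pixel to its
    macropixel; ``percent`` records whether intensities have been
    normalized to percent of the global maximum.
    """

    intensity: np.ndarray
    row_edges: np.ndarray
    col_edges: np.ndarray
    frame_interval_s: float
    t0_s: float = 0.0
    laterality: str = "OD"
    percent: bool = False
    normalization_max: float | None = None
    centers_px: np.ndarray = field(init=False)

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be time x rows x cols")
        rc = (self.row_edges[:-1] + self.row_edges[1:] - 1) / 2.0
        cc = (self.col_edges[:-1] + self.col_edges[1:] - 1) / 2.0
        self.centers_px = np.stack(np.meshgrid(rc, cc, indexing="ij"), axis=-1)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.intensity.shape[1:]

    @property
    def n_macropixels(self) -> int:
        r, c = self.grid_shape
        return r * c

    @property
    def n_frames(self) -> int:
        return self.intensity.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + self.frame_interval_s * np.arange(self.n_frames)

    @property
    def image_shape(self) -> tuple[int, int]:
        return int(self.row_edges[-1]), int(self.col_edges[-1])

    @property
    def block_sizes(self) -> np.ndarray:
        """Pixel count of each block (grid_rows x grid_cols)."""
        rs = np.diff(self.row_edges)
        cs = np.diff(self.col_edges)
        return np.outer(rs, cs)

    @property
    def block_map(self) -> np.ndarray:
        """(image_rows, image_cols, 2) map of each pixel to its macropixel."""
        rows, cols = self.image_shape
        rmap = np.searchsorted(self.row_edges, np.arange(rows), side="right") - 1
        cmap = np.searchsorted(self.col_edges, np.arange(cols), side="right") - 1
        return np.stack(np.meshgrid(rmap, cmap, indexing="ij"), axis=-1)


def downsample(stack, grid_rows: int = 32, grid_cols: int = 32) -> MacropixelSeries:
    """Block-mean the stack onto a grid_rows x grid_cols macropixel grid."""
    t, rows, cols = stack.frames.shape
    re = block_edges(rows, grid_rows)
    ce = block_edges(cols, grid_cols)
    # two reduceat passes = block sums; divide by block areas for means
    sums = np.add.reduceat(stack.frames, re[:-1], axis=1)
    sums = np.add.reduceat(sums, ce[:-1], axis=2)
    areas = np.outer(np.diff(re), np.diff(ce))
    means = sums / areas[None, :, :]
    return MacropixelSeries(intensity=means, row_edges=re, col_edges=ce,
                            frame_interval_s=stack.frame_interval_s,
                            t0_s=stack.t0_s, laterality=stack.laterality)


def normalize_percent(series: MacropixelSeries) -> MacropixelSeries:
    """Rescale so the brightest macropixel observation over the whole
    stack maps to 100 percent; output values lie in [0, 100]."""
    gmax = float(series.intensity.max())
    if gmax <= 0:
        raise ValueError("no signal: all macropixel intensities are zero")
    return MacropixelSeries(intensity=series.intensity * (100.0 / gmax),
                            row_edges=series.row_edges,
                            col_edges=series.col_edges,
                            frame_interval_s=series.frame_interval_s,
                            t0_s=series.t0_s, laterality=series.laterality,
                            percent=True, normalization_max=gmax)
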