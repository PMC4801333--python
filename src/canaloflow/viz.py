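"""Dot plots, ring plots and time-lapse montages.

The dot plot shows one marker per included, filling macropixel: marker
*area* grows with the fitted maximum intensity and marker color runs
blue -> red with increasing filling rate, so bright early-filling
vessels appear as large red dots.  The ring plot shows the 36-region
global model as 12 x 3 annular sectors colored by half-max time and by
filling rate.  Figures are rotated only for display; analysis
coordinates are never rotated.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import Wedge

_MIN_AREA, _MAX_AREA = 4.0, 220.0   # marker areas (pt^2) for legibility


@dataclass
class DotPlotSpec:
    """Backend-independent dot-plot encoding, one entry per drawn marker."""

    grid_row: np.ndarray
    grid_col: np.ndarray
    marker_area: np.ndarray   # strictly increasing in I_max
    color_value: np.ndarray   # in [0,1]; redness strictly increasing in rate
    I_max: np.ndarray
    rate: np.ndarray
    cmap: str = "coolwarm"

    def colors(self) -> np.ndarray:
        return plt.get_cmap(self.cmap)(self.color_value)


def dot_plot_spec(fits, assignment=None) -> DotPlotSpec:
    """Marker encodings for every included, filling macropixel."""
    rows, cols, imax, rate = [], [], [], []
    for f in fits:
        if not (f.included and f.filling):
            continue
        if not (np.isfinite(f.I_max) and np.isfinite(f.filling_rate)):
            continue
        rows.append(f.grid_row)
        cols.append(f.grid_col)
        imax.append(f.I_max)
        rate.append(f.filling_rate)
    rows = np.asarray(rows)
    cols = np.asarray(cols)
    imax = np.asarray(imax, dtype=float)
    rate = np.asarray(rate, dtype=float)
    if imax.size:
        lo, hi = imax.min(), imax.max()
        span = hi - lo if hi > lo else 1.0
        area = _MIN_AREA + (_MAX_AREA - _MIN_AREA) * (imax - lo) / span
        rlo, rhi = rate.min(), rate.max()
        rspan = rhi - rlo if rhi > rlo else 1.0
        cval = (rate - rlo) / rspan
    else:
        area = np.empty(0)
        cval = np.empty(0)
    return DotPlotSpec(grid_row=rows, grid_col=cols, marker_area=area,
                       color_value=cval, I_max=imax, rate=rate)


def dot_plot(fits, assignment=None, ax=None):
    """Render the dot plot; returns (DotPlotSpec, figure)."""
    spec = dot_plot_spec(fits, assignment)
    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 6))
    else:
        fig = ax.figure
    if spec.grid_row.size:
        ax.scatter(spec.grid_col, spec.grid_row, s=spec.marker_area,
                   c=spec.color_value, cmap=spec.cmap, vmin=0, vmax=1,
                   edgecolors="none")
    gr = max(fits.grid_shape)
    ax.set_xlim(-1, fits.grid_shape[1])
    ax.set_ylim(fits.grid_shape[0], -1)   # image convention: row 0 on top
    ax.set_aspect("equal")
    ax.set_xlabel("macropixel column")
    ax.set_ylabel("macropixel row")
    ax.set_title("fill kinetics (size: I_max, color: rate)")
    return spec, fig


def ring_plot(regional_fit, fig=None):
    """36-sector annulus panels colored by t_half and by filling rate.

    Empty regions are drawn hatched.  Hour 12 is at the top and hours
    advance clockwise, matching the charting convention.
    """
    tab = regional_fit.region_table
    if fig is None:
        fig, axes = plt.subplots(1, 2, figsize=(11, 5.5))
    else:
        axes = fig.subplots(1, 2)
    panels = [("t_half_s", "half-max time (s)", "coolwarm_r"),
              ("filling_rate", "filling rate (%/s)", "coolwarm")]
    for ax, (col, title, cmap) in zip(axes, panels):
        vals = tab[col].to_numpy(dtype=float)
        finite = np.isfinite(vals)
        vmin = vals[finite].min() if finite.any() else 0.0
        vmax = vals[finite].max() if finite.any() else 1.0
        span = vmax - vmin if vmax > vmin else 1.0
        cm = plt.get_cmap(cmap)
        n_drawn = 0
        for _, row in tab.iterrows():
            h, r = int(row["clock_hour"]), int(row["ring"])
            # hour h sector spans [h*30-15, h*30+15) clockwise from 12
            # o'clock; matplotlib wedges are counterclockwise from +x
            theta_mid = 90.0 - (h % 12) * 30.0
            r_in, r_out = 0.4 + (r - 1) * 0.2, 0.4 + r * 0.2
            if row["empty"] or not np.isfinite(row[col]):
                w = Wedge((0, 0), r_out, theta_mid - 15, theta_mid + 15,
                          width=r_out - r_in, facecolor="white",
                          edgecolor="gray", hatch="///")
            else:
                c = cm((row[col] - vmin) / span)
                w = Wedge((0, 0), r_out, theta_mid - 15, theta_mid + 15,
                          width=r_out - r_in, facecolor=c, edgecolor="gray",
                          linewidth=0.3)
            ax.add_patch(w)
            n_drawn += 1
        ax.set_xlim(-1.1, 1.1)
        ax.set_ylim(-1.1, 1.1)
        ax.set_aspect("equal")
        ax.axis("off")
        ax.set_title(title)
    return fig


def montage(stack, times_min, fig=None):
    """Row of frames nearest the requested times (minutes)."""
    duration_min = stack.duration_s / 60.0
    for t in times_min:
        if not 0 <= t <= duration_min:
            raise ValueError(
                f"time {t} min outside stack duration [0, {duration_min:g}] min")
    idx = [int(round(t * 60.0 / stack.frame_interval_s)) for t in times_min]
    if fig is None:
        fig, axes = plt.subplots(1, len(idx), figsize=(3 * len(idx), 3))
    else:
        axes = fig.subplots(1, len(idx))
    axes = np.atleast_1d(axes)
    vmax = stack.frames.max()
    for ax, i, t in zip(axes, idx, times_min):
        ax.imshow(stack.frames[i], cmap="gray", vmin=0, vmax=vmax)
        ax.set_title(f"{t:g} min")
        ax.axis("off")
    return fig
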