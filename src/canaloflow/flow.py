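"""Flow imputation, quadrant attribution and group comparison.

Per-macropixel flow is the fitted rise in percent fluorescence from the
first frame to the half-max time, divided by the number of frame
intervals in between — "percent fluorescence per frame".  The fitted
curve is the macropixel's region curve from the single global model
(``source='global'``, the default) or the macropixel's own individual
fit (``source='individual'``).  Increments are summed to a total; each
quadrant's share of that total is converted to microliters per minute
against a configurable whole-eye reference flow (default 3 ul/min, the
established bulk aqueous production), so quadrant flows always sum to
the reference — the method measures the *distribution* of outflow, not
its absolute magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import QUADRANTS

DEFAULT_TOTAL_FLOW_UL_MIN = 3.0
DEFAULT_ONSET_THRESHOLD_PCT = 5.0


@dataclass
class FlowReport:
    """Per-macropixel increments and per-quadrant flows for one eye."""

    per_macropixel: pd.DataFrame
    per_quadrant: pd.DataFrame
    total_flow_ul_min: float = DEFAULT_TOTAL_FLOW_UL_MIN
    eye_id: str = ""
    condition: str = ""
    region_table: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def quadrant_flows_ul_min(self) -> dict[str, float]:
        return dict(zip(self.per_quadrant["quadrant"],
                        self.per_quadrant["flow_ul_min"]))

    @property
    def quadrant_filling_times_min(self) -> dict[str, float]:
        return dict(zip(self.per_quadrant["quadrant"],
                        self.per_quadrant["filling_time_min"]))


def impute_flow(fits, regional=None, assignment=None,
                source: str = "global") -> np.ndarray:
    """Per-macropixel flow increments in percent fluorescence per frame.

    For each included, filling macropixel the increment is
    ``(F(t_half) - F(t_first)) / n_frame_intervals(t_first, t_half)``
    with F the region's global-fit curve (``source='global'``) or the
    macropixel's own fit (``source='individual'``); non-filling and
    excluded macropixels contribute 0.  A degenerate instantaneous fill
    (t_half == t_first) contributes 0.  Negative fitted rises are
    floored at 0.
    """
    if source not in ("global", "individual"):
        raise ValueError("source must be 'global' or 'individual'")
    if source == "global" and (regional is None or assignment is None):
        raise ValueError("source='global' needs the regional fit and assignment")

    gr, gc = fits.grid_shape
    times = fits.times_s
    t_first = float(times[0])
    interval = float(times[1] - times[0])
    inc = np.zeros((gr, gc))
    for f in fits:
        if not (f.included and f.filling):
            continue
        if source == "individual":
            curve, t_half = f.curve, f.t_half_s
        else:
            h = int(assignment.clock_hour[f.grid_row, f.grid_col])
            r = int(assignment.ring[f.grid_row, f.grid_col])
            if r not in regional.surfaces:
                continue
            row = regional.region_table
            sel = row[(row["clock_hour"] == h) & (row["ring"] == r)]
            t_half = float(sel["t_half_s"].iloc[0])
            curve = lambda t, _h=h, _r=r: regional.evaluate(_h, _r, t)
        if not np.isfinite(t_half) or t_half <= t_first:
            continue
        n_intervals = (t_half - t_first) / interval
        v_half = np.asarray(curve(t_half), dtype=float).reshape(-1)[0]
        v_first = np.asarray(curve(t_first), dtype=float).reshape(-1)[0]
        rise = v_half - v_first
        inc[f.grid_row, f.grid_col] = max(rise, 0.0) / n_intervals
    return inc


def quadrant_flows(increments: np.ndarray, assignment,
                   total_flow_ul_min: float = DEFAULT_TOTAL_FLOW_UL_MIN
                   ) -> pd.DataFrame:
    """Attribute the total imputed flow to quadrants, in ul/min.

    quadrant flow = total x (sum of increments in quadrant) / (sum of
    all increments); rows in fixed order IN, SN, ST, IT.
    """
    inc = np.asarray(increments, dtype=float)
    sums = {}
    for q in QUADRANTS:
        m = assignment.included & (assignment.quadrant == q)
        sums[q] = float(inc[m].sum())
    total = sum(sums.values())
    if total <= 0:
        raise ValueError("no detectable flow: all increments are zero")
    rows = [{"quadrant": q,
             "flow_fraction": sums[q] / total,
             "flow_ul_min": total_flow_ul_min * sums[q] / total}
            for q in QUADRANTS]
    return pd.DataFrame(rows)


def quadrant_filling_time(series, assignment,
                          onset_threshold: float = DEFAULT_ONSET_THRESHOLD_PCT
                          ) -> pd.DataFrame:
    """First-appearance filling time per quadrant, in minutes.

    Per quadrant: the earliest frame time at which any member macropixel
    exceeds its own first-frame baseline by ``onset_threshold`` percent
    of the global maximum; quadrants never crossing are censored at the
    stack end.
    """
    times = series.times_s
    gmax = float(series.intensity.max())
    delta = series.intensity - series.intensity[0][None, :, :]
    thresh = onset_threshold * gmax / 100.0
    rows = []
    for q in QUADRANTS:
        m = assignment.included & (assignment.quadrant == q)
        if not m.any():
            rows.append({"quadrant": q, "filling_time_min": np.nan,
                         "censored": True})
            continue
        crossed = (delta[:, m] > thresh).any(axis=1)
        idx = np.nonzero(crossed)[0]
        if idx.size:
            rows.append({"quadrant": q,
                         "filling_time_min": float(times[idx[0]] / 60.0),
                         "censored": False})
        else:
            rows.append({"quadrant": q,
                         "filling_time_min": float(times[-1] / 60.0),
                         "censored": True})
    return pd.DataFrame(rows)


def paired_compare(values_a, values_b) -> tuple[float, float]:
    """Two-sided paired t-test on matched per-eye metrics.

    Returns (t statistic, p value).  The zero-variance degenerate case
    (all differences identical) is reported as t=0, p=1 when the common
    difference is 0, else as an infinite t with p=0.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired samples must be matched with length >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), 0.0
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def build_report(series, assignment, fits, regional=None,
                 source: str = "global",
                 total_flow_ul_min: float = DEFAULT_TOTAL_FLOW_UL_MIN,
                 onset_threshold: float = DEFAULT_ONSET_THRESHOLD_PCT,
                 eye_id: str = "", condition: str = "") -> FlowReport:
    """Assemble the per-macropixel and per-quadrant flow tables."""
    inc = impute_flow(fits, regional=regional, assignment=assignment,
                      source=source)
    qf = quadrant_flows(inc, assignment, total_flow_ul_min)
    ft = quadrant_filling_time(series, assignment, onset_threshold)
    per_quadrant = qf.merge(ft, on="quadrant")
    per_quadrant.insert(0, "eye_id", eye_id)
    per_quadrant.insert(1, "condition", condition)

    gr, gc = fits.grid_shape
    rr, cc = np.meshgrid(np.arange(gr), np.arange(gc), indexing="ij")
    frac_map = np.zeros_like(inc)
    total_inc = inc.sum()
    if total_inc > 0:
        frac_map = inc / total_inc
    per_mp = pd.DataFrame({
        "grid_row": rr.ravel(), "grid_col": cc.ravel(),
        "included": assignment.included.ravel(),
        "quadrant": assignment.quadrant.ravel(),
        "clock_hour": assignment.clock_hour.ravel(),
        "ring": assignment.ring.ravel(),
        "filling": [f.filling for f in fits],
        "flow_increment": inc.ravel(),
        "flow_ul_min": (frac_map * total_flow_ul_min).ravel(),
    })
    region_table = None if regional is None else regional.region_table
    return FlowReport(per_macropixel=per_mp, per_quadrant=per_quadrant,
                      total_flow_ul_min=total_flow_ul_min, eye_id=eye_id,
                      condition=condition, region_table=region_table)
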