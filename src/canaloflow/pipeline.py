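"""End-to-end analysis: stack -> macropixels -> fits -> regions -> flows."""

from __future__ import annotations

from dataclasses import dataclass

from . import flow as flow_mod
from .flow import FlowReport, build_report
from .geometry import EyeGeometry, PolarAssignment, auto_outer_radius, build_mask
from .kinetics import FitCollection, fit_all, DEFAULT_NOISE_FLOOR_PCT
from .macropixels import MacropixelSeries, downsample, normalize_percent
from .regional import RegionalFit, RegionSeries, aggregate_regions, fit_global


@dataclass
class AnalysisResult:
    """Everything the pipeline computes for one canalogram."""

    series: MacropixelSeries       # percent-normalized macropixel series
    assignment: PolarAssignment
    fits: FitCollection
    regions: RegionSeries
    regional: RegionalFit
    report: FlowReport


def analyze_stack(stack, geometry: EyeGeometry, grid_rows: int = 32,
                  grid_cols: int = 32,
                  noise_floor: float = DEFAULT_NOISE_FLOOR_PCT,
                  source: str = "global",
                  total_flow_ul_min: float = flow_mod.DEFAULT_TOTAL_FLOW_UL_MIN,
                  onset_threshold: float | None = None,
                  eye_id: str = "", condition: str = "") -> AnalysisResult:
    """Run the full quantitative-canalography pipeline on one stack.

    Steps: block-mean downsampling to the macropixel grid, percent
    normalization against the global maximum, annulus masking and polar
    assignment, per-macropixel penalized-spline fits, the 36-region
    global smooth, flow imputation and quadrant attribution.
    """
    if geometry.outer_radius_px is None:
        geometry.outer_radius_px = auto_outer_radius(geometry, stack,
                                                     grid_rows=grid_rows)
    series = normalize_percent(downsample(stack, grid_rows, grid_cols))
    assignment = build_mask(geometry, series)
    fits = fit_all(series, assignment, noise_floor=noise_floor)
    regions = aggregate_regions(series, assignment)
    regional = fit_global(regions)
    report = build_report(
        series, assignment, fits, regional, source=source,
        total_flow_ul_min=total_flow_ul_min,
        onset_threshold=(noise_floor if onset_threshold is None
                         else onset_threshold),
        eye_id=eye_id, condition=condition)
    return AnalysisResult(series=series, assignment=assignment, fits=fits,
                          regions=regions, regional=regional, report=report)
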