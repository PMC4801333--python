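"""Per-eye geometry: corneal exclusion, perilimbal rings, clock hours,
quadrants.

The analysis region is the perilimbal annulus between the corneal disk
and an outer radius (the compression-ring inner edge in anterior-segment
cultures, or an automatic "complete ring" radius).  Macropixels inside
the annulus are assigned

* a clock hour 1-12: 30-degree sectors, hour 12 centered on the superior
  pole, advancing clockwise in the displayed image (ophthalmic charting
  convention);
* a perilimbal ring 1-3: three equal-radial-width sub-annuli, ring 1
  innermost — together 36 (hour, ring) regions;
* an anatomical quadrant IN / SN / ST / IT: the four 90-degree sectors
  bounded by the vertical and horizontal meridians, with the nasal side
  mirrored between right (OD, nasal = image left) and left (OS, nasal =
  image right) eyes.

Membership is by macropixel center point.  Ties: a radius exactly on a
ring boundary goes to the inner ring; an angle exactly on a meridian or
hour boundary goes to the clockwise-following sector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

QUADRANTS = ("IN", "SN", "ST", "IT")

# sector index (floor(theta/90), theta clockwise from superior) -> quadrant
_SECTOR_TO_QUADRANT = {
    "OD": {0: "ST", 1: "IT", 2: "IN", 3: "SN"},  # nasal = image left
    "OS": {0: "SN", 1: "IN", 2: "IT", 3: "ST"},  # nasal = image right
}


@dataclass
class EyeGeometry:
    """Corneal center/radius and outer analysis radius, in image pixels.

    ``superior_angle_deg`` is the displayed-image direction of the
    superior pole, measured clockwise from "up" (toward row 0); the
    default 0 means superior is up.
    """

    center_row: float
    center_col: float
    corneal_radius_px: float
    outer_radius_px: float | None = None
    superior_angle_deg: float = 0.0
    laterality: str = "OD"

    def __post_init__(self):
        if self.corneal_radius_px < 0:
            raise ValueError("corneal_radius_px must be >= 0")
        if self.outer_radius_px is not None and \
                self.outer_radius_px <= self.corneal_radius_px:
            raise ValueError("outer_radius_px must exceed corneal_radius_px")
        if self.laterality not in ("OD", "OS"):
            raise ValueError("laterality must be 'OD' or 'OS'")

    @classmethod
    def from_config(cls, path: str) -> "EyeGeometry":
        """Load geometry from a YAML/JSON config file."""
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        outer = cfg.get("outer_radius_px")
        if isinstance(outer, str) and outer.lower() == "auto":
            outer = None
        return cls(center_row=float(cfg["center_row"]),
                   center_col=float(cfg["center_col"]),
                   corneal_radius_px=float(cfg["corneal_radius_px"]),
                   outer_radius_px=None if outer is None else float(outer),
                   superior_angle_deg=float(cfg.get("superior_angle_deg", 0.0)),
                   laterality=cfg.get("laterality", "OD"))


@dataclass
class PolarAssignment:
    """Per-macropixel polar labels over a grid.

    All arrays have the grid shape.  ``clock_hour``/``ring``/``quadrant``
    are valid only where ``included``; excluded cells hold 0 / '' .
    """

    included: np.ndarray          # bool
    radius_px: np.ndarray         # float, distance of center from corneal center
    angle_deg: np.ndarray         # float, clockwise from superior pole, [0, 360)
    clock_hour: np.ndarray        # int 1..12 (0 where excluded)
    ring: np.ndarray              # int 1..3 (0 where excluded)
    quadrant: np.ndarray          # str 'IN','SN','ST','IT' ('' where excluded)
    geometry: EyeGeometry

    @property
    def n_included(self) -> int:
        return int(self.included.sum())

    def region_labels(self) -> set[tuple[int, int]]:
        """Distinct (clock_hour, ring) labels among included macropixels."""
        hrs = self.clock_hour[self.included]
        rng = self.ring[self.included]
        return set(zip(hrs.tolist(), rng.tolist()))


def image_angle_deg(d_row: np.ndarray, d_col: np.ndarray,
                    superior_angle_deg: float = 0.0) -> np.ndarray:
    """Polar angle measured from the superior pole, positive clockwise in
    the displayed image (row down, col right)."""
    phi = np.degrees(np.arctan2(d_col, -np.asarray(d_row, dtype=float)))
    return np.mod(phi - superior_angle_deg, 360.0)


def assign_quadrant(angle_deg, laterality: str = "OD"):
    """Quadrant label(s) for angle(s) measured clockwise from superior.

    The four quadrants are the meridian-bounded 90-degree sectors; an
    angle exactly on a meridian falls in the clockwise-following sector.
    """
    if laterality not in _SECTOR_TO_QUADRANT:
        raise ValueError("laterality must be 'OD' or 'OS'")
    ang = np.mod(np.asarray(angle_deg, dtype=float), 360.0)
    sector = np.floor_divide(ang, 90.0).astype(int) % 4
    lut = _SECTOR_TO_QUADRANT[laterality]
    labels = np.vectorize(lut.__getitem__, otypes=[object])(sector)
    if np.isscalar(angle_deg) or np.ndim(angle_deg) == 0:
        return str(labels[()])
    return labels.astype(str)


def assign_clock_hour(angle_deg) -> np.ndarray:
    """Clock hour 1-12; hour h spans [h*30-15, h*30+15) degrees so hour 12
    is centered on the superior pole."""
    ang = np.mod(np.asarray(angle_deg, dtype=float), 360.0)
    hour = (np.floor_divide(ang + 15.0, 30.0).astype(int)) % 12
    hour = np.where(hour == 0, 12, hour)
    if np.ndim(angle_deg) == 0:
        return int(hour[()])
    return hour


def build_mask(geometry: EyeGeometry, grid) -> PolarAssignment:
    """Assign every macropixel of ``grid`` its polar labels.

    A macropixel is included iff its center lies in the closed annulus
    [corneal_radius_px, outer_radius_px].  Rings are
    ceil(3 (r - r_c) / (r_o - r_c)) clamped to 1..3 (boundary radii go
    inward).  Raises ``incomplete ring`` if the outer circle leaves the
    image covered by the grid.
    """
    if geometry.outer_radius_px is None:
        raise ValueError("outer_radius_px unset; call auto_outer_radius first")
    rows_px, cols_px = grid.image_shape
    r_o = geometry.outer_radius_px
    if (geometry.center_row - r_o < -0.5 or geometry.center_col - r_o < -0.5
            or geometry.center_row + r_o > rows_px - 0.5
            or geometry.center_col + r_o > cols_px - 0.5):
        raise ValueError("incomplete ring: analysis circle exceeds image bounds")

    crow = grid.centers_px[..., 0] - geometry.center_row
    ccol = grid.centers_px[..., 1] - geometry.center_col
    radius = np.hypot(crow, ccol)
    angle = image_angle_deg(crow, ccol, geometry.superior_angle_deg)

    r_c = geometry.corneal_radius_px
    included = (radius >= r_c) & (radius <= r_o)

    frac = (radius - r_c) / (r_o - r_c)
    ring = np.ceil(3.0 * frac).astype(int)
    ring = np.clip(ring, 1, 3)
    ring = np.where(included, ring, 0)

    hour = np.where(included, assign_clock_hour(angle), 0)
    quad = np.where(included, assign_quadrant(angle, geometry.laterality), "")

    return PolarAssignment(included=included, radius_px=radius,
                           angle_deg=angle, clock_hour=hour, ring=ring,
                           quadrant=quad, geometry=geometry)


def auto_outer_radius(geometry: EyeGeometry, stack,
                      exclusion_mask: np.ndarray | None = None,
                      margin_px: float | None = None,
                      grid_rows: int = 32) -> float:
    """Largest outer radius forming a complete ring inside the image.

    The circle must fit within the image bounds (minus ``margin_px``,
    default half a macropixel block) and must not reach any pixel of the
    optional compression-ring ``exclusion_mask``.  Raises
    ``incomplete ring`` if no radius > corneal_radius_px remains.
    """
    rows, cols = stack.shape
    if margin_px is None:
        margin_px = max(rows, cols) / grid_rows / 2.0
    edge_limit = min(geometry.center_row, rows - geometry.center_row,
                     geometry.center_col, cols - geometry.center_col)
    r = edge_limit - margin_px
    if exclusion_mask is not None:
        er, ec = np.nonzero(exclusion_mask)
        if er.size:
            d = np.hypot(er - geometry.center_row, ec - geometry.center_col)
            r = min(r, float(d.min()) - 1.0)
    if r <= geometry.corneal_radius_px:
        raise ValueError("incomplete ring: no valid outer radius")
    return float(r)


def suggest_cornea(frame: np.ndarray) -> tuple[float, float, float]:
    """Propose a corneal (center_row, center_col, radius) from one frame.

    The cornea blocks fluorescence, so in a late frame it is the dark
    disk: Otsu-threshold the frame and take the centroid and equivalent
    radius of the dark region.  A convenience for drafting config files;
    never applied automatically.
    """
    from skimage.filters import threshold_otsu  # optional helper path

    thr = threshold_otsu(frame)
    dark = frame < thr
    rr, cc = np.nonzero(dark)
    if rr.size == 0:
        raise ValueError("no dark region found")
    radius = float(np.sqrt(rr.size / np.pi))
    return float(rr.mean()), float(cc.mean()), radius
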