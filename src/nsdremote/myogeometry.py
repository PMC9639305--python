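"""Myocardial sector geometry.

Builds the per-pixel circumferential/transmural coordinate system from
endocardial and epicardial contours, constructs rim-excluded sector ROIs,
enumerates admissible ROI positions and sizes inside the infarct-free arc,
and applies the per-slice inclusion filter.

Conventions (fixed so tests are portable):

* pixel centers sit at integer coordinates, images are indexed ``[y, x]``;
* a pixel belongs to a region iff its center lies inside the region's
  analytic boundary;
* circumferential angle ``theta`` is measured in degrees, counter-clockwise
  from the +x axis, about the epicardial contour centroid;
* transmural ``depth`` runs from 0 at the endocardium to 1 at the epicardium.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon

__all__ = [
    "Contour",
    "PolarMap",
    "ArcSet",
    "InclusionResult",
    "EmptyROIError",
    "circle_contour",
    "angular_distance",
    "rasterize_myocardium",
    "polar_parameterize",
    "sector_roi",
    "remote_arcs",
    "slice_includable",
    "candidate_positions",
    "candidate_sizes",
]


class EmptyROIError(ValueError):
    """Raised when a requested sector ROI contains no myocardial pixels."""

    def __init__(self, message: str, pixel_count: int = 0):
        super().__init__(message)
        self.pixel_count = pixel_count


@dataclass(frozen=True)
class Contour:
    """Closed simple polygon given as an ordered ``(N, 2)`` array of (x, y)."""

    vertices: np.ndarray

    def __post_init__(self):
        verts = np.asarray(self.vertices, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
            raise ValueError("contour needs an (N>=3, 2) vertex array")
        object.__setattr__(self, "vertices", verts)
        poly = Polygon(verts)
        if not poly.is_valid or not poly.is_simple:
            raise ValueError("contour polygon is self-intersecting or degenerate")

    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    def translated(self, dx: float, dy: float) -> "Contour":
        return Contour(self.vertices + np.array([dx, dy]))


def circle_contour(center: tuple[float, float], radius_px: float, n_vertices: int = 720) -> Contour:
    """Sample an exact circle as a dense polygon (CCW)."""
    if radius_px <= 0:
        raise ValueError("radius must be positive")
    ang = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    xs = center[0] + radius_px * np.cos(ang)
    ys = center[1] + radius_px * np.sin(ang)
    return Contour(np.column_stack([xs, ys]))


def angular_distance(a, b):
    """Smallest absolute angular separation in degrees, in [0, 180]."""
    return np.abs((np.asarray(a, dtype=float) - np.asarray(b, dtype=float) + 180.0) % 360.0 - 180.0)


@dataclass
class PolarMap:
    """Per-pixel circumferential angle and transmural depth over the myocardium.

    ``theta`` and ``depth`` are float grids carrying NaN outside the
    myocardium mask.
    """

    theta: np.ndarray
    depth: np.ndarray
    myo_mask: np.ndarray
    center: tuple[float, float]

    def __post_init__(self):
        m = self.myo_mask
        if np.isnan(self.theta[m]).any() or np.isnan(self.depth[m]).any():
            raise ValueError("polar coordinates undefined on myocardial pixels")


def rasterize_myocardium(endo: Contour, epi: Contour, grid_shape: tuple[int, int]) -> np.ndarray:
    """Boolean myocardium mask: pixel centers inside epi and outside-or-on endo.

    ``grid_shape`` is ``(ny, nx)`` in image (row, column) order.
    """
    endo_poly = endo.polygon()
    epi_poly = epi.polygon()
    if not epi_poly.contains_properly(endo_poly):
        raise ValueError("endocardial contour must lie strictly inside the epicardial contour")
    ny, nx = grid_shape
    ys, xs = np.mgrid[0:ny, 0:nx]
    inside_epi = shapely.contains_xy(epi_poly, xs.ravel(), ys.ravel()).reshape(ny, nx)
    inside_endo = shapely.contains_xy(endo_poly, xs.ravel(), ys.ravel()).reshape(ny, nx)
    return inside_epi & ~inside_endo


def _radial_profile(contour: Contour, center: tuple[float, float]):
    """Contour radius as a function of angle about ``center``.

    Requires the contour to be star-shaped about the center (each ray meets
    the boundary exactly once); returns sorted angle/radius arrays for
    periodic linear interpolation.
    """
    d = contour.vertices - np.asarray(center, dtype=float)
    radii = np.hypot(d[:, 0], d[:, 1])
    if np.any(radii <= 0):
        raise ValueError("contour passes through the centroid; malformed contour")
    ang = np.degrees(np.arctan2(d[:, 1], d[:, 0])) % 360.0
    # star-shapedness: vertex angles must be monotone around the circle
    order = np.argsort(ang)
    unwrapped = np.unwrap(np.radians(ang))
    steps = np.diff(unwrapped)
    if not (np.all(steps > 0) or np.all(steps < 0)):
        raise ValueError("contour is not star-shaped about the centroid")
    return ang[order], radii[order]


def _interp_radius(theta_deg: np.ndarray, ang: np.ndarray, rad: np.ndarray) -> np.ndarray:
    return np.interp(theta_deg, ang, rad, period=360.0)


def polar_parameterize(endo: Contour, epi: Contour, myo_mask: np.ndarray) -> PolarMap:
    """Assign (theta, depth) to every myocardial pixel.

    Depth is the radial position between the endo and epi contour radii
    along the ray through the pixel, linearly interpolated between polygon
    vertices and clipped to [0, 1].
    """
    centroid = epi.polygon().centroid
    cx, cy = centroid.x, centroid.y
    ny, nx = myo_mask.shape
    ys, xs = np.nonzero(myo_mask)
    dx = xs - cx
    dy = ys - cy
    theta_pix = np.degrees(np.arctan2(dy, dx)) % 360.0
    r_pix = np.hypot(dx, dy)

    ang_endo, rad_endo = _radial_profile(endo, (cx, cy))
    ang_epi, rad_epi = _radial_profile(epi, (cx, cy))
    r_endo = _interp_radius(theta_pix, ang_endo, rad_endo)
    r_epi = _interp_radius(theta_pix, ang_epi, rad_epi)
    wall = r_epi - r_endo
    if np.any(wall <= 0):
        raise ValueError("epicardial radius does not exceed endocardial radius on some rays")

    theta = np.full((ny, nx), np.nan)
    depth = np.full((ny, nx), np.nan)
    theta[ys, xs] = theta_pix
    depth[ys, xs] = np.clip((r_pix - r_endo) / wall, 0.0, 1.0)
    return PolarMap(theta=theta, depth=depth, myo_mask=myo_mask.astype(bool), center=(cx, cy))


def sector_roi(
    polar: PolarMap,
    center_angle: float,
    width: float,
    rim_fraction: float = 0.15,
) -> np.ndarray:
    """Sector ROI mask: myocardial pixels within ``width/2`` of ``center_angle``
    and with transmural depth in ``[rim_fraction, 1 - rim_fraction]``.

    Wraps correctly across 0/360 degrees.
    """
    if not (0 < width <= 360):
        raise ValueError("width must be in (0, 360]")
    if not (0 <= rim_fraction < 0.5):
        raise ValueError("rim_fraction must be in [0, 0.5)")
    roi = (
        polar.myo_mask
        & (angular_distance(polar.theta, center_angle) <= width / 2.0)
        & (polar.depth >= rim_fraction)
        & (polar.depth <= 1.0 - rim_fraction)
    )
    count = int(roi.sum())
    if count == 0:
        raise EmptyROIError(
            f"sector ROI at {center_angle:.1f} deg (width {width:.1f}) is empty", pixel_count=count
        )
    return roi


@dataclass
class ArcSet:
    """Disjoint angular intervals ``(start, end)`` in degrees with ``end > start``.

    ``end`` may exceed 360 for intervals wrapping through zero; ``start`` is
    normalized to ``[0, 360)``.
    """

    intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self):
        norm = []
        for start, end in self.intervals:
            length = end - start
            if length <= 0 or length > 360 + 1e-9:
                raise ValueError(f"invalid arc ({start}, {end})")
            start = start % 360.0
            norm.append((start, start + length))
        self.intervals = sorted(norm)

    @property
    def coverage(self) -> float:
        return float(sum(end - start for start, end in self.intervals))

    def largest(self) -> tuple[float, float] | None:
        if not self.intervals:
            return None
        return max(self.intervals, key=lambda iv: iv[1] - iv[0])


def _infarcted_bins(truth_infarct_mask: np.ndarray, polar: PolarMap, bin_width: float) -> np.ndarray:
    n_bins = 360.0 / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("bin_width must divide 360")
    n_bins = int(round(n_bins))
    flags = np.zeros(n_bins, dtype=bool)
    thetas = polar.theta[truth_infarct_mask & polar.myo_mask]
    if thetas.size:
        idx = np.floor(thetas / bin_width).astype(int) % n_bins
        flags[idx] = True
    return flags


def remote_arcs(truth_infarct_mask: np.ndarray, polar: PolarMap, bin_width: float = 1.0) -> ArcSet:
    """Maximal contiguous infarct-free arcs of the circumference.

    The circle is split into ``360/bin_width`` bins; a bin counts as
    infarcted if at least one truth-infarct pixel falls in it.
    """
    infarcted = _infarcted_bins(truth_infarct_mask, polar, bin_width)
    n_bins = infarcted.size
    if not infarcted.any():
        return ArcSet([(0.0, 360.0)])
    if infarcted.all():
        return ArcSet([])
    # rotate so position 0 is infarcted, then take linear runs of free bins
    first_inf = int(np.argmax(infarcted))
    rolled = np.roll(infarcted, -first_inf)
    free = ~rolled
    edges = np.diff(np.concatenate([[0], free.view(np.int8), [0]]))
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0]
    intervals = []
    for s, e in zip(starts, ends):
        start_deg = ((s + first_inf) % n_bins) * bin_width
        intervals.append((start_deg, start_deg + (e - s) * bin_width))
    return ArcSet(intervals)


@dataclass(frozen=True)
class InclusionResult:
    included: bool
    infarct_coverage_deg: float
    largest_remote_arc_deg: float

    @property
    def infarct_coverage_pct(self) -> float:
        return self.infarct_coverage_deg / 360.0 * 100.0

    @property
    def largest_remote_arc_pct(self) -> float:
        return self.largest_remote_arc_deg / 360.0 * 100.0

    def __bool__(self) -> bool:
        return self.included


def slice_includable(
    truth_infarct_mask: np.ndarray,
    polar: PolarMap,
    bin_width: float = 1.0,
    min_infarct_coverage_deg: float = 36.0,
    min_remote_arc_deg: float = 180.0,
) -> InclusionResult:
    """Per-slice inclusion filter.

    A slice qualifies when the infarct spans at least 10% of the
    circumference (36 degrees) and a contiguous infarct-free arc of at least
    half the circumference (180 degrees) remains.
    """
    infarcted = _infarcted_bins(truth_infarct_mask, polar, bin_width)
    coverage = float(infarcted.sum()) * bin_width
    arcs = remote_arcs(truth_infarct_mask, polar, bin_width)
    largest = arcs.largest()
    largest_deg = 0.0 if largest is None else largest[1] - largest[0]
    ok = bool(coverage >= min_infarct_coverage_deg and largest_deg >= min_remote_arc_deg)
    return InclusionResult(ok, float(coverage), float(largest_deg))


def candidate_positions(
    arcs: ArcSet,
    roi_width: float = 45.0,
    min_step: float = 10.0,
    max_positions: int = 7,
) -> np.ndarray:
    """Admissible sector-center angles inside the largest remote arc.

    A center is admissible when the whole sector fits inside the arc. If the
    admissible span supports ``max_positions`` centers at ``min_step``
    spacing they are spread evenly over the span; otherwise as many as fit
    at exactly ``min_step`` spacing are placed, centered within the span.
    Angles are returned in traversal order along the arc, normalized to
    [0, 360).
    """
    if roi_width <= 0:
        raise ValueError("roi_width must be positive")
    largest = arcs.largest()
    if largest is None:
        return np.empty(0)
    start, end = largest
    span = (end - start) - roi_width
    if span < 0:
        return np.empty(0)
    lo = start + roi_width / 2.0
    if span == 0:
        centers = np.array([lo])
    elif span >= (max_positions - 1) * min_step:
        centers = np.linspace(lo, lo + span, max_positions)
    else:
        k = int(np.floor(span / min_step)) + 1
        offset = (span - (k - 1) * min_step) / 2.0
        centers = lo + offset + min_step * np.arange(k)
    return centers % 360.0


def candidate_sizes(
    arcs: ArcSet,
    size_grid: tuple[float, ...] = (15.0, 30.0, 45.0, 60.0, 75.0, 90.0, 105.0),
) -> list[tuple[float, float]]:
    """Sector widths from ``size_grid`` that fit in the largest remote arc,
    each paired with the arc midpoint as center angle."""
    if not size_grid:
        raise ValueError("size_grid must be non-empty")
    largest = arcs.largest()
    if largest is None:
        return []
    start, end = largest
    arc_len = end - start
    mid = ((start + end) / 2.0) % 360.0
    return [(float(w), mid) for w in size_grid if w <= arc_len]
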