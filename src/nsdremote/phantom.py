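"""Synthetic short-axis LGE slice generation with known ground truth.

A slice is an annular myocardium on a square pixel grid: nulled remote
tissue, a hyper-enhanced infarct sector of configurable circumferential
extent and transmurality, an optional dark microvascular-obstruction (MVO)
core nested subendocardially inside the infarct, a smooth multiplicative
coil-sensitivity bias field, and magnitude-image noise (Gaussian, Rician or
non-central chi). Geometry is analytic: a pixel belongs to a region iff its
center lies inside the region's boundary, with pixel centers at integer
coordinates.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .myogeometry import Contour, angular_distance, circle_contour

__all__ = [
    "NOISE_MODELS",
    "InvalidSpecError",
    "PhantomSpec",
    "PhantomSlice",
    "CohortTemplate",
    "sample_noise",
    "generate_slice",
    "generate_cohort",
]

NOISE_MODELS = ("none", "gaussian", "rician", "noncentral_chi")


class InvalidSpecError(ValueError):
    pass


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of one synthetic slice.

    Lengths are millimetres, angles degrees, intensities on a normalized
    [0, 1] scale. ``center`` defaults to the grid center ``((g-1)/2, (g-1)/2)``
    in (x, y) pixel coordinates. ``transmurality`` is the infarct's share of
    wall thickness measured from the endocardium; ``mvo_fraction`` is the
    share of infarct area forming the dark core (intensity ``mvo_mean``,
    defaulting to ``remote_mean``). ``edge_smooth_px`` optionally smooths the
    pre-noise intensity image with a Gaussian of that many pixels to emulate
    partial-volume ramps at tissue borders (0 = hard edges).
    """

    grid_size: int = 128
    pixel_spacing: float = 1.5
    center: tuple[float, float] | None = None
    endo_radius: float = 20.0
    epi_radius: float = 30.0
    infarct_center_angle: float = 0.0
    infarct_extent: float = 90.0
    transmurality: float = 1.0
    mvo_fraction: float = 0.0
    mvo_mean: float | None = None
    remote_mean: float = 0.1
    remote_sd: float = 0.02
    infarct_mean: float = 0.7
    infarct_sd: float = 0.05
    noise_model: str = "rician"
    coil_count: int = 1
    bias_amplitude: float = 0.0
    bias_scale: float = 40.0
    edge_smooth_px: float = 0.0
    seed: int = 0
    site_label: str = "site0"

    @property
    def center_xy(self) -> tuple[float, float]:
        if self.center is not None:
            return (float(self.center[0]), float(self.center[1]))
        c = (self.grid_size - 1) / 2.0
        return (c, c)

    @property
    def mvo_intensity(self) -> float:
        return self.remote_mean if self.mvo_mean is None else self.mvo_mean

    def validate(self) -> None:
        if self.grid_size < 8:
            raise InvalidSpecError("grid_size too small")
        if self.pixel_spacing <= 0:
            raise InvalidSpecError("pixel_spacing must be positive")
        if not (self.epi_radius > self.endo_radius > 0):
            raise InvalidSpecError(
                f"need epi_radius > endo_radius > 0, got epi_radius={self.epi_radius}, "
                f"endo_radius={self.endo_radius}"
            )
        cx, cy = self.center_xy
        r_px = self.epi_radius / self.pixel_spacing
        if cx - r_px < 0 or cy - r_px < 0 or cx + r_px > self.grid_size - 1 or cy + r_px > self.grid_size - 1:
            raise InvalidSpecError("annulus exceeds the pixel grid")
        if not (0 <= self.infarct_center_angle < 360):
            raise InvalidSpecError("infarct_center_angle must be in [0, 360)")
        if not (0 <= self.infarct_extent <= 360):
            raise InvalidSpecError("infarct_extent must be in [0, 360]")
        if not (0 < self.transmurality <= 1):
            raise InvalidSpecError("transmurality must be in (0, 1]")
        if not (0 <= self.mvo_fraction < 1):
            raise InvalidSpecError("mvo_fraction must be in [0, 1)")
        for name in ("remote_mean", "infarct_mean", "mvo_intensity"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise InvalidSpecError(f"{name} must be in [0, 1]")
        if self.infarct_mean <= self.remote_mean:
            raise InvalidSpecError("infarct_mean must exceed remote_mean (hyper-enhancement)")
        if self.mvo_intensity > self.remote_mean:
            raise InvalidSpecError("mvo_mean must not exceed remote_mean (dark core)")
        if self.remote_sd < 0 or self.infarct_sd < 0:
            raise InvalidSpecError("noise SDs must be non-negative")
        if self.noise_model not in NOISE_MODELS:
            raise InvalidSpecError(f"unknown noise_model {self.noise_model!r}")
        if self.coil_count < 1:
            raise InvalidSpecError("coil_count must be >= 1")
        if not (0 <= self.bias_amplitude < 1):
            raise InvalidSpecError("bias_amplitude must be in [0, 1)")
        if self.bias_scale <= 0:
            raise InvalidSpecError("bias_scale must be positive")
        if self.edge_smooth_px < 0:
            raise InvalidSpecError("edge_smooth_px must be non-negative")


@dataclass
class PhantomSlice:
    """One realized slice: intensity image, contours and ground-truth masks.

    ``truth_infarct_mask`` includes the MVO core (MVO is part of the
    infarct); ``truth_mvo_mask`` is nested inside it.
    """

    image: np.ndarray
    endo_contour: Contour
    epi_contour: Contour
    myo_mask: np.ndarray
    truth_infarct_mask: np.ndarray
    truth_mvo_mask: np.ndarray
    spec: PhantomSpec

    @property
    def site_label(self) -> str:
        if self.spec is not None:
            return self.spec.site_label
        return getattr(self, "site_label_override", "unknown")


def sample_noise(clean_value, sd, model: str, coil_count: int = 1, rng=None):
    """Draw magnitude-image noise around ``clean_value``.

    gaussian: clean + N(0, sd^2). rician: sqrt((clean + n1)^2 + n2^2) with
    independent N(0, sd^2) components. noncentral_chi: magnitude over
    2*coil_count Gaussian components with the signal carried by one. With
    sd = 0 every model degrades to the identity. Accepts scalars or arrays
    (broadcast); returns floats/arrays accordingly.
    """
    clean = np.asarray(clean_value, dtype=float)
    sd_arr = np.asarray(sd, dtype=float)
    if np.any(sd_arr < 0):
        raise ValueError("sd must be non-negative")
    if model not in NOISE_MODELS:
        raise ValueError(f"unknown noise model {model!r}")
    scalar = clean.ndim == 0 and sd_arr.ndim == 0
    if model == "none":
        out = clean.copy()
    else:
        if rng is None:
            rng = np.random.default_rng()
        shape = np.broadcast_shapes(clean.shape, sd_arr.shape)
        if model == "gaussian":
            out = clean + rng.standard_normal(shape) * sd_arr
        elif model == "rician":
            n1 = rng.standard_normal(shape) * sd_arr
            n2 = rng.standard_normal(shape) * sd_arr
            out = np.hypot(clean + n1, n2)
        else:  # noncentral_chi
            if coil_count < 1:
                raise ValueError("coil_count must be >= 1 for noncentral_chi")
            k = 2 * int(coil_count)
            sq = (clean + rng.standard_normal(shape) * sd_arr) ** 2
            for _ in range(k - 1):
                sq = sq + (rng.standard_normal(shape) * sd_arr) ** 2
            out = np.sqrt(sq)
    return float(out) if scalar else out


def _analytic_geometry(spec: PhantomSpec):
    """Myocardium/infarct/MVO masks from the analytic circle geometry."""
    g = spec.grid_size
    cx, cy = spec.center_xy
    ys, xs = np.mgrid[0:g, 0:g]
    dx = (xs - cx) * spec.pixel_spacing
    dy = (ys - cy) * spec.pixel_spacing
    r = np.hypot(dx, dy)
    theta = np.degrees(np.arctan2(dy, dx)) % 360.0

    myo = (r < spec.epi_radius) & (r >= spec.endo_radius)
    depth = (r - spec.endo_radius) / (spec.epi_radius - spec.endo_radius)

    if spec.infarct_extent > 0:
        in_sector = angular_distance(theta, spec.infarct_center_angle) <= spec.infarct_extent / 2.0
        infarct = myo & in_sector & (depth <= spec.transmurality)
    else:
        infarct = np.zeros_like(myo)

    mvo = np.zeros_like(myo)
    n_inf = int(infarct.sum())
    if spec.mvo_fraction > 0 and n_inf > 0:
        n_mvo = int(round(spec.mvo_fraction * n_inf))
        if n_mvo > 0:
            iy, ix = np.nonzero(infarct)
            order = np.argsort(depth[iy, ix], kind="stable")  # innermost first
            sel = order[:n_mvo]
            mvo[iy[sel], ix[sel]] = True
    return myo, infarct, mvo, r, theta


def _bias_field(spec: PhantomSpec) -> np.ndarray:
    """Single smooth multiplicative bump, amplitude ``bias_amplitude``,
    truncated Gaussian profile of width ``bias_scale`` centered off-axis."""
    g = spec.grid_size
    if spec.bias_amplitude == 0:
        return np.ones((g, g))
    cx, cy = spec.center_xy
    off = spec.epi_radius / spec.pixel_spacing / math.sqrt(2.0)
    bx, by = cx + off, cy + off
    ys, xs = np.mgrid[0:g, 0:g]
    d = np.hypot(xs - bx, ys - by) * spec.pixel_spacing
    bump = np.exp(-0.5 * (d / spec.bias_scale) ** 2)
    bump[d > 3 * spec.bias_scale] = 0.0
    return 1.0 + spec.bias_amplitude * bump


def generate_slice(spec: PhantomSpec) -> PhantomSlice:
    """Realize one slice from its spec. Deterministic given (spec, seed).

    Pipeline: rasterize annulus -> paint tissue-class means -> optional
    partial-volume smoothing -> multiplicative bias field -> tissue-class
    noise (remote_sd on remote and MVO, infarct_sd on enhancing infarct;
    background stays noiseless at 0) -> clip to [0, 1].
    """
    spec.validate()
    myo, infarct, mvo, _, _ = _analytic_geometry(spec)

    clean = np.zeros((spec.grid_size, spec.grid_size))
    clean[myo] = spec.remote_mean
    clean[infarct] = spec.infarct_mean
    clean[mvo] = spec.mvo_intensity
    if spec.edge_smooth_px > 0:
        clean = gaussian_filter(clean, spec.edge_smooth_px)

    img = clean * _bias_field(spec)

    if spec.noise_model != "none":
        sd_map = np.zeros_like(img)
        sd_map[myo] = spec.remote_sd
        sd_map[infarct & ~mvo] = spec.infarct_sd
        sd_map[mvo] = spec.remote_sd
        rng = np.random.default_rng(spec.seed)
        noisy = sample_noise(img, sd_map, spec.noise_model, spec.coil_count, rng)
        img = np.where(myo, noisy, img)

    img = np.clip(img, 0.0, 1.0)

    cx, cy = spec.center_xy
    endo = circle_contour((cx, cy), spec.endo_radius / spec.pixel_spacing)
    epi = circle_contour((cx, cy), spec.epi_radius / spec.pixel_spacing)
    return PhantomSlice(
        image=img,
        endo_contour=endo,
        epi_contour=epi,
        myo_mask=myo,
        truth_infarct_mask=infarct,
        truth_mvo_mask=mvo,
        spec=spec,
    )


@dataclass(frozen=True)
class CohortTemplate:
    """A PhantomSpec plus optional per-slice uniform sampling ranges for the
    infarct geometry. Fields left as ``None`` keep the base value fixed."""

    base: PhantomSpec
    infarct_center_angle_range: tuple[float, float] | None = None
    infarct_extent_range: tuple[float, float] | None = None
    transmurality_range: tuple[float, float] | None = None
    mvo_fraction_range: tuple[float, float] | None = None


def _draw_spec(template: CohortTemplate, rng: np.random.Generator, seed: int) -> PhantomSpec:
    updates: dict = {"seed": seed}
    for field_name, rng_attr in (
        ("infarct_center_angle", "infarct_center_angle_range"),
        ("infarct_extent", "infarct_extent_range"),
        ("transmurality", "transmurality_range"),
        ("mvo_fraction", "mvo_fraction_range"),
    ):
        bounds = getattr(template, rng_attr)
        if bounds is not None:
            lo, hi = bounds
            updates[field_name] = float(rng.uniform(lo, hi))
    return dataclasses.replace(template.base, **updates)


def generate_cohort(
    site_specs: Sequence[tuple[CohortTemplate | PhantomSpec, int]],
    master_seed: int,
) -> list[PhantomSlice]:
    """Generate a multi-site cohort of slices.

    Per-slice seeds derive from ``numpy.random.SeedSequence(master_seed)``
    spawned once per slice in (site, slice) order, so the cohort is fully
    reproducible and slices are statistically independent. Geometry fields
    with ranges in the template are drawn uniformly per slice.
    """
    if not site_specs:
        raise ValueError("site list must be non-empty")
    for _, count in site_specs:
        if count < 1:
            raise ValueError("slice counts must be >= 1")
    total = sum(count for _, count in site_specs)
    children = np.random.SeedSequence(master_seed).spawn(total)
    slices: list[PhantomSlice] = []
    i = 0
    for template, count in site_specs:
        if isinstance(template, PhantomSpec):
            template = CohortTemplate(base=template)
        for _ in range(count):
            rng = np.random.default_rng(children[i])
            slice_seed = int(rng.integers(0, 2**63 - 1))
            spec = _draw_spec(template, rng, slice_seed)
            slices.append(generate_slice(spec))
            i += 1
    return slices
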