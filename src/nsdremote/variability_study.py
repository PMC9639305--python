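"""Error-source experiments for the n-SD-from-remote method.

Four factor sweeps (remote ROI position, remote ROI size, the SD multiplier
n, spurious-pixel removal), the per-slice optimal-n search, and the
signal-variability comparison across site groups. Accuracy is the mean
measurement error in infarct-percentage units; precision is the per-slice
coefficient of variation, SD of the error across factor levels divided by
the reference infarct size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import myogeometry as geo
from . import nsd_core
from .nsd_core import SegParams
from .phantom import PhantomSlice

__all__ = [
    "StudyConfig",
    "SlicePrep",
    "StudySummary",
    "StudyResult",
    "PairedComparison",
    "OptimalNResult",
    "SignalVariabilityReport",
    "prepare_slice",
    "run_position_study",
    "run_size_study",
    "run_nsd_study",
    "run_spurious_comparison",
    "optimal_n_per_slice",
    "optimal_n_study",
    "signal_variability_report",
    "summarize",
]

log = logging.getLogger(__name__)

OUTCOME_COLUMNS = [
    "slice_id",
    "site_label",
    "factor",
    "factor_level",
    "measured_pct",
    "reference_pct",
    "error_pct",
    "threshold",
]


@dataclass(frozen=True)
class StudyConfig:
    """Configuration shared by the factor-sweep studies."""

    baseline_n: float = 3.5
    baseline_width: float = 45.0
    rim_fraction: float = 0.15
    n_grid: tuple[float, ...] = (2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0)
    size_grid: tuple[float, ...] = (15.0, 30.0, 45.0, 60.0, 75.0, 90.0, 105.0)
    min_step: float = 10.0
    max_positions: int = 7
    remove_spurious: bool = False
    min_island: int = 10
    connectivity: int = 8
    min_roi_pixels: int = 10
    bin_width: float = 1.0

    def seg_params(self, n: float | None = None) -> SegParams:
        return SegParams(
            n=self.baseline_n if n is None else n,
            remove_spurious=self.remove_spurious,
            min_island=self.min_island,
            connectivity=self.connectivity,
        )


@dataclass
class SlicePrep:
    """Per-slice geometry derived once and reused across studies."""

    slice_id: str
    site_label: str
    image: np.ndarray
    myo_mask: np.ndarray
    truth_mask: np.ndarray
    polar: geo.PolarMap
    arcs: geo.ArcSet
    inclusion: geo.InclusionResult
    reference_pct: float
    infarct_center_angle: float | None


def prepare_slice(sl: PhantomSlice, slice_id: str, bin_width: float = 1.0) -> SlicePrep:
    """Build the polar map, remote arcs and reference size for one slice."""
    myo = sl.myo_mask
    if myo is None:
        myo = geo.rasterize_myocardium(sl.endo_contour, sl.epi_contour, sl.image.shape)
    polar = geo.polar_parameterize(sl.endo_contour, sl.epi_contour, myo)
    truth = sl.truth_infarct_mask
    arcs = geo.remote_arcs(truth, polar, bin_width)
    inclusion = geo.slice_includable(truth, polar, bin_width)
    reference_pct = nsd_core.infarct_fraction(truth, myo)
    center = None
    thetas = polar.theta[truth & myo]
    if thetas.size:
        rad = np.radians(thetas)
        center = float(np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean())) % 360.0)
    return SlicePrep(
        slice_id=slice_id,
        site_label=sl.site_label,
        image=sl.image,
        myo_mask=myo,
        truth_mask=truth,
        polar=polar,
        arcs=arcs,
        inclusion=inclusion,
        reference_pct=reference_pct,
        infarct_center_angle=center,
    )


def _prepare_all(slices, bin_width: float) -> list[SlicePrep]:
    preps = []
    for i, sl in enumerate(slices):
        sl_id = getattr(sl, "slice_id", None) or f"slice_{i:04d}"
        preps.append(prepare_slice(sl, sl_id, bin_width))
    return preps


@dataclass(frozen=True)
class StudySummary:
    """Accuracy and precision aggregates for one factor sweep.

    ``mean_error``/``error_sd`` pool errors over all ROIs; ``cov_mean``/
    ``cov_sd`` aggregate the per-slice CoV (SD of error across factor levels
    over reference size, percent) across slices; ``median_abs_diff`` is the
    absolute difference of the medians of measured and reference sizes.
    """

    mean_error: float
    error_sd: float
    cov_mean: float
    cov_sd: float
    median_abs_diff: float
    slice_count: int
    roi_count: int

    def to_dict(self) -> dict:
        return {
            "mean_error_pct_units": self.mean_error,
            "error_sd_pct_units": self.error_sd,
            "cov_mean_pct": self.cov_mean,
            "cov_sd_pct": self.cov_sd,
            "median_abs_diff_pct_units": self.median_abs_diff,
            "slice_count": self.slice_count,
            "roi_count": self.roi_count,
        }


@dataclass
class StudyResult:
    summary: StudySummary
    table: pd.DataFrame
    excluded: list[tuple[str, str]] = field(default_factory=list)


def summarize(outcomes: pd.DataFrame) -> StudySummary:
    """Aggregate an outcome table into accuracy/precision statistics."""
    if len(outcomes) == 0:
        raise ValueError("no outcomes to summarize")
    errors = outcomes["error_pct"].to_numpy(dtype=float)
    mean_error = float(errors.mean())
    error_sd = float(errors.std(ddof=1)) if errors.size > 1 else 0.0

    covs = []
    for _, grp in outcomes.groupby("slice_id", sort=True):
        if len(grp) < 2:
            continue  # CoV undefined with a single factor level
        ref = float(grp["reference_pct"].iloc[0])
        covs.append(100.0 * float(grp["error_pct"].std(ddof=1)) / ref)
    covs = np.asarray(covs, dtype=float)
    cov_mean = float(covs.mean()) if covs.size else float("nan")
    cov_sd = float(covs.std(ddof=1)) if covs.size > 1 else 0.0

    median_abs_diff = abs(
        float(outcomes["measured_pct"].median()) - float(outcomes["reference_pct"].median())
    )
    return StudySummary(
        mean_error=mean_error,
        error_sd=error_sd,
        cov_mean=cov_mean,
        cov_sd=cov_sd,
        median_abs_diff=median_abs_diff,
        slice_count=int(outcomes["slice_id"].nunique()),
        roi_count=int(len(outcomes)),
    )


def _segment(prep: SlicePrep, roi: np.ndarray, params: SegParams, config: StudyConfig):
    return nsd_core.segment_slice(
        prep.image, prep.myo_mask, roi, params, min_roi_pixels=config.min_roi_pixels
    )


def _outcome_row(prep: SlicePrep, factor: str, level, result) -> dict:
    return {
        "slice_id": prep.slice_id,
        "site_label": prep.site_label,
        "factor": factor,
        "factor_level": level,
        "measured_pct": result.infarct_fraction_pct,
        "reference_pct": prep.reference_pct,
        "error_pct": result.infarct_fraction_pct - prep.reference_pct,
        "threshold": result.threshold,
    }


def _finish(rows: list[dict], excluded: list[tuple[str, str]]) -> StudyResult:
    table = pd.DataFrame(rows, columns=OUTCOME_COLUMNS)
    for sl_id, reason in excluded:
        log.info("excluded %s: %s", sl_id, reason)
    return StudyResult(summary=summarize(table), table=table, excluded=excluded)


def run_position_study(slices, config: StudyConfig = StudyConfig()) -> StudyResult:
    """Sweep the remote-ROI center over admissible positions in the remote
    arc (fixed width, fixed n) and measure the induced size variability."""
    rows: list[dict] = []
    excluded: list[tuple[str, str]] = []
    params = config.seg_params()
    for prep in _prepare_all(slices, config.bin_width):
        if not prep.inclusion:
            excluded.append((prep.slice_id, "inclusion filter"))
            continue
        centers = geo.candidate_positions(
            prep.arcs, config.baseline_width, config.min_step, config.max_positions
        )
        if centers.size == 0:
            excluded.append((prep.slice_id, "no admissible ROI position"))
            continue
        for c in centers:
            roi = geo.sector_roi(prep.polar, c, config.baseline_width, config.rim_fraction)
            res = _segment(prep, roi, params, config)
            rows.append(_outcome_row(prep, "roi_position", float(c), res))
    return _finish(rows, excluded)


def run_size_study(slices, config: StudyConfig = StudyConfig()) -> StudyResult:
    """Sweep the remote-ROI width over the size grid at the remote-arc
    midpoint (fixed n)."""
    rows: list[dict] = []
    excluded: list[tuple[str, str]] = []
    params = config.seg_params()
    for prep in _prepare_all(slices, config.bin_width):
        if not prep.inclusion:
            excluded.append((prep.slice_id, "inclusion filter"))
            continue
        sizes = geo.candidate_sizes(prep.arcs, config.size_grid)
        if not sizes:
            excluded.append((prep.slice_id, "no ROI size fits the remote arc"))
            continue
        for width, center in sizes:
            roi = geo.sector_roi(prep.polar, center, width, config.rim_fraction)
            res = _segment(prep, roi, params, config)
            rows.append(_outcome_row(prep, "roi_size", float(width), res))
    return _finish(rows, excluded)


def _diametric_center(prep: SlicePrep, width: float) -> float | None:
    """ROI center diametrically opposed to the infarct, pulled to the
    nearest admissible center when the sector does not fit there."""
    largest = prep.arcs.largest()
    if largest is None or prep.infarct_center_angle is None:
        return None
    start, end = largest
    if (end - start) < width:
        return None
    lo, hi = start + width / 2.0, end - width / 2.0
    target = (prep.infarct_center_angle + 180.0) % 360.0
    t = start + ((target - start) % 360.0)  # target on the arc's unwrapped axis
    if lo <= t <= hi:
        return t % 360.0
    # fall back to whichever admissible end is circularly closer
    best = min((lo, hi), key=lambda c: geo.angular_distance(c % 360.0, target))
    log.info("%s: diametric ROI moved to nearest admissible center", prep.slice_id)
    return best % 360.0


def run_nsd_study(slices, config: StudyConfig = StudyConfig()) -> StudyResult:
    """Sweep the SD multiplier n over ``n_grid`` with a fixed-width ROI
    placed diametrically opposite the infarct."""
    rows: list[dict] = []
    excluded: list[tuple[str, str]] = []
    for prep in _prepare_all(slices, config.bin_width):
        if not prep.inclusion:
            excluded.append((prep.slice_id, "inclusion filter"))
            continue
        center = _diametric_center(prep, config.baseline_width)
        if center is None:
            excluded.append((prep.slice_id, "no admissible diametric ROI"))
            continue
        roi = geo.sector_roi(prep.polar, center, config.baseline_width, config.rim_fraction)
        for n in config.n_grid:
            res = _segment(prep, roi, config.seg_params(n), config)
            rows.append(_outcome_row(prep, "n_sd", float(n), res))
    return _finish(rows, excluded)


@dataclass
class PairedComparison:
    naive: StudySummary
    no_spurious: StudySummary
    paired_mean_diff: float
    naive_table: pd.DataFrame
    no_spurious_table: pd.DataFrame


def run_spurious_comparison(slices, config: StudyConfig = StudyConfig()) -> PairedComparison:
    """Naive vs island-removal variants on identical ROIs (paired design).

    The ROI is the remote-arc midpoint sector at the baseline width and n.
    """
    naive_rows: list[dict] = []
    clean_rows: list[dict] = []
    excluded: list[tuple[str, str]] = []
    p_naive = replace(config.seg_params(), remove_spurious=False)
    p_clean = replace(config.seg_params(), remove_spurious=True)
    for prep in _prepare_all(slices, config.bin_width):
        if not prep.inclusion:
            excluded.append((prep.slice_id, "inclusion filter"))
            continue
        largest = prep.arcs.largest()
        if largest is None or (largest[1] - largest[0]) < config.baseline_width:
            excluded.append((prep.slice_id, "no admissible ROI"))
            continue
        center = ((largest[0] + largest[1]) / 2.0) % 360.0
        roi = geo.sector_roi(prep.polar, center, config.baseline_width, config.rim_fraction)
        res_n = _segment(prep, roi, p_naive, config)
        res_c = _segment(prep, roi, p_clean, config)
        naive_rows.append(_outcome_row(prep, "spurious", "naive", res_n))
        clean_rows.append(_outcome_row(prep, "spurious", "no_spurious", res_c))
    naive_table = pd.DataFrame(naive_rows, columns=OUTCOME_COLUMNS)
    clean_table = pd.DataFrame(clean_rows, columns=OUTCOME_COLUMNS)
    if len(naive_table) == 0:
        raise ValueError("no slices admissible for the paired comparison")
    diff = float(
        (naive_table["measured_pct"].to_numpy() - clean_table["measured_pct"].to_numpy()).mean()
    )
    for sl_id, reason in excluded:
        log.info("excluded %s: %s", sl_id, reason)
    return PairedComparison(
        naive=summarize(naive_table),
        no_spurious=summarize(clean_table),
        paired_mean_diff=diff,
        naive_table=naive_table,
        no_spurious_table=clean_table,
    )


@dataclass(frozen=True)
class OptimalN:
    n_star: float
    abs_error: float
    degenerate: bool


def optimal_n_per_slice(
    image: np.ndarray,
    myo_mask: np.ndarray,
    roi_mask: np.ndarray,
    reference_pct: float,
    search_grid: np.ndarray | None = None,
    params: SegParams | None = None,
    min_roi_pixels: int = 10,
) -> OptimalN:
    """Grid search for the n that best matches the reference size.

    Minimizes |measured(n) - reference| over the grid; ties go to the
    smallest n. A result pinned at either grid end is flagged degenerate.
    """
    if reference_pct <= 0:
        raise ValueError("reference size must be positive")
    if search_grid is None:
        search_grid = np.round(np.arange(0.1, 15.0 + 1e-9, 0.1), 10)
    grid = np.asarray(search_grid, dtype=float)
    stats = nsd_core.remote_stats(image, roi_mask, min_roi_pixels=min_roi_pixels)
    myo = np.asarray(myo_mask, dtype=bool)
    myo_count = int(myo.sum())

    spurious = params is not None and params.remove_spurious
    if not spurious:
        vals = np.sort(np.asarray(image, dtype=float)[myo])
        thresholds = stats.mu + grid * stats.sigma
        counts = vals.size - np.searchsorted(vals, thresholds, side="right")
        measured = 100.0 * counts / myo_count
    else:
        measured = np.empty(grid.size)
        for i, n in enumerate(grid):
            mask = nsd_core.classify(image, myo, stats.mu + n * stats.sigma)
            mask, _ = nsd_core.remove_spurious(mask, params.min_island, params.connectivity)
            measured[i] = 100.0 * mask.sum() / myo_count

    errors = np.abs(measured - reference_pct)
    best = int(np.argmin(errors))  # argmin takes the first (smallest-n) tie
    return OptimalN(
        n_star=float(grid[best]),
        abs_error=float(errors[best]),
        degenerate=best in (0, grid.size - 1),
    )


@dataclass
class OptimalNResult:
    table: pd.DataFrame
    mean: float
    sd: float


def optimal_n_study(
    slices,
    config: StudyConfig = StudyConfig(),
    search_grid: np.ndarray | None = None,
) -> OptimalNResult:
    """Per-slice optimal n with a fixed-width mid-remote ROI, aggregated as
    mean and SD across slices (grouped by site in the table)."""
    rows = []
    for prep in _prepare_all(slices, config.bin_width):
        if not prep.inclusion:
            continue
        largest = prep.arcs.largest()
        if largest is None or (largest[1] - largest[0]) < config.baseline_width:
            continue
        center = ((largest[0] + largest[1]) / 2.0) % 360.0
        roi = geo.sector_roi(prep.polar, center, config.baseline_width, config.rim_fraction)
        opt = optimal_n_per_slice(
            prep.image,
            prep.myo_mask,
            roi,
            prep.reference_pct,
            search_grid,
            params=config.seg_params(),
            min_roi_pixels=config.min_roi_pixels,
        )
        rows.append(
            {
                "slice_id": prep.slice_id,
                "site_label": prep.site_label,
                "n_star": opt.n_star,
                "abs_error": opt.abs_error,
                "degenerate": opt.degenerate,
            }
        )
    if not rows:
        raise ValueError("no slices admissible for the optimal-n study")
    table = pd.DataFrame(rows)
    vals = table["n_star"].to_numpy(dtype=float)
    return OptimalNResult(
        table=table,
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
    )


@dataclass
class SignalVariabilityReport:
    """Per-group remote-ROI SD measured on min-max normalized images."""

    table: pd.DataFrame
    group_stats: pd.DataFrame


def signal_variability_report(
    slices,
    config: StudyConfig = StudyConfig(),
) -> SignalVariabilityReport:
    """Remote signal variability per site group.

    Each image is min-max normalized to [0, 1]; the statistic is the SD of
    normalized intensity in the mid-remote sector ROI at the baseline width.
    """
    rows = []
    for prep in _prepare_all(slices, config.bin_width):
        lo, hi = float(prep.image.min()), float(prep.image.max())
        if hi <= lo:
            raise ValueError(f"{prep.slice_id}: constant image cannot be normalized")
        norm = (prep.image - lo) / (hi - lo)
        largest = prep.arcs.largest()
        if largest is None or (largest[1] - largest[0]) < config.baseline_width:
            continue
        center = ((largest[0] + largest[1]) / 2.0) % 360.0
        roi = geo.sector_roi(prep.polar, center, config.baseline_width, config.rim_fraction)
        sd = float(norm[roi].std(ddof=1))
        rows.append({"slice_id": prep.slice_id, "site_label": prep.site_label, "remote_sd": sd})
    if not rows:
        raise ValueError("no slices usable for the signal-variability report")
    table = pd.DataFrame(rows)
    group_stats = (
        table.groupby("site_label")["remote_sd"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0, count="count")
        .reset_index()
    )
    return SignalVariabilityReport(table=table, group_stats=group_stats)
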