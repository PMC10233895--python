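"""Per-colony growth curves: calibration, smoothing, QC, doubling times.

The doubling time D of a colony is extracted from the exponential phase of
its growth curve as the inverse of the maximum slope of log2(population)
versus time, taken over sliding regression windows that fit well (r^2 at
or above a threshold). On the log2 scale the slope is directly in
doublings per hour, so D = 1/slope.

Curves are median-then-mean smoothed with edge-truncated windows before
QC and estimation. QC flags curves with insufficient dynamic range,
excessive non-monotonicity, or too few points; flagged curves receive no
doubling-time estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import InvalidCalibrationError, InvalidParameterError, NoGrowthError

# flag labels used by qc_curve
FLAG_TOO_FEW_POINTS = "too_few_points"
FLAG_LOW_DYNAMIC_RANGE = "low_dynamic_range"
FLAG_NON_MONOTONE = "non_monotone"
FLAG_NO_GROWTH = "no_growth"

MIN_POINTS = 10


@dataclass
class GrowthCurve:
    """Time series of population size (or raw intensity) for one colony."""

    plate_id: str
    row: int
    col: int
    times: np.ndarray  # hours, strictly increasing
    values: np.ndarray
    qc_flags: set = field(default_factory=set)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise InvalidParameterError("times and values must have equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise InvalidParameterError("times must be strictly increasing")


@dataclass
class DoublingTimeEstimate:
    """Doubling time with fit diagnostics for one colony."""

    D: float  # hours
    log2D: float
    window_start_index: int
    window_length: int
    fit_r2: float
    qc_pass: bool


@dataclass
class QCRules:
    """Thresholds for rejecting erroneous growth curves.

    min_fold: minimum max/min dynamic range (default 2 = at least one
    doubling observed). max_decreasing_frac: maximum tolerated fraction of
    decreasing steps (default 0.25). min_points: minimum series length.
    """

    min_fold: float = 2.0
    max_decreasing_frac: float = 0.25
    min_points: int = MIN_POINTS


def calibrate_intensity(values, calibration: Callable | None = None) -> np.ndarray:
    """Convert background-subtracted intensities to cell counts.

    ``calibration`` is a monotone non-decreasing scalar function applied
    element-wise (None = identity). Negative inputs are clamped to 0 before
    calibration. Monotonicity is checked on a dense grid spanning the data.
    """
    v = np.clip(np.asarray(values, dtype=float), 0.0, None)
    if calibration is None:
        return v
    lo, hi = 0.0, float(v.max(initial=1.0))
    grid = np.linspace(lo, hi if hi > lo else lo + 1.0, 256)
    out_grid = np.asarray([calibration(g) for g in grid], dtype=float)
    if np.any(np.diff(out_grid) < -1e-9 * max(1.0, np.abs(out_grid).max())):
        raise InvalidCalibrationError("calibration function is not monotone non-decreasing")
    return np.asarray([calibration(x) for x in v], dtype=float)


def _check_window(w: int, n: int, name: str) -> None:
    if w < 1 or w % 2 == 0:
        raise InvalidParameterError(f"{name} must be odd and >= 1, got {w}")
    if w > n:
        raise InvalidParameterError(f"{name}={w} exceeds series length {n}")


def smooth_matrix(values: np.ndarray, median_window: int = 5, mean_window: int = 5) -> np.ndarray:
    """Median then moving-average filter along the last axis of a matrix.

    Both filters use edge-truncated windows so the series length is
    preserved and no padding values are invented at the boundaries.
    """
    y = np.atleast_2d(np.asarray(values, dtype=float))
    n = y.shape[-1]
    _check_window(median_window, n, "median_window")
    _check_window(mean_window, n, "mean_window")

    # median with truncated edges
    h = median_window // 2
    med = np.empty_like(y)
    if median_window == 1:
        med[:] = y
    else:
        from numpy.lib.stride_tricks import sliding_window_view

        med[:, h : n - h] = np.median(sliding_window_view(y, median_window, axis=-1), axis=-1)
        for i in range(h):
            med[:, i] = np.median(y[:, : i + h + 1], axis=-1)
            med[:, n - 1 - i] = np.median(y[:, n - 1 - i - h :], axis=-1)

    # moving average with truncated edges, via cumulative sums
    h = mean_window // 2
    cs = np.concatenate([np.zeros((med.shape[0], 1)), np.cumsum(med, axis=-1)], axis=-1)
    idx = np.arange(n)
    lo = np.maximum(idx - h, 0)
    hi = np.minimum(idx + h + 1, n)
    out = (cs[:, hi] - cs[:, lo]) / (hi - lo)
    return out.reshape(np.asarray(values).shape)


def smooth_curve(curve: GrowthCurve, median_window: int = 5, mean_window: int = 5) -> GrowthCurve:
    """Return a new curve with median(median_window) + mean(mean_window) smoothing."""
    smoothed = smooth_matrix(curve.values[None, :], median_window, mean_window)[0]
    return GrowthCurve(
        plate_id=curve.plate_id,
        row=curve.row,
        col=curve.col,
        times=curve.times,
        values=smoothed,
        qc_flags=set(curve.qc_flags),
    )


def qc_curve(curve: GrowthCurve, rules: QCRules | None = None) -> set:
    """Quality-control flags for a calibrated, smoothed curve (empty = pass)."""
    rules = rules or QCRules()
    flags = set()
    v = curve.values
    if v.size < rules.min_points:
        flags.add(FLAG_TOO_FEW_POINTS)
        return flags
    vmax = float(v.max())
    vmin = float(v.min())
    if vmax <= 0:
        flags.add(FLAG_LOW_DYNAMIC_RANGE)
    else:
        fold = np.inf if vmin <= 0 else vmax / vmin
        if fold < rules.min_fold:
            flags.add(FLAG_LOW_DYNAMIC_RANGE)
    steps = np.diff(v)
    if steps.size and float(np.mean(steps < 0)) > rules.max_decreasing_frac:
        flags.add(FLAG_NON_MONOTONE)
    return flags


def _sliding_fits(times: np.ndarray, log2_values: np.ndarray, window: int):
    """Slope and r^2 of log2(value) ~ time for every sliding window.

    ``log2_values`` is (m, n); returns (slopes, r2) each (m, n - window + 1).
    """
    from numpy.lib.stride_tricks import sliding_window_view

    w = window
    xw = sliding_window_view(times, w)  # (nw, w)
    Sx = xw.sum(axis=-1)
    Sxx = (xw * xw).sum(axis=-1)
    yw = sliding_window_view(log2_values, w, axis=-1)  # (m, nw, w)
    Sy = yw.sum(axis=-1)
    Syy = (yw * yw).sum(axis=-1)
    Sxy = (yw * xw[None, :, :]).sum(axis=-1)
    ssx = Sxx - Sx * Sx / w
    ssy = Syy - Sy * Sy / w
    sxy = Sxy - Sx * Sy / w
    with np.errstate(divide="ignore", invalid="ignore"):
        slopes = sxy / ssx
        r2 = np.where(ssy > 0, (sxy * sxy) / (ssx * ssy), 0.0)
    return slopes, np.clip(r2, 0.0, 1.0)


def estimate_doubling_times_matrix(
    times: np.ndarray,
    values: np.ndarray,
    window: int = 7,
    min_r2: float = 0.95,
):
    """Vectorized doubling-time estimation for a stack of curves.

    ``values`` is (m, n). Returns arrays (D, log2D, window_start, r2, ok)
    of length m; curves with no positive well-fit window get ok=False and
    NaN estimates. Windows containing non-positive values are skipped.
    """
    times = np.asarray(times, dtype=float)
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n = times.size
    if window < 3:
        raise InvalidParameterError("window must be >= 3")
    if n < window:
        raise InvalidParameterError(f"need >= {window} time points, got {n}")

    from numpy.lib.stride_tricks import sliding_window_view

    positive = sliding_window_view(values > 0, window, axis=-1).all(axis=-1)
    safe = np.where(values > 0, values, np.nan)
    with np.errstate(invalid="ignore"):
        logv = np.log2(safe)
    logv = np.nan_to_num(logv, nan=0.0)  # masked windows are discarded below
    slopes, r2 = _sliding_fits(times, logv, window)

    valid = positive & (slopes > 0) & (r2 >= min_r2)
    slopes_masked = np.where(valid, slopes, -np.inf)
    best = np.argmax(slopes_masked, axis=-1)
    m = values.shape[0]
    rows = np.arange(m)
    ok = valid[rows, best]
    best_slope = slopes[rows, best]
    with np.errstate(divide="ignore", invalid="ignore"):
        D = np.where(ok, 1.0 / best_slope, np.nan)
        log2D = np.where(ok, np.log2(D), np.nan)
    best_r2 = np.where(ok, r2[rows, best], np.nan)
    return D, log2D, best, best_r2, ok


def estimate_doubling_time(
    curve: GrowthCurve, window: int = 7, min_r2: float = 0.95
) -> DoublingTimeEstimate:
    """Doubling time of one QC-passed curve from its max log2 growth slope.

    Raises :class:`NoGrowthError` when no window has a positive slope with
    fit r^2 >= ``min_r2``.
    """
    D, log2D, start, r2, ok = estimate_doubling_times_matrix(
        curve.times, curve.values[None, :], window, min_r2
    )
    if not ok[0]:
        raise NoGrowthError(
            f"no window with positive slope and r2 >= {min_r2} for colony "
            f"({curve.plate_id}, {curve.row}, {curve.col})"
        )
    return DoublingTimeEstimate(
        D=float(D[0]),
        log2D=float(log2D[0]),
        window_start_index=int(start[0]),
        window_length=window,
        fit_r2=float(r2[0]),
        qc_pass=True,
    )


def process_plate(
    curves: Sequence[GrowthCurve],
    median_window: int = 5,
    mean_window: int = 5,
    rules: QCRules | None = None,
    window: int = 7,
    min_r2: float = 0.95,
    calibration: Callable | None = None,
):
    """Calibrate, smooth, QC and estimate doubling times for a whole plate.

    Returns a pandas DataFrame with one row per colony: plate_id, row, col,
    D_hours, log2D, r2, qc_pass, flags. All curves must share one time grid.
    """
    import pandas as pd

    rules = rules or QCRules()
    times = curves[0].times
    raw = np.vstack([c.values for c in curves])
    if calibration is not None:
        raw = np.vstack([calibrate_intensity(v, calibration) for v in raw])
    else:
        raw = np.clip(raw, 0.0, None)
    smoothed = smooth_matrix(raw, median_window, mean_window)

    flag_lists = []
    for i, c in enumerate(curves):
        sc = GrowthCurve(c.plate_id, c.row, c.col, times, smoothed[i])
        flag_lists.append(qc_curve(sc, rules))
    passed = np.array([len(f) == 0 for f in flag_lists])

    D = np.full(len(curves), np.nan)
    log2D = np.full(len(curves), np.nan)
    r2 = np.full(len(curves), np.nan)
    if passed.any():
        Dm, Lm, _, r2m, ok = estimate_doubling_times_matrix(
            times, smoothed[passed], window, min_r2
        )
        idx = np.flatnonzero(passed)
        D[idx] = Dm
        log2D[idx] = Lm
        r2[idx] = r2m
        for j, good in zip(idx, ok):
            if not good:
                flag_lists[j].add(FLAG_NO_GROWTH)
                passed[j] = False

    return pd.DataFrame(
        {
            "plate_id": [c.plate_id for c in curves],
            "row": [c.row for c in curves],
            "col": [c.col for c in curves],
            "D_hours": D,
            "log2D": log2D,
            "r2": r2,
            "qc_pass": passed,
            "flags": [",".join(sorted(f)) for f in flag_lists],
        }
    )
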