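"""Nutrigonometry: peak regions and nutritional trade-off trigonometry.

An optimum in (protein, carbohydrate) intake space is summarised by the
vector from the origin to the centroid of the peak region of the fitted
landscape. Its direction gives the optimal P:C ratio; the signed angle theta
between two optima (measured from the carbohydrate axis, in degrees)
measures a trade-off in nutrient *balance*, while the hypotenuse — the
length of the centroid vector — measures total diet *quantity*. With the
first region taken as females and the second as males, theta < 0 exactly
when the female optimal P:C ratio is below the male one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import FittedLandscape, PeakRegion, TradeoffMetrics, validate_points
from .reconstruction import fit_tps
from .tps import select_smoothing_gcv


def find_peak_region(landscape: FittedLandscape, q: float = 0.95) -> PeakRegion:
    """Grid points with predicted performance >= the q-quantile of the grid.

    The centroid (unweighted mean of the region's grid coordinates) is the
    optimum used by all trade-off metrics; it is robust to grid resolution
    and plateau-shaped peaks, unlike the single argmax cell.
    """
    if not 0.0 <= q < 1.0:
        raise ValueError("q must lie in [0, 1)")
    grid = landscape.grid_table()
    if len(grid) == 0:
        raise ValueError("landscape grid is empty")
    thr = float(np.quantile(grid["performance"], q))
    region = grid[grid["performance"] >= thr].reset_index(drop=True)
    centroid = (
        float(region["protein"].mean()),
        float(region["carbohydrate"].mean()),
    )
    return PeakRegion(grid_points=region, centroid=centroid, threshold_q=q)


def peak_argmax(landscape: FittedLandscape) -> tuple[float, float]:
    """The single best grid cell, as an alternative to the region centroid."""
    grid = landscape.grid_table()
    i = int(grid["performance"].idxmax())
    return float(grid.loc[i, "protein"]), float(grid.loc[i, "carbohydrate"])


def optimal_pc_ratio(region: PeakRegion) -> float:
    """Protein:carbohydrate ratio of the peak-region centroid."""
    p, c = region.centroid
    if abs(c) < 1e-12:
        raise ValueError("carbohydrate centroid is zero; P:C ratio undefined")
    return p / c


def _angle_from_carb_axis(region: PeakRegion) -> float:
    p, c = region.centroid
    if np.hypot(p, c) < 1e-12:
        raise ValueError("zero-length centroid vector; angle undefined")
    return float(np.degrees(np.arctan2(p, c)))


def angle_theta(region_a: PeakRegion, region_b: PeakRegion) -> float:
    """Signed angle (degrees) between two optima, a minus b.

    Angles are measured from the carbohydrate axis, so a larger P:C ratio
    means a larger angle; with a = female and b = male, theta < 0 exactly
    when the female optimal P:C ratio is lower than the male one.
    """
    return _angle_from_carb_axis(region_a) - _angle_from_carb_axis(region_b)


def hypotenuse(region: PeakRegion) -> float:
    """Euclidean distance from the origin to the peak-region centroid."""
    p, c = region.centroid
    return float(np.hypot(p, c))


def _prepare_fit(points: pd.DataFrame, smoothing, seed: int):
    """Resolve GCV once so bootstrap replicates reuse a fixed penalty."""
    if smoothing == "gcv" or smoothing is None:
        coords = points[["protein", "carbohydrate"]].to_numpy(float)
        values = points["performance"].to_numpy(float)
        from .tps import average_duplicates

        coords, values, _ = average_duplicates(coords, values)
        if len(coords) > 400:
            rng = np.random.default_rng(seed)
            sub = rng.choice(len(coords), size=400, replace=False)
            return select_smoothing_gcv(coords[sub], values[sub]) * (
                len(coords) / 400
            )
        return select_smoothing_gcv(coords, values)
    return float(smoothing)


def _region_from_points(points, smoothing, q, grid_size, seed) -> PeakRegion:
    landscape = fit_tps(
        points, smoothing=smoothing, grid_size=grid_size, seed=seed
    )
    return find_peak_region(landscape, q=q)


def bootstrap_metrics(
    points: pd.DataFrame,
    B: int = 1000,
    q: float = 0.95,
    seed: int = 0,
    smoothing: float | str = "gcv",
    grid_size: int = 40,
) -> TradeoffMetrics:
    """Bootstrap the optimal P:C ratio and hypotenuse of one landscape.

    Resamples points with replacement B times, refits the spline (with a
    penalty chosen once by GCV on the original data) and recomputes the
    metrics; reports replicate means and percentile 95% intervals.
    Degenerate replicates (e.g. collinear resamples) are skipped and
    counted; more than 10% skips is an error.
    """
    validate_points(points)
    if B < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    if len(points) < 6:
        raise ValueError("need at least 6 points")
    if np.ptp(points["performance"].to_numpy(float)) < 1e-12:
        raise ValueError("flat landscape: all performance values identical")
    pen = _prepare_fit(points, smoothing, seed)
    rng = np.random.default_rng(seed)

    ratios, hyps = [], []
    skipped = 0
    for _ in range(B):
        idx = rng.integers(len(points), size=len(points))
        try:
            region = _region_from_points(
                points.iloc[idx], pen, q, grid_size, seed
            )
            ratios.append(optimal_pc_ratio(region))
            hyps.append(hypotenuse(region))
        except (ValueError, np.linalg.LinAlgError):
            skipped += 1
    if skipped > 0.1 * B:
        raise ValueError(
            f"{skipped}/{B} bootstrap replicates were degenerate; "
            "check the input points"
        )
    ratios = np.asarray(ratios)
    hyps = np.asarray(hyps)
    ci = {
        "pc_ratio": tuple(np.percentile(ratios, [2.5, 97.5])),
        "hypotenuse": tuple(np.percentile(hyps, [2.5, 97.5])),
    }
    return TradeoffMetrics(
        pc_ratio=float(ratios.mean()),
        hypotenuse=float(hyps.mean()),
        theta=None,
        ci=ci,
        n_boot=B - skipped,
        n_skipped=skipped,
    )


def validate_reconstruction(
    original_points: pd.DataFrame,
    reconstructed_points: pd.DataFrame,
    B: int = 200,
    q: float = 0.95,
    seed: int = 0,
    smoothing: float | str = "gcv",
    grid_size: int = 40,
) -> dict:
    """Test whether a reconstructed landscape relocates the optimum.

    Bootstraps both point sets, computing per replicate the angle theta
    between the original and reconstructed optima and the difference of
    their hypotenuses. The verdict is "consistent" when both 95% intervals
    of these differences contain 0 — the two landscapes place their peak
    region in a comparable location.
    """
    pen_o = _prepare_fit(original_points, smoothing, seed)
    pen_r = _prepare_fit(reconstructed_points, smoothing, seed)
    region_o = _region_from_points(original_points, pen_o, q, grid_size, seed)
    region_r = _region_from_points(reconstructed_points, pen_r, q, grid_size, seed)

    rng = np.random.default_rng(seed)
    d_theta, d_hyp = [], []
    skipped = 0
    for _ in range(B):
        io = rng.integers(len(original_points), size=len(original_points))
        ir = rng.integers(len(reconstructed_points), size=len(reconstructed_points))
        try:
            ro = _region_from_points(
                original_points.iloc[io], pen_o, q, grid_size, seed
            )
            rr = _region_from_points(
                reconstructed_points.iloc[ir], pen_r, q, grid_size, seed
            )
            d_theta.append(angle_theta(ro, rr))
            d_hyp.append(hypotenuse(ro) - hypotenuse(rr))
        except (ValueError, np.linalg.LinAlgError):
            skipped += 1
    if skipped > 0.1 * B:
        raise ValueError(f"{skipped}/{B} bootstrap replicates were degenerate")
    ci_theta = tuple(np.percentile(d_theta, [2.5, 97.5]))
    ci_hyp = tuple(np.percentile(d_hyp, [2.5, 97.5]))
    consistent = ci_theta[0] <= 0 <= ci_theta[1] and ci_hyp[0] <= 0 <= ci_hyp[1]
    return {
        "delta_theta": angle_theta(region_o, region_r),
        "delta_theta_ci": ci_theta,
        "delta_hypotenuse": hypotenuse(region_o) - hypotenuse(region_r),
        "delta_hypotenuse_ci": ci_hyp,
        "verdict": "consistent" if consistent else "inconsistent",
        "n_boot": B - skipped,
        "n_skipped": skipped,
    }
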