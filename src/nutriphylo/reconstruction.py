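"""Semi-automated extraction of performance landscapes from contour images.

The five-stage algorithm turns a published banded contour plot back into an
analysable surface:

1. :func:`segment_layers` — cluster pixel colours into z-bands;
2. :func:`assign_layer_values` — attach a performance value to each band
   (for real figures these come from the legend and are supplied by hand);
3. :func:`pixels_to_nutrient_coords` — calibrate pixels into (protein,
   carbohydrate) intake coordinates;
4. :func:`add_jitter` + :func:`filter_noise` — break the ladder-like
   discretised z-axis with small Normal(0, 0.25) perturbations (a thin-plate
   spline cannot be estimated from exactly tied layers) and drop stray
   mis-segmented pixels;
5. :func:`fit_tps` — fit a penalised thin-plate spline and predict on a
   regular grid clipped to the data hull.

:func:`reconstruct_from_image` chains all five with a step-by-step log.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from scipy.spatial import Delaunay
from shapely.geometry import MultiPoint

from .containers import (
    Calibration,
    ContourImage,
    FittedLandscape,
    SegmentedLayer,
    validate_points,
)
from .tps import ThinPlateSpline, average_duplicates, select_smoothing_gcv

logger = logging.getLogger("nutriphylo")

_LUM = np.array([0.299, 0.587, 0.114])


def _border_majority_colour(pixels: np.ndarray) -> np.ndarray:
    border = np.concatenate(
        [pixels[0], pixels[-1], pixels[:, 0], pixels[:, -1]], axis=0
    )
    colours, counts = np.unique(border.reshape(-1, 3), axis=0, return_counts=True)
    return colours[np.argmax(counts)]


def _kmeans_colours(
    colours: np.ndarray, weights: np.ndarray, k: int, max_iter: int = 100
) -> np.ndarray:
    """Deterministic weighted k-means over unique colours.

    Farthest-point seeding from the most frequent colour; Lloyd iterations;
    ties broken by index. Returns cluster centres (k, 3).
    """
    X = colours.astype(float)
    centres = [X[int(np.argmax(weights))]]
    for _ in range(1, k):
        d = np.min(
            [np.linalg.norm(X - c, axis=1) for c in centres], axis=0
        )
        centres.append(X[int(np.argmax(d))])
    centres = np.array(centres)
    for _ in range(max_iter):
        d = np.linalg.norm(X[:, None, :] - centres[None, :, :], axis=2)
        assign = np.argmin(d, axis=1)
        new = centres.copy()
        for j in range(k):
            m = assign == j
            if m.any():
                new[j] = np.average(X[m], axis=0, weights=weights[m])
        if np.allclose(new, centres):
            break
        centres = new
    return centres


def segment_layers(
    image: ContourImage,
    n_colors: int,
    background_tol: float = 10.0,
) -> list[SegmentedLayer]:
    """Cluster non-background pixels into <= n_colors colour bands.

    The background colour is taken as the majority colour of the image
    border; pixels within ``background_tol`` (Euclidean RGB distance) of it
    are excluded. When the image holds no more than ``n_colors`` distinct
    colours each exact colour becomes its own cluster; otherwise a
    deterministic k-means in RGB space is used. Clusters are ordered by mean
    luminance (darkest first) and given 1-based ids.
    """
    if n_colors < 1:
        raise ValueError("n_colors must be >= 1")
    pixels = image.pixels
    bg = _border_majority_colour(pixels)
    flat = pixels.reshape(-1, 3).astype(float)
    if len(np.unique(flat, axis=0)) == 1:
        # uniform image: no background to strip, the one colour is the layer
        non_bg = np.ones(len(flat), dtype=bool)
    else:
        non_bg = np.linalg.norm(flat - bg, axis=1) > background_tol
    if image.plot_mask is not None:
        non_bg &= image.plot_mask.ravel()
    if not non_bg.any():
        raise ValueError("image contains only background pixels")

    H, W = pixels.shape[:2]
    rows, cols = np.divmod(np.flatnonzero(non_bg), W)
    fg = flat[non_bg]
    colours, inverse, counts = np.unique(
        fg, axis=0, return_inverse=True, return_counts=True
    )
    if len(colours) <= n_colors:
        if len(colours) < n_colors:
            warnings.warn(
                f"image has only {len(colours)} distinct foreground colours; "
                f"returning {len(colours)} clusters instead of {n_colors}",
                stacklevel=2,
            )
        centres = colours
        assign = inverse
    else:
        centres = _kmeans_colours(colours, counts.astype(float), n_colors)
        d = np.linalg.norm(colours[:, None, :] - centres[None, :, :], axis=2)
        assign = np.argmin(d, axis=1)[inverse]

    layers = []
    for j in range(len(centres)):
        m = assign == j
        if not m.any():
            continue
        layers.append(
            SegmentedLayer(
                cluster_id=-1,
                colour_centre=np.asarray(centres[j]),
                pixel_set=np.column_stack([rows[m], cols[m]]).astype(int),
            )
        )
    layers.sort(key=lambda l: float(l.colour_centre @ _LUM))
    for i, layer in enumerate(layers):
        layer.cluster_id = i + 1
    return layers


def assign_layer_values(
    layers: list[SegmentedLayer], band_value_map: dict[int, float]
) -> list[SegmentedLayer]:
    """Attach a performance value to each segmented layer.

    ``band_value_map`` maps cluster id -> z value (for published figures the
    user reads these off the legend; ordering need not follow luminance).
    """
    missing = [l.cluster_id for l in layers if l.cluster_id not in band_value_map]
    if missing:
        raise ValueError(f"band_value_map is missing cluster ids: {missing}")
    return [
        SegmentedLayer(
            cluster_id=l.cluster_id,
            colour_centre=l.colour_centre,
            pixel_set=l.pixel_set,
            assigned_value=float(band_value_map[l.cluster_id]),
        )
        for l in layers
    ]


def pixels_to_nutrient_coords(
    pixels: np.ndarray, calibration: Calibration
) -> np.ndarray:
    """Map (row, col) pixel coordinates to (protein, carbohydrate) pairs."""
    pixels = np.atleast_2d(np.asarray(pixels, float))
    protein, carb = calibration.pixel_to_nutrient(pixels[:, 0], pixels[:, 1])
    return np.column_stack([protein, carb])


def layers_to_points(
    layers: list[SegmentedLayer], calibration: Calibration
) -> pd.DataFrame:
    """Flatten value-assigned layers into a point table (with pixel coords)."""
    unassigned = [l.cluster_id for l in layers if l.assigned_value is None]
    if unassigned:
        raise ValueError(f"layers without assigned values: {unassigned}")
    frames = []
    for l in layers:
        nut = pixels_to_nutrient_coords(l.pixel_set, calibration)
        frames.append(
            pd.DataFrame(
                {
                    "protein": nut[:, 0],
                    "carbohydrate": nut[:, 1],
                    "performance": l.assigned_value,
                    "row": l.pixel_set[:, 0],
                    "col": l.pixel_set[:, 1],
                    "cluster_id": l.cluster_id,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def add_jitter(points: pd.DataFrame, sd: float = 0.25, seed: int = 0) -> pd.DataFrame:
    """Perturb performance by independent Normal(0, sd^2) draws.

    The default sd of 0.25 z-units (absolute, regardless of the trait's
    scale) breaks the ladder-like discretised z-axis so the spline is
    estimable; (protein, carbohydrate) coordinates are untouched.
    """
    if sd < 0:
        raise ValueError("jitter sd must be >= 0")
    validate_points(points)
    out = points.copy()
    if sd > 0:
        rng = np.random.default_rng(seed)
        out["performance"] = out["performance"].to_numpy(float) + rng.normal(
            0.0, sd, size=len(out)
        )
    return out


def filter_noise(
    points: pd.DataFrame,
    min_cluster_pixels: int = 10,
    hull_margin: float | None = None,
) -> pd.DataFrame:
    """Drop mis-segmented stray points.

    Two rules: (a) points whose pixels fall in 8-connected components
    smaller than ``min_cluster_pixels`` are removed; (b) points outside the
    convex hull of the largest component, expanded by ``hull_margin``
    (nutrient units; default 5% of the axis range, ``inf`` disables), are
    removed. Requires pixel ``row``/``col`` columns for rule (a); point
    tables without them get rule (b) only, anchored on all points.
    """
    validate_points(points)
    out = points
    if {"row", "col"}.issubset(points.columns):
        r = points["row"].to_numpy(int)
        c = points["col"].to_numpy(int)
        raster = np.zeros((r.max() + 2, c.max() + 2), dtype=bool)
        raster[r, c] = True
        labels, _ = ndimage.label(raster, structure=np.ones((3, 3), int))
        comp = labels[r, c]
        sizes = np.bincount(comp.ravel())
        keep = sizes[comp] >= min_cluster_pixels
        largest = int(np.argmax(sizes[1:]) + 1)
        anchor = points.loc[comp == largest, ["protein", "carbohydrate"]]
        out = points.loc[keep]
    else:
        anchor = points[["protein", "carbohydrate"]]

    if hull_margin is None:
        rng_p = float(np.ptp(points["protein"]))
        rng_c = float(np.ptp(points["carbohydrate"]))
        hull_margin = 0.05 * max(rng_p, rng_c)
    if np.isfinite(hull_margin) and len(out):
        hull = MultiPoint(anchor.to_numpy(float)).convex_hull.buffer(hull_margin)
        inside = shapely.contains_xy(
            hull, out["protein"].to_numpy(float), out["carbohydrate"].to_numpy(float)
        )
        out = out.loc[inside]
    if len(out) == 0:
        raise ValueError(
            "noise filter would remove every point; relax min_cluster_pixels "
            "or hull_margin"
        )
    return out.reset_index(drop=True)


def thin_points(
    points: pd.DataFrame, max_points: int = 2000, seed: int = 0
) -> pd.DataFrame:
    """Uniformly subsample a point table to at most ``max_points`` rows."""
    if len(points) <= max_points:
        return points.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(points), size=max_points, replace=False))
    return points.iloc[idx].reset_index(drop=True)


def fit_tps(
    points: pd.DataFrame,
    smoothing: float | str = "gcv",
    grid_size: int = 60,
    max_points: int = 2000,
    seed: int = 0,
) -> FittedLandscape:
    """Fit a penalised thin-plate spline and predict on a regular grid.

    ``smoothing`` is either a non-negative bending-energy penalty or "gcv",
    which minimises the generalised cross-validation score over a log-spaced
    grid (selected on a 400-point subsample for large tables, with the
    penalty rescaled in proportion to the fitted point count). Coincident
    duplicate coordinates are averaged. The grid is clipped to the convex
    hull of the points (NaN outside).
    """
    validate_points(points)
    points = thin_points(points, max_points=max_points, seed=seed)
    coords = points[["protein", "carbohydrate"]].to_numpy(float)
    values = points["performance"].to_numpy(float)
    coords, values, n_merged = average_duplicates(coords, values)
    if n_merged:
        logger.debug("averaged %d duplicate coordinates", n_merged)
    if len(coords) < 6:
        raise ValueError("need at least 6 distinct points")

    if smoothing == "gcv":
        n = len(coords)
        if n > 400:
            rng = np.random.default_rng(seed)
            sub = rng.choice(n, size=400, replace=False)
            smoothing = select_smoothing_gcv(coords[sub], values[sub]) * (n / 400)
        else:
            smoothing = select_smoothing_gcv(coords, values)
    spline = ThinPlateSpline(coords, values, smoothing=float(smoothing))

    gp = np.linspace(coords[:, 0].min(), coords[:, 0].max(), grid_size)
    gc = np.linspace(coords[:, 1].min(), coords[:, 1].max(), grid_size)
    pp, cc = np.meshgrid(gp, gc, indexing="ij")
    grid_coords = np.column_stack([pp.ravel(), cc.ravel()])
    tri = Delaunay(coords)
    inside = tri.find_simplex(grid_coords) >= 0
    z = np.full(len(grid_coords), np.nan)
    z[inside] = spline.predict(grid_coords[inside])
    return FittedLandscape(
        points=points,
        smoothing=float(smoothing),
        grid_protein=gp,
        grid_carbohydrate=gc,
        grid_performance=z.reshape(grid_size, grid_size),
        residuals=spline.residuals,
        spline=spline,
    )


def reconstruct_from_image(
    image: ContourImage,
    n_colors: int,
    band_value_map: dict[int, float] | None = None,
    jitter_sd: float = 0.25,
    min_cluster_pixels: int = 10,
    hull_margin: float | None = None,
    smoothing: float | str = "gcv",
    grid_size: int = 60,
    max_points: int = 2000,
    seed: int = 0,
) -> tuple[pd.DataFrame, FittedLandscape, dict]:
    """Run the full extraction: segment, assign, calibrate, jitter, filter, fit.

    Returns the reconstructed point table, the fitted landscape, and a log
    dict with per-step point/pixel counts for auditability.
    """
    bvm = band_value_map if band_value_map is not None else image.band_value_map
    if bvm is None:
        raise ValueError("no band_value_map supplied (argument or image metadata)")
    layers = segment_layers(image, n_colors=n_colors)
    layers = assign_layer_values(layers, bvm)
    points = layers_to_points(layers, image.calibration)
    n_raw = len(points)
    points = add_jitter(points, sd=jitter_sd, seed=seed)
    points = filter_noise(
        points, min_cluster_pixels=min_cluster_pixels, hull_margin=hull_margin
    )
    n_filtered = len(points)
    landscape = fit_tps(
        points,
        smoothing=smoothing,
        grid_size=grid_size,
        max_points=max_points,
        seed=seed,
    )
    log = {
        "n_layers": len(layers),
        "n_pixels_segmented": n_raw,
        "n_points_after_filter": n_filtered,
        "n_points_fitted": len(landscape.points),
        "smoothing": landscape.smoothing,
        "jitter_sd": jitter_sd,
        "seed": seed,
    }
    return points, landscape, log
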