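"""Shared data containers for landscape reconstruction and trade-off metrics.

Point tables are plain :class:`pandas.DataFrame` objects with columns
``protein``, ``carbohydrate``, ``performance`` (intake-space units on the
first two, the source figure's z-axis units — e.g. lifespan in days — on the
third). Points derived from an image additionally carry ``row`` and ``col``
pixel coordinates so that the noise filter can reason about pixel
connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

POINT_COLUMNS = ("protein", "carbohydrate", "performance")


def validate_points(points: pd.DataFrame) -> pd.DataFrame:
    """Check a point table has the required columns and finite values."""
    missing = [c for c in POINT_COLUMNS if c not in points.columns]
    if missing:
        raise ValueError(f"point table missing columns: {missing}")
    if len(points) == 0:
        raise ValueError("point table is empty")
    vals = points[list(POINT_COLUMNS)].to_numpy(float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("point table contains non-finite values")
    return points


@dataclass(frozen=True)
class Calibration:
    """Affine pixel-to-nutrient axis calibration.

    Two reference pixels per axis with their nutrient values. ``protein_axis``
    declares whether protein runs along image columns ("horizontal") or rows
    ("vertical"); the other nutrient takes the remaining axis. Row indices
    increase downwards while nutrient values increase upwards, so a vertical
    axis is calibrated with a negative slope — the affine map handles the
    inversion with no special casing.
    """

    protein_pixels: tuple[float, float]
    protein_values: tuple[float, float]
    carb_pixels: tuple[float, float]
    carb_values: tuple[float, float]
    protein_axis: str = "horizontal"  # "horizontal" (columns) or "vertical" (rows)

    def __post_init__(self) -> None:
        if self.protein_axis not in ("horizontal", "vertical"):
            raise ValueError("protein_axis must be 'horizontal' or 'vertical'")
        for name, (a, b) in (
            ("protein", self.protein_pixels),
            ("carbohydrate", self.carb_pixels),
        ):
            if a == b:
                raise ValueError(
                    f"coincident calibration reference pixels on {name} axis"
                )

    @staticmethod
    def _affine(pixels: tuple[float, float], values: tuple[float, float]):
        slope = (values[1] - values[0]) / (pixels[1] - pixels[0])
        return slope, values[0] - slope * pixels[0]

    def pixel_to_nutrient(self, rows: np.ndarray, cols: np.ndarray):
        """Map pixel (row, col) arrays to (protein, carbohydrate) arrays."""
        ps, pi = self._affine(self.protein_pixels, self.protein_values)
        cs, ci = self._affine(self.carb_pixels, self.carb_values)
        if self.protein_axis == "horizontal":
            protein = ps * np.asarray(cols, float) + pi
            carb = cs * np.asarray(rows, float) + ci
        else:
            protein = ps * np.asarray(rows, float) + pi
            carb = cs * np.asarray(cols, float) + ci
        return protein, carb

    def nutrient_to_pixel(self, protein: np.ndarray, carb: np.ndarray):
        """Inverse map, returning (rows, cols) as floats."""
        ps, pi = self._affine(self.protein_pixels, self.protein_values)
        cs, ci = self._affine(self.carb_pixels, self.carb_values)
        p_pix = (np.asarray(protein, float) - pi) / ps
        c_pix = (np.asarray(carb, float) - ci) / cs
        if self.protein_axis == "horizontal":
            return c_pix, p_pix
        return p_pix, c_pix


@dataclass
class ContourImage:
    """A banded contour-plot raster plus the metadata needed to read it.

    ``band_value_map`` maps a colour-cluster id (1-based, clusters ordered by
    luminance after segmentation) to the performance value of that band; for
    published figures it is supplied by the user from the legend, for
    synthetic images it is produced by the renderer.
    """

    pixels: np.ndarray  # (H, W, 3) uint8
    calibration: Calibration
    band_value_map: Optional[dict[int, float]] = None
    plot_mask: Optional[np.ndarray] = None  # (H, W) bool, True inside plot region

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty (H, W, 3) raster")
        if self.band_value_map is not None and not all(
            np.isfinite(v) for v in self.band_value_map.values()
        ):
            raise ValueError("band_value_map values must be finite")


@dataclass
class SegmentedLayer:
    """One colour cluster of a segmented contour image (one z-band)."""

    cluster_id: int
    colour_centre: np.ndarray  # RGB triple
    pixel_set: np.ndarray  # (N, 2) int array of (row, col)
    assigned_value: Optional[float] = None

    @property
    def n_pixels(self) -> int:
        return len(self.pixel_set)


@dataclass
class FittedLandscape:
    """A thin-plate-spline performance surface over the intake plane.

    ``grid_performance`` holds predictions on the regular
    ``grid_protein`` x ``grid_carbohydrate`` lattice, NaN outside the convex
    hull of the fitted points.
    """

    points: pd.DataFrame
    smoothing: float
    grid_protein: np.ndarray  # (gp,)
    grid_carbohydrate: np.ndarray  # (gc,)
    grid_performance: np.ndarray  # (gp, gc), NaN outside hull
    residuals: np.ndarray
    spline: object = field(repr=False, default=None)

    def grid_table(self) -> pd.DataFrame:
        """Long-format (protein, carbohydrate, performance) grid table."""
        pp, cc = np.meshgrid(self.grid_protein, self.grid_carbohydrate, indexing="ij")
        df = pd.DataFrame(
            {
                "protein": pp.ravel(),
                "carbohydrate": cc.ravel(),
                "performance": self.grid_performance.ravel(),
            }
        )
        return df.dropna().reset_index(drop=True)


@dataclass
class PeakRegion:
    """Grid points whose predicted performance is in the top quantile."""

    grid_points: pd.DataFrame  # columns protein, carbohydrate, performance
    centroid: tuple[float, float]  # (protein, carbohydrate)
    threshold_q: float

    def __post_init__(self) -> None:
        if len(self.grid_points) == 0:
            raise ValueError("peak region is empty")


@dataclass
class TradeoffMetrics:
    """Nutrigonometry summary of one optimum (or a pair of optima).

    ``theta`` is only defined for a pair of peak regions (e.g. female vs
    male); single-landscape bootstraps leave it None.
    """

    pc_ratio: float
    hypotenuse: float
    theta: Optional[float] = None
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_boot: int = 0
    n_skipped: int = 0
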