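"""Synthetic study generators: landscapes, contour images, trees, traits.

Every downstream stage of the pipeline gets a ground-truth oracle from here:

* single-peaked (Gaussian) performance surfaces sampled along Geometric
  Framework diet rails — rays from the origin in (protein, carbohydrate)
  intake space with a fixed P:C ratio, sampled at several total-intake
  (dilution) levels;
* those point clouds rendered as discrete colour-band contour images, the
  inverse of the extraction algorithm, with per-band pixel masks kept;
* pure-birth (Yule) phylogenies; and
* tip traits evolved under Brownian motion or its lambda-scaled relaxation,
  with known phylogenetic signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import matplotlib
import numpy as np
import pandas as pd
from scipy.spatial import Delaunay

from .containers import Calibration, ContourImage, validate_points
from .phylo import lambda_transform, vcv_from_tree
from .tps import ThinPlateSpline, average_duplicates

# Rail ratios span 1:8 to 8:1 P:C and dilutions cover low to high total
# intake, mirroring typical Geometric Framework designs; the peak sits at a
# carbohydrate-biased optimum (P:C = 1:2) as found for lifespan in most
# insect studies, with lifespan-scaled heights in days.
DEFAULT_RAILS = (0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0)
DEFAULT_DILUTIONS = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0)


@dataclass(frozen=True)
class LandscapeSpec:
    """Ground-truth single-peak performance surface and its sampling design."""

    peak_p: float = 2.0
    peak_c: float = 4.0
    peak_height: float = 30.0
    baseline: float = 20.0
    width_p: float = 1.5
    width_c: float = 2.5
    noise_sd: float = 0.0
    rails: tuple[float, ...] = DEFAULT_RAILS
    dilutions: tuple[float, ...] = DEFAULT_DILUTIONS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.peak_p < 0 or self.peak_c < 0:
            raise ValueError("peak coordinates must be non-negative")
        if self.width_p <= 0 or self.width_c <= 0:
            raise ValueError("widths must be positive")
        if self.baseline + self.peak_height <= self.baseline:
            raise ValueError("peak performance must exceed the baseline floor")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if any(r <= 0 for r in self.rails):
            raise ValueError("rail ratios must be positive")
        if any(d <= 0 for d in self.dilutions):
            raise ValueError("dilutions must be strictly positive")

    def surface(self, protein, carbohydrate) -> np.ndarray:
        """Noise-free performance at the given intake coordinates."""
        p = np.asarray(protein, float)
        c = np.asarray(carbohydrate, float)
        bump = np.exp(
            -((p - self.peak_p) ** 2) / (2 * self.width_p**2)
            - ((c - self.peak_c) ** 2) / (2 * self.width_c**2)
        )
        return self.baseline + self.peak_height * bump


def simulate_performance_points(spec: LandscapeSpec) -> pd.DataFrame:
    """Sample the surface at every (rail, dilution) intake point.

    A rail with P:C ratio r at total intake d contributes the point
    P = d*r/(1+r), C = d/(1+r) (so P + C = d and P/C = r), with performance
    drawn as surface value + Normal(0, noise_sd).
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for r in spec.rails:
        for d in spec.dilutions:
            p = d * r / (1.0 + r)
            c = d / (1.0 + r)
            rows.append((r, d, p, c))
    df = pd.DataFrame(rows, columns=["rail", "dilution", "protein", "carbohydrate"])
    perf = spec.surface(df["protein"], df["carbohydrate"])
    if spec.noise_sd > 0:
        perf = perf + rng.normal(0.0, spec.noise_sd, size=len(df))
    df["performance"] = np.asarray(perf, float)
    return df


def default_palette(n_bands: int) -> np.ndarray:
    """n_bands distinct, non-white RGB colours from the viridis map."""
    cmap = matplotlib.colormaps["viridis"]
    cols = (np.array([cmap(x)[:3] for x in np.linspace(0.0, 0.92, n_bands)]) * 255)
    return np.round(cols).astype(np.uint8)


def _check_palette(palette: np.ndarray, min_dist: float = 20.0) -> None:
    pal = palette.astype(float)
    for i in range(len(pal)):
        if np.linalg.norm(pal[i] - 255.0) < 60.0:
            raise ValueError("palette colour too close to the white background")
        for j in range(i + 1, len(pal)):
            if np.linalg.norm(pal[i] - pal[j]) < min_dist:
                raise ValueError("palette colours are not pairwise distinct enough")


def render_contour_image(
    points: pd.DataFrame,
    n_bands: int = 6,
    palette: np.ndarray | None = None,
    image_size: tuple[int, int] = (240, 240),
    margin: int = 12,
) -> tuple[ContourImage, dict]:
    """Render a point cloud as a discrete colour-band contour image.

    Fits an exact interpolating thin-plate spline to the points, discretises
    the predicted performance into ``n_bands`` equal-width value bands inside
    the convex hull of the points, and paints each band a flat palette colour
    on a pure-white background. Returns the image (with axis calibration and
    the cluster-id -> band-value map) plus a ground-truth dict with per-band
    pixel masks, band edges/mid-values and the nutrient extent.
    """
    validate_points(points)
    if n_bands < 2:
        raise ValueError("need at least 2 bands")
    palette = default_palette(n_bands) if palette is None else np.asarray(palette)
    if len(palette) != n_bands:
        raise ValueError("palette must supply one colour per band")
    _check_palette(palette)

    coords = points[["protein", "carbohydrate"]].to_numpy(float)
    values = points["performance"].to_numpy(float)
    coords, values, _ = average_duplicates(coords, values)
    if np.ptp(values) < 1e-12:
        raise ValueError("all points share one performance value; cannot band")
    spline = ThinPlateSpline(coords, values, smoothing=0.0)

    H, W = image_size
    pmin, pmax = coords[:, 0].min(), coords[:, 0].max()
    cmin, cmax = coords[:, 1].min(), coords[:, 1].max()
    calibration = Calibration(
        protein_pixels=(margin, W - 1 - margin),
        protein_values=(pmin, pmax),
        carb_pixels=(H - 1 - margin, margin),  # rows invert: bottom row = cmin
        carb_values=(cmin, cmax),
        protein_axis="horizontal",
    )
    rows, cols = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    protein, carb = calibration.pixel_to_nutrient(rows.ravel(), cols.ravel())
    tri = Delaunay(coords)
    inside = tri.find_simplex(np.column_stack([protein, carb])) >= 0

    z = np.full(H * W, np.nan)
    z[inside] = spline.predict(np.column_stack([protein[inside], carb[inside]]))
    zin = z[inside]
    zmin, zmax = zin.min(), zin.max()
    if zmax - zmin < 1e-12:
        raise ValueError("predicted surface is flat; cannot band")
    edges = np.linspace(zmin, zmax, n_bands + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    band = np.clip(np.digitize(z, edges) - 1, 0, n_bands - 1)

    pixels = np.full((H * W, 3), 255, dtype=np.uint8)
    masks = []
    for b in range(n_bands):
        m = inside & (band == b)
        pixels[m] = palette[b]
        masks.append(m.reshape(H, W))
    pixels = pixels.reshape(H, W, 3)

    # cluster ids follow luminance order (ascending), matching segment_layers
    lum = palette.astype(float) @ np.array([0.299, 0.587, 0.114])
    order = np.argsort(lum, kind="stable")
    band_value_map = {rank + 1: float(mids[b]) for rank, b in enumerate(order)}

    image = ContourImage(
        pixels=pixels,
        calibration=calibration,
        band_value_map=band_value_map,
        plot_mask=inside.reshape(H, W),
    )
    truth = {
        "masks": masks,
        "band_edges": edges,
        "band_mids": mids,
        "palette": palette,
        "extent": (pmin, pmax, cmin, cmax),
        "calibration": calibration,
    }
    return image, truth


@dataclass(frozen=True)
class TreeSim:
    n_tips: int
    model: str = "pure-birth"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tips < 3:
            raise ValueError("need at least 3 tips")
        if self.model != "pure-birth":
            raise ValueError("only the pure-birth model is supported")


def simulate_tree(sim: TreeSim | int, seed: int | None = None) -> dendropy.Tree:
    """Pure-birth (Yule, unit rate) tree with ``n_tips`` labelled tips.

    Branch lengths are in arbitrary time units. Tips are labelled t1..tn;
    the Newick string is bit-reproducible under a fixed seed.
    """
    if not isinstance(sim, TreeSim):
        sim = TreeSim(n_tips=int(sim), seed=0 if seed is None else int(seed))
    rng = np.random.default_rng(sim.seed)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = True
    root = tree.seed_node
    active = [root.new_child(edge_length=0.0), root.new_child(edge_length=0.0)]
    while len(active) < sim.n_tips:
        k = len(active)
        wait = rng.exponential(1.0 / k)
        for nd in active:
            nd.edge.length += wait
        nd = active.pop(int(rng.integers(k)))
        active.append(nd.new_child(edge_length=0.0))
        active.append(nd.new_child(edge_length=0.0))
    wait = rng.exponential(1.0 / len(active))
    for nd in active:
        nd.edge.length += wait
    for i, nd in enumerate(active):
        nd.taxon = tns.new_taxon(f"t{i + 1}")
    return tree


def _draw_tip_values(C: np.ndarray, sigma2: float, rng) -> np.ndarray:
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    if sigma2 == 0:
        return np.zeros(len(C))
    try:
        L = np.linalg.cholesky(sigma2 * C)
    except np.linalg.LinAlgError:
        L = np.linalg.cholesky(sigma2 * C + 1e-10 * np.eye(len(C)))
    return L @ rng.standard_normal(len(C))


def _trait_frame(labels, values, trait, study, sex) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "species": labels,
            "trait": trait,
            "value": values,
            "study": study,
            "sex": sex,
        }
    )


def simulate_bm_traits(
    tree: dendropy.Tree,
    sigma2: float = 1.0,
    seed: int = 0,
    trait: str = "optimal_pc_ratio",
    study: str = "s1",
    sex: str = "female",
) -> pd.DataFrame:
    """Tip traits under Brownian motion: MVN(0, sigma2 * C(tree))."""
    cov = vcv_from_tree(tree)
    rng = np.random.default_rng(seed)
    vals = _draw_tip_values(cov.matrix, sigma2, rng)
    return _trait_frame(cov.labels, vals, trait, study, sex)


def simulate_lambda_traits(
    tree: dendropy.Tree,
    lam: float,
    sigma2: float = 1.0,
    seed: int = 0,
    trait: str = "optimal_pc_ratio",
    study: str = "s1",
    sex: str = "female",
) -> pd.DataFrame:
    """Tip traits with Pagel's-lambda-scaled covariance.

    lam = 1 reproduces :func:`simulate_bm_traits` draw-for-draw under the
    same seed; lam = 0 gives independent tips (variances preserved).
    """
    cov = vcv_from_tree(tree)
    C = lambda_transform(cov.matrix, lam)
    rng = np.random.default_rng(seed)
    vals = _draw_tip_values(C, sigma2, rng)
    return _trait_frame(cov.labels, vals, trait, study, sex)


def simulate_trait_dataset(
    tree: dendropy.Tree,
    lam: float = 1.0,
    sigma2: float = 1.0,
    n_studies: int = 3,
    study_sd: float = 0.3,
    resid_sd: float = 0.2,
    seed: int = 0,
    trait: str = "optimal_pc_ratio",
    sex: str = "female",
) -> pd.DataFrame:
    """Replicated trait observations: species-level phylogenetic value plus
    study-level and observation-level Gaussian effects, one observation per
    species per study. Suited to mixed-model parameter-recovery tests."""
    cov = vcv_from_tree(tree)
    rng = np.random.default_rng(seed)
    species_vals = _draw_tip_values(lambda_transform(cov.matrix, lam), sigma2, rng)
    frames = []
    for s in range(n_studies):
        eff = rng.normal(0.0, study_sd)
        vals = species_vals + eff + rng.normal(0.0, resid_sd, size=len(species_vals))
        frames.append(_trait_frame(cov.labels, vals, trait, f"s{s + 1}", sex))
    return pd.concat(frames, ignore_index=True)
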