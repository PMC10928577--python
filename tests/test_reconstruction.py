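"""Extraction algorithm: segmentation, calibration, jitter, filtering, fit."""

import numpy as np
import pandas as pd
import pytest

from nutriphylo import (
    Calibration,
    ContourImage,
    add_jitter,
    assign_layer_values,
    filter_noise,
    fit_tps,
    pixels_to_nutrient_coords,
    reconstruct_from_image,
    segment_layers,
)
from nutriphylo.reconstruction import layers_to_points


def _mask_from_layer(layer, shape):
    m = np.zeros(shape, dtype=bool)
    m[layer.pixel_set[:, 0], layer.pixel_set[:, 1]] = True
    return m


class TestSegmentation:
    def test_exact_flat_colours_recover_generator_masks(self, rendered):
        image, truth = rendered
        layers = segment_layers(image, n_colors=len(truth["band_mids"]))
        assert len(layers) == len(truth["band_mids"])
        # match layers to generator bands by colour and compare pixel sets
        shape = image.pixels.shape[:2]
        for layer in layers:
            band = int(np.argmin(
                np.linalg.norm(truth["palette"] - layer.colour_centre, axis=1)
            ))
            np.testing.assert_array_equal(
                _mask_from_layer(layer, shape), truth["masks"][band]
            )

    def test_segmentation_partitions_non_background(self, rendered):
        image, truth = rendered
        layers = segment_layers(image, n_colors=len(truth["band_mids"]))
        non_bg = int((~np.all(image.pixels == 255, axis=2)).sum())
        assert sum(l.n_pixels for l in layers) == non_bg
        ids = [l.cluster_id for l in layers]
        assert ids == sorted(ids) == list(range(1, len(layers) + 1))

    def test_uniform_image_single_layer(self):
        pixels = np.full((20, 30, 3), [40, 80, 120], dtype=np.uint8)
        cal = Calibration((0, 29), (0.0, 10.0), (19, 0), (0.0, 5.0))
        layers = segment_layers(ContourImage(pixels=pixels, calibration=cal), 1)
        assert len(layers) == 1
        assert layers[0].n_pixels == 20 * 30

    def test_fewer_colours_than_requested_warns(self, rendered):
        image, truth = rendered
        with pytest.warns(UserWarning, match="distinct foreground colours"):
            layers = segment_layers(image, n_colors=len(truth["band_mids"]) + 2)
        assert len(layers) == len(truth["band_mids"])

    def test_all_background_image_rejected(self):
        pixels = np.full((10, 10, 3), 255, dtype=np.uint8)
        pixels[5, 5] = [250, 250, 250]  # within background tolerance
        cal = Calibration((0, 9), (0.0, 1.0), (9, 0), (0.0, 1.0))
        with pytest.raises(ValueError, match="background"):
            segment_layers(ContourImage(pixels=pixels, calibration=cal), 2)


class TestAssignLayerValues:
    def test_values_attached(self, rendered):
        image, truth = rendered
        layers = segment_layers(image, n_colors=len(truth["band_mids"]))
        assigned = assign_layer_values(layers, image.band_value_map)
        got = {l.cluster_id: l.assigned_value for l in assigned}
        assert got == image.band_value_map

    def test_missing_id_reported(self, rendered):
        image, truth = rendered
        layers = segment_layers(image, n_colors=len(truth["band_mids"]))
        incomplete = {k: v for k, v in image.band_value_map.items() if k != 3}
        with pytest.raises(ValueError, match=r"\[3\]"):
            assign_layer_values(layers, incomplete)


class TestCalibration:
    def test_column_midpoint(self):
        cal = Calibration(protein_pixels=(0, 100), protein_values=(0.0, 1.0),
                          carb_pixels=(10, 110), carb_values=(0.0, 10.0),
                          protein_axis="vertical")
        # carbohydrate on columns: col 10 -> 0, col 110 -> 10, col 60 -> 5
        nut = pixels_to_nutrient_coords(np.array([[0, 60]]), cal)
        assert nut[0, 1] == pytest.approx(5.0)

    def test_row_inversion(self):
        cal = Calibration(protein_pixels=(200, 100), protein_values=(0.0, 10.0),
                          carb_pixels=(0, 50), carb_values=(0.0, 5.0),
                          protein_axis="vertical")
        nut = pixels_to_nutrient_coords(np.array([[150, 0]]), cal)
        assert nut[0, 0] == pytest.approx(5.0)  # row 150 between 200 and 100

    def test_random_affine_round_trip(self):
        rng = np.random.default_rng(4)
        cal = Calibration(protein_pixels=(13, 217), protein_values=(0.4, 8.7),
                          carb_pixels=(190, 22), carb_values=(0.1, 11.3))
        protein = rng.uniform(0.4, 8.7, 50)
        carb = rng.uniform(0.1, 11.3, 50)
        rows, cols = cal.nutrient_to_pixel(protein, carb)
        p2, c2 = cal.pixel_to_nutrient(rows, cols)
        np.testing.assert_allclose(p2, protein, atol=1e-10)
        np.testing.assert_allclose(c2, carb, atol=1e-10)

    def test_coincident_references_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            Calibration((5, 5), (0.0, 1.0), (0, 9), (0.0, 1.0))


class TestJitter:
    def test_sd_zero_is_identity(self, gaussian_points):
        out = add_jitter(gaussian_points, sd=0.0, seed=1)
        pd.testing.assert_frame_equal(out, gaussian_points)

    def test_normal_moments_at_scale(self, gaussian_points):
        base = pd.concat([gaussian_points] * 1786, ignore_index=True)  # ~100k
        out = add_jitter(base, sd=0.25, seed=2)
        delta = out["performance"] - base["performance"]
        assert abs(delta.mean()) < 0.01
        assert delta.std() == pytest.approx(0.25, abs=0.01)

    def test_deterministic_and_coordinate_preserving(self, gaussian_points):
        a = add_jitter(gaussian_points, sd=0.25, seed=3)
        b = add_jitter(gaussian_points, sd=0.25, seed=3)
        pd.testing.assert_frame_equal(a, b)
        assert len(a) == len(gaussian_points)
        pd.testing.assert_frame_equal(
            a[["protein", "carbohydrate"]],
            gaussian_points[["protein", "carbohydrate"]],
        )


def _points_with_pixels(rendered):
    image, truth = rendered
    layers = segment_layers(image, n_colors=len(truth["band_mids"]))
    layers = assign_layer_values(layers, image.band_value_map)
    return layers_to_points(layers, image.calibration), image


class TestFilterNoise:
    def test_clean_segmentation_untouched(self, rendered):
        points, _ = _points_with_pixels(rendered)
        out = filter_noise(points, min_cluster_pixels=10)
        assert len(out) == len(points)

    def test_salt_noise_removed(self, rendered):
        points, image = _points_with_pixels(rendered)
        H, W = image.pixels.shape[:2]
        # 5 isolated pixels in the far image corner, well outside the plot
        salt_px = [(1, W - 2), (3, W - 3), (1, W - 6), (5, W - 2), (3, W - 8)]
        nut = pixels_to_nutrient_coords(np.array(salt_px), image.calibration)
        salt = pd.DataFrame({
            "protein": nut[:, 0], "carbohydrate": nut[:, 1],
            "performance": 10.0,
            "row": [p[0] for p in salt_px], "col": [p[1] for p in salt_px],
            "cluster_id": 1,
        })
        noisy = pd.concat([points, salt], ignore_index=True)
        out = filter_noise(noisy, min_cluster_pixels=10)
        assert len(out) == len(points)

    def test_infinite_margin_leaves_only_component_rule(self, rendered):
        points, image = _points_with_pixels(rendered)
        out = filter_noise(points, min_cluster_pixels=1, hull_margin=np.inf)
        assert len(out) == len(points)

    def test_removing_everything_is_an_error(self, rendered):
        points, _ = _points_with_pixels(rendered)
        with pytest.raises(ValueError, match="remove every point"):
            filter_noise(points, min_cluster_pixels=10**9)


class TestFitTps:
    def test_noiseless_gaussian_peak_argmax_near_truth(self, gaussian_points):
        land = fit_tps(gaussian_points, smoothing=0.0, grid_size=60)
        grid = land.grid_table()
        best = grid.loc[grid["performance"].idxmax()]
        cell_p = np.diff(land.grid_protein)[0]
        cell_c = np.diff(land.grid_carbohydrate)[0]
        assert abs(best["protein"] - 3.0) <= cell_p + 1e-9
        assert abs(best["carbohydrate"] - 1.0) <= cell_c + 1e-9

    def test_grid_clipped_to_hull(self, gaussian_points):
        land = fit_tps(gaussian_points, smoothing=0.0, grid_size=40)
        assert np.isnan(land.grid_performance).any()
        assert np.isfinite(land.grid_performance[~np.isnan(land.grid_performance)]).all()

    def test_too_few_points_rejected(self):
        pts = pd.DataFrame({"protein": [1, 2, 3], "carbohydrate": [1, 2, 1],
                            "performance": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            fit_tps(pts)


class TestFullPipelineRoundTrip:
    def test_round_trip_recovers_peak(self, rendered, default_points):
        image, truth = rendered
        _, land, log = reconstruct_from_image(
            image, n_colors=len(truth["band_mids"]), seed=5, max_points=800,
        )
        grid = land.grid_table()
        top = grid[grid["performance"] >= grid["performance"].quantile(0.95)]
        pmin, pmax, cmin, cmax = truth["extent"]
        # centroid of the peak region within 10% of the axis range of truth
        assert abs(top["protein"].mean() - 2.0) < 0.1 * (pmax - pmin)
        assert abs(top["carbohydrate"].mean() - 4.0) < 0.1 * (cmax - cmin)
        assert log["n_points_fitted"] <= 800

    def test_missing_band_map_is_an_error(self, rendered):
        image, truth = rendered
        stripped = ContourImage(pixels=image.pixels, calibration=image.calibration)
        with pytest.raises(ValueError, match="band_value_map"):
            reconstruct_from_image(stripped, n_colors=len(truth["band_mids"]))
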