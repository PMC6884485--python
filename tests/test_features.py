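import numpy as np
import pytest
from shapely.geometry import Polygon

from etilscore.detection import Cell
from etilscore.features import (
    BASE_FEATURE_NAMES,
    FeatureTable,
    compute_features,
    smooth_features,
)


def _disk_polygon(cx, cy, r, n=128):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Polygon(np.column_stack([cx + r * np.cos(t), cy + r * np.sin(t)]))


def _cell(poly, cell_poly=None):
    return Cell(
        nucleus_polygon=poly,
        cell_polygon=cell_poly or poly,
        centroid_um=np.array(poly.centroid.coords[0]),
        nucleus_area_um2=poly.area,
        cell_area_um2=(cell_poly or poly).area,
    )


@pytest.fixture
def uniform_od():
    """OD channels with hematoxylin fixed at 0.7 everywhere."""
    od = np.zeros((100, 100, 3))
    od[..., 0] = 0.7
    od[..., 1] = 0.2
    return od


class TestComputeFeatures:
    def test_base_set_has_64_features(self):
        assert len(BASE_FEATURE_NAMES) == 64

    def test_empty_cell_list_gives_empty_table(self, uniform_od):
        table = compute_features([], uniform_od, 0.5)
        assert table.values.shape == (0, 64)

    def test_disk_circularity_near_one(self, uniform_od):
        cell = _cell(_disk_polygon(50, 50, 20))
        table = compute_features([cell], uniform_od, 0.5)
        row = dict(zip(table.feature_names, table.values[0]))
        assert row["nucleus_circularity"] == pytest.approx(1.0, abs=0.05)
        assert row["nucleus_eccentricity"] == pytest.approx(0.0, abs=0.05)
        assert row["nucleus_caliper_max_um"] == pytest.approx(2 * 20 * 0.5, rel=0.02)

    def test_area_matches_shoelace_oracle(self, uniform_od):
        coords = [(10, 10), (60, 15), (70, 60), (30, 80), (8, 40)]
        x, y = np.array(coords).T
        # independent shoelace computation
        shoelace = 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))
        px = 0.5
        cell = _cell(Polygon(coords))
        table = compute_features([cell], uniform_od, px)
        row = dict(zip(table.feature_names, table.values[0]))
        assert row["nucleus_area_um2"] == pytest.approx(shoelace * px**2, abs=1e-6)

    def test_uniform_intensity_statistics(self, uniform_od):
        cell = _cell(_disk_polygon(50, 50, 15))
        table = compute_features([cell], uniform_od, 0.5)
        row = dict(zip(table.feature_names, table.values[0]))
        assert row["nucleus_hematoxylin_mean"] == pytest.approx(0.7)
        assert row["nucleus_hematoxylin_std"] == pytest.approx(0.0, abs=1e-12)
        assert row["nucleus_hematoxylin_range"] == pytest.approx(0.0, abs=1e-12)
        assert row["nucleus_eosin_mean"] == pytest.approx(0.2)

    def test_no_cytoplasm_flagged_with_zeros(self, uniform_od):
        poly = _disk_polygon(50, 50, 10)
        cell = _cell(poly, cell_poly=poly)  # no expansion: cell == nucleus
        table = compute_features([cell], uniform_od, 0.5)
        row = dict(zip(table.feature_names, table.values[0]))
        assert row["has_cytoplasm"] == 0.0
        assert row["cytoplasm_hematoxylin_mean"] == 0.0
        assert not np.isnan(table.values).any()

    def test_elongated_polygon_has_high_eccentricity(self, uniform_od):
        rect = Polygon([(10, 48), (90, 48), (90, 52), (10, 52)])
        table = compute_features([_cell(rect)], uniform_od, 0.5)
        row = dict(zip(table.feature_names, table.values[0]))
        assert row["nucleus_eccentricity"] > 0.9
        assert row["nucleus_aspect_ratio"] > 5

    def test_csv_round_trip(self, uniform_od, tmp_path):
        cells = [_cell(_disk_polygon(30, 30, 8)), _cell(_disk_polygon(70, 70, 12))]
        table = compute_features(cells, uniform_od, 0.5)
        path = table.to_csv(tmp_path / "features.csv")
        back = FeatureTable.from_csv(path)
        assert back.feature_names == table.feature_names
        np.testing.assert_allclose(back.values, table.values, rtol=1e-12)


class TestSmoothing:
    def _table(self, values):
        values = np.asarray(values, dtype=float)
        return FeatureTable(
            cell_ids=list(range(len(values))),
            feature_names=[f"f{i}" for i in range(values.shape[1])],
            values=values,
        )

    def test_rejects_nonpositive_radius(self):
        with pytest.raises(ValueError):
            smooth_features(self._table([[1.0]]), np.zeros((1, 2)), 0.0)

    def test_isolated_cell_keeps_raw_value(self):
        table = self._table([[3.5, -1.0]])
        out = smooth_features(table, np.array([[0.0, 0.0]]), 25.0)
        assert out.values[0, 2] == pytest.approx(3.5)
        assert out.values[0, 3] == pytest.approx(-1.0)
        assert out.feature_names == ["f0", "f1", "f0_smoothed_25um", "f1_smoothed_25um"]

    def test_constant_features_stay_constant(self):
        table = self._table(np.full((10, 3), 7.25))
        centroids = np.random.default_rng(0).uniform(0, 30, size=(10, 2))
        out = smooth_features(table, centroids, 50.0)
        assert np.all(out.values[:, 3:] == pytest.approx(7.25))

    def test_three_collinear_cells_match_bruteforce(self):
        """Hand-computable configuration: cells at x = 0, 10, 30 µm."""
        centroids = np.array([[0.0, 0.0], [10.0, 0.0], [30.0, 0.0]])
        values = np.array([[1.0], [2.0], [4.0]])
        radius = 25.0
        out = smooth_features(self._table(values), centroids, radius)
        sigma2 = (radius / 2) ** 2
        for i in range(3):
            d = np.abs(centroids[:, 0] - centroids[i, 0])
            w = np.where(d <= radius, np.exp(-(d**2) / (2 * sigma2)), 0.0)
            expected = (w * values[:, 0]).sum() / w.sum()
            assert out.values[i, 1] == pytest.approx(expected, abs=1e-9)

    def test_smoothed_values_are_convex_combinations(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(200, 4))
        centroids = rng.uniform(0, 100, size=(200, 2))
        out = smooth_features(self._table(values), centroids, 25.0)
        sm = out.values[:, 4:]
        assert np.all(sm >= values.min(axis=0) - 1e-12)
        assert np.all(sm <= values.max(axis=0) + 1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=(50, 2))
        centroids = rng.uniform(0, 60, size=(50, 2))
        out = smooth_features(self._table(values), centroids, 25.0)
        perm = rng.permutation(50)
        out_p = smooth_features(self._table(values[perm]), centroids[perm], 25.0)
        np.testing.assert_allclose(out_p.values, out.values[perm], atol=1e-12)

    def test_spatial_index_agrees_with_bruteforce(self):
        rng = np.random.default_rng(5)
        n = 400
        values = rng.normal(size=(n, 3))
        centroids = rng.uniform(0, 150, size=(n, 2))
        radius = 30.0
        out = smooth_features(self._table(values), centroids, radius)
        # O(n^2) brute force
        d2 = ((centroids[:, None, :] - centroids[None, :, :]) ** 2).sum(-1)
        w = np.where(d2 <= radius**2, np.exp(-d2 / (2 * (radius / 2) ** 2)), 0.0)
        expected = (w @ values) / w.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(out.values[:, 3:], expected, atol=1e-10)

    def test_two_radii_give_192_columns(self):
        rng = np.random.default_rng(6)
        values = rng.normal(size=(20, 64))
        table = FeatureTable(
            cell_ids=list(range(20)),
            feature_names=list(BASE_FEATURE_NAMES),
            values=values,
        )
        centroids = rng.uniform(0, 100, size=(20, 2))
        for r in (25.0, 50.0):
            table = smooth_features(table, centroids, r)
        assert len(table.feature_names) == 64 * 3
        assert table.smoothing_radii_um == [25.0, 50.0]
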