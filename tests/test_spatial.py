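import numpy as np
import pandas as pd
import pytest

from cortaxis.io import CellTable, ValidationError
from cortaxis.spatial import (
    NeighborhoodProfile,
    cross_region_profile_correlation,
    depth_density,
    neighborhood_composition,
    normalize_depth,
    normalize_neighborhood,
    regional_composition,
)


def _spatial_cells(rows):
    return CellTable(pd.DataFrame(
        rows, columns=["cell_id", "subclass", "region", "donor", "x", "y"]
    ))


FLAT_PIAL = np.array([[0.0, 0.0], [1000.0, 0.0]])
FLAT_WM = np.array([[0.0, 400.0], [1000.0, 400.0]])


class TestNormalizeDepth:
    def test_distance_ratio(self):
        cells = _spatial_cells([["c1", "A", "ACC", "D1", 500.0, 100.0]])
        depth = normalize_depth(cells, FLAT_PIAL, FLAT_WM)
        assert depth.loc["c1"] == pytest.approx(0.25)  # 100 vs 300 um

    def test_on_pial_boundary_is_zero(self):
        cells = _spatial_cells([["c1", "A", "ACC", "D1", 500.0, 0.0]])
        assert normalize_depth(cells, FLAT_PIAL, FLAT_WM).loc["c1"] == 0.0

    def test_midway_between_parallel_boundaries(self):
        cells = _spatial_cells([["c1", "A", "ACC", "D1", 123.0, 200.0]])
        assert normalize_depth(cells, FLAT_PIAL, FLAT_WM).loc["c1"] == pytest.approx(0.5)

    def test_nearest_point_on_segment_not_vertex(self):
        # diagonal pial line y = x; cell at (500, 0) is 500/sqrt(2) away
        pial = np.array([[0.0, 0.0], [1000.0, 1000.0]])
        wm = np.array([[0.0, 2000.0], [1000.0, 3000.0]])
        cells = _spatial_cells([["c1", "A", "ACC", "D1", 500.0, 0.0]])
        depth = normalize_depth(cells, pial, wm)
        d_p = 500 / np.sqrt(2)          # foot of perpendicular at (250, 250)
        d_w = np.hypot(500, 2000)       # projection clamps to vertex (0, 2000)
        assert depth.loc["c1"] == pytest.approx(d_p / (d_p + d_w))

    def test_intersecting_boundaries_rejected(self):
        cells = _spatial_cells([["c1", "A", "ACC", "D1", 0.0, 0.0]])
        with pytest.raises(ValidationError, match="boundar"):
            normalize_depth(cells, FLAT_PIAL, np.array([[0.0, 0.0], [10.0, 0.0]]))


class TestDepthDensity:
    def test_unimodal_peak_near_sample_mean(self):
        rng = np.random.default_rng(0)
        prof = depth_density(rng.normal(0.5, 0.01, size=500))
        assert abs(prof.argmax_depth() - 0.5) <= 0.01

    def test_uniform_sample_is_flat_in_interior(self):
        rng = np.random.default_rng(1)
        prof = depth_density(rng.uniform(0, 1, size=10_000))
        grid_mask = (prof.grid >= 0.1) & (prof.grid <= 0.9)
        interior = prof.density[grid_mask]
        assert interior.max() / interior.min() < 1.5

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(2)
        prof = depth_density(rng.beta(2, 5, size=300))
        delta = prof.grid[1] - prof.grid[0]
        assert prof.density.sum() * delta == pytest.approx(1.0, abs=1e-6)
        assert (prof.density >= 0).all()

    def test_degenerate_sample_flagged_undefined(self):
        prof = depth_density([0.4, 0.4, 0.4])
        assert prof.undefined
        prof1 = depth_density([0.4])
        assert prof1.undefined


class TestCrossRegionCorrelation:
    def test_identical_profiles_correlate_perfectly(self):
        v = np.array([0.0, 1.0, 3.0, 1.0])
        corr = cross_region_profile_correlation({"ACC": v, "V1C": v.copy()})
        assert corr.loc["ACC", "V1C"] == pytest.approx(1.0)

    def test_reflected_asymmetric_profile_below_one(self):
        tri = np.array([0.0, 1.0, 2.0, 3.0, 0.5, 0.2, 0.1])
        corr = cross_region_profile_correlation({"a": tri, "b": tri[::-1].copy()})
        expected = np.corrcoef(tri, tri[::-1])[0, 1]
        assert corr.loc["a", "b"] == pytest.approx(expected)
        assert corr.loc["a", "b"] < 1.0

    def test_diagonal_exactly_one_and_symmetric(self):
        rng = np.random.default_rng(0)
        profiles = {r: rng.normal(size=10) for r in ("a", "b", "c")}
        corr = cross_region_profile_correlation(profiles)
        assert (np.diag(corr.to_numpy()) == 1.0).all()
        np.testing.assert_allclose(corr.to_numpy(), corr.to_numpy().T)

    def test_constant_vector_flagged_nan(self):
        corr = cross_region_profile_correlation(
            {"a": np.arange(4.0), "b": np.full(4, 2.0)}
        )
        assert np.isnan(corr.loc["a", "b"])
        assert corr.loc["b", "b"] == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            cross_region_profile_correlation({"a": np.arange(4.0),
                                              "b": np.arange(5.0)})


class TestNeighborhood:
    def _grid(self):
        # query Q at origin; A neighbors at 50, 100, 150 um; B at exactly
        # 200 um; B at 250 um is outside the closed ball
        rows = [
            ["q", "Q", "ACC", "D1", 0.0, 0.0],
            ["a1", "A", "ACC", "D1", 50.0, 0.0],
            ["a2", "A", "ACC", "D1", 0.0, 100.0],
            ["a3", "A", "ACC", "D1", -150.0, 0.0],
            ["b1", "B", "ACC", "D1", 0.0, 200.0],
            ["b2", "B", "ACC", "D1", 0.0, 250.0],
        ]
        return _spatial_cells(rows)

    def test_closed_ball_counting_excludes_self(self):
        profiles = neighborhood_composition(self._grid(), "Q", radius_um=200,
                                            n_query=100, seed=0)
        raw = profiles["ACC"].raw_proportions
        assert raw["A"] == pytest.approx(0.75)   # 3 of 4 neighbors
        assert raw["B"] == pytest.approx(0.25)   # boundary cell included
        assert raw["Q"] == 0.0                   # self excluded

    def test_proportions_sum_to_one(self):
        profiles = neighborhood_composition(self._grid(), "A", radius_um=200,
                                            n_query=100, seed=0)
        total = sum(profiles["ACC"].raw_proportions.values())
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_small_subclass_uses_all_cells(self):
        rng = np.random.default_rng(0)
        rows = [["q%d" % i, "Q", "ACC", "D1", *rng.uniform(0, 500, 2)]
                for i in range(40)]
        rows += [["a%d" % i, "A", "ACC", "D1", *rng.uniform(0, 500, 2)]
                 for i in range(10)]
        profiles = neighborhood_composition(_spatial_cells(rows), "Q",
                                            n_query=100, seed=0)
        assert profiles["ACC"].n_query_cells == 40

    def test_absent_query_subclass_region_omitted_with_warning(self):
        cells = self._grid()
        with pytest.warns(UserWarning, match="absent"):
            profiles = neighborhood_composition(cells, "Z", seed=0)
        assert profiles == {}

    def test_deterministic_sampling(self):
        rng = np.random.default_rng(3)
        rows = [["c%d" % i, "Q" if i % 2 else "A", "ACC", "D1",
                 *rng.uniform(0, 300, 2)] for i in range(300)]
        cells = _spatial_cells(rows)
        a = neighborhood_composition(cells, "Q", n_query=20, seed=9)
        b = neighborhood_composition(cells, "Q", n_query=20, seed=9)
        assert a["ACC"].raw_proportions == b["ACC"].raw_proportions


class TestNormalizeNeighborhood:
    def _profile(self, raw):
        return NeighborhoodProfile("Q", "ACC", raw, {}, n_query_cells=10)

    def test_matching_composition_gives_unity(self):
        out = normalize_neighborhood(self._profile({"A": 0.5, "B": 0.5}),
                                     {"A": 0.5, "B": 0.5})
        assert out.normalized_proportions["A"] == pytest.approx(1.0)

    def test_enrichment_ratio(self):
        out = normalize_neighborhood(self._profile({"A": 0.6, "B": 0.4}),
                                     {"A": 0.3, "B": 0.7})
        assert out.normalized_proportions["A"] == pytest.approx(2.0)

    def test_absent_neighbor_subclass_is_zero(self):
        out = normalize_neighborhood(self._profile({"A": 1.0, "B": 0.0}),
                                     {"A": 0.5, "B": 0.5})
        assert out.normalized_proportions["B"] == 0.0

    def test_zero_composition_for_observed_subclass_rejected(self):
        with pytest.raises(ValidationError):
            normalize_neighborhood(self._profile({"A": 1.0}), {"A": 0.0, "B": 1.0})

    def test_composition_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            normalize_neighborhood(self._profile({"A": 1.0}), {"A": 0.8})


def test_regional_composition_fractions():
    rows = [["c%d" % i, sc, "ACC", "D1", 0.0, 0.0]
            for i, sc in enumerate(["A", "A", "A", "B"])]
    comp = regional_composition(_spatial_cells(rows), "ACC")
    assert comp == {"A": 0.75, "B": 0.25}
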