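"""Spatial basis construction: projection, distances, MST, PCNM."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metanema import spatial

# WGS84 inverse geodesics frozen from an independent ellipsoid-geodesic
# implementation (Karney's algorithm): (lat1, lon1, lat2, lon2) -> km
GEODESIC_ORACLE = [
    ((42.5, 0.0, 43.5, 0.0), 111.092738),
    ((42.5, 0.0, 42.5, 1.0), 82.198536),
    ((42.40, -1.00, 42.90, 2.00), 252.183744),
    ((42.61, -0.35, 42.75, 1.85), 180.982441),
    ((42.45, 0.12, 42.88, 0.95), 83.137062),
]


def lake_frame(lat, lon):
    return pd.DataFrame({
        "lake_id": [f"L{i}" for i in range(len(lat))],
        "lat": lat, "lon": lon, "altitude_m": 2000.0,
    })


class TestProjection:
    def test_origin_maps_to_zero(self):
        lakes = lake_frame([42.0, 43.0], [0.0, 1.0])
        coords = spatial.project_to_cartesian(lakes, origin=(42.0, 0.0))
        assert coords.x[0] == pytest.approx(0.0, abs=1e-12)
        assert coords.y[0] == pytest.approx(0.0, abs=1e-12)

    def test_meridian_degree_matches_geodesic(self):
        lakes = lake_frame([42.5, 43.5], [0.0, 0.0])
        coords = spatial.project_to_cartesian(lakes)
        dy = abs(coords.y[1] - coords.y[0])
        assert dy == pytest.approx(111.092738, rel=0.005)

    @pytest.mark.parametrize("pair,expected_km", GEODESIC_ORACLE)
    def test_planar_distances_track_geodesics(self, pair, expected_km):
        lat1, lon1, lat2, lon2 = pair
        coords = spatial.project_to_cartesian(lake_frame([lat1, lat2], [lon1, lon2]))
        d = spatial.distance_matrix(coords).d[0, 1]
        assert d == pytest.approx(expected_km, rel=0.005)

    @pytest.mark.parametrize("pair,expected_km", GEODESIC_ORACLE)
    def test_vincenty_matches_karney_oracle(self, pair, expected_km):
        assert spatial.geodesic_km(*pair) == pytest.approx(expected_km, abs=1e-5)

    def test_duplicate_lake_id_rejected(self):
        lakes = lake_frame([42.0, 43.0], [0.0, 1.0])
        lakes["lake_id"] = ["A", "A"]
        with pytest.raises(ValueError, match="duplicate"):
            spatial.project_to_cartesian(lakes)

    def test_invalid_latitude_rejected(self):
        with pytest.raises(ValueError, match="latitude"):
            spatial.project_to_cartesian(lake_frame([95.0, 42.0], [0.0, 1.0]))


class TestDistanceMatrix:
    def test_three_four_five(self):
        coords = spatial.PlanarCoords(["a", "b"], np.array([0.0, 3.0]), np.array([0.0, 4.0]), (0, 0))
        assert spatial.distance_matrix(coords).d[0, 1] == pytest.approx(5.0)

    def test_matches_pairwise_loop(self, rng):
        pts = rng.uniform(0, 100, (10, 2))
        coords = spatial.PlanarCoords([f"L{i}" for i in range(10)], pts[:, 0], pts[:, 1], (0, 0))
        d = spatial.distance_matrix(coords).d
        for i in range(10):
            assert d[i, i] == 0.0
            for j in range(10):
                expect = math.hypot(pts[i, 0] - pts[j, 0], pts[i, 1] - pts[j, 1])
                assert d[i, j] == pytest.approx(expect, abs=1e-12)
        assert np.allclose(d, d.T)


def _kruskal_max_edge(d: np.ndarray) -> float:
    """Brute-force Kruskal with union-find; returns the longest MST edge."""
    n = d.shape[0]
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    edges = sorted((d[i, j], i, j) for i in range(n) for j in range(i + 1, n))
    longest, used = 0.0, 0
    for w, i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            longest = max(longest, w)
            used += 1
            if used == n - 1:
                break
    return longest


class TestMstThreshold:
    def test_single_edge(self):
        d = spatial.DistanceMatrix(["a", "b"], np.array([[0.0, 7.0], [7.0, 0.0]]))
        assert spatial.mst_threshold(d) == pytest.approx(7.0)

    def test_collinear(self):
        x = np.array([0.0, 1.0, 5.0])
        d = spatial.DistanceMatrix(list("abc"), np.abs(x[:, None] - x[None, :]))
        assert spatial.mst_threshold(d) == pytest.approx(4.0)

    def test_matches_kruskal_oracle(self, rng):
        for _ in range(5):
            pts = rng.uniform(0, 50, (12, 2))
            dm = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
            d = spatial.DistanceMatrix([str(i) for i in range(12)], dm)
            assert spatial.mst_threshold(d) == pytest.approx(_kruskal_max_edge(dm), abs=1e-12)

    def test_rejects_single_lake(self):
        with pytest.raises(ValueError):
            spatial.mst_threshold(spatial.DistanceMatrix(["a"], np.zeros((1, 1))))


def _pcoa_oracle(dstar: np.ndarray):
    """Independent principal-coordinates oracle (scikit-bio)."""
    from skbio.stats.ordination import pcoa

    res = pcoa(dstar.astype(float), number_of_dimensions=dstar.shape[0])
    return np.asarray(res.eigvals), res.samples.to_numpy()


class TestPcnm:
    def test_matches_pcoa_oracle_on_line(self):
        x = np.arange(5, dtype=float)
        dm = np.abs(x[:, None] - x[None, :])
        d = spatial.DistanceMatrix(list("abcde"), dm)
        t = spatial.mst_threshold(d)
        basis = spatial.pcnm(d, t)
        dstar = np.where(dm > t, 4 * t, dm)
        np.fill_diagonal(dstar, 0.0)
        evals, evecs = _pcoa_oracle(dstar)
        pos = evals[evals > 1e-8 * evals.max()]
        assert basis.n_axes == len(pos)
        assert np.allclose(basis.eigenvalues, pos[: basis.n_axes], atol=1e-8)
        for j in range(basis.n_axes):
            v = basis.vectors[:, j]
            w = evecs[:, j] / np.linalg.norm(evecs[:, j])
            assert min(np.abs(v - w).max(), np.abs(v + w).max()) < 1e-8

    def test_matches_pcoa_oracle_random(self, rng):
        pts = rng.uniform(0, 100, (15, 2))
        dm = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        d = spatial.DistanceMatrix([str(i) for i in range(15)], dm)
        t = spatial.mst_threshold(d)
        basis = spatial.pcnm(d, t)
        dstar = np.where(dm > t, 4 * t, dm)
        np.fill_diagonal(dstar, 0.0)
        evals, _ = _pcoa_oracle(dstar)
        pos = evals[evals > 1e-8 * evals.max()]
        assert np.allclose(basis.eigenvalues, pos, atol=1e-8 * evals.max())

    def test_vectors_orthonormal(self, rng):
        pts = rng.uniform(0, 200, (20, 2))
        dm = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        d = spatial.DistanceMatrix([str(i) for i in range(20)], dm)
        basis = spatial.pcnm(d, spatial.mst_threshold(d))
        gram = basis.vectors.T @ basis.vectors
        assert np.allclose(gram, np.eye(basis.n_axes), atol=1e-8)
        assert basis.n_axes <= 19

    def test_rejects_bad_threshold_and_degenerate(self):
        d = spatial.DistanceMatrix(["a", "b"], np.zeros((2, 2)))
        with pytest.raises(ValueError):
            spatial.pcnm(spatial.DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]])), 0.0)
        with pytest.raises(ValueError, match="degenerate"):
            spatial.pcnm(d, 1.0)


class TestClassifyScale:
    def _basis(self, eigenvalues):
        ev = np.asarray(eigenvalues, dtype=float)
        return spatial.SpatialBasis(ids=["x"], eigenvalues=ev,
                                    vectors=np.zeros((1, len(ev))), threshold_t=1.0)

    @pytest.mark.parametrize("lam,label", [(30000.0, "large"), (1000.0, "medium"), (999.9, "small"),
                                           (25000.0, "medium"), (25000.1, "large")])
    def test_boundaries(self, lam, label):
        basis = spatial.classify_scale(self._basis([lam]))
        assert basis.scale_label == [label]

    def test_blocks_contiguous_and_exhaustive(self):
        basis = spatial.classify_scale(self._basis([9e4, 4e4, 2e4, 5e3, 1e3, 800, 2]))
        assert basis.scale_label == ["large"] * 2 + ["medium"] * 3 + ["small"] * 2

    def test_rejects_inverted_cuts(self):
        with pytest.raises(ValueError):
            spatial.classify_scale(self._basis([1.0]), cut_large=10, cut_small=100)


class TestConnectivity:
    def _random_d(self, rng, n=12):
        pts = rng.uniform(0, 80, (n, 2))
        dm = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        return spatial.DistanceMatrix([str(i) for i in range(n)], dm)

    def test_below_min_distance_all_zero(self, rng):
        d = self._random_d(rng)
        tiny = d.d[d.d > 0].min() / 2
        with pytest.warns(UserWarning, match="isolated"):
            w = spatial.connectivity(d, tiny)
        assert w.w.sum() == 0
        assert len(w.isolated) == len(d.ids)

    def test_above_max_distance_complete(self, rng):
        d = self._random_d(rng)
        w = spatial.connectivity(d, d.d.max() + 1)
        n = len(d.ids)
        assert w.w.sum() == n * (n - 1)
        assert np.all(np.diag(w.w) == 0)

    def test_mst_threshold_connects_graph(self, rng):
        """Breadth-first-search oracle: one component at the MST threshold."""
        for _ in range(5):
            d = self._random_d(rng, n=15)
            w = spatial.connectivity(d, spatial.mst_threshold(d))
            seen = {0}
            frontier = [0]
            while frontier:
                i = frontier.pop()
                for j in np.flatnonzero(w.w[i]):
                    if j not in seen:
                        seen.add(int(j))
                        frontier.append(int(j))
            assert len(seen) == len(d.ids)


@settings(max_examples=25, deadline=None)
@given(st.lists(st.tuples(st.floats(-100, 100), st.floats(-100, 100)),
                min_size=4, max_size=10, unique=True))
def test_distance_matrix_triangle_inequality(pts):
    pts = np.asarray(pts)
    coords = spatial.PlanarCoords([str(i) for i in range(len(pts))], pts[:, 0], pts[:, 1], (0, 0))
    d = spatial.distance_matrix(coords).d
    n = len(pts)
    for i in range(n):
        for j in range(n):
            for k in range(n):
                assert d[i, j] <= d[i, k] + d[k, j] + 1e-9
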