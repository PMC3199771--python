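"""Range polygon construction, overlap and distance geometry.

Oracles: convex-hull areas against a direct cross-product hull; centroids and
overlaps against Monte-Carlo sampling.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sisterrange as sr
from sisterrange.range_geometry import (BUFFER_RADII_M, build_range,
                                        lonlat_to_planar, overlap_pct)


def _mc_hull_area(points_km, rng, n_samples=200_000):
    """Monte-Carlo area of the convex hull of points (km coords): rejection
    sampling inside the bounding box, point-in-hull by all-halfplane check."""
    from scipy.spatial import ConvexHull

    hull = ConvexHull(points_km)
    eqs = hull.equations  # A x + b <= 0 inside
    lo, hi = points_km.min(axis=0), points_km.max(axis=0)
    box_area = np.prod(hi - lo)
    samples = rng.uniform(lo, hi, size=(n_samples, 2))
    inside = np.all(samples @ eqs[:, :2].T + eqs[:, 2] <= 1e-12, axis=1)
    return box_area * inside.mean()


class TestBuildRange:
    def test_single_point_disc_area(self):
        rp = build_range(np.array([[0.0, 0.0]]), "RSA")
        assert rp.construction == "buffer"
        assert rp.area_km2 == pytest.approx(math.pi * 25.0**2, rel=1e-3)
        assert rp.centroid_km == (0.0, 0.0)

    def test_square_hull_area_and_centroid(self):
        pts = np.array([[0, 0], [10e3, 0], [10e3, 10e3], [0, 10e3]], float)
        rp = build_range(pts, "RSB")
        assert rp.construction == "mcp"
        assert rp.area_km2 == pytest.approx(100.0)
        assert rp.centroid_km == pytest.approx((5.0, 5.0))

    def test_two_locality_capsule_and_midpoint_centroid(self):
        pts = np.array([[0.0, 0.0], [10e3, 0.0]])
        rp = build_range(pts, "RSA")
        # capsule = rectangle 10 x 2r km plus full disc at the ends
        r = 25.0
        assert rp.area_km2 == pytest.approx(10 * 2 * r + math.pi * r**2, rel=2e-3)
        assert rp.centroid_km == pytest.approx((5.0, 0.0))

    def test_collinear_points_get_buffered_segment(self):
        pts = np.array([[0.0, 0.0], [5e3, 0.0], [10e3, 0.0]])
        rp = build_range(pts, "RSB")
        assert rp.construction == "buffer"
        assert rp.area_km2 > 0

    def test_empty_locality_set_rejected(self):
        with pytest.raises(ValueError):
            build_range(np.empty((0, 2)), "RSA")

    def test_random_cloud_hull_matches_monte_carlo(self, rng):
        """50 uniform points in a triangle: hull area vs rejection sampling."""
        tri = np.array([[0, 0], [80, 10], [30, 60]], float)
        w = rng.dirichlet(np.ones(3), size=50)
        pts_km = w @ tri
        rp = build_range(pts_km * 1e3, "RSB")
        mc = _mc_hull_area(pts_km, rng)
        assert rp.area_km2 == pytest.approx(mc, rel=0.02)

    def test_random_polygon_centroid_matches_sampling(self, rng):
        pts_km = rng.uniform(0, 50, size=(12, 2))
        rp = build_range(pts_km * 1e3, "RSB")
        from scipy.spatial import ConvexHull

        hull = ConvexHull(pts_km)
        eqs = hull.equations
        lo, hi = pts_km.min(axis=0), pts_km.max(axis=0)
        samples = rng.uniform(lo, hi, size=(400_000, 2))
        inside = np.all(samples @ eqs[:, :2].T + eqs[:, 2] <= 1e-12, axis=1)
        mc_centroid = samples[inside].mean(axis=0)
        assert rp.centroid_km == pytest.approx(tuple(mc_centroid), abs=0.1)


class TestOverlap:
    def test_disjoint_squares_zero(self):
        a = build_range(np.array([[0, 0], [1e4, 0], [1e4, 1e4], [0, 1e4]], float), "RSB")
        b = build_range(np.array([[2e4, 0], [3e4, 0], [3e4, 1e4], [2e4, 1e4]], float), "RSB")
        assert overlap_pct(a, b) == 0.0

    def test_contained_square_is_full_overlap(self):
        big = build_range(np.array([[0, 0], [1e4, 0], [1e4, 1e4], [0, 1e4]], float), "RSB")
        small = build_range(
            np.array([[4e3, 4e3], [6e3, 4e3], [6e3, 6e3], [4e3, 6e3]], float), "RSB")
        assert overlap_pct(big, small) == pytest.approx(100.0)

    def test_overlapping_discs_match_monte_carlo(self, rng):
        a = build_range(np.array([[0.0, 0.0]]), "RSA")
        b = build_range(np.array([[30e3, 0.0]]), "RSA")
        pct = overlap_pct(a, b)
        r = 25.0
        lo, hi = np.array([-r, -r]), np.array([r, r])
        s = rng.uniform(lo, hi, size=(100_000, 2))
        inside = (np.hypot(s[:, 0], s[:, 1]) <= r) & (
            np.hypot(s[:, 0] - 30.0, s[:, 1]) <= r)
        mc_area = (2 * r) ** 2 * inside.mean()
        mc_pct = 100 * mc_area / (math.pi * r**2)
        assert pct == pytest.approx(mc_pct, abs=1.0)

    def test_symmetry_and_self_overlap(self, toy):
        rset = sr.build_range_set(toy.localities, "RSA")
        a, b = rset["sp5"], rset["sp6"]
        assert overlap_pct(a, b) == overlap_pct(b, a)
        assert overlap_pct(a, a) == pytest.approx(100.0)


class TestMatrices:
    def test_centroid_distances_3_4_5(self):
        locs = __import__("pandas").DataFrame(
            {"species": ["a", "b"], "x": [0.0, 3e3], "y": [0.0, 4e3]})
        rset = sr.build_range_set(locs, "RSB")
        d = sr.centroid_distance_matrix(rset)
        assert d.loc["a", "b"] == pytest.approx(5.0)
        assert d.loc["a", "a"] == 0.0

    def test_matrix_matches_pairwise_recomputation(self, synth_small):
        rset = sr.build_range_set(synth_small.localities.iloc[:120], "RSA")
        d = sr.centroid_distance_matrix(rset)
        assert (d.values == d.values.T).all()
        for a in rset.species[:10]:
            for b in rset.species[:10]:
                ca, cb = rset[a].centroid_km, rset[b].centroid_km
                assert d.loc[a, b] == pytest.approx(math.hypot(
                    ca[0] - cb[0], ca[1] - cb[1]), abs=1e-9)

    def test_overlap_matrix_invariants(self, toy):
        rset = sr.build_range_set(toy.localities, "RSA")
        m = sr.overlap_matrix(rset)
        assert (m.values == m.values.T).all()
        assert (np.diag(m.values) == 100.0).all()
        assert ((m.values >= 0) & (m.values <= 100)).all()


class TestClassification:
    def test_toy_counts_two_allopatric_two_sympatric(self, toy):
        pairs = sr.find_sister_pairs(toy.tree_subst)
        rset = sr.build_range_set(toy.localities, "RSA")
        labels = sr.classify_pairs(pairs, rset)
        counts = {"allopatric": 0, "sympatric": 0}
        for v in labels.values():
            counts[v] += 1
        assert counts == {"allopatric": 2, "sympatric": 2}

    def test_missing_range_skips_pair(self, toy, caplog):
        pairs = sr.find_sister_pairs(toy.tree_subst)
        rset = sr.build_range_set(toy.localities[toy.localities.species != "sp1"], "RSA")
        labels = sr.classify_pairs(pairs, rset)
        assert ("sp1", "sp2") not in labels
        assert len(labels) == 3


class TestBufferPolicies:
    def test_rsa_area_at_least_rsb_everywhere(self, synth_small):
        rsa = sr.build_range_set(synth_small.localities, "RSA")
        rsb = sr.build_range_set(synth_small.localities, "RSB")
        for spp in rsa.species:
            assert rsa[spp].area_km2 >= rsb[spp].area_km2 - 1e-12
            if rsa[spp].n_localities <= 2:
                assert rsa[spp].area_km2 > rsb[spp].area_km2

    def test_shrinking_buffer_never_increases_overlap_area(self, toy):
        from sisterrange.range_geometry import overlap_area_km2

        rsa = sr.build_range_set(toy.localities, "RSA")
        rsb = sr.build_range_set(toy.localities, "RSB")
        for a in rsa.species:
            for b in rsa.species:
                if a < b:
                    assert (overlap_area_km2(rsa[a], rsa[b])
                            >= overlap_area_km2(rsb[a], rsb[b]) - 1e-12)


class TestProperties:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_hull_invariant_to_permutation_and_interior_points(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 1e5, size=(8, 2))
        base = build_range(pts, "RSB")
        permuted = build_range(pts[rng.permutation(8)], "RSB")
        assert base.area_km2 == pytest.approx(permuted.area_km2, rel=1e-12)
        if base.construction == "mcp":
            interior = pts.mean(axis=0, keepdims=True)
            augmented = build_range(np.vstack([pts, interior]), "RSB")
            assert augmented.area_km2 == pytest.approx(base.area_km2, rel=1e-12)


def test_lonlat_projection_roundtrip_scale():
    """1 degree of latitude is ~111.2 km; longitude shrinks with cos(lat)."""
    x, y = lonlat_to_planar(np.array([47.0, 48.0]), np.array([-20.0, -20.0]),
                            lat0=-20.0)
    dx = (x[1] - x[0]) / 1e3
    assert dx == pytest.approx(111.19 * math.cos(math.radians(20.0)), rel=1e-3)
    x, y = lonlat_to_planar(np.array([47.0, 47.0]), np.array([-20.0, -19.0]),
                            lat0=-20.0)
    assert (y[1] - y[0]) / 1e3 == pytest.approx(111.19, rel=1e-3)
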