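"""Telomere geometry, clustering, bouquet calls and nucleolus position."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from meiotrack import (
    NucleusGeometry,
    Sphere,
    TelomereSet,
    bouquet_area_fraction,
    classify_nucleolus,
    classify_periphery,
    detect_bouquet,
    distance_to_periphery,
    knn_average_distance,
)
from meiotrack.errors import GeometryError
from meiotrack.nucleus import load_geometry, load_telomeres, save_geometry, save_telomeres


def geometry(R=5.0, nucleolus_offset=0.0, r_n=2.0):
    return NucleusGeometry(
        periphery=Sphere([0.0, 0.0, 0.0], R),
        nucleolus=Sphere([nucleolus_offset, 0.0, 0.0], r_n),
    )


def telomeres(points, nor=None):
    points = np.asarray(points, dtype=float)
    nor = np.zeros(len(points), bool) if nor is None else np.asarray(nor, bool)
    return TelomereSet(points, nor)


def cap_and_spread(n_cap, R=4.4, cap_geodesic=1.0, seed=0):
    """n_cap ends in a tight cap at +z plus (16 - n_cap) mutually remote ends."""
    rng = np.random.default_rng(seed)
    theta_max = cap_geodesic / R
    cost = 1 - rng.random(n_cap) * (1 - np.cos(theta_max))
    sint = np.sqrt(1 - cost**2)
    phi = rng.random(n_cap) * 2 * np.pi
    cap = R * np.c_[sint * np.cos(phi), sint * np.sin(phi), cost]
    # octahedron-like directions away from +z keep all pairs >= 5 µm on R=4.4
    dirs = np.array(
        [[1, 0, -0.3], [-1, 0, -0.3], [0, 1, -0.3], [0, -1, -0.3], [0.7, 0.7, -0.6],
         [-0.7, -0.7, -0.6], [0.7, -0.7, -0.6], [-0.7, 0.7, -0.6], [0, 0, -1]]
    )[: 16 - n_cap]
    spread = R * dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    return np.vstack([cap, spread])


class TestDistances:
    @pytest.mark.parametrize(
        "point, expected",
        [([4.0, 0, 0], 1.0), ([0.0, 0, 0], 5.0), ([6.0, 0, 0], -1.0)],
    )
    def test_signed_distance(self, point, expected):
        d = distance_to_periphery(telomeres([point]), geometry(R=5.0))
        assert d[0] == pytest.approx(expected)

    def test_classify_half_on_surface(self):
        rng = np.random.default_rng(1)
        dirs = rng.normal(size=(16, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pts = np.vstack([5.0 * dirs[:8], 2.0 * dirs[8:]])
        mask, frac = classify_periphery(telomeres(pts), geometry(R=5.0), eps=0.5)
        assert frac == pytest.approx(0.5)
        assert mask[:8].all() and not mask[8:].any()

    def test_all_central_points_zero_fraction(self):
        _, frac = classify_periphery(telomeres(np.zeros((5, 3))), geometry(), eps=0.5)
        assert frac == 0.0

    def test_fractions_partition(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(-4, 4, size=(20, 3))
        mask, frac = classify_periphery(telomeres(pts), geometry(), eps=1.0)
        assert frac + np.mean(~mask) == pytest.approx(1.0)


class TestKnnAverageDistance:
    def test_collinear_three_points(self):
        pts = [[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]]
        vals = knn_average_distance(telomeres(pts), k=2)
        np.testing.assert_allclose(vals, [1.5, 1.0, 1.5])

    def test_coincident_points_zero(self):
        vals = knn_average_distance(telomeres(np.zeros((5, 3))), k=3)
        np.testing.assert_array_equal(vals, 0.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        pts = rng.uniform(-4, 4, size=(16, 3))
        vals = knn_average_distance(telomeres(pts), k=9)
        dm = squareform(pdist(pts))
        for i in range(16):
            expect = np.mean(np.sort(np.delete(dm[i], i))[:9])
            assert vals[i] == pytest.approx(expect)

    def test_k_reduced_with_warning_when_too_few_points(self):
        with pytest.warns(UserWarning, match="reduced"):
            vals = knn_average_distance(telomeres(np.eye(3)), k=9)
        assert len(vals) == 3


class TestDetectBouquet:
    def test_ten_end_cap_is_a_bouquet_of_ten(self):
        pts = cap_and_spread(10)
        res = detect_bouquet(telomeres(pts), geometry(R=4.4, r_n=2.0))
        assert res.bouquet
        assert res.n_in_bouquet == 10
        assert res.clustered_mask.sum() == 10
        assert res.clustered_mask[:10].all()

    def test_five_end_cap_is_not_a_bouquet(self):
        pts = cap_and_spread(5)
        res = detect_bouquet(telomeres(pts), geometry(R=4.4, r_n=2.0))
        assert not res.bouquet
        assert res.n_in_bouquet == 0

    def test_uniformly_remote_ends_no_bouquet(self):
        rng = np.random.default_rng(2)
        # 16 well-spread directions, pairwise > 4 µm apart on an R = 6 sphere
        from meiotrack.simulate import _spread_on_sphere

        pts = _spread_on_sphere(rng, 16, 6.0, min_sep=4.5)
        res = detect_bouquet(telomeres(pts), geometry(R=6.0, r_n=2.0))
        assert not res.bouquet

    def test_nor_ends_excluded_from_counting(self):
        pts = cap_and_spread(10)
        nor = np.zeros(16, bool)
        nor[:5] = True  # flag 5 of the cap ends as NOR
        res = detect_bouquet(telomeres(pts, nor), geometry(R=4.4, r_n=2.0))
        # only 5 non-NOR cap ends remain: below the 6-end minimum
        assert not res.bouquet

    def test_all_nor_is_error(self):
        with pytest.raises(GeometryError):
            detect_bouquet(telomeres(np.eye(3), [1, 1, 1]), geometry())

    def test_agrees_with_brute_force_oracle_on_random_configs(self):
        rng = np.random.default_rng(99)
        for _ in range(40):
            n = int(rng.integers(10, 21))
            pts = rng.uniform(-4.4, 4.4, size=(n, 3))
            res = detect_bouquet(telomeres(pts), geometry(R=8.0, r_n=2.0),
                                 knn_threshold=4.0, min_cluster=6)
            # oracle: mark by explicit all-pairs 9-NN mean, then exhaustively
            # grow connected components among marked points at <= 4 µm
            dm = squareform(pdist(pts))
            k = min(9, n - 1)
            marked = np.array(
                [np.mean(np.sort(np.delete(dm[i], i))[:k]) < 4.0 for i in range(n)]
            )
            best = 0
            idx = np.flatnonzero(marked)
            seen = set()
            for start in idx:
                if start in seen:
                    continue
                comp = {start}
                frontier = [start]
                while frontier:
                    cur = frontier.pop()
                    for j in idx:
                        if j not in comp and dm[cur, j] <= 4.0:
                            comp.add(j)
                            frontier.append(j)
                seen |= comp
                best = max(best, len(comp))
            expected_n = best if best >= 6 else 0
            assert res.n_in_bouquet == expected_n

    def test_knn_threshold_monotonicity(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(-4, 4, size=(16, 3))
        ts = telomeres(pts)
        marked_small = knn_average_distance(ts, k=9) < 3.0
        marked_large = knn_average_distance(ts, k=9) < 5.0
        assert np.all(marked_large | ~marked_small)


class TestAreaFraction:
    def test_three_orthogonal_axis_points_cover_one_eighth(self):
        g = geometry(R=1.0, r_n=0.4)
        pts = np.eye(3)
        assert bouquet_area_fraction(pts, g) == pytest.approx(1.0 / 8.0, rel=1e-6)

    def test_coincident_points_near_zero(self):
        g = geometry(R=4.4, r_n=2.0)
        pts = np.tile([0, 0, 4.4], (4, 1)) + 1e-6 * np.arange(12).reshape(4, 3)
        assert bouquet_area_fraction(pts, g) < 1e-6

    def test_against_monte_carlo_membership_oracle(self):
        rng = np.random.default_rng(11)
        # points in a moderate cap around +z
        theta = rng.uniform(0, 0.9, 25)
        phi = rng.uniform(0, 2 * np.pi, 25)
        pts = np.c_[np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi),
                    np.cos(theta)]
        g = geometry(R=1.0, r_n=0.4)
        frac = bouquet_area_fraction(pts, g)
        # oracle: fraction of random sphere points inside the conic hull
        import scipy.optimize as so

        samples = rng.normal(size=(3000, 3))
        samples /= np.linalg.norm(samples, axis=1, keepdims=True)
        inside = 0
        for s in samples:
            _, resid = so.nnls(pts.T, s)
            if resid < 1e-6:
                inside += 1
        mc = inside / len(samples)
        assert frac == pytest.approx(mc, abs=0.02)

    def test_two_points_fallback_warns(self):
        g = geometry(R=1.0, r_n=0.4)
        with pytest.warns(UserWarning, match="fallback"):
            frac = bouquet_area_fraction(np.array([[0, 0, 1.0], [0, 1.0, 0]]), g)
        assert 0 <= frac < 0.5


class TestNucleolusPosition:
    def test_tangent_is_peripheral(self):
        g = geometry(R=5.0, nucleolus_offset=3.0, r_n=2.0)
        assert classify_nucleolus(g) == "peripheral"

    def test_concentric_is_internal(self):
        g = geometry(R=5.0, nucleolus_offset=0.0, r_n=2.0)
        assert classify_nucleolus(g) == "internal"

    def test_nucleolus_outside_envelope_is_error(self):
        bad = NucleusGeometry(
            periphery=Sphere([0, 0, 0], 5.0), nucleolus=Sphere([4.5, 0, 0], 2.0)
        )
        with pytest.raises(GeometryError):
            classify_nucleolus(bad)


class TestRigidInvariance:
    def test_geometric_outputs_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(21)
        pts = cap_and_spread(8)
        g = geometry(R=4.4, r_n=2.0)
        res = detect_bouquet(telomeres(pts), g)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        shift = rng.normal(0, 10, 3)
        g2 = NucleusGeometry(
            periphery=Sphere(g.periphery.center @ q.T + shift, g.periphery.radius),
            nucleolus=Sphere(g.nucleolus.center @ q.T + shift, g.nucleolus.radius),
        )
        res2 = detect_bouquet(telomeres(pts @ q.T + shift), g2)
        assert res2.bouquet == res.bouquet
        assert res2.n_in_bouquet == res.n_in_bouquet
        assert res2.periphery_fraction == pytest.approx(res.periphery_fraction)
        if res.area_fraction is not None:
            assert res2.area_fraction == pytest.approx(res.area_fraction, rel=1e-6)


class TestIO:
    def test_geometry_and_telomere_roundtrip(self, tmp_path):
        g = geometry(R=4.4, nucleolus_offset=2.0, r_n=2.25)
        pts = cap_and_spread(10)
        nor = np.zeros(16, bool)
        nor[-2:] = True
        ts = telomeres(pts, nor)
        save_geometry(g, tmp_path / "g.json")
        save_telomeres(ts, tmp_path / "t.csv")
        g2 = load_geometry(tmp_path / "g.json")
        ts2 = load_telomeres(tmp_path / "t.csv")
        assert g2.periphery.radius == g.periphery.radius
        np.testing.assert_allclose(g2.nucleolus.center, g.nucleolus.center)
        np.testing.assert_allclose(ts2.points, ts.points)
        np.testing.assert_array_equal(ts2.nor_flag, ts.nor_flag)
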