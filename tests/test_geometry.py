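import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from airshed.geometry import (
    NetworkDiscretization,
    RoadNetwork,
    RoadSegment,
    kernel_line_density,
    length_in_disc,
    lengths_in_discs,
    point_to_polyline_distance,
    sector_lengths,
)

from oracles import (
    dense_kernel_density,
    dense_length_in_disc,
    dense_point_distance,
    dense_sector_lengths,
    random_polyline,
)


class TestPointToPolylineDistance:
    def test_perpendicular_foot_interior(self):
        assert point_to_polyline_distance((3, 4), [(0, 0), (10, 0)]) == pytest.approx(4.0)

    def test_nearest_is_endpoint(self):
        assert point_to_polyline_distance((-3, 4), [(0, 0), (10, 0)]) == pytest.approx(5.0)

    def test_degenerate_line_rejected(self):
        with pytest.raises(ValueError):
            point_to_polyline_distance((0, 0), [(1.0, 1.0), (1.0, 1.0)])

    def test_matches_dense_discretization(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            line = random_polyline(rng)
            p = rng.uniform(-600, 600, size=2)
            got = point_to_polyline_distance(p, line)
            assert got <= dense_point_distance(p, line) + 1e-9
            assert got == pytest.approx(dense_point_distance(p, line), abs=0.01)


class TestLengthInDisc:
    def test_diameter_chord(self):
        road = np.array([[-1000.0, 0.0], [1000.0, 0.0]])
        assert length_in_disc(road, (0, 0), 100.0) == pytest.approx(200.0, abs=1e-9)

    def test_offset_chord(self):
        road = np.array([[-1000.0, 60.0], [1000.0, 60.0]])
        expected = 2.0 * np.sqrt(100.0**2 - 60.0**2)
        assert length_in_disc(road, (0, 0), 100.0) == pytest.approx(expected, abs=1e-9)

    def test_empty_intersection_is_zero(self):
        road = np.array([[500.0, 500.0], [600.0, 500.0]])
        assert length_in_disc(road, (0, 0), 100.0) == 0.0

    def test_matches_dense_discretization(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            line = random_polyline(rng)
            center = rng.uniform(-300, 300, size=2)
            radius = rng.uniform(50, 400)
            got = length_in_disc(line, center, radius)
            ref = dense_length_in_disc(line, center, radius)
            assert got == pytest.approx(ref, rel=0.005, abs=0.15)

    def test_monotone_in_radius(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            line = random_polyline(rng)
            center = rng.uniform(-200, 200, size=2)
            lens = [length_in_disc(line, center, r) for r in (50, 100, 200, 400)]
            assert all(a <= b + 1e-12 for a, b in zip(lens, lens[1:]))

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(11)
        line = random_polyline(rng)
        centers = rng.uniform(-300, 300, size=(20, 2))
        vec = lengths_in_discs(centers, line, 150.0)
        for c, v in zip(centers, vec):
            assert v == pytest.approx(length_in_disc(line, c, 150.0), abs=1e-9)


class TestSectorLengths:
    def test_east_west_road_splits_into_e_and_w(self):
        road = np.array([[-1000.0, 0.0], [1000.0, 0.0]])
        lens = sector_lengths(road, (0, 0), 200.0, 8)
        # compass order N, NE, E, SE, S, SW, W, NW; every point of the
        # road sits at azimuth exactly 90 or 270
        assert lens[2] == pytest.approx(200.0, abs=1e-9)
        assert lens[6] == pytest.approx(200.0, abs=1e-9)
        assert lens[[0, 1, 3, 4, 5, 7]].sum() == pytest.approx(0.0, abs=1e-9)

    def test_partition_conserves_total_length(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            lines = [random_polyline(rng) for _ in range(3)]
            center = rng.uniform(-200, 200, size=2)
            radius = rng.uniform(50, 400)
            lens = sector_lengths(lines, center, radius, 8)
            total = sum(length_in_disc(l, center, radius) for l in lines)
            assert lens.sum() == pytest.approx(total, rel=1e-9, abs=1e-9)

    def test_rotation_permutes_sectors_cyclically(self):
        rng = np.random.default_rng(9)
        theta = np.radians(-45.0)  # 45 deg clockwise = +1 compass sector
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        for _ in range(20):
            lines = [random_polyline(rng) for _ in range(2)]
            lens = sector_lengths(lines, (0, 0), 300.0, 8)
            rotated = [l @ rot.T for l in lines]
            lens_rot = sector_lengths(rotated, (0, 0), 300.0, 8)
            assert np.allclose(np.roll(lens, 1), lens_rot, atol=1e-6)

    def test_matches_dense_discretization(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            lines = [random_polyline(rng) for _ in range(2)]
            center = rng.uniform(-100, 100, size=2)
            lens = sector_lengths(lines, center, 250.0, 8)
            ref = dense_sector_lengths(lines, center, 250.0, 8)
            assert np.allclose(lens, ref, rtol=0.01, atol=0.2)


class TestKernelLineDensity:
    def test_empty_support_is_zero(self):
        net = RoadNetwork([RoadSegment(np.array([[500.0, 0.0], [600.0, 0.0]]), 3, 1000.0)])
        assert kernel_line_density((0, 0), 100.0, net) == 0.0

    def test_point_mass_closed_form(self):
        # 10 m stub centered on the evaluation point
        net = RoadNetwork([RoadSegment(np.array([[-5.0, 0.0], [5.0, 0.0]]), 3, 1000.0)])
        r = 100.0
        # exact: 2 * adt * integral_0^5 K(x) dx for the quartic kernel
        x = 5.0
        integral = x - 2 * x**3 / (3 * r**2) + x**5 / (5 * r**4)
        exact = 2 * 1000.0 * 3.0 / (np.pi * r**2) * integral
        got = kernel_line_density((0, 0), r, net, weight="adt",
                                  kernel="quartic", step=0.05)
        assert got == pytest.approx(exact, rel=1e-6)
        # the point-mass approximation adt * L * K(0) holds to ~0.2%
        approx = 1000.0 * 10.0 * 3.0 / (np.pi * r**2)
        assert got == pytest.approx(approx, rel=2e-3)

    def test_linearity_in_weights(self):
        rng = np.random.default_rng(21)
        segs = [RoadSegment(random_polyline(rng, scale=150), 3, float(rng.uniform(100, 1000)))
                for _ in range(4)]
        net1 = RoadNetwork(segs)
        net2 = RoadNetwork([RoadSegment(s.vertices, s.road_class, 2 * s.adt) for s in segs])
        d1 = kernel_line_density((0, 0), 200.0, net1)
        d2 = kernel_line_density((0, 0), 200.0, net2)
        assert d2 == pytest.approx(2 * d1, rel=1e-12)

    def test_missing_adt_raises(self):
        net = RoadNetwork([RoadSegment(np.array([[0.0, 10.0], [50.0, 10.0]]), 4, None)])
        with pytest.raises(ValueError, match="segment 0"):
            kernel_line_density((0, 0), 100.0, net, weight="adt")

    @pytest.mark.parametrize("kernel,step", [("quartic", 1.0), ("uniform", 0.1)])
    def test_matches_dense_discretization(self, kernel, step):
        # the quartic kernel vanishes smoothly at the search radius, so
        # the production 1 m step already matches a 0.02 m brute force;
        # the uniform kernel is discontinuous at the edge and needs a
        # finer step for the same agreement
        rng = np.random.default_rng(17)
        for _ in range(200):
            verts = random_polyline(rng, scale=200)
            adt = float(rng.uniform(100, 10_000))
            net = RoadNetwork([RoadSegment(verts, 3, adt)])
            center = rng.uniform(-150, 150, size=2)
            radius = rng.uniform(60, 300)
            got = kernel_line_density(center, radius, net, kernel=kernel, step=step)
            ref = dense_kernel_density(center, radius, [(verts, adt)], kernel=kernel)
            assert got == pytest.approx(ref, rel=0.005, abs=1e-4)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(dx=st.floats(-1e5, 1e5), dy=st.floats(-1e5, 1e5))
def test_rigid_translation_invariance(dx, dy):
    rng = np.random.default_rng(31)
    line = random_polyline(rng)
    center = np.array([20.0, -40.0])
    shift = np.array([dx, dy])
    assert length_in_disc(line + shift, center + shift, 150.0) == pytest.approx(
        length_in_disc(line, center, 150.0), abs=1e-9)
    assert point_to_polyline_distance(center + shift, line + shift) == pytest.approx(
        point_to_polyline_distance(center, line), abs=1e-9)


def test_discretization_caches_segments():
    net = RoadNetwork([RoadSegment(np.array([[0.0, 0.0], [100.0, 0.0]]), 2, 500.0)])
    disc = NetworkDiscretization.build(net, 1.0)
    assert len(disc.points) == 100
    assert disc.step_lengths.sum() == pytest.approx(100.0)
    d1 = kernel_line_density((50, 10), 80.0, disc)
    d2 = kernel_line_density((50, 10), 80.0, net, step=1.0)
    assert d1 == pytest.approx(d2, rel=1e-12)
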