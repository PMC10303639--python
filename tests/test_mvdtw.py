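import math

import numpy as np
import pytest

from mobileqrs.mvdtw import (
    MultiViewBeat, build_views, local_angles, local_distance, path_table,
    locate_qrs, distortion, warp_beat,
)
from mobileqrs.templates import HeartbeatTemplate


def exhaustive_min_path_cost(d):
    """Independent oracle: minimum monotone-path cost by explicit
    enumeration of every path from (0,0) to (M-1,N-1)."""
    M, N = d.shape
    best = [math.inf]

    def walk(m, n, cost):
        cost += d[m, n]
        if cost >= best[0]:
            return
        if m == M - 1 and n == N - 1:
            best[0] = cost
            return
        if m + 1 < M and n + 1 < N:
            walk(m + 1, n + 1, cost)
        if m + 1 < M:
            walk(m + 1, n, cost)
        if n + 1 < N:
            walk(m, n + 1, cost)

    walk(0, 0, 0.0)
    return best[0]


def single_view_beat(values):
    """A MultiViewBeat whose extra views are zero, so the DTW cost reduces
    to the amplitude view alone."""
    v = np.asarray(values, dtype=float)
    return MultiViewBeat(views=np.vstack([v, np.zeros_like(v), np.zeros_like(v)]))


def single_view_template(values, off=None, on=None):
    v = np.asarray(values, dtype=float)
    return HeartbeatTemplate(views=np.vstack([v, np.zeros_like(v), np.zeros_like(v)]),
                             qrs_temp_off=off, qrs_temp_on=on)


class TestViews:
    def test_straight_line_constant_derivative_and_angle(self):
        beat = np.linspace(0, 1, 64)
        # collinear points: raw first difference and raw angle are constant
        deriv = np.diff(beat)
        assert np.allclose(deriv, deriv[0], atol=1e-12)
        raw_ang = local_angles(beat, 10)
        assert np.allclose(raw_ang, raw_ang[0], atol=1e-9)

    def test_triangular_beat_angle_minimal_at_apex(self):
        n = 65
        beat = 1.0 - np.abs(np.linspace(-1, 1, n))
        ang = local_angles(beat, 10)
        assert np.argmin(ang) == n // 2

    def test_angles_match_vector_geometry_oracle(self):
        rng = np.random.default_rng(0)
        beat = rng.uniform(size=80)
        g = 10
        ang = local_angles(beat, g)
        for i in range(g, 80 - g):
            # vertices in coordinates where g sample steps span one unit
            a = np.array([-1.0, beat[i - g] - beat[i]])
            b = np.array([1.0, beat[i + g] - beat[i]])
            expected = math.acos(np.clip(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)), -1, 1))
            assert ang[i] == pytest.approx(expected, abs=1e-12)

    def test_views_scaled_to_unit_interval(self):
        rng = np.random.default_rng(1)
        mv = build_views(rng.uniform(size=100), angle_gap=10)
        assert mv.views.min() >= 0 and mv.views.max() <= 1

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            build_views(np.zeros(15), angle_gap=10)


class TestLocalDistance:
    def test_self_match_zero_diagonal(self):
        rng = np.random.default_rng(2)
        mv = build_views(rng.uniform(size=64), angle_gap=5)
        t = HeartbeatTemplate(views=mv.views.copy())
        d = local_distance(mv, t)
        assert np.allclose(np.diag(d), 0)

    def test_hand_example(self):
        test = single_view_beat([0.0, 1.0])
        templ = single_view_template([0.0, 1.0, 1.0])
        d = local_distance(test, templ)
        np.testing.assert_allclose(d, [[0, 1, 1], [1, 0, 0]])

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(3)
        tv = rng.uniform(size=(3, 7))
        xv = rng.uniform(size=(3, 5))
        d = local_distance(MultiViewBeat(views=xv), HeartbeatTemplate(views=tv))
        for m in range(5):
            for n in range(7):
                expected = sum((xv[l, m] - tv[l, n]) ** 2 for l in range(3))
                assert d[m, n] == pytest.approx(expected)

    def test_symmetry_transposes_cost(self):
        rng = np.random.default_rng(4)
        a, b = rng.uniform(size=(3, 6)), rng.uniform(size=(3, 9))
        d_ab = local_distance(MultiViewBeat(views=a), HeartbeatTemplate(views=b))
        d_ba = local_distance(MultiViewBeat(views=b), HeartbeatTemplate(views=a))
        np.testing.assert_allclose(d_ab, d_ba.T)
        assert distortion(path_table(d_ab)) == pytest.approx(distortion(path_table(d_ba)))


class TestPathTable:
    def test_identical_sequences_diagonal_path(self):
        rng = np.random.default_rng(5)
        v = rng.uniform(size=(3, 20))
        d = local_distance(MultiViewBeat(views=v), HeartbeatTemplate(views=v.copy()))
        table = path_table(d)
        assert distortion(table) == pytest.approx(0.0, abs=1e-12)
        assert table.path == [(i, i) for i in range(20)]

    def test_hand_dp_example(self):
        d = np.array([[0.0, 1.0, 1.0], [1.0, 0.0, 0.0]])
        table = path_table(d)
        assert table.D[1, 2] == pytest.approx(0.0)

    def test_path_cost_equals_terminal(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            d = rng.uniform(size=(rng.integers(2, 9), rng.integers(2, 9)))
            table = path_table(d)
            assert sum(d[m, n] for m, n in table.path) == pytest.approx(table.D[-1, -1])
            # path structure: monotone steps from corner to corner
            assert table.path[0] == (0, 0)
            assert table.path[-1] == (d.shape[0] - 1, d.shape[1] - 1)
            steps = {(m2 - m1, n2 - n1) for (m1, n1), (m2, n2)
                     in zip(table.path[:-1], table.path[1:])}
            assert steps <= {(1, 0), (0, 1), (1, 1)}

    def test_terminal_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            M, N = rng.integers(1, 9, size=2)
            d = rng.uniform(size=(M, N))
            assert path_table(d).D[-1, -1] == pytest.approx(
                exhaustive_min_path_cost(d))

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            path_table(np.empty((0, 0)))


class TestBoundaryTransfer:
    def test_identity_warp_exact_boundaries(self):
        rng = np.random.default_rng(8)
        v = rng.uniform(size=(3, 40))
        templ = HeartbeatTemplate(views=v.copy(), qrs_temp_off=6, qrs_temp_on=33)
        r = warp_beat(MultiViewBeat(views=v), templ)
        assert (r.qrs_off, r.qrs_on) == (6, 33)
        assert r.distortion == pytest.approx(0.0, abs=1e-12)

    def test_uniform_stretch_doubles_boundaries(self):
        rng = np.random.default_rng(9)
        base = rng.uniform(size=30)
        stretched = np.repeat(base, 2)
        templ = single_view_template(base, off=5, on=24)
        r = warp_beat(single_view_beat(stretched), templ)
        assert abs(r.qrs_off - 2 * 5) <= 1
        assert abs(r.qrs_on - 2 * 24) <= 1

    def test_unannotated_template_errors(self):
        v = np.random.default_rng(10).uniform(size=(3, 20))
        with pytest.raises(ValueError):
            warp_beat(MultiViewBeat(views=v), HeartbeatTemplate(views=v))

    def test_boundary_order_preserved(self):
        rng = np.random.default_rng(11)
        templ_v = rng.uniform(size=(3, 32))
        templ = HeartbeatTemplate(views=templ_v, qrs_temp_off=5, qrs_temp_on=26)
        for _ in range(25):
            r = warp_beat(MultiViewBeat(views=rng.uniform(size=(3, 32))), templ)
            assert r.qrs_off < r.qrs_on


class TestDistortion:
    def test_noise_monotonicity(self):
        """Median distortion over seeded replicates is nondecreasing in the
        amplitude of noise added to a fixed beat."""
        rng = np.random.default_rng(12)
        base = np.sin(np.linspace(0, 2 * np.pi, 64)) * 0.5 + 0.5
        templ_mv = build_views(base, angle_gap=5)
        templ = HeartbeatTemplate(views=templ_mv.views.copy())
        medians = []
        for amp in (0.0, 0.05, 0.15, 0.4):
            vals = []
            for _ in range(100):
                noisy = np.clip(base + rng.normal(0, amp, size=64), 0, 1)
                mv = build_views(noisy, angle_gap=5)
                vals.append(distortion(path_table(local_distance(mv, templ))))
            medians.append(np.median(vals))
        assert all(b >= a for a, b in zip(medians[:-1], medians[1:]))

    def test_zero_iff_exact_alignment(self):
        # pi = 0 exactly when a perfect warping alignment exists
        templ = single_view_template([0.0, 0.5, 1.0])
        aligned = single_view_beat([0.0, 0.0, 0.5, 1.0, 1.0])
        d = local_distance(aligned, templ)
        assert distortion(path_table(d)) == pytest.approx(0.0, abs=1e-15)
        misaligned = single_view_beat([0.0, 0.4, 1.0])
        d2 = local_distance(misaligned, templ)
        assert distortion(path_table(d2)) > 0
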