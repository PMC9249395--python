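"""GPA, sliding-semilandmark and Procrustes-distance tests.

The key checks compare the implementation with independently coded
oracles: a brute-force alternating-minimisation GPA, the SVD closed form
for Procrustes distance, and a dense grid search for the slider optimum.
"""

import numpy as np
import pytest

from cuspkit.landmarks import CurveSlideSpec
from cuspkit.procrustes import (AlignedShapes, align_gpa,
                                bending_energy, bending_energy_matrix,
                                centroid_size, procrustes_distance,
                                slide_semilandmarks)


def rot(theta):
    return np.array([[np.cos(theta), -np.sin(theta)],
                     [np.sin(theta), np.cos(theta)]])


class TestCentroidSize:
    def test_unit_square_hand_geometry(self):
        pts = np.array([[0.5, 0.5], [0.5, -0.5], [-0.5, 0.5], [-0.5, -0.5]])
        assert centroid_size(pts) == pytest.approx(np.sqrt(2.0), abs=1e-12)

    def test_rotation_and_translation_invariance(self, rng):
        pts = rng.random((38, 2))
        moved = pts @ rot(np.pi / 2).T + [5.0, -3.0]
        assert centroid_size(moved) == pytest.approx(centroid_size(pts))

    def test_scales_linearly(self, rng):
        pts = rng.random((10, 2))
        assert centroid_size(3.7 * pts) == pytest.approx(
            3.7 * centroid_size(pts))

    def test_matches_direct_formula_loop(self, rng):
        pts = rng.random((38, 2)) * 10
        cx, cy = pts[:, 0].mean(), pts[:, 1].mean()
        acc = 0.0
        for x, y in pts:
            acc += (x - cx) ** 2 + (y - cy) ** 2
        assert centroid_size(pts) == pytest.approx(np.sqrt(acc), rel=1e-12)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            centroid_size(np.ones((4, 2)))


class TestProcrustesDistance:
    def test_self_distance_zero(self, rng):
        a = rng.random((12, 2))
        assert procrustes_distance(a, a) == pytest.approx(0.0, abs=1e-8)

    def test_symmetry(self, rng):
        for _ in range(5):
            a, b = rng.random((9, 2)), rng.random((9, 2))
            assert procrustes_distance(a, b) == pytest.approx(
                procrustes_distance(b, a), rel=1e-10)

    def test_similarity_transform_removed(self, rng):
        a = rng.random((15, 2))
        b = 2.3 * a @ rot(37 * np.pi / 180).T + [4.0, 7.0]
        assert procrustes_distance(a, b) < 1e-10

    def test_svd_closed_form(self, rng):
        # on centred unit-size pairs, d = sqrt(2 - 2*sum(singular values))
        # provided the optimal rotation is proper
        for _ in range(10):
            a, b = rng.random((8, 2)), rng.random((8, 2))
            ac = a - a.mean(0)
            ac /= np.sqrt((ac ** 2).sum())
            bc = b - b.mean(0)
            bc /= np.sqrt((bc ** 2).sum())
            m = bc.T @ ac
            u, s, vt = np.linalg.svd(m)
            if np.linalg.det(u @ vt) < 0:
                continue
            expected = np.sqrt(max(0.0, 2.0 - 2.0 * s.sum()))
            assert procrustes_distance(a, b) == pytest.approx(expected,
                                                              abs=1e-10)


def brute_force_gpa(arrs, tol=1e-14, iters=2000):
    """Independent alternating-minimisation GPA oracle.

    Explicitly parameterises each specimen's rotation angle and minimises
    the summed squared distance to the mean by coordinate descent with a
    closed-form angle update per specimen.
    """
    X = []
    for a in arrs:
        c = a - a.mean(0)
        X.append(c / np.sqrt((c ** 2).sum()))
    X = np.array(X)
    n = len(X)
    for _ in range(iters):
        mean = X.mean(axis=0)
        mean = mean - mean.mean(0)
        mean /= np.sqrt((mean ** 2).sum())
        moved = 0.0
        for i in range(n):
            # optimal angle: argmin ||R(t) x - m||^2 has closed form
            x, m = X[i], mean
            num = (x[:, 0] * m[:, 1] - x[:, 1] * m[:, 0]).sum()
            den = (x * m).sum()
            t = np.arctan2(num, den)
            Xi = x @ rot(t).T
            moved += ((Xi - X[i]) ** 2).sum()
            X[i] = Xi
        if moved < tol:
            break
    mean = X.mean(axis=0)
    return X, mean


class TestAlignGPA:
    def test_identical_configurations(self, rng):
        a = rng.random((7, 2))
        res = align_gpa([a, a.copy(), a.copy()])
        for x in res.procrustes_coords:
            assert procrustes_distance(x, res.mean_shape) < 1e-9

    def test_similarity_copy_aligns_exactly(self, rng):
        a = rng.random((10, 2))
        b = 2.3 * a @ rot(37 * np.pi / 180).T + [1.0, -2.0]
        res = align_gpa([a, b])
        d = np.sqrt(((res.procrustes_coords[0]
                      - res.procrustes_coords[1]) ** 2).sum())
        assert d < 1e-10

    def test_unit_size_and_zero_centroid_invariants(self, rng):
        arrs = [rng.random((6, 2)) * (i + 1) for i in range(5)]
        res = align_gpa(arrs)
        for x in res.procrustes_coords:
            assert np.abs(x.mean(axis=0)).max() < 1e-9
            assert abs(np.sqrt((x ** 2).sum()) - 1.0) < 1e-9
        np.testing.assert_allclose(res.mean_shape,
                                   res.procrustes_coords.mean(axis=0),
                                   atol=1e-12)

    def test_matches_brute_force_oracle_on_triangles(self, rng):
        arrs = [rng.random((3, 2)) for _ in range(5)]
        res = align_gpa(arrs, tol=1e-14, max_iter=1000)
        Xo, mo = brute_force_gpa(arrs)
        # compare up to a common rotation: rotate oracle mean onto ours
        from cuspkit.procrustes import _optimal_rotation

        R = _optimal_rotation(mo, res.mean_shape)
        np.testing.assert_allclose(mo @ R, res.mean_shape, atol=1e-8)
        for xo, x in zip(Xo, res.procrustes_coords):
            np.testing.assert_allclose(xo @ R, x, atol=1e-8)

    def test_invariant_under_common_similarity_transform(self, rng):
        arrs = [rng.random((9, 2)) for _ in range(4)]
        res1 = align_gpa(arrs)
        moved = [1.7 * a @ rot(0.9).T + [3.0, 4.0] for a in arrs]
        res2 = align_gpa(moved)
        from cuspkit.procrustes import _optimal_rotation

        R = _optimal_rotation(res2.mean_shape, res1.mean_shape)
        np.testing.assert_allclose(res2.mean_shape @ R, res1.mean_shape,
                                   atol=1e-9)
        np.testing.assert_allclose(res2.procrustes_coords @ R,
                                   res1.procrustes_coords, atol=1e-9)

    def test_centroid_sizes_keep_original_units(self, rng):
        a = rng.random((8, 2))
        res = align_gpa([a, 3.0 * a])
        assert res.centroid_sizes[1] == pytest.approx(
            3.0 * res.centroid_sizes[0])

    def test_degenerate_configuration_named(self, rng):
        line = np.column_stack([np.arange(5.0), np.zeros(5)])
        with pytest.raises(ValueError, match="spec7"):
            align_gpa([rng.random((5, 2)), line], ids=["ok", "spec7"])

    def test_needs_two_shapes_three_landmarks(self, rng):
        with pytest.raises(ValueError):
            align_gpa([rng.random((5, 2))])
        with pytest.raises(ValueError):
            align_gpa([rng.random((2, 2)), rng.random((2, 2))])


def arc_setup(rng=None, perturb=None):
    """8-landmark arc with 3 sliders (indices 2, 3, 4)."""
    th = np.linspace(0.2, np.pi - 0.2, 8)
    ref = np.column_stack([np.cos(th), np.sin(th)])
    curves = CurveSlideSpec(np.array([[1, 2, 3], [2, 3, 4], [3, 4, 5]]))
    x = ref.copy()
    if perturb is not None:
        x = x + perturb
    return ref, x, curves


class TestSliding:
    def test_specimen_at_consensus_does_not_move(self):
        ref, x, curves = arc_setup()
        for mode in ("bending-energy", "procrustes-distance"):
            out = slide_semilandmarks(x[None], curves, ref, mode=mode)[0]
            np.testing.assert_allclose(out, x, atol=1e-9)

    def test_tangent_perturbation_recovered_in_procrustes_mode(self):
        ref, x, curves = arc_setup()
        tangent = ref[3] - ref[1]
        tangent = tangent / np.linalg.norm(tangent)
        x[2] = x[2] + 0.05 * tangent
        out = slide_semilandmarks(x[None], curves, ref,
                                  mode="procrustes-distance")[0]
        # slider 2 moves back toward the consensus position
        assert np.linalg.norm(out[2] - ref[2]) < np.linalg.norm(x[2] - ref[2])
        resid = (out[2] - ref[2]) @ ((x[4] - x[1]) /
                                     np.linalg.norm(x[4] - x[1]))
        assert abs(resid) < 5e-3

    def test_fixed_landmarks_never_move(self, rng):
        ref, x, curves = arc_setup(perturb=0.03 * rng.standard_normal((8, 2)))
        for mode in ("bending-energy", "procrustes-distance"):
            out = slide_semilandmarks(x[None], curves, ref, mode=mode)[0]
            fixed = [0, 1, 5, 6, 7]
            np.testing.assert_allclose(out[fixed], x[fixed], atol=1e-12)

    def test_matches_grid_search_oracle(self, rng):
        ref, x, curves = arc_setup(perturb=0.02 * rng.standard_normal((8, 2)))
        E = bending_energy_matrix(ref)
        slid = curves.rows[:, 1]
        before, after = curves.rows[:, 0], curves.rows[:, 2]
        tang = x[after] - x[before]
        tang = tang / np.linalg.norm(tang, axis=1, keepdims=True)

        def objective(d, mode):
            y = x.copy()
            y[slid] += d[:, None] * tang
            if mode == "bending-energy":
                return bending_energy(ref, y, E)
            return ((y - ref) ** 2).sum()

        for mode in ("bending-energy", "procrustes-distance"):
            out = slide_semilandmarks(x[None], curves, ref, mode=mode)[0]
            got = np.einsum("mc,mc->m", out[slid] - x[slid], tang)
            # dense nested grid search over the three tangent offsets
            grid = np.linspace(-0.06, 0.06, 41)
            best, bestval = None, np.inf
            for d0 in grid:
                for d1 in grid:
                    for d2 in grid:
                        v = objective(np.array([d0, d1, d2]), mode)
                        if v < bestval:
                            bestval, best = v, np.array([d0, d1, d2])
            # refine around the coarse optimum
            for _ in range(2):
                span = grid[1] - grid[0]
                ref_grid = [np.linspace(b - span, b + span, 21) for b in best]
                for i0 in ref_grid[0]:
                    for i1 in ref_grid[1]:
                        for i2 in ref_grid[2]:
                            v = objective(np.array([i0, i1, i2]), mode)
                            if v < bestval:
                                bestval, best = v, np.array([i0, i1, i2])
                grid = ref_grid[0]
            np.testing.assert_allclose(got, best, atol=1e-4)

    def test_objective_never_increases(self, rng):
        ref, x, curves = arc_setup(perturb=0.04 * rng.standard_normal((8, 2)))
        E = bending_energy_matrix(ref)
        for mode, obj in (
                ("bending-energy", lambda y: bending_energy(ref, y, E)),
                ("procrustes-distance", lambda y: ((y - ref) ** 2).sum())):
            out = slide_semilandmarks(x[None], curves, ref, mode=mode)[0]
            assert obj(out) <= obj(x) + 1e-12

    def test_degenerate_tangent_rejected(self):
        ref, x, curves = arc_setup()
        x[1] = x[3]  # before == after for slider 2
        with pytest.raises(ValueError, match="tangent"):
            slide_semilandmarks(x[None], curves, ref)

    def test_gpa_with_sliding_reduces_bending_energy(self, synthetic_default):
        ds, _ = synthetic_default
        sub = ds.configs[:12]
        plain = align_gpa(sub, curves=None)
        slid = align_gpa(sub, curves=ds.curves)
        E = bending_energy_matrix(plain.mean_shape)
        be_plain = sum(bending_energy(plain.mean_shape, x, E)
                       for x in plain.procrustes_coords)
        E2 = bending_energy_matrix(slid.mean_shape)
        be_slid = sum(bending_energy(slid.mean_shape, x, E2)
                      for x in slid.procrustes_coords)
        assert slid.slid and not plain.slid
        assert be_slid < be_plain
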