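"""Elliptical Fourier analysis: closed forms, oracle equivalence,
normalization invariances and morphospace properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenobank import morphometrics as mm
from phenobank.exceptions import DegenerateOutlineError

from oracles import fourier_coefficients, random_smooth_outline

BASE_SHAPE = random_smooth_outline(np.random.default_rng(2718))
BASE_NORMALIZED = mm.normalize_efd(mm.efa(BASE_SHAPE, 10))


def circle(r=1.0, center=(0.0, 0.0), n=256):
    t = 2 * np.pi * np.arange(n) / n
    return np.column_stack([center[0] + r * np.cos(t), center[1] + r * np.sin(t)])


def ellipse(a, b, n=256, angle=0.0):
    t = 2 * np.pi * np.arange(n) / n
    pts = np.column_stack([a * np.cos(t), b * np.sin(t)])
    c, s = np.cos(angle), np.sin(angle)
    return pts @ np.array([[c, s], [-s, c]])


class TestEFA:
    def test_circle_first_harmonic_is_radius(self):
        e = mm.efa(circle(r=5.0, center=(3, -2)), n_harmonics=8)
        a1, b1, c1, d1 = e.coefficients[0]
        assert abs(abs(a1) - 5.0) < 0.01
        assert abs(abs(d1) - 5.0) < 0.01
        assert np.all(np.abs(e.coefficients[1:]) < 0.01 * 5.0)
        assert np.allclose(e.offset, (3, -2), atol=1e-3)

    def test_axis_aligned_ellipse(self):
        # arc-length parameterization shifts a1/d1 away from the semiaxes
        # as eccentricity grows, so use a mild ellipse for the size check;
        # symmetry forces b1 = c1 = 0 regardless
        e = mm.efa(ellipse(2.0, 1.7), n_harmonics=4)
        a1, b1, c1, d1 = e.coefficients[0]
        assert a1 == pytest.approx(2.0, rel=0.03)
        assert d1 == pytest.approx(1.7, rel=0.03)
        assert abs(b1) < 1e-6 and abs(c1) < 1e-6
        # eccentric case: coefficients redistribute but the reconstruction
        # still lies on the original ellipse
        rec = mm.reconstruct(mm.efa(ellipse(4.0, 1.5), 16), 256)
        assert np.allclose((rec[:, 0] / 4.0) ** 2 + (rec[:, 1] / 1.5) ** 2,
                           1.0, atol=5e-3)

    def test_translation_changes_only_offset(self, rng):
        pts = random_smooth_outline(rng)
        e0 = mm.efa(pts, 10)
        e1 = mm.efa(pts + np.array([17.0, -4.0]), 10)
        assert np.allclose(e0.coefficients, e1.coefficients, atol=1e-9)
        assert np.allclose(
            np.subtract(e1.offset, e0.offset), (17.0, -4.0), atol=1e-9
        )

    def test_matches_numerical_integration_oracle(self):
        """Closed-form chain sums agree with Gauss-quadrature Fourier
        integrals of the same piecewise-linear curve."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            pts = random_smooth_outline(rng)
            e = mm.efa(pts, 20)
            ref, (a0, c0) = fourier_coefficients(pts, 20)
            scale = np.max(np.abs(ref))
            assert np.max(np.abs(e.coefficients - ref)) / scale < 1e-6
            assert abs(e.offset[0] - a0) / scale < 1e-6
            assert abs(e.offset[1] - c0) / scale < 1e-6

    def test_too_few_distinct_points_error(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        with pytest.raises(DegenerateOutlineError):
            mm.efa(pts, 2)


class TestNormalize:
    def test_rotation_scale_start_invariance(self, rng):
        pts = random_smooth_outline(rng)
        base = mm.normalize_efd(mm.efa(pts, 12))
        angle = np.deg2rad(37.0)
        c, s = np.cos(angle), np.sin(angle)
        rotated = 2.5 * pts @ np.array([[c, s], [-s, c]])
        rolled = np.roll(rotated, 61, axis=0)       # different starting point
        other = mm.normalize_efd(mm.efa(rolled, 12))
        assert np.allclose(base.coefficients, other.coefficients, atol=1e-6)

    def test_first_harmonic_unit_magnitude(self, rng):
        pts = random_smooth_outline(rng)
        n = mm.normalize_efd(mm.efa(pts, 12))
        a1, _, c1, _ = n.coefficients[0]
        assert abs(np.hypot(a1, c1) - 1.0) < 1e-9

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        angle=st.floats(0.0, 2 * np.pi),
        scale=st.floats(0.2, 8.0),
        shift=st.integers(0, 255),
    )
    def test_similarity_invariance_property(self, angle, scale, shift):
        """Any rotation, uniform scaling and starting-point shift leaves
        the normalized coefficients unchanged."""
        c, s = np.cos(angle), np.sin(angle)
        pts = scale * BASE_SHAPE @ np.array([[c, s], [-s, c]])
        pts = np.roll(pts, shift, axis=0)
        norm = mm.normalize_efd(mm.efa(pts, 10))
        assert np.allclose(
            norm.coefficients, BASE_NORMALIZED.coefficients, atol=1e-6
        )

    def test_mirror_image_not_collapsed(self, rng):
        pts = random_smooth_outline(rng)
        mirrored = pts * np.array([-1.0, 1.0])
        n0 = mm.normalize_efd(mm.efa(pts, 12))
        n1 = mm.normalize_efd(mm.efa(mirrored[::-1], 12))
        assert not np.allclose(n0.coefficients, n1.coefficients, atol=1e-3)


class TestReconstruct:
    def test_round_trip_close_to_original(self, rng):
        pts = random_smooth_outline(rng)
        rec = mm.reconstruct(mm.efa(pts, 20), 512)
        # mean distance from reconstructed points to the original polygon
        from shapely.geometry import LineString, Point

        poly = LineString(np.vstack([pts, pts[:1]]))
        dist = np.mean([poly.distance(Point(p)) for p in rec[::8]])
        assert dist < 0.5 * np.ptp(pts) / 100  # well under half a "pixel"

    def test_l2_error_nonincreasing_in_harmonics(self, rng):
        """Each added harmonic is an orthogonal refinement, so the L2
        distance to the original curve (compared at matching arc-length
        phases) cannot increase."""
        pts = random_smooth_outline(rng, n_points=128)
        closed = np.vstack([pts, pts[:1]])
        seg = np.diff(closed, axis=0)
        t = np.concatenate(([0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))))
        grid = np.linspace(0.0, t[-1], 8192)
        x_true = np.interp(grid, t, closed[:, 0])
        y_true = np.interp(grid, t, closed[:, 1])
        phi = 2 * np.pi * grid / t[-1]
        full = mm.efa(pts, 16)
        errors = []
        for h in (1, 2, 4, 8, 16):
            a, b, c, d = full.coefficients[:h].T
            n = np.arange(1, h + 1)
            cos, sin = np.cos(np.outer(phi, n)), np.sin(np.outer(phi, n))
            x = full.offset[0] + cos @ a + sin @ b
            y = full.offset[1] + cos @ c + sin @ d
            errors.append(np.mean((x - x_true) ** 2 + (y - y_true) ** 2))
        assert all(e2 <= e1 + 1e-9 for e1, e2 in zip(errors, errors[1:]))

    def test_single_harmonic_is_ellipse(self, rng):
        pts = random_smooth_outline(rng)
        e = mm.efa(pts, 1)
        rec = mm.reconstruct(e, 64) - np.array(e.offset)
        # algebraic check: points satisfy a common conic x'Qx = 1
        design = np.column_stack(
            [rec[:, 0] ** 2, rec[:, 0] * rec[:, 1], rec[:, 1] ** 2]
        )
        sol, res, *_ = np.linalg.lstsq(design, np.ones(len(rec)), rcond=None)
        assert np.allclose(design @ sol, 1.0, atol=1e-8)


class TestMeasures:
    def test_unit_square(self):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        sq = np.vstack([np.linspace(p, q, 5)[:-1] for p, q in zip(sq, np.roll(sq, -1, 0))])
        m = mm.measures(sq)
        assert m.area == pytest.approx(1.0)
        assert m.perimeter == pytest.approx(4.0)
        assert m.length == pytest.approx(1.0) and m.width == pytest.approx(1.0)

    def test_rotated_rectangle_extents(self):
        rect = np.array([[-2, -1], [2, -1], [2, 1], [-2, 1]], dtype=float)
        rect = np.vstack(
            [np.linspace(p, q, 20)[:-1] for p, q in zip(rect, np.roll(rect, -1, 0))]
        )
        angle = np.deg2rad(30)
        c, s = np.cos(angle), np.sin(angle)
        m = mm.measures(rect @ np.array([[c, s], [-s, c]]))
        assert m.length == pytest.approx(4.0, rel=0.01)
        assert m.width == pytest.approx(2.0, rel=0.01)

    def test_isoperimetric_inequality_on_random_shapes(self, rng):
        for _ in range(10):
            m = mm.measures(random_smooth_outline(rng))
            assert m.perimeter**2 >= 4 * np.pi * m.area * (1 - 1e-9)


class TestMorphospace:
    @staticmethod
    def _family(rng, bump, n):
        out = []
        for _ in range(n):
            coeffs = np.zeros((4, 4))
            coeffs[0] = [1, 0, 0, 0.6]
            coeffs[2, 0] = bump + rng.normal(0, 0.002)
            coeffs += rng.normal(0, 0.002, coeffs.shape)
            e = mm.EFDSet(coeffs)
            out.append(mm.normalize_efd(mm.efa(mm.reconstruct(e, 128), 4)))
        return out

    def test_identical_shapes_zero_scores(self, rng):
        e = mm.normalize_efd(mm.efa(random_smooth_outline(rng), 8))
        space = mm.morphospace([e] * 5, k=3)
        assert np.all(np.abs(space.scores.to_numpy()) < 1e-10)

    def test_two_families_separate_on_pc1(self, rng):
        fams = self._family(rng, 0.0, 10) + self._family(rng, 0.15, 10)
        space = mm.morphospace(fams, k=3)
        pc1 = space.scores.iloc[:, 0].to_numpy()
        assert max(pc1[:10]) < min(pc1[10:]) or min(pc1[:10]) > max(pc1[10:])

    def test_explained_variance_properties(self, rng):
        efds = [mm.normalize_efd(mm.efa(random_smooth_outline(rng), 8)) for _ in range(12)]
        space = mm.morphospace(efds, k=10)
        evr = space.explained_variance_ratio
        assert evr.sum() <= 1 + 1e-9
        assert np.all(np.diff(evr) <= 1e-12)
        assert np.allclose(space.scores.mean(axis=0), 0.0, atol=1e-8)

    def test_full_rank_preserves_distances(self, rng):
        efds = [mm.normalize_efd(mm.efa(random_smooth_outline(rng), 6)) for _ in range(8)]
        space = mm.morphospace(efds, k=7)
        x = np.array([e.flatten() for e in efds])
        from scipy.spatial.distance import pdist

        assert np.allclose(pdist(x), pdist(space.scores.to_numpy()), atol=1e-8)

    def test_needs_three_outlines(self, rng):
        e = mm.normalize_efd(mm.efa(random_smooth_outline(rng), 6))
        with pytest.raises(ValueError):
            mm.morphospace([e, e], k=2)
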