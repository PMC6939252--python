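import numpy as np
import pytest
from scipy.optimize import minimize_scalar

import arcmorph as am
from arcmorph.io import SEMILANDMARK, LandmarkConfiguration, SliderScheme, SymmetryScheme
from arcmorph.superimpose import _standardize, opa_align

from conftest import random_rigid


class TestCentroidSize:
    def test_unit_square(self):
        square = [[0, 0], [1, 0], [1, 1], [0, 1]]
        assert am.centroid_size(square) == pytest.approx(np.sqrt(2))

    def test_positive_homogeneity(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]])
        assert am.centroid_size(3 * square) == pytest.approx(3 * np.sqrt(2))

    def test_collinear_points(self):
        # centroid (1,0); squared distances 1+0+1 = 2
        assert am.centroid_size([[0, 0], [1, 0], [2, 0]]) == pytest.approx(np.sqrt(2))

    def test_identical_points_give_zero(self):
        assert am.centroid_size([[1, 1], [1, 1], [1, 1]]) == 0.0


class TestOpaAlign:
    def test_self_alignment_distance_zero(self, rng):
        shape = rng.normal(size=(7, 2))
        aligned, dist = opa_align(shape, shape)
        assert dist == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(aligned, _standardize(shape), atol=1e-12)

    def test_similarity_invariance(self, rng):
        ref = rng.normal(size=(6, 2))
        th = np.pi / 6
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = ref @ rot.T * 2.5 + [3.0, -1.0]
        _, dist = opa_align(moved, ref)
        assert dist == pytest.approx(0.0, abs=1e-10)

    def test_matches_rotation_grid_search(self, rng):
        """2-D OPA distance equals a brute-force minimization over the
        rotation angle on a fine grid."""
        a = rng.normal(size=(5, 2))
        b = rng.normal(size=(5, 2))
        _, dist = opa_align(a, b)
        a_s, b_s = _standardize(a), _standardize(b)

        def resid(theta):
            c, s = np.cos(theta), np.sin(theta)
            rot = np.array([[c, -s], [s, c]])
            return np.sqrt(np.sum((a_s @ rot - b_s) ** 2))

        grid = np.linspace(0, 2 * np.pi, 2_000_001)
        brute = np.min([resid(t) for t in grid[:: 10000]])
        # refine around the coarse winner with a scalar minimizer
        coarse = grid[::10000][np.argmin([resid(t) for t in grid[::10000]])]
        fine = minimize_scalar(resid, bracket=(coarse - 0.1, coarse, coarse + 0.1))
        assert dist == pytest.approx(min(brute, fine.fun), abs=1e-6)

    def test_degenerate_configuration_raises(self):
        flat = np.ones((4, 2))
        with pytest.raises(ValueError, match="degenerate"):
            opa_align(flat, np.eye(2).repeat(2, 0))

    def test_rotation_is_proper(self, rng):
        # a reflected shape must NOT be recovered: distance stays large
        shape = rng.normal(size=(6, 2))
        mirrored = shape * [-1, 1]
        _, dist = opa_align(mirrored, shape)
        assert dist > 0.1


class TestProcrustesDistance:
    def test_zero_on_self(self, rng):
        s = rng.normal(size=(5, 2))
        assert am.procrustes_distance(s, s) == pytest.approx(0, abs=1e-12)

    def test_symmetric(self, rng):
        a, b = rng.normal(size=(5, 2)), rng.normal(size=(5, 2))
        assert am.procrustes_distance(a, b) == pytest.approx(
            am.procrustes_distance(b, a), abs=1e-12
        )

    def test_consistent_with_opa(self, rng):
        tri = rng.normal(size=(3, 2))
        pert = tri + rng.normal(scale=0.05, size=(3, 2))
        assert am.procrustes_distance(tri, pert) == pytest.approx(
            opa_align(tri, pert)[1], abs=1e-12
        )


class TestSlideSemilandmarks:
    def _setup(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.5], [2.0, 0.0]])
        roles = ["fixed", SEMILANDMARK, "fixed"]
        scheme = SliderScheme(((0, 1, 2),))
        return pts, roles, scheme

    def test_no_displacement_when_at_reference(self):
        pts, _, scheme = self._setup()
        out = am.slide_semilandmarks(pts, pts.copy(), scheme)
        np.testing.assert_allclose(out, pts, atol=1e-14)

    def test_perpendicular_offset_gives_zero_displacement(self):
        pts, _, scheme = self._setup()
        ref = pts.copy()
        ref[1] += [0.0, 0.7]  # chord is the x-axis; offset purely normal
        out = am.slide_semilandmarks(pts, ref, scheme)
        np.testing.assert_allclose(out, pts, atol=1e-14)

    def test_tangent_offset_matches_scalar_minimization(self):
        pts, _, scheme = self._setup()
        ref = pts.copy()
        ref[1] += [0.37, 0.0]
        out = am.slide_semilandmarks(pts, ref, scheme)
        # oracle: minimize squared distance to ref along the tangent line
        chord = pts[2] - pts[0]
        u = chord / np.linalg.norm(chord)

        def cost(t):
            return np.sum((pts[1] + t * u - ref[1]) ** 2)

        best = minimize_scalar(cost)
        np.testing.assert_allclose(out[1], pts[1] + best.x * u, atol=1e-8)
        np.testing.assert_allclose(out[1] - pts[1], [0.37, 0.0], atol=1e-12)

    def test_coincident_neighbours_leave_point_unmoved(self, caplog):
        pts = np.array([[1.0, 0.0], [0.5, 0.5], [1.0, 0.0]])
        scheme = SliderScheme(((0, 1, 2),))
        with caplog.at_level("WARNING"):
            out = am.slide_semilandmarks(pts, pts + 1.0, scheme)
        np.testing.assert_allclose(out, pts)
        assert "coincident" in caplog.text

    def test_sliding_never_increases_distance_to_reference(self, rng):
        """Per-semilandmark and overall distance to the reference is
        non-increasing under tangent sliding."""
        ref = _standardize(rng.normal(size=(10, 2)))
        cur = ref + rng.normal(scale=0.05, size=(10, 2))
        scheme = SliderScheme(tuple((i - 1, i, i + 1) for i in range(1, 9)))
        out = am.slide_semilandmarks(cur, ref, scheme)
        for _, idx, _ in scheme.triples:
            before = np.sum((cur[idx] - ref[idx]) ** 2)
            after = np.sum((out[idx] - ref[idx]) ** 2)
            assert after <= before + 1e-14
        assert np.sum((out - ref) ** 2) <= np.sum((cur - ref) ** 2) + 1e-14


class TestSymmetrize:
    def _scheme(self):
        # 2 pairs + 1 midline point, reflection across x=0
        return SymmetryScheme(paired=((0, 1), (2, 3)), midline=(4,))

    def _symmetric_config(self):
        return np.array(
            [[-1.0, 0.5], [1.0, 0.5], [-0.4, -0.6], [0.4, -0.6], [0.0, 1.0]]
        )

    def test_symmetric_configuration_unchanged(self):
        pts = self._symmetric_config()
        out = am.symmetrize(pts, self._scheme())
        np.testing.assert_allclose(out, pts, atol=1e-9)

    def test_output_invariant_under_reflect_and_relabel(self, rng):
        pts = self._symmetric_config() + rng.normal(scale=0.1, size=(5, 2))
        scheme = self._scheme()
        out = am.symmetrize(pts, scheme)
        centered = out - out.mean(axis=0)
        mirrored = centered * [-1, 1]
        mirrored = mirrored[scheme.permutation(5)]
        _, dist = opa_align(mirrored, centered)
        assert dist == pytest.approx(0.0, abs=1e-9)

    def test_idempotent(self, rng):
        pts = self._symmetric_config() + rng.normal(scale=0.1, size=(5, 2))
        once = am.symmetrize(pts, self._scheme())
        twice = am.symmetrize(once, self._scheme())
        np.testing.assert_allclose(twice, once, atol=1e-9)

    def test_matches_direct_arithmetic_oracle(self):
        """One asymmetric pair; the averaged positions must match an explicit
        reflect-relabel-align-average computation done from scratch."""
        pts = np.array(
            [[-1.0, 0.1], [1.0, -0.3], [-0.4, -0.6], [0.4, -0.6], [0.0, 1.0]]
        )
        scheme = self._scheme()
        out = am.symmetrize(pts, scheme)

        centered = pts - pts.mean(axis=0)
        mirrored = (centered * [-1, 1])[[1, 0, 3, 2, 4]]
        # align mirrored onto centered by brute-force rotation search
        def resid(theta):
            c, s = np.cos(theta), np.sin(theta)
            rot = np.array([[c, -s], [s, c]])
            return np.sum((mirrored @ rot - centered) ** 2)

        thetas = np.linspace(0, 2 * np.pi, 100000)
        best = thetas[np.argmin([resid(t) for t in thetas])]
        fine = minimize_scalar(resid, bracket=(best - 1e-3, best, best + 1e-3))
        c, s = np.cos(fine.x), np.sin(fine.x)
        rot = np.array([[c, -s], [s, c]])
        expected = (centered + mirrored @ rot) / 2 + pts.mean(axis=0)
        np.testing.assert_allclose(out, expected, atol=1e-6)


class TestGPA:
    def test_rigid_copies_collapse_to_consensus(self, rng):
        base = rng.normal(size=(8, 2))
        configs = [random_rigid(base, rng) for _ in range(6)]
        res = am.gpa(configs)
        for a in res.aligned:
            assert am.procrustes_distance(a.shape, res.consensus) < 1e-9
            np.testing.assert_allclose(a.shape, res.consensus, atol=1e-9)

    def test_aligned_shapes_have_unit_centroid_size(self, ellipse_dataset):
        res = am.gpa(ellipse_dataset.configs, sliders=ellipse_dataset.sliders)
        for a in res.aligned:
            assert am.centroid_size(a.shape) == pytest.approx(1.0, abs=1e-9)
            np.testing.assert_allclose(a.shape.mean(axis=0), 0.0, atol=1e-9)

    def test_centroid_sizes_recorded_before_scaling(self, rng):
        base = _standardize(rng.normal(size=(6, 2)))
        configs = [base * 2.0, base * 5.0]
        res = am.gpa(configs)
        np.testing.assert_allclose(res.centroid_sizes, [2.0, 5.0], rtol=1e-9)

    def test_two_shape_gpa_matches_closed_oracle(self, rng):
        """Two-specimen consensus equals the normalized midpoint of the
        OPA-aligned pair, computed directly."""
        a = rng.normal(size=(7, 2))
        b = a + rng.normal(scale=0.3, size=(7, 2))
        res = am.gpa([a, b])
        a_s = _standardize(a)
        b_aligned, _ = opa_align(b, a)
        midpoint = _standardize((a_s + b_aligned) / 2)
        assert am.procrustes_distance(res.consensus, midpoint) < 1e-8

    def test_consensus_is_rescaled_mean_of_aligned(self, mandible_dataset):
        res = am.gpa(mandible_dataset.configs)
        mean = res.shapes.mean(axis=0)
        np.testing.assert_allclose(
            res.consensus, mean / np.sqrt(np.sum(mean**2)), atol=1e-8
        )

    def test_fixed_point_reconverges_in_one_iteration(self, mandible_dataset):
        res = am.gpa(mandible_dataset.configs)
        again = am.gpa([a.shape for a in res.aligned])
        assert again.iterations == 1
        assert again.converged

    def test_similarity_invariance(self, ellipse_dataset, rng):
        res = am.gpa(ellipse_dataset.configs, sliders=ellipse_dataset.sliders)
        transformed = [
            LandmarkConfiguration(c.specimen_id, c.element,
                                  random_rigid(c.points, rng), list(c.roles))
            for c in ellipse_dataset.configs
        ]
        res2 = am.gpa(transformed, sliders=ellipse_dataset.sliders)
        assert np.max(np.abs(res2.shapes - res.shapes)) < 1e-8

    def test_symmetrized_gpa_output_is_symmetric(self, rng):
        tpl = am.make_template("toy_cranium_3d")
        spec = am.SimulationSpec(
            tpl, [am.GroupSpec("A", 6), am.GroupSpec("B", 6, offset=0.03)],
            landmark_noise_sd=0.01, seed=3,
        )
        data = am.simulate_landmarks(spec)
        res = am.gpa(data.configs, symmetry=tpl.symmetry)
        perm = tpl.symmetry.permutation(30)
        for a in res.aligned:
            mirrored = (a.shape * [-1, 1, 1])[perm]
            _, dist = opa_align(mirrored, a.shape)
            assert dist < 1e-8

    def test_non_convergence_flagged_not_raised(self, mandible_dataset):
        res = am.gpa(mandible_dataset.configs, max_iter=1, tol=1e-300)
        assert res.converged is False

    def test_fewer_than_two_configs_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            am.gpa([rng.normal(size=(5, 2))])
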