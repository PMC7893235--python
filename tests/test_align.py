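"""Superimposition: centroid size, pairwise alignment, GPA, symmetry ops."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_rigid_motion
from morphosig.align import (DegenerateConfigurationError,
                             RetrodeformationError, align_pair,
                             bilateral_obliquity_deg, centroid_size,
                             estimate_midline_plane, gpa, procrustes_distance,
                             symmetric_gpa, symmetrize_retrodeform)
from morphosig.data import LandmarkConfiguration
from morphosig.simulate import make_consensus, make_scheme, make_truth, \
    simulate_dataset


class TestCentroidSize:
    def test_square_of_unit_points_is_sqrt8(self):
        pts = np.array([[1, 1, 0], [1, -1, 0], [-1, 1, 0], [-1, -1, 0]],
                       dtype=float)
        assert centroid_size(pts) == pytest.approx(np.sqrt(8.0), abs=1e-12)

    @given(st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_equivariance(self, c):
        rng = np.random.default_rng(0)
        pts = rng.standard_normal((7, 3))
        assert centroid_size(c * pts) == pytest.approx(c * centroid_size(pts),
                                                       rel=1e-12)

    def test_coincident_landmarks_rejected(self):
        with pytest.raises(DegenerateConfigurationError):
            centroid_size(np.ones((5, 3)))


class TestAlignPair:
    def test_exact_recovery_of_rigid_motion(self):
        rng = np.random.default_rng(1)
        Y = rng.standard_normal((9, 3))
        R = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], dtype=float)
        target = Y @ R + np.array([3.0, -1.0, 2.0])
        a = align_pair(target, Y)
        assert a.residual == pytest.approx(0.0, abs=1e-20)
        np.testing.assert_allclose(a.apply(target), Y, atol=1e-10)

    def test_reflection_needs_permission(self):
        rng = np.random.default_rng(2)
        Y = rng.standard_normal((8, 3))
        mirrored = Y * np.array([-1.0, 1.0, 1.0])
        assert align_pair(mirrored, Y, allow_reflection=False).residual > 1e-3
        assert align_pair(mirrored, Y,
                          allow_reflection=True).residual == pytest.approx(
                              0.0, abs=1e-18)

    def test_proper_rotation_determinant(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            a = align_pair(rng.standard_normal((6, 3)),
                           rng.standard_normal((6, 3)))
            assert np.linalg.det(a.rotation) == pytest.approx(1.0, abs=1e-10)


class TestGPA:
    def test_copies_of_one_shape_align_exactly(self):
        rng = np.random.default_rng(4)
        base = rng.standard_normal((10, 3))
        stack = []
        for _ in range(6):
            Q, t = random_rigid_motion(rng)
            stack.append(rng.uniform(0.5, 2.0) * (base @ Q) + t)
        al = gpa(np.stack(stack))
        assert np.sum((al.coords - al.coords.mean(axis=0)) ** 2) < 1e-12
        al.validate(atol=1e-8)

    def test_order_invariance_of_consensus_and_residuals(self):
        truth = make_truth(make_scheme(8, 3), seed=2)
        ds, _ = simulate_dataset(truth, n_specimens=10, seed=5)
        X = ds.coords_array()
        rng = np.random.default_rng(0)
        perm = rng.permutation(10)
        a1 = gpa(X, tol=1e-14)
        a2 = gpa(X[perm], tol=1e-14)
        np.testing.assert_allclose(a1.consensus, a2.consensus, atol=1e-9)
        r1 = np.sum((a1.coords - a1.consensus) ** 2, axis=(1, 2))
        r2 = np.sum((a2.coords - a2.consensus) ** 2, axis=(1, 2))
        np.testing.assert_allclose(r1[perm], r2, atol=1e-9)

    def test_invariance_to_per_specimen_similarity_transforms(self):
        truth = make_truth(make_scheme(8, 3), seed=3)
        ds, _ = simulate_dataset(truth, n_specimens=8, seed=6)
        X = ds.coords_array()
        rng = np.random.default_rng(1)
        Y = np.empty_like(X)
        for i in range(X.shape[0]):
            Q, t = random_rigid_motion(rng)
            Y[i] = rng.uniform(0.2, 5.0) * (X[i] @ Q) + t
        a1 = gpa(X, tol=1e-14)
        a2 = gpa(Y, tol=1e-14)
        np.testing.assert_allclose(a1.coords, a2.coords, atol=1e-9)

    def test_two_specimens_match_pairwise_alignment(self):
        rng = np.random.default_rng(7)
        A = rng.standard_normal((12, 3))
        B = A + 0.05 * rng.standard_normal((12, 3))
        al = gpa(np.stack([A, B]), tol=1e-14)
        # after mutual unit-scaling, the gpa residual between the two aligned
        # shapes equals the pairwise full-Procrustes residual
        An = (A - A.mean(0)) / centroid_size(A)
        Bn = (B - B.mean(0)) / centroid_size(B)
        pair = align_pair(Bn, An, scale=False)
        d_gpa = float(np.sum((al.coords[0] - al.coords[1]) ** 2))
        assert d_gpa == pytest.approx(pair.residual, rel=1e-6)

    def test_unit_size_and_centering_postconditions(self, desk_aligned):
        desk_aligned.validate(atol=1e-8)
        cs = np.sqrt(np.sum(desk_aligned.coords ** 2, axis=(1, 2)))
        np.testing.assert_allclose(cs, 1.0, atol=1e-8)


class TestMidlinePlane:
    def _config(self, coords, scheme=None):
        if scheme is None:
            scheme = make_scheme(10, 2)
        return LandmarkConfiguration(scheme, coords, None, "s")

    def test_exact_plane_x0(self):
        scheme = make_scheme(10, 2)
        coords = make_consensus(scheme, seed=1)
        point, normal = estimate_midline_plane(self._config(coords, scheme))
        np.testing.assert_allclose(np.abs(normal), [1, 0, 0], atol=1e-10)

    def test_noise_perturbs_plane_proportionally(self):
        scheme = make_scheme(10, 2)
        base = make_consensus(scheme, seed=1)
        rng = np.random.default_rng(2)
        sigma = 1e-3
        coords = base + sigma * rng.standard_normal(base.shape)
        _, normal = estimate_midline_plane(self._config(coords, scheme))
        tilt = np.arccos(np.clip(abs(normal[0]), 0, 1))
        assert tilt < 50 * sigma

    def test_collinear_midline_rejected(self):
        scheme = make_scheme(10, 2)
        coords = make_consensus(scheme, seed=1).copy()
        mid = scheme.midline_indices
        coords[mid] = np.outer(np.linspace(0, 1, mid.size), [0.0, 1.0, 1.0])
        with pytest.raises(DegenerateConfigurationError, match="collinear"):
            estimate_midline_plane(self._config(coords, scheme))


class TestSymmetricGPA:
    def test_symmetric_specimens_match_plain_gpa(self):
        scheme = make_scheme(10, 3)
        truth = make_truth(scheme, seed=4, noise_sigma=0.0,
                           variance_scale={m: 1.0 for m in scheme.module_names})
        ds, _ = simulate_dataset(truth, n_specimens=6, seed=7)
        plain = gpa(ds.complete_subset(), tol=1e-14)
        sym = symmetric_gpa(ds.complete_subset(), tol=1e-14)
        assert procrustes_distance(sym.consensus, plain.consensus) < 1e-6

    def test_midline_spread_not_worse_than_plain_gpa(self):
        # width-heterogeneous specimens: symmetric alignment keeps the
        # midline registered to a common plane
        scheme = make_scheme(10, 3)
        base = make_consensus(scheme, seed=5)
        rng = np.random.default_rng(8)
        stack = []
        for i in range(12):
            w = rng.uniform(0.6, 1.6)      # lateral width factor
            spec = base.copy()
            spec[:, 0] *= w
            spec += 0.002 * rng.standard_normal(spec.shape)
            Q, t = random_rigid_motion(rng)
            stack.append(LandmarkConfiguration(scheme, spec @ Q + t, None,
                                               f"s{i}"))
        from morphosig.data import SpecimenDataset
        ds = SpecimenDataset(scheme, stack)
        plain = gpa(ds)
        sym = symmetric_gpa(ds)
        mid = scheme.midline_indices

        def spread(al):
            pts = al.coords[:, mid, :].reshape(-1, 3)
            c = pts.mean(axis=0)
            _, _, Vt = np.linalg.svd(pts - c)
            d = (pts - c) @ Vt[2]
            # normalize by the mean aligned half-size so frames are comparable
            scale = np.mean(np.sqrt(np.sum(
                (al.coords - al.coords.mean(axis=1, keepdims=True)) ** 2,
                axis=(1, 2))))
            return np.mean(np.abs(d)) / scale
        assert spread(sym) <= spread(plain) * 1.05

    def test_single_specimen_is_centered_scaled_input(self):
        scheme = make_scheme(10, 3)
        truth = make_truth(scheme, seed=6)
        ds, _ = simulate_dataset(truth, n_specimens=4, seed=9)
        one = ds.complete_subset()
        one.configurations = one.configurations[:1]
        sym = symmetric_gpa(one)
        assert procrustes_distance(sym.coords[0],
                                   one.configurations[0].coords) < 1e-8


class TestRetrodeformation:
    def _specimen(self, shear_deg=0.0, seed=0):
        scheme = make_scheme(12, 3)
        coords = make_consensus(scheme, seed=seed).copy()
        if shear_deg:
            coords[:, 0] += np.tan(np.radians(shear_deg)) * coords[:, 2]
        return LandmarkConfiguration(scheme, coords, None, "s")

    def test_symmetric_configuration_is_fixed_point(self):
        cfg = self._specimen()
        out = symmetrize_retrodeform(cfg)
        np.testing.assert_allclose(out.coords, cfg.coords, atol=1e-12)

    def test_sheared_specimen_symmetrized_and_idempotent(self):
        cfg = self._specimen(shear_deg=5.0)
        assert bilateral_obliquity_deg(cfg) == pytest.approx(5.0, abs=0.5)
        once = symmetrize_retrodeform(cfg)
        assert bilateral_obliquity_deg(once) < 1e-6
        twice = symmetrize_retrodeform(once)
        np.testing.assert_allclose(twice.coords, once.coords, atol=1e-10)

    def test_strongly_sheared_specimen_refused(self):
        cfg = self._specimen(shear_deg=15.0)
        with pytest.raises(RetrodeformationError, match="exceeds"):
            symmetrize_retrodeform(cfg)
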