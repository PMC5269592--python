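"""Virtual 10/20 measurement: plane-surface curves, Cz fixed point, the 21
landmarks against closed-form sphere values, and the candidate grid."""

import math

import numpy as np
import pytest

from s3r.head_model import ReferenceSet, TriangleSurface, make_ellipsoid_head
from s3r.virtual_1020 import (
    LANDMARK_NAMES,
    REGIONS,
    CurveError,
    SurfaceCurve,
    locate_cz,
    measure_105_grid,
    measure_1020,
    plane_surface_curve,
    point_at_fraction,
)

from conftest import (
    closed_form_sphere_landmarks,
    random_rigid_motion,
    sphere_point_sagittal,
)


class TestPlaneSurfaceCurve:
    def test_sagittal_great_half_circle_length(self, sphere_head):
        refs = sphere_head.refs
        curve = plane_surface_curve(sphere_head.surface, refs.nz, refs.iz, (0, 0, 90))
        assert abs(curve.length - math.pi * 90) / (math.pi * 90) < 5e-4

    def test_curve_stays_in_cutting_plane(self, sphere_head):
        refs = sphere_head.refs
        a, b, c = refs.nz, refs.iz, np.array([0.0, 0.0, 90.0])
        n = np.cross(b - a, c - a)
        n = n / np.linalg.norm(n)
        curve = plane_surface_curve(sphere_head.surface, a, b, c)
        assert np.abs((curve.points - a) @ n).max() < 1e-6

    def test_coincident_endpoints_rejected(self, sphere_head):
        refs = sphere_head.refs
        with pytest.raises(CurveError):
            plane_surface_curve(sphere_head.surface, refs.nz, refs.nz, (0, 0, 90))

    def test_arc_length_converges_with_mesh_refinement(self):
        from s3r import make_sphere_head

        lengths = []
        for n_az in (48, 96):
            head = make_sphere_head(90.0, n_azimuth=n_az)
            refs = head.refs
            c = plane_surface_curve(head.surface, refs.nz, refs.iz, (0, 0, 90))
            lengths.append(c.length)
        exact = math.pi * 90
        assert abs(lengths[1] - exact) < abs(lengths[0] - exact)
        assert abs(lengths[1] - exact) / exact < 5e-3


class TestPointAtFraction:
    def test_endpoints(self):
        curve = SurfaceCurve(points=np.array([[0, 0, 0], [1, 0, 0], [3, 0, 0]], dtype=float))
        assert np.allclose(point_at_fraction(curve, 0.0), [0, 0, 0])
        assert np.allclose(point_at_fraction(curve, 1.0), [3, 0, 0])

    def test_midpoint_of_symmetric_great_circle_is_pole(self, sphere_head):
        refs = sphere_head.refs
        curve = plane_surface_curve(sphere_head.surface, refs.nz, refs.iz, (0, 0, 90))
        assert np.allclose(point_at_fraction(curve, 0.5), [0, 0, 90], atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_cumulative_length_scan(self, seed):
        rng = np.random.default_rng(seed)
        pts = np.cumsum(rng.uniform(-1, 1, size=(20, 3)), axis=0)
        curve = SurfaceCurve(points=pts)
        f = rng.uniform(0, 1)
        target = f * curve.length
        # brute-force scan
        acc = 0.0
        expected = pts[-1]
        for p, q in zip(pts[:-1], pts[1:]):
            step = np.linalg.norm(q - p)
            if acc + step >= target - 1e-12:
                t = (target - acc) / step
                expected = p + t * (q - p)
                break
            acc += step
        assert np.allclose(point_at_fraction(curve, f), expected, atol=1e-9)

    def test_out_of_range_fraction(self):
        curve = SurfaceCurve(points=np.array([[0, 0, 0], [1, 0, 0]], dtype=float))
        with pytest.raises(ValueError):
            point_at_fraction(curve, 1.5)


class TestLocateCz:
    def test_sphere_pole(self, sphere_head):
        cz = locate_cz(sphere_head.surface, sphere_head.refs)
        assert np.linalg.norm(cz - [0, 0, 90]) < 1e-3

    def test_loose_tolerance_converges_fast(self, sphere_head):
        cz = locate_cz(sphere_head.surface, sphere_head.refs, tol=10.0)
        assert np.linalg.norm(cz - [0, 0, 90]) < 10.0

    def test_ellipsoid_matches_exhaustive_vertex_search(self):
        head = make_ellipsoid_head(80, 95, 85, n_azimuth=32)
        S, refs = head.surface, head.refs
        cz = locate_cz(S, refs)

        # oracle: residual of the two 50%-criteria over all top vertices
        cand_idx = np.nonzero(S.vertices[:, 2] > 0.9 * S.vertices[:, 2].max())[0]
        best, best_res = None, np.inf
        for i in cand_idx:
            v = S.vertices[i]
            c1 = plane_surface_curve(S, refs.nz, refs.iz, v)
            c2 = plane_surface_curve(S, refs.al, refs.ar, v)
            res = np.linalg.norm(point_at_fraction(c1, 0.5) - v) + np.linalg.norm(
                point_at_fraction(c2, 0.5) - v
            )
            if res < best_res:
                best, best_res = v, res
        edge = S.vertices[S.faces[:, 0]] - S.vertices[S.faces[:, 1]]
        max_edge = np.linalg.norm(edge, axis=1).max()
        assert np.linalg.norm(cz - best) <= max_edge


class TestMeasure1020:
    def test_sphere_landmarks_match_closed_form(self, sphere_head, sphere_truth):
        oracle = closed_form_sphere_landmarks()
        for name in LANDMARK_NAMES:
            err = np.linalg.norm(sphere_truth[name] - oracle[name])
            assert err < 0.2, f"{name}: {err:.3f} mm"

    def test_all_landmarks_on_surface(self, sphere_head, sphere_truth):
        from s3r.head_model import closest_surface_points

        _, d = closest_surface_points(
            sphere_head.surface, np.array([sphere_truth[n] for n in LANDMARK_NAMES])
        )
        assert d.max() < 1e-6

    def test_left_right_mirror_symmetry(self, sphere_truth):
        pairs = [("Fp1", "Fp2"), ("F3", "F4"), ("F7", "F8"), ("C3", "C4"),
                 ("T3", "T4"), ("P3", "P4"), ("T5", "T6"), ("O1", "O2")]
        flip = np.array([-1.0, 1.0, 1.0])
        for left, right in pairs:
            assert np.abs(sphere_truth[left] * flip - sphere_truth[right]).max() < 1e-6

    def test_nominal_arc_fractions(self, sphere_head):
        """Sagittal landmarks sit at their exact nominal fractions of the
        measured curve."""
        S, refs = sphere_head.surface, sphere_head.refs
        lm = measure_1020(S, refs)
        sag = plane_surface_curve(S, refs.nz, refs.iz, lm["Cz"])
        for name, f in zip(("Fpz", "Fz", "Cz", "Pz", "Oz"), (0.1, 0.3, 0.5, 0.7, 0.9)):
            assert np.allclose(lm[name], point_at_fraction(sag, f), atol=1e-9)

    def test_rigid_motion_invariance(self, sphere_head, sphere_truth):
        rng = np.random.default_rng(12)
        rot, t = random_rigid_motion(rng)
        S = sphere_head.surface
        moved = TriangleSurface(S.vertices @ rot.T + t, S.faces)
        moved_refs = sphere_head.refs.transform(lambda p: rot @ p + t)
        lm = measure_1020(moved, moved_refs)
        for name in LANDMARK_NAMES:
            back = rot.T @ (lm[name] - t)
            assert np.linalg.norm(back - sphere_truth[name]) < 1e-5, name

    def test_resolution_refinement_stability(self):
        from s3r import make_sphere_head

        heads = [make_sphere_head(90.0, n_azimuth=n) for n in (48, 96)]
        lms = [measure_1020(h.surface, h.refs) for h in heads]
        for name in LANDMARK_NAMES:
            assert np.linalg.norm(lms[0][name] - lms[1][name]) < 0.5, name


class TestCandidateGrid:
    def test_grid_size_and_partition(self, sphere_grid):
        assert len(sphere_grid) >= 100
        subsets = sphere_grid.subsets
        assert set(subsets) == set(REGIONS)
        counted = sum(len(v) for v in subsets.values())
        assert counted == len(sphere_grid)
        assert all(len(v) > 0 for v in subsets.values())

    def test_five_percent_sagittal_point(self, sphere_grid):
        target = sphere_point_sagittal(0.05)
        d = np.linalg.norm(sphere_grid.points - target, axis=1).min()
        assert d < 0.2

    def test_points_pairwise_distinct(self, sphere_grid):
        from scipy.spatial.distance import pdist

        assert pdist(sphere_grid.points).min() > 1.0

    def test_points_on_surface(self, sphere_head, sphere_grid):
        from s3r.head_model import closest_surface_points

        _, d = closest_surface_points(sphere_head.surface, sphere_grid.points)
        assert d.max() < 1e-6

    def test_supports_sweep_sample_sizes(self, sphere_grid):
        # the full-scale sweep needs balanced draws up to n = 110
        assert min(len(v) for v in sphere_grid.subsets.values()) >= 11
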