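"""Visual-hull reconstruction, scan planning and co-registration."""

import numpy as np
import pytest
import trimesh
from scipy.spatial import cKDTree

from marginscan import surface_scan as ss
from marginscan.probe import contact_area, estimate_point_count
from marginscan.synthetic_phantom import make_phantom, render_silhouettes

SPHERE = make_phantom(n_spots=0)  # 50 mm sphere, no spots
R = 25.0


@pytest.fixture(scope="module")
def sphere_hull():
    sil = render_silhouettes(SPHERE, n_views=36, scale=0.25)
    return ss.reconstruct_visual_hull(sil, voxel_size=0.25)


class TestSilhouettes:
    def test_needs_two_views(self):
        sil = render_silhouettes(SPHERE, n_views=4)
        with pytest.raises(ValueError, match=">= 2"):
            ss.SilhouetteSet(sil.images[:1], sil.angles_deg[:1],
                             sil.scale, sil.origin)

    def test_empty_mask_rejected(self):
        sil = render_silhouettes(SPHERE, n_views=4)
        imgs = sil.images.copy()
        imgs[2] = False
        with pytest.raises(ValueError, match="non-empty"):
            ss.SilhouetteSet(imgs, sil.angles_deg, sil.scale, sil.origin)


class TestVisualHull:
    def test_sphere_volume_and_radius_within_tolerance(self, sphere_hull):
        true_vol = 4.0 / 3.0 * np.pi * R**3
        assert abs(sphere_hull.volume / true_vol - 1.0) < 0.02
        radii = np.linalg.norm(sphere_hull.vertices, axis=1)
        assert np.abs(radii - R).max() < 0.5

    def test_hull_is_watertight_with_outward_normals(self, sphere_hull):
        assert sphere_hull.is_watertight
        assert sphere_hull.volume > 0  # consistent outward orientation

    def test_two_views_over_approximate(self):
        sil = render_silhouettes(SPHERE, n_views=4, scale=0.5)
        two = ss.SilhouetteSet(sil.images[:2], sil.angles_deg[:2],
                               sil.scale, sil.origin)
        hull = ss.reconstruct_visual_hull(two, voxel_size=0.5)
        assert hull.volume >= 4.0 / 3.0 * np.pi * R**3

    def test_volume_non_increasing_as_views_added(self):
        ell = make_phantom(semi_axes=(30.0, 15.0, 10.0), n_spots=0)
        vols = []
        for n_views in (4, 8, 16, 36):
            sil = render_silhouettes(ell, n_views=n_views, scale=0.5)
            vols.append(ss.reconstruct_visual_hull(sil, voxel_size=0.5).volume)
        assert np.all(np.diff(vols) <= 1e-9)
        # and the hull contains the true convex body up to meshing
        # discretisation (the isosurface sits within half a voxel)
        assert vols[-1] >= 0.98 * (4.0 / 3.0 * np.pi * 30 * 15 * 10)

    def test_true_surface_never_carved_away(self, sphere_hull):
        # the hull surface never dips below the true sphere by more than
        # one voxel anywhere (star-shaped check over all surface vertices)
        radii = np.linalg.norm(sphere_hull.vertices, axis=1)
        assert radii.min() >= R - 0.25

    def test_inconsistent_masks_rejected(self):
        sil = render_silhouettes(SPHERE, n_views=4, scale=0.5)
        imgs = sil.images.copy()
        imgs[0] = False
        imgs[0, :5, :5] = True  # tiny blob disjoint from the other views
        bad = ss.SilhouetteSet(imgs, sil.angles_deg, sil.scale, sil.origin)
        with pytest.raises(ValueError, match="empty visual hull"):
            ss.reconstruct_visual_hull(bad, voxel_size=0.5)


@pytest.fixture(scope="module")
def plan35(sphere_hull):
    return ss.plan_points(sphere_hull, step=3.5)


class TestPlanPoints:
    def test_spacing_invariant(self, plan35):
        d, _ = cKDTree(plan35.points).query(plan35.points, k=2)
        nn = d[:, 1]
        assert nn.min() >= 0.5 * 3.5
        assert nn.max() <= 1.5 * 3.5

    def test_point_count_matches_geometric_budget(self, plan35):
        # footprint budget scaled by footprint/step^2 packing
        budget = estimate_point_count(np.pi * 50.0**2, 7.0)
        expected = budget * contact_area(7.0) / 3.5**2
        assert abs(len(plan35) / expected - 1.0) < 0.15

    def test_points_lie_on_the_mesh(self, sphere_hull, plan35):
        # sampled along face cross-sections, so on-mesh to precision
        closest = ss._project_to_mesh(sphere_hull, plan35.points[::50])
        assert np.linalg.norm(closest - plan35.points[::50], axis=1).max() < 1e-6

    def test_normals_point_outward(self, plan35):
        radial = plan35.points / np.linalg.norm(plan35.points, axis=1,
                                                keepdims=True)
        assert np.einsum("ij,ij->i", plan35.normals, radial).min() > 0.9

    def test_mounting_disc_excluded_and_flagged(self, sphere_hull, plan35):
        pole = sphere_hull.vertices[np.argmin(sphere_hull.vertices[:, 0])]
        dist = np.linalg.norm(plan35.points - pole, axis=1)
        assert dist.min() > 3.5
        assert plan35.manual_point_required

    def test_rotation_major_traversal(self, plan35):
        assert np.all(np.diff(plan35.band_index) >= 0)

    def test_step_equal_to_circumference_degenerates_gracefully(self,
                                                                sphere_hull):
        plan = ss.plan_points(sphere_hull, step=np.pi * 50.0)
        assert 1 <= len(plan) <= 5

    def test_absurd_step_rejected(self, sphere_hull):
        with pytest.raises(ValueError, match="too large"):
            ss.plan_points(sphere_hull, step=1e4)

    def test_reproducible(self, sphere_hull):
        p1 = ss.plan_points(sphere_hull, step=3.5)
        p2 = ss.plan_points(sphere_hull, step=3.5)
        assert np.array_equal(p1.points, p2.points)


@pytest.fixture(scope="module")
def small():
    mesh = trimesh.creation.icosphere(subdivisions=3, radius=R)
    plan = ss.ScanPlan(mesh.vertices[::20].copy(),
                       mesh.vertices[::20] / R, 3.5,
                       np.zeros(len(mesh.vertices[::20]), int),
                       np.zeros(len(mesh.vertices[::20])))
    return mesh, plan


class TestCoregister:
    def test_uniform_labels_give_uniform_colors(self, small):
        mesh, plan = small
        mm = ss.coregister(plan, ["fatty"] * len(plan), mesh)
        assert (mm.vertex_colors == ss.LABEL_COLORS["fatty"]).all()

    def test_single_positive_point_colors_its_voronoi_cell(self, small):
        mesh, plan = small
        labels = ["fatty"] * len(plan)
        labels[7] = "fibroadenomatoid"
        mm = ss.coregister(plan, labels, mesh)
        # brute-force nearest-point assignment over face centroids
        # (compare assigned distances, so exact ties are tolerated)
        d = np.linalg.norm(mesh.triangles_center[:, None, :]
                           - plan.points[None, :, :], axis=2)
        assigned = d[np.arange(len(d)), mm.face_point_index]
        assert np.allclose(assigned, d.min(axis=1), atol=1e-12)
        blue = np.flatnonzero(mm.face_point_index == 7)
        assert len(blue) > 0
        assert np.allclose(d[blue].min(axis=1), d[blue, 7], atol=1e-12)

    def test_label_count_mismatch_rejected(self, small):
        mesh, plan = small
        with pytest.raises(ValueError, match="one label per"):
            ss.coregister(plan, ["fatty"], mesh)

    def test_idempotent_and_order_independent(self, small):
        mesh, plan = small
        labels = ["fatty"] * len(plan)
        labels[3] = "fibroadenomatoid"
        m1 = ss.coregister(plan, labels, mesh)
        m2 = ss.coregister(plan, list(labels), mesh)
        assert np.array_equal(m1.vertex_colors, m2.vertex_colors)


class TestEvaluateLocalisation:
    def _map_with(self, mesh, points, labels, fractions):
        plan = ss.ScanPlan(np.asarray(points, float),
                           np.asarray(points, float), 0.5,
                           np.zeros(len(points), int),
                           np.zeros(len(points)))
        return ss.MarginMap(mesh, plan, labels, fractions,
                            np.empty(0, int), np.empty((0, 3), np.uint8))

    def test_exact_centers_give_zero_error_and_unit_r2(self):
        mesh = trimesh.creation.icosphere(subdivisions=4, radius=R)
        centers = mesh.vertices[[10, 500, 1200, 2000]]
        pts = np.vstack([centers, mesh.vertices[[50, 300]]])
        labels = ["paraffin_positive"] * 4 + ["clean"] * 2
        fr = [{"paraffin": 0.5}] * 4 + [{"paraffin": 0.0}] * 2
        res = ss.evaluate_localisation(self._map_with(mesh, pts, labels, fr),
                                       centers)
        assert res.n_detected == 4
        assert res.max_abs_error == pytest.approx(0.0, abs=1e-9)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_no_positives_is_detection_failure(self):
        mesh = trimesh.creation.icosphere(subdivisions=2, radius=R)
        res = ss.evaluate_localisation(
            self._map_with(mesh, mesh.vertices[:5], ["clean"] * 5,
                           [{"paraffin": 0.0}] * 5),
            mesh.vertices[[0, 30]])
        assert res.detection_failure
        assert res.n_detected == 0
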