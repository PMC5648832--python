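"""Phantom generator, silhouette renders, scan simulation, study twin."""

import numpy as np
import pytest
import trimesh

from marginscan import synthetic_phantom as sp
from marginscan.pipeline import build_cls_library, classify_scan
from marginscan.surface_scan import plan_points, reconstruct_visual_hull
from marginscan.unmixing import fit_cls
from marginscan.spectral_processing import Spectrum


class TestMakePhantom:
    def test_default_geometry_and_ground_truth(self):
        spec = sp.make_phantom(seed=0)
        assert spec.surface_area() == pytest.approx(np.pi * 50.0**2)
        assert len(spec.spots) == 4
        assert len(spec.true_pairwise_distances()) == 6
        for s in spec.spots:
            assert 3.0 <= s.extent <= 12.0
            assert np.linalg.norm(s.center) == pytest.approx(25.0, abs=1e-6)

    def test_spots_do_not_overlap(self):
        spec = sp.make_phantom(seed=3)
        c = spec.true_spot_centers
        e = np.array([s.extent for s in spec.spots])
        for i in range(4):
            for j in range(i + 1, 4):
                assert np.linalg.norm(c[i] - c[j]) >= (e[i] + e[j]) / 2

    def test_zero_spots_is_uniform_phantom(self):
        spec = sp.make_phantom(n_spots=0)
        assert spec.spots == ()
        assert spec.components == ("polymer_film", "soft_paper")

    def test_seeded_determinism(self):
        a = sp.make_phantom(seed=7)
        b = sp.make_phantom(seed=7)
        assert a == b
        assert a != sp.make_phantom(seed=8)

    def test_impossible_placement_raises(self):
        with pytest.raises(ValueError, match="could not place"):
            sp.make_phantom(n_spots=4, spot_extents=(12.0,) * 4,
                            belt_halfwidth=2.0, min_separation=30.0,
                            max_tries=50)


class TestRenderSilhouettes:
    def test_sphere_masks_are_discs_of_the_right_radius(self):
        spec = sp.make_phantom(n_spots=0)
        sil = sp.render_silhouettes(spec, n_views=6, scale=0.25)
        for img in sil.images:
            area = img.sum() * sil.scale**2
            r_eff = np.sqrt(area / np.pi)
            assert r_eff == pytest.approx(25.0, abs=2 * sil.scale)

    def test_ellipsoid_extents_oscillate_with_angle(self):
        spec = sp.make_phantom(semi_axes=(30.0, 10.0, 10.0), n_spots=0)
        sil = sp.render_silhouettes(spec, n_views=8, scale=0.25)
        for img in sil.images:
            rows = np.flatnonzero(img.any(axis=1))
            cols = np.flatnonzero(img.any(axis=0))
            width = (cols[-1] - cols[0] + 1) * sil.scale
            height = (rows[-1] - rows[0] + 1) * sil.scale
            assert width == pytest.approx(60.0, abs=1.0)
            assert height == pytest.approx(20.0, abs=1.0)

    def test_render_reconstruct_round_trip_volume(self):
        spec = sp.make_phantom(semi_axes=(30.0, 10.0, 10.0), n_spots=0)
        sil = sp.render_silhouettes(spec, n_views=36, scale=0.25)
        mesh = reconstruct_visual_hull(sil, voxel_size=0.4)
        true = 4.0 / 3.0 * np.pi * 30 * 10 * 10
        assert abs(mesh.volume / true - 1.0) < 0.02

    def test_too_coarse_scale_rejected(self):
        with pytest.raises(ValueError, match="coarse"):
            sp.render_silhouettes(sp.make_phantom(n_spots=0), scale=10.0)


class TestDepthWeightModel:
    def test_outer_ring_slab_anchor_is_5_percent(self):
        dm = sp.DepthWeightModel.calibrated(3)
        ell = dm.decay_lengths[-1]
        slab = np.exp(-2.0 / ell) - np.exp(-3.0 / ell)
        assert slab == pytest.approx(0.05, abs=1e-9)

    def test_inner_rings_strictly_more_surface_weighted(self):
        dm = sp.DepthWeightModel.calibrated(3)
        assert np.all(np.diff(dm.decay_lengths) > 0)
        # surface-layer share decreases from inner to outer ring
        shares = [dm.column_fractions(r, [("fatty", 1.0), ("fatty", np.inf)])
                  for r in range(3)]
        tops = [dm.column_fractions(r, [("a", 1.0), ("b", np.inf)])["a"]
                for r in range(3)]
        assert np.all(np.diff(tops) < 0)
        del shares

    def test_column_fractions_sum_to_one(self):
        dm = sp.DepthWeightModel.calibrated(3)
        for r in range(3):
            for layers in ([("polymer_film", 2.0), ("soft_paper", np.inf)],
                           [("polymer_film", 2.0), ("paraffin", 2.0),
                            ("soft_paper", np.inf)]):
                total = sum(dm.column_fractions(r, layers).values())
                assert total == pytest.approx(1.0, abs=1e-9)

    def test_clear_film_contributes_less_than_tissue_of_same_thickness(self):
        dm = sp.DepthWeightModel.calibrated(3)
        film = dm.column_fractions(2, [("polymer_film", 2.0),
                                       ("soft_paper", np.inf)])["polymer_film"]
        tissue = dm.column_fractions(2, [("fatty", 2.0),
                                         ("soft_paper", np.inf)])["fatty"]
        assert film < tissue


@pytest.fixture(scope="module")
def small_scan():
    """A quick band scan of the default phantom on an exact sphere mesh."""
    spec = sp.make_phantom(seed=5)
    mesh = trimesh.creation.icosphere(subdivisions=4, radius=25.0)
    xs = np.array([s.center[0] for s in spec.spots])
    plan = plan_points(mesh, step=2.0,
                       x_range=(xs.min() - 8, xs.max() + 8))
    return spec, plan


class TestSimulateScan:
    def test_point_far_from_spots_sees_only_film_and_paper(self, small_scan):
        spec, plan = small_scan
        sim = sp.simulate_scan(spec, plan, noise_sigma=0.0,
                               baseline_amplitude=0.0, seed=1)
        d = np.min(np.linalg.norm(
            plan.points[:, None, :] - spec.true_spot_centers[None], axis=2),
            axis=1)
        far = d > 12.0
        assert far.any()
        k = list(sim.components).index("paraffin")
        assert np.abs(sim.true_fractions[far, k]).max() == 0.0

    def test_zero_noise_cls_recovers_true_fractions(self, small_scan):
        # the forward model is linear, so noiseless depth-averaged spectra
        # invert exactly (no smoothing/baseline in this configuration)
        spec, plan = small_scan
        sim = sp.simulate_scan(spec, plan, noise_sigma=0.0,
                               baseline_amplitude=0.0, seed=1)
        library = build_cls_library(sim.components, sim.wavenumbers,
                                    do_smooth=False)
        for i in range(0, len(sim), 257):
            s = Spectrum(sim.wavenumbers, sim.depth_avg_intensities[i])
            fit = fit_cls(library, s, nonnegative=False)
            assert np.abs(fit.fractions - sim.true_fractions[i]).max() < 1e-6

    def test_seeded_determinism(self, small_scan):
        spec, plan = small_scan
        s1 = sp.simulate_scan(spec, plan, seed=3)
        s2 = sp.simulate_scan(spec, plan, seed=3)
        assert np.array_equal(s1.depth_avg_intensities,
                              s2.depth_avg_intensities)
        assert np.array_equal(s1.ring_fractions, s2.ring_fractions)

    def test_bundle_average_equals_stored_depth_average(self, small_scan):
        spec, plan = small_scan
        sim = sp.simulate_scan(spec, plan, seed=3)
        for i in (0, len(sim) // 2):
            bundle = sim.bundle(i)
            mean = np.mean([b.intensities for b in bundle.spectra.values()],
                           axis=0)
            assert np.allclose(mean, sim.depth_avg_intensities[i], atol=1e-12)

    def test_on_spot_paraffin_exceeds_detection_threshold(self, small_scan):
        spec, plan = small_scan
        sim = sp.simulate_scan(spec, plan, noise_sigma=0.0, seed=1)
        k = list(sim.components).index("paraffin")
        d = np.min(np.linalg.norm(
            plan.points[:, None, :] - spec.true_spot_centers[None], axis=2),
            axis=1)
        on_center = d < 1.0
        assert sim.true_fractions[on_center, k].min() >= 0.05

    def test_plan_off_the_surface_rejected(self, small_scan):
        spec, plan = small_scan
        bad = plan_points(trimesh.creation.icosphere(subdivisions=3,
                                                     radius=40.0), step=5.0)
        with pytest.raises(ValueError, match="surface"):
            sp.simulate_scan(spec, bad, seed=0)


class TestForwardModelConsistency:
    def test_zero_noise_pipeline_reproduces_ground_truth_labels(self,
                                                                small_scan):
        spec, plan = small_scan
        sim = sp.simulate_scan(spec, plan, noise_sigma=0.0,
                               baseline_amplitude=0.0, seed=2)
        labels, frac, ve = classify_scan(sim, do_baseline=False)
        assert labels == sim.true_labels
        assert ve > 99.9


class TestLabeledStudy:
    def test_default_emulates_printed_structure(self):
        data = sp.make_labeled_study(seed=0)
        assert len(data) == 28
        assert sum(1 for l in data.labels if l == "fatty") == 13
        assert sum(1 for l in data.labels if l == "fibroadenomatoid") == 15
        counts = [data.specimen_ids.count(s) for s in set(data.specimen_ids)]
        assert len(counts) == 5
        assert all(4 <= c <= 6 for c in counts)
        assert data.spectra[0].stages == ("raw", "smoothed",
                                          "baseline_subtracted", "normalized")

    def test_labels_follow_the_50_percent_rule(self):
        data = sp.make_labeled_study(seed=4)
        for s, lab in zip(data.spectra, data.labels):
            f = s.meta["true_fat_fraction"]
            assert lab == ("fatty" if f >= 0.5 else "fibroadenomatoid")

    def test_seeded_determinism(self):
        a = sp.make_labeled_study(seed=11)
        b = sp.make_labeled_study(seed=11)
        for sa, sb in zip(a.spectra, b.spectra):
            assert np.array_equal(sa.intensities, sb.intensities)
        assert a.labels == b.labels

    def test_zero_effect_size_is_a_null(self, coarse_axis):
        from marginscan.margin_classifier import loso_cv

        data = sp.make_labeled_study(seed=1, effect_size=0.0,
                                     wavenumbers=coarse_axis)
        rep = loso_cv(data)
        assert 0.2 <= rep.accuracy <= 0.8

    def test_infeasible_balance_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            sp.make_labeled_study(n_specimens=2, spots_per_specimen=(4, 6),
                                  class_balance=(13, 15))


def test_tissue_specimen_inclusion_depths_in_range():
    spec = sp.make_tissue_specimen(seed=2)
    for s in spec.spots:
        assert 0.5 <= s.depth <= 1.5
        assert s.component == "fibroadenomatoid"
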