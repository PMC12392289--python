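"""Phantom construction, boundary tracing, cohorts and the PD confound."""

import numpy as np
import pytest

from conftest import DX, DZ, GRID, small_spec
from visrsim import (CohortSpec, MaterialPoint, PhantomSpec, confound_pair,
                     double_push_schedule, lesion_boundary, make_phantom,
                     msd_response_numeric, peak_displacement, sample_cohort,
                     tracking_times)


class TestMakePhantom:
    def test_degenerate_uniform_case(self):
        spec = small_spec(lesion_E=3.0, lesion_mu=0.6, background_E=3.0,
                          background_mu=0.6)
        ph = make_phantom(spec)
        assert np.all(ph.E_map == 3.0)
        assert np.all(ph.mu_map == 0.6)

    def test_mask_area_matches_ellipse(self):
        ph = make_phantom(small_spec())
        area = ph.bmode_mask.sum() * DZ * DX
        assert area == pytest.approx(np.pi * 6 * 4, rel=0.02)

    def test_same_seed_bit_identical(self):
        spec = small_spec(heterogeneity_cv=0.1, seed=5)
        a, b = make_phantom(spec), make_phantom(spec)
        assert np.array_equal(a.E_map, b.E_map)
        assert np.array_equal(a.mu_map, b.mu_map)
        for (pa, ra), (pb, rb) in zip(a.scatterers, b.scatterers):
            assert np.array_equal(pa, pb) and np.array_equal(ra, rb)

    def test_margin_regions(self):
        # positive margin: annulus outside the mask at lesion*factor
        ph = make_phantom(small_spec(margin_width=1.5, margin_E_factor=2.0,
                                     margin_mu_factor=3.0))
        ring = (ph.E_map == 15.0)
        assert ring.any() and not (ring & ph.bmode_mask).any()
        assert np.all(ph.mu_map[ring] == 4.5)
        # negative margin: annulus inside the mask at background values
        ph2 = make_phantom(small_spec(margin_width=-1.0))
        inner_ring = ph.bmode_mask & (ph2.E_map == 3.0) & ph2.bmode_mask
        assert inner_ring.any()

    def test_lesion_outside_grid_names_axis(self):
        with pytest.raises(ValueError, match="axial"):
            make_phantom(small_spec(lesion_center=(10.0, 3.0)))
        with pytest.raises(ValueError, match="lateral"):
            make_phantom(small_spec(lesion_center=(2.0, 20.0)))

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            small_spec(lesion_axes=(6.0, 0.0))
        with pytest.raises(ValueError):
            small_spec(margin_width=4.5)   # |margin| >= semi-minor
        with pytest.raises(ValueError):
            small_spec(background_E=-1.0)

    def test_maps_strictly_positive_over_random_specs(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            spec = PhantomSpec(
                grid_shape=(64, 20), axial_spacing=0.625, lateral_spacing=1.0,
                lesion_center=(rng.uniform(8, 12), rng.uniform(15, 25)),
                lesion_axes=(rng.uniform(3, 6), rng.uniform(2, 3)),
                lesion_rotation=rng.uniform(0, 180),
                lesion_E=rng.uniform(0.5, 20), lesion_mu=rng.uniform(0, 5),
                background_E=rng.uniform(0.5, 10),
                background_mu=rng.uniform(0, 3),
                margin_width=rng.uniform(-1.5, 1.5),
                margin_E_factor=rng.uniform(0.2, 3),
                margin_mu_factor=rng.uniform(0.2, 3),
                heterogeneity_cv=rng.uniform(0, 0.5),
                seed=int(rng.integers(2 ** 31)))
            ph = make_phantom(spec)
            assert np.all(ph.E_map > 0)
            assert np.all(ph.mu_map >= 0)

    def test_scatterer_density_supports_speckle(self):
        ph = make_phantom(small_spec())
        # >= 10 scatterers per ~0.25 mm pulse length -> >= 40 per mm
        pos, _ = ph.scatterers[0]
        assert pos.size / ph.spec.axial_extent_mm >= 40


class TestBoundary:
    def test_circle_perimeter_and_area(self):
        spec = small_spec(grid_shape=(512, 40), axial_spacing=0.078125,
                          lesion_axes=(5.0, 5.0))
        ph = make_phantom(spec)
        poly = lesion_boundary(ph)
        assert poly.perimeter == pytest.approx(10 * np.pi, rel=0.01)
        assert poly.area == pytest.approx(np.pi * 25, rel=0.02)

    def test_polygon_area_consistent_with_mask(self):
        # on a grid fine enough that pixel counting itself is reliable
        rng = np.random.default_rng(4)
        for _ in range(20):
            spec = PhantomSpec(grid_shape=(512, 80), axial_spacing=0.078125,
                               lateral_spacing=0.25,
                               lesion_center=(10.0, 20.0),
                               lesion_axes=(rng.uniform(3.5, 7),
                                            rng.uniform(2.8, 3.5)),
                               lesion_rotation=rng.uniform(0, 180), seed=0)
            ph = make_phantom(spec)
            poly = lesion_boundary(ph)
            mask_area = ph.bmode_mask.sum() * 0.078125 * 0.25
            assert poly.area == pytest.approx(mask_area, rel=0.02)

    def test_positive_orientation_and_vertex_count(self):
        poly = lesion_boundary(make_phantom(small_spec()))
        assert len(poly.vertices) >= 256
        assert poly.area > 0     # signed area: consistent orientation

    def test_empty_mask_rejected(self):
        ph = make_phantom(small_spec())
        ph.bmode_mask = np.zeros_like(ph.bmode_mask)
        with pytest.raises(ValueError, match="empty"):
            lesion_boundary(ph)

    def test_csv_roundtrip(self, tmp_path):
        poly = lesion_boundary(make_phantom(small_spec()))
        path = tmp_path / "boundary.csv"
        poly.to_csv(path)
        back = type(poly).from_csv(path)
        np.testing.assert_allclose(back.vertices, poly.vertices, rtol=1e-6)


class TestCohort:
    def test_class_balance_rounding(self):
        lesions = sample_cohort(CohortSpec(n_lesions=20, seed=1))
        labels = [l.label for l in lesions]
        assert labels.count("benign") == 13
        assert labels.count("malignant") == 7

    def test_same_seed_identical(self):
        a = sample_cohort(CohortSpec(n_lesions=10, seed=9))
        b = sample_cohort(CohortSpec(n_lesions=10, seed=9))
        assert [l.label for l in a] == [l.label for l in b]
        pa = make_phantom(a[0].specs[0])
        pb = make_phantom(b[0].specs[0])
        assert np.array_equal(pa.E_map, pb.E_map)

    def test_rotations_swap_apparent_axes(self):
        les = sample_cohort(CohortSpec(n_lesions=2, seed=2,
                                       rotations=(0.0, 90.0)))[0]
        s0, s90 = les.specs
        assert (s90.lesion_rotation - s0.lesion_rotation) % 180 == 90
        # measure physical extents of the two masks
        def extents(spec):
            m = make_phantom(spec).bmode_mask
            rows, cols = np.nonzero(m)
            return (np.ptp(rows) * spec.axial_spacing,
                    np.ptp(cols) * spec.lateral_spacing)
        ax0, lat0 = extents(s0)
        ax90, lat90 = extents(s90)
        assert ax90 == pytest.approx(lat0, abs=2 * DX)
        assert lat90 == pytest.approx(ax0, abs=2 * DX)

    def test_programmed_extent_ratio_by_class(self):
        lesions = sample_cohort(CohortSpec(n_lesions=40, seed=5))
        ben = [l.programmed_ratio for l in lesions if l.label == "benign"]
        mal = [l.programmed_ratio for l in lesions if l.label == "malignant"]
        assert np.median(ben) < 1.0
        assert np.median(mal) > 1.0

    def test_null_mode_has_no_margin_effects(self):
        lesions = sample_cohort(CohortSpec(n_lesions=6, seed=3,
                                           margin_mode="null"))
        assert all(l.specs[0].margin_width == 0 for l in lesions)
        assert all(l.programmed_ratio == 1.0 for l in lesions)

    def test_both_classes_required(self):
        with pytest.raises(ValueError):
            CohortSpec(n_lesions=2, benign_fraction=0.95)


class TestConfoundPair:
    def test_pd_matched_via_ode_oracle(self, seq, schedule, sample_times):
        e1, mu1 = 3.0, 0.6
        e2, mu2 = confound_pair(e1, mu1, seq)
        pd1 = peak_displacement(msd_response_numeric(
            MaterialPoint(e1, mu1), 0.0, schedule, sample_times))
        pd2 = peak_displacement(msd_response_numeric(
            MaterialPoint(e2, mu2), 0.0, schedule, sample_times))
        assert pd2 / pd1 == pytest.approx(1.0, abs=0.01)

    def test_constructed_relations(self, seq):
        e2, mu2 = confound_pair(3.0, 0.6, seq)
        assert e2 == 1.5                        # E2 = E1/2 by convention
        assert mu2 > 0.6                        # more viscous
        assert mu2 / e2 > 0.6 / 3.0             # slower time constant

    def test_no_root_reports_bracket(self, seq):
        # tau1 already ~49 ms: the matching tau2 would exceed the 50 ms cap
        with pytest.raises(ValueError, match="bracket"):
            confound_pair(1.0, 49.0, seq)
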