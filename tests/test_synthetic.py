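"""Generator: determinism, the pixel signal model, and fixture tables."""
import dataclasses
import pickle

import numpy as np
import pytest
from scipy import stats

from fluoromargin import (
    ConfigurationError,
    GeneratorConfig,
    InputError,
    TumorGeometry,
    activation,
    encode_printed_tables,
    generate_cohort,
    generate_transected_specimens,
    render_image,
)
from fluoromargin.evaluation import specimen_tn_ratio

from conftest import CLEAN_CONFIG, SMALL_CONFIG


class TestGenerateCohort:
    def test_seed_determinism_byte_identical(self):
        cfg = dataclasses.replace(SMALL_CONFIG, n_patients=5)
        a = pickle.dumps(generate_cohort(cfg))
        b = pickle.dumps(generate_cohort(cfg))
        assert a == b

    def test_different_seeds_differ(self):
        a = generate_cohort(dataclasses.replace(SMALL_CONFIG, seed=1))
        b = generate_cohort(dataclasses.replace(SMALL_CONFIG, seed=2))
        assert a.patients[0].baseline_true != b.patients[0].baseline_true

    def test_zero_prevalence_means_no_tumor_surfaces(self):
        cfg = dataclasses.replace(SMALL_CONFIG, tumor_prevalence_per_margin=0.0)
        cohort = generate_cohort(cfg)
        assert not any(s.contains_tumor for s in cohort.surfaces)

    def test_tumor_fraction_within_exact_binomial_bounds(self):
        # 40 patients x 12 surfaces; the observed tumor-surface count must
        # fall inside the exact central 99% binomial interval.
        cfg = dataclasses.replace(
            GeneratorConfig(seed=7), n_patients=40, image_size_px=32, halo_sigma_px=2.0
        )
        cohort = generate_cohort(cfg)
        n = len(cohort.surfaces)
        k = sum(s.contains_tumor for s in cohort.surfaces)
        lo = stats.binom.ppf(0.005, n, cfg.tumor_prevalence_per_margin)
        hi = stats.binom.ppf(0.995, n, cfg.tumor_prevalence_per_margin)
        assert lo <= k <= hi

    def test_surface_structure(self, small_cohort):
        seen = set()
        for s in small_cohort.surfaces:
            assert len(s.images) >= 1
            key = (s.patient_id, s.stage, s.orientation)
            assert key not in seen
            seen.add(key)
            for img in s.images:
                assert not np.any(img.truth_tumor_mask & ~img.circular_mask)
                assert 0 < img.contact_factor <= 1
                valid = img.pixels[img.circular_mask]
                assert np.all(valid >= 0) and np.all(np.isfinite(valid))

    @pytest.mark.parametrize(
        "field,value",
        [
            ("tumor_prevalence_per_margin", 1.5),
            ("tn_ratio_mean", 0.9),
            ("image_size_px", 16),
            ("benign_hotspot_rate", -0.1),
            ("n_patients", 0),
        ],
    )
    def test_invalid_config_names_field(self, field, value):
        cfg = dataclasses.replace(SMALL_CONFIG, **{field: value})
        with pytest.raises(ConfigurationError, match=field):
            cfg.validate()


class TestRenderImage:
    def test_identity_no_tumor_no_noise(self, patient):
        cfg = dataclasses.replace(CLEAN_CONFIG, noise_cv=0.0)
        patient.injection_to_imaging_min = 1e7 * cfg.activation_halftime_min
        img = render_image(patient, None, cfg, contact_factor=1.0)
        amp = activation(patient.injection_to_imaging_min, cfg.activation_halftime_min)
        valid = img.pixels[img.circular_mask]
        assert np.all(valid == amp * patient.baseline_true)
        np.testing.assert_allclose(valid, patient.baseline_true, rtol=1e-6)

    def test_peak_to_far_field_ratio_equals_drawn_r(self, patient):
        cfg = dataclasses.replace(CLEAN_CONFIG, image_size_px=96)
        center = (96 - 1) / 2
        img = render_image(
            patient, TumorGeometry(center, center, 8.0), cfg, tn_ratio=3.9
        )
        valid = img.pixels[img.circular_mask]
        np.testing.assert_allclose(np.nanmax(valid) / np.nanmin(valid), 3.9, rtol=1e-12)

    def test_halo_extends_signal_beyond_truth_mask(self, patient):
        cfg = dataclasses.replace(CLEAN_CONFIG, image_size_px=96, halo_sigma_px=4.0)
        center = (96 - 1) / 2
        img = render_image(
            patient, TumorGeometry(center, center, 8.0), cfg, tn_ratio=3.9
        )
        outside = img.circular_mask & ~img.truth_tumor_mask
        assert np.any(img.pixels[outside] > 1.5 * patient.baseline_true)

    def test_contact_and_activation_monotonicity(self, patient):
        cfg = CLEAN_CONFIG
        lo = render_image(patient, None, cfg, contact_factor=0.5)
        hi = render_image(patient, None, cfg, contact_factor=0.9)
        assert np.all(hi.pixels[hi.circular_mask] >= lo.pixels[lo.circular_mask])
        h = cfg.activation_halftime_min
        ts = np.linspace(1.0, 500.0, 100)
        assert np.all(np.diff([activation(t, h) for t in ts]) >= 0)

    def test_geometry_outside_field_rejected(self, patient):
        with pytest.raises(InputError):
            render_image(patient, TumorGeometry(2.0, 2.0, 10.0), CLEAN_CONFIG)

    def test_truth_mask_recorded_before_halo(self, patient):
        cfg = dataclasses.replace(CLEAN_CONFIG, image_size_px=96, halo_sigma_px=5.0)
        center = (96 - 1) / 2
        geometry = TumorGeometry(center, center, 7.0)
        img = render_image(patient, geometry, cfg, tn_ratio=3.9)
        rr, cc = np.ogrid[:96, :96]
        expected = (rr - center) ** 2 + (cc - center) ** 2 <= 7.0**2
        assert np.array_equal(img.truth_tumor_mask, expected & img.circular_mask)


class TestTransectedSpecimens:
    def test_noise_free_ratio_equals_drawn_to_machine_precision(self):
        cfg = dataclasses.replace(CLEAN_CONFIG, image_size_px=128, halo_sigma_px=4.0)
        for spec in generate_transected_specimens(cfg, 5, seed=3):
            np.testing.assert_allclose(
                specimen_tn_ratio(spec), spec.tn_ratio_true, rtol=1e-12
            )

    def test_regions_disjoint_and_nonempty(self):
        for spec in generate_transected_specimens(GeneratorConfig(seed=2), 3, seed=2):
            assert spec.tumor_mask.any() and spec.normal_mask.any()
            assert not np.any(spec.tumor_mask & spec.normal_mask)

    def test_halo_too_wide_for_image_rejected(self):
        cfg = dataclasses.replace(SMALL_CONFIG, image_size_px=32, halo_sigma_px=6.0)
        with pytest.raises(ConfigurationError):
            generate_transected_specimens(cfg, 1, seed=1)


class TestPrintedTables:
    def test_row_counts(self):
        t2, t3 = encode_printed_tables()
        assert len(t2) == 9
        assert len(t3) == 8

    def test_footnote_flags(self):
        _, t3 = encode_printed_tables()
        assert int(t3["footnote_a"].astype(bool).sum()) == 6
        assert int((~t3["footnote_a"].astype(bool)).sum()) == 2
        assert (t3["excised_intraoperatively"] == ~t3["footnote_a"].astype(bool)).all()

    def test_device_negative_counts(self):
        t2, t3 = encode_printed_tables()
        assert int((t2["device_reading"] == "-").sum()) == 3
        assert int((t3["device_reading"] == "-").sum()) == 2
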