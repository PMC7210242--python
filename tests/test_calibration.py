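"""Baseline estimation, ROC construction, and coefficient selection.

The ROC path is checked two independent ways: against an exhaustive
brute-force confusion-matrix scan, and (as an area) against
sklearn.metrics.roc_auc_score.
"""
import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluoromargin import (
    BaselineEstimate,
    CalibrationError,
    InputError,
    RocPoint,
    build_roc,
    estimate_baseline,
    fit_threshold_model,
    generate_cohort,
    normalize_signal,
    render_image,
    select_coefficient,
    surface_sample,
)
from fluoromargin.calibration import TrainingSample
from fluoromargin.pipeline import run_analysis

from conftest import CLEAN_CONFIG, make_constant_image


def brute_force_roc(values, labels):
    """Independent oracle: full confusion-matrix count per candidate."""
    points = []
    for theta in sorted(set(values)):
        tp = sum(1 for v, t in zip(values, labels) if t and v > theta)
        fn = sum(1 for v, t in zip(values, labels) if t and v <= theta)
        tn = sum(1 for v, t in zip(values, labels) if not t and v <= theta)
        fp = sum(1 for v, t in zip(values, labels) if not t and v > theta)
        points.append((theta, tp / (tp + fn), tn / (tn + fp)))
    return points


class TestEstimateBaseline:
    def test_single_constant_image(self):
        assert estimate_baseline([make_constant_image(7.5)]).baseline_hat == 7.5

    def test_median_of_pooled_pixels(self):
        images = [make_constant_image(4.0), make_constant_image(8.0)]
        assert estimate_baseline(images).baseline_hat == 6.0

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            estimate_baseline([])

    def test_recovery_from_noisy_normal_fields(self, patient):
        cfg = dataclasses.replace(CLEAN_CONFIG, noise_cv=0.1)
        patient.injection_to_imaging_min = 1e6
        rng = np.random.default_rng(11)
        images = [render_image(patient, None, cfg, rng=rng) for _ in range(3)]
        estimate = estimate_baseline(images, patient.patient_id)
        assert estimate.baseline_hat == pytest.approx(100.0, rel=0.02)
        assert estimate.n_pixels_used == sum(
            int(i.circular_mask.sum()) for i in images
        )


class TestNormalizeSignal:
    @pytest.mark.parametrize("value,expected", [(10.0, 1.0), (39.0, 3.9), (0.0, 0.0)])
    def test_examples(self, value, expected):
        baseline = BaselineEstimate("P1", 10.0, 100)
        assert normalize_signal(value, baseline) == pytest.approx(expected)


class TestBuildRoc:
    def test_two_sample_case(self):
        points = build_roc([(1.0, False), (2.0, True)])
        at_one = next(p for p in points if p.coefficient == 1.0)
        assert at_one.sensitivity == 1.0 and at_one.specificity == 1.0

    def test_perfect_separation_has_perfect_point(self):
        rng = np.random.default_rng(0)
        samples = [(float(v), False) for v in rng.uniform(0.8, 1.2, 30)]
        samples += [(float(v), True) for v in rng.uniform(3.0, 4.5, 10)]
        points = build_roc(samples)
        assert any(p.sensitivity == 1.0 and p.specificity == 1.0 for p in points)

    def test_single_class_rejected(self):
        with pytest.raises(CalibrationError):
            build_roc([(1.0, True), (2.0, True)])

    def test_matches_brute_force_on_random_samples(self):
        rng = np.random.default_rng(42)
        labels = rng.random(200) < 0.3
        values = np.where(labels, rng.normal(3.5, 1.0, 200), rng.normal(1.5, 1.0, 200))
        points = build_roc(list(zip(values.tolist(), labels.tolist())))
        oracle = brute_force_roc(values.tolist(), labels.tolist())
        assert len(points) == len(oracle)
        for p, (theta, sens, spec) in zip(points, oracle):
            assert p.coefficient == pytest.approx(theta)
            assert p.sensitivity == pytest.approx(sens)
            assert p.specificity == pytest.approx(spec)

    def test_monotone_sensitivity_and_specificity(self):
        rng = np.random.default_rng(3)
        labels = rng.random(150) < 0.4
        values = rng.normal(2.0 + labels, 1.0)
        points = build_roc(list(zip(values.tolist(), labels.tolist())))
        sens = [p.sensitivity for p in points]
        spec = [p.specificity for p in points]
        assert all(a >= b for a, b in zip(sens, sens[1:]))
        assert all(a <= b for a, b in zip(spec, spec[1:]))

    def test_area_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(9)
        labels = rng.random(300) < 0.25
        values = rng.normal(2.0 + 1.5 * labels, 1.0)
        points = build_roc(list(zip(values.tolist(), labels.tolist())))
        # Step curve through (fpr, tpr) vertices, plus the trivial corner.
        fpr = np.array([1.0] + [1.0 - p.specificity for p in points])
        tpr = np.array([1.0] + [p.sensitivity for p in points])
        auc = -np.trapezoid(tpr, fpr)
        assert auc == pytest.approx(roc_auc_score(labels, values), abs=1e-12)

    @given(
        st.lists(
            st.tuples(st.integers(-50, 50), st.booleans()), min_size=2, max_size=60
        ).filter(lambda xs: len({t for _, t in xs}) == 2)
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_property_matches_brute_force(self, pairs):
        values = [float(v) / 7.0 for v, _ in pairs]
        labels = [t for _, t in pairs]
        points = build_roc(list(zip(values, labels)))
        for p, (theta, sens, spec) in zip(points, brute_force_roc(values, labels)):
            assert (p.coefficient, p.sensitivity, p.specificity) == pytest.approx(
                (theta, sens, spec)
            )


class TestSelectCoefficient:
    def test_hand_computed_example(self):
        points = [RocPoint(0.5, 1.0, 0.2), RocPoint(2.0, 0.9, 0.9), RocPoint(4.0, 0.3, 1.0)]
        assert select_coefficient(points) == 2.0

    def test_tie_breaks_to_smaller_coefficient(self):
        points = [RocPoint(1.0, 0.9, 0.8), RocPoint(3.0, 0.8, 0.9), RocPoint(5.0, 0.2, 0.9)]
        assert select_coefficient(points) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(CalibrationError):
            select_coefficient([])

    def test_agrees_with_brute_force_argmax_on_500_samples(self):
        rng = np.random.default_rng(17)
        labels = rng.random(500) < 0.3
        values = rng.normal(2.0 + 1.2 * labels, 0.9)
        pairs = list(zip(values.tolist(), labels.tolist()))
        chosen = select_coefficient(build_roc(pairs))
        oracle = brute_force_roc(values.tolist(), labels.tolist())
        best_j = max(sens + spec - 1.0 for _, sens, spec in oracle)
        best_theta = min(
            theta
            for theta, sens, spec in oracle
            if sens + spec - 1.0 == pytest.approx(best_j)
        )
        assert chosen == pytest.approx(best_theta)


class TestFitThresholdModel:
    def _samples(self):
        return [
            TrainingSample("P1", "m1", "final", 1.0, False),
            TrainingSample("P1", "m2", "final", 3.5, True),
            TrainingSample("P2", "m3", "final", 1.1, False),
        ]

    def test_threshold_is_coefficient_times_baseline(self):
        baselines = {"P1": BaselineEstimate("P1", 10.0, 10)}
        model = fit_threshold_model(
            [TrainingSample("P1", "m", "final", 2.0, True),
             TrainingSample("P1", "m2", "final", 1.0, False)],
            baselines,
            coefficient=1.5,
        )
        assert model.per_patient_threshold["P1"] == pytest.approx(15.0)

    def test_thresholds_scale_with_baselines(self):
        baselines = {
            "P1": BaselineEstimate("P1", 10.0, 10),
            "P2": BaselineEstimate("P2", 20.0, 10),
        }
        model = fit_threshold_model(self._samples(), baselines)
        t = model.per_patient_threshold
        assert t["P2"] == pytest.approx(2.0 * t["P1"])

    def test_missing_baseline_rejected(self):
        with pytest.raises(CalibrationError, match="P2"):
            fit_threshold_model(self._samples(), {"P1": BaselineEstimate("P1", 10.0, 10)})


class TestOnSyntheticCohorts:
    def test_low_noise_coefficient_between_one_and_tn_ratio(self):
        # with any pixel noise the largest tumor-free sample exceeds 1, so
        # the selected coefficient must land strictly inside (1, T:N)
        cfg = dataclasses.replace(
            CLEAN_CONFIG, tn_ratio_sd=0.0, tn_ratio_specimen_cv=0.0, noise_cv=0.02
        )
        result = run_analysis(generate_cohort(cfg))
        assert 1.0 < result.model.coefficient < cfg.tn_ratio_mean

    def test_noise_free_perfect_separation(self, clean_cohort):
        result = run_analysis(clean_cohort)
        assert result.report.sensitivity == 1.0
        assert result.report.specificity == 1.0

    def test_normalization_scale_equivariance(self, clean_cohort):
        """Rescaling one patient's fluorescence scale by k changes nothing
        downstream: normalized samples, ROC, and classifications match."""
        result = run_analysis(clean_cohort)
        pid = clean_cohort.patients[0].patient_id
        k = 7.3
        scaled = generate_cohort(clean_cohort.config)  # fresh identical copy
        for surface in scaled.surfaces:
            if surface.patient_id == pid:
                for img in surface.images:
                    img.pixels = img.pixels * k
                    img.ex_vivo_reference_signal *= k
        for img in scaled.init_scans[pid]:
            img.pixels = img.pixels * k
            img.ex_vivo_reference_signal *= k
        result_scaled = run_analysis(scaled)
        for a, b in zip(result.samples, result_scaled.samples):
            assert a.value == pytest.approx(b.value, rel=1e-12)
        assert result_scaled.model.coefficient == pytest.approx(
            result.model.coefficient, rel=1e-12
        )
        assert [x.call for x in result_scaled.assessments] == [
            x.call for x in result.assessments
        ]

    def test_surface_sample_uses_peak_over_fields(self, clean_cohort):
        baseline = estimate_baseline(
            clean_cohort.init_scans[clean_cohort.patients[0].patient_id], "p"
        )
        surface = clean_cohort.surfaces[0]
        sample = surface_sample(surface, baseline)
        assert sample.margin_id == surface.margin_id
        assert sample.value > 0
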