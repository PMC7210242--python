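"""End-to-end orchestration: simulate -> qc -> calibrate -> detect ->
adjudicate -> evaluate, with all randomness flowing from one seed."""
from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .adjudication import MarginAssessment, adjudicate_reading, margin_status
from .calibration import (
    BaselineEstimate,
    ThresholdModel,
    TrainingSample,
    estimate_baseline,
    fit_threshold_model,
    surface_sample,
)
from .detection import DetectionConfig, DetectionResult, aggregate_margin, classify_image
from .errors import ConfigurationError
from .evaluation import CohortReport, performance_summary
from .io import save_json, save_threshold_model, write_manifest
from .qc import ExclusionRecord, QcConfig, apply_exclusions
from .synthetic import Cohort, GeneratorConfig, generate_cohort

EVAL_MODES = ("resubstitution", "leave_one_patient_out")


@dataclass(frozen=True)
class PipelineConfig:
    generator: GeneratorConfig = GeneratorConfig()
    qc: QcConfig = QcConfig()
    detection: DetectionConfig = DetectionConfig()
    eval_mode: str = "resubstitution"
    apply_qc: bool = True
    coefficient_override: Optional[float] = None
    #: Coefficient used when the training data contains a single class and
    #: no ROC can be built (e.g. a cohort with zero tumor surfaces).
    default_coefficient: float = 2.0
    seed: Optional[int] = None

    def validate(self) -> None:
        self.generator.validate()
        self.qc.validate()
        self.detection.validate()
        if self.eval_mode not in EVAL_MODES:
            raise ConfigurationError(
                f"eval_mode must be one of {EVAL_MODES}, got {self.eval_mode!r}"
            )
        if self.default_coefficient <= 0:
            raise ConfigurationError("default_coefficient must be > 0")

    def resolved_generator(self) -> GeneratorConfig:
        if self.seed is None:
            return self.generator
        return dataclasses.replace(self.generator, seed=self.seed)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        def build(sub_cls, sub: dict):
            names = {f.name for f in dataclasses.fields(sub_cls)}
            unknown = set(sub) - names
            if unknown:
                raise ConfigurationError(
                    f"unknown {sub_cls.__name__} keys: {sorted(unknown)}"
                )
            return sub_cls(**sub)

        data = dict(data)
        kwargs = {}
        for name, sub_cls in (
            ("generator", GeneratorConfig),
            ("qc", QcConfig),
            ("detection", DetectionConfig),
        ):
            if name in data:
                kwargs[name] = build(sub_cls, data.pop(name) or {})
        names = {f.name for f in dataclasses.fields(cls)} - {
            "generator",
            "qc",
            "detection",
        }
        unknown = set(data) - names
        if unknown:
            raise ConfigurationError(f"unknown PipelineConfig keys: {sorted(unknown)}")
        kwargs.update(data)
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class AnalysisResult:
    model: ThresholdModel
    baselines: dict[str, BaselineEstimate]
    samples: list[TrainingSample]
    detections: list[DetectionResult]
    assessments: list[MarginAssessment]
    exclusions: list[ExclusionRecord]
    report: CohortReport
    coefficient_by_patient: dict[str, float] = field(default_factory=dict)


def _fit_or_fallback(samples, baselines, override, fallback):
    if override is not None:
        return fit_threshold_model(samples, baselines, coefficient=override)
    labels = {s.tumor for s in samples}
    if len(labels) < 2:
        return fit_threshold_model(samples, baselines, coefficient=fallback)
    return fit_threshold_model(samples, baselines)


def run_analysis(
    cohort: Cohort,
    qc_config: QcConfig = QcConfig(),
    detection_config: DetectionConfig = DetectionConfig(),
    eval_mode: str = "resubstitution",
    apply_qc: bool = True,
    coefficient_override: Optional[float] = None,
    default_coefficient: float = 2.0,
) -> AnalysisResult:
    """Run qc, calibration, detection and adjudication on a cohort.

    In ``leave_one_patient_out`` mode each patient's surfaces are classified
    with a coefficient selected on all other patients' samples, giving
    held-out performance estimates; the reported model is still the pooled
    (resubstitution) fit.
    """
    if eval_mode not in EVAL_MODES:
        raise ConfigurationError(f"unknown eval_mode {eval_mode!r}")
    if apply_qc:
        eligible, exclusions = apply_exclusions(cohort, qc_config)
    else:
        eligible, exclusions = cohort, []

    baselines = {
        p.patient_id: estimate_baseline(eligible.init_scans[p.patient_id], p.patient_id)
        for p in eligible.patients
    }
    samples = [
        surface_sample(
            surface,
            baselines[surface.patient_id],
            smoothing_px=detection_config.smoothing_px,
        )
        for surface in eligible.surfaces
    ]

    model = _fit_or_fallback(
        samples, baselines, coefficient_override, default_coefficient
    )
    coefficient_by_patient = {p.patient_id: model.coefficient for p in eligible.patients}
    if eval_mode == "leave_one_patient_out" and coefficient_override is None:
        for p in eligible.patients:
            held_out = [s for s in samples if s.patient_id != p.patient_id]
            if len({s.tumor for s in held_out}) < 2:
                continue  # keep pooled coefficient
            from .calibration import build_roc, select_coefficient

            roc = build_roc([(s.value, s.tumor) for s in held_out])
            coefficient_by_patient[p.patient_id] = select_coefficient(roc)

    detections: list[DetectionResult] = []
    assessments: list[MarginAssessment] = []
    for surface in eligible.surfaces:
        b = baselines[surface.patient_id]
        threshold = coefficient_by_patient[surface.patient_id] * b.baseline_hat
        results = [
            classify_image(
                image, threshold, detection_config, baseline=b.baseline_hat
            )
            for image in surface.images
        ]
        detections.extend(results)
        reading = aggregate_margin(results)
        finding = surface.histopath
        call = adjudicate_reading(reading, finding, finding)
        assessments.append(
            MarginAssessment(
                margin_id=surface.margin_id,
                patient_id=surface.patient_id,
                stage=surface.stage,
                device_reading=reading,  # type: ignore[arg-type]
                histopath_margin_status=margin_status(finding),
                surface_contains_tumor=finding.tumor_present_anywhere,
                call=call,
            )
        )

    report = performance_summary(assessments)
    report.n_patients_enrolled = len(cohort.patients)
    report.n_patients_analyzed = len(eligible.patients)
    return AnalysisResult(
        model=model,
        baselines=baselines,
        samples=samples,
        detections=detections,
        assessments=assessments,
        exclusions=exclusions,
        report=report,
        coefficient_by_patient=coefficient_by_patient,
    )


def _config_hash(config: PipelineConfig) -> str:
    canonical = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir: Path) -> CohortReport:
    """Run the full pipeline and write all artifacts under ``out_dir``.

    ``report.json`` is deterministic for a given config and seed; timings
    and provenance go to ``log.txt``.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings: list[tuple[str, float]] = []

    def timed(name, fn):
        start = time.perf_counter()
        value = fn()
        timings.append((name, time.perf_counter() - start))
        return value

    gen_config = config.resolved_generator()
    save_json({"pipeline": config.to_dict(), "resolved_seed": gen_config.seed},
              out_dir / "resolved_config.json")

    cohort = timed("simulate", lambda: generate_cohort(gen_config))
    write_manifest(cohort, out_dir / "manifest.csv")

    result = timed(
        "analyze",
        lambda: run_analysis(
            cohort,
            qc_config=config.qc,
            detection_config=config.detection,
            eval_mode=config.eval_mode,
            apply_qc=config.apply_qc,
            coefficient_override=config.coefficient_override,
            default_coefficient=config.default_coefficient,
        ),
    )

    import pandas as pd

    pd.DataFrame(
        [dataclasses.asdict(r) for r in result.exclusions],
        columns=["entity_id", "level", "reason"],
    ).to_csv(out_dir / "exclusions.csv", index=False)
    save_threshold_model(result.model, out_dir / "threshold_model.json")
    pd.DataFrame([dataclasses.asdict(s) for s in result.samples]).to_csv(
        out_dir / "samples.csv", index=False
    )
    pd.DataFrame(
        [
            {
                "margin_id": d.margin_id,
                "field_index": d.field_index,
                "positive": d.positive,
                "max_normalized_signal": d.max_normalized_signal,
                "suprathreshold_area_px": d.suprathreshold_area_px,
            }
            for d in result.detections
        ]
    ).to_csv(out_dir / "detections.csv", index=False)
    pd.DataFrame([dataclasses.asdict(a) for a in result.assessments]).to_csv(
        out_dir / "assessments.csv", index=False
    )
    save_json(result.report.to_dict(), out_dir / "report.json")

    if result.model.roc_points:
        _write_roc_plot(result.model, out_dir / "roc.png")

    exclusion_counts: dict[str, int] = {}
    for r in result.exclusions:
        exclusion_counts[r.reason] = exclusion_counts.get(r.reason, 0) + 1
    log_lines = [
        f"config_hash: {_config_hash(config)}",
        f"seed: {gen_config.seed}",
        f"exclusions: {json.dumps(exclusion_counts, sort_keys=True)}",
    ] + [f"stage {name}: {seconds:.2f}s" for name, seconds in timings]
    (out_dir / "log.txt").write_text("\n".join(log_lines) + "\n")
    return result.report


def _write_roc_plot(model: ThresholdModel, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fpr = [1.0 - p.specificity for p in model.roc_points]
    tpr = [p.sensitivity for p in model.roc_points]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(fpr, tpr, drawstyle="steps-post", color="C0")
    ax.plot([0, 1], [0, 1], ls="--", color="gray", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"coefficient = {model.coefficient:.3g}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
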