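"""Per-patient threshold calibration on a pooled ROC.

The detection rule is a per-patient absolute threshold obtained by scaling
that patient's normal-tissue baseline by a single pooled coefficient.  The
coefficient is chosen on a receiver operating characteristic built from
per-surface summary samples (maximum baseline-normalized in-field pixel
after 3x3 median smoothing), labeled by ground-truth tumor presence.  The
operating point maximizes Youden's J = sensitivity + specificity - 1, with
ties broken toward the smaller coefficient (higher sensitivity).

Because samples are normalized by the per-session baseline, the whole
calibration is invariant to rescaling any one patient's fluorescence scale.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .errors import CalibrationError, InputError
from .imageops import smoothed_peak
from .synthetic import MarginImage, MarginSurface


@dataclass(frozen=True)
class BaselineEstimate:
    patient_id: str
    baseline_hat: float
    n_pixels_used: int
    method: str = "pooled-median"


@dataclass(frozen=True)
class RocPoint:
    coefficient: float
    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class TrainingSample:
    """One per-surface calibration sample."""

    patient_id: str
    margin_id: str
    stage: str
    value: float  # baseline-normalized smoothed peak signal
    tumor: bool


@dataclass
class ThresholdModel:
    """Pooled normal-tissue-baseline coefficient plus per-patient thresholds."""

    coefficient: float
    per_patient_threshold: dict[str, float]
    roc_points: list[RocPoint] = field(default_factory=list)
    baselines: dict[str, float] = field(default_factory=dict)


def estimate_baseline(
    init_scan_images: Sequence[MarginImage], patient_id: str = ""
) -> BaselineEstimate:
    """Median of valid in-field pixels pooled across initialization scans.

    The median is robust to occasional benign hotspots in the scans, which
    would bias a mean upward.
    """
    if len(init_scan_images) == 0:
        raise InputError("estimate_baseline requires at least one image")
    pooled = np.concatenate(
        [img.pixels[img.circular_mask] for img in init_scan_images]
    )
    pooled = pooled[np.isfinite(pooled)]
    if pooled.size == 0:
        raise InputError("no valid pixels in initialization scans")
    return BaselineEstimate(
        patient_id=patient_id,
        baseline_hat=float(np.median(pooled)),
        n_pixels_used=int(pooled.size),
    )


def normalize_signal(value: float, baseline: BaselineEstimate) -> float:
    """Express a signal in units of the patient's normal-tissue baseline."""
    if baseline.baseline_hat <= 0:
        raise InputError("baseline_hat must be > 0")
    return value / baseline.baseline_hat


def surface_sample(
    surface: MarginSurface, baseline: BaselineEstimate, smoothing_px: int = 3
) -> TrainingSample:
    """Per-surface summary sample: max normalized smoothed peak over fields."""
    peak = max(
        smoothed_peak(img.pixels, img.circular_mask, size=smoothing_px)
        for img in surface.images
    )
    return TrainingSample(
        patient_id=surface.patient_id,
        margin_id=surface.margin_id,
        stage=surface.stage,
        value=normalize_signal(peak, baseline),
        tumor=surface.contains_tumor,
    )


def build_roc(normalized_samples: Iterable[tuple[float, bool]]) -> list[RocPoint]:
    """ROC over candidate coefficients (the sorted unique sample values).

    At each candidate coefficient ``c`` the decision rule is ``value > c``;
    sensitivity and specificity are computed at the sample level.
    """
    pairs = list(normalized_samples)
    values = np.asarray([v for v, _ in pairs], dtype=float)
    labels = np.asarray([bool(t) for _, t in pairs])
    if values.size == 0 or labels.all() or not labels.any():
        raise CalibrationError(
            "ROC requires at least one tumor and one tumor-free sample"
        )
    pos = np.sort(values[labels])
    neg = np.sort(values[~labels])
    coefficients = np.unique(values)
    sens = 1.0 - np.searchsorted(pos, coefficients, side="right") / pos.size
    spec = np.searchsorted(neg, coefficients, side="right") / neg.size
    return [
        RocPoint(float(c), float(se), float(sp))
        for c, se, sp in zip(coefficients, sens, spec)
    ]


def select_coefficient(roc_points: Sequence[RocPoint]) -> float:
    """Coefficient maximizing Youden's J; ties go to the smaller coefficient."""
    if len(roc_points) == 0:
        raise CalibrationError("empty ROC")
    pts = sorted(roc_points, key=lambda p: p.coefficient)
    j = np.asarray([p.sensitivity + p.specificity - 1.0 for p in pts])
    return float(pts[int(np.argmax(j))].coefficient)


def fit_threshold_model(
    training_samples: Sequence[TrainingSample],
    baselines: Mapping[str, BaselineEstimate],
    coefficient: Optional[float] = None,
) -> ThresholdModel:
    """Fit the pooled coefficient and derive per-patient absolute thresholds.

    ``coefficient`` overrides ROC selection (used for sensitivity analyses
    and for degenerate single-class training sets).
    """
    for s in training_samples:
        if s.patient_id not in baselines:
            raise CalibrationError(f"missing baseline for patient {s.patient_id}")
    roc: list[RocPoint] = []
    if coefficient is None:
        roc = build_roc([(s.value, s.tumor) for s in training_samples])
        coefficient = select_coefficient(roc)
    else:
        labels = {s.tumor for s in training_samples}
        if len(labels) == 2:
            roc = build_roc([(s.value, s.tumor) for s in training_samples])
    if coefficient <= 0:
        raise CalibrationError("coefficient must be > 0")
    return ThresholdModel(
        coefficient=float(coefficient),
        per_patient_threshold={
            pid: float(coefficient) * b.baseline_hat for pid, b in baselines.items()
        },
        roc_points=roc,
        baselines={pid: b.baseline_hat for pid, b in baselines.items()},
    )
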