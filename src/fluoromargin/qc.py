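"""Eligibility and quality-control filters applied before calibration.

Patient-level rules: imaging must start at least a minimum interval after
agent injection (signal activation is incomplete earlier), the planned dose
must have been delivered, and cavities with extensive hematoma/necrosis or
lost data are unusable.  Image-level rule: the contact score — the ratio of
the in-vivo cavity-wall signal to the matched ex-vivo specimen signal —
must exceed a cutoff; low ratios indicate poor probe-tissue contact.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Optional

import numpy as np

from .errors import ConfigurationError, InputError
from .synthetic import Cohort, MarginImage, MarginSurface, Patient

EXCLUSION_REASONS = (
    "short_interval",
    "dose_failure",
    "hematoma_necrosis",
    "data_lost",
    "poor_contact",
)


@dataclass(frozen=True)
class QcConfig:
    min_interval_min: float = 101.0
    #: Longest interval observed in practice; informational, not enforced.
    max_interval_min: Optional[float] = None
    contact_cutoff: float = 0.84

    def validate(self) -> None:
        if self.min_interval_min <= 0:
            raise ConfigurationError("min_interval_min must be > 0")
        if not 0.0 < self.contact_cutoff <= 1.0:
            raise ConfigurationError("contact_cutoff must be in (0, 1]")


@dataclass(frozen=True)
class ExclusionRecord:
    entity_id: str
    level: str  # "patient" | "image"
    reason: str

    def __post_init__(self) -> None:
        if self.reason not in EXCLUSION_REASONS:
            raise InputError(f"unknown exclusion reason {self.reason!r}")


def timepoint_eligible(interval_min: float, config: QcConfig) -> bool:
    """True iff the injection-to-imaging interval meets the minimum."""
    if interval_min <= 0:
        raise InputError("interval_min must be > 0")
    return interval_min >= config.min_interval_min


def contact_score(in_vivo_signal: float, ex_vivo_signal: float) -> float:
    """In-vivo / ex-vivo signal ratio; ~1 or greater under good contact."""
    if ex_vivo_signal <= 0:
        raise InputError("ex_vivo_signal must be > 0")
    return in_vivo_signal / ex_vivo_signal


def poor_contact(score: float, cutoff: float) -> bool:
    """Inclusive cutoff rule (score <= cutoff), robust to float round-off
    so that e.g. a ratio of 8.4/10.0 is flagged at a 0.84 cutoff."""
    return score <= cutoff or math.isclose(score, cutoff, rel_tol=1e-9)


def image_contact_score(image: MarginImage) -> float:
    """Contact score of one image (mean in-field signal vs ex-vivo reference)."""
    in_vivo = float(np.nanmean(image.pixels[image.circular_mask]))
    return contact_score(in_vivo, image.ex_vivo_reference_signal)


def patient_exclusions(
    patients: Iterable[Patient], config: QcConfig
) -> list[ExclusionRecord]:
    """Patient-level exclusion records, one reason per excluded patient."""
    records = []
    for p in patients:
        if not timepoint_eligible(p.injection_to_imaging_min, config):
            reason = "short_interval"
        elif not p.dose_ok:
            reason = "dose_failure"
        elif p.hematoma:
            reason = "hematoma_necrosis"
        elif p.data_lost:
            reason = "data_lost"
        else:
            continue
        records.append(ExclusionRecord(p.patient_id, "patient", reason))
    return records


def apply_exclusions(
    cohort: Cohort, config: QcConfig
) -> tuple[Cohort, list[ExclusionRecord]]:
    """Filter a cohort: patient-level rules first, then poor-contact images.

    Records are returned in deterministic order (patients in roster order,
    then images in surface order).  Surfaces whose every image is excluded
    are dropped.  The filter is idempotent.
    """
    config.validate()
    patient_records = patient_exclusions(cohort.patients, config)
    excluded_patients = {r.entity_id for r in patient_records}
    kept_patients = [p for p in cohort.patients if p.patient_id not in excluded_patients]

    image_records: list[ExclusionRecord] = []
    kept_surfaces: list[MarginSurface] = []
    for surface in cohort.surfaces:
        if surface.patient_id in excluded_patients:
            continue
        kept_images = []
        for image in surface.images:
            if poor_contact(image_contact_score(image), config.contact_cutoff):
                image_records.append(
                    ExclusionRecord(image.image_id, "image", "poor_contact")
                )
            else:
                kept_images.append(image)
        if kept_images:
            kept_surfaces.append(replace(surface, images=kept_images))

    eligible = Cohort(
        config=cohort.config,
        patients=kept_patients,
        surfaces=kept_surfaces,
        init_scans={
            pid: scans
            for pid, scans in cohort.init_scans.items()
            if pid not in excluded_patients
        },
        subtype_tn_mean=dict(cohort.subtype_tn_mean),
    )
    return eligible, patient_records + image_records
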