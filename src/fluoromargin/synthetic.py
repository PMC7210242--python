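"""Synthetic cavity-margin cohort generator with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes for an intraoperative protease-activated fluorescence study of
lumpectomy cavity margins:

* a latent per-patient normal-tissue baseline fluorescence ``B_p`` (AFU),
* a tumor-to-normal (T:N) signal ratio ``R`` drawn around a per-histology
  subtype mean (subtype means clustered near 3.9),
* a protease-activation halo: fluorescent signal extends smoothly beyond
  the true tumor border,
* saturating activation kinetics in the injection-to-imaging interval,
* multiplicative attenuation by imperfect probe-tissue contact,
* benign hotspots — small halo-free foci of elevated signal in tumor-free
  tissue, the dominant source of false-positive readings,
* multiplicative lognormal pixel noise.

The rendered pixel model for a field of view is

    S(x) = A(t) * c * B_p * [1 + (R - 1) * K(x)] * (1 + eps(x))

where ``A(t) = t / (t + halftime)`` is the activation curve, ``c`` the
contact factor, ``K`` the tumor indicator extended by a Gaussian halo
(``K = 1`` inside the tumor, decaying outside), and ``eps`` mean-one
multiplicative noise.  The ground-truth tumor mask is recorded before the
halo is applied.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .adjudication import HistopathFinding
from .errors import ConfigurationError, InputError
from .imageops import circular_field_mask

ORIENTATIONS = ("superior", "inferior", "medial", "lateral", "anterior", "posterior")
STAGES = ("intermediate", "final")

SUBTYPES = ("IDC", "ILC", "IC_mixed", "DCIS")
#: Histology mix of the simulated cohort (invasive ductal, lobular, mixed, DCIS).
SUBTYPE_WEIGHTS = (0.55, 0.11, 0.07, 0.27)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    Rates are probabilities in [0, 1]; fluorescence is in arbitrary
    fluorescence units (AFU); lengths are cm or pixels as named.
    """

    n_patients: int = 40
    fields_per_margin: int = 1
    image_size_px: int = 256
    field_diameter_cm: float = 2.6
    #: Mean of the per-subtype T:N ratio distribution.
    tn_ratio_mean: float = 3.9
    #: SD of per-subtype mean T:N ratios (~95% of subtype means in 3.78-4.11).
    tn_ratio_sd: float = 0.07
    #: Specimen-to-specimen lognormal CV of the T:N ratio within a subtype.
    tn_ratio_specimen_cv: float = 0.10
    baseline_mean: float = 100.0
    baseline_cv: float = 0.2
    halo_sigma_px: float = 6.0
    activation_halftime_min: float = 5.0
    noise_cv: float = 0.10
    tumor_prevalence_per_margin: float = 0.03
    benign_hotspot_rate: float = 0.75
    hotspot_ratio_mean: float = 2.8
    hotspot_ratio_cv: float = 0.22
    #: Fraction of benign hotspots that fluoresce as brightly as tumor
    #: (e.g. inflamed biopsy sites); these read positive at any plausible
    #: threshold and are the floor on the false-positive rate.
    hotspot_bright_fraction: float = 0.25
    hotspot_bright_ratio_mean: float = 5.5
    contact_failure_rate: float = 0.05
    #: Lower edge of the contact-factor range for technically adequate scans.
    contact_ok_min: float = 0.85
    #: Lower edge of the contact-factor range for failed scans.
    contact_fail_min: float = 0.45
    #: Measurement noise (CV) of the ex-vivo reference used by the contact score.
    contact_jitter_cv: float = 0.04
    #: Patient-level exclusion rates (imaging started too early after
    #: injection; injection extravasation; hematoma/necrosis; data loss).
    short_interval_rate: float = 0.044
    dose_failure_rate: float = 0.022
    hematoma_rate: float = 0.022
    data_loss_rate: float = 0.022
    seed: int = 0

    def validate(self) -> None:
        rates = (
            "tumor_prevalence_per_margin",
            "benign_hotspot_rate",
            "contact_failure_rate",
            "short_interval_rate",
            "dose_failure_rate",
            "hematoma_rate",
            "data_loss_rate",
        )
        for name in rates:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.n_patients < 1:
            raise ConfigurationError(f"n_patients must be >= 1, got {self.n_patients}")
        if self.fields_per_margin < 1:
            raise ConfigurationError(
                f"fields_per_margin must be >= 1, got {self.fields_per_margin}"
            )
        if self.image_size_px < 32:
            raise ConfigurationError(
                f"image_size_px must be >= 32, got {self.image_size_px}"
            )
        if self.tn_ratio_mean <= 1.0:
            raise ConfigurationError(
                f"tn_ratio_mean must be > 1, got {self.tn_ratio_mean}"
            )
        for name in ("field_diameter_cm", "baseline_mean", "activation_halftime_min"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in (
            "tn_ratio_sd",
            "tn_ratio_specimen_cv",
            "baseline_cv",
            "halo_sigma_px",
            "noise_cv",
            "hotspot_ratio_cv",
            "contact_jitter_cv",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0 < self.contact_fail_min < self.contact_ok_min <= 1.0:
            raise ConfigurationError(
                "require 0 < contact_fail_min < contact_ok_min <= 1"
            )
        if self.hotspot_ratio_mean <= 1.0:
            raise ConfigurationError("hotspot_ratio_mean must be > 1")
        if self.hotspot_bright_ratio_mean <= 1.0:
            raise ConfigurationError("hotspot_bright_ratio_mean must be > 1")
        if not 0.0 <= self.hotspot_bright_fraction <= 1.0:
            raise ConfigurationError("hotspot_bright_fraction must be in [0, 1]")


@dataclass
class Patient:
    patient_id: str
    injection_to_imaging_min: float
    baseline_true: float
    dose_ok: bool = True
    hematoma: bool = False
    data_lost: bool = False
    subtype: str = "IDC"

    def __post_init__(self) -> None:
        if self.injection_to_imaging_min <= 0:
            raise InputError("injection_to_imaging_min must be > 0")


@dataclass(frozen=True)
class TumorGeometry:
    """A circular tumor focus in pixel coordinates."""

    center_row: float
    center_col: float
    radius_px: float


@dataclass(frozen=True)
class Hotspot:
    """A benign halo-free focus of elevated signal."""

    center_row: float
    center_col: float
    radius_px: float
    ratio: float


@dataclass
class MarginImage:
    margin_id: str
    field_index: int
    pixels: np.ndarray
    circular_mask: np.ndarray
    truth_tumor_mask: np.ndarray
    contact_factor: float
    ex_vivo_reference_signal: float

    @property
    def image_id(self) -> str:
        return f"{self.margin_id}:f{self.field_index}"


@dataclass
class MarginSurface:
    margin_id: str
    patient_id: str
    orientation: str
    stage: str
    images: list[MarginImage]
    histopath: Optional[HistopathFinding] = None

    @property
    def contains_tumor(self) -> bool:
        return any(img.truth_tumor_mask.any() for img in self.images)


@dataclass
class TransectedSpecimen:
    """An ex-vivo transected lumpectomy specimen with labeled regions."""

    specimen_id: str
    pixels: np.ndarray
    circular_mask: np.ndarray
    tumor_mask: np.ndarray
    normal_mask: np.ndarray
    subtype: str
    tn_ratio_true: float


@dataclass
class Cohort:
    config: GeneratorConfig
    patients: list[Patient]
    surfaces: list[MarginSurface]
    #: Tumor-free initialization-scan images per patient, used for the
    #: normal-tissue baseline estimate.
    init_scans: dict[str, list[MarginImage]]
    subtype_tn_mean: dict[str, float] = field(default_factory=dict)

    def surfaces_of(self, patient_id: str) -> list[MarginSurface]:
        return [s for s in self.surfaces if s.patient_id == patient_id]


def activation(t_min: float, halftime_min: float) -> float:
    """Saturating activation curve A(t) = t / (t + halftime), -> 1 at plateau."""
    if t_min <= 0:
        raise InputError("injection-to-imaging interval must be > 0")
    return t_min / (t_min + halftime_min)


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative lognormal factors with the given CV."""
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _disk(size: int, row: float, col: float, radius: float) -> np.ndarray:
    rr, cc = np.ogrid[:size, :size]
    return (rr - row) ** 2 + (cc - col) ** 2 <= radius**2


def render_image(
    patient: Patient,
    tumor_geometry: Optional[TumorGeometry],
    config: GeneratorConfig,
    *,
    rng: Optional[np.random.Generator] = None,
    contact_factor: float = 1.0,
    tn_ratio: Optional[float] = None,
    hotspots: Sequence[Hotspot] = (),
    margin_id: str = "margin",
    field_index: int = 0,
) -> MarginImage:
    """Render one field-of-view image for a patient.

    The ground-truth tumor mask is the un-blurred tumor indicator; the halo
    kernel extends signal beyond it without enlarging the truth mask.  With
    noise disabled, full contact and no tumor, every in-field pixel equals
    ``A(t) * contact_factor * B_p`` exactly.
    """
    if not 0.0 < contact_factor <= 1.0:
        raise InputError(f"contact_factor must be in (0, 1], got {contact_factor}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    size = config.image_size_px
    mask = circular_field_mask(size)
    field_radius = (size - 1) / 2.0
    center = (size - 1) / 2.0

    truth = np.zeros((size, size), dtype=bool)
    relative = np.ones((size, size), dtype=float)
    if tumor_geometry is not None:
        g = tumor_geometry
        offset = math.hypot(g.center_row - center, g.center_col - center)
        if offset + g.radius_px > field_radius:
            raise InputError("tumor geometry extends outside the circular field")
        indicator = _disk(size, g.center_row, g.center_col, g.radius_px)
        truth = indicator & mask
        r = config.tn_ratio_mean if tn_ratio is None else tn_ratio
        if config.halo_sigma_px > 0:
            halo = gaussian_filter(
                indicator.astype(float), sigma=config.halo_sigma_px, truncate=4.0
            )
            kernel = np.maximum(halo, indicator)
        else:
            kernel = indicator.astype(float)
        relative = 1.0 + (r - 1.0) * kernel
    for h in hotspots:
        spot = _disk(size, h.center_row, h.center_col, h.radius_px)
        np.maximum(relative, np.where(spot, h.ratio, 1.0), out=relative)

    amp = activation(patient.injection_to_imaging_min, config.activation_halftime_min)
    pixels = amp * contact_factor * patient.baseline_true * relative
    if config.noise_cv > 0:
        pixels = pixels * _lognormal_factors(rng, config.noise_cv, pixels.shape)
    pixels[~mask] = np.nan

    # Matched ex-vivo specimen signal: same tissue imaged with full contact.
    ex_vivo = amp * patient.baseline_true * float(np.mean(relative[mask]))
    if config.contact_jitter_cv > 0:
        ex_vivo *= float(_lognormal_factors(rng, config.contact_jitter_cv, None))

    return MarginImage(
        margin_id=margin_id,
        field_index=field_index,
        pixels=pixels,
        circular_mask=mask,
        truth_tumor_mask=truth,
        contact_factor=contact_factor,
        ex_vivo_reference_signal=float(ex_vivo),
    )


def _draw_patient(rng: np.random.Generator, config: GeneratorConfig, idx: int) -> Patient:
    short = rng.random() < config.short_interval_rate
    interval = rng.uniform(50.0, 100.0) if short else rng.uniform(105.0, 400.0)
    baseline = config.baseline_mean * float(
        _lognormal_factors(rng, config.baseline_cv, None)
    )
    return Patient(
        patient_id=f"P{idx + 1:03d}",
        injection_to_imaging_min=float(interval),
        baseline_true=baseline,
        dose_ok=not rng.random() < config.dose_failure_rate,
        hematoma=rng.random() < config.hematoma_rate,
        data_lost=rng.random() < config.data_loss_rate,
        subtype=str(rng.choice(SUBTYPES, p=SUBTYPE_WEIGHTS)),
    )


def _draw_contact(rng: np.random.Generator, config: GeneratorConfig) -> float:
    if rng.random() < config.contact_failure_rate:
        return float(rng.uniform(config.contact_fail_min, 0.84))
    return float(rng.uniform(config.contact_ok_min, 1.0))


def _draw_tumor_geometry(
    rng: np.random.Generator, config: GeneratorConfig
) -> TumorGeometry:
    size = config.image_size_px
    px_per_cm = size / config.field_diameter_cm
    field_radius = (size - 1) / 2.0
    center = (size - 1) / 2.0
    # Tumor focus radii ~0.15-0.8 cm, matching small residual-disease foci.
    radius_cm = float(np.clip(0.4 * _lognormal_factors(rng, 0.4, None), 0.15, 0.8))
    radius_px = min(radius_cm * px_per_cm, 0.35 * size)
    max_offset = max(field_radius - radius_px - 2.0, 0.0)
    offset = rng.uniform(0.0, max_offset)
    angle = rng.uniform(0.0, 2.0 * math.pi)
    return TumorGeometry(
        center_row=center + offset * math.sin(angle),
        center_col=center + offset * math.cos(angle),
        radius_px=float(radius_px),
    )


def _draw_hotspots(
    rng: np.random.Generator, config: GeneratorConfig
) -> list[Hotspot]:
    if rng.random() >= config.benign_hotspot_rate:
        return []
    size = config.image_size_px
    px_per_cm = size / config.field_diameter_cm
    field_radius = (size - 1) / 2.0
    center = (size - 1) / 2.0
    radius_px = float(rng.uniform(0.08, 0.16) * px_per_cm)
    max_offset = max(field_radius - radius_px - 2.0, 0.0)
    offset = rng.uniform(0.0, max_offset)
    angle = rng.uniform(0.0, 2.0 * math.pi)
    bright = rng.random() < config.hotspot_bright_fraction
    mean = config.hotspot_bright_ratio_mean if bright else config.hotspot_ratio_mean
    ratio = mean * float(_lognormal_factors(rng, config.hotspot_ratio_cv, None))
    return [
        Hotspot(
            center_row=center + offset * math.sin(angle),
            center_col=center + offset * math.cos(angle),
            radius_px=radius_px,
            ratio=max(ratio, 1.0 + 1e-6),
        )
    ]


def _surface_histopath(
    rng: np.random.Generator, patient: Patient, contains_tumor: bool
) -> HistopathFinding:
    if not contains_tumor:
        return HistopathFinding(
            histology="benign", specimen_kind="shave", tumor_present_anywhere=False
        )
    on_ink = bool(rng.random() < 0.5)
    distance = 0.0 if on_ink else float(rng.uniform(0.0, 3.0))
    return HistopathFinding(
        histology=patient.subtype,
        specimen_kind="shave",
        on_ink=on_ink,
        distance_to_ink_mm=distance,
        tumor_present_anywhere=True,
    )


def _draw_subtype_means(
    rng: np.random.Generator, config: GeneratorConfig
) -> dict[str, float]:
    return {
        s: float(rng.normal(config.tn_ratio_mean, config.tn_ratio_sd))
        for s in SUBTYPES
    }


def _draw_specimen_ratio(
    rng: np.random.Generator, config: GeneratorConfig, subtype_mean: float
) -> float:
    r = subtype_mean * float(_lognormal_factors(rng, config.tn_ratio_specimen_cv, None))
    return max(r, 1.05)


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Generate a full synthetic cohort; deterministic for a given seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    subtype_mean = _draw_subtype_means(rng, config)

    patients = [_draw_patient(rng, config, i) for i in range(config.n_patients)]

    init_scans: dict[str, list[MarginImage]] = {}
    surfaces: list[MarginSurface] = []
    for patient in patients:
        init_scans[patient.patient_id] = [
            render_image(
                patient,
                None,
                config,
                rng=rng,
                contact_factor=1.0,
                margin_id=f"{patient.patient_id}-init",
                field_index=k,
            )
            for k in range(2)
        ]
        for stage in STAGES:
            for orientation in ORIENTATIONS:
                margin_id = f"{patient.patient_id}-{stage}-{orientation}"
                contains_tumor = rng.random() < config.tumor_prevalence_per_margin
                images = []
                for k in range(config.fields_per_margin):
                    geometry = None
                    ratio = None
                    if contains_tumor and k == 0:
                        geometry = _draw_tumor_geometry(rng, config)
                        ratio = _draw_specimen_ratio(
                            rng, config, subtype_mean[patient.subtype]
                        )
                    images.append(
                        render_image(
                            patient,
                            geometry,
                            config,
                            rng=rng,
                            contact_factor=_draw_contact(rng, config),
                            tn_ratio=ratio,
                            hotspots=_draw_hotspots(rng, config),
                            margin_id=margin_id,
                            field_index=k,
                        )
                    )
                surfaces.append(
                    MarginSurface(
                        margin_id=margin_id,
                        patient_id=patient.patient_id,
                        orientation=orientation,
                        stage=stage,
                        images=images,
                        histopath=_surface_histopath(rng, patient, contains_tumor),
                    )
                )
    return Cohort(
        config=config,
        patients=patients,
        surfaces=surfaces,
        init_scans=init_scans,
        subtype_tn_mean=subtype_mean,
    )


def generate_transected_specimens(
    config: GeneratorConfig, n_specimens: int, seed: Optional[int] = None
) -> list[TransectedSpecimen]:
    """Generate ex-vivo transected-specimen images with labeled regions.

    Each specimen carries a central tumor region and a surrounding normal
    region separated by a guard band wider than the halo support, so the
    normal-region signal is untouched by halo bleed.
    """
    config.validate()
    if n_specimens < 1:
        raise InputError("n_specimens must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    subtype_mean = _draw_subtype_means(rng, config)
    size = config.image_size_px
    px_per_cm = size / config.field_diameter_cm
    field_radius = (size - 1) / 2.0
    center = (size - 1) / 2.0
    mask = circular_field_mask(size)
    # The separable Gaussian kernel has square support (truncate=4), so the
    # guard band uses the corner distance 4*sigma*sqrt(2).
    guard = 4.0 * config.halo_sigma_px * math.sqrt(2.0) + 2.0

    specimens = []
    for i in range(n_specimens):
        subtype = str(rng.choice(SUBTYPES, p=SUBTYPE_WEIGHTS))
        ratio = _draw_specimen_ratio(rng, config, subtype_mean[subtype])
        radius_px = float(rng.uniform(0.30, 0.55) * px_per_cm)
        if radius_px + guard + 3.0 >= field_radius:
            raise ConfigurationError(
                "image_size_px too small for halo_sigma_px: no normal region "
                "remains outside the halo guard band"
            )
        patient = Patient(
            patient_id=f"S{i + 1:03d}",
            injection_to_imaging_min=float(rng.uniform(105.0, 400.0)),
            baseline_true=config.baseline_mean
            * float(_lognormal_factors(rng, config.baseline_cv, None)),
        )
        image = render_image(
            patient,
            TumorGeometry(center, center, radius_px),
            config,
            rng=rng,
            contact_factor=1.0,
            tn_ratio=ratio,
            margin_id=patient.patient_id,
        )
        rr, cc = np.ogrid[:size, :size]
        dist = np.sqrt((rr - center) ** 2 + (cc - center) ** 2)
        specimens.append(
            TransectedSpecimen(
                specimen_id=patient.patient_id,
                pixels=image.pixels,
                circular_mask=mask,
                tumor_mask=image.truth_tumor_mask,
                normal_mask=mask & (dist > radius_px + guard),
                subtype=subtype,
                tn_ratio_true=ratio,
            )
        )
    return specimens
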