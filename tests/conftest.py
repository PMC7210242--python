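import dataclasses

import numpy as np
import pytest

from fluoromargin import GeneratorConfig, MarginImage, Patient, generate_cohort
from fluoromargin.imageops import circular_field_mask

#: Small, fast configuration used by most unit tests.
SMALL_CONFIG = GeneratorConfig(
    n_patients=6,
    image_size_px=64,
    halo_sigma_px=3.0,
    tumor_prevalence_per_margin=0.15,
    seed=1,
)

#: Noise-free, hotspot-free, full-contact configuration: the idealized
#: regime in which calibration must separate tumor from normal perfectly.
CLEAN_CONFIG = dataclasses.replace(
    SMALL_CONFIG,
    noise_cv=0.0,
    benign_hotspot_rate=0.0,
    contact_failure_rate=0.0,
    contact_jitter_cv=0.0,
    contact_ok_min=0.95,
    short_interval_rate=0.0,
    dose_failure_rate=0.0,
    hematoma_rate=0.0,
    data_loss_rate=0.0,
    tumor_prevalence_per_margin=0.25,
)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(SMALL_CONFIG)


@pytest.fixture(scope="session")
def clean_cohort():
    return generate_cohort(CLEAN_CONFIG)


@pytest.fixture
def patient():
    return Patient(patient_id="P1", injection_to_imaging_min=200.0, baseline_true=100.0)


def make_constant_image(
    value: float,
    size: int = 32,
    margin_id: str = "m",
    field_index: int = 0,
    contact_factor: float = 1.0,
) -> MarginImage:
    """A constant-valued field of view with no tumor."""
    mask = circular_field_mask(size)
    pixels = np.full((size, size), float(value))
    pixels[~mask] = np.nan
    return MarginImage(
        margin_id=margin_id,
        field_index=field_index,
        pixels=pixels,
        circular_mask=np.asarray(mask),
        truth_tumor_mask=np.zeros((size, size), dtype=bool),
        contact_factor=contact_factor,
        ex_vivo_reference_signal=float(value),
    )
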