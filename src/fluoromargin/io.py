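"""File formats: 16-bit grayscale TIFF fields, PNG masks/overlays, CSV
manifests and reports, JSON sidecars and threshold models."""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .calibration import RocPoint, ThresholdModel
from .errors import ParseError
from .imageops import circular_field_mask
from .synthetic import Cohort, MarginImage

_TIFF_MAX = 65000  # headroom below uint16 max to survive round-off


def write_margin_image(directory: Path, image: MarginImage, meta: Optional[dict] = None) -> Path:
    """Write one field as TIFF + truth-mask PNG + JSON sidecar.

    Pixels are quantized to 16-bit with a recorded AFU-per-count scale;
    out-of-field pixels are stored as 0 but remain invalid (the circular
    field is reconstructed from the image size on read).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = f"{image.margin_id}_f{image.field_index}"
    valid = image.pixels[image.circular_mask]
    vmax = float(np.nanmax(valid)) if valid.size else 1.0
    scale = vmax / _TIFF_MAX if vmax > 0 else 1.0
    counts = np.zeros(image.pixels.shape, dtype=np.uint16)
    counts[image.circular_mask] = np.round(valid / scale).astype(np.uint16)
    tiff_path = directory / f"{stem}.tif"
    tifffile.imwrite(tiff_path, counts)
    mask_path = directory / f"{stem}_truth.png"
    iio.imwrite(mask_path, (image.truth_tumor_mask * np.uint8(255)))
    sidecar = {
        "margin_id": image.margin_id,
        "field_index": image.field_index,
        "afu_per_count": scale,
        "contact_factor": image.contact_factor,
        "ex_vivo_reference_signal": image.ex_vivo_reference_signal,
        "truth_mask": mask_path.name,
        "image_size_px": int(image.pixels.shape[0]),
    }
    if meta:
        sidecar.update(meta)
    (directory / f"{stem}.json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return tiff_path


def read_margin_image(tiff_path: Path) -> MarginImage:
    """Read a field written by :func:`write_margin_image`."""
    tiff_path = Path(tiff_path)
    sidecar_path = tiff_path.with_suffix(".json")
    try:
        sidecar = json.loads(sidecar_path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ParseError(f"cannot read sidecar {sidecar_path}: {exc}") from exc
    try:
        counts = tifffile.imread(tiff_path)
    except Exception as exc:
        raise ParseError(f"cannot read TIFF {tiff_path}: {exc}") from exc
    try:
        truth = iio.imread(tiff_path.parent / sidecar["truth_mask"]) > 0
        mask = circular_field_mask(int(sidecar["image_size_px"]))
        pixels = counts.astype(float) * float(sidecar["afu_per_count"])
        pixels[~mask] = np.nan
        return MarginImage(
            margin_id=sidecar["margin_id"],
            field_index=int(sidecar["field_index"]),
            pixels=pixels,
            circular_mask=mask,
            truth_tumor_mask=truth,
            contact_factor=float(sidecar["contact_factor"]),
            ex_vivo_reference_signal=float(sidecar["ex_vivo_reference_signal"]),
        )
    except KeyError as exc:
        raise ParseError(f"sidecar {sidecar_path} missing field {exc}") from exc


def cohort_manifest(cohort: Cohort) -> pd.DataFrame:
    """One row per field of view."""
    rows = []
    for surface in cohort.surfaces:
        patient = next(p for p in cohort.patients if p.patient_id == surface.patient_id)
        for image in surface.images:
            rows.append(
                {
                    "patient_id": surface.patient_id,
                    "margin_id": surface.margin_id,
                    "field_index": image.field_index,
                    "stage": surface.stage,
                    "orientation": surface.orientation,
                    "injection_to_imaging_min": patient.injection_to_imaging_min,
                    "contact_factor": image.contact_factor,
                    "ex_vivo_reference_signal": image.ex_vivo_reference_signal,
                    "tumor_pixels": int(image.truth_tumor_mask.sum()),
                }
            )
    return pd.DataFrame(rows)


def write_manifest(cohort: Cohort, path: Path) -> pd.DataFrame:
    manifest = cohort_manifest(cohort)
    manifest.to_csv(path, index=False)
    return manifest


def read_manifest(path: Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"cannot parse manifest {path}: {exc}") from exc


def save_threshold_model(model: ThresholdModel, path: Path) -> None:
    payload = {
        "coefficient": model.coefficient,
        "per_patient_threshold": model.per_patient_threshold,
        "baselines": model.baselines,
        "roc_points": [dataclasses.asdict(p) for p in model.roc_points],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def load_threshold_model(path: Path) -> ThresholdModel:
    try:
        payload = json.loads(Path(path).read_text())
        return ThresholdModel(
            coefficient=float(payload["coefficient"]),
            per_patient_threshold={
                k: float(v) for k, v in payload["per_patient_threshold"].items()
            },
            roc_points=[RocPoint(**p) for p in payload["roc_points"]],
            baselines={k: float(v) for k, v in payload["baselines"].items()},
        )
    except (OSError, json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"cannot parse threshold model {path}: {exc}") from exc


def save_json(payload: dict, path: Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
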