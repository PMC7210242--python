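"""Histopathology margin status and device-reading adjudication.

Margin status follows the standard clinical rules for breast-conserving
surgery: invasive carcinoma (ductal, lobular, or mixed) renders a margin
positive only when tumor is present on the inked specimen surface, while
pure ductal carcinoma in situ (DCIS) renders a margin positive when disease
lies strictly less than 2 mm from ink.  Device readings are adjudicated
against the tissue actually removed at the imaged site: when a shaved
cavity-margin specimen exists for the site, any tumor found anywhere in the
shave defines ground truth; otherwise the margin status of the outer surface
of the main excised specimen is used.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Literal, Optional

from .errors import AdjudicationError, InputError

INVASIVE_HISTOLOGIES = ("IDC", "ILC", "IC_mixed")
HISTOLOGIES = INVASIVE_HISTOLOGIES + ("DCIS", "benign")

Reading = Literal["positive", "negative"]
Call = Literal["TP", "FP", "TN", "FN"]

#: DCIS margins are positive when disease is strictly closer than this (mm).
DCIS_MARGIN_MM = 2.0


@dataclass
class HistopathFinding:
    """One histopathology result for a specimen associated with a margin site.

    ``secondary`` carries the second component of a mixed finding (for
    example invasive tumor close to ink together with DCIS on ink); margin
    status is positive if either component fires its rule.
    """

    histology: str
    specimen_kind: str = "shave"
    on_ink: bool = False
    distance_to_ink_mm: Optional[float] = None
    tumor_present_anywhere: bool = True
    secondary: Optional["HistopathFinding"] = None

    def __post_init__(self) -> None:
        if self.histology not in HISTOLOGIES:
            raise InputError(f"unknown histology {self.histology!r}")
        if self.histology == "benign" and self.tumor_present_anywhere:
            raise InputError("benign finding cannot have tumor_present_anywhere=True")
        if self.distance_to_ink_mm is not None and self.distance_to_ink_mm < 0:
            raise InputError("distance_to_ink_mm must be >= 0")


def _component_status(finding: HistopathFinding) -> bool:
    if finding.histology == "benign":
        return False
    if finding.on_ink:
        return True
    if finding.distance_to_ink_mm is None:
        raise InputError(
            f"distance_to_ink_mm required for non-benign histology "
            f"{finding.histology!r} not on ink"
        )
    if finding.histology in INVASIVE_HISTOLOGIES:
        # Invasive rule: positive only on ink; the 2-mm band does not apply.
        return False
    return finding.distance_to_ink_mm < DCIS_MARGIN_MM


def margin_status(finding: HistopathFinding) -> Reading:
    """Histopathologic margin status (positive/negative) of a finding."""
    status = _component_status(finding)
    if finding.secondary is not None:
        status = status or _component_status(finding.secondary)
    return "positive" if status else "negative"


def _as_bool_reading(reading: str) -> bool:
    if reading in ("positive", "+"):
        return True
    if reading in ("negative", "-", "–"):
        return False
    raise InputError(f"unrecognized device reading {reading!r}")


def adjudicate_reading(
    device_reading: str,
    shave: Optional[HistopathFinding],
    specimen_surface: HistopathFinding,
) -> Call:
    """Confusion-matrix call for one device reading.

    Ground truth is tumor found anywhere in the shave taken at the site when
    a shave exists, otherwise the margin status of the main-specimen surface.
    """
    device_pos = _as_bool_reading(device_reading)
    if shave is not None:
        truth = shave.tumor_present_anywhere
    else:
        truth = margin_status(specimen_surface) == "positive"
    if device_pos:
        return "TP" if truth else "FP"
    return "FN" if truth else "TN"


Outcome = Literal[
    "spared_reoperation",
    "reoperation_required",
    "no_action_needed",
    "correctly_predicted_clear",
]


def clinical_outcome(
    device_reading: str,
    excised_intraoperatively: bool,
    tumor_found_at_reexcision: bool,
) -> Outcome:
    """Clinical outcome for one positive final margin.

    A patient whose surgeon excised additional tissue at the signal site
    during the index operation was spared a second surgery.  A device-positive
    final margin left unexcised mandated reoperation.  A device-negative final
    margin whose later re-excision found only benign tissue was a correct
    prediction that no residual tumor remained.
    """
    device_pos = _as_bool_reading(device_reading)
    if excised_intraoperatively:
        if not device_pos:
            raise AdjudicationError(
                "tissue excised intraoperatively at a device-negative site"
            )
        return "spared_reoperation"
    if device_pos:
        return "reoperation_required"
    if tumor_found_at_reexcision:
        raise AdjudicationError(
            "device-negative final margin with tumor at re-excision has no "
            "defined outcome"
        )
    return "correctly_predicted_clear"


@dataclass
class MarginAssessment:
    """Adjudicated assessment of one cavity margin surface."""

    margin_id: str
    device_reading: Reading
    histopath_margin_status: Reading
    surface_contains_tumor: bool
    call: Call
    patient_id: str = ""
    stage: str = ""
    excised_intraoperatively: bool = False
    outcome: Optional[Outcome] = None


# ---------------------------------------------------------------------------
# Parsing of printed margin-finding strings ("IDC < 1 mm from ink, DCIS on ink")

_DISTANCE_CLASSES = {
    "on ink": (True, 0.0),
    "< 1 mm from ink": (False, 0.5),
    "< 2 mm from ink": (False, 1.0),
    "> 2 mm from ink": (False, 3.0),
}
_HISTOLOGY_ALIASES = {"IC": "IC_mixed", "IDC": "IDC", "ILC": "ILC", "DCIS": "DCIS"}
_COMPONENT_RE = re.compile(
    r"^(IC|IDC|ILC|DCIS)\s+(on ink|< 1 mm from ink|< 2 mm from ink|> 2 mm from ink)$"
)


def parse_finding(
    text: str,
    specimen_kind: str = "shave",
    tumor_present_anywhere: Optional[bool] = None,
) -> HistopathFinding:
    """Parse a printed margin finding into a structured :class:`HistopathFinding`.

    Distance classes are encoded by class representatives (0.5 mm for
    "< 1 mm", 1.0 mm for "< 2 mm", 3.0 mm for "> 2 mm"); each representative
    classifies identically to every member of its class under the margin
    rules, so status is preserved.
    """
    text = text.strip()
    if text.lower() == "benign":
        return HistopathFinding(
            histology="benign",
            specimen_kind=specimen_kind,
            tumor_present_anywhere=False,
        )
    components = []
    for part in text.split(", "):
        m = _COMPONENT_RE.match(part.strip())
        if m is None:
            raise InputError(f"cannot parse margin finding component {part!r}")
        on_ink, distance = _DISTANCE_CLASSES[m.group(2)]
        components.append(
            HistopathFinding(
                histology=_HISTOLOGY_ALIASES[m.group(1)],
                specimen_kind=specimen_kind,
                on_ink=on_ink,
                distance_to_ink_mm=distance,
                tumor_present_anywhere=(
                    True if tumor_present_anywhere is None else tumor_present_anywhere
                ),
            )
        )
    finding = components[0]
    if len(components) == 2:
        finding.secondary = components[1]
    elif len(components) > 2:
        raise InputError(f"more than two components in finding {text!r}")
    return finding
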