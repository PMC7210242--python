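"""Packaged clinical accounting tables.

Two small CSV fixtures hand-encode the published per-margin device readings
of the feasibility cohort: the nine histopathology-positive intermediate
cavity margins (with their device readings) and the eight positive final
lumpectomy margins (with device reading, whether additional tissue was
taken at the site, and the histology of that tissue).  ``footnote_a`` marks
final margins where the surgeon did not excise additional tissue during the
index operation, so the listed histology comes from a later re-excision.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .errors import ParseError

_T2_COLUMNS = ["histology", "device_reading"]
_T3_COLUMNS = [
    "surface_histology",
    "device_reading",
    "tumor_found",
    "reexcision_histology",
    "footnote_a",
]


def _read_fixture(name: str, columns: list[str]) -> pd.DataFrame:
    ref = resources.files("fluoromargin.fixtures").joinpath(name)
    with resources.as_file(ref) as path:
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # pragma: no cover - defensive
            raise ParseError(f"cannot parse fixture {name}: {exc}") from exc
    if list(df.columns) != columns:
        raise ParseError(f"fixture {name} has columns {list(df.columns)}, expected {columns}")
    return df


def encode_printed_tables() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return the intermediate-margin and final-margin fixture tables.

    The final-margin table gains a derived boolean column
    ``excised_intraoperatively`` (the complement of ``footnote_a``).
    """
    t2 = _read_fixture("table2_intermediate_margins.csv", _T2_COLUMNS)
    t3 = _read_fixture("table3_final_margins.csv", _T3_COLUMNS)
    t3 = t3.assign(excised_intraoperatively=~t3["footnote_a"].astype(bool))
    return t2, t3
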