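"""Shared fixtures: small compound universes and the packaged networks."""

from __future__ import annotations

import math

import pytest

from gapless.chem_core import CompoundRecord, parse_formula
from gapless.fba import MediaSpec


@pytest.fixture(scope="session")
def small_compounds() -> dict[str, CompoundRecord]:
    """A hand-picked compound index used across balance tests."""
    table = {
        "C00031": ("C6H12O6", 0),  # glucose
        "C00469": ("C2H6O", 0),  # ethanol
        "C00011": ("CO2", 0),  # carbon dioxide
        "C00001": ("H2O", 0),  # water
        "C00084": ("C2H4O", 0),  # acetaldehyde
        "C00033": ("C2H4O2", 0),  # acetate
        "C00022": ("C3H4O3", 0),  # pyruvate
        "C00186": ("C3H6O3", 0),  # lactate
        "C00116": ("C3H8O3", 0),  # glycerol
        "C00080": ("H", 1),  # proton
        "PENTOSE": ("C5H10O5", 0),
        "KETENE": ("C2H2O", 0),
    }
    return {
        cid: CompoundRecord(cid, parse_formula(f), charge)
        for cid, (f, charge) in table.items()
    }


@pytest.fixture(scope="session")
def valine_media() -> MediaSpec:
    """Glucose at 10 units; nitrogen, water, oxygen unlimited."""
    return MediaSpec(
        {
            "C00031": 10.0,
            "C00014": math.inf,
            "C00001": math.inf,
            "C00007": math.inf,
        }
    )
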