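"""Lab panel configuration: which tests are analysed, which first-day
extreme counts as "worst" for each, and the hospital reference interval.

The panel is configuration, not code: :func:`load_panel` reads it from a
YAML/JSON mapping, and two built-in panels are provided — the full adult ICU
panel with typical hospital reference intervals, and a smaller demo panel
matching the synthetic cohort generator's default analytes.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .exceptions import ConfigurationError
from .reference import LabSpec, ReferenceInterval

__all__ = ["default_panel", "demo_panel", "load_panel", "panel_to_mapping"]

MIN = ("minimum",)
MAX = ("maximum",)
BOTH = ("minimum", "maximum")

# Typical adult hospital reference intervals; the lactate interval of
# 0.5-2.0 mmol/L is the conventional venous range.  Every entry is
# overridable through a panel config file.
_DEFAULT_PANEL = [
    ("albumin", "Albumin", "g/dL", MIN, 3.5, 5.0, True),
    ("ionized_calcium", "Ionized calcium", "mmol/L", MIN, 1.14, 1.30, True),
    ("hemoglobin", "Hemoglobin", "g/dL", MIN, 12.0, 16.0, True),
    ("platelets", "Platelet count", "10^3/uL", MIN, 150.0, 400.0, True),
    ("lactate", "Lactate", "mmol/L", MAX, 0.5, 2.0, True),
    ("bicarbonate", "Bicarbonate", "mEq/L", BOTH, 22.0, 32.0, True),
    ("bun", "Blood urea nitrogen", "mg/dL", BOTH, 6.0, 20.0, True),
    ("creatinine", "Creatinine", "mg/dL", BOTH, 0.4, 1.1, True),
    ("calcium", "Calcium", "mg/dL", BOTH, 8.4, 10.3, True),
    ("magnesium", "Magnesium", "mEq/L", BOTH, 1.6, 2.6, True),
    ("phosphate", "Phosphate", "mg/dL", BOTH, 2.7, 4.5, True),
    ("potassium", "Potassium", "mEq/L", BOTH, 3.3, 5.1, True),
    ("sodium", "Sodium", "mEq/L", BOTH, 133.0, 145.0, False),
    ("glucose", "Glucose", "mg/dL", BOTH, 70.0, 105.0, True),
    ("wbc", "White blood cell count", "10^3/uL", BOTH, 4.5, 11.0, True),
    ("bilirubin", "Bilirubin", "mg/dL", MAX, 0.0, 1.5, True),
]

_DEMO_PANEL_IDS = {
    "albumin",
    "lactate",
    "hemoglobin",
    "sodium",
    "creatinine",
    "glucose",
}


def _make(row) -> LabSpec:
    test_id, name, units, directions, lo, hi, nonneg = row
    return LabSpec(
        test_id=test_id,
        name=name,
        units=units,
        directions=directions,
        reference=ReferenceInterval(lo, hi),
        nonnegative=nonneg,
    )


def default_panel() -> list[LabSpec]:
    """Full adult ICU lab panel: minimum-only for albumin, ionized calcium,
    hemoglobin and platelets; maximum-only for lactate and bilirubin; both
    directions for the remaining chemistries and counts."""
    return [_make(row) for row in _DEFAULT_PANEL]


def demo_panel() -> list[LabSpec]:
    """Six-analyte subset aligned with the synthetic generator defaults."""
    return [_make(row) for row in _DEFAULT_PANEL if row[0] in _DEMO_PANEL_IDS]


def load_panel(source) -> list[LabSpec]:
    """Build a panel from a YAML/JSON file path or an already-parsed mapping.

    Expected shape::

        panel:
          - test_id: lactate
            name: Lactate
            units: mmol/L
            directions: [maximum]
            nonnegative: true
            reference: {lower: 0.5, upper: 2.0}
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            source = yaml.safe_load(fh)
    if isinstance(source, dict) and "panel" in source:
        entries = source["panel"]
    else:
        entries = source
    if not isinstance(entries, list) or not entries:
        raise ConfigurationError("panel config must contain a non-empty 'panel' list")
    panel = []
    seen: set[str] = set()
    for entry in entries:
        try:
            ref = entry["reference"]
            spec = LabSpec(
                test_id=entry["test_id"],
                name=entry.get("name", ""),
                units=entry.get("units", ""),
                directions=tuple(entry.get("directions", BOTH)),
                reference=ReferenceInterval(
                    float(ref["lower"]),
                    float(ref["upper"]),
                    float(ref.get("coverage", 0.95)),
                ),
                nonnegative=bool(entry.get("nonnegative", False)),
            )
        except (KeyError, TypeError) as exc:
            raise ConfigurationError(f"malformed panel entry {entry!r}: {exc}") from exc
        if spec.test_id in seen:
            raise ConfigurationError(f"duplicate panel test_id {spec.test_id!r}")
        seen.add(spec.test_id)
        panel.append(spec)
    return panel


def panel_to_mapping(panel: list[LabSpec]) -> dict:
    """Serialize a panel back to the :func:`load_panel` mapping shape."""
    return {
        "panel": [
            {
                "test_id": s.test_id,
                "name": s.name,
                "units": s.units,
                "directions": list(s.directions),
                "nonnegative": s.nonnegative,
                "reference": {
                    "lower": s.reference.lower,
                    "upper": s.reference.upper,
                    "coverage": s.reference.coverage,
                },
            }
            for s in panel
        ]
    }
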