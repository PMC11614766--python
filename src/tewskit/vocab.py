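"""Controlled variable vocabulary, canonical units, and default clinical bounds.

Every raw observation carries a ``variable`` name drawn from this vocabulary and a
value expressed in the canonical unit declared here.  Unit conversion is the
responsibility of the upstream adapter that produces the input tables; the library
validates units and rejects mismatches rather than converting.
"""

from __future__ import annotations

# Variable classes drive per-class imputation and aggregation rules.
VITALS = ("heart_rate", "sbp", "dbp", "map", "temperature")
LABS = ("lactate", "creatinine", "bilirubin", "platelets", "pao2", "fio2",
        "arterial_ph")
GCS_COMPONENTS = ("gcs_eye", "gcs_motor", "gcs_verbal")
BODY = ("height", "weight")
VOLUMES = ("urine_out",)          # summed per hourly bin
IRRIGANTS = ("irrigant_in", "irrigant_out")  # consumed by urine correction

#: Variables that receive summary statistics (mean/median/max/min), slopes and
#: presence flags in the hourly feature matrix.
SUMMARY_VARIABLES = VITALS + LABS + GCS_COMPONENTS + BODY
#: Variables aggregated as per-hour sums.
SUM_VARIABLES = VOLUMES

VOCABULARY = SUMMARY_VARIABLES + SUM_VARIABLES + IRRIGANTS

#: Intervention kinds carried as per-hour activity flags (no derived features).
INTERVENTION_KINDS = ("vasopressor", "fluid", "antibiotic", "ventilation")

CANONICAL_UNITS = {
    "heart_rate": "bpm",
    "sbp": "mmHg",
    "dbp": "mmHg",
    "map": "mmHg",
    "temperature": "C",
    "lactate": "mmol/L",
    "creatinine": "mg/dL",
    "bilirubin": "mg/dL",
    "platelets": "K/uL",
    "pao2": "mmHg",
    "fio2": "fraction",
    "arterial_ph": "pH",
    "gcs_eye": "points",
    "gcs_motor": "points",
    "gcs_verbal": "points",
    "urine_out": "mL",
    "irrigant_in": "mL",
    "irrigant_out": "mL",
    "height": "cm",
    "weight": "kg",
}

# Clinician-plausible physiological plausibility bounds in canonical units.
# Heart rate 0-300 bpm is the published example; the remainder are defaults a
# deployment overrides from its own criteria file.
DEFAULT_OUTLIER_CRITERIA = {
    "heart_rate": (0.0, 300.0),
    "sbp": (0.0, 300.0),
    "dbp": (0.0, 250.0),
    "map": (0.0, 250.0),
    "temperature": (25.0, 45.0),
    "lactate": (0.0, 30.0),
    "creatinine": (0.0, 40.0),
    "bilirubin": (0.0, 80.0),
    "platelets": (0.0, 2000.0),
    "pao2": (0.0, 700.0),
    "fio2": (0.21, 1.0),
    "arterial_ph": (6.5, 8.0),
    "gcs_eye": (1.0, 4.0),
    "gcs_motor": (1.0, 6.0),
    "gcs_verbal": (1.0, 5.0),
    "urine_out": (0.0, 5000.0),
    "irrigant_in": (0.0, 10000.0),
    "irrigant_out": (0.0, 10000.0),
    "height": (50.0, 260.0),
    "weight": (20.0, 400.0),
}

#: Variables a stay must have recorded at least once to support Sepsis-3
#: annotation.  GCS counts as present when any of its components is recorded.
REQUIRED_VARIABLES = ("sbp", "dbp", "pao2", "fio2", "gcs", "bilirubin",
                      "platelets", "creatinine", "lactate")


def variable_class(variable: str) -> str:
    """Return the imputation/aggregation class of a vocabulary variable."""
    if variable in VITALS or variable in BODY:
        return "interpolate"
    if variable in LABS or variable in GCS_COMPONENTS:
        return "fill"
    if variable in SUM_VARIABLES:
        return "sum"
    if variable in IRRIGANTS:
        return "irrigant"
    raise KeyError(f"unknown variable {variable!r}")
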