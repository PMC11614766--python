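import numpy as np
import pandas as pd
import pytest

from tewskit import vocab
from tewskit.cohort import annotate_cohort, episodes_frame
from tewskit.preprocess import build_feature_matrix, feature_columns
from tewskit.synthcohort import (DEFAULT_INFECTION_CODES,
                                 SyntheticCohortParams, generate_cohort)


def make_stay_matrix(n_hours, stay_id="S1", **columns) -> pd.DataFrame:
    """Single-stay hourly matrix with physiologically normal defaults.

    Keyword arguments override columns (scalar or length-n array), using the
    short variable name for the hourly mean (e.g. ``lactate=...`` sets
    ``lactate__mean``).
    """
    defaults = {
        "heart_rate__mean": 80.0, "sbp__mean": 120.0, "dbp__mean": 65.0,
        "map__mean": 85.0, "temperature__mean": 37.0, "lactate__mean": 1.0,
        "creatinine__mean": 0.9, "bilirubin__mean": 0.8,
        "platelets__mean": 250.0, "pao2__mean": 95.0, "fio2__mean": 0.21,
        "arterial_ph__mean": 7.4, "gcs_eye__mean": 4.0, "gcs_motor__mean": 6.0,
        "gcs_verbal__mean": 5.0, "urine_out__sum": 60.0,
        "vasopressor__active": 0, "fluid__active": 0, "antibiotic__active": 0,
        "ventilation__active": 0, "vasopressor__rate": 0.0,
    }
    index = pd.MultiIndex.from_product([[stay_id], range(n_hours)],
                                       names=["stay_id", "hour"])
    frame = pd.DataFrame(defaults, index=index)
    for key, val in columns.items():
        col = key if "__" in key else (
            f"{key}__sum" if key in vocab.SUM_VARIABLES else f"{key}__mean")
        frame[col] = val
    return frame


@pytest.fixture(scope="session")
def small_tables():
    """A compact synthetic cohort shared across tests (deterministic)."""
    params = SyntheticCohortParams(n_stays=60, seed=11, effect_size=2.0)
    return generate_cohort(params)


@pytest.fixture(scope="session")
def small_cohort(small_tables):
    obs, interv, stays, truth = small_tables
    matrix, log = build_feature_matrix(obs, interv, stays)
    annotations = annotate_cohort(matrix, obs, interv, stays,
                                  DEFAULT_INFECTION_CODES)
    episodes = episodes_frame(annotations)
    return {
        "obs": obs, "interv": interv, "stays": stays, "truth": truth,
        "matrix": matrix, "log": log, "annotations": annotations,
        "episodes": episodes,
        "features": feature_columns(matrix),
    }
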