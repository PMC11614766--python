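"""Sepsis-3 style cohort annotation.

Per stay the module determines:

* suspected infection — antibiotics given AND a blood culture drawn AND an
  infection-related diagnosis code issued (conjunction of all three),
* sepsis onset — the first hour the total SOFA score reaches 2 or more, defined
  only for stays with suspected infection,
* septic-shock episodes — maximal runs of hours in which the (imputed) lactate
  is at least 2 mmol/L while a vasopressor is active, gated to hours at or
  after sepsis onset,
* cohort exclusions — missing required variables, no sepsis, or shock (on the
  ungated hour set) strictly before sepsis onset,
* the first hour of vasopressor + fluid co-administration (treatment start).

SOFA subscores follow the consensus thresholds for the six organ systems; the
urine-output criterion uses rolling 24-hour totals where a full day of history
exists, otherwise the creatinine tier stands alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .vocab import GCS_COMPONENTS, REQUIRED_VARIABLES

LACTATE_SHOCK_THRESHOLD = 2.0  # mmol/L
SOFA_SEPSIS_THRESHOLD = 2

EXCLUSION_REASONS = ("missing_required_variables", "no_sepsis",
                     "shock_before_sepsis", "none")


@dataclass
class ShockEpisode:
    stay_id: object
    onset_hour: int
    end_hour: int
    is_first: bool = False

    def __post_init__(self):
        if self.onset_hour > self.end_hour:
            raise ValueError("episode onset after end")


@dataclass
class StayAnnotation:
    stay_id: object
    suspected_infection: bool = False
    sepsis_onset_hour: int | None = None
    episodes: list[ShockEpisode] = field(default_factory=list)
    excluded: bool = False
    reason: str = "none"
    intervention_start_hour: int | None = None
    n_hours: int = 0

    @property
    def has_shock(self) -> bool:
        return not self.excluded and len(self.episodes) > 0


# ---------------------------------------------------------------------------
# eligibility
# ---------------------------------------------------------------------------

def check_required_variables(observations: pd.DataFrame) -> bool:
    """True iff every variable needed for Sepsis-3 annotation has >=1 record.

    GCS counts as present when any of its three components was charted.
    """
    present = set(observations["variable"].unique())
    for var in REQUIRED_VARIABLES:
        if var == "gcs":
            if not present & set(GCS_COMPONENTS):
                return False
        elif var not in present:
            return False
    return True


def detect_suspected_infection(has_antibiotics: bool,
                               culture_times: Sequence[float],
                               diagnosis_codes: Sequence[str],
                               infection_codes: Sequence[str]) -> bool:
    """Conjunction of antibiotics given, culture drawn and infection code issued.

    Code matching is prefix-based on the configured code set.
    """
    codes = [str(c).strip() for c in infection_codes if str(c).strip()]
    if not codes:
        raise ConfigurationError("infection code set is empty")
    has_culture = len(culture_times) > 0
    has_code = any(str(d).strip().startswith(tuple(codes))
                   for d in diagnosis_codes)
    return bool(has_antibiotics and has_culture and has_code)


# ---------------------------------------------------------------------------
# SOFA
# ---------------------------------------------------------------------------

def _respiration_score(pf_ratio: np.ndarray, ventilated: np.ndarray) -> np.ndarray:
    s = np.zeros(len(pf_ratio), dtype=np.int8)
    s[pf_ratio < 400] = 1
    s[pf_ratio < 300] = 2
    s[(pf_ratio < 200) & ventilated] = 3
    s[(pf_ratio < 100) & ventilated] = 4
    return s


def _coagulation_score(platelets: np.ndarray) -> np.ndarray:
    s = np.zeros(len(platelets), dtype=np.int8)
    s[platelets < 150] = 1
    s[platelets < 100] = 2
    s[platelets < 50] = 3
    s[platelets < 20] = 4
    return s


def _liver_score(bilirubin: np.ndarray) -> np.ndarray:
    s = np.zeros(len(bilirubin), dtype=np.int8)
    s[bilirubin >= 1.2] = 1
    s[bilirubin >= 2.0] = 2
    s[bilirubin >= 6.0] = 3
    s[bilirubin >= 12.0] = 4
    return s


def _cardiovascular_score(mean_ap: np.ndarray, vaso_active: np.ndarray,
                          vaso_rate: np.ndarray) -> np.ndarray:
    """MAP and vasopressor support.

    Dose rates are interpreted as norepinephrine-equivalent ug/kg/min:
    <=0.1 scores 3, >0.1 scores 4.  A vasopressor with no recorded rate maps to
    the minimum vasopressor tier (2).
    """
    s = np.zeros(len(mean_ap), dtype=np.int8)
    s[mean_ap < 70] = 1
    on = vaso_active.astype(bool)
    s[on] = 2
    s[on & (vaso_rate > 0)] = 3
    s[on & (vaso_rate > 0.1)] = 4
    return s


def _cns_score(gcs_total: np.ndarray) -> np.ndarray:
    s = np.zeros(len(gcs_total), dtype=np.int8)
    s[gcs_total <= 14] = 1
    s[gcs_total <= 12] = 2
    s[gcs_total <= 9] = 3
    s[gcs_total <= 5] = 4
    return s


def _renal_score(creatinine: np.ndarray, urine_24h: np.ndarray | None
                 ) -> np.ndarray:
    s = np.zeros(len(creatinine), dtype=np.int8)
    s[creatinine >= 1.2] = 1
    s[creatinine >= 2.0] = 2
    s[creatinine >= 3.5] = 3
    s[creatinine >= 5.0] = 4
    if urine_24h is not None:
        u = np.asarray(urine_24h, dtype=float)
        have = ~np.isnan(u)
        s = np.maximum(s, np.where(have & (u < 500), 3, 0).astype(np.int8))
        s = np.maximum(s, np.where(have & (u < 200), 4, 0).astype(np.int8))
    return s


def compute_sofa(stay_matrix: pd.DataFrame) -> pd.DataFrame:
    """Hourly SOFA panel (six subscores and their total) for one stay.

    ``stay_matrix`` is the imputed hourly feature matrix of a single stay,
    indexed by hour.  Urine totals use a rolling 24-hour sum once a full day of
    history is available.
    """
    m = stay_matrix
    n = len(m)
    col = lambda c, default=0.0: (m[c].to_numpy(dtype=float)
                                  if c in m.columns
                                  else np.full(n, default))

    fio2 = np.clip(col("fio2__mean", 0.21), 0.21, None)
    pf = np.where(fio2 > 0, col("pao2__mean", 500.0) / fio2, np.inf)
    vent = col("ventilation__active").astype(bool)

    map_vals = col("map__mean", np.nan)
    if np.isnan(map_vals).any():
        # derive MAP from systolic/diastolic where it was not charted
        derived = (col("sbp__mean", 90.0) + 2.0 * col("dbp__mean", 60.0)) / 3.0
        map_vals = np.where(np.isnan(map_vals), derived, map_vals)

    gcs_total = sum(col(f"{c}__mean", 0.0) for c in GCS_COMPONENTS)
    # a stay with no GCS charted at all imputes to 0; treat as normal (15)
    gcs_total = np.where(gcs_total <= 0, 15.0, gcs_total)

    urine_24h = None
    if "urine_out__sum" in m.columns:
        roll = (pd.Series(col("urine_out__sum"))
                .rolling(window=24, min_periods=24).sum())
        urine_24h = roll.to_numpy()

    panel = pd.DataFrame({
        "respiration": _respiration_score(pf, vent),
        "coagulation": _coagulation_score(col("platelets__mean", 300.0)),
        "liver": _liver_score(col("bilirubin__mean", 0.5)),
        "cardiovascular": _cardiovascular_score(
            map_vals, col("vasopressor__active"), col("vasopressor__rate")),
        "cns": _cns_score(gcs_total),
        "renal": _renal_score(col("creatinine__mean", 0.8), urine_24h),
    }, index=m.index)
    panel["total"] = panel.sum(axis=1)
    return panel


def detect_sepsis_onset(sofa: pd.DataFrame, suspected: bool) -> int | None:
    """First hour total SOFA >= 2, or None; None whenever not suspected."""
    if not suspected:
        return None
    hit = sofa.index[sofa["total"] >= SOFA_SEPSIS_THRESHOLD]
    return int(hit[0]) if len(hit) else None


# ---------------------------------------------------------------------------
# shock episodes
# ---------------------------------------------------------------------------

def in_shock_hours(stay_matrix: pd.DataFrame,
                   lactate_threshold: float = LACTATE_SHOCK_THRESHOLD
                   ) -> np.ndarray:
    """Boolean per-hour vector: imputed lactate >= threshold AND vasopressor on."""
    lact = stay_matrix.get("lactate__mean")
    vaso = stay_matrix.get("vasopressor__active")
    if lact is None or vaso is None:
        return np.zeros(len(stay_matrix), dtype=bool)
    return (lact.to_numpy(dtype=float) >= lactate_threshold) & \
           (vaso.to_numpy() > 0)


def _runs(mask: np.ndarray, min_gap: int = 1) -> list[tuple[int, int]]:
    """Maximal runs of True; runs separated by < min_gap False hours merge."""
    hours = np.flatnonzero(mask)
    if len(hours) == 0:
        return []
    runs = []
    start = prev = hours[0]
    for h in hours[1:]:
        if h - prev > min_gap:
            runs.append((int(start), int(prev)))
            start = h
        prev = h
    runs.append((int(start), int(prev)))
    return runs


def detect_shock_episodes(stay_matrix: pd.DataFrame,
                          sepsis_onset: int | None,
                          lactate_threshold: float = LACTATE_SHOCK_THRESHOLD,
                          min_gap: int = 1) -> list[ShockEpisode]:
    """Maximal runs of in-shock hours at or after sepsis onset."""
    if sepsis_onset is None:
        return []
    mask = in_shock_hours(stay_matrix, lactate_threshold)
    hours = np.arange(len(mask))
    mask &= hours >= sepsis_onset
    sid = stay_matrix.index.get_level_values("stay_id")[0] \
        if "stay_id" in (stay_matrix.index.names or []) else None
    episodes = [ShockEpisode(sid, on, end) for on, end in _runs(mask, min_gap)]
    if episodes:
        episodes[0].is_first = True
    return episodes


def first_intervention_time(stay_matrix: pd.DataFrame) -> int | None:
    """First hour with a vasopressor and a fluid simultaneously active."""
    vaso = stay_matrix.get("vasopressor__active")
    fluid = stay_matrix.get("fluid__active")
    if vaso is None or fluid is None:
        return None
    both = np.flatnonzero((vaso.to_numpy() > 0) & (fluid.to_numpy() > 0))
    return int(both[0]) if len(both) else None


# ---------------------------------------------------------------------------
# per-stay and cohort-level annotation
# ---------------------------------------------------------------------------

def annotate_stay(stay_id,
                  stay_matrix: pd.DataFrame,
                  observations: pd.DataFrame,
                  has_antibiotics: bool,
                  culture_times: Sequence[float],
                  diagnosis_codes: Sequence[str],
                  infection_codes: Sequence[str],
                  lactate_threshold: float = LACTATE_SHOCK_THRESHOLD,
                  min_gap: int = 1) -> StayAnnotation:
    """Full Sepsis-3 annotation of one stay, including exclusion screening."""
    ann = StayAnnotation(stay_id=stay_id, n_hours=len(stay_matrix))
    if not check_required_variables(observations):
        ann.excluded, ann.reason = True, "missing_required_variables"
        return ann

    ann.suspected_infection = detect_suspected_infection(
        has_antibiotics, culture_times, diagnosis_codes, infection_codes)
    sofa = compute_sofa(stay_matrix)
    ann.sepsis_onset_hour = detect_sepsis_onset(sofa, ann.suspected_infection)
    if ann.sepsis_onset_hour is None:
        ann.excluded, ann.reason = True, "no_sepsis"
        return ann

    # shock-before-sepsis screening runs on the UNGATED in-shock hour set
    ungated = np.flatnonzero(in_shock_hours(stay_matrix, lactate_threshold))
    if len(ungated) and ungated[0] < ann.sepsis_onset_hour:
        ann.excluded, ann.reason = True, "shock_before_sepsis"
        return ann

    episodes = detect_shock_episodes(stay_matrix, ann.sepsis_onset_hour,
                                     lactate_threshold, min_gap)
    for ep in episodes:
        ep.stay_id = stay_id
    ann.episodes = episodes
    ann.intervention_start_hour = first_intervention_time(stay_matrix)
    return ann


def annotate_cohort(matrix: pd.DataFrame,
                    observations: pd.DataFrame,
                    interventions: pd.DataFrame,
                    stays: pd.DataFrame,
                    infection_codes: Sequence[str],
                    lactate_threshold: float = LACTATE_SHOCK_THRESHOLD,
                    min_gap: int = 1) -> list[StayAnnotation]:
    """Annotate every stay of a preprocessed cohort."""
    abx_stays = set(
        interventions.loc[interventions["kind"] == "antibiotic", "stay_id"])
    obs_by_stay = dict(tuple(observations.groupby("stay_id", sort=False)))
    empty_obs = observations.iloc[0:0]
    meta = stays.set_index("stay_id")

    annotations = []
    for stay_id, stay_matrix in matrix.groupby(level="stay_id", sort=False):
        stay_matrix = stay_matrix.droplevel("stay_id")
        row = meta.loc[stay_id]
        cultures = _split_field(row.get("culture_minutes", ""))
        codes = _split_field(row.get("icd_codes", ""))
        annotations.append(annotate_stay(
            stay_id, stay_matrix,
            obs_by_stay.get(stay_id, empty_obs),
            has_antibiotics=stay_id in abx_stays,
            culture_times=cultures,
            diagnosis_codes=codes,
            infection_codes=infection_codes,
            lactate_threshold=lactate_threshold,
            min_gap=min_gap))
    return annotations


def _split_field(raw) -> list[str]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return []
    return [tok for tok in str(raw).split(";") if tok not in ("", "nan")]


# ---------------------------------------------------------------------------
# serialization helpers
# ---------------------------------------------------------------------------

def annotations_to_frame(annotations: Iterable[StayAnnotation]) -> pd.DataFrame:
    rows = []
    for a in annotations:
        rows.append({
            "stay_id": a.stay_id,
            "suspected": int(a.suspected_infection),
            "sepsis_onset_hour": a.sepsis_onset_hour,
            "excluded": int(a.excluded),
            "reason": a.reason,
            "episodes": ";".join(f"{e.onset_hour}:{e.end_hour}"
                                 for e in a.episodes),
            "intervention_start_hour": a.intervention_start_hour,
            "n_hours": a.n_hours,
        })
    return pd.DataFrame(rows)


def episodes_frame(annotations: Iterable[StayAnnotation],
                   included_only: bool = True) -> pd.DataFrame:
    """Long table of shock episodes: stay_id, onset, end, is_first."""
    rows = [(a.stay_id, e.onset_hour, e.end_hour, e.is_first)
            for a in annotations if not (included_only and a.excluded)
            for e in a.episodes]
    return pd.DataFrame(rows, columns=["stay_id", "onset", "end", "is_first"])


def load_infection_codes(path) -> list[str]:
    """Read a plain-text infection-code prefix file (one prefix per line)."""
    with open(path, "r", encoding="utf-8") as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
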