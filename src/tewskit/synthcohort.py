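"""Synthetic ICU cohort generator with ground-truth shock annotations.

Each stay follows a latent hourly physiology model: a stable phase of
autocorrelated noise around personal baselines, optionally a deterioration
ramp (6-12 h by default) during which mean arterial pressure drifts down and
heart rate and lactate drift up in proportion to ``effect_size``, and a shock
phase in which a clinician-response model starts a vasopressor once the
pressure falls below 65 mmHg, which together with lactate >= 2 mmol/L realises
a septic-shock onset under the same definition the cohort module detects.
Fluid boluses triggered at MAP < 70 may abort the progression (treated
near-misses); cleared episodes may recur.

Observations are sampled from the latent paths at class-specific periods
(vitals hourly, labs sporadically with event-driven draws at clinical
responses), thinned by a missingness rate, and emitted in the exact input
schema of the preprocessing module.  Ground truth (true onset runs, ramp
starts, intervention hours, aborted flags) is derived from the *emitted*
record so that information lost to sampling never counts against a detector.

With ``effect_size = 0`` the pre-onset ramp vanishes and onsets become abrupt:
events still occur, but no advance signal exists to learn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .preprocess import OBS_COLUMNS, INTERV_COLUMNS
from .vocab import CANONICAL_UNITS

STAYS_COLUMNS = ["stay_id", "admit_iso", "discharge_iso", "age", "gender",
                 "icd_codes", "culture_minutes"]

INFECTION_CODE = "A41"
DEFAULT_INFECTION_CODES = [INFECTION_CODE]

_ADMIT_BASE = pd.Timestamp("2023-01-01 00:00:00")


@dataclass
class SyntheticCohortParams:
    n_stays: int = 200
    shock_prevalence: float = 0.37
    stay_hours: tuple = (36, 96)
    ramp_hours: tuple = (6, 12)
    effect_size: float = 1.0
    recurrence_prob: float = 0.15
    treatment_abort_prob: float = 0.2
    uninfected_frac: float = 0.1
    irrigation_frac: float = 0.05
    vitals_period_h: int = 1
    labs_period_h: int = 4
    missingness: float = 0.1
    seed: int = 0

    def __post_init__(self):
        for p in (self.shock_prevalence, self.recurrence_prob,
                  self.treatment_abort_prob, self.missingness,
                  self.uninfected_frac, self.irrigation_frac):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("probabilities must lie in [0, 1]")
        for lo, hi in (self.stay_hours, self.ramp_hours):
            if lo > hi:
                raise ConfigurationError("range min exceeds max")
        if self.stay_hours[0] < self.ramp_hours[1] + 16:
            raise ConfigurationError(
                "stays too short for the deterioration ramp plus an episode")


@dataclass
class StayTruth:
    stay_id: str
    shock_intended: bool
    aborted: bool
    infected: bool
    deterioration_start: int | None
    vaso_start: int | None
    onsets: list[int] = field(default_factory=list)
    ends: list[int] = field(default_factory=list)
    intervention_hour: int | None = None


def _ar1(rng: np.random.Generator, n: int, sigma: float,
         rho: float = 0.7) -> np.ndarray:
    noise = rng.normal(0.0, sigma, n)
    out = np.empty(n)
    acc = 0.0
    for i in range(n):
        acc = rho * acc + noise[i]
        out[i] = acc
    return out


def _ramp(n: int, start: int, length: int, total: float) -> np.ndarray:
    """Linear drift reaching ``total`` at ``start + length``, flat afterwards."""
    h = np.arange(n)
    frac = np.clip((h - start + 1) / max(1, length), 0.0, 1.0)
    frac[h < start] = 0.0
    return frac * total


class _StayBuilder:
    """Latent paths plus the emitted record for a single stay."""

    def __init__(self, stay_id: str, T: int, params: SyntheticCohortParams,
                 rng: np.random.Generator):
        self.stay_id, self.T, self.p, self.rng = stay_id, T, params, rng
        self.obs_rows: list[tuple] = []
        self.interv_rows: list[tuple] = []

    # -- latent physiology ------------------------------------------------
    def build_paths(self, profile: str) -> StayTruth:
        p, rng, T = self.p, self.rng, self.T
        base = {
            "heart_rate": rng.normal(80, 8), "sbp": rng.normal(120, 10),
            "dbp": rng.normal(65, 6), "temperature": rng.normal(37.0, 0.4),
            "lactate": max(0.4, rng.normal(1.0, 0.2)),
            "creatinine": max(0.4, rng.normal(0.9, 0.15)),
            "bilirubin": max(0.2, rng.normal(0.8, 0.3)),
            "platelets": max(120.0, rng.normal(250, 40)),
            "pao2": rng.normal(95, 8), "fio2": 0.21,
            "arterial_ph": rng.normal(7.40, 0.02),
        }
        if profile == "sepsis_only":
            # mild stable organ dysfunction: SOFA ~2 without shock physiology
            base["platelets"] = rng.normal(120, 12)
            base["creatinine"] = rng.normal(1.5, 0.15)

        paths = {}
        sig = {"heart_rate": 2.5, "sbp": 3.0, "dbp": 2.0, "temperature": 0.1,
               "lactate": 0.06, "creatinine": 0.03, "bilirubin": 0.05,
               "platelets": 4.0, "pao2": 3.0, "arterial_ph": 0.01}
        for var, b in base.items():
            if var == "fio2":
                paths[var] = np.full(T, b)
            else:
                paths[var] = b + _ar1(rng, T, sig[var])

        truth = StayTruth(self.stay_id, shock_intended=(profile == "shock"),
                          aborted=False, infected=(profile != "uninfected"),
                          deterioration_start=None, vaso_start=None)
        self.bolus_hours: list[int] = []
        self.vaso_intervals: list[tuple[int, int]] = []
        self.vent_interval: tuple[int, int] | None = None

        if profile == "shock":
            self._add_shock_course(paths, truth)
        self.paths = paths
        return truth

    def _add_shock_course(self, paths: dict, truth: StayTruth) -> None:
        p, rng, T = self.p, self.rng, self.T
        R = int(rng.integers(p.ramp_hours[0], p.ramp_hours[1] + 1))
        d = int(rng.integers(4, max(5, T - R - 14)))
        truth.deterioration_start = d
        aborted = rng.uniform() < p.treatment_abort_prob
        eff = p.effect_size

        if aborted:
            # ramp reverses after a fluid bolus mid-way; no vasopressor
            truth.aborted = True
            half = max(1, R // 2)
            up = _ramp(T, d, half, 1.0)
            down = _ramp(T, d + half, R, 1.0)
            shape = up - down  # rises then resolves
            self._apply_drift(paths, shape, eff)
            self.bolus_hours.append(d + half)
            return

        v = d + R  # vasopressor start = shock onset hour
        dur = int(rng.integers(6, 13))
        end = min(T - 1, v + dur - 1)
        shape = np.clip(_ramp(T, d, R, 1.0), 0.0, 1.0)
        recovery = _ramp(T, end + 1, 6, 1.0)
        shape = np.clip(shape - recovery, 0.0, 1.0)
        self._apply_drift(paths, shape, eff)

        in_shock = (np.arange(T) >= v) & (np.arange(T) <= end)
        # shock physiology at onset is definitional, not scaled by effect size
        paths["sbp"][in_shock] = rng.normal(82, 3, in_shock.sum())
        paths["dbp"][in_shock] = rng.normal(45, 2, in_shock.sum())
        paths["lactate"][in_shock] = np.maximum(
            paths["lactate"][in_shock], rng.normal(2.8, 0.3, in_shock.sum()))

        truth.vaso_start = v
        self.bolus_hours.append(max(d + 1, v - int(rng.integers(1, 4))))
        self.bolus_hours.append(v)  # co-administration at vasopressor start
        vaso_end = min(T - 1, end + int(rng.integers(0, 3)))
        self.vaso_intervals.append((v, vaso_end))
        if rng.uniform() < 0.5:
            self.vent_interval = (max(0, v - 1), end)

        # recurrence: a second, shorter course after clearance
        if (rng.uniform() < p.recurrence_prob
                and T - (end + 8) > p.ramp_hours[0] + 8):
            d2 = end + int(rng.integers(4, 7))
            R2 = p.ramp_hours[0]
            v2 = d2 + R2
            dur2 = int(rng.integers(4, 9))
            end2 = min(T - 1, v2 + dur2 - 1)
            if end2 > v2:
                shape2 = np.clip(_ramp(self.T, d2, R2, 1.0)
                                 - _ramp(self.T, end2 + 1, 6, 1.0), 0, 1)
                self._apply_drift(paths, shape2, eff)
                in2 = (np.arange(T) >= v2) & (np.arange(T) <= end2)
                paths["lactate"][in2] = np.maximum(
                    paths["lactate"][in2], rng.normal(2.6, 0.3, in2.sum()))
                self.vaso_intervals.append((v2, min(T - 1, end2 + 1)))
                self.bolus_hours.append(v2)

    def _apply_drift(self, paths: dict, shape: np.ndarray, eff: float) -> None:
        paths["sbp"] -= eff * 25.0 * shape
        paths["dbp"] -= eff * 12.0 * shape
        paths["heart_rate"] += eff * 25.0 * shape
        paths["lactate"] += eff * 1.8 * shape
        paths["platelets"] -= eff * 120.0 * shape
        paths["creatinine"] += eff * 0.8 * shape
        paths["bilirubin"] += eff * 1.2 * shape
        paths["arterial_ph"] -= eff * 0.06 * shape

    # -- emission ---------------------------------------------------------
    def _emit(self, var: str, minute: float, value: float,
              force: bool = False) -> None:
        if not force and self.rng.uniform() < self.p.missingness:
            return
        self.obs_rows.append((self.stay_id, var, float(minute), float(value),
                              CANONICAL_UNITS[var]))

    def emit_observations(self, profile: str, use_irrigation: bool) -> None:
        p, rng, T = self.p, self.rng, self.T
        paths = self.paths
        map_path = (paths["sbp"] + 2 * paths["dbp"]) / 3.0
        vitals = {"heart_rate": paths["heart_rate"], "sbp": paths["sbp"],
                  "dbp": paths["dbp"], "map": map_path,
                  "temperature": paths["temperature"]}
        for h in range(0, T, p.vitals_period_h):
            minute = h * 60 + 5
            for var, path in vitals.items():
                self._emit(var, minute, path[h] + rng.normal(0, 0.5))

        lab_vars = ("lactate", "creatinine", "bilirubin", "platelets",
                    "pao2", "fio2", "arterial_ph")
        lab_hours = set(range(0, T, p.labs_period_h))
        lab_hours |= {h for h in self.bolus_hours if h < T}
        for (v0, _) in self.vaso_intervals:
            lab_hours.add(v0)
        for h in sorted(lab_hours):
            minute = h * 60 + 15
            for var in lab_vars:
                val = paths[var][h] + rng.normal(0, 0.01 if var == "fio2" else
                                                 0.02 * abs(paths[var][h]))
                if var in ("lactate", "creatinine", "bilirubin"):
                    val = max(0.1, val)
                if var == "fio2":
                    val = float(np.clip(val, 0.21, 1.0))
                if var == "platelets":
                    val = max(5.0, val)
                self._emit(var, minute, val)

        gcs = {"gcs_eye": 4, "gcs_motor": 6, "gcs_verbal": 5}
        for h in range(0, T, 4):
            for var, val in gcs.items():
                self._emit(var, h * 60 + 10, val)

        self._emit("height", 20, rng.normal(170, 10), force=True)
        self._emit("weight", 25, rng.normal(78, 14), force=True)

        shock_hours = np.zeros(T, dtype=bool)
        for (a, b) in self.vaso_intervals:
            shock_hours[a:b + 1] = True
        for h in range(T):
            vol = rng.normal(20, 5) if shock_hours[h] else rng.normal(60, 10)
            vol = max(0.0, vol)
            minute = h * 60 + 50
            if use_irrigation and 4 <= h < 8:
                irr = max(0.0, rng.normal(100, 10))
                self._emit("irrigant_in", minute - 20, irr)
                self._emit("irrigant_out", minute, irr + vol)
            else:
                self._emit("urine_out", minute, vol)

    def emit_interventions(self, profile: str) -> None:
        rng, T = self.rng, self.T
        for (a, b) in self.vaso_intervals:
            rate = float(rng.uniform(0.05, 0.3))
            self.interv_rows.append(
                (self.stay_id, "vasopressor", "norepinephrine",
                 a * 60.0, min(T * 60.0, (b + 1) * 60.0 - 1), rate,
                 "ug/kg/min"))
        for h in sorted(set(self.bolus_hours)):
            if h >= T:
                continue
            self.interv_rows.append(
                (self.stay_id, "fluid", "crystalloid", h * 60.0,
                 min(T * 60.0, h * 60.0 + 59.0), float(rng.uniform(8, 17)),
                 "mL/kg/h"))
        if profile != "uninfected":
            start = float(rng.integers(60, 300))
            self.interv_rows.append(
                (self.stay_id, "antibiotic", "ceftriaxone", start,
                 min(T * 60.0, start + 24 * 60.0), np.nan, ""))
        if self.vent_interval is not None:
            a, b = self.vent_interval
            self.interv_rows.append(
                (self.stay_id, "ventilation", "invasive", a * 60.0,
                 min(T * 60.0, (b + 1) * 60.0 - 1), np.nan, ""))


def _emitted_truth(builder: _StayBuilder, truth: StayTruth) -> None:
    """Derive true onset runs from the emitted record (post-missingness).

    Replicates the pipeline's lactate handling (hourly mean, forward then
    backward fill) and the half-open interval-overlap rule for vasopressor
    activity, so the truth reflects exactly the information a detector can
    recover from the tables.
    """
    T = builder.T
    lact = [(r[2], r[3]) for r in builder.obs_rows if r[1] == "lactate"]
    hourly = np.full(T, np.nan)
    if lact:
        df = pd.DataFrame(lact, columns=["minute", "value"])
        df["hour"] = np.minimum((df["minute"] // 60).astype(int), T - 1)
        means = df.groupby("hour")["value"].mean()
        hourly[means.index.to_numpy()] = means.to_numpy()
        hourly = pd.Series(hourly).ffill().bfill().to_numpy()
    vaso = np.zeros(T, dtype=bool)
    for r in builder.interv_rows:
        if r[1] != "vasopressor":
            continue
        lo = max(0, int(r[3] // 60))
        hi = min(T - 1, int(r[4] // 60))
        vaso[lo:hi + 1] = True
    in_shock = (hourly >= 2.0) & vaso
    hours = np.flatnonzero(in_shock)
    truth.onsets, truth.ends = [], []
    if len(hours):
        start = prev = hours[0]
        for h in hours[1:]:
            if h - prev > 1:
                truth.onsets.append(int(start))
                truth.ends.append(int(prev))
                start = h
            prev = h
        truth.onsets.append(int(start))
        truth.ends.append(int(prev))

    fluid = np.zeros(T, dtype=bool)
    for r in builder.interv_rows:
        if r[1] == "fluid":
            lo = max(0, int(r[3] // 60))
            hi = min(T - 1, int(r[4] // 60))
            fluid[lo:hi + 1] = True
    both = np.flatnonzero(vaso & fluid)
    truth.intervention_hour = int(both[0]) if len(both) else None


def generate_cohort(params: SyntheticCohortParams
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame,
                               pd.DataFrame]:
    """Generate (observations, interventions, stays, truth) tables.

    Deterministic given ``params.seed``; tables conform to the preprocessing
    input schema.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    obs_frames, interv_frames, stay_rows, truth_rows = [], [], [], []

    for i in range(p.n_stays):
        stay_id = f"S{i:05d}"
        T = int(rng.integers(p.stay_hours[0], p.stay_hours[1] + 1))
        if rng.uniform() < p.shock_prevalence:
            profile = "shock"
        elif rng.uniform() < p.uninfected_frac:
            profile = "uninfected"
        else:
            profile = "sepsis_only"
        use_irrigation = rng.uniform() < p.irrigation_frac

        b = _StayBuilder(stay_id, T, p, rng)
        truth = b.build_paths(profile)
        b.emit_observations(profile, use_irrigation)
        b.emit_interventions(profile)
        _emitted_truth(b, truth)

        admit = _ADMIT_BASE + pd.Timedelta(days=i % 365)
        codes = ["I10"]
        cultures = ""
        if profile != "uninfected":
            codes.append(f"{INFECTION_CODE}9")
            cultures = str(int(rng.integers(30, 360)))
        stay_rows.append((stay_id, admit.isoformat(),
                          (admit + pd.Timedelta(hours=T)).isoformat(),
                          float(rng.integers(30, 91)),
                          "M" if rng.uniform() < 0.5 else "F",
                          ";".join(codes), cultures))
        truth_rows.append({
            "stay_id": stay_id, "shock_intended": truth.shock_intended,
            "aborted": truth.aborted, "infected": truth.infected,
            "deterioration_start": truth.deterioration_start,
            "vaso_start": truth.vaso_start,
            "onsets": ";".join(map(str, truth.onsets)),
            "ends": ";".join(map(str, truth.ends)),
            "intervention_hour": truth.intervention_hour,
            "n_hours": T,
        })
        if b.obs_rows:
            obs_frames.append(pd.DataFrame(b.obs_rows, columns=OBS_COLUMNS))
        if b.interv_rows:
            interv_frames.append(pd.DataFrame(b.interv_rows,
                                              columns=INTERV_COLUMNS))

    observations = pd.concat(obs_frames, ignore_index=True)
    interventions = pd.concat(interv_frames, ignore_index=True)
    stays = pd.DataFrame(stay_rows, columns=STAYS_COLUMNS)
    truth = pd.DataFrame(truth_rows)
    return observations, interventions, stays, truth


def truth_onsets(truth: pd.DataFrame) -> pd.DataFrame:
    """Long (stay_id, onset, end) table of true shock runs."""
    rows = []
    for r in truth.itertuples(index=False):
        if not r.onsets:
            continue
        for o, e in zip(str(r.onsets).split(";"), str(r.ends).split(";")):
            if o:
                rows.append((r.stay_id, int(o), int(e)))
    return pd.DataFrame(rows, columns=["stay_id", "onset", "end"])


def verify_ground_truth(observations: pd.DataFrame,
                        interventions: pd.DataFrame,
                        stays: pd.DataFrame,
                        truth: pd.DataFrame,
                        tolerance_h: int = 1) -> dict:
    """Run the full annotation pipeline and report onset recovery.

    Recovery is the fraction of true onsets matched by a detected episode
    onset within ``tolerance_h`` hours.
    """
    from .preprocess import build_feature_matrix
    from .cohort import annotate_cohort, episodes_frame

    matrix, _ = build_feature_matrix(observations, interventions, stays)
    annotations = annotate_cohort(matrix, observations, interventions, stays,
                                  infection_codes=DEFAULT_INFECTION_CODES)
    detected = episodes_frame(annotations)
    det_by_stay = {sid: grp["onset"].to_numpy()
                   for sid, grp in detected.groupby("stay_id")} \
        if len(detected) else {}

    true_eps = truth_onsets(truth)
    n_true = len(true_eps)
    n_recovered = 0
    for r in true_eps.itertuples(index=False):
        onsets = det_by_stay.get(r.stay_id, np.array([]))
        if len(onsets) and np.min(np.abs(onsets - r.onset)) <= tolerance_h:
            n_recovered += 1

    aborted_ids = set(truth.loc[truth["aborted"], "stay_id"])
    aborted_detected = sum(len(det_by_stay.get(s, [])) for s in aborted_ids)
    return {
        "n_true_onsets": n_true,
        "n_recovered": n_recovered,
        "recovery": (n_recovered / n_true) if n_true else None,
        "n_detected": int(len(detected)),
        "aborted_with_detected_onsets": aborted_detected,
    }
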