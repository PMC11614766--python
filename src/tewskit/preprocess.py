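"""Raw-record cleaning and hourly feature-matrix construction.

The module turns long-format per-stay observation and intervention tables into a
dense per-stay, per-hour feature matrix:

* physiological-plausibility outlier removal,
* timestamp sanity rules (records outside the stay, or beyond two days of it),
* GCS component timestamp alignment and urine/irrigant correction,
* hourly resampling (mean/median/max/min per measurement variable, sums for
  volumes, activity flags for drug and ventilation intervals),
* per-class imputation (labs fill forward then backward, vitals interpolate
  linearly, never-recorded variables become zeros),
* slope features (difference of the hourly mean against 1, 3 and 5 hours
  earlier) and presence flags marking measured versus imputed hours.

Hour ``h`` covers minutes ``[60h, 60(h+1))`` from ICU admission (half-open);
an observation exactly at admission belongs to hour 0.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SchemaError
from . import vocab

OBS_COLUMNS = ["stay_id", "variable", "minutes", "value", "unit"]
INTERV_COLUMNS = ["stay_id", "kind", "agent", "start_min", "end_min", "rate",
                  "rate_unit"]

#: Columns of the feature matrix that are not model inputs.
NON_FEATURE_COLUMNS = ("label", "train_mask", "partition")

SUMMARY_STATS = ("mean", "median", "max", "min")
SLOPE_LAGS = (1, 3, 5)
# Retention margin for grossly mistimed records: two days on either side.
TIME_ERROR_MARGIN_MIN = 2 * 24 * 60


# ---------------------------------------------------------------------------
# stay bookkeeping
# ---------------------------------------------------------------------------

def stay_minutes(stays: pd.DataFrame) -> pd.Series:
    """Length of each stay in minutes, from the admission/discharge timestamps."""
    admit = pd.to_datetime(stays["admit_iso"])
    disch = pd.to_datetime(stays["discharge_iso"])
    minutes = (disch - admit).dt.total_seconds() / 60.0
    if (minutes <= 0).any():
        bad = stays.loc[minutes <= 0, "stay_id"].tolist()
        raise SchemaError(f"non-positive stay length for stays {bad}")
    return pd.Series(minutes.values, index=stays["stay_id"].values)


def stay_hours(stays: pd.DataFrame) -> pd.Series:
    """Number of hourly bins per stay: ceiling of the stay length, minimum 1."""
    mins = stay_minutes(stays)
    return mins.apply(lambda m: max(1, math.ceil(m / 60.0))).astype(int)


# ---------------------------------------------------------------------------
# record-level cleaning
# ---------------------------------------------------------------------------

def remove_outliers(observations: pd.DataFrame,
                    criteria: Mapping[str, tuple] | None = None) -> pd.DataFrame:
    """Drop observations outside the plausibility bounds for their variable.

    ``criteria`` maps variable name to ``(lower, upper)`` in canonical units and
    must cover every variable present; a variable without an entry raises
    :class:`ConfigurationError`.  Retention is inclusive on both bounds.
    """
    if criteria is None:
        criteria = vocab.DEFAULT_OUTLIER_CRITERIA
    present = observations["variable"].unique()
    missing = [v for v in present if v not in criteria]
    if missing:
        raise ConfigurationError(
            f"no outlier criteria for variable(s): {sorted(missing)}")
    lower = observations["variable"].map(lambda v: criteria[v][0])
    upper = observations["variable"].map(lambda v: criteria[v][1])
    keep = (observations["value"] >= lower) & (observations["value"] <= upper)
    return observations.loc[keep].copy()


def adjust_time_errors(observations: pd.DataFrame,
                       interventions: pd.DataFrame,
                       stays: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop records whose timestamps are incongruent with their stay.

    Point observations must fall inside ``[admission, discharge]``; interval
    records must have both endpoints inside it; anything beyond two days before
    admission or two days after discharge is an error regardless of type.
    """
    lengths = stay_minutes(stays)

    obs = observations.copy()
    disch = obs["stay_id"].map(lengths)
    in_margin = (obs["minutes"] >= -TIME_ERROR_MARGIN_MIN) & \
                (obs["minutes"] <= disch + TIME_ERROR_MARGIN_MIN)
    in_stay = (obs["minutes"] >= 0) & (obs["minutes"] <= disch)
    obs = obs.loc[in_margin & in_stay]

    interv = interventions.copy()
    disch_i = interv["stay_id"].map(lengths)
    ok = ((interv["start_min"] >= 0) & (interv["end_min"] >= interv["start_min"])
          & (interv["end_min"] <= disch_i))
    interv = interv.loc[ok]
    return obs, interv


def impute_gcs_components(gcs_records: pd.DataFrame
                          ) -> tuple[pd.DataFrame, list[str]]:
    """Align GCS component timestamps so the total score is computable.

    At every timestamp where at least one component was charted, the missing
    components are filled from the nearest earlier record of that component,
    else the nearest later one.  A component never recorded in the whole stay
    stays absent and is listed in the returned provenance log.
    """
    extra = set(gcs_records["variable"]) - set(vocab.GCS_COMPONENTS)
    if extra:
        raise ConfigurationError(
            f"impute_gcs_components expects GCS components only, got {sorted(extra)}")
    out_frames = []
    provenance: list[str] = []
    for stay_id, grp in gcs_records.groupby("stay_id", sort=False):
        wide = grp.pivot_table(index="minutes", columns="variable",
                               values="value", aggfunc="last")
        wide = wide.reindex(columns=list(vocab.GCS_COMPONENTS)).sort_index()
        for comp in vocab.GCS_COMPONENTS:
            if wide[comp].notna().sum() == 0:
                provenance.append(
                    f"stay {stay_id}: GCS component {comp} never recorded")
        filled = wide.ffill().bfill()
        long = filled.reset_index().melt(id_vars="minutes",
                                         var_name="variable",
                                         value_name="value").dropna(subset=["value"])
        long.insert(0, "stay_id", stay_id)
        long["unit"] = "points"
        out_frames.append(long[OBS_COLUMNS])
    if not out_frames:
        return gcs_records.iloc[0:0][OBS_COLUMNS].copy(), provenance
    out = pd.concat(out_frames, ignore_index=True)
    return out.sort_values(["stay_id", "minutes", "variable"],
                           kind="stable").reset_index(drop=True), provenance


def compute_urine_output(observations: pd.DataFrame
                         ) -> tuple[pd.DataFrame, list[str]]:
    """Correct urine output for bladder irrigation.

    Plain ``urine_out`` records pass through.  Each ``irrigant_out`` record is
    replaced by a ``urine_out`` record whose value is the cumulative irrigant-out
    volume minus the cumulative irrigant-in volume up to that time (0 when no
    irrigant-in precedes it).  Negative corrected volumes are clamped to 0 and
    logged.  ``irrigant_in`` records are consumed.
    """
    log: list[str] = []
    is_irr = observations["variable"].isin(vocab.IRRIGANTS)
    passthrough = observations.loc[~is_irr]
    irr = observations.loc[is_irr]
    if irr.empty:
        return observations.copy(), log

    corrected_frames = [passthrough]
    for stay_id, grp in irr.groupby("stay_id", sort=False):
        grp = grp.sort_values("minutes", kind="stable")
        cum_in = 0.0
        cum_out = 0.0
        rows = []
        for _, rec in grp.iterrows():
            if rec["variable"] == "irrigant_in":
                cum_in += rec["value"]
                continue
            cum_out += rec["value"]
            corrected = cum_out - cum_in
            if corrected < 0:
                log.append(f"stay {stay_id}: negative corrected urine volume "
                           f"{corrected:.1f} mL at minute {rec['minutes']:.0f}, "
                           "clamped to 0")
                corrected = 0.0
            rows.append((stay_id, "urine_out", rec["minutes"], corrected, "mL"))
        if rows:
            corrected_frames.append(pd.DataFrame(rows, columns=OBS_COLUMNS))
    out = pd.concat(corrected_frames, ignore_index=True)
    return out.sort_values(["stay_id", "minutes"],
                           kind="stable").reset_index(drop=True), log


# ---------------------------------------------------------------------------
# hourly resampling
# ---------------------------------------------------------------------------

def _full_index(hours: pd.Series) -> pd.MultiIndex:
    pairs = [(sid, h) for sid, T in hours.items() for h in range(T)]
    return pd.MultiIndex.from_tuples(pairs, names=["stay_id", "hour"])


def _interval_hours(start: float, end: float, T: int) -> range:
    """Hours whose bin [60h, 60(h+1)) overlaps the closed interval [start, end]."""
    lo = max(0, int(math.floor(start / 60.0)))
    hi = min(T - 1, int(math.floor(end / 60.0)))
    return range(lo, hi + 1)


def resample_hourly(observations: pd.DataFrame,
                    interventions: pd.DataFrame,
                    stays: pd.DataFrame) -> pd.DataFrame:
    """Discretize cleaned records onto the hourly grid.

    Measurement variables get mean/median/max/min and a presence flag per bin;
    volume variables are summed; intervention intervals become per-hour activity
    flags (plus a max dose rate for vasopressors).  Empty bins are left missing
    for :func:`impute_features`.
    """
    hours = stay_hours(stays)
    index = _full_index(hours)
    grid = pd.DataFrame(index=index)

    obs = observations.copy()
    obs["hour"] = (obs["minutes"] // 60).astype(int)
    # A measurement exactly at discharge on a whole-hour boundary belongs to the
    # last bin rather than one past it.
    last_hour = obs["stay_id"].map(hours) - 1
    obs["hour"] = np.minimum(obs["hour"], last_hour)

    summ = obs[obs["variable"].isin(vocab.SUMMARY_VARIABLES)]
    if not summ.empty:
        agg = summ.groupby(["stay_id", "hour", "variable"])["value"] \
                  .agg(["mean", "median", "max", "min"])
        wide = agg.unstack("variable")
        wide.columns = [f"{var}__{stat}" for stat, var in wide.columns]
        grid = grid.join(wide)

    for var in vocab.SUMMARY_VARIABLES:
        col = f"{var}__mean"
        if col not in grid.columns:
            for stat in SUMMARY_STATS:
                grid[f"{var}__{stat}"] = np.nan
        grid[f"{var}__presence"] = grid[col].notna().astype(np.int8)

    vol = obs[obs["variable"].isin(vocab.SUM_VARIABLES)]
    for var in vocab.SUM_VARIABLES:
        sub = vol[vol["variable"] == var]
        sums = sub.groupby(["stay_id", "hour"])["value"].sum()
        grid[f"{var}__sum"] = sums.reindex(index)
        grid[f"{var}__presence"] = grid[f"{var}__sum"].notna().astype(np.int8)

    for kind in vocab.INTERVENTION_KINDS:
        grid[f"{kind}__active"] = np.int8(0)
    grid["vasopressor__rate"] = 0.0

    if not interventions.empty:
        active_rows: dict[str, list] = {k: [] for k in vocab.INTERVENTION_KINDS}
        rate_rows: list[tuple] = []
        for rec in interventions.itertuples(index=False):
            T = int(hours.get(rec.stay_id, 0))
            if T == 0 or rec.kind not in vocab.INTERVENTION_KINDS:
                continue
            for h in _interval_hours(rec.start_min, rec.end_min, T):
                active_rows[rec.kind].append((rec.stay_id, h))
                if rec.kind == "vasopressor" and pd.notna(rec.rate):
                    rate_rows.append((rec.stay_id, h, float(rec.rate)))
        for kind, pairs in active_rows.items():
            if pairs:
                idx = pd.MultiIndex.from_tuples(set(pairs),
                                                names=["stay_id", "hour"])
                grid.loc[grid.index.isin(idx), f"{kind}__active"] = np.int8(1)
        if rate_rows:
            rates = pd.DataFrame(rate_rows, columns=["stay_id", "hour", "rate"])
            mx = rates.groupby(["stay_id", "hour"])["rate"].max()
            aligned = mx.reindex(index).fillna(0.0)
            grid["vasopressor__rate"] = aligned.values

    return grid


# ---------------------------------------------------------------------------
# imputation and feature engineering
# ---------------------------------------------------------------------------

def impute_features(grid: pd.DataFrame) -> pd.DataFrame:
    """Fill empty hourly bins per variable class.

    Labs and GCS components carry the last value forward (then backward for a
    leading gap); vitals, height and weight are interpolated linearly between
    measured hours with nearest-value extension at the edges; volume sums
    default to 0.  A variable never recorded in a stay becomes all zeros with
    presence 0 throughout.  Presence flags are never modified.  Idempotent.
    """
    out = grid.copy()
    by_stay = lambda df: df.groupby(level="stay_id", group_keys=False, sort=False)

    fill_cols = [f"{v}__{s}" for v in (vocab.LABS + vocab.GCS_COMPONENTS)
                 for s in SUMMARY_STATS]
    fill_cols = [c for c in fill_cols if c in out.columns]
    if fill_cols:
        filled = by_stay(out[fill_cols]).ffill()
        filled = by_stay(filled).bfill()
        out[fill_cols] = filled.fillna(0.0)

    interp_cols = [f"{v}__{s}" for v in (vocab.VITALS + vocab.BODY)
                   for s in SUMMARY_STATS]
    interp_cols = [c for c in interp_cols if c in out.columns]
    if interp_cols:
        interp = by_stay(out[interp_cols]).apply(
            lambda g: g.interpolate(method="linear", limit_direction="both"))
        out[interp_cols] = interp.fillna(0.0)

    for var in vocab.SUM_VARIABLES:
        col = f"{var}__sum"
        if col in out.columns:
            out[col] = out[col].fillna(0.0)
    return out


def engineer_features(grid: pd.DataFrame) -> pd.DataFrame:
    """Append slope features: hourly-mean difference against 1, 3 and 5 h prior.

    Hours with insufficient history get slope 0 by convention.  Slopes are not
    derived for drug or ventilation flags or static variables.
    """
    out = grid.copy()
    slope_sources = [(v, f"{v}__mean") for v in vocab.SUMMARY_VARIABLES] + \
                    [(v, f"{v}__sum") for v in vocab.SUM_VARIABLES]
    grouped = out.groupby(level="stay_id", sort=False)
    for var, col in slope_sources:
        if col not in out.columns:
            continue
        for k in SLOPE_LAGS:
            out[f"{var}__slope{k}"] = (out[col] -
                                       grouped[col].shift(k)).fillna(0.0)
    return out


def attach_static(grid: pd.DataFrame, stays: pd.DataFrame) -> pd.DataFrame:
    """Broadcast age and gender onto every hourly row of each stay."""
    out = grid.copy()
    meta = stays.set_index("stay_id")
    sid = out.index.get_level_values("stay_id")
    out["age"] = pd.Series(sid, index=out.index).map(meta["age"]).astype(float)
    gender = pd.Series(sid, index=out.index).map(meta["gender"])
    out["gender_male"] = (gender.astype(str).str.upper()
                          .str.startswith("M")).astype(np.int8)
    return out


def feature_columns(matrix: pd.DataFrame) -> list[str]:
    """Model-input columns of a feature matrix (labels and masks excluded)."""
    return [c for c in matrix.columns if c not in NON_FEATURE_COLUMNS]


def build_feature_matrix(observations: pd.DataFrame,
                         interventions: pd.DataFrame,
                         stays: pd.DataFrame,
                         criteria: Mapping[str, tuple] | None = None,
                         ) -> tuple[pd.DataFrame, list[str]]:
    """Run the full preprocessing chain; returns (matrix, provenance log)."""
    _check_units(observations)
    log: list[str] = []
    obs = remove_outliers(observations, criteria)
    obs, interv = adjust_time_errors(obs, interventions, stays)

    obs, urine_log = compute_urine_output(obs)
    log.extend(urine_log)

    is_gcs = obs["variable"].isin(vocab.GCS_COMPONENTS)
    gcs, gcs_log = impute_gcs_components(obs.loc[is_gcs])
    log.extend(gcs_log)
    obs = pd.concat([obs.loc[~is_gcs], gcs], ignore_index=True)

    grid = resample_hourly(obs, interv, stays)
    grid = impute_features(grid)
    grid = engineer_features(grid)
    grid = attach_static(grid, stays)
    return grid, log


def _check_units(observations: pd.DataFrame) -> None:
    known = observations["variable"].isin(vocab.CANONICAL_UNITS)
    expected = observations.loc[known, "variable"].map(vocab.CANONICAL_UNITS)
    bad = observations.loc[known][observations.loc[known, "unit"] != expected]
    if not bad.empty:
        pairs = bad[["variable", "unit"]].drop_duplicates().values.tolist()
        raise SchemaError(f"non-canonical units (convert upstream): {pairs}")
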