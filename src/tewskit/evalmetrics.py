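"""Event-based timeliness evaluation for continuous hourly warning systems.

An hourly risk trace becomes an alarm stream by thresholding.  Each alarm is
then classified against the stay's shock episodes:

* **timely** — within the evaluation window ``[onset + earliest, onset + latest]``
  of an eligible episode (eligible = the first episode only in first-shock
  mode, any episode otherwise).  An alarm matching several episodes is
  attributed to the earliest matching onset.
* **in-shock excluded** — strictly after an episode's onset and at or before
  its end.  Alarms during ongoing shock reflect genuinely elevated risk and are
  excluded from the false count rather than penalised.
* **false** — everything else.

From the classification:

* ``TER`` (target event recall) — fraction of eligible episodes preceded by at
  least one timely alarm inside their window,
* ``TAR`` (true alarm rate) — timely / (timely + false),
* ``TER_stay`` / ``TAR_stay`` — per-stay versions averaged over shock stays,
* evaluation-window sweeps, cohort-level screening metrics, time-point AUPRC,
* the misalignment procedure contrasting clinically-timely settings with their
  rank under conventional metrics, and failure-case analytics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, f1_score

from .errors import ConfigurationError

TIMELY, FALSE, EXCLUDED = "timely", "false", "in_shock_excluded"

ALARM_COLUMNS = ["stay_id", "hour"]


@dataclass(frozen=True)
class EvaluationWindow:
    earliest: float  # hours relative to onset, <= latest; -inf allowed
    latest: int = 0

    def __post_init__(self):
        if not (self.earliest <= self.latest <= 0):
            raise ConfigurationError(
                f"invalid evaluation window ({self.earliest}, {self.latest})")


DEFAULT_WINDOW = EvaluationWindow(-8, 0)


@dataclass
class TimelinessReport:
    ter: float | None
    tar: float
    ter_stay: float | None
    tar_stay: float | None
    n_timely: int
    n_false: int
    n_excluded: int
    n_events: int
    n_events_warned: int
    window: EvaluationWindow
    first_only: bool

    def as_dict(self) -> dict:
        return {
            "ter": self.ter, "tar": self.tar,
            "ter_stay": self.ter_stay, "tar_stay": self.tar_stay,
            "n_timely": self.n_timely, "n_false": self.n_false,
            "n_excluded": self.n_excluded, "n_events": self.n_events,
            "n_events_warned": self.n_events_warned,
            "window": [self.window.earliest, self.window.latest],
            "first_only": self.first_only,
        }


# ---------------------------------------------------------------------------
# alarm generation and classification
# ---------------------------------------------------------------------------

def generate_alarms(scores: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Alarm at every (stay, hour) whose score >= threshold."""
    hit = scores.loc[scores["score"] >= threshold, ALARM_COLUMNS]
    return hit.drop_duplicates().sort_values(ALARM_COLUMNS,
                                             kind="stable").reset_index(drop=True)


def _check_episodes(eps: pd.DataFrame) -> pd.DataFrame:
    eps = eps.sort_values("onset", kind="stable")
    onsets = eps["onset"].to_numpy()
    ends = eps["end"].to_numpy()
    if (ends < onsets).any() or (onsets[1:] <= ends[:-1]).any():
        raise ConfigurationError("episodes overlap or are malformed")
    return eps


def classify_hours(hours: np.ndarray, episodes: pd.DataFrame,
                   window: EvaluationWindow, first_only: bool
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Would-be classification of each hour if it alarmed.

    Returns (class array, matched-onset array; NaN where no match).  The
    classification of an hour does not depend on the threshold, which makes
    exhaustive threshold sweeps cheap.
    """
    eps = _check_episodes(episodes) if len(episodes) else episodes
    cls = np.full(len(hours), FALSE, dtype=object)
    matched = np.full(len(hours), np.nan)
    if len(eps) == 0:
        return cls, matched
    eligible = eps[eps["is_first"]] if first_only else eps
    for onset in eligible["onset"]:
        lo = onset + window.earliest
        hi = onset + window.latest
        in_win = (hours >= lo) & (hours <= hi) & (cls == FALSE)
        cls[in_win] = TIMELY
        matched[in_win] = onset
    for onset, end in zip(eps["onset"], eps["end"]):
        in_shock = (hours > onset) & (hours <= end) & (cls == FALSE)
        cls[in_shock] = EXCLUDED
    return cls, matched


def classify_alarms(alarms: pd.DataFrame, episodes: pd.DataFrame,
                    window: EvaluationWindow = DEFAULT_WINDOW,
                    first_only: bool = False) -> pd.DataFrame:
    """Partition an alarm stream into timely / false / in-shock-excluded."""
    eps_by_stay = dict(tuple(episodes.groupby("stay_id", sort=False))) \
        if len(episodes) else {}
    empty = pd.DataFrame(columns=["stay_id", "onset", "end", "is_first"])
    frames = []
    for stay_id, grp in alarms.groupby("stay_id", sort=False):
        hours = grp["hour"].to_numpy()
        cls, matched = classify_hours(hours, eps_by_stay.get(stay_id, empty),
                                      window, first_only)
        frames.append(pd.DataFrame({"stay_id": stay_id, "hour": hours,
                                    "cls": cls, "matched_onset": matched}))
    if not frames:
        return pd.DataFrame(columns=["stay_id", "hour", "cls", "matched_onset"])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# timeliness metrics
# ---------------------------------------------------------------------------

def _warned_episodes(classification: pd.DataFrame, episodes: pd.DataFrame,
                     window: EvaluationWindow) -> np.ndarray:
    """Boolean per episode row: has >=1 timely alarm inside its own window."""
    warned = np.zeros(len(episodes), dtype=bool)
    timely = classification[classification["cls"] == TIMELY]
    by_stay = dict(tuple(timely.groupby("stay_id", sort=False))) \
        if len(timely) else {}
    for i, ep in enumerate(episodes.itertuples(index=False)):
        t = by_stay.get(ep.stay_id)
        if t is None:
            continue
        h = t["hour"].to_numpy()
        warned[i] = bool(np.any((h >= ep.onset + window.earliest) &
                                (h <= ep.onset + window.latest)))
    return warned


def compute_timeliness(classification: pd.DataFrame, episodes: pd.DataFrame,
                       window: EvaluationWindow = DEFAULT_WINDOW,
                       first_only: bool = False,
                       zero_alarm_stays_as_zero: bool = False
                       ) -> TimelinessReport:
    """TER / TAR and their per-stay variants from a classified alarm stream."""
    eligible = episodes[episodes["is_first"]] if first_only else episodes
    eligible = eligible.reset_index(drop=True)
    warned = _warned_episodes(classification, eligible, window)

    n_events = len(eligible)
    n_warned = int(warned.sum())
    ter = (n_warned / n_events) if n_events > 0 else None

    counts = classification["cls"].value_counts() if len(classification) else {}
    n_timely = int(counts.get(TIMELY, 0))
    n_false = int(counts.get(FALSE, 0))
    n_excluded = int(counts.get(EXCLUDED, 0))
    denom = n_timely + n_false
    tar = (n_timely / denom) if denom > 0 else 0.0

    # per-stay variants over stays that experienced shock
    ter_stay = tar_stay = None
    shock_stays = episodes["stay_id"].unique() if len(episodes) else []
    if len(shock_stays):
        per_ter, per_tar = [], []
        warned_by_stay = pd.Series(warned).groupby(
            eligible["stay_id"].values).agg(["sum", "count"]) \
            if n_events else pd.DataFrame(columns=["sum", "count"])
        cls_by_stay = dict(tuple(classification.groupby("stay_id", sort=False))) \
            if len(classification) else {}
        for sid in shock_stays:
            if sid in warned_by_stay.index:
                row = warned_by_stay.loc[sid]
                per_ter.append(row["sum"] / row["count"])
            c = cls_by_stay.get(sid)
            nt = int((c["cls"] == TIMELY).sum()) if c is not None else 0
            nf = int((c["cls"] == FALSE).sum()) if c is not None else 0
            if nt + nf > 0:
                per_tar.append(nt / (nt + nf))
            elif zero_alarm_stays_as_zero:
                per_tar.append(0.0)
        ter_stay = float(np.mean(per_ter)) if per_ter else None
        tar_stay = float(np.mean(per_tar)) if per_tar else None

    return TimelinessReport(ter=ter, tar=tar, ter_stay=ter_stay,
                            tar_stay=tar_stay, n_timely=n_timely,
                            n_false=n_false, n_excluded=n_excluded,
                            n_events=n_events, n_events_warned=n_warned,
                            window=window, first_only=first_only)


def timeliness_from_scores(scores: pd.DataFrame, episodes: pd.DataFrame,
                           threshold: float,
                           window: EvaluationWindow = DEFAULT_WINDOW,
                           first_only: bool = False) -> TimelinessReport:
    alarms = generate_alarms(scores, threshold)
    classification = classify_alarms(alarms, episodes, window, first_only)
    return compute_timeliness(classification, episodes, window, first_only)


def sweep_windows(alarms: pd.DataFrame, episodes: pd.DataFrame,
                  earliest_range=range(-8, -3), latest_range=range(-2, 1),
                  first_only: bool = False) -> pd.DataFrame:
    """TER for every (earliest, latest) window pair in the given ranges."""
    rows = []
    for earliest in earliest_range:
        for latest in latest_range:
            window = EvaluationWindow(earliest, latest)
            classification = classify_alarms(alarms, episodes, window,
                                             first_only)
            rep = compute_timeliness(classification, episodes, window,
                                     first_only)
            rows.append((earliest, latest, rep.ter, rep.tar))
    return pd.DataFrame(rows, columns=["earliest", "latest", "ter", "tar"])


# ---------------------------------------------------------------------------
# cohort- and time-point-based metrics
# ---------------------------------------------------------------------------

def cohort_metrics(alarms: pd.DataFrame, shock_flags: pd.Series) -> dict:
    """Screening metrics treating a stay as predicted-positive iff it alarmed."""
    alarmed = set(alarms["stay_id"].unique()) if len(alarms) else set()
    y_true = shock_flags.astype(bool)
    y_pred = pd.Series([sid in alarmed for sid in shock_flags.index],
                       index=shock_flags.index)
    tp = int((y_true & y_pred).sum())
    fn = int((y_true & ~y_pred).sum())
    fp = int((~y_true & y_pred).sum())
    tn = int((~y_true & ~y_pred).sum())
    div = lambda a, b: a / b if b > 0 else 0.0
    sens = div(tp, tp + fn)
    prec = div(tp, tp + fp)
    return {
        "sensitivity": sens,
        "specificity": div(tn, tn + fp),
        "precision": prec,
        "accuracy": div(tp + tn, tp + fn + fp + tn),
        "f1": div(2 * prec * sens, prec + sens),
        "tp": tp, "fn": fn, "fp": fp, "tn": tn,
    }


def timepoint_metrics(scores: np.ndarray, labels: np.ndarray,
                      threshold: float) -> dict:
    """AUPRC over all thresholds plus F1 at the operating threshold."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        auprc = None
    else:
        auprc = float(average_precision_score(labels, scores))
    preds = (scores >= threshold).astype(int)
    f1 = float(f1_score(labels, preds, zero_division=0.0))
    return {"auprc": auprc, "f1": f1}


# ---------------------------------------------------------------------------
# misalignment between event-based and conventional metrics
# ---------------------------------------------------------------------------

def misalignment(results: pd.DataFrame, metrics: list[str],
                 ter_floor: float = 0.9, tar_floor: float = 0.2
                 ) -> tuple[float, pd.DataFrame]:
    """Quantify how many clinically-timely settings rank low on other metrics.

    ``results`` holds one row per training setting (without oversampling or
    calibration) with columns ``ter``, ``tar`` and each comparison metric.
    With ``p`` the fraction of settings meeting the clinical floors (set C),
    the discrepancy of metric m is the fraction of C strictly below the
    empirical (1-p) quantile of m over all settings (linear interpolation;
    ties at the quantile count as achieving it).
    """
    n = len(results)
    if n == 0:
        raise ConfigurationError("no settings supplied")
    in_c = (results["ter"] >= ter_floor) & (results["tar"] >= tar_floor)
    c = results[in_c]
    if c.empty:
        raise ConfigurationError("no clinically applicable settings")
    p = len(c) / n
    rows = []
    for m in metrics:
        values = results[m].to_numpy(dtype=float)
        q = float(np.quantile(values, 1.0 - p, method="linear"))
        failed = c[c[m].to_numpy(dtype=float) < q]
        disc = len(failed) / len(c)
        rows.append({
            "metric": m, "quantile": q, "discrepancy": disc,
            "max_ter": float(failed["ter"].max()) if len(failed) else None,
            "max_tar": float(failed["tar"].max()) if len(failed) else None,
        })
    return p, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# intervention anticipation and failure cases
# ---------------------------------------------------------------------------

def pre_intervention_fraction(classification: pd.DataFrame,
                              episodes: pd.DataFrame,
                              intervention_hours: pd.Series,
                              window: EvaluationWindow = DEFAULT_WINDOW,
                              first_only: bool = False) -> float | None:
    """Fraction of eligible episodes warned before treatment started.

    An episode counts as anticipated when a timely alarm inside its window
    falls strictly before the stay's first vasopressor+fluid co-administration
    hour; episodes in stays without such an intervention count as anticipated
    iff they have any timely alarm.
    """
    eligible = episodes[episodes["is_first"]] if first_only else episodes
    if eligible.empty:
        return None
    timely = classification[classification["cls"] == TIMELY]
    by_stay = dict(tuple(timely.groupby("stay_id", sort=False))) \
        if len(timely) else {}
    anticipated = 0
    for ep in eligible.itertuples(index=False):
        t = by_stay.get(ep.stay_id)
        if t is None:
            continue
        h = t["hour"].to_numpy()
        in_win = (h >= ep.onset + window.earliest) & \
                 (h <= ep.onset + window.latest)
        cut = intervention_hours.get(ep.stay_id)
        if cut is not None and not pd.isna(cut):
            in_win &= h < cut
        anticipated += bool(in_win.any())
    return anticipated / len(eligible)


def failure_analysis(alarms: pd.DataFrame, episodes: pd.DataFrame,
                     matrix: pd.DataFrame,
                     window: EvaluationWindow = DEFAULT_WINDOW,
                     extended_earliest=(-24, -48, -96, float("-inf")),
                     association_hours: int = 3,
                     look_back_only: bool = False,
                     rapid_onset_hours: int = 12,
                     variables: tuple = ("map", "lactate", "arterial_ph",
                                         "creatinine", "bilirubin",
                                         "platelets")) -> dict:
    """Failure-case analytics for a final alarm stream.

    Reports (a) the fraction of false alarms with vasopressor / fluid /
    ventilation activity within ``association_hours``, (b) among shock stays
    without a timely warning, the fraction with a first onset earlier than
    ``rapid_onset_hours`` after admission, (c) false-negative and false-alarm
    ratios under widened evaluation windows, and (d) a mean clinical-variable
    comparison between false-negative stays and false-positive alarm hours.
    """
    classification = classify_alarms(alarms, episodes, window)
    report = compute_timeliness(classification, episodes, window)

    # (a) intervention association of false alarms
    false_alarms = classification[classification["cls"] == FALSE]
    activity_cols = [c for c in ("vasopressor__active", "fluid__active",
                                 "ventilation__active") if c in matrix.columns]
    n_assoc = 0
    activity = matrix[activity_cols].sum(axis=1) > 0 if activity_cols else None
    for row in false_alarms.itertuples(index=False):
        if activity is None:
            break
        lo = row.hour - association_hours
        hi = row.hour if look_back_only else row.hour + association_hours
        stay_act = activity.loc[row.stay_id]
        hours = stay_act.index.to_numpy()
        if bool(stay_act[(hours >= lo) & (hours <= hi)].any()):
            n_assoc += 1
    assoc_frac = n_assoc / len(false_alarms) if len(false_alarms) else None

    # (b) rapid onset among unwarned shock stays
    eligible = episodes.reset_index(drop=True)
    warned = _warned_episodes(classification, eligible, window)
    warned_stays = set(eligible.loc[warned, "stay_id"])
    shock_stays = eligible.groupby("stay_id")["onset"].min()
    unwarned = shock_stays[~shock_stays.index.isin(warned_stays)]
    rapid_frac = (float((unwarned < rapid_onset_hours).mean())
                  if len(unwarned) else None)

    # (c) widened evaluation windows
    widened = []
    for earliest in extended_earliest:
        w = EvaluationWindow(earliest, 0)
        cl = classify_alarms(alarms, episodes, w)
        rep = compute_timeliness(cl, episodes, w)
        fn_ratio = (1.0 - rep.ter) if rep.ter is not None else None
        denom = rep.n_timely + rep.n_false
        fa_ratio = rep.n_false / denom if denom else None
        widened.append({"earliest": earliest, "fn_ratio": fn_ratio,
                        "false_alarm_ratio": fa_ratio,
                        "n_false": rep.n_false})

    # (d) clinical-variable comparison: unwarned-stay hours vs false-alarm hours
    comparison = {}
    fn_rows = matrix.loc[matrix.index.get_level_values("stay_id")
                         .isin(unwarned.index)] if len(unwarned) else None
    fp_idx = pd.MultiIndex.from_frame(false_alarms[["stay_id", "hour"]]) \
        if len(false_alarms) else None
    fp_rows = matrix.loc[matrix.index.isin(fp_idx)] if fp_idx is not None \
        else None
    for var in variables:
        col = f"{var}__mean"
        comparison[var] = {
            "false_negative": (float(fn_rows[col].mean())
                               if fn_rows is not None and col in matrix.columns
                               and len(fn_rows) else None),
            "false_positive": (float(fp_rows[col].mean())
                               if fp_rows is not None and col in matrix.columns
                               and len(fp_rows) else None),
        }

    return {
        "base": report.as_dict(),
        "intervention_associated_false_fraction": assoc_frac,
        "rapid_onset_unwarned_fraction": rapid_frac,
        "widened_windows": widened,
        "variable_comparison": comparison,
    }
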