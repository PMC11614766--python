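"""Training harness: per-setting scorers, threshold selection, setting search.

A *training setting* is a learner plus a data-task configuration (prediction
window, training window, first-shock focus) plus optional oversampling and
calibration.  Each setting is fitted on the training partition, its alarm
threshold is chosen on the validation partition by maximising TER subject to a
TAR floor, and the search keeps settings that clear the clinical floors
(TER >= 0.9, TAR >= 0.2 in the -8..0 window by default) and, within those, the
ones whose time-point AUPRC is at least the mean AUPRC of the kept set.
Surviving settings are combined into hard- (member-majority, ties alarm) or
soft- (mean calibrated score) voting ensembles.

SMOTE and ADASYN are implemented here directly: both synthesise minority-class
rows by interpolating towards random minority k-nearest neighbours, ADASYN
allocating more synthetic rows to minority points surrounded by the majority
class.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.isotonic import IsotonicRegression
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import MultinomialNB
from sklearn.neighbors import NearestNeighbors
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler, StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .datatask import DataTaskConfig
from .errors import ConfigurationError
from .evalmetrics import (DEFAULT_WINDOW, EvaluationWindow, TIMELY, FALSE,
                          classify_hours, timepoint_metrics,
                          timeliness_from_scores)

MODEL_IDS = ("gradient_boosting", "lightgbm", "xgboost", "random_forest",
             "logistic_regression", "decision_tree", "naive_bayes")
OVERSAMPLERS = ("none", "smote", "adasyn")
CALIBRATORS = ("none", "isotonic", "sigmoid")

CLINICAL_TER_FLOOR = 0.9
CLINICAL_TAR_FLOOR = 0.2

# harmless estimator-interface quirk when mixing ndarray fit/predict calls
warnings.filterwarnings("ignore",
                        message="X does not have valid feature names")


@dataclass
class TrainingSetting:
    model_id: str
    dt: DataTaskConfig
    oversampler: str = "none"
    calibrator: str = "none"
    threshold: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.model_id not in MODEL_IDS:
            raise ConfigurationError(f"unknown model_id {self.model_id!r}")
        if self.oversampler not in OVERSAMPLERS:
            raise ConfigurationError(f"unknown oversampler {self.oversampler!r}")
        if self.calibrator not in CALIBRATORS:
            raise ConfigurationError(f"unknown calibrator {self.calibrator!r}")

    def tag(self) -> str:
        return (f"{self.model_id}_{self.dt.tag()}"
                f"_os-{self.oversampler}_cal-{self.calibrator}")


@dataclass
class SettingResult:
    setting: TrainingSetting
    ter: float | None
    tar: float
    ter_stay: float | None
    tar_stay: float | None
    auprc: float | None
    threshold_feasible: bool
    passes_clinical: bool

    def as_dict(self) -> dict:
        return {
            "model_id": self.setting.model_id,
            "pw": self.setting.dt.pw, "tw": self.setting.dt.tw,
            "fsf": int(self.setting.dt.fsf),
            "oversampler": self.setting.oversampler,
            "calibrator": self.setting.calibrator,
            "threshold": self.setting.threshold,
            "ter": self.ter, "tar": self.tar,
            "ter_stay": self.ter_stay, "tar_stay": self.tar_stay,
            "auprc": self.auprc,
            "threshold_feasible": self.threshold_feasible,
            "passes_clinical": self.passes_clinical,
        }


# ---------------------------------------------------------------------------
# oversampling
# ---------------------------------------------------------------------------

def _interpolate(seed_rows: np.ndarray, neigh_rows: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    gaps = rng.uniform(size=(len(seed_rows), 1))
    return seed_rows + gaps * (neigh_rows - seed_rows)


def smote(X: np.ndarray, y: np.ndarray, seed: int = 0, k: int = 5
          ) -> tuple[np.ndarray, np.ndarray]:
    """Balance classes by interpolating minority rows towards minority kNNs."""
    return _knn_oversample(X, y, seed, k, adaptive=False)


def adasyn(X: np.ndarray, y: np.ndarray, seed: int = 0, k: int = 5
           ) -> tuple[np.ndarray, np.ndarray]:
    """SMOTE-style synthesis weighted towards minority rows in majority-dense
    neighbourhoods."""
    return _knn_oversample(X, y, seed, k, adaptive=True)


def _knn_oversample(X, y, seed, k, adaptive):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ConfigurationError("oversampling expects a binary label")
    minority = classes[np.argmin(counts)]
    n_needed = int(counts.max() - counts.min())
    Xmin = X[y == minority]
    if n_needed == 0 or len(Xmin) < 2:
        return X.copy(), y.copy()

    rng = np.random.default_rng(seed)
    k_eff = min(k, len(Xmin) - 1)
    nn_min = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xmin)
    _, idx_min = nn_min.kneighbors(Xmin)
    idx_min = idx_min[:, 1:]  # drop self

    if adaptive:
        # weight each minority row by the majority share of its neighbourhood
        k_all = min(k, len(X) - 1)
        nn_all = NearestNeighbors(n_neighbors=k_all + 1).fit(X)
        _, idx_all = nn_all.kneighbors(Xmin)
        maj_share = (y[idx_all[:, 1:]] != minority).mean(axis=1)
        if maj_share.sum() == 0:
            weights = np.full(len(Xmin), 1.0 / len(Xmin))
        else:
            weights = maj_share / maj_share.sum()
    else:
        weights = np.full(len(Xmin), 1.0 / len(Xmin))

    seeds = rng.choice(len(Xmin), size=n_needed, p=weights)
    neigh = idx_min[seeds, rng.integers(0, k_eff, size=n_needed)]
    synthetic = _interpolate(Xmin[seeds], Xmin[neigh], rng)
    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])
    return X_out, y_out


# ---------------------------------------------------------------------------
# learners and calibration
# ---------------------------------------------------------------------------

def make_model(model_id: str, seed: int = 0):
    """Instantiate a registered learner with its ecosystem defaults."""
    if model_id == "gradient_boosting":
        return HistGradientBoostingClassifier(random_state=seed)
    if model_id == "lightgbm":
        from lightgbm import LGBMClassifier
        return LGBMClassifier(random_state=seed, verbosity=-1, n_jobs=1)
    if model_id == "xgboost":
        from xgboost import XGBClassifier
        return XGBClassifier(random_state=seed, n_jobs=1, verbosity=0,
                             eval_metric="logloss")
    if model_id == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1)
    if model_id == "logistic_regression":
        return Pipeline([("scale", StandardScaler()),
                         ("clf", LogisticRegression(max_iter=2000))])
    if model_id == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if model_id == "naive_bayes":
        # multinomial NB needs non-negative inputs; min-max scale first
        return Pipeline([("scale", MinMaxScaler()),
                         ("clf", MultinomialNB())])
    raise ConfigurationError(f"unknown model_id {model_id!r}")


class FittedScorer:
    """A fitted learner plus optional calibration map; scores rows to [0, 1]."""

    def __init__(self, model, calibration=None, feature_names=None):
        self.model = model
        self.calibration = calibration
        self.feature_names = feature_names

    def _raw(self, X) -> np.ndarray:
        return self.model.predict_proba(np.asarray(X, dtype=float))[:, 1]

    def predict_risk(self, X) -> np.ndarray:
        raw = self._raw(X)
        if self.calibration is None:
            return raw
        kind, mapper = self.calibration
        if kind == "isotonic":
            return np.clip(mapper.predict(raw), 0.0, 1.0)
        return mapper.predict_proba(raw.reshape(-1, 1))[:, 1]  # sigmoid


def fit_setting(X_train: np.ndarray, y_train: np.ndarray,
                setting: TrainingSetting,
                X_calib: np.ndarray | None = None,
                y_calib: np.ndarray | None = None,
                feature_names=None) -> FittedScorer:
    """Fit one setting: oversample training rows, fit, fit calibration map.

    Oversampling touches training rows only; calibration is fitted on the
    dedicated calibration partition.
    """
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        raise ConfigurationError("training partition has a single class")
    X, y = np.asarray(X_train, dtype=float), y_train
    if setting.oversampler == "smote":
        X, y = smote(X, y, seed=setting.seed)
    elif setting.oversampler == "adasyn":
        X, y = adasyn(X, y, seed=setting.seed)

    model = make_model(setting.model_id, setting.seed)
    model.fit(X, y)
    scorer = FittedScorer(model, feature_names=feature_names)

    if setting.calibrator != "none":
        if X_calib is None or y_calib is None:
            raise ConfigurationError(
                "calibration requested but no calibration partition given")
        raw = scorer._raw(X_calib)
        if setting.calibrator == "isotonic":
            iso = IsotonicRegression(out_of_bounds="clip")
            iso.fit(raw, np.asarray(y_calib))
            scorer.calibration = ("isotonic", iso)
        else:
            lr = LogisticRegression(max_iter=1000)
            lr.fit(raw.reshape(-1, 1), np.asarray(y_calib))
            scorer.calibration = ("sigmoid", lr)
    return scorer


# ---------------------------------------------------------------------------
# threshold selection
# ---------------------------------------------------------------------------

@dataclass
class SelectedThreshold:
    threshold: float
    ter: float
    tar: float
    feasible: bool  # False when no threshold met the TAR floor


def select_threshold(scores: pd.DataFrame, episodes: pd.DataFrame,
                     window: EvaluationWindow = DEFAULT_WINDOW,
                     tar_floor: float = CLINICAL_TAR_FLOOR,
                     first_only: bool = False) -> SelectedThreshold:
    """Exhaustive threshold sweep maximising TER subject to TAR >= floor.

    Candidates are every distinct validation score plus {0, 1}; ties break
    towards the higher threshold.  When no candidate satisfies the floor the
    max-TAR threshold is returned flagged infeasible.  The sweep exploits the
    fact that an hour's would-be classification does not depend on the
    threshold: only counts of hours with score >= t change.
    """
    if scores.empty:
        raise ConfigurationError("empty validation score set")
    eps_by_stay = dict(tuple(episodes.groupby("stay_id", sort=False))) \
        if len(episodes) else {}
    empty = pd.DataFrame(columns=["stay_id", "onset", "end", "is_first"])

    timely_scores, false_scores, episode_best = [], [], []
    eligible_count = 0
    for stay_id, grp in scores.groupby("stay_id", sort=False):
        eps = eps_by_stay.get(stay_id, empty)
        hours = grp["hour"].to_numpy()
        vals = grp["score"].to_numpy(dtype=float)
        cls, matched = classify_hours(hours, eps, window, first_only)
        timely_scores.append(vals[cls == TIMELY])
        false_scores.append(vals[cls == FALSE])
        eligible = eps[eps["is_first"]] if first_only else eps
        for ep in eligible.itertuples(index=False):
            eligible_count += 1
            in_win = (hours >= ep.onset + window.earliest) & \
                     (hours <= ep.onset + window.latest) & (cls == TIMELY)
            episode_best.append(vals[in_win].max() if in_win.any() else -np.inf)

    timely_scores = np.sort(np.concatenate(timely_scores)) \
        if timely_scores else np.array([])
    false_scores = np.sort(np.concatenate(false_scores)) \
        if false_scores else np.array([])
    episode_best = np.sort(np.asarray(episode_best)) \
        if episode_best else np.array([])

    candidates = np.unique(np.concatenate(
        [scores["score"].to_numpy(dtype=float), [0.0, 1.0]]))
    # descending so that on TER ties the higher threshold wins
    candidates = candidates[::-1]

    def counts_ge(sorted_vals: np.ndarray, t: float) -> int:
        return len(sorted_vals) - np.searchsorted(sorted_vals, t, side="left")

    best = None
    fallback = None
    for t in candidates:
        n_t = counts_ge(timely_scores, t)
        n_f = counts_ge(false_scores, t)
        tar = n_t / (n_t + n_f) if (n_t + n_f) else 0.0
        ter = (counts_ge(episode_best, t) / eligible_count
               if eligible_count else 0.0)
        if tar >= tar_floor and (best is None or ter > best.ter):
            best = SelectedThreshold(float(t), ter, tar, True)
        if fallback is None or tar > fallback.tar:
            fallback = SelectedThreshold(float(t), ter, tar, False)
    return best if best is not None else fallback


# ---------------------------------------------------------------------------
# setting search and ensembling
# ---------------------------------------------------------------------------

@dataclass
class SearchData:
    """Partitioned cohort views used by the setting search.

    ``matrix`` is the engineered feature matrix indexed by (stay_id, hour);
    ``episodes`` the included-stay episode table; ``split`` maps stay_id to
    partition.  Labels and masks are rebuilt per data-task configuration.
    """
    matrix: pd.DataFrame
    episodes: pd.DataFrame
    split: pd.Series
    feature_cols: list[str] = field(default_factory=list)

    def stays_in(self, partition: str) -> set:
        return set(self.split[self.split == partition].index)


def _partition_rows(data: SearchData, partition: str) -> pd.DataFrame:
    stays = data.stays_in(partition)
    sid = data.matrix.index.get_level_values("stay_id")
    return data.matrix[sid.isin(stays)]


def _episodes_in(data: SearchData, partition: str) -> pd.DataFrame:
    stays = data.stays_in(partition)
    if data.episodes.empty:
        return data.episodes
    return data.episodes[data.episodes["stay_id"].isin(stays)]


def _scores_frame(matrix_rows: pd.DataFrame, risk: np.ndarray) -> pd.DataFrame:
    idx = matrix_rows.index
    return pd.DataFrame({"stay_id": idx.get_level_values("stay_id"),
                         "hour": idx.get_level_values("hour"),
                         "score": risk})


def evaluate_setting(data: SearchData, setting: TrainingSetting,
                     window: EvaluationWindow = DEFAULT_WINDOW,
                     tar_floor: float = CLINICAL_TAR_FLOOR,
                     ter_floor: float = CLINICAL_TER_FLOOR,
                     ) -> tuple[FittedScorer, SettingResult]:
    """Fit a setting, choose its threshold on validation, score it there."""
    from .datatask import apply_datatask

    labeled = apply_datatask(data.matrix, data.episodes, setting.dt)
    feats = data.feature_cols
    train_rows = _partition_rows(
        SearchData(labeled, data.episodes, data.split, feats), "train")
    train_rows = train_rows[train_rows["train_mask"] == 1]
    calib_rows = _partition_rows(
        SearchData(labeled, data.episodes, data.split, feats), "calibration")
    val_rows = _partition_rows(
        SearchData(labeled, data.episodes, data.split, feats), "validation")

    scorer = fit_setting(train_rows[feats].to_numpy(dtype=float),
                         train_rows["label"].to_numpy(),
                         setting,
                         calib_rows[feats].to_numpy(dtype=float),
                         calib_rows["label"].to_numpy(),
                         feature_names=feats)

    risk = scorer.predict_risk(val_rows[feats].to_numpy(dtype=float))
    scores = _scores_frame(val_rows, risk)
    val_eps = _episodes_in(data, "validation")
    sel = select_threshold(scores, val_eps, window, tar_floor)
    setting.threshold = sel.threshold

    report = timeliness_from_scores(scores, val_eps, sel.threshold, window)
    tp = timepoint_metrics(risk, val_rows["label"].to_numpy(), sel.threshold)
    passes = (report.ter is not None and report.ter >= ter_floor
              and report.tar >= tar_floor)
    result = SettingResult(setting=setting, ter=report.ter, tar=report.tar,
                           ter_stay=report.ter_stay, tar_stay=report.tar_stay,
                           auprc=tp["auprc"], threshold_feasible=sel.feasible,
                           passes_clinical=passes)
    return scorer, result


def auprc_filter(kept: list) -> list:
    """Keep (scorer, result) pairs whose AUPRC reaches the mean of the kept set.

    Results without an AUPRC (single-class validation labels) are dropped when
    any scored result exists.
    """
    with_auprc = [(s, r) for s, r in kept if r.auprc is not None]
    if not with_auprc:
        return list(kept)
    mean_auprc = float(np.mean([r.auprc for _, r in with_auprc]))
    return [(s, r) for s, r in with_auprc if r.auprc >= mean_auprc]


def search_settings(data: SearchData,
                    model_ids=("lightgbm", "logistic_regression"),
                    pws=(4, 8, 12), tws=(0, "all"), fsfs=(False, True),
                    oversamplers=("none",), calibrators=("none",),
                    window: EvaluationWindow = DEFAULT_WINDOW,
                    ter_floor: float = CLINICAL_TER_FLOOR,
                    tar_floor: float = CLINICAL_TAR_FLOOR,
                    seed: int = 0,
                    ) -> tuple[list[tuple[FittedScorer, SettingResult]],
                               list[SettingResult]]:
    """Three-phase setting search.

    Phase 1 fits every (model, pw, tw, fsf) cell without oversampling or
    calibration, keeps cells clearing the clinical floors on validation and,
    of those, the ones with AUPRC at least the mean AUPRC of the kept set.
    Phase 2 expands survivors over oversampler x calibrator variants and keeps
    variants still clearing the floors.  Returns (survivors with their fitted
    scorers, all phase-1 results for misalignment analysis).
    """
    grid = list(itertools.product(model_ids, pws, tws, fsfs))
    if not grid:
        raise ConfigurationError("empty search grid")

    phase1: list[tuple[FittedScorer, SettingResult]] = []
    for model_id, pw, tw, fsf in grid:
        setting = TrainingSetting(model_id, DataTaskConfig(pw, tw, fsf),
                                  seed=seed)
        phase1.append(evaluate_setting(data, setting, window,
                                       tar_floor, ter_floor))
    all_results = [r for _, r in phase1]

    kept = auprc_filter([(s, r) for s, r in phase1 if r.passes_clinical])

    survivors = list(kept)
    extra = [(os_, cal) for os_, cal
             in itertools.product(oversamplers, calibrators)
             if (os_, cal) != ("none", "none")]
    for _, base in kept:
        for os_, cal in extra:
            variant = replace(base.setting, oversampler=os_, calibrator=cal,
                              threshold=None)
            scorer, result = evaluate_setting(data, variant, window,
                                              tar_floor, ter_floor)
            if result.passes_clinical:
                survivors.append((scorer, result))
    return survivors, all_results


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

@dataclass
class EnsembleModel:
    members: list  # (FittedScorer, threshold) pairs
    mode: str = "hard"
    soft_threshold: float | None = None

    def __post_init__(self):
        if not self.members:
            raise ConfigurationError("ensemble needs at least one member")
        if self.mode not in ("hard", "soft"):
            raise ConfigurationError(f"unknown ensemble mode {self.mode!r}")

    def member_scores(self, X) -> np.ndarray:
        return np.column_stack([s.predict_risk(X) for s, _ in self.members])

    def alarms(self, X) -> np.ndarray:
        """Boolean alarm per row; hard mode uses member-majority with ties
        alarming, soft mode thresholds the mean calibrated score."""
        scores = self.member_scores(X)
        if self.mode == "hard":
            votes = (scores >= np.array([t for _, t in self.members])).sum(axis=1)
            return 2 * votes >= len(self.members)
        mean = scores.mean(axis=1)
        return mean >= self.soft_threshold


def build_ensemble(members: list[tuple[FittedScorer, float]], mode: str,
                   validation_rows: pd.DataFrame | None = None,
                   feature_cols: list[str] | None = None,
                   episodes: pd.DataFrame | None = None,
                   window: EvaluationWindow = DEFAULT_WINDOW,
                   tar_floor: float = CLINICAL_TAR_FLOOR) -> EnsembleModel:
    """Assemble a voting ensemble; soft mode picks its threshold on validation."""
    ens = EnsembleModel(members=list(members), mode=mode)
    if mode == "soft":
        if validation_rows is None or episodes is None:
            raise ConfigurationError(
                "soft voting needs validation data to choose its threshold")
        mean = ens.member_scores(
            validation_rows[feature_cols].to_numpy(dtype=float)).mean(axis=1)
        scores = _scores_frame(validation_rows, mean)
        sel = select_threshold(scores, episodes, window, tar_floor)
        ens.soft_threshold = sel.threshold
    return ens


def ensemble_alarm_frame(ens: EnsembleModel, rows: pd.DataFrame,
                         feature_cols: list[str]) -> pd.DataFrame:
    """Alarm stream (stay_id, hour) of an ensemble over feature-matrix rows."""
    flags = ens.alarms(rows[feature_cols].to_numpy(dtype=float))
    idx = rows.index[flags]
    return pd.DataFrame({"stay_id": idx.get_level_values("stay_id"),
                         "hour": idx.get_level_values("hour")})
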