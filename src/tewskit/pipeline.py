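"""End-to-end orchestration: simulate -> preprocess -> annotate -> split ->
search -> ensemble -> evaluate -> misalignment.

``run_pipeline`` takes a configuration mapping (typically loaded from YAML),
executes every stage in order, writes the artifacts into ``out_dir`` and
returns the final report as a dict.  All randomness flows from the single
``seed`` entry; rerunning with an identical configuration reproduces
identical outputs.  Every artifact embeds the configuration hash and seed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort, datatask, evalmetrics, modeling, preprocess, synthcohort
from .errors import StageError

DEFAULT_CONFIG = {
    "seed": 0,
    "simulate": {"n_stays": 200, "effect_size": 2.0},
    "split_fractions": [0.7, 0.1, 0.1, 0.1],
    "grid": {
        "model_ids": ["lightgbm", "logistic_regression"],
        "pws": [4, 8, 12],
        "tws": [0, "all"],
        "fsfs": [False, True],
        "oversamplers": ["none"],
        "calibrators": ["none"],
    },
    "window": [-8, 0],
    "ter_floor": 0.9,
    "tar_floor": 0.2,
    "ensemble_mode": "hard",
}


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            out[k] = _merge(base[k], v)
        else:
            out[k] = v
    return out


def run_pipeline(config: dict | None = None,
                 out_dir: str | Path | None = None,
                 tables: tuple | None = None) -> dict:
    """Execute the full pipeline; returns the evaluation report dict.

    ``tables`` may supply pre-existing (observations, interventions, stays)
    frames, in which case the simulate stage is skipped.
    """
    cfg = _merge(DEFAULT_CONFIG, config or {})
    seed = int(cfg["seed"])
    tag = {"config_hash": _config_hash(cfg), "seed": seed}
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    def _write_frame(df: pd.DataFrame, name: str):
        if out_dir is not None:
            df.to_csv(out_dir / name, index=False)

    # -- simulate ---------------------------------------------------------
    truth = None
    if tables is None:
        try:
            params = synthcohort.SyntheticCohortParams(
                seed=seed, **cfg["simulate"])
            obs, interv, stays, truth = synthcohort.generate_cohort(params)
        except Exception as exc:
            raise StageError("simulate", str(exc)) from exc
    else:
        obs, interv, stays = tables

    # -- preprocess -------------------------------------------------------
    try:
        matrix, log = preprocess.build_feature_matrix(obs, interv, stays)
    except Exception as exc:
        raise StageError("preprocess", str(exc)) from exc

    # -- annotate ---------------------------------------------------------
    try:
        annotations = cohort.annotate_cohort(
            matrix, obs, interv, stays,
            infection_codes=cfg.get("infection_codes",
                                    synthcohort.DEFAULT_INFECTION_CODES))
        ann_frame = cohort.annotations_to_frame(annotations)
        episodes = cohort.episodes_frame(annotations)
        included = [a for a in annotations if not a.excluded]
    except Exception as exc:
        raise StageError("annotate", str(exc)) from exc
    _write_frame(ann_frame, "annotations.csv")

    included_ids = [a.stay_id for a in included]
    sid = matrix.index.get_level_values("stay_id")
    matrix = matrix[sid.isin(included_ids)]

    # -- split ------------------------------------------------------------
    try:
        shock_flags = {a.stay_id: a.has_shock for a in included}
        split = datatask.split_cohort(included_ids,
                                      tuple(cfg["split_fractions"]),
                                      seed=seed, shock_flags=shock_flags)
    except Exception as exc:
        raise StageError("split", str(exc)) from exc
    _write_frame(datatask.split_to_frame(split), "split.csv")

    window = evalmetrics.EvaluationWindow(*cfg["window"])
    data = modeling.SearchData(matrix=matrix, episodes=episodes, split=split,
                               feature_cols=preprocess.feature_columns(matrix))

    # -- search -----------------------------------------------------------
    grid = cfg["grid"]
    try:
        survivors, all_results = modeling.search_settings(
            data, model_ids=tuple(grid["model_ids"]), pws=tuple(grid["pws"]),
            tws=tuple(grid["tws"]), fsfs=tuple(grid["fsfs"]),
            oversamplers=tuple(grid.get("oversamplers", ("none",))),
            calibrators=tuple(grid.get("calibrators", ("none",))),
            window=window, ter_floor=cfg["ter_floor"],
            tar_floor=cfg["tar_floor"], seed=seed)
    except Exception as exc:
        raise StageError("search", str(exc)) from exc
    settings_records = [r.as_dict() for _, r in survivors]
    phase1_records = [r.as_dict() for r in all_results]
    if out_dir is not None:
        with open(out_dir / "settings.json", "w") as fh:
            json.dump({**tag, "survivors": settings_records,
                       "phase1": phase1_records}, fh, indent=2, default=str)

    # -- ensemble ---------------------------------------------------------
    try:
        if not survivors:
            raise ValueError("no setting cleared the clinical floors")
        members = [(s, r.setting.threshold) for s, r in survivors]
        val_rows = matrix[matrix.index.get_level_values("stay_id")
                          .isin(split[split == "validation"].index)]
        val_eps = episodes[episodes["stay_id"]
                           .isin(split[split == "validation"].index)] \
            if len(episodes) else episodes
        ensemble = modeling.build_ensemble(
            members, cfg["ensemble_mode"], validation_rows=val_rows,
            feature_cols=data.feature_cols, episodes=val_eps, window=window,
            tar_floor=cfg["tar_floor"])
    except Exception as exc:
        raise StageError("ensemble", str(exc)) from exc

    # -- evaluate ---------------------------------------------------------
    try:
        test_ids = split[split == "test"].index
        test_rows = matrix[matrix.index.get_level_values("stay_id")
                           .isin(test_ids)]
        test_eps = episodes[episodes["stay_id"].isin(test_ids)] \
            if len(episodes) else episodes
        alarms = modeling.ensemble_alarm_frame(ensemble, test_rows,
                                               data.feature_cols)
        classification = evalmetrics.classify_alarms(alarms, test_eps, window)
        report = evalmetrics.compute_timeliness(classification, test_eps,
                                                window)
        first_report = evalmetrics.compute_timeliness(
            evalmetrics.classify_alarms(alarms, test_eps, window,
                                        first_only=True),
            test_eps, window, first_only=True)
        shock_by_stay = pd.Series(
            {s: shock_flags[s] for s in test_ids}).sort_index()
        screening = evalmetrics.cohort_metrics(alarms, shock_by_stay)
        sweep = evalmetrics.sweep_windows(alarms, test_eps)
        interv_hours = pd.Series({a.stay_id: a.intervention_start_hour
                                  for a in included if a.stay_id in
                                  set(test_ids)})
        pre_frac = evalmetrics.pre_intervention_fraction(
            classification, test_eps, interv_hours, window)
        failure = evalmetrics.failure_analysis(alarms, test_eps, test_rows,
                                               window)
        member_test = []
        X_test = test_rows[data.feature_cols].to_numpy(dtype=float)
        for scorer, res in survivors:
            risk = scorer.predict_risk(X_test)
            m_rep = evalmetrics.timeliness_from_scores(
                modeling._scores_frame(test_rows, risk), test_eps,
                res.setting.threshold, window)
            member_test.append({"setting": res.setting.tag(),
                                "ter": m_rep.ter, "tar": m_rep.tar})
    except Exception as exc:
        raise StageError("evaluate", str(exc)) from exc

    # -- misalignment -----------------------------------------------------
    misalign = None
    try:
        frame = pd.DataFrame(phase1_records)
        frame = frame[frame["auprc"].notna()]
        if len(frame):
            meets = (frame["ter"].fillna(0) >= cfg["ter_floor"]) & \
                    (frame["tar"] >= cfg["tar_floor"])
            if meets.any():
                p, table = evalmetrics.misalignment(
                    frame, ["auprc"], cfg["ter_floor"], cfg["tar_floor"])
                misalign = {"p": p,
                            "table": table.to_dict(orient="records")}
    except Exception as exc:
        raise StageError("misalign", str(exc)) from exc

    result = {
        **tag,
        "n_stays": len(stays),
        "n_included": len(included_ids),
        "n_shock_stays": int(sum(shock_flags.values())),
        "n_surviving_settings": len(survivors),
        "member_test": member_test,
        "timeliness_all": report.as_dict(),
        "timeliness_first": first_report.as_dict(),
        "cohort_metrics": screening,
        "window_sweep": sweep.to_dict(orient="records"),
        "pre_intervention_fraction": pre_frac,
        "failure_analysis": failure,
        "misalignment": misalign,
        "preprocess_log_lines": len(log),
    }
    if truth is not None and cfg.get("verify_truth", False):
        result["onset_recovery"] = synthcohort.verify_ground_truth(
            obs, interv, stays, truth)
    if out_dir is not None:
        with open(out_dir / "report.json", "w") as fh:
            json.dump(result, fh, indent=2, default=str)
    return result
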