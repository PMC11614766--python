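import math

import numpy as np
import pandas as pd
import pytest

from tewskit import vocab
from tewskit.errors import ConfigurationError
from tewskit.preprocess import (adjust_time_errors, build_feature_matrix,
                                compute_urine_output, engineer_features,
                                impute_features, impute_gcs_components,
                                remove_outliers, resample_hourly)


def obs_frame(rows):
    return pd.DataFrame(rows,
                        columns=["stay_id", "variable", "minutes", "value",
                                 "unit"])


def stays_frame(stay_hours):
    rows = []
    for sid, T in stay_hours.items():
        rows.append((sid, "2023-01-01T00:00:00",
                     f"2023-01-01T00:00:00", 60.0, "F", "I10", ""))
    df = pd.DataFrame(rows, columns=["stay_id", "admit_iso", "discharge_iso",
                                     "age", "gender", "icd_codes",
                                     "culture_minutes"])
    df["discharge_iso"] = [
        (pd.Timestamp("2023-01-01") + pd.Timedelta(hours=T)).isoformat()
        for T in stay_hours.values()]
    return df


def interv_frame(rows=()):
    return pd.DataFrame(rows,
                        columns=["stay_id", "kind", "agent", "start_min",
                                 "end_min", "rate", "rate_unit"])


class TestRemoveOutliers:
    def test_out_of_range_record_dropped(self):
        obs = obs_frame([("A", "heart_rate", 10, 310.0, "bpm"),
                         ("A", "heart_rate", 20, 90.0, "bpm")])
        kept = remove_outliers(obs, {"heart_rate": (0, 300)})
        assert kept["value"].tolist() == [90.0]

    def test_empty_input_passes_through(self):
        assert remove_outliers(obs_frame([]), {}).empty

    def test_infinite_bounds_keep_everything(self):
        rng = np.random.default_rng(0)
        obs = obs_frame([("A", "heart_rate", i, float(v), "bpm")
                         for i, v in enumerate(rng.normal(80, 50, 100))])
        kept = remove_outliers(obs, {"heart_rate": (-math.inf, math.inf)})
        assert len(kept) == 100

    def test_unknown_variable_raises_naming_it(self):
        obs = obs_frame([("A", "lactate", 5, 1.0, "mmol/L")])
        with pytest.raises(ConfigurationError, match="lactate"):
            remove_outliers(obs, {"heart_rate": (0, 300)})

    def test_idempotent(self):
        obs = obs_frame([("A", "heart_rate", 10, 310.0, "bpm"),
                         ("A", "heart_rate", 20, 90.0, "bpm")])
        once = remove_outliers(obs, vocab.DEFAULT_OUTLIER_CRITERIA)
        twice = remove_outliers(once, vocab.DEFAULT_OUTLIER_CRITERIA)
        pd.testing.assert_frame_equal(once, twice)

    def test_input_not_mutated(self):
        obs = obs_frame([("A", "heart_rate", 10, 310.0, "bpm")])
        before = obs.copy()
        remove_outliers(obs, {"heart_rate": (0, 300)})
        pd.testing.assert_frame_equal(obs, before)


class TestAdjustTimeErrors:
    def test_record_days_before_admission_dropped(self):
        stays = stays_frame({"A": 48})
        obs = obs_frame([("A", "lactate", -3 * 24 * 60, 1.0, "mmol/L"),
                         ("A", "lactate", 60, 1.5, "mmol/L")])
        out, _ = adjust_time_errors(obs, interv_frame(), stays)
        assert out["value"].tolist() == [1.5]

    def test_interval_ending_after_discharge_dropped(self):
        stays = stays_frame({"A": 48})
        interv = interv_frame([("A", "vasopressor", "norepi", 100.0,
                                48 * 60 + 60.0, 0.1, "ug/kg/min")])
        _, out = adjust_time_errors(obs_frame([]), interv, stays)
        assert out.empty

    def test_observation_at_admission_retained(self):
        stays = stays_frame({"A": 48})
        obs = obs_frame([("A", "lactate", 0.0, 1.0, "mmol/L")])
        out, _ = adjust_time_errors(obs, interv_frame(), stays)
        assert len(out) == 1

    def test_point_record_outside_stay_dropped(self):
        stays = stays_frame({"A": 48})
        obs = obs_frame([("A", "lactate", 48 * 60 + 30, 1.0, "mmol/L")])
        out, _ = adjust_time_errors(obs, interv_frame(), stays)
        assert out.empty


class TestGcsImputation:
    def test_hand_traced_fill(self):
        recs = obs_frame([("A", "gcs_eye", 10, 4, "points"),
                          ("A", "gcs_motor", 10, 6, "points"),
                          ("A", "gcs_verbal", 20, 5, "points")])
        out, prov = impute_gcs_components(recs)
        at = lambda t, v: out[(out["minutes"] == t)
                              & (out["variable"] == v)]["value"].iloc[0]
        assert at(10, "gcs_verbal") == 5  # backfilled
        assert at(20, "gcs_eye") == 4 and at(20, "gcs_motor") == 6
        assert prov == []

    def test_complete_records_identity(self):
        recs = obs_frame([("A", v, t, 4, "points")
                          for t in (10, 20)
                          for v in vocab.GCS_COMPONENTS])
        out, _ = impute_gcs_components(recs)
        assert len(out) == 6
        assert (out["value"] == 4).all()

    def test_never_recorded_component_logged(self):
        recs = obs_frame([("A", "gcs_motor", 10, 6, "points")])
        out, prov = impute_gcs_components(recs)
        assert set(out["variable"]) == {"gcs_motor"}
        assert any("gcs_eye" in line for line in prov)
        assert any("gcs_verbal" in line for line in prov)

    def test_rejects_non_gcs_variables(self):
        recs = obs_frame([("A", "lactate", 10, 1.0, "mmol/L")])
        with pytest.raises(ConfigurationError):
            impute_gcs_components(recs)


class TestUrineCorrection:
    def test_cumulative_subtraction(self):
        obs = obs_frame([("A", "irrigant_in", 30, 200.0, "mL"),
                         ("A", "irrigant_out", 60, 500.0, "mL")])
        out, log = compute_urine_output(obs)
        assert out["variable"].tolist() == ["urine_out"]
        assert out["value"].iloc[0] == 300.0
        assert log == []

    def test_no_prior_irrigant_in_counts_as_zero(self):
        obs = obs_frame([("A", "irrigant_out", 60, 400.0, "mL")])
        out, _ = compute_urine_output(obs)
        assert out["value"].iloc[0] == 400.0

    def test_no_irrigants_is_identity(self):
        obs = obs_frame([("A", "urine_out", 60, 50.0, "mL")])
        out, _ = compute_urine_output(obs)
        pd.testing.assert_frame_equal(out, obs)

    def test_negative_volume_clamped_and_logged(self):
        obs = obs_frame([("A", "irrigant_in", 30, 500.0, "mL"),
                         ("A", "irrigant_out", 60, 200.0, "mL")])
        out, log = compute_urine_output(obs)
        assert out["value"].iloc[0] == 0.0
        assert len(log) == 1 and "clamped" in log[0]


class TestResample:
    def test_bin_statistics(self):
        stays = stays_frame({"A": 6})
        obs = obs_frame([("A", "heart_rate", 3 * 60 + 5, 80.0, "bpm"),
                         ("A", "heart_rate", 3 * 60 + 40, 90.0, "bpm")])
        grid = resample_hourly(obs, interv_frame(), stays)
        row = grid.loc[("A", 3)]
        assert row["heart_rate__mean"] == 85.0
        assert row["heart_rate__min"] == 80.0
        assert row["heart_rate__max"] == 90.0
        assert row["heart_rate__presence"] == 1

    def test_interval_overlap_hours(self):
        stays = stays_frame({"A": 6})
        interv = interv_frame([("A", "vasopressor", "norepi", 90.0, 200.0,
                                0.1, "ug/kg/min")])
        grid = resample_hourly(obs_frame([]), interv, stays)
        active = grid["vasopressor__active"].loc["A"]
        assert active.loc[[1, 2, 3]].tolist() == [1, 1, 1]
        assert active.loc[[0, 4, 5]].tolist() == [0, 0, 0]

    def test_empty_bin_left_missing(self):
        stays = stays_frame({"A": 6})
        obs = obs_frame([("A", "lactate", 30, 1.0, "mmol/L")])
        grid = resample_hourly(obs, interv_frame(), stays)
        assert np.isnan(grid.loc[("A", 5), "lactate__mean"])
        assert grid.loc[("A", 5), "lactate__presence"] == 0

    def test_admission_boundary_belongs_to_hour_zero(self):
        stays = stays_frame({"A": 3})
        obs = obs_frame([("A", "heart_rate", 0.0, 70.0, "bpm")])
        grid = resample_hourly(obs, interv_frame(), stays)
        assert grid.loc[("A", 0), "heart_rate__mean"] == 70.0

    def test_conservation_against_raw_bins(self):
        rng = np.random.default_rng(5)
        rows = [("A", "heart_rate", float(rng.uniform(0, 24 * 60)),
                 float(rng.normal(80, 10)), "bpm") for _ in range(200)]
        stays = stays_frame({"A": 24})
        obs = obs_frame(rows)
        grid = resample_hourly(obs, interv_frame(), stays)
        for h in range(24):
            raw = [v for _, _, t, v, _ in rows if int(t // 60) == h]
            cell = grid.loc[("A", h)]
            if raw:
                assert cell["heart_rate__mean"] == pytest.approx(np.mean(raw))
                assert cell["heart_rate__max"] == max(raw)
                assert cell["heart_rate__presence"] == 1
            else:
                assert cell["heart_rate__presence"] == 0


class TestImputeAndSlopes:
    def _grid(self, var, values, T=8):
        stays = stays_frame({"A": T})
        rows = [("A", var, h * 60 + 5, v, vocab.CANONICAL_UNITS[var])
                for h, v in values.items()]
        return resample_hourly(obs_frame(rows), interv_frame(), stays)

    def test_vital_linear_interpolation(self):
        grid = impute_features(self._grid("sbp", {2: 120.0, 6: 100.0}))
        assert grid.loc[("A", 4), "sbp__mean"] == pytest.approx(110.0)
        # edge extension by nearest value
        assert grid.loc[("A", 0), "sbp__mean"] == 120.0
        assert grid.loc[("A", 7), "sbp__mean"] == 100.0

    def test_lab_fill_from_single_measurement(self):
        grid = impute_features(self._grid("creatinine", {5: 1.2}))
        assert (grid["creatinine__mean"] == 1.2).all()
        assert grid["creatinine__presence"].sum() == 1

    def test_absent_variable_becomes_zeros(self):
        grid = impute_features(self._grid("sbp", {2: 120.0}))
        assert (grid["lactate__mean"] == 0.0).all()
        assert (grid["lactate__presence"] == 0).all()

    def test_imputation_idempotent(self):
        grid = self._grid("sbp", {2: 120.0, 6: 100.0})
        once = impute_features(grid)
        twice = impute_features(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_interpolated_values_within_bracketing_measurements(self):
        rng = np.random.default_rng(9)
        measured = {int(h): float(rng.uniform(80, 160))
                    for h in rng.choice(24, size=6, replace=False)}
        grid = impute_features(self._grid("sbp", measured, T=24))
        hours = sorted(measured)
        for lo, hi in zip(hours, hours[1:]):
            seg = grid.loc["A"].loc[lo:hi, "sbp__mean"]
            assert seg.min() >= min(measured[lo], measured[hi]) - 1e-9
            assert seg.max() <= max(measured[lo], measured[hi]) + 1e-9

    def test_slope_example_and_insufficient_history(self):
        grid = impute_features(self._grid(
            "lactate", {0: 1.0, 1: 1.0, 2: 1.0, 3: 1.0, 4: 1.4}))
        out = engineer_features(grid)
        assert out.loc[("A", 4), "lactate__slope1"] == pytest.approx(0.4)
        assert out.loc[("A", 2), "lactate__slope3"] == 0.0  # h - K < 0

    def test_constant_series_has_zero_slopes(self):
        grid = impute_features(self._grid("sbp", {h: 120.0 for h in range(8)}))
        out = engineer_features(grid)
        for k in (1, 3, 5):
            assert (out[f"sbp__slope{k}"] == 0.0).all()

    def test_slope1_telescopes(self):
        rng = np.random.default_rng(3)
        vals = {h: float(rng.normal(120, 10)) for h in range(8)}
        out = engineer_features(impute_features(self._grid("sbp", vals)))
        s = out.loc["A", "sbp__slope1"]
        total = sum(s.loc[h] for h in range(3, 8))
        assert total == pytest.approx(vals[7] - vals[2])


class TestFullMatrix:
    def test_presence_flags_partition_measured_hours(self, small_cohort):
        matrix, obs = small_cohort["matrix"], small_cohort["obs"]
        lact = obs[obs["variable"] == "lactate"].copy()
        lact["hour"] = (lact["minutes"] // 60).astype(int)
        measured = set(zip(lact["stay_id"], lact["hour"]))
        presence = matrix["lactate__presence"]
        for (sid, h), flag in presence.items():
            assert flag in (0, 1)
            assert (flag == 1) == ((sid, h) in measured)

    def test_no_missing_values_after_pipeline(self, small_cohort):
        matrix = small_cohort["matrix"]
        numeric = matrix.drop(columns=["gender_male"], errors="ignore")
        assert not numeric.isna().any().any()

    def test_summary_ordering_where_measured(self, small_cohort):
        m = small_cohort["matrix"]
        measured = m["heart_rate__presence"] == 1
        assert (m.loc[measured, "heart_rate__min"]
                <= m.loc[measured, "heart_rate__mean"] + 1e-9).all()
        assert (m.loc[measured, "heart_rate__mean"]
                <= m.loc[measured, "heart_rate__max"] + 1e-9).all()
        assert (m.loc[measured, "heart_rate__min"]
                <= m.loc[measured, "heart_rate__median"] + 1e-9).all()
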