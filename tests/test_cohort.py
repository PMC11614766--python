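import numpy as np
import pandas as pd
import pytest

from conftest import make_stay_matrix
from tewskit.cohort import (StayAnnotation, annotate_stay,
                            check_required_variables, compute_sofa,
                            detect_sepsis_onset, detect_shock_episodes,
                            detect_suspected_infection,
                            first_intervention_time, in_shock_hours)
from tewskit.errors import ConfigurationError


def obs_with(variables):
    rows = [("A", v, 10.0, 1.0, "u") for v in variables]
    return pd.DataFrame(rows, columns=["stay_id", "variable", "minutes",
                                       "value", "unit"])


ALL_REQUIRED = ["sbp", "dbp", "pao2", "fio2", "gcs_motor", "bilirubin",
                "platelets", "creatinine", "lactate"]


class TestRequiredVariables:
    def test_complete_stay_passes(self):
        assert check_required_variables(obs_with(ALL_REQUIRED))

    def test_missing_lactate_fails(self):
        short = [v for v in ALL_REQUIRED if v != "lactate"]
        assert not check_required_variables(obs_with(short))

    def test_empty_stay_fails(self):
        assert not check_required_variables(obs_with([]))

    def test_any_gcs_component_counts(self):
        swapped = [v if v != "gcs_motor" else "gcs_verbal"
                   for v in ALL_REQUIRED]
        assert check_required_variables(obs_with(swapped))


class TestSuspectedInfection:
    def test_all_three_conditions(self):
        assert detect_suspected_infection(True, [120.0], ["A419"], ["A41"])

    def test_no_matching_code(self):
        assert not detect_suspected_infection(True, [120.0], ["I10"], ["A41"])

    def test_no_antibiotics(self):
        assert not detect_suspected_infection(False, [120.0], ["A419"],
                                              ["A41"])

    def test_no_culture(self):
        assert not detect_suspected_infection(True, [], ["A419"], ["A41"])

    def test_empty_code_set_is_config_error(self):
        with pytest.raises(ConfigurationError):
            detect_suspected_infection(True, [120.0], ["A419"], [])


# Independent transcription of the consensus organ-dysfunction tiers, written
# as literal dict lookups to cross-check the vectorised implementation.
def reference_sofa_row(pf, ventilated, platelets, bilirubin, map_, vaso,
                       rate, gcs, creatinine):
    resp = 0 if pf >= 400 else 1 if pf >= 300 else 2
    if pf < 200 and ventilated:
        resp = 3 if pf >= 100 else 4
    coag = 0 if platelets >= 150 else 1 if platelets >= 100 else \
        2 if platelets >= 50 else 3 if platelets >= 20 else 4
    liver = 0 if bilirubin < 1.2 else 1 if bilirubin < 2.0 else \
        2 if bilirubin < 6.0 else 3 if bilirubin < 12.0 else 4
    if vaso:
        cardio = 2 if rate <= 0 else (3 if rate <= 0.1 else 4)
    else:
        cardio = 0 if map_ >= 70 else 1
    cns = 0 if gcs >= 15 else 1 if gcs >= 13 else 2 if gcs >= 10 else \
        3 if gcs >= 6 else 4
    renal = 0 if creatinine < 1.2 else 1 if creatinine < 2.0 else \
        2 if creatinine < 3.5 else 3 if creatinine < 5.0 else 4
    return resp, coag, liver, cardio, cns, renal


class TestSofa:
    def test_normal_physiology_scores_zero(self):
        panel = compute_sofa(make_stay_matrix(4))
        assert (panel["total"] == 0).all()

    def test_platelets_90_scores_coagulation_two(self):
        panel = compute_sofa(make_stay_matrix(2, platelets=90.0))
        assert (panel["coagulation"] == 2).all()
        assert (panel["total"] == 2).all()

    def test_gcs_floor_scores_cns_four(self):
        panel = compute_sofa(make_stay_matrix(
            2, gcs_eye=1.0, gcs_motor=1.0, gcs_verbal=1.0))
        assert (panel["cns"] == 4).all()

    def test_vasopressor_without_rate_maps_to_minimum_tier(self):
        panel = compute_sofa(make_stay_matrix(2, vasopressor__active=1,
                                              vasopressor__rate=0.0))
        assert (panel["cardiovascular"] == 2).all()

    def test_high_dose_vasopressor_scores_four(self):
        panel = compute_sofa(make_stay_matrix(2, vasopressor__active=1,
                                              vasopressor__rate=0.2))
        assert (panel["cardiovascular"] == 4).all()

    def test_matches_reference_on_random_panels(self):
        rng = np.random.default_rng(17)
        n = 1000
        m = make_stay_matrix(
            n,
            pao2=rng.uniform(40, 120, n),
            fio2=rng.uniform(0.21, 1.0, n),
            ventilation__active=rng.integers(0, 2, n),
            platelets=rng.uniform(5, 400, n),
            bilirubin=rng.uniform(0.2, 20, n),
            map=rng.uniform(40, 110, n),
            vasopressor__active=rng.integers(0, 2, n),
            vasopressor__rate=rng.choice([0.0, 0.05, 0.2], n),
            gcs_eye=rng.integers(1, 5, n).astype(float),
            gcs_motor=rng.integers(1, 7, n).astype(float),
            gcs_verbal=rng.integers(1, 6, n).astype(float),
            creatinine=rng.uniform(0.4, 8.0, n),
            urine_out=1000.0,  # hourly volumes keeping 24-h totals normal
        )
        panel = compute_sofa(m)
        for h in range(n):
            row = m.iloc[h]
            pf = row["pao2__mean"] / row["fio2__mean"]
            gcs = (row["gcs_eye__mean"] + row["gcs_motor__mean"]
                   + row["gcs_verbal__mean"])
            expected = reference_sofa_row(
                pf, row["ventilation__active"], row["platelets__mean"],
                row["bilirubin__mean"], row["map__mean"],
                row["vasopressor__active"], row["vasopressor__rate"], gcs,
                row["creatinine__mean"])
            got = tuple(panel.iloc[h][["respiration", "coagulation", "liver",
                                       "cardiovascular", "cns", "renal"]])
            assert got == expected, f"hour {h}"
            assert panel.iloc[h]["total"] == sum(expected)

    def test_low_rolling_urine_raises_renal_tier(self):
        m = make_stay_matrix(30, urine_out=10.0)  # 240 mL / 24 h -> oliguria
        panel = compute_sofa(m)
        assert (panel["renal"].iloc[24:] == 3).all()
        assert (panel["renal"].iloc[:23] == 0).all()  # no full day yet


class TestSepsisOnset:
    def test_first_crossing(self):
        sofa = pd.DataFrame({"total": [0, 1, 2, 3]})
        assert detect_sepsis_onset(sofa, suspected=True) == 2

    def test_requires_suspected_infection(self):
        sofa = pd.DataFrame({"total": [3, 3, 3]})
        assert detect_sepsis_onset(sofa, suspected=False) is None

    def test_never_reached(self):
        sofa = pd.DataFrame({"total": [0, 1, 1]})
        assert detect_sepsis_onset(sofa, suspected=True) is None


def shock_matrix(n, lactate_hours, vaso_hours):
    lact = np.full(n, 1.0)
    lact[list(lactate_hours)] = 2.5
    vaso = np.zeros(n, dtype=int)
    vaso[list(vaso_hours)] = 1
    return make_stay_matrix(n, lactate=lact, vasopressor__active=vaso)


class TestShockEpisodes:
    def test_conjunction_intersection_run(self):
        m = shock_matrix(25, range(10, 15), range(12, 21))
        eps = detect_shock_episodes(m, sepsis_onset=0)
        assert [(e.onset_hour, e.end_hour) for e in eps] == [(12, 14)]

    def test_lactate_never_elevated_gives_no_episode(self):
        m = shock_matrix(25, [], range(12, 21))
        assert detect_shock_episodes(m, sepsis_onset=0) == []

    def test_recurrence_splits_runs_and_flags_first(self):
        m = shock_matrix(40, list(range(12, 16)) + [30, 31],
                         list(range(12, 16)) + [30, 31])
        eps = detect_shock_episodes(m, sepsis_onset=0)
        assert [(e.onset_hour, e.end_hour) for e in eps] == [(12, 15),
                                                             (30, 31)]
        assert [e.is_first for e in eps] == [True, False]

    def test_hours_before_sepsis_onset_gated_out(self):
        m = shock_matrix(25, range(5, 15), range(5, 15))
        eps = detect_shock_episodes(m, sepsis_onset=10)
        assert [(e.onset_hour, e.end_hour) for e in eps] == [(10, 14)]

    def test_no_sepsis_means_no_episodes(self):
        m = shock_matrix(25, range(5, 15), range(5, 15))
        assert detect_shock_episodes(m, sepsis_onset=None) == []

    def test_raising_lactate_threshold_shrinks_hours(self):
        rng = np.random.default_rng(2)
        m = make_stay_matrix(50, lactate=rng.uniform(0, 6, 50),
                             vasopressor__active=rng.integers(0, 2, 50))
        prev = None
        for thr in (1.0, 2.0, 3.0, 4.0):
            hours = set(np.flatnonzero(in_shock_hours(m, thr)))
            if prev is not None:
                assert hours <= prev
            prev = hours

    def test_episode_union_covers_in_shock_hours(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            n = 40
            m = make_stay_matrix(
                n, lactate=rng.choice([1.0, 2.5], n),
                vasopressor__active=rng.integers(0, 2, n))
            eps = detect_shock_episodes(m, sepsis_onset=0)
            union = set()
            for e in eps:
                hours = set(range(e.onset_hour, e.end_hour + 1))
                assert not (union & hours)  # disjoint
                union |= hours
            assert union == set(np.flatnonzero(in_shock_hours(m)))
            assert sum(e.is_first for e in eps) == (1 if eps else 0)


class TestAnnotateStay:
    CODES = ["A41"]

    def _annotate(self, matrix, observations=None, suspected=True):
        obs = observations if observations is not None else obs_with(
            ALL_REQUIRED)
        return annotate_stay("A", matrix.droplevel("stay_id"), obs,
                             has_antibiotics=suspected,
                             culture_times=[60.0] if suspected else [],
                             diagnosis_codes=["A419"] if suspected else [],
                             infection_codes=self.CODES)

    def test_same_hour_shock_and_sepsis_retained(self):
        # vasopressor at hour 3 makes sepsis onset 3 == first shock hour:
        # "prior to sepsis" is strict, so the stay is kept
        m = shock_matrix(20, range(3, 6), range(3, 6))
        ann = self._annotate(m)
        assert not ann.excluded
        assert ann.sepsis_onset_hour == 3

    def test_shock_strictly_before_sepsis_excluded(self, monkeypatch):
        # under consensus scoring a vasopressor hour always reaches SOFA >= 2,
        # so the screening branch is exercised with an injected SOFA panel
        # whose first crossing comes after the ungated shock hours
        import tewskit.cohort as cohort_mod
        n = 20
        delayed = pd.DataFrame({"total": [0] * 8 + [3] * (n - 8)})
        monkeypatch.setattr(cohort_mod, "compute_sofa",
                            lambda m: delayed)
        m = shock_matrix(n, range(5, 8), range(5, 8))
        ann = self._annotate(m)
        assert ann.excluded and ann.reason == "shock_before_sepsis"

    def test_missing_required_variables_excluded(self):
        ann = self._annotate(make_stay_matrix(10), observations=obs_with([]))
        assert ann.excluded and ann.reason == "missing_required_variables"

    def test_suspected_without_organ_dysfunction_excluded(self):
        ann = self._annotate(make_stay_matrix(10))
        assert ann.excluded and ann.reason == "no_sepsis"

    def test_sepsis_then_shock_retained(self):
        n = 30
        lact = np.full(n, 1.0)
        lact[10:15] = 2.5
        vaso = np.zeros(n, dtype=int)
        vaso[10:15] = 1
        m = make_stay_matrix(n, lactate=lact, vasopressor__active=vaso,
                             platelets=90.0)  # sepsis from hour 0
        ann = self._annotate(m)
        assert not ann.excluded
        assert ann.sepsis_onset_hour == 0
        assert [(e.onset_hour, e.end_hour) for e in ann.episodes] == [(10, 14)]


class TestFirstIntervention:
    def test_overlap_minimum(self):
        vaso = np.zeros(30, dtype=int)
        vaso[10:21] = 1
        fluid = np.zeros(30, dtype=int)
        fluid[[12, 15]] = 1
        m = make_stay_matrix(30, vasopressor__active=vaso,
                             fluid__active=fluid)
        assert first_intervention_time(m) == 12

    def test_vasopressor_alone_gives_none(self):
        vaso = np.zeros(30, dtype=int)
        vaso[10:21] = 1
        m = make_stay_matrix(30, vasopressor__active=vaso)
        assert first_intervention_time(m) is None

    def test_non_overlapping_administration_gives_none(self):
        vaso = np.zeros(30, dtype=int)
        vaso[9:] = 1
        fluid = np.zeros(30, dtype=int)
        fluid[5] = 1
        m = make_stay_matrix(30, vasopressor__active=vaso,
                             fluid__active=fluid)
        assert first_intervention_time(m) is None
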