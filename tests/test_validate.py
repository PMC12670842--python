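import numpy as np
import pandas as pd
import pytest

from demlife import CaseDefinition, SimConfig, simulate_cohort
from demlife._time import ym, ym_to_yq, yq
from demlife.errors import InputFormatError, WindowError
from demlife.synthclaims import GompertzParams
from demlife.validate import build_episodes, validate_diagnoses

from conftest import make_panel

B2006 = ym(2006, 1)
COV = (ym(2004, 1), ym(2008, 12))  # wash-out 2004-05, follow-up 2006-08


def person(pid, birth_year=1935, death=None, cov=COV, sex="m"):
    return (pid, sex, ym(birth_year, 6), death, cov[0], cov[1])


class TestValidateDiagnoses:
    def test_single_unverified_outpatient_is_rejected(self):
        panel = make_panel(
            [person(1)], [(1, yq(2006, 3), "F03", "outpatient", "unverified")]
        )
        assert validate_diagnoses(panel, CaseDefinition()).empty

    def test_two_verified_records_same_quarter_valid_in_that_quarter(self):
        panel = make_panel(
            [person(1)],
            [(1, yq(2006, 3), "G30", "outpatient", "verified"),
             (1, yq(2006, 3), "G30", "outpatient", "verified")],
        )
        first = validate_diagnoses(panel, CaseDefinition())
        assert first.loc[1] == ym(2006, 8)  # middle month of Q3

    def test_single_record_in_death_quarter_is_valid(self):
        panel = make_panel(
            [person(1, death=ym(2007, 4), cov=(COV[0], ym(2007, 4)))],
            [(1, yq(2007, 2), "F01", "inpatient_discharge", "unverified")],
        )
        first = validate_diagnoses(panel, CaseDefinition())
        assert first.loc[1] == ym(2007, 4)  # clamped to the death month

    def test_single_admissible_record_alive_is_rejected(self):
        panel = make_panel(
            [person(1)], [(1, yq(2006, 3), "F03", "outpatient", "verified")]
        )
        assert validate_diagnoses(panel, CaseDefinition()).empty

    def test_two_records_in_different_quarters_validate_the_first(self):
        panel = make_panel(
            [person(1)],
            [(1, yq(2006, 2), "F03", "outpatient", "verified"),
             (1, yq(2008, 1), "F00", "inpatient_secondary", "unverified")],
        )
        first = validate_diagnoses(panel, CaseDefinition())
        assert first.loc[1] == ym(2006, 5)

    def test_inpatient_admissible_regardless_of_status(self):
        panel = make_panel(
            [person(1)],
            [(1, yq(2006, 2), "F03", "inpatient_discharge", "unverified"),
             (1, yq(2006, 4), "F03", "inpatient_secondary", "unverified")],
        )
        assert len(validate_diagnoses(panel, CaseDefinition())) == 1

    def test_code_matching_is_dot_stripped_prefix(self):
        panel = make_panel(
            [person(1), person(2)],
            [(1, yq(2006, 2), "F051", "outpatient", "verified"),
             (1, yq(2006, 3), "F05.1", "outpatient", "verified"),
             # F05.0 (delirium not superimposed on dementia) must not match
             (2, yq(2006, 2), "F050", "outpatient", "verified"),
             (2, yq(2006, 3), "F05.0", "outpatient", "verified")],
        )
        first = validate_diagnoses(panel, CaseDefinition())
        assert list(first.index) == [1]

    def test_non_dementia_codes_are_ignored(self):
        panel = make_panel(
            [person(1)],
            [(1, yq(2006, 2), "I10", "outpatient", "verified"),
             (1, yq(2006, 3), "I10", "outpatient", "verified")],
        )
        assert validate_diagnoses(panel, CaseDefinition()).empty

    def test_unknown_setting_raises_format_error(self):
        panel = make_panel(
            [person(1)], [(1, yq(2006, 2), "F03", "telehealth", "verified")]
        )
        with pytest.raises(InputFormatError, match="setting/status"):
            validate_diagnoses(panel, CaseDefinition())


class TestBuildEpisodes:
    def test_age_floor_excludes_person_aged_64(self):
        panel = make_panel([person(1, birth_year=1941)], [])  # 64 at 2006-01
        table = build_episodes(panel, CaseDefinition())
        assert table.data.empty

    def test_washout_diagnosis_excludes_person(self):
        panel = make_panel(
            [person(1), person(2)],
            [(1, yq(2005, 2), "F03", "outpatient", "verified"),
             (1, yq(2005, 3), "F03", "outpatient", "verified")],
        )
        table = build_episodes(panel, CaseDefinition())
        assert list(table.data["person_id"]) == [2]

    def test_incomplete_washout_coverage_excludes_person(self):
        panel = make_panel(
            [person(1, cov=(ym(2005, 6), COV[1])), person(2)], []
        )
        table = build_episodes(panel, CaseDefinition())
        assert list(table.data["person_id"]) == [2]

    def test_survivor_censored_at_study_end(self):
        panel = make_panel([person(1)], [])
        row = build_episodes(panel, CaseDefinition()).data.iloc[0]
        assert row["censor_reason"] == "study_end"
        assert row["censor_ym"] == ym(2008, 12)
        assert pd.isna(row["death_ym"]) and pd.isna(row["first_valid_dx_ym"])

    def test_insurer_exit_censors_at_coverage_end(self):
        panel = make_panel([person(1, cov=(COV[0], ym(2007, 7)))], [])
        row = build_episodes(panel, CaseDefinition()).data.iloc[0]
        assert row["censor_reason"] == "coverage_end"
        assert row["censor_ym"] == ym(2007, 7)

    def test_death_censors_with_reason_death(self):
        panel = make_panel(
            [person(1, death=ym(2007, 2), cov=(COV[0], ym(2007, 2)))], []
        )
        row = build_episodes(panel, CaseDefinition()).data.iloc[0]
        assert row["censor_reason"] == "death"
        assert row["censor_ym"] == ym(2007, 2) == row["death_ym"]

    def test_window_error_when_panel_too_short(self):
        panel = make_panel([person(1, cov=(ym(2005, 1), ym(2008, 12)))], [])
        with pytest.raises(WindowError):
            build_episodes(panel, CaseDefinition(), baseline_year=2006)

    def test_entry_age_is_completed_years_at_baseline(self):
        panel = make_panel([person(1, birth_year=1935)], [])  # born 1935-06
        row = build_episodes(panel, CaseDefinition()).data.iloc[0]
        assert row["entry_age"] == 70


class TestFilteringProperties:
    def test_enlarging_code_set_never_decreases_cases(self, small_sim):
        _, panel, _ = small_sim
        n_prev = 0
        codes = ["G30", "F00", "F01", "F02", "F03", "F05.1"]
        for k in range(1, len(codes) + 1):
            cdef = CaseDefinition(code_set=tuple(codes[:k]))
            n = len(validate_diagnoses(panel, cdef))
            assert n >= n_prev
            n_prev = n

    def test_longer_washout_never_increases_cohort(self, small_sim):
        _, panel, _ = small_sim
        sizes = [
            len(build_episodes(panel, CaseDefinition(washout_years=w)).data)
            for w in (0, 1, 2)
        ]
        assert sizes[0] >= sizes[1] >= sizes[2]


@pytest.fixture(scope="module")
def perfect_recording():
    cfg = SimConfig(n_per_cohort=20_000, seed=7, record_prob=1.0,
                    false_pos_rate=0.0)
    panel = simulate_cohort(cfg, "P1")
    episodes = build_episodes(panel, CaseDefinition())
    return panel, episodes


class TestRecovery:
    def test_detected_quarter_matches_true_onset(self, perfect_recording):
        """With every quarter recorded and no noise, the first valid
        diagnosis falls in the true onset quarter (or the one after) for
        >= 99% of onsets at least one quarter before censoring."""
        panel, episodes = perfect_recording
        d = episodes.data.merge(panel.truth, on="person_id")
        d = d[d["onset_ym"] >= d["baseline_ym"]]
        d = d[ym_to_yq(d["onset_ym"].to_numpy())
              < ym_to_yq(d["censor_ym"].to_numpy())]
        assert len(d) > 100
        detected = d["first_valid_dx_ym"].notna()
        assert detected.mean() >= 0.99
        dq = ym_to_yq(d.loc[detected, "first_valid_dx_ym"].astype(int).to_numpy())
        tq = ym_to_yq(d.loc[detected, "onset_ym"].to_numpy())
        assert np.mean((dq == tq) | (dq == tq + 1)) >= 0.99

    def test_isolated_unverified_false_positives_all_rejected(self):
        cfg = SimConfig(
            n_per_cohort=10_000, seed=9, false_pos_rate=0.01,
            incidence_params=GompertzParams(a={"m": 0.0, "f": 0.0},
                                            b={"m": 0.1, "f": 0.1}),
        )
        panel = simulate_cohort(cfg, "P1")
        assert panel.truth.empty
        episodes = build_episodes(panel, CaseDefinition())
        assert episodes.data["first_valid_dx_ym"].notna().sum() == 0

    def test_paired_false_positives_defeat_the_count_rule(self):
        cfg = SimConfig(
            n_per_cohort=10_000, seed=9, false_pos_rate=0.01,
            paired_false_positives=True,
            incidence_params=GompertzParams(a={"m": 0.0, "f": 0.0},
                                            b={"m": 0.1, "f": 0.1}),
        )
        panel = simulate_cohort(cfg, "P1")
        episodes = build_episodes(panel, CaseDefinition())
        assert episodes.data["first_valid_dx_ym"].notna().sum() > 0
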