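import numpy as np
import pandas as pd
import pytest

from demlife import (CaseDefinition, EventTable, aggregate_rate,
                     age_specific_rates, person_time_slices)
from demlife._time import ym
from demlife.errors import UndefinedRateError
from demlife.rates import AGES
from demlife.validate import EpisodeTable


def episode_frame(rows):
    """rows: (pid, sex, birth_ym, dx_ym|None, death_ym|None, censor_ym, reason)"""
    base = ym(2006, 1)
    d = pd.DataFrame(
        rows, columns=["person_id", "sex", "birth_ym", "first_valid_dx_ym",
                       "death_ym", "censor_ym", "censor_reason"],
    )
    d["baseline_ym"] = base
    d["entry_age"] = (base - d["birth_ym"]) // 12
    for c in ("first_valid_dx_ym", "death_ym"):
        d[c] = pd.array([pd.NA if v is None else v for v in d[c]], dtype="Int64")
    return EpisodeTable(data=d, period="P1", baseline_ym=base), d["birth_ym"].to_numpy()


class TestPersonTimeSlices:
    def test_three_years_no_events(self):
        ep, birth = episode_frame(
            [(1, "m", ym(1936, 1), None, None, ym(2008, 12), "study_end")]
        )
        di, dm, nondm = person_time_slices(ep, birth_ym=birth)
        assert di.data["person_years"].sum() == pytest.approx(3.0)
        assert di.data["events"].sum() == 0
        assert dm.data["person_years"].sum() == 0
        # aged exactly 70 at baseline: 1y at 70, 1y at 71, 1y at 72
        ev, py = di.stratum("m", "P1")
        assert py[70 - 65] == pytest.approx(1.0)
        assert py[71 - 65] == pytest.approx(1.0)
        assert py[72 - 65] == pytest.approx(1.0)

    def test_diagnosis_then_death_splits_exposure(self):
        # diagnosed 18 months in, dies 30 months in
        ep, birth = episode_frame(
            [(1, "f", ym(1936, 1), ym(2007, 7), ym(2008, 7), ym(2008, 7), "death")]
        )
        di, dm, nondm = person_time_slices(ep, birth_ym=birth)
        assert di.data["person_years"].sum() == pytest.approx(1.5)
        assert nondm.data["person_years"].sum() == pytest.approx(1.5)
        assert dm.data["person_years"].sum() == pytest.approx(1.0)
        assert di.data["events"].sum() == 1
        assert dm.data["events"].sum() == 1
        assert nondm.data["events"].sum() == 0

    def test_death_without_diagnosis_is_nondementia_death(self):
        ep, birth = episode_frame(
            [(1, "m", ym(1930, 7), None, ym(2007, 1), ym(2007, 1), "death")]
        )
        di, dm, nondm = person_time_slices(ep, birth_ym=birth)
        assert nondm.data["events"].sum() == 1
        assert di.data["events"].sum() == 0
        ev, _ = nondm.stratum("m", "P1")
        assert ev[76 - 65] == 1  # 76 completed years at death

    def test_same_month_diagnosis_and_death_keeps_positive_exposure(self):
        ep, birth = episode_frame(
            [(1, "m", ym(1936, 1), ym(2007, 7), ym(2007, 7), ym(2007, 7), "death")]
        )
        di, dm, nondm = person_time_slices(ep, birth_ym=birth)
        assert di.data["events"].sum() == 1
        assert dm.data["events"].sum() == 1  # dies in the dementia state
        assert dm.data["person_years"].sum() == pytest.approx(1 / 24)
        for tab in (di, dm, nondm):
            tab.check_invariants()

    def test_di_and_nondm_share_exposure(self, small_sim):
        _, panel, episodes = small_sim
        di, dm, nondm = person_time_slices(episodes, persons=panel.persons)
        pd.testing.assert_series_equal(
            di.data["person_years"], nondm.data["person_years"]
        )

    def test_exposure_conservation(self, small_sim):
        """Total DI + DM person-years equal total follow-up within the
        half-month-per-person rounding allowance."""
        _, panel, episodes = small_sim
        di, dm, _ = person_time_slices(episodes, persons=panel.persons)
        d = episodes.data
        end = d["censor_ym"] + (d["censor_reason"] != "death").astype(int)
        followup = (end - d["baseline_ym"]).sum() / 12
        total = di.data["person_years"].sum() + dm.data["person_years"].sum()
        assert abs(total - followup) <= len(d) / 24.0

    def test_invariant_to_row_order_and_ids(self, small_sim):
        _, panel, episodes = small_sim
        di1, _, _ = person_time_slices(episodes, persons=panel.persons)
        shuffled = episodes.data.sample(frac=1, random_state=0).reset_index(drop=True)
        ep2 = EpisodeTable(data=shuffled, period="P1",
                           baseline_ym=episodes.baseline_ym)
        di2, _, _ = person_time_slices(ep2, persons=panel.persons)
        pd.testing.assert_frame_equal(di1.data, di2.data)


class TestAggregateRate:
    @pytest.mark.parametrize(
        "events,py,rate_1dp",
        [
            (2823, 145876, 19.4),   # men, first period dementia incidence
            (974, 3407, 285.9),     # men, first period dementia mortality
            (6455, 224367, 28.8),   # women, first period non-dementia mortality
            (17994, 705109, 25.5),  # pooled dementia incidence
            (5433, 22688, 239.5),   # pooled dementia mortality
        ],
    )
    def test_reference_crude_rates(self, events, py, rate_1dp):
        assert round(aggregate_rate(events, py).rate_per_1000, 1) == rate_1dp

    def test_reference_confidence_intervals(self):
        r = aggregate_rate(2823, 145876)
        assert (round(r.ci_low, 1), round(r.ci_high, 1)) == (18.6, 20.1)
        r = aggregate_rate(6144, 224367)
        assert (round(r.ci_low, 1), round(r.ci_high, 1)) == (26.7, 28.1)

    def test_zero_events(self):
        r = aggregate_rate(0, 1000)
        assert (r.rate_per_1000, r.ci_low, r.ci_high) == (0.0, 0.0, 0.0)

    def test_zero_person_years_raises(self):
        with pytest.raises(UndefinedRateError):
            aggregate_rate(5, 0.0)


class TestAgeSpecificRates:
    def _table(self, transition, cells):
        rows = [
            {"sex": "m", "period": "P1", "age": a, "events": e, "person_years": p}
            for a, e, p in cells
        ]
        return EventTable(transition=transition, data=pd.DataFrame(rows))

    def test_simple_division(self):
        di = self._table("DI", [(70, 5, 250.0)])
        dm = self._table("DM", [(70, 0, 10.0)])
        nondm = self._table("nonDM", [(70, 2, 250.0)])
        r = age_specific_rates(di, dm, nondm, "m", "P1")
        assert r.di[70 - 65] == pytest.approx(0.02)
        assert r.nondm[70 - 65] == pytest.approx(0.008)

    def test_zero_exposure_cells(self):
        di = self._table("DI", [(70, 0, 100.0)])
        dm = self._table("DM", [(70, 0, 100.0)])
        nondm = self._table("nonDM", [(70, 0, 100.0)])
        r = age_specific_rates(di, dm, nondm, "m", "P1")
        # observed zero-rate cell
        assert r.di[70 - 65] == 0.0
        # zero exposure below 80 -> treated as zero; at 80+ left missing
        assert r.di[75 - 65] == 0.0
        assert np.isnan(r.di[90 - 65])

    def test_pooled_rate_recovers_constant_hazard(self):
        rng = np.random.default_rng(5)
        py = np.full(len(AGES), 2000.0)
        ev = rng.poisson(0.03 * py)
        di = self._table("DI", list(zip(AGES, ev, py)))
        rate = ev.sum() / py.sum()
        se = np.sqrt(ev.sum()) / py.sum()
        assert abs(rate - 0.03) < 3 * se
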