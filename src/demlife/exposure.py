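"""Person-years at risk and event counts by age, sex and period.

Each episode is split at integer-age boundaries with exact-month
arithmetic. Time before the first valid dementia diagnosis accrues to
the incidence (DI) and non-dementia-mortality (non-DM) exposures — the
two share denominators by construction — and time after it accrues to
the dementia-mortality (DM) exposure. Ages above 100 are pooled into the
age-100 cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConsistencyError, UndefinedRateError
from .rates import AGE_HI, AGE_LO, AGES, N_AGES, TransitionRates
from .validate import EpisodeTable

logger = logging.getLogger(__name__)

HALF_MONTH_YEARS = 1.0 / 24.0  # exposure granted when onset and death share a month


@dataclass
class EventTable:
    """events and person-years by (sex, period, age) for one transition."""

    transition: str
    data: pd.DataFrame  # columns: sex, period, age, events, person_years

    def check_invariants(self) -> None:
        d = self.data
        if (d["events"] < 0).any() or (d["person_years"] < 0).any():
            raise ValueError("negative events or person-years")
        if ((d["person_years"] == 0) & (d["events"] > 0)).any():
            raise ValueError("events in a cell with zero person-years")
        if (d["age"] < AGE_LO).any() or (d["age"] > AGE_HI).any():
            raise ValueError(f"ages outside [{AGE_LO}, {AGE_HI}]")

    def stratum(self, sex: str, period: str):
        """(events, person_years) arrays on the full 65..100 age grid."""
        sub = self.data[(self.data["sex"] == sex) & (self.data["period"] == period)]
        ev = np.zeros(N_AGES)
        py = np.zeros(N_AGES)
        idx = sub["age"].to_numpy() - AGE_LO
        ev[idx] = sub["events"].to_numpy()
        py[idx] = sub["person_years"].to_numpy()
        return ev, py

    def totals(self, sex=None, period=None):
        d = self.data
        if sex is not None:
            d = d[d["sex"] == sex]
        if period is not None:
            d = d[d["period"] == period]
        return int(d["events"].sum()), float(d["person_years"].sum())


def _accumulate_segments(py, start_ym, end_ym, birth_ym, sex_idx):
    """Split [start_ym, end_ym) at integer-age boundaries, month precision.

    ``py`` has shape (2, N_AGES); months of exposure are added as
    months/12, pooling ages > 100 into the age-100 cell.
    """
    if start_ym.size == 0:
        return
    start_age = (start_ym - birth_ym) // 12
    max_span = int(np.max((end_ym - start_ym) // 12, initial=0)) + 2
    for j in range(max_span):
        seg_lo = np.maximum(start_ym, birth_ym + 12 * (start_age + j))
        seg_hi = np.minimum(end_ym, birth_ym + 12 * (start_age + j + 1))
        months = np.clip(seg_hi - seg_lo, 0, None)
        age = np.clip(start_age + j, AGE_LO, AGE_HI) - AGE_LO
        np.add.at(py, (sex_idx, age), months / 12.0)


def _count_events(ev, event_ym, birth_ym, sex_idx):
    if event_ym.size == 0:
        return
    age = np.clip((event_ym - birth_ym) // 12, AGE_LO, AGE_HI) - AGE_LO
    np.add.at(ev, (sex_idx, age), 1)


def person_time_slices(episodes: EpisodeTable, birth_ym: pd.Series | np.ndarray = None,
                       persons: pd.DataFrame = None):
    """Event tables (DI, DM, non-DM) for one period cohort.

    Needs each person's birth month to place exposure on the age grid;
    pass either ``birth_ym`` aligned with the episode rows or the
    panel's ``persons`` frame to merge on person_id.
    """
    d = episodes.data
    if birth_ym is None:
        if persons is None:
            raise ValueError("provide birth_ym or the persons frame")
        birth_ym = (
            d[["person_id"]]
            .merge(persons[["person_id", "birth_ym"]], on="person_id", how="left")
            ["birth_ym"]
            .to_numpy()
        )
    birth = np.asarray(birth_ym, dtype=int)

    has_dx = d["first_valid_dx_ym"].notna().to_numpy()
    dx = d["first_valid_dx_ym"].fillna(-1).to_numpy(dtype=int)
    censor = d["censor_ym"].to_numpy(dtype=int)
    if np.any(has_dx & (dx > censor)):
        raise ConsistencyError("first valid diagnosis after censoring month")
    baseline = d["baseline_ym"].to_numpy(dtype=int)
    died = d["death_ym"].notna().to_numpy()
    death = d["death_ym"].fillna(-1).to_numpy(dtype=int)
    sex_idx = (d["sex"] == "f").to_numpy().astype(int)

    ndpy = np.zeros((2, N_AGES))
    di_ev = np.zeros((2, N_AGES))
    nd_ev = np.zeros((2, N_AGES))
    dm_py = np.zeros((2, N_AGES))
    dm_ev = np.zeros((2, N_AGES))

    # exposure runs to the event month exclusive (deaths, diagnoses) but
    # through the censor month inclusive for administrative censoring,
    # so a person followed exactly 3 years contributes 3.0 person-years
    end_obs = censor + (~died).astype(int)
    nd_end = np.where(has_dx, dx, end_obs)
    _accumulate_segments(ndpy, baseline, nd_end, birth, sex_idx)
    _count_events(di_ev, dx[has_dx], birth[has_dx], sex_idx[has_dx])
    nondem_death = died & ~has_dx
    _count_events(nd_ev, death[nondem_death], birth[nondem_death],
                  sex_idx[nondem_death])

    # dementia segment: dx .. censor; a same-month diagnosis and death
    # receives half a month of exposure so no cell holds events with
    # zero person-years
    if has_dx.any():
        _accumulate_segments(dm_py, dx[has_dx], end_obs[has_dx], birth[has_dx],
                             sex_idx[has_dx])
        same_month = has_dx & (dx == censor) & died
        if same_month.any():
            age = np.clip((dx[same_month] - birth[same_month]) // 12, AGE_LO, AGE_HI)
            np.add.at(dm_py, (sex_idx[same_month], age - AGE_LO), HALF_MONTH_YEARS)
        dem_death = died & has_dx
        _count_events(dm_ev, death[dem_death], birth[dem_death],
                      sex_idx[dem_death])

    period = episodes.period
    tables = []
    for name, ev, py in (
        ("DI", di_ev, ndpy), ("DM", dm_ev, dm_py), ("nonDM", nd_ev, ndpy)
    ):
        rows = []
        for s, sname in ((0, "m"), (1, "f")):
            rows.append(
                pd.DataFrame(
                    {
                        "sex": sname,
                        "period": period,
                        "age": AGES,
                        "events": ev[s].astype(int),
                        "person_years": py[s],
                    }
                )
            )
        t = EventTable(transition=name, data=pd.concat(rows, ignore_index=True))
        t.check_invariants()
        tables.append(t)
    return tuple(tables)


@dataclass
class RateSummary:
    """A crude rate per 1,000 person-years with its 95% CI."""

    rate_per_1000: float
    ci_low: float
    ci_high: float
    events: int
    person_years: float


def aggregate_rate(events: int, person_years: float) -> RateSummary:
    """Crude rate per 1,000 person-years, Poisson-normal 95% CI.

    The CI is rate +/- 1.96 * 1000 * sqrt(events) / person_years, the
    normal approximation on the count scale.
    """
    if person_years <= 0:
        raise UndefinedRateError("rate undefined: person_years must be > 0")
    if events < 0:
        raise ValueError("events must be >= 0")
    rate = 1000.0 * events / person_years
    half = 1.96 * 1000.0 * np.sqrt(events) / person_years
    return RateSummary(
        rate_per_1000=rate,
        ci_low=max(rate - half, 0.0),
        ci_high=rate + half,
        events=int(events),
        person_years=float(person_years),
    )


def rate_series(events: np.ndarray, person_years: np.ndarray):
    """Age-specific rates events/person-years; zero-exposure cells -> NaN."""
    ev = np.asarray(events, float)
    py = np.asarray(person_years, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(py > 0, ev / np.where(py > 0, py, 1.0), np.nan)
    return r


def age_specific_rates(di: EventTable, dm: EventTable, nondm: EventTable,
                       sex: str, period: str) -> TransitionRates:
    """Observed hazard grid for one stratum.

    Zero-exposure cells stay missing (NaN): at ages 80+ the smoothing
    stage fills them; below 80 they are set to zero with a warning,
    since the life table needs a complete young-age grid.
    """
    series = {}
    for name, tab in (("DI", di), ("DM", dm), ("nonDM", nondm)):
        ev, py = tab.stratum(sex, period)
        r = rate_series(ev, py)
        young_missing = np.isnan(r) & (AGES < 80)
        if young_missing.any():
            logger.warning(
                "%s %s/%s: %d zero-exposure cells below age 80 treated as rate 0",
                name, sex, period, int(young_missing.sum()),
            )
            r[young_missing] = 0.0
        series[name] = r
    return TransitionRates(
        di=series["DI"], dm=series["DM"], nondm=series["nonDM"],
        sex=sex, period=period,
    )


def summary_table(di: EventTable, dm: EventTable, nondm: EventTable) -> pd.DataFrame:
    """Crude rates per 1,000 PY by sex and period plus pooled margins."""
    rows = []
    periods = sorted(di.data["period"].unique())
    strata = [(s, p) for s in ("m", "f") for p in periods] + [(None, None)]
    for tab in (di, dm, nondm):
        for sex, period in strata:
            ev, py = tab.totals(sex, period)
            if py <= 0:
                continue
            rs = aggregate_rate(ev, py)
            rows.append(
                {
                    "transition": tab.transition,
                    "sex": sex or "all",
                    "period": period or "all",
                    "events": ev,
                    "person_years": py,
                    "rate_per_1000": rs.rate_per_1000,
                    "ci_low": rs.ci_low,
                    "ci_high": rs.ci_high,
                }
            )
    return pd.DataFrame(rows)
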