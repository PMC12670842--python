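import numpy as np
import pandas as pd
import pytest

from demlife import CaseDefinition, EventTable, SimConfig, simulate_cohort
from demlife.rates import AGES
from demlife.synthclaims import ClaimsPanel
from demlife.validate import build_episodes


def make_panel(persons_rows, dx_rows, period="P1", baseline_year=2006):
    """Hand-written tiny claims panel.

    persons_rows: (person_id, sex, birth_ym, death_ym|None, cov_start, cov_end)
    dx_rows: (person_id, yq, icd10, setting, status)
    """
    persons = pd.DataFrame(
        persons_rows,
        columns=["person_id", "sex", "birth_ym", "death_ym",
                 "coverage_start_ym", "coverage_end_ym"],
    )
    persons["death_ym"] = pd.array(
        [pd.NA if v is None else v for v in persons["death_ym"]], dtype="Int64"
    )
    diagnoses = pd.DataFrame(
        dx_rows, columns=["person_id", "yq", "icd10", "setting", "status"]
    )
    if diagnoses.empty:
        diagnoses = diagnoses.astype({"person_id": np.int64, "yq": int})
    return ClaimsPanel(persons=persons, diagnoses=diagnoses,
                       truth=pd.DataFrame(columns=["person_id", "onset_ym"]),
                       period=period, baseline_year=baseline_year)


def stratum_event_arrays(rates, py_nd, py_dm, rng=None):
    """(events, person_years) per transition for one stratum; expected
    counts when rng is None, else Poisson draws."""
    out = {}
    for name, py in (("DI", py_nd), ("DM", py_dm), ("nonDM", py_nd)):
        mu = py * rates.series(name)
        ev = mu if rng is None else rng.poisson(mu).astype(float)
        out[name] = (ev, py.astype(float))
    return out


def event_table_from_arrays(transition, strata):
    """strata: dict (sex, period) -> (events, person_years) arrays."""
    rows = []
    for (sex, period), (ev, py) in strata.items():
        rows.append(pd.DataFrame({
            "sex": sex, "period": period, "age": AGES,
            "events": np.asarray(ev), "person_years": np.asarray(py),
        }))
    return EventTable(transition=transition,
                      data=pd.concat(rows, ignore_index=True))


@pytest.fixture(scope="session")
def small_sim():
    """One simulated cohort with episodes, reused across tests."""
    cfg = SimConfig(n_per_cohort=20_000, seed=11)
    panel = simulate_cohort(cfg, "P1")
    episodes = build_episodes(panel, CaseDefinition())
    return cfg, panel, episodes
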