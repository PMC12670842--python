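"""Dementia case definition and episode construction.

A claims diagnosis only counts as a dementia case when it survives
internal validation: the ICD-10 code must belong to the dementia code
set, outpatient diagnoses must be physician-verified, inpatient
diagnoses must be discharge or secondary diagnoses, and a person needs
at least two admissible records — within one quarter or anywhere in the
observation period — unless their single record falls in the quarter of
death. Cohort entry further requires being dementia-free through a
wash-out window and aged 65+ at baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._time import ym, ym_to_yq, yq_mid_ym
from .errors import InputFormatError, WindowError
from .synthclaims import ClaimsPanel, DEMENTIA_CODES

VALID_SETTINGS = {"outpatient", "inpatient_discharge", "inpatient_secondary"}
VALID_STATUSES = {"verified", "unverified"}

CENSOR_DEATH = "death"
CENSOR_COVERAGE_END = "coverage_end"
CENSOR_STUDY_END = "study_end"


@dataclass(frozen=True)
class CaseDefinition:
    """Operational dementia definition applied to claims records."""

    code_set: tuple = DEMENTIA_CODES
    washout_years: int = 2
    followup_years: int = 3
    min_age: int = 65

    def __post_init__(self):
        if not self.code_set:
            raise ValueError("code_set must be non-empty")
        if self.washout_years < 0:
            raise ValueError("washout_years must be >= 0")
        if self.followup_years < 1:
            raise ValueError("followup_years must be >= 1")

    def code_prefixes(self) -> tuple:
        # dot-stripped uppercase prefixes: F05.1 and F051 both match F051x
        return tuple(c.replace(".", "").upper() for c in self.code_set)


def _admissible_mask(diagnoses: pd.DataFrame, cdef: CaseDefinition) -> np.ndarray:
    bad_setting = ~diagnoses["setting"].isin(VALID_SETTINGS)
    bad_status = ~diagnoses["status"].isin(VALID_STATUSES)
    if bad_setting.any() or bad_status.any():
        rows = diagnoses.index[bad_setting | bad_status].tolist()[:20]
        raise InputFormatError(
            f"unknown setting/status values in diagnosis rows {rows}"
        )
    codes = diagnoses["icd10"].str.replace(".", "", regex=False).str.upper()
    code_ok = np.zeros(len(diagnoses), dtype=bool)
    for prefix in cdef.code_prefixes():
        code_ok |= codes.str.startswith(prefix).to_numpy()
    outpatient_ok = (diagnoses["setting"] == "outpatient") & (
        diagnoses["status"] == "verified"
    )
    inpatient_ok = diagnoses["setting"].isin(
        ["inpatient_discharge", "inpatient_secondary"]
    )
    return code_ok & (outpatient_ok | inpatient_ok).to_numpy()


def validate_diagnoses(panel: ClaimsPanel, cdef: CaseDefinition) -> pd.Series:
    """First internally valid dementia diagnosis month per person.

    A person has a valid diagnosis when they carry at least two
    admissible dementia records during the observation period (which
    subsumes the two-records-in-one-quarter rule), or exactly one
    admissible record in the quarter of their death. The first valid
    month is the middle month of the earliest admissible record's
    quarter, clamped to the death month if the death falls earlier
    within that quarter.

    Returns a Series indexed by person_id.
    """
    dx = panel.diagnoses
    if dx.empty:
        return pd.Series(dtype="Int64", name="first_valid_dx_ym")
    adm = dx.loc[_admissible_mask(dx, cdef), ["person_id", "yq"]]
    if adm.empty:
        return pd.Series(dtype="Int64", name="first_valid_dx_ym")

    per = adm.groupby("person_id")["yq"].agg(n="size", first_q="min")
    death = panel.persons.set_index("person_id")["death_ym"]
    death_q = death.dropna().astype(int).map(lambda m: ym_to_yq(m))
    per = per.join(death_q.rename("death_q"))

    multi = per["n"] >= 2
    death_quarter_single = (per["n"] == 1) & (per["first_q"] == per["death_q"])
    valid = per[multi | death_quarter_single]

    first_ym = valid["first_q"].map(lambda q: int(yq_mid_ym(q)))
    # diagnosis cannot postdate the recorded death month
    dmonth = death.reindex(valid.index)
    has_death = dmonth.notna()
    first_ym = first_ym.where(
        ~has_death, np.minimum(first_ym, dmonth.fillna(0).astype(int))
    )
    first_ym.name = "first_valid_dx_ym"
    return first_ym.astype("Int64")


@dataclass
class EpisodeTable:
    """Analysis-ready follow-up episodes for one period cohort.

    One row per included person: entry age, baseline month, first valid
    diagnosis month (nullable), death month (nullable), censoring month
    and reason.
    """

    data: pd.DataFrame
    period: str | None = None
    baseline_ym: int | None = None

    COLUMNS = (
        "person_id", "sex", "entry_age", "baseline_ym", "first_valid_dx_ym",
        "death_ym", "censor_ym", "censor_reason",
    )

    def check_invariants(self) -> None:
        d = self.data
        has_dx = d["first_valid_dx_ym"].notna()
        if (d.loc[has_dx, "first_valid_dx_ym"] < d.loc[has_dx, "baseline_ym"]).any():
            raise ValueError("first_valid_dx before baseline")
        if (d["censor_ym"] < d["baseline_ym"]).any():
            raise ValueError("censoring before baseline")
        dead = d["death_ym"].notna()
        if (d.loc[dead, "censor_reason"] != CENSOR_DEATH).any():
            raise ValueError("death without censor_reason=death")


def build_episodes(
    panel: ClaimsPanel, cdef: CaseDefinition, baseline_year: int | None = None
) -> EpisodeTable:
    """Apply wash-out eligibility and censoring to a claims panel.

    Includes persons aged >= min_age at baseline, continuously covered
    through the wash-out window and free of valid dementia diagnoses
    during it. Follow-up runs from baseline to the earliest of death,
    coverage end (insurer exit) and study end (baseline + followup
    years); the first valid diagnosis within follow-up defines dementia
    onset for the exposure stage.
    """
    if baseline_year is None:
        baseline_year = panel.baseline_year
    baseline = ym(baseline_year, 1)
    washout_start = baseline - 12 * cdef.washout_years
    study_end = baseline + 12 * cdef.followup_years  # exclusive month

    p = panel.persons
    if (p["coverage_start_ym"].min() > washout_start) or (
        p["coverage_end_ym"].max() < baseline
    ):
        raise WindowError(
            f"panel does not cover the analysis window "
            f"[{washout_start}, {study_end}) for baseline {baseline_year}"
        )

    first_dx = validate_diagnoses(panel, cdef)
    d = p.merge(
        first_dx.rename("first_valid_dx_ym"),
        left_on="person_id",
        right_index=True,
        how="left",
    )
    d["first_valid_dx_ym"] = d["first_valid_dx_ym"].astype("Int64")

    entry_age = (baseline - d["birth_ym"]) // 12
    alive_at_baseline = d["death_ym"].isna() | (d["death_ym"] >= baseline)
    covered_washout = (d["coverage_start_ym"] <= washout_start) & (
        d["coverage_end_ym"] >= baseline
    )
    dementia_free = d["first_valid_dx_ym"].isna() | (
        d["first_valid_dx_ym"] >= baseline
    )
    keep = (entry_age >= cdef.min_age) & alive_at_baseline & covered_washout & dementia_free
    d = d.loc[keep].copy()
    entry_age = entry_age.loc[keep]

    censor = np.minimum(d["coverage_end_ym"].to_numpy(), study_end - 1)
    death = d["death_ym"].to_numpy(dtype="object")
    is_death = pd.notna(death) & (pd.array(death, dtype="Int64") <= censor)
    reason = np.where(
        is_death,
        CENSOR_DEATH,
        np.where(d["coverage_end_ym"].to_numpy() < study_end - 1,
                 CENSOR_COVERAGE_END, CENSOR_STUDY_END),
    )

    dx = d["first_valid_dx_ym"]
    dx_in_window = dx.notna() & (dx <= pd.array(censor, dtype="Int64"))
    out = pd.DataFrame(
        {
            "person_id": d["person_id"].to_numpy(),
            "sex": d["sex"].to_numpy(),
            "entry_age": entry_age.to_numpy(),
            "baseline_ym": baseline,
            "first_valid_dx_ym": dx.where(dx_in_window, pd.NA).astype("Int64"),
            "death_ym": pd.array(
                [int(v) if k else pd.NA for v, k in zip(death, is_death)],
                dtype="Int64",
            ),
            "censor_ym": censor,
            "censor_reason": reason,
        }
    ).reset_index(drop=True)
    table = EpisodeTable(data=out, period=panel.period, baseline_ym=baseline)
    table.check_invariants()
    return table
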