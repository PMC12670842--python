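"""Synthetic health-claims panels with known transition hazards.

Real claims panels of this kind (quarterly ICD-10-GM diagnoses plus
month-precision vital events from a statutory insurer) are access
restricted, so every downstream stage is exercised against simulated
panels whose ground truth is known exactly.

Two period cohorts are generated (baselines 2006 and 2016). Each person
enters the panel two years before baseline (the wash-out window), ages
through piecewise-constant (single-year-of-age) Gompertz hazards of
dementia onset and of death with and without dementia, and may leave the
insurer at a small constant rate. Period 2 applies multiplicative rate
ratios to all three hazards. True dementia cases emit quarterly verified
diagnosis claims from onset onward; non-cases emit isolated unverified
claims at a small false-positive rate, which the validation stage must
reject.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._time import ym, ym_str, parse_ym, ym_to_yq, yq_str, parse_yq
from .errors import ConfigurationError
from .rates import AGES, TransitionRates

PERIOD_BASELINE = {"P1": 2006, "P2": 2016}
WASHOUT_YEARS = 2
FOLLOWUP_YEARS = 3
HORIZON_YEARS = WASHOUT_YEARS + FOLLOWUP_YEARS

DEMENTIA_CODES = ("F03", "G30", "F01", "F00", "F02", "F05.1")
_CODE_WEIGHTS = (0.55, 0.20, 0.12, 0.06, 0.04, 0.03)  # F03 dominates in claims
FILLER_CODE = "I10"

SEXES = ("m", "f")


@dataclass(frozen=True)
class GompertzParams:
    """Per-sex exponential hazard h(x) = a * exp(b * (x - 65)).

    ``a`` is the hazard level at age 65 (per person-year), ``b`` the
    log-slope per year of age. ``rr_period2`` multiplies the hazard in
    the later period cohort.
    """

    a: dict
    b: dict
    rr_period2: float = 1.0

    def hazard(self, sex: str, age, period: str = "P1"):
        rr = self.rr_period2 if period == "P2" else 1.0
        return rr * self.a[sex] * np.exp(self.b[sex] * (np.asarray(age, float) - 65.0))


def _default_incidence():
    return GompertzParams(
        a={"m": 0.007, "f": 0.008}, b={"m": 0.105, "f": 0.115}, rr_period2=0.91
    )


def _default_nondem_mortality():
    return GompertzParams(
        a={"m": 0.018, "f": 0.011}, b={"m": 0.085, "f": 0.100}, rr_period2=0.93
    )


def _default_dem_mortality():
    return GompertzParams(
        a={"m": 0.12, "f": 0.07}, b={"m": 0.055, "f": 0.060}, rr_period2=0.97
    )


@dataclass
class SimConfig:
    """Study design of the synthetic two-period claims panels.

    Defaults emulate a statutory-insurer sample of ages 65+: roughly
    120,000 insured per period cohort, ~60% women, an entry-age
    distribution decaying with age, dementia incidence around 20-30 per
    1,000 person-years, mortality with dementia an order of magnitude
    above mortality without, and mild declines in incidence and
    mortality between the two periods.
    """

    n_per_cohort: int = 120_000
    entry_age_scale: float = 8.0  # truncated-exponential scale, years above 65
    frac_female: float = 0.60
    incidence_params: GompertzParams = field(default_factory=_default_incidence)
    nondem_mortality_params: GompertzParams = field(
        default_factory=_default_nondem_mortality
    )
    dem_mortality_params: GompertzParams = field(default_factory=_default_dem_mortality)
    record_prob: float = 0.90  # per-quarter P(true case emits a verified claim)
    false_pos_rate: float = 0.002  # per person-quarter among the non-demented
    switch_rate: float = 0.005  # annual probability of leaving the insurer
    filler_rate: float = 0.05  # per person-quarter rate of a non-dementia claim
    paired_false_positives: bool = False  # emit 2 verified claims per false event
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_cohort < 1:
            raise ConfigurationError("n_per_cohort must be >= 1")
        if self.entry_age_scale <= 0:
            raise ConfigurationError("entry_age_scale must be > 0")
        for name in ("frac_female", "record_prob", "false_pos_rate",
                     "switch_rate", "filler_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for pname in ("incidence_params", "nondem_mortality_params",
                      "dem_mortality_params"):
            p = getattr(self, pname)
            for sex in SEXES:
                if sex not in p.a or sex not in p.b:
                    raise ConfigurationError(f"{pname} missing sex '{sex}'")
                if p.a[sex] < 0:
                    raise ConfigurationError(f"{pname}.a[{sex}] must be >= 0")
                if not np.isfinite(p.hazard(sex, 100.0)):
                    raise ConfigurationError(f"{pname} hazard not finite on [65,100)")
            if p.rr_period2 < 0:
                raise ConfigurationError(f"{pname}.rr_period2 must be >= 0")


@dataclass
class ClaimsPanel:
    """Person-level coverage plus quarterly diagnosis claims.

    ``persons``: person_id, sex, birth_ym, death_ym (nullable),
    coverage_start_ym, coverage_end_ym (month indices, coverage_end
    inclusive). ``diagnoses``: person_id, yq, icd10, setting, status.
    ``truth``: person_id, onset_ym for true dementia onsets — carried
    only in synthetic panels, for recovery tests.
    """

    persons: pd.DataFrame
    diagnoses: pd.DataFrame
    truth: pd.DataFrame
    period: str
    baseline_year: int

    def check_invariants(self) -> None:
        p = self.persons
        if p["person_id"].duplicated().any():
            raise ValueError("person_ids are not unique")
        if (p["coverage_start_ym"] > p["coverage_end_ym"]).any():
            raise ValueError("coverage_start after coverage_end")
        dead = p["death_ym"].notna()
        if (p.loc[dead, "death_ym"] != p.loc[dead, "coverage_end_ym"]).any():
            raise ValueError("death not at end of coverage")
        d = self.diagnoses.merge(
            p[["person_id", "coverage_start_ym", "coverage_end_ym"]], on="person_id"
        )
        inside = (ym_to_yq(d["coverage_start_ym"]) <= d["yq"]) & (
            d["yq"] <= ym_to_yq(d["coverage_end_ym"])
        )
        if not inside.all():
            raise ValueError("diagnosis quarter outside coverage")


def _piecewise_event_times(exp_draws, age_start, rate_of_age, horizon):
    """Invert cumulative piecewise-constant hazards to event times.

    ``rate_of_age`` maps a float array of integer ages to hazards. Event
    times beyond ``horizon`` are returned as +inf. Hazards are constant
    on single-year-of-age intervals, so the inversion walks at most
    ceil(horizon)+1 segments.
    """
    n = exp_draws.shape[0]
    remaining = exp_draws.astype(float).copy()
    t = np.zeros(n)
    out = np.full(n, np.inf)
    active = np.ones(n, dtype=bool)
    horizon = np.broadcast_to(np.asarray(horizon, float), (n,)).copy()
    for _ in range(int(np.ceil(np.nanmax(horizon, initial=0.0))) + 1):
        if not active.any():
            break
        age_now = np.floor(age_start + t)
        seg = np.minimum(age_now + 1.0 - (age_start + t), horizon - t)
        seg = np.maximum(seg, 0.0)
        r = rate_of_age(age_now)
        with np.errstate(divide="ignore", invalid="ignore"):
            need = np.where(r > 0, remaining / np.where(r > 0, r, 1.0), np.inf)
        hit = active & (need <= seg)
        out[hit] = t[hit] + need[hit]
        remaining = remaining - r * seg
        t = t + seg
        active &= ~hit & (t < horizon - 1e-12)
    return out


def simulate_cohort(config: SimConfig, period_label: str) -> ClaimsPanel:
    """Simulate one period cohort's claims panel.

    The panel spans baseline-2y .. baseline+3y. Onset and death times
    are drawn by competing-risks inversion sampling from the configured
    piecewise-constant hazards; vital events are recorded to the month,
    diagnoses to the quarter.
    """
    config.validate()
    if period_label not in PERIOD_BASELINE:
        raise ConfigurationError(f"period_label must be one of {list(PERIOD_BASELINE)}")
    baseline_ym = ym(PERIOD_BASELINE[period_label], 1)
    start_ym = baseline_ym - 12 * WASHOUT_YEARS
    last_ym = baseline_ym + 12 * FOLLOWUP_YEARS - 1  # inclusive last covered month

    rng = np.random.default_rng(
        [int(config.seed), {"P1": 1, "P2": 2}[period_label], 90210]
    )
    n = config.n_per_cohort
    sex = np.where(rng.random(n) < config.frac_female, "f", "m")
    is_f = sex == "f"

    # entry age at baseline: 65 + truncated exponential on [0, 35)
    span, scale = 35.0, config.entry_age_scale
    u = rng.random(n)
    age_baseline = 65.0 + -scale * np.log1p(-u * (1.0 - np.exp(-span / scale)))
    age_months = np.floor(age_baseline * 12.0).astype(int)
    birth_ym = baseline_ym - age_months
    age_start = (start_ym - birth_ym) / 12.0  # continuous age at panel start

    def haz(params: GompertzParams):
        a = np.where(is_f, params.a["f"], params.a["m"])
        b = np.where(is_f, params.b["f"], params.b["m"])
        rr = params.rr_period2 if period_label == "P2" else 1.0

        def f(age):
            return rr * a * np.exp(b * (age - 65.0))

        return f

    horizon = float(HORIZON_YEARS)
    t_onset = _piecewise_event_times(
        rng.exponential(size=n), age_start, haz(config.incidence_params), horizon
    )
    t_nd_death = _piecewise_event_times(
        rng.exponential(size=n), age_start, haz(config.nondem_mortality_params), horizon
    )
    if config.switch_rate > 0:
        exit_hazard = -np.log1p(-config.switch_rate)
        t_exit = rng.exponential(1.0 / exit_hazard, size=n)
    else:
        t_exit = np.full(n, np.inf)
    t_cens = np.minimum(t_exit, horizon)

    has_onset = (t_onset < t_nd_death) & (t_onset < t_cens)
    # post-onset survival under the dementia-mortality hazard
    s_dm = _piecewise_event_times(
        rng.exponential(size=n),
        age_start + np.where(has_onset, t_onset, 0.0),
        haz(config.dem_mortality_params),
        np.where(has_onset, horizon - t_onset, horizon),
    )
    t_death = np.where(has_onset, t_onset + s_dm, t_nd_death)
    died = t_death < t_cens

    death_ym = np.where(
        died, np.minimum(start_ym + np.floor(t_death * 12.0), last_ym), -1
    ).astype(int)
    exited = ~died & (t_exit < horizon)
    cov_end = np.where(
        died,
        death_ym,
        np.where(
            exited,
            np.minimum(start_ym + np.floor(t_exit * 12.0), last_ym).astype(int),
            last_ym,
        ),
    ).astype(int)
    onset_ym = np.where(
        has_onset, np.minimum(start_ym + np.floor(t_onset * 12.0), cov_end), -1
    ).astype(int)

    persons = pd.DataFrame(
        {
            "person_id": np.arange(n, dtype=np.int64),
            "sex": sex,
            "birth_ym": birth_ym,
            "death_ym": pd.array(
                np.where(died, death_ym, -1), dtype="Int64"
            ),
            "coverage_start_ym": np.full(n, start_ym, dtype=int),
            "coverage_end_ym": cov_end,
        }
    )
    persons.loc[persons["death_ym"] == -1, "death_ym"] = pd.NA

    diagnoses = _simulate_diagnoses(
        config, rng, persons, onset_ym, has_onset, cov_end, start_ym
    )
    truth = pd.DataFrame(
        {
            "person_id": persons.loc[has_onset, "person_id"].to_numpy(),
            "onset_ym": onset_ym[has_onset],
        }
    )
    panel = ClaimsPanel(
        persons=persons,
        diagnoses=diagnoses,
        truth=truth,
        period=period_label,
        baseline_year=PERIOD_BASELINE[period_label],
    )
    return panel


def _quarter_grid(start_q, end_q):
    """(row person index, quarter) pairs spanning [start_q, end_q] per person."""
    n_q = np.maximum(end_q - start_q + 1, 0)
    idx = np.repeat(np.arange(start_q.size), n_q)
    offs = np.arange(idx.size) - np.repeat(np.cumsum(n_q) - n_q, n_q)
    return idx, start_q[idx] + offs


def _simulate_diagnoses(config, rng, persons, onset_ym, has_onset, cov_end, start_ym):
    pid = persons["person_id"].to_numpy()
    frames = []

    # true cases: one verified claim per quarter with prob record_prob,
    # from the onset quarter through end of coverage
    case_rows = np.flatnonzero(has_onset)
    if case_rows.size:
        q0 = ym_to_yq(onset_ym[case_rows])
        q1 = ym_to_yq(cov_end[case_rows])
        ridx, q = _quarter_grid(q0, q1)
        keep = rng.random(q.size) < config.record_prob
        ridx, q = ridx[keep], q[keep]
        outpatient = rng.random(q.size) < 0.8
        inp_secondary = rng.random(q.size) < 0.25
        setting = np.where(
            outpatient,
            "outpatient",
            np.where(inp_secondary, "inpatient_secondary", "inpatient_discharge"),
        )
        status = np.where(outpatient, "verified", "unverified")
        code = rng.choice(DEMENTIA_CODES, size=q.size, p=_CODE_WEIGHTS)
        frames.append(
            pd.DataFrame(
                {
                    "person_id": pid[case_rows][ridx],
                    "yq": q,
                    "icd10": code,
                    "setting": setting,
                    "status": status,
                }
            )
        )

    # false positives: isolated spurious dementia claims among the
    # non-demented; unverified singles by default (the validator must
    # reject them), optionally paired verified claims to demonstrate the
    # two-records rule's failure mode
    if config.false_pos_rate > 0:
        fp_rows = np.flatnonzero(~has_onset)
        q0 = np.full(fp_rows.size, ym_to_yq(start_ym))
        q1 = ym_to_yq(cov_end[fp_rows])
        ridx, q = _quarter_grid(q0, q1)
        keep = rng.random(q.size) < config.false_pos_rate
        ridx, q = ridx[keep], q[keep]
        code = rng.choice(DEMENTIA_CODES, size=q.size, p=_CODE_WEIGHTS)
        reps = 2 if config.paired_false_positives else 1
        status = "verified" if config.paired_false_positives else "unverified"
        frames.append(
            pd.DataFrame(
                {
                    "person_id": np.tile(pid[fp_rows][ridx], reps),
                    "yq": np.tile(q, reps),
                    "icd10": np.tile(code, reps),
                    "setting": "outpatient",
                    "status": status,
                }
            )
        )

    # generic filler claims (non-dementia code) for realism
    if config.filler_rate > 0:
        q0 = np.full(pid.size, ym_to_yq(start_ym))
        q1 = ym_to_yq(cov_end)
        ridx, q = _quarter_grid(q0, q1)
        keep = rng.random(q.size) < config.filler_rate
        ridx, q = ridx[keep], q[keep]
        frames.append(
            pd.DataFrame(
                {
                    "person_id": pid[ridx],
                    "yq": q,
                    "icd10": FILLER_CODE,
                    "setting": "outpatient",
                    "status": "verified",
                }
            )
        )

    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(
            columns=["person_id", "yq", "icd10", "setting", "status"]
        ).astype({"person_id": np.int64, "yq": int})
    return out.sort_values(["person_id", "yq"], kind="stable").reset_index(drop=True)


def true_rates(config: SimConfig, period_label: str, sex: str) -> TransitionRates:
    """Exact configured hazards on the 65..100 grid — the simulation oracle."""
    config.validate()
    if period_label not in PERIOD_BASELINE:
        raise ConfigurationError(f"period_label must be one of {list(PERIOD_BASELINE)}")
    if sex not in SEXES:
        raise ConfigurationError(f"sex must be one of {SEXES}")
    return TransitionRates(
        di=config.incidence_params.hazard(sex, AGES, period_label),
        dm=config.dem_mortality_params.hazard(sex, AGES, period_label),
        nondm=config.nondem_mortality_params.hazard(sex, AGES, period_label),
        sex=sex,
        period=period_label,
    )


# ---------------------------------------------------------------------------
# CSV / YAML round-tripping

def write_panel(panel: ClaimsPanel, outdir, include_truth: bool = True) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = panel.persons.copy()
    for col in ("birth_ym", "coverage_start_ym", "coverage_end_ym"):
        p[col] = p[col].map(ym_str)
    p["death_ym"] = p["death_ym"].map(lambda v: "" if pd.isna(v) else ym_str(int(v)))
    p.rename(
        columns={c: c.replace("_ym", "") for c in p.columns if c.endswith("_ym")}
    ).to_csv(outdir / "persons.csv", index=False)

    d = panel.diagnoses.copy()
    d["quarter"] = d.pop("yq").map(yq_str)
    d[["person_id", "quarter", "icd10", "setting", "status"]].to_csv(
        outdir / "diagnoses.csv", index=False
    )
    if include_truth and len(panel.truth):
        t = panel.truth.copy()
        t["onset"] = t.pop("onset_ym").map(ym_str)
        t.to_csv(outdir / "truth.csv", index=False)
    meta = {"period": panel.period, "baseline_year": panel.baseline_year}
    (outdir / "panel.yaml").write_text(yaml.safe_dump(meta))


def read_panel(indir) -> ClaimsPanel:
    indir = Path(indir)
    p = pd.read_csv(indir / "persons.csv", dtype={"death": "string"})
    persons = pd.DataFrame(
        {
            "person_id": p["person_id"].astype(np.int64),
            "sex": p["sex"],
            "birth_ym": p["birth"].map(parse_ym),
            "death_ym": pd.array(
                [pd.NA if (pd.isna(v) or v == "") else parse_ym(v) for v in p["death"]],
                dtype="Int64",
            ),
            "coverage_start_ym": p["coverage_start"].map(parse_ym),
            "coverage_end_ym": p["coverage_end"].map(parse_ym),
        }
    )
    d = pd.read_csv(indir / "diagnoses.csv")
    diagnoses = pd.DataFrame(
        {
            "person_id": d["person_id"].astype(np.int64),
            "yq": d["quarter"].map(parse_yq),
            "icd10": d["icd10"],
            "setting": d["setting"],
            "status": d["status"],
        }
    )
    truth_path = indir / "truth.csv"
    if truth_path.exists():
        t = pd.read_csv(truth_path)
        truth = pd.DataFrame(
            {
                "person_id": t["person_id"].astype(np.int64),
                "onset_ym": t["onset"].map(parse_ym),
            }
        )
    else:
        truth = pd.DataFrame(columns=["person_id", "onset_ym"])
    meta = yaml.safe_load((indir / "panel.yaml").read_text())
    return ClaimsPanel(
        persons=persons,
        diagnoses=diagnoses,
        truth=truth,
        period=meta["period"],
        baseline_year=int(meta["baseline_year"]),
    )


def config_from_yaml(path) -> SimConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = SimConfig()
    for pname in ("incidence_params", "nondem_mortality_params", "dem_mortality_params"):
        if pname in raw:
            d = raw.pop(pname)
            cfg = replace(cfg, **{pname: GompertzParams(**d)})
    cfg = replace(cfg, **raw)
    cfg.validate()
    return cfg
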