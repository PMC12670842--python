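"""Period trends in transition rates via negative binomial regression.

For each transition and sex, event counts aggregated by single year of
age and period are modelled as NB2 (variance mu + alpha*mu^2) with a log
link, log person-years offset, a quadratic age polynomial centred at the
person-years-weighted mean age of the exposed population, and a period
dummy. The exponentiated period coefficient is the rate ratio between
the two period cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DegenerateDataError, EstimationError
from .exposure import EventTable

# person-years-weighted mean ages of the exposed population in the
# reference claims study, accepted as centering overrides
REFERENCE_CENTERING_AGES = {
    ("DI", "m"): 73.92, ("DI", "f"): 75.87,
    ("nonDM", "m"): 73.92, ("nonDM", "f"): 75.87,
    ("DM", "m"): 79.67, ("DM", "f"): 82.99,
}


@dataclass(frozen=True)
class TrendModelSpec:
    transition: str
    sex: str
    centering_age: float | None = None  # None -> computed from the data
    period_reference: str = "P1"

    def __post_init__(self):
        if self.centering_age is not None and not 65 <= self.centering_age <= 100:
            raise ValueError("centering_age must lie in [65, 100]")


@dataclass
class TrendResult:
    rr_period: float
    ci_low: float
    ci_high: float
    p_value: float
    coef_age: float
    coef_age2: float
    intercept: float
    dispersion: float
    centering_age: float

    def __post_init__(self):
        if not (self.ci_low <= self.rr_period <= self.ci_high):
            raise ValueError("rate-ratio CI does not bracket the estimate")


def compute_centering_age(table: EventTable, sex: str | None = None) -> float:
    """Person-years-weighted mean age over both periods."""
    d = table.data
    if sex is not None:
        d = d[d["sex"] == sex]
    total = d["person_years"].sum()
    if total <= 0:
        raise DegenerateDataError("cannot centre age: zero total person-years")
    return float((d["age"] * d["person_years"]).sum() / total)


def _design(d: pd.DataFrame, c: float, reference: str):
    age_c = d["age"].to_numpy(float) - c
    period = (d["period"] != reference).astype(float).to_numpy()
    X = np.column_stack([np.ones_like(age_c), age_c, age_c ** 2, period])
    return X


def fit_trend(table: EventTable, spec: TrendModelSpec) -> TrendResult:
    """Fit the NB2 period-trend model for one transition and sex.

    Cells with zero person-years are excluded (their rates are
    undefined, not zero). Raises on non-convergence, carrying the
    solver trace.
    """
    d = table.data
    d = d[(d["sex"] == spec.sex) & (d["person_years"] > 0)]
    if d["period"].nunique() < 2:
        raise DegenerateDataError("need two periods with positive exposure")
    if d["age"].nunique() < 3:
        raise DegenerateDataError("need >= 3 distinct ages with positive exposure")
    if d["events"].sum() == 0:
        raise DegenerateDataError("all-zero event counts")

    c = spec.centering_age
    if c is None:
        c = compute_centering_age(table, spec.sex)
    X = _design(d, c, spec.period_reference)
    y = d["events"].to_numpy(float)
    offset = np.log(d["person_years"].to_numpy(float))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pois = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
        model = sm.NegativeBinomial(y, X, offset=offset, loglike_method="nb2")
        start = np.append(pois.params, 0.05)
        res, err = None, None
        for method in ("bfgs", "newton", "nm"):
            try:
                cand = model.fit(start_params=start, method=method,
                                 maxiter=500, disp=False)
            except Exception as exc:  # noqa: BLE001 - keep trying solvers
                err = exc
                continue
            ok = cand.mle_retvals.get("converged", False) and np.all(
                np.isfinite(cand.params)
            ) and np.all(np.isfinite(cand.bse[:4]))
            if ok:
                res = cand
                break

    if res is not None and res.params[-1] > 1e-6:
        beta, ci = res.params, res.conf_int()
        return TrendResult(
            rr_period=float(np.exp(beta[3])),
            ci_low=float(np.exp(ci[3][0])),
            ci_high=float(np.exp(ci[3][1])),
            p_value=float(res.pvalues[3]),
            coef_age=float(beta[1]),
            coef_age2=float(beta[2]),
            intercept=float(beta[0]),
            dispersion=float(max(beta[-1], 0.0)),
            centering_age=float(c),
        )

    # NB2 collapses to Poisson as alpha -> 0; at (or numerically near)
    # that boundary the joint information matrix is singular, so the
    # Poisson limit is reported with dispersion 0
    alpha_boundary = res is not None and res.params[-1] <= 1e-6
    pearson_disp = float(pois.pearson_chi2 / pois.df_resid) if pois.df_resid else 1.0
    if alpha_boundary or pearson_disp < 1.5:
        beta, ci = pois.params, np.asarray(pois.conf_int())
        return TrendResult(
            rr_period=float(np.exp(beta[3])),
            ci_low=float(np.exp(ci[3, 0])),
            ci_high=float(np.exp(ci[3, 1])),
            p_value=float(pois.pvalues[3]),
            coef_age=float(beta[1]),
            coef_age2=float(beta[2]),
            intercept=float(beta[0]),
            dispersion=0.0,
            centering_age=float(c),
        )
    raise EstimationError(
        "negative binomial fit did not converge",
        diagnostics=err if err is not None else (res.mle_retvals if res else None),
    )


def trend_table(tables: dict, centering_overrides: dict | None = None) -> pd.DataFrame:
    """Fit all transition x sex trend models; one row per fit."""
    rows = []
    for name, tab in tables.items():
        for sex in ("m", "f"):
            c = None
            if centering_overrides and (name, sex) in centering_overrides:
                c = centering_overrides[(name, sex)]
            r = fit_trend(tab, TrendModelSpec(transition=name, sex=sex,
                                              centering_age=c))
            rows.append(
                {
                    "transition": name, "sex": sex,
                    "rr_period": r.rr_period, "ci_low": r.ci_low,
                    "ci_high": r.ci_high, "p_value": r.p_value,
                    "coef_age": r.coef_age, "coef_age2": r.coef_age2,
                    "intercept": r.intercept, "dispersion": r.dispersion,
                    "centering_age": r.centering_age,
                }
            )
    return pd.DataFrame(rows)
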