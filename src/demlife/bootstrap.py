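"""Binomial bootstrap of age-specific event counts through the pipeline.

Each replicate redraws the age-specific incident-dementia and
dementia-death counts as Binomial(n = rounded person-years,
p = events / n), refits the old-age smoothing on the resampled series,
rebuilds the life table and recomputes the ALE quantities. Percentile
bounds over replicates give the confidence intervals; significance
between two estimates is judged by CI non-overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import KannistoFitError, UnstableStratumError
from .exposure import EventTable, rate_series
from .lifetable import ale_from_rates
from .rates import AGES, TransitionRates
from .smooth import SMOOTH_AGE_LO, fit_kannisto

ALE_FIELDS = ("ale_dem", "ale_nondem", "ale_total", "lyl", "ratio")


@dataclass(frozen=True)
class BootstrapConfig:
    replications: int = 1000
    seed: int = 0
    ci_level: float = 0.95
    resample_set: tuple = ("DI", "DM")  # non-DM deaths held fixed by default
    poisson: bool = False  # sensitivity switch: Poisson instead of binomial
    di_model: str = "kannisto"
    nondem_mode: str = "threestate"

    def __post_init__(self):
        if self.replications < 1:
            raise ValueError("replications must be >= 1")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")


@dataclass
class IntervalEstimate:
    point: float
    lo: float
    hi: float
    n_reps_used: int

    def __post_init__(self):
        if self.lo > self.hi:
            raise ValueError("interval lower bound exceeds upper bound")


def nonoverlap_significant(a: IntervalEstimate, b: IntervalEstimate) -> bool:
    """True iff the two confidence intervals do not overlap."""
    return a.hi < b.lo or b.hi < a.lo


def resample_counts_arrays(events, person_years, rng, poisson=False):
    """Binomial (or Poisson) redraw of an age-count series.

    n is the rounded person-years per cell; cells where events exceed n
    are clipped to p = 1.
    """
    ev = np.asarray(events, float)
    py = np.asarray(person_years, float)
    n = np.round(py).astype(np.int64)
    if poisson:
        return rng.poisson(ev).astype(float)
    out = np.zeros_like(ev)
    ok = n > 0
    p = np.clip(np.where(ok, ev / np.where(ok, n, 1), 0.0), 0.0, 1.0)
    out[ok] = rng.binomial(n[ok], p[ok])
    return out


def resample_counts(table: EventTable, rng, poisson=False) -> EventTable:
    """Replicate EventTable with redrawn event counts, exposures unchanged."""
    d = table.data.copy()
    d["events"] = resample_counts_arrays(
        d["events"].to_numpy(), d["person_years"].to_numpy(), rng, poisson
    ).astype(int)
    return EventTable(transition=table.transition, data=d)


def _observed_and_smoothed(stratum_events, cfg):
    """Point-estimate rate grid: observed below 80, fitted at 80+."""
    series = {}
    smooth_mask = AGES >= SMOOTH_AGE_LO
    for name in ("DI", "DM", "nonDM"):
        ev, py = stratum_events[name]
        r = rate_series(ev, py)
        r[np.isnan(r) & (AGES < SMOOTH_AGE_LO)] = 0.0
        model = cfg.di_model if name == "DI" else "kannisto"
        fit = fit_kannisto(ev[smooth_mask], py[smooth_mask], AGES[smooth_mask],
                           model=model)
        r[smooth_mask] = fit.hazard(AGES[smooth_mask])
        series[name] = r
    return series


def bootstrap_ale(stratum_events: dict, cfg: BootstrapConfig,
                  sex: str | None = None, period: str | None = None) -> dict:
    """Percentile CIs for the ALE quantities of one stratum.

    ``stratum_events`` maps transition name -> (events, person_years)
    arrays on the 65..100 grid. The point estimate comes from the
    unresampled data; replicates whose smoothing fit fails are dropped
    and counted, and more than 5% failures abort the stratum.

    Returns a dict field name -> IntervalEstimate.
    """
    rng = np.random.default_rng([int(cfg.seed), 77003])
    point_series = _observed_and_smoothed(stratum_events, cfg)
    point = ale_from_rates(
        TransitionRates(di=point_series["DI"], dm=point_series["DM"],
                        nondm=point_series["nonDM"], sex=sex, period=period),
        nondem_mode=cfg.nondem_mode,
    )

    smooth_mask = AGES >= SMOOTH_AGE_LO
    reps = {f: [] for f in ALE_FIELDS}
    failures = 0
    for _ in range(cfg.replications):
        series = {}
        try:
            for name in ("DI", "DM", "nonDM"):
                ev, py = stratum_events[name]
                if name in cfg.resample_set:
                    ev = resample_counts_arrays(ev, py, rng, cfg.poisson)
                    r = rate_series(ev, py)
                    r[np.isnan(r) & (AGES < SMOOTH_AGE_LO)] = 0.0
                    model = cfg.di_model if name == "DI" else "kannisto"
                    fit = fit_kannisto(ev[smooth_mask], py[smooth_mask],
                                       AGES[smooth_mask], model=model)
                    r[smooth_mask] = fit.hazard(AGES[smooth_mask])
                    series[name] = r
                else:
                    series[name] = point_series[name]
            res = ale_from_rates(
                TransitionRates(di=series["DI"], dm=series["DM"],
                                nondm=series["nonDM"]),
                nondem_mode=cfg.nondem_mode,
            )
        except KannistoFitError:
            failures += 1
            continue
        for f in ALE_FIELDS:
            reps[f].append(getattr(res, f))

    if failures > 0.05 * cfg.replications:
        raise UnstableStratumError(
            f"{failures}/{cfg.replications} bootstrap replicates failed "
            f"for stratum {sex}/{period}"
        )
    n_used = cfg.replications - failures
    alpha = (1.0 - cfg.ci_level) / 2.0
    out = {}
    for f in ALE_FIELDS:
        arr = np.asarray(reps[f])
        lo, hi = np.percentile(arr, [100 * alpha, 100 * (1 - alpha)])
        out[f] = IntervalEstimate(point=getattr(point, f), lo=float(lo),
                                  hi=float(hi), n_reps_used=n_used)
    return out
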