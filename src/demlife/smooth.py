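"""Old-age rate smoothing with the Kannisto logistic hazard.

Observed age-specific rates fluctuate randomly above age 80, where
exposure thins out. Before life-table construction, rates at ages
80-100 are replaced by a Kannisto logistic fit

    mu(x) = a * exp(b (x - 80)) / (1 + a * exp(b (x - 80))),  a, b > 0,

estimated by Poisson maximum likelihood on the (events, exposure) pairs.
Anchoring the exponent at age 80 is a pure reparameterisation that keeps
the optimisation well conditioned. Rates below 80 are never altered.
The incidence hazard can alternatively be smoothed log-linearly
(Gompertz), since it is not bounded by the logistic asymptote's
rationale; both forms share the same likelihood machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .errors import KannistoFitError
from .rates import AGES, OBSERVED, SMOOTHED, TRANSITIONS, TransitionRates

SMOOTH_AGE_LO = 80
SMOOTH_AGES = np.arange(SMOOTH_AGE_LO, 101)


@dataclass
class KannistoFit:
    """Fitted logistic (or log-linear) old-age hazard."""

    a: float
    b: float
    loglik: float
    model: str = "kannisto"  # or "gompertz"
    fit_age_range: tuple = (80, 100)

    def hazard(self, ages) -> np.ndarray:
        z = self.a * np.exp(self.b * (np.asarray(ages, float) - 80.0))
        if self.model == "gompertz":
            return z
        return z / (1.0 + z)


def _poisson_nll_grad(theta, x, events, exposure, logistic, inv_scale):
    """Normalised Poisson negative log-likelihood and gradient in
    (log a, log b); log-space hazard evaluation avoids overflow during
    line searches."""
    la, lb = theta
    b = np.exp(lb)
    log_z = np.clip(la + b * x, -600.0, 600.0)
    if logistic:
        mu = expit(log_z)
        log_mu = -np.logaddexp(0.0, -log_z)
        resid = (exposure * mu - events) * (1.0 - mu)
    else:
        mu = np.exp(log_z)
        log_mu = log_z
        resid = exposure * mu - events
    nll = float(np.sum(exposure * mu - events * log_mu)) * inv_scale
    grad = inv_scale * np.array(
        [np.sum(resid), np.sum(resid * b * x)]
    )
    return nll, grad


def fit_kannisto(events, exposure, ages=SMOOTH_AGES, model: str = "kannisto"
                 ) -> KannistoFit:
    """Poisson-MLE fit of the old-age hazard on the given ages.

    Cells with zero exposure contribute nothing to the likelihood.
    Starts from a = observed rate at the first informative age (clipped
    to (1e-6, 0.9)) and b = 0.1; a small deterministic grid of restarts
    guards against bad starts.
    """
    events = np.asarray(events, float)
    exposure = np.asarray(exposure, float)
    ages = np.asarray(ages, float)
    use = exposure > 0
    if use.sum() < 3:
        raise KannistoFitError("need >= 3 ages with positive exposure")
    if events[use].sum() <= 0:
        raise KannistoFitError("cannot smooth an all-zero hazard")
    x = ages[use] - 80.0
    ev, py = events[use], exposure[use]
    logistic = model == "kannisto"

    rate0 = ev[0] / py[0] if ev[0] > 0 else ev.sum() / py.sum()
    a0 = float(np.clip(rate0, 1e-6, 0.9))
    starts = [(a0, 0.1)]
    starts += [(np.clip(ev.sum() / py.sum(), 1e-6, 0.9), b) for b in (0.05, 0.15)]
    starts += [(0.05, 0.11), (0.2, 0.08)]

    inv_scale = 1.0 / max(1.0, float(ev.sum()))
    best = None
    for a_s, b_s in starts:
        res = minimize(
            _poisson_nll_grad,
            x0=np.log([a_s, b_s]),
            args=(x, ev, py, logistic, inv_scale),
            jac=True,
            method="L-BFGS-B",
            bounds=[(-25.0, 8.0), (-12.0, 1.5)],
            options={"gtol": 1e-8, "ftol": 1e-14, "maxiter": 500},
        )
        converged = (
            np.all(np.isfinite(res.x))
            and np.isfinite(res.fun)
            and float(np.linalg.norm(res.jac)) < 1e-6
        )
        if converged and (best is None or res.fun < best.fun - 1e-12):
            best = res
            break
        if np.all(np.isfinite(res.x)) and np.isfinite(res.fun) and (
            best is None or res.fun < best.fun
        ):
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise KannistoFitError(
            "old-age smoothing failed to converge", diagnostics=best
        )
    a, b = np.exp(best.x)
    return KannistoFit(a=float(a), b=float(b), loglik=-float(best.fun), model=model,
                       fit_age_range=(int(ages[use][0]), int(ages[use][-1])))


def smooth_rates(raw: TransitionRates, stratum_events: dict,
                 di_model: str = "kannisto") -> TransitionRates:
    """Replace rates at ages 80-100 with fitted old-age hazards.

    ``stratum_events`` maps transition name -> (events, person_years)
    arrays on the 65..100 grid for the same stratum as ``raw``. Each
    transition is fitted independently; failures name the stratum.
    Ages below 80 are returned untouched.
    """
    out = raw.copy()
    mask = AGES >= SMOOTH_AGE_LO
    for name in TRANSITIONS:
        ev, py = stratum_events[name]
        model = di_model if name == "DI" else "kannisto"
        try:
            fit = fit_kannisto(np.asarray(ev)[mask], np.asarray(py)[mask],
                               AGES[mask], model=model)
        except KannistoFitError as exc:
            raise KannistoFitError(
                f"smoothing failed for {name} ({raw.sex}/{raw.period}): {exc}",
                diagnostics=getattr(exc, "diagnostics", None),
            ) from exc
        series = out.series(name)
        series[mask] = fit.hazard(AGES[mask])
        prov = out.provenance[name]
        prov[mask] = SMOOTHED
        prov[~mask] = OBSERVED
    if not out.is_complete():
        raise KannistoFitError("rate grid incomplete after smoothing")
    return out
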