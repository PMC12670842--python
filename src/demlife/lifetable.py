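"""Three-state Markov health-disease life table and average life expectancy.

States: non-dementia -> dementia -> dead, plus non-dementia -> dead,
driven by the age-specific hazards DI(x), DM(x) and non-DM(x) on single
year-of-age intervals with constant hazards within each interval
(exponential survival). The table is truncated at age 100: all
expectancies are temporary expectancies between x and 100.

The decrements d(x) — transitions into the dementia state in [x, x+1) —
weight the age-specific temporary expectancies into a single average
life expectancy (ALE) that accounts for the distribution of age at
onset:

    ALE_dem     = sum_x e(x)  d(x) / sum_x d(x)
    ALE_nondem  = sum_x e*(x) d(x) / sum_x d(x)

where e(x) is the remaining-years expectancy of a person in the dementia
state at exact age x and e*(x) that of a person currently dementia-free.
Their difference is the excess life years lost (LYL) to dementia and
ALE_dem / (ALE_dem + ALE_nondem) is the proportion of remaining years
lived with dementia.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateDataError
from .rates import AGES, TransitionRates

_N_INT = 35  # single-year intervals 65..99


def _phi(u):
    """(1 - exp(-u)) / u, the expected time alive in a unit interval
    under constant hazard u; phi(0) = 1."""
    u = np.asarray(u, float)
    small = np.abs(u) < 1e-9
    safe = np.where(small, 1.0, u)
    return np.where(small, 1.0 - u / 2.0 + u * u / 6.0, -np.expm1(-safe) / safe)


def _ediff(h, m):
    """(exp(-m) - exp(-h)) / (h - m), continuous at h = m."""
    h = np.asarray(h, float)
    m = np.asarray(m, float)
    u = h - m
    small = np.abs(u) < 1e-9
    safe = np.where(small, 1.0, u)
    return np.where(
        small,
        np.exp(-m) * (1.0 - u / 2.0),
        (np.exp(-m) - np.exp(-h)) / safe,
    )


def _psi(h):
    """integral_0^1 t exp(-h t) dt; psi(0) = 1/2."""
    h = np.asarray(h, float)
    small = np.abs(h) < 1e-6
    safe = np.where(small, 1.0, h)
    return np.where(
        small,
        0.5 - h / 3.0 + h * h / 8.0,
        (1.0 - (1.0 + h) * np.exp(-h)) / (safe * safe),
    )


def _check_rates(rates: TransitionRates) -> None:
    for name in ("DI", "DM", "nonDM"):
        s = rates.series(name)
        if not np.all(np.isfinite(s)) or np.any(s < 0):
            raise ValueError(f"{name} rates must be finite and >= 0 on the full grid")


@dataclass
class LifeTable:
    """Survivorship, decrements and person-years of the illness-death model.

    Arrays indexed by age: ``l_nd`` and ``l_d`` at exact ages 65..100
    (radix l_nd(65) = 1), the rest on intervals [x, x+1) for x = 65..99.
    """

    ages: np.ndarray  # 65..100
    l_nd: np.ndarray  # 36
    l_d: np.ndarray  # 36
    d: np.ndarray  # 35, non-dementia -> dementia decrements
    deaths_nd: np.ndarray  # 35
    deaths_d: np.ndarray  # 35
    L_nd: np.ndarray  # 35, person-years in the non-dementia state
    L_d: np.ndarray  # 35


@dataclass
class StateExpectancies:
    """Temporary (to-age-100) expectancies at exact integer ages.

    ``e``: remaining years of a person in the dementia state at exact
    age x (survival under DM alone). ``e_star``: remaining years alive
    of a person currently dementia-free at exact age x; in the default
    three-state mode this includes years lived after a later onset.
    """

    ages: np.ndarray  # 65..100
    e: np.ndarray
    e_star: np.ndarray
    nondem_mode: str = "threestate"


@dataclass
class ALEResult:
    ale_dem: float
    ale_nondem: float
    ale_total: float
    lyl: float
    ratio: float
    weights: np.ndarray  # normalised d(x), 35 entries


def build_lifetable(rates: TransitionRates) -> LifeTable:
    """Run the illness-death model forward from radix 1 at age 65.

    Within each interval the competing exit hazards split the exits
    proportionally (constant-hazard result); deaths without dementia
    are taken as the residual so the accounting identity
    l_nd(x) = l_nd(x+1) + d(x) + deaths_nd(x) holds exactly. New
    dementia cases enter the dementia state at mid-interval for the
    occupancy and person-years bookkeeping.
    """
    _check_rates(rates)
    di = rates.di[:_N_INT]
    dm = rates.dm[:_N_INT]
    nondm = rates.nondm[:_N_INT]
    h = di + nondm

    l_nd = np.ones(_N_INT + 1)
    l_d = np.zeros(_N_INT + 1)
    d = np.zeros(_N_INT)
    deaths_nd = np.zeros(_N_INT)
    deaths_d = np.zeros(_N_INT)
    L_nd = np.zeros(_N_INT)
    L_d = np.zeros(_N_INT)

    for i in range(_N_INT):
        surv = np.exp(-h[i])
        l_nd[i + 1] = l_nd[i] * surv
        exits = l_nd[i] - l_nd[i + 1]
        frac_di = di[i] / h[i] if h[i] > 0 else 0.0
        d[i] = exits * frac_di
        # residual, grouped exactly as in the accounting identity so that
        # l_nd(x) = (l_nd(x+1) + d(x)) + deaths_nd(x) holds bit-exactly
        deaths_nd[i] = l_nd[i] - (l_nd[i + 1] + d[i])
        L_nd[i] = l_nd[i] * float(_phi(h[i]))

        m = dm[i]
        stay = np.exp(-m)
        half_stay = np.exp(-m / 2.0)
        l_d[i + 1] = l_d[i] * stay + d[i] * half_stay
        deaths_d[i] = l_d[i] * (1.0 - stay) + d[i] * (1.0 - half_stay)
        L_d[i] = l_d[i] * float(_phi(m)) + d[i] * 0.5 * float(_phi(m / 2.0))

    return LifeTable(
        ages=AGES.copy(), l_nd=l_nd, l_d=l_d, d=d, deaths_nd=deaths_nd,
        deaths_d=deaths_d, L_nd=L_nd, L_d=L_d,
    )


def state_expectancies(rates: TransitionRates,
                       nondem_mode: str = "threestate") -> StateExpectancies:
    """Backward recursion for e(x) and e*(x) on exact ages 65..100.

    e(x) follows from survival under DM alone. In the default
    ``threestate`` mode, e*(x) counts all remaining years alive of a
    currently dementia-free person, including years after a possible
    later onset; the within-interval onset time is integrated in closed
    form. ``nondem_hazard_only`` instead evaluates survival under
    non-DM(x) alone.
    """
    if nondem_mode not in ("threestate", "nondem_hazard_only"):
        raise ValueError(f"unknown nondem_mode: {nondem_mode}")
    _check_rates(rates)
    di = rates.di[:_N_INT]
    dm = rates.dm[:_N_INT]
    nondm = rates.nondm[:_N_INT]
    h = di + nondm

    e = np.zeros(_N_INT + 1)
    e_star = np.zeros(_N_INT + 1)
    for i in range(_N_INT - 1, -1, -1):
        m = dm[i]
        e[i] = float(_phi(m)) + np.exp(-m) * e[i + 1]
        if nondem_mode == "nondem_hazard_only":
            e_star[i] = float(_phi(nondm[i])) + np.exp(-nondm[i]) * e_star[i + 1]
            continue
        # expected years alive after an onset at time t in (0,1),
        # integrated over the onset density di * exp(-h t)
        if m > 1e-9:
            ed = float(_ediff(h[i], m))
            onset_int = (float(_phi(h[i])) - ed) / m + e[i + 1] * ed
        else:
            onset_int = (1.0 + e[i + 1]) * float(_phi(h[i])) - float(_psi(h[i]))
        e_star[i] = (
            float(_phi(h[i]))            # time alive while still dementia-free
            + di[i] * onset_int          # alive time after in-interval onset
            + np.exp(-h[i]) * e_star[i + 1]
        )
    return StateExpectancies(ages=AGES.copy(), e=e, e_star=e_star,
                             nondem_mode=nondem_mode)


def average_life_expectancy(exps: StateExpectancies, lt: LifeTable) -> ALEResult:
    """Decrement-weighted ALE, excess LYL and the dementia/total ratio.

    Weights are the normalised decrements d(x): the distribution of age
    at dementia onset implied by the model itself. Expectancies enter at
    the integer age of the onset interval.
    """
    total_d = lt.d.sum()
    if total_d <= 0:
        raise DegenerateDataError(
            "no dementia incidence in the life table: ALE undefined"
        )
    w = lt.d / total_d
    ale_dem = float(np.dot(exps.e[:_N_INT], w))
    ale_nondem = float(np.dot(exps.e_star[:_N_INT], w))
    ale_total = ale_dem + ale_nondem
    return ALEResult(
        ale_dem=ale_dem,
        ale_nondem=ale_nondem,
        ale_total=ale_total,
        lyl=ale_nondem - ale_dem,
        ratio=ale_dem / ale_total,
        weights=w,
    )


def ale_identities(ale_dem: float, ale_nondem: float):
    """(total, lyl, ratio) implied by a pair of ALE values.

    The total is the sum of the two state expectancies, the excess life
    years lost their difference, and the ratio the dementia share of the
    total — the internal arithmetic that ties the reported tables
    together.
    """
    total = ale_dem + ale_nondem
    return total, ale_nondem - ale_dem, ale_dem / total


def ale_from_rates(rates: TransitionRates,
                   nondem_mode: str = "threestate") -> ALEResult:
    """Convenience: rates -> life table + expectancies -> ALE."""
    lt = build_lifetable(rates)
    exps = state_expectancies(rates, nondem_mode=nondem_mode)
    return average_life_expectancy(exps, lt)
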