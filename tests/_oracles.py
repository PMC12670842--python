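"""Independent oracles used by the test suite.

These deliberately avoid the package's own recursion/accounting code
paths: expectancies are estimated by brute-force agent simulation and
expected claims-panel rates by exact per-segment integration of the
piecewise-constant hazards.
"""

from __future__ import annotations

import numpy as np

from demlife.rates import AGES

N_INT = 35


def sample_exit_times(rng, n, rates, start_idx):
    """Years from exact age AGES[start_idx] to event under the
    piecewise-constant hazard ``rates`` (35 interval values); inf means
    survival to age 100."""
    E = rng.exponential(size=n)
    t = np.zeros(n)
    out = np.full(n, np.inf)
    active = np.ones(n, bool)
    for i in range(start_idx, N_INT):
        r = rates[i]
        need = np.where(r > 0, E / np.where(r > 0, r, 1.0), np.inf)
        hit = active & (need <= 1.0)
        out[hit] = t[hit] + need[hit]
        E = E - r
        t += 1.0
        active &= ~hit
    return out


def _post_onset_years(rng, ages_cont, dm, horizon):
    """Years alive after dementia onset at continuous ages, capped at 100."""
    n = ages_cont.size
    E = rng.exponential(size=n)
    t = np.zeros(n)
    out = horizon.copy()
    active = np.ones(n, bool)
    cur = ages_cont.copy()
    for _ in range(N_INT + 1):
        idx = np.clip(np.floor(cur).astype(int) - 65, 0, N_INT - 1)
        seg = np.clip(np.minimum(np.floor(cur) + 1.0 - cur, horizon - t), 0, None)
        r = dm[idx]
        need = np.where(r > 0, E / np.where(r > 0, r, 1.0), np.inf)
        hit = active & (need <= seg)
        out[hit] = t[hit] + need[hit]
        E = E - r * seg
        t = t + seg
        cur = cur + seg
        active &= ~hit & (t < horizon - 1e-12)
        if not active.any():
            break
    return out


def microsim_ale(rates, rng, n_weights=200_000, n_per_age=20_000):
    """Monte-Carlo estimates of ale_dem / ale_nondem with standard errors.

    Decrement weights come from simulating dementia-free agents from 65;
    the per-age expectancies e(x) and e*(x) come from dropping fresh
    agent cohorts at each exact integer age. Returns
    (ale_dem, se_dem, ale_nondem, se_nondem).
    """
    di, dm, nd = rates.di[:N_INT], rates.dm[:N_INT], rates.nondm[:N_INT]

    # onset-age distribution of the non-dementia process
    t_on = sample_exit_times(rng, n_weights, di, 0)
    t_nd = sample_exit_times(rng, n_weights, nd, 0)
    onset = (t_on < t_nd) & (t_on < N_INT)
    onset_age_idx = np.floor(t_on[onset]).astype(int)
    counts = np.bincount(onset_age_idx, minlength=N_INT).astype(float)
    n_onsets = counts.sum()
    w = counts / n_onsets

    e_hat = np.zeros(N_INT)
    e_var = np.zeros(N_INT)
    es_hat = np.zeros(N_INT)
    es_var = np.zeros(N_INT)
    for ix in range(N_INT):
        horizon = float(N_INT - ix)
        yrs = np.minimum(sample_exit_times(rng, n_per_age, dm, ix), horizon)
        e_hat[ix] = yrs.mean()
        e_var[ix] = yrs.var(ddof=1) / n_per_age

        t1 = sample_exit_times(rng, n_per_age, di, ix)
        t2 = sample_exit_times(rng, n_per_age, nd, ix)
        got = (t1 < t2) & (t1 < horizon)
        alive = np.minimum(np.where(got, t1, t2), horizon)
        if got.any():
            extra = _post_onset_years(
                rng, AGES[ix] + t1[got], dm, horizon - t1[got]
            )
            alive = alive.copy()
            alive[got] += extra
        es_hat[ix] = alive.mean()
        es_var[ix] = alive.var(ddof=1) / n_per_age

    def combine(vals, vvars):
        est = float(np.dot(w, vals))
        var_w = float(np.dot(w, vals ** 2) - est ** 2) / n_onsets
        var_e = float(np.dot(w ** 2, vvars))
        return est, np.sqrt(var_w + var_e)

    ale_dem, se_dem = combine(e_hat, e_var)
    ale_nondem, se_nondem = combine(es_hat, es_var)
    return ale_dem, se_dem, ale_nondem, se_nondem


def expected_panel_di_rate(config, period="P1"):
    """Truth-implied aggregate dementia onset rate of a simulated panel.

    Exact integration: entry ages are month-discretised draws from the
    truncated-exponential design, hazards are constant on single-year
    age segments, so expected onsets and non-dementia person-years over
    the 5-year panel have closed forms per segment.
    """
    scale, span = config.entry_age_scale, 35.0
    months = np.arange(65 * 12, 100 * 12)  # age in months at baseline
    lo = (months - 65 * 12) / 12.0
    hi = lo + 1.0 / 12.0
    z = 1.0 - np.exp(-span / scale)
    pmass = (np.exp(-lo / scale) - np.exp(-hi / scale)) / z

    total_onsets = 0.0
    total_py = 0.0
    exit_h = -np.log1p(-config.switch_rate) if config.switch_rate > 0 else 0.0
    for sex, frac in (("m", 1 - config.frac_female), ("f", config.frac_female)):
        a_start = months / 12.0 - 2.0  # continuous age at panel start
        S = np.ones_like(a_start)
        t = np.zeros_like(a_start)
        onsets = np.zeros_like(a_start)
        py = np.zeros_like(a_start)
        for _ in range(6):
            age_int = np.floor(a_start + t)
            seg = np.minimum(age_int + 1.0 - (a_start + t), 5.0 - t)
            seg = np.clip(seg, 0.0, None)
            h_di = config.incidence_params.hazard(sex, age_int, period)
            h_nd = config.nondem_mortality_params.hazard(sex, age_int, period)
            H = h_di + h_nd + exit_h
            with np.errstate(divide="ignore", invalid="ignore"):
                decay = np.exp(-H * seg)
                time_alive = np.where(H > 0, (1.0 - decay) / np.where(H > 0, H, 1), seg)
            onsets += S * h_di * time_alive
            py += S * time_alive
            S = S * decay
            t = t + seg
        total_onsets += frac * float(np.dot(pmass, onsets))
        total_py += frac * float(np.dot(pmass, py))
    return total_onsets / total_py
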