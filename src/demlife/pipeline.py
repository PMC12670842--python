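"""End-to-end orchestration: simulate -> validate -> rates -> trends ->
smooth -> life table -> bootstrap, with CSV outputs shaped like the
standard reporting tables (crude rates, trend rate ratios, ALE/LYL/ratio
with CIs) and a machine-readable run manifest.

All randomness flows from one global seed via named substreams, so a
fixed configuration reproduces byte-identical outputs. Every interchange
format is CSV; a pre-aggregated rate table can enter the pipeline
mid-stream in place of the claims stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bootstrap import ALE_FIELDS, BootstrapConfig, bootstrap_ale
from .errors import InputFormatError
from .exposure import (EventTable, age_specific_rates, person_time_slices,
                       summary_table)
from .lifetable import (average_life_expectancy, build_lifetable,
                        state_expectancies)
from .rates import AGES, TRANSITIONS, TransitionRates
from .smooth import smooth_rates
from .synthclaims import SimConfig, simulate_cohort, write_panel
from .trends import trend_table
from .validate import CaseDefinition, build_episodes

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "validate", "rates", "trends", "smooth",
              "lifetable", "bootstrap")

RATE_TABLE_COLUMNS = ("sex", "period", "age", "events", "person_years")


@dataclass
class RunConfig:
    outdir: str = "demlife_out"
    seed: int = 0
    stages: tuple = ALL_STAGES
    sim: SimConfig = field(default_factory=SimConfig)
    case_definition: CaseDefinition = field(default_factory=CaseDefinition)
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    periods: tuple = ("P1", "P2")
    event_table_paths: dict = field(default_factory=dict)  # mid-stream entry
    nondem_mode: str = "threestate"
    di_smooth_model: str = "kannisto"
    write_panels: bool = False
    plot_rates: bool = False

    def config_hash(self) -> str:
        blob = yaml.safe_dump(_jsonable(asdict(self)), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def write_rate_table(table: EventTable, path) -> None:
    table.data.loc[:, list(RATE_TABLE_COLUMNS)].to_csv(path, index=False)


def read_rate_table(path, transition: str) -> EventTable:
    """Tolerant CSV reader for pre-aggregated (sex, period, age) counts."""
    path = Path(path)
    try:
        d = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise InputFormatError(f"{path}: empty rate table") from exc
    missing = set(RATE_TABLE_COLUMNS) - set(d.columns)
    if missing:
        raise InputFormatError(f"{path}: missing columns {sorted(missing)}")
    extra = set(d.columns) - set(RATE_TABLE_COLUMNS)
    if extra:
        logger.warning("%s: ignoring unknown columns %s", path, sorted(extra))
    bad = d.index[
        d["events"].isna() | d["person_years"].isna() | d["age"].isna()
    ].tolist()
    if bad:
        raise InputFormatError(
            f"{path}: malformed rows at lines {[i + 2 for i in bad[:20]]}"
        )
    d = d.loc[:, list(RATE_TABLE_COLUMNS)].astype(
        {"age": int, "events": int, "person_years": float}
    )
    t = EventTable(transition=transition, data=d)
    t.check_invariants()
    return t


def run_all(cfg: RunConfig) -> dict:
    """Execute the enabled stages in order; returns the summary tables.

    Stage outputs are persisted as CSV under ``cfg.outdir`` as they
    complete, so a failing stage leaves all earlier results on disk.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}
    stages = set(cfg.stages)

    tables: dict[str, EventTable] | None = None
    if {"simulate", "validate", "rates"} & stages:
        sim_cfg = replace(cfg.sim, seed=cfg.seed)
        parts = {t: [] for t in TRANSITIONS}
        episodes_frames = []
        for period in cfg.periods:
            panel = simulate_cohort(sim_cfg, period)
            if cfg.write_panels:
                write_panel(panel, out / f"panel_{period}")
            episodes = build_episodes(panel, cfg.case_definition)
            ep = episodes.data.copy()
            ep["period"] = period
            episodes_frames.append(ep)
            di, dm, nondm = person_time_slices(episodes, persons=panel.persons)
            for t, tab in zip(TRANSITIONS, (di, dm, nondm)):
                parts[t].append(tab.data)
        pd.concat(episodes_frames, ignore_index=True).to_csv(
            out / "episodes.csv", index=False
        )
        tables = {
            t: EventTable(transition=t,
                          data=pd.concat(parts[t], ignore_index=True))
            for t in TRANSITIONS
        }
    elif cfg.event_table_paths:
        tables = {
            t: read_rate_table(cfg.event_table_paths[t], t)
            for t in cfg.event_table_paths
        }
        for t in TRANSITIONS:
            tables.setdefault(t, tables["DI"])

    if tables is None:
        raise InputFormatError(
            "no input: enable the claims stages or provide event_table_paths"
        )
    for t, tab in tables.items():
        write_rate_table(tab, out / f"event_table_{t}.csv")

    if "rates" in stages or tables is not None:
        summary["rates"] = summary_table(tables["DI"], tables["DM"],
                                         tables["nonDM"])
        summary["rates"].to_csv(out / "rates_summary.csv", index=False)

    if "trends" in stages:
        try:
            summary["trends"] = trend_table(tables)
            summary["trends"].to_csv(out / "trend_results.csv", index=False)
        except Exception as exc:
            raise RuntimeError(f"stage 'trends' failed: {exc}") from exc

    strata = [
        (s, p)
        for s in ("m", "f")
        for p in sorted(tables["DI"].data["period"].unique())
        if tables["DI"].stratum(s, p)[1].sum() > 0
    ]
    smoothed: dict = {}
    if {"smooth", "lifetable", "bootstrap"} & stages:
        rows = []
        for sex, period in strata:
            raw = age_specific_rates(tables["DI"], tables["DM"],
                                     tables["nonDM"], sex, period)
            ev_py = {t: tables[t].stratum(sex, period) for t in TRANSITIONS}
            sm = smooth_rates(raw, ev_py, di_model=cfg.di_smooth_model)
            smoothed[(sex, period)] = (sm, ev_py)
            for t in TRANSITIONS:
                rows.append(pd.DataFrame({
                    "sex": sex, "period": period, "transition": t,
                    "age": AGES, "rate": sm.series(t),
                    "provenance": sm.provenance[t],
                }))
        pd.DataFrame(pd.concat(rows, ignore_index=True)).to_csv(
            out / "smoothed_rates.csv", index=False
        )
        if cfg.plot_rates:
            _plot_rates(smoothed, tables, out / "rates_diagnostics.png")

    if {"lifetable", "bootstrap"} & stages:
        lt_rows, ale_rows = [], []
        for (sex, period), (sm, _) in smoothed.items():
            lt = build_lifetable(sm)
            exps = state_expectancies(sm, nondem_mode=cfg.nondem_mode)
            ale = average_life_expectancy(exps, lt)
            lt_rows.append(pd.DataFrame({
                "sex": sex, "period": period, "age": AGES,
                "l_nd": lt.l_nd, "l_d": lt.l_d,
                "d": np.append(lt.d, np.nan),
                "deaths_nd": np.append(lt.deaths_nd, np.nan),
                "deaths_d": np.append(lt.deaths_d, np.nan),
                "L_nd": np.append(lt.L_nd, np.nan),
                "L_d": np.append(lt.L_d, np.nan),
                "e": exps.e, "e_star": exps.e_star,
            }))
            ale_rows.append({
                "sex": sex, "period": period, "ale_dem": ale.ale_dem,
                "ale_nondem": ale.ale_nondem, "ale_total": ale.ale_total,
                "lyl": ale.lyl, "ratio": ale.ratio,
            })
        pd.concat(lt_rows, ignore_index=True).to_csv(out / "lifetable.csv",
                                                     index=False)
        summary["ale"] = pd.DataFrame(ale_rows)
        summary["ale"].to_csv(out / "ale_results.csv", index=False)

    if "bootstrap" in stages:
        ci_rows = []
        for k, ((sex, period), (_, ev_py)) in enumerate(smoothed.items()):
            bcfg = BootstrapConfig(
                replications=cfg.bootstrap.replications,
                seed=int(np.random.SeedSequence(
                    [cfg.seed, 1000 + k]
                ).generate_state(1)[0] % (2 ** 31)),
                ci_level=cfg.bootstrap.ci_level,
                resample_set=cfg.bootstrap.resample_set,
                poisson=cfg.bootstrap.poisson,
                di_model=cfg.di_smooth_model,
                nondem_mode=cfg.nondem_mode,
            )
            est = bootstrap_ale(ev_py, bcfg, sex=sex, period=period)
            row = {"sex": sex, "period": period}
            for f in ALE_FIELDS:
                row[f] = est[f].point
                row[f"{f}_lo"] = est[f].lo
                row[f"{f}_hi"] = est[f].hi
            row["n_reps_used"] = est["ale_dem"].n_reps_used
            ci_rows.append(row)
        summary["ale_ci"] = pd.DataFrame(ci_rows)
        summary["ale_ci"].to_csv(out / "ale_ci.csv", index=False)

    manifest = {
        "package": "demlife",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "stages": sorted(stages),
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    summary["manifest"] = manifest
    return summary


def _plot_rates(smoothed, tables, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(len(smoothed), 3, figsize=(12, 3 * len(smoothed)),
                             squeeze=False)
    for i, ((sex, period), (sm, ev_py)) in enumerate(smoothed.items()):
        for j, t in enumerate(TRANSITIONS):
            ev, py = ev_py[t]
            with np.errstate(divide="ignore", invalid="ignore"):
                obs = np.where(py > 0, ev / np.where(py > 0, py, 1), np.nan)
            ax = axes[i][j]
            ax.plot(AGES, obs, "o", ms=3, label="observed")
            ax.plot(AGES, sm.series(t), "-", label="smoothed")
            ax.set_yscale("log")
            ax.set_title(f"{t} {sex}/{period}", fontsize=9)
            if i == 0 and j == 0:
                ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
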