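"""Epidemiological outcome measures and the scenario-suite report.

Incident cases and T2DM-related deaths are integrals of the corresponding
hazard flows (not differences of prevalent counts), so mortality and aging
cannot masquerade as prevention.  Averted burden is always a difference
against a named counterfactual baseline sharing grid and initial state.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import SimulationError, Trajectory, simulate
from .scenarios import ScenarioSpec, build_forcing
from .strata import ADULT_BANDS, FACTOR_ON, FACTORS, T2DM


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (reported percentages use 1 decimal place)."""
    q = decimal.Decimal(10) ** -ndigits
    return float(
        decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    )


def prevalence(traj: Trajectory, year: float, ages: slice = ADULT_BANDS) -> float:
    """T2DM prevalence (fraction) over the age range, both sexes."""
    ti = traj.year_index(year)
    sub = traj.counts[ti][:, ages]
    total = sub.sum()
    if total <= 0:
        raise ValueError("empty population in requested age range")
    return float(sub[..., T2DM].sum() / total)


def factor_prevalence(
    traj: Trajectory, year: float, factor: str, ages: slice = ADULT_BANDS
) -> float:
    """Aggregate prevalence (fraction) of one risk factor, whole population."""
    ti = traj.year_index(year)
    k = FACTORS.index(factor)
    sub = traj.counts[ti][:, ages]
    return float(sub[:, :, list(FACTOR_ON[k]), :].sum() / sub.sum())


def _cum_window(cum: np.ndarray, traj: Trajectory, window: tuple) -> float:
    i0, i1 = traj.year_index(window[0]), traj.year_index(window[1])
    return float(cum[i1].sum() - cum[i0].sum())


def _check_grids(baseline: Trajectory, scen: Trajectory) -> None:
    if len(baseline.years) != len(scen.years) or not np.allclose(
        baseline.years, scen.years
    ):
        raise ValueError("trajectories are on different reporting grids")


def cases_averted(
    baseline: Trajectory, scen: Trajectory, window: tuple
) -> dict[str, float]:
    """Cumulative incident T2DM cases averted vs baseline over a window."""
    _check_grids(baseline, scen)
    base = _cum_window(baseline.cum_cases, baseline, window)
    count = base - _cum_window(scen.cum_cases, scen, window)
    return {"count": count, "proportion": count / base if base > 0 else 0.0}


def deaths_averted(
    baseline: Trajectory, scen: Trajectory, window: tuple
) -> dict[str, float]:
    """Cumulative T2DM-related deaths averted vs baseline over a window."""
    _check_grids(baseline, scen)
    base = _cum_window(baseline.cum_deaths, baseline, window)
    count = base - _cum_window(scen.cum_deaths, scen, window)
    return {"count": count, "proportion": count / base if base > 0 else 0.0}


def relative_reduction(p_base: float, p_scen: float) -> float:
    """(p_base - p_scen) / p_base, computed on unrounded prevalences."""
    if p_base <= 0:
        raise ValueError("baseline prevalence must be positive")
    return (p_base - p_scen) / p_base


def case_fatality_rate(traj: Trajectory, year: float, ages: slice = ADULT_BANDS) -> float:
    """Annual T2DM-related deaths per 1000 prevalent cases.

    Annual deaths are the cumulative-death increment over the calendar year
    starting at ``year``; prevalent cases are the mid-year value (average of
    the two bracketing grid points).
    """
    i0 = traj.year_index(year)
    i1 = traj.year_index(year + 1.0)
    deaths = float(
        traj.cum_deaths[i1][:, ages].sum() - traj.cum_deaths[i0][:, ages].sum()
    )
    cases0 = traj.counts[i0][:, ages, :, T2DM].sum()
    cases1 = traj.counts[i1][:, ages, :, T2DM].sum()
    cases = 0.5 * (cases0 + cases1)
    if cases <= 0:
        raise ValueError("no prevalent cases at requested year")
    return 1000.0 * deaths / cases


@dataclass
class OutcomeReport:
    """Suite results: one row per scenario plus the baseline trajectory."""

    table: pd.DataFrame
    baseline: Trajectory
    trajectories: dict[str, Trajectory] = field(default_factory=dict)

    def to_csv(self, path, **kw) -> None:
        self.table.to_csv(path, index=False, **kw)


REPORT_COLUMNS = [
    "scenario",
    "prev_2031_pct", "rel_reduction_2031_pct",
    "cases_averted_2016_2031", "prop_cases_averted_2031_pct",
    "deaths_averted_2016_2031", "prop_deaths_averted_2031_pct",
    "prev_2050_pct", "rel_reduction_2050_pct",
    "cases_averted_2016_2050", "prop_cases_averted_2050_pct",
    "deaths_averted_2016_2050", "prop_deaths_averted_2050_pct",
    "status",
]


def suite_report(
    scenario_library: dict[str, ScenarioSpec],
    params,
    initial,
    *,
    t0: float = 2016.0,
    t1: float = 2050.0,
    mid_year: float = 2031.0,
    keep_trajectories: bool = False,
    **sim_kw,
) -> OutcomeReport:
    """Run the baseline plus every scenario and tabulate averted burden.

    Columns mirror the standard intervention-impact layout: prevalence and
    relative prevalence reduction at the intermediate and final horizon, plus
    cases/deaths averted (counts and proportions) over both windows.  A
    failing scenario is marked in its ``status`` column and the run continues.
    """
    base = simulate(params, None, initial, t0, t1, **sim_kw)
    p0 = {k: factor_prevalence(base, t0, k) for k in FACTORS}
    rows = []
    trajs: dict[str, Trajectory] = {}
    rows.append(_report_row("baseline", base, base, mid_year, t1) | {"status": "ok"})
    for name, spec in scenario_library.items():
        try:
            forcing = build_forcing(spec, p0)
            traj = simulate(params, forcing, initial, t0, t1, **sim_kw)
            rows.append(_report_row(name, base, traj, mid_year, t1) | {"status": "ok"})
            if keep_trajectories:
                trajs[name] = traj
        except (SimulationError, ValueError) as exc:  # keep the suite going
            rows.append({"scenario": name, "status": f"failed: {exc}"})
    table = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    return OutcomeReport(table=table, baseline=base, trajectories=trajs)


def _report_row(
    name: str, base: Trajectory, traj: Trajectory, mid: float, end: float
) -> dict:
    row: dict = {"scenario": name}
    for year, tag in ((mid, "2031"), (end, "2050")):
        pb = prevalence(base, year)
        ps = prevalence(traj, year)
        ca = cases_averted(base, traj, (base.years[0], year))
        da = deaths_averted(base, traj, (base.years[0], year))
        row[f"prev_{tag}_pct"] = round_half_up(100 * ps)
        row[f"rel_reduction_{tag}_pct"] = round_half_up(100 * relative_reduction(pb, ps))
        row[f"cases_averted_2016_{tag}"] = round_half_up(ca["count"], 0)
        row[f"prop_cases_averted_{tag}_pct"] = round_half_up(100 * ca["proportion"])
        row[f"deaths_averted_2016_{tag}"] = round_half_up(da["count"], 0)
        row[f"prop_deaths_averted_{tag}_pct"] = round_half_up(100 * da["proportion"])
    return row
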