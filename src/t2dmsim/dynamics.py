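"""Deterministic dynamics: flows, numerical integration, trajectories.

The model is a linear (given fixed forcing) system of ordinary differential
equations over the 768 compartments, extended with 2 x 16 cumulative incident
T2DM cases and 2 x 16 cumulative T2DM-related excess deaths accumulated as
integrals of the corresponding hazard flows.

Flows
-----
1. entry into the youngest band (susceptible, risk-free, no intervention);
2. aging between adjacent bands at 1/(band width) per year;
3. background mortality ``mu`` from every compartment;
4. per-factor acquisition ``eta_k`` (off -> on) and cessation ``rho_k``
   (on -> off), preserving disease and intervention status;
5. T2DM incidence at the multiplicative-relative-risk hazard from each
   susceptible stratum to the t2dm stratum with the same sex/age/risk combo
   (the intervention label is dropped on conversion);
6. T2DM-related excess mortality ``nu`` from t2dm strata;
7. PA-intervention recruitment from (susceptible, none) to
   (susceptible, pa_active) at the forcing's recruitment rate, ages 15-64.

Integration uses an adaptive explicit Runge-Kutta solver (scipy ``RK45``,
rtol 1e-8, atol 1e-10 by default); a fixed-step classical RK4 mode exists for
oracle comparisons and for smooth calibration objectives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .parameters import ParameterSet
from .strata import (
    ADULT_BANDS,
    AGE_BANDS,
    COMBO_BITS,
    FACTOR_OFF,
    FACTOR_ON,
    N_AGE,
    N_COMBO,
    N_SEX,
    N_STATE,
    SEXES,
    SHAPE,
    STATES,
    SUSCEPTIBLE_NONE,
    SUSCEPTIBLE_PA,
    T2DM,
    StratumIndex,
    unflatten,
)

N_COUNTS = int(np.prod(SHAPE))
N_FLOW = N_SEX * N_AGE
N_Y = N_COUNTS + 2 * N_FLOW  # packed state-vector length


class SimulationError(RuntimeError):
    pass


@dataclass
class PopulationState:
    """Compartment occupancy (persons) at one calendar time."""

    counts: np.ndarray  # (2, 16, 8, 3)
    time: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float).reshape(SHAPE)

    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class StepControls:
    """Forcing controls held constant over one control step.

    ``eta_mult``/``rho_mult`` are (3, 2, 16) multipliers applied to the
    acquisition/cessation hazards of *susceptible* compartments only;
    ``pa_recruit_rate`` is the per-capita recruitment hazard (/year) from
    (susceptible, none) to (susceptible, pa_active) among ages 15-64.
    """

    eta_mult: np.ndarray | None = None
    rho_mult: np.ndarray | None = None
    pa_recruit_rate: float = 0.0


def incidence_hazard(stratum: StratumIndex, params: ParameterSet) -> float:
    """T2DM incidence hazard (/year) for one susceptible stratum.

    ``lambda0(sex, age) * rr_obesity^[obese] * rr_smoking^[smoker] *
    rr_inactivity^[inactive] * rr_pa^[pa_active]`` — relative risks compose
    multiplicatively under the independence assumption.
    """
    if stratum.disease != "susceptible":
        raise ValueError("incidence hazard is defined for susceptible strata only")
    s = SEXES.index(stratum.sex)
    a = AGE_BANDS.index(stratum.age_band)
    h = params.lambda0[s, a]
    if stratum.obese:
        h *= params.rr_obesity
    if stratum.smoker:
        h *= params.rr_smoking
    if stratum.inactive:
        h *= params.rr_inactivity
    if stratum.intervention == "pa_active":
        h *= params.rr_pa
    return float(h)


def rhs(
    t: float,
    counts: np.ndarray,
    params: ParameterSet,
    controls: StepControls | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Time derivative of (counts, cumulative cases, cumulative deaths)."""
    if controls is None:
        controls = StepControls()
    c = counts
    dc = np.zeros(SHAPE)

    # (1) entry
    entry = params.entry_at(t)
    dc[:, 0, 0, SUSCEPTIBLE_NONE] += entry

    # (2) aging
    flow = params.aging_rate[None, :, None, None] * c
    dc -= flow
    dc[:, 1:] += flow[:, :-1]

    # (3) background mortality
    dc -= params.mu[:, :, None, None] * c

    # (4) risk-factor acquisition / cessation
    for k in range(3):
        off, on = list(FACTOR_OFF[k]), list(FACTOR_ON[k])
        e = params.eta[k][:, :, None, None]
        r = params.rho[k][:, :, None, None]
        acq = e * c[:, :, off, :]
        ces = r * c[:, :, on, :]
        if controls.eta_mult is not None:
            acq[..., :T2DM] *= controls.eta_mult[k][:, :, None, None]
        if controls.rho_mult is not None:
            ces[..., :T2DM] *= controls.rho_mult[k][:, :, None, None]
        dc[:, :, off, :] += ces - acq
        dc[:, :, on, :] += acq - ces

    # (5) incidence
    haz = params.lambda0[:, :, None] * params.rr_combo[None, None, :]
    inc0 = haz * c[..., SUSCEPTIBLE_NONE]
    inc1 = haz * params.rr_pa * c[..., SUSCEPTIBLE_PA]
    dc[..., SUSCEPTIBLE_NONE] -= inc0
    dc[..., SUSCEPTIBLE_PA] -= inc1
    inc = inc0 + inc1
    dc[..., T2DM] += inc
    dcases = inc.sum(axis=2)

    # (6) excess mortality
    death = params.nu[:, :, None] * c[..., T2DM]
    dc[..., T2DM] -= death
    ddeaths = death.sum(axis=2)

    # (7) PA recruitment (ages 15-64)
    r = controls.pa_recruit_rate
    if r:
        rec = r * c[:, ADULT_BANDS, :, SUSCEPTIBLE_NONE]
        dc[:, ADULT_BANDS, :, SUSCEPTIBLE_NONE] -= rec
        dc[:, ADULT_BANDS, :, SUSCEPTIBLE_PA] += rec

    return dc, dcases, ddeaths


def _pack(counts: np.ndarray, cases: np.ndarray, deaths: np.ndarray) -> np.ndarray:
    return np.concatenate([counts.ravel(), cases.ravel(), deaths.ravel()])


def _unpack(y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    counts = y[:N_COUNTS].reshape(SHAPE)
    cases = y[N_COUNTS : N_COUNTS + N_FLOW].reshape(N_SEX, N_AGE)
    deaths = y[N_COUNTS + N_FLOW :].reshape(N_SEX, N_AGE)
    return counts, cases, deaths


def _ode_fun(params: ParameterSet, controls: StepControls | None):
    def fun(t, y):
        counts, _, _ = _unpack(y)
        dc, dca, dde = rhs(t, counts, params, controls)
        return _pack(dc, dca, dde)

    return fun


def _rk4(fun, t0: float, t1: float, y0: np.ndarray, dt: float) -> np.ndarray:
    """Classical fixed-step RK4 from t0 to t1 (step shortened to land on t1)."""
    n = max(1, int(np.ceil((t1 - t0) / dt - 1e-12)))
    h = (t1 - t0) / n
    y = y0
    t = t0
    for _ in range(n):
        k1 = fun(t, y)
        k2 = fun(t + h / 2, y + h / 2 * k1)
        k3 = fun(t + h / 2, y + h / 2 * k2)
        k4 = fun(t + h, y + h * k3)
        y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += h
    return y


@dataclass
class Trajectory:
    """Model solution on the reporting grid plus cumulative flow integrals."""

    years: np.ndarray  # (T,)
    counts: np.ndarray  # (T, 2, 16, 8, 3)
    cum_cases: np.ndarray  # (T, 2, 16)
    cum_deaths: np.ndarray  # (T, 2, 16)

    def year_index(self, year: float) -> int:
        hits = np.nonzero(np.isclose(self.years, year))[0]
        if len(hits) == 0:
            raise ValueError(f"year {year} is not on the reporting grid")
        return int(hits[0])

    def state_at(self, year: float) -> PopulationState:
        return PopulationState(self.counts[self.year_index(year)].copy(), float(year))

    def to_frame(self) -> pd.DataFrame:
        """Tidy long format: one row per (year, compartment)."""
        rows = []
        for ti, year in enumerate(self.years):
            flat = self.counts[ti].ravel()
            for pos, v in enumerate(flat):
                st = unflatten(pos)
                rows.append(
                    (year, st.sex, st.age_band, int(st.obese), int(st.smoker),
                     int(st.inactive), st.disease, st.intervention, v)
                )
        return pd.DataFrame(
            rows,
            columns=["year", "sex", "age_band", "obese", "smoker", "inactive",
                     "disease", "intervention", "count"],
        )

    def flows_frame(self) -> pd.DataFrame:
        rows = []
        for ti, year in enumerate(self.years):
            for s, sex in enumerate(SEXES):
                for a, band in enumerate(AGE_BANDS):
                    rows.append(
                        (year, sex, band, self.cum_cases[ti, s, a],
                         self.cum_deaths[ti, s, a])
                    )
        return pd.DataFrame(
            rows, columns=["year", "sex", "age_band", "cum_cases", "cum_deaths"]
        )


def _check_and_clamp(counts: np.ndarray, t: float, neg_tol: float) -> np.ndarray:
    lo = counts.min()
    if lo < -neg_tol:
        pos = int(np.argmin(counts.ravel()))
        st = unflatten(pos)
        raise SimulationError(
            f"negative compartment count {lo:.3e} at t={t:.3f} in stratum {st}"
        )
    return np.maximum(counts, 0.0)


def simulate(
    params: ParameterSet,
    forcing,
    initial: PopulationState,
    t0: float = 2016.0,
    t1: float = 2050.0,
    *,
    method: str = "adaptive",
    rtol: float = 1e-8,
    atol: float = 1e-10,
    rk4_dt: float = 0.01,
    control_dt: float = 0.5,
    report_dt: float = 1.0,
    neg_tol_rel: float = 1e-9,
) -> Trajectory:
    """Integrate the model from ``t0`` to ``t1``.

    ``forcing`` is ``None`` for the no-intervention baseline, or an object
    with a ``step_controls(t, dt, counts, params)`` method returning
    :class:`StepControls` (held constant over each control step of length
    ``control_dt``).  Cumulative incidence and excess-death flows are
    co-integrated with the state.  Counts below ``-neg_tol_rel`` times the
    total population abort with an error naming time and compartment; smaller
    negatives are clamped to zero at reporting times only.
    """
    if not t0 < t1:
        raise ValueError("need t0 < t1")
    if np.any(initial.counts < 0):
        raise ValueError("initial counts must be nonnegative")
    if method not in ("adaptive", "rk4"):
        raise ValueError("method must be 'adaptive' or 'rk4'")
    # the forcing selects the PA intensity actually applied
    forcing_rr = getattr(forcing, "rr_pa", None)
    if forcing_rr is not None and forcing_rr != params.rr_pa:
        params = params.replace(rr_pa=forcing_rr)

    report_times = np.round(np.arange(t0, t1 + report_dt / 2, report_dt), 9)
    y = _pack(initial.counts, np.zeros((N_SEX, N_AGE)), np.zeros((N_SEX, N_AGE)))
    neg_tol = neg_tol_rel * max(1.0, initial.counts.sum())

    out_t: list[float] = []
    out_y: list[np.ndarray] = []

    def record(t: float, yv: np.ndarray) -> None:
        counts, cases, deaths = _unpack(yv)
        counts = _check_and_clamp(counts.copy(), t, neg_tol)
        out_t.append(t)
        out_y.append(_pack(counts, cases, deaths))

    record(t0, y)

    def integrate(fun, ta: float, tb: float, y0: np.ndarray, t_eval) -> np.ndarray:
        if method == "rk4":
            yv = y0
            tprev = ta
            for te in t_eval:
                yv = _rk4(fun, tprev, te, yv, rk4_dt)
                tprev = te
                if te < tb - 1e-9:
                    record(te, yv)
            if tprev < tb - 1e-9:
                yv = _rk4(fun, tprev, tb, yv, rk4_dt)
            return yv
        t_all = sorted(set(list(t_eval) + [tb]))
        sol = solve_ivp(
            fun, (ta, tb), y0, method="RK45", rtol=rtol, atol=atol, t_eval=t_all
        )
        if not sol.success:
            raise SimulationError(f"solver failed on [{ta}, {tb}]: {sol.message}")
        for tt, yy in zip(sol.t, sol.y.T):
            if tt < tb - 1e-9:
                record(tt, yy)
        return sol.y[:, -1]

    if forcing is None:
        fun = _ode_fun(params, None)
        inner = [tt for tt in report_times if t0 < tt < t1 - 1e-9]
        y = integrate(fun, t0, t1, y, inner)
        record(t1, y)
    else:
        bounds = np.round(np.arange(t0, t1 + control_dt / 2, control_dt), 9)
        if not np.isclose(bounds[-1], t1):
            bounds = np.append(bounds, t1)
        for ta, tb in zip(bounds[:-1], bounds[1:]):
            counts, _, _ = _unpack(y)
            controls = forcing.step_controls(ta, tb - ta, counts, params)
            fun = _ode_fun(params, controls)
            inner = [tt for tt in report_times if ta < tt < tb - 1e-9]
            y = integrate(fun, ta, tb, y, inner)
            if any(np.isclose(tb, report_times)) and tb < t1 - 1e-9:
                record(tb, y)
        record(t1, y)

    order = np.argsort(out_t)
    ys = np.array([out_y[i] for i in order])
    ts = np.array([out_t[i] for i in order])
    # keep reporting-grid times only
    keep = [i for i, tt in enumerate(ts) if np.any(np.isclose(tt, report_times))]
    ts = ts[keep]
    ys = ys[keep]
    counts = ys[:, :N_COUNTS].reshape(-1, *SHAPE)
    cases = ys[:, N_COUNTS : N_COUNTS + N_FLOW].reshape(-1, N_SEX, N_AGE)
    deaths = ys[:, N_COUNTS + N_FLOW :].reshape(-1, N_SEX, N_AGE)
    return Trajectory(years=ts, counts=counts, cum_cases=cases, cum_deaths=deaths)
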