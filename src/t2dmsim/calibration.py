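"""Nonlinear least-squares calibration of the model to prevalence targets.

The fitted quantities are multiplicative family-level scales applied to a
template :class:`~t2dmsim.parameters.ParameterSet`: the baseline incidence
hazard per sex, the acquisition hazard per risk factor, the excess-mortality
hazard and the entry stream.  Cessation hazards are held at their configured
priors (acquisition and cessation are only jointly weakly identified by
prevalence data).  Residuals are computed with a fixed-step RK4 integrator so
the objective is smooth in the parameters; optimisation is bounded
trust-region least squares (scipy) with optional seeded multi-start
(log-uniform perturbations within the bounds).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .dynamics import PopulationState, SimulationError, Trajectory, simulate
from .parameters import ParameterSet
from .strata import (
    ADULT_BANDS,
    ADULT_LABEL,
    AGE_BANDS,
    FACTOR_ON,
    FACTORS,
    SEXES,
    T2DM,
    band_index,
)

PREVALENCE_QUANTITIES = ("t2dm", "obesity", "smoking", "inactivity")
VALID_QUANTITIES = PREVALENCE_QUANTITIES + ("population",)

#: fitted scale knobs and the target quantity that identifies each
DEFAULT_KNOBS = {
    "lambda0_female": "t2dm",
    "lambda0_male": "t2dm",
    "eta_obesity": "obesity",
    "eta_smoking": "smoking",
    "eta_inactivity": "inactivity",
    "nu": "t2dm",
    "entry": "population",
}


class CalibrationTargets:
    """Tabular fit targets.

    Columns: ``quantity`` (t2dm/obesity/smoking/inactivity prevalence, or
    population), ``sex`` (female/male/all), ``age_band`` (a 5-year band or
    the 15-64 aggregate), ``year``, ``value`` (fraction for prevalences,
    persons for population), ``weight`` (nonnegative)."""

    COLUMNS = ["quantity", "sex", "age_band", "year", "value", "weight"]

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"targets table missing columns {sorted(missing)}")
        self.frame = frame[self.COLUMNS].reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.frame
        bad = set(df.quantity) - set(VALID_QUANTITIES)
        if bad:
            raise ValueError(f"unknown target quantities {sorted(bad)}")
        prev = df[df.quantity != "population"]
        if ((prev.value < 0) | (prev.value > 1)).any():
            raise ValueError("prevalence targets must be fractions in [0, 1]")
        if (df.weight < 0).any():
            raise ValueError("weights must be nonnegative")

    def check_identifiable(self, knobs: dict[str, str]) -> None:
        present = set(self.frame.quantity)
        missing = {k: q for k, q in knobs.items() if q not in present}
        if missing:
            raise ValueError(
                f"no targets identify fitted families {sorted(missing)}; "
                "add at least one target per fitted parameter family"
            )

    def to_csv(self, path, **kw) -> None:
        self.frame.to_csv(path, index=False, **kw)

    @classmethod
    def from_csv(cls, path) -> "CalibrationTargets":
        return cls(pd.read_csv(path, comment="#"))


def _model_value(traj: Trajectory, quantity: str, sex: str, age_band: str, year) -> float:
    counts = traj.counts[traj.year_index(float(year))]
    if sex == "all":
        sub = counts
    else:
        sub = counts[SEXES.index(sex) : SEXES.index(sex) + 1]
    if age_band == ADULT_LABEL:
        sub = sub[:, ADULT_BANDS]
    else:
        a = band_index(age_band)
        sub = sub[:, a : a + 1]
    total = sub.sum()
    if quantity == "population":
        return float(total)
    if total <= 0:
        return 0.0
    if quantity == "t2dm":
        return float(sub[..., T2DM].sum() / total)
    on = list(FACTOR_ON[FACTORS.index(quantity)])
    return float(sub[:, :, on, :].sum() / total)


def residuals(
    params: ParameterSet,
    targets: CalibrationTargets,
    initial: PopulationState,
    *,
    forcing=None,
    t0: float = 2016.0,
    rk4_dt: float = 0.25,
) -> pd.DataFrame:
    """Per-target (model - target) under the no-intervention baseline."""
    t1 = float(max(targets.frame.year.max(), t0 + 1.0))
    traj = simulate(params, forcing, initial, t0, t1, method="rk4", rk4_dt=rk4_dt)
    df = targets.frame.copy()
    df["model"] = [
        _model_value(traj, r.quantity, r.sex, r.age_band, r.year)
        for r in df.itertuples()
    ]
    df["residual"] = df.model - df.value
    return df


def loss(
    params: ParameterSet,
    targets: CalibrationTargets,
    initial: PopulationState,
    *,
    forcing=None,
    **kw,
) -> float:
    """Weighted sum of squared residuals, sum_i w_i (model_i - target_i)^2."""
    df = residuals(params, targets, initial, forcing=forcing, **kw)
    return float((df.weight * df.residual**2).sum())


def relative_weights(targets: CalibrationTargets) -> CalibrationTargets:
    """Reweight residuals by inverse squared target (relative error), useful
    when age-band prevalences span an order of magnitude."""
    df = targets.frame.copy()
    nz = df.value > 0
    df.loc[nz, "weight"] = df.loc[nz, "weight"] / df.loc[nz, "value"] ** 2
    return CalibrationTargets(df)


def apply_knobs(init: ParameterSet, scales: dict[str, float]) -> ParameterSet:
    """Multiplicative family scales on a template parameter set."""
    p = init.replace()
    for name, s in scales.items():
        if name == "lambda0_female":
            p.lambda0[0] *= s
        elif name == "lambda0_male":
            p.lambda0[1] *= s
        elif name.startswith("eta_"):
            p.eta[FACTORS.index(name[4:])] *= s
        elif name == "nu":
            p.nu *= s
        elif name == "entry":
            p.entry_rate *= s
        else:
            raise KeyError(f"unknown knob {name!r}")
    return p


@dataclass
class FitResult:
    params: ParameterSet
    scales: dict[str, float]
    residual_table: pd.DataFrame
    loss: float
    converged: bool
    at_bounds: list = field(default_factory=list)
    n_restarts_used: int = 1
    seed: int = 0
    bounds: tuple = (0.5, 2.0)

    def to_json(self, path) -> None:
        doc = {
            "scales": self.scales,
            "loss": self.loss,
            "converged": self.converged,
            "at_bounds": self.at_bounds,
            "n_restarts_used": self.n_restarts_used,
            "seed": self.seed,
            "bounds": list(self.bounds),
            "params": self.params.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


def fit(
    targets: CalibrationTargets,
    init: ParameterSet,
    initial_state: PopulationState,
    *,
    knobs: dict[str, str] | None = None,
    bounds: tuple = (0.5, 2.0),
    n_restarts: int = 1,
    seed: int = 0,
    rk4_dt: float = 0.25,
    xtol: float = 1e-12,
    ftol: float = 1e-14,
    max_nfev: int | None = None,
) -> FitResult:
    """Bounded least-squares fit of the family scales.

    Starts at scale 1 on ``init`` plus ``n_restarts - 1`` seeded log-uniform
    perturbed starts within the bounds; returns the best solution.
    Deterministic given ``seed``.  A solution pinned at a bound is reported in
    ``at_bounds`` and flagged as not converged (boundary solution, never a
    silent success).
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    knobs = dict(DEFAULT_KNOBS if knobs is None else knobs)
    targets.check_identifiable(knobs)
    names = list(knobs)
    lo, hi = np.log(bounds[0]), np.log(bounds[1])
    sqw = np.sqrt(targets.frame.weight.to_numpy())
    tvals = targets.frame.value.to_numpy()

    def resid_vec(x: np.ndarray) -> np.ndarray:
        params = apply_knobs(init, dict(zip(names, np.exp(x))))
        df = residuals(params, targets, initial_state, rk4_dt=rk4_dt)
        return sqw * (df.model.to_numpy() - tvals)

    rng = np.random.default_rng(seed)
    starts = [np.zeros(len(names))]
    for _ in range(n_restarts - 1):
        starts.append(rng.uniform(lo * 0.99, hi * 0.99, size=len(names)))

    best = None
    errors = []
    for x0 in starts:
        try:
            sol = least_squares(
                resid_vec, x0, bounds=(lo, hi), xtol=xtol, ftol=ftol, gtol=1e-14,
                diff_step=1e-4, max_nfev=max_nfev,
            )
        except (SimulationError, ValueError) as exc:
            errors.append(str(exc))
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError(f"all {n_restarts} restarts failed: {errors}")

    scales = dict(zip(names, np.exp(best.x)))
    params = apply_knobs(init, scales)
    table = residuals(params, targets, initial_state, rk4_dt=rk4_dt)
    total = float((table.weight * table.residual**2).sum())
    at_bounds = [
        n for n, xv in zip(names, best.x)
        if xv - lo < 1e-6 or hi - xv < 1e-6
    ]
    return FitResult(
        params=params,
        scales=scales,
        residual_table=table,
        loss=total,
        converged=bool(best.success) and not at_bounds,
        at_bounds=at_bounds,
        n_restarts_used=len(starts) - len(errors),
        seed=seed,
        bounds=bounds,
    )
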