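"""Intervention scenarios and their translation into model forcing.

A scenario is declarative: per-factor relative prevalence reductions achieved
linearly over a scale-up window (2016-2031 by default, held to 2050), and/or
an explicit physical-activity intervention ramping coverage linearly to a
target (25% by default) among susceptible adults.  A "halt" is a relative
reduction of 0 — the controller pins the factor's aggregate prevalence at its
2016 level even though the no-intervention baseline drifts upward with
population aging.

Enforcement mechanism: target prevalence trajectories are tracked by a
per-step deadbeat feedback controller that rescales the acquisition and
cessation hazards of the susceptible population in the targeted age range
(bounded multipliers in [0, 10]), compensating the demographic drift estimated
from the instantaneous baseline derivative.  This preserves compartmental
bookkeeping and person conservation exactly.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import yaml

from .dynamics import StepControls, rhs
from .parameters import PA_RELATIVE_RISK, ParameterSet
from .strata import (
    FACTOR_OFF,
    FACTOR_ON,
    FACTORS,
    N_AGE,
    N_SEX,
    SUSCEPTIBLE_NONE,
    SUSCEPTIBLE_PA,
    T2DM,
)

MULT_BOUNDS = (0.0, 10.0)


class ControllerSaturationWarning(UserWarning):
    pass


@dataclass(frozen=True)
class ScenarioSpec:
    """Declarative description of one intervention scenario.

    ``factor_reductions`` maps factor name to relative reduction F in [0, 1]
    (0 = halt at the 2016 level); untargeted factors are simply absent.
    ``pa_intensity`` enables the explicit PA intervention at one of the five
    intensity levels; ``pa_coverage`` is the coverage reached by ``ramp_end``.
    ``target_bands`` is the (first, last) age-band index range targeted
    (inclusive), ages 15-64 by default.
    """

    name: str
    factor_reductions: dict = field(default_factory=dict)
    ramp_start: float = 2016.0
    ramp_end: float = 2031.0
    hold_until: float = 2050.0
    pa_intensity: str | None = None
    pa_coverage: float = 0.25
    target_bands: tuple = (3, 12)

    def __post_init__(self) -> None:
        if not self.ramp_start < self.ramp_end <= self.hold_until:
            raise ValueError("need ramp_start < ramp_end <= hold_until")
        for k, F in self.factor_reductions.items():
            if k not in FACTORS:
                raise ValueError(f"unknown factor {k!r}; valid: {FACTORS}")
            if not 0.0 <= F <= 1.0:
                raise ValueError(f"relative reduction for {k} must be in [0, 1]")
        if self.pa_intensity is not None and self.pa_intensity not in PA_RELATIVE_RISK:
            raise ValueError(
                f"unknown PA intensity {self.pa_intensity!r}; "
                f"valid: {sorted(PA_RELATIVE_RISK)}"
            )
        if not 0.0 <= self.pa_coverage <= 1.0:
            raise ValueError("pa_coverage must be in [0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["target_bands"] = list(self.target_bands)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        d = dict(d)
        if "target_bands" in d:
            d["target_bands"] = tuple(d["target_bands"])
        return cls(**d)


def ramp_target(p0: float, F: float, t: float, ramp_start: float, ramp_end: float) -> float:
    """Linear scale-up of a relative prevalence reduction.

    Returns ``p0`` before the ramp, the linear interpolation
    ``p0 * (1 - F * (t - ramp_start)/(ramp_end - ramp_start))`` on it, and
    ``p0 * (1 - F)`` after.
    """
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must be a fraction")
    if not 0.0 <= F <= 1.0:
        raise ValueError("F must be in [0, 1]")
    if t <= ramp_start:
        return p0
    if t >= ramp_end:
        return p0 * (1.0 - F)
    return p0 * (1.0 - F * (t - ramp_start) / (ramp_end - ramp_start))


def _band_slice(target_bands: tuple) -> slice:
    return slice(target_bands[0], target_bands[1] + 1)


@dataclass
class ScenarioForcing:
    """Time-dependent forcing handed to :func:`t2dmsim.dynamics.simulate`.

    ``factor_targets`` maps factor name to a target-prevalence function of
    calendar time (aggregate over the targeted age range); ``pa_coverage_fn``
    is the coverage target among susceptible adults, or ``None``.
    ``denominator`` selects whether factor prevalence is measured over the
    whole targeted-age population (default, matching population-level WHO
    targets) or over susceptibles only.
    """

    factor_targets: dict[str, Callable[[float], float]] = field(default_factory=dict)
    pa_coverage_fn: Callable[[float], float] | None = None
    rr_pa: float = 1.0
    target_bands: tuple = (3, 12)
    denominator: str = "population"
    mult_bounds: tuple = MULT_BOUNDS

    def step_controls(
        self, t: float, dt: float, counts: np.ndarray, params: ParameterSet
    ) -> StepControls:
        """Deadbeat controls for the step [t, t+dt] from the current state."""
        bands = _band_slice(self.target_bands)
        # drift estimate: instantaneous derivative at base rates, no recruitment
        dc, _, _ = rhs(t, counts, params, StepControls())
        eta_mult = np.ones((3, N_SEX, N_AGE))
        rho_mult = np.ones((3, N_SEX, N_AGE))

        for name, target_fn in self.factor_targets.items():
            k = FACTORS.index(name)
            on = list(FACTOR_ON[k])
            sub = counts[:, bands]
            dsub = dc[:, bands]
            if self.denominator == "susceptible":
                sub = sub[..., :T2DM]
                dsub = dsub[..., :T2DM]
            N = sub.sum()
            P = sub[:, :, on, ...].sum()
            if N <= 0:
                continue
            dN = dsub.sum()
            dP = dsub[:, :, on, ...].sum()
            p = P / N
            dp_base = (dP - p * dN) / N
            dp_req = (target_fn(t + dt) - p) / dt
            extra = N * (dp_req - dp_base)  # persons/year of net on-flow needed
            me, mr = self._solve_multipliers(extra, counts, params, k, bands)
            eta_mult[k][:, bands] = me
            rho_mult[k][:, bands] = mr

        pa_rate = 0.0
        if self.pa_coverage_fn is not None:
            sus = counts[:, bands, :, :T2DM]
            S = sus.sum()
            if S > 0:
                cov = counts[:, bands, :, SUSCEPTIBLE_PA].sum() / S
                dsus = dc[:, bands, :, :T2DM]
                dS = dsus.sum()
                dPA = dc[:, bands, :, SUSCEPTIBLE_PA].sum()
                dcov_base = (dPA - cov * dS) / S
                dcov_req = (self.pa_coverage_fn(t + dt) - cov) / dt
                extra = S * (dcov_req - dcov_base)
                pool = counts[:, bands, :, SUSCEPTIBLE_NONE].sum()
                if extra > 0 and pool > 0:
                    pa_rate = min(extra / pool, self.mult_bounds[1])
                    if extra / pool > self.mult_bounds[1]:
                        warnings.warn(
                            "PA recruitment rate saturated at bound",
                            ControllerSaturationWarning,
                            stacklevel=2,
                        )
        return StepControls(eta_mult=eta_mult, rho_mult=rho_mult, pa_recruit_rate=pa_rate)

    def _solve_multipliers(
        self, extra: float, counts: np.ndarray, params: ParameterSet,
        k: int, bands: slice,
    ) -> tuple[float, float]:
        """Scalar acquisition/cessation multipliers delivering ``extra`` net
        on-flow (persons/year) from susceptible strata in the targeted bands."""
        off, on = list(FACTOR_OFF[k]), list(FACTOR_ON[k])
        lo, hi = self.mult_bounds
        sus = slice(None, T2DM)
        A = (params.eta[k][:, bands, None, None] * counts[:, bands][:, :, off, sus]).sum()
        C = (params.rho[k][:, bands, None, None] * counts[:, bands][:, :, on, sus]).sum()
        me, mr = 1.0, 1.0
        if extra >= 0:
            if A > 0:
                me = min(1.0 + extra / A, hi)
                extra -= (me - 1.0) * A
            if extra > 1e-9 and C > 0:
                mr = max(1.0 - extra / C, lo)
                extra -= (1.0 - mr) * C
        else:
            deficit = -extra
            if C > 0:
                mr = min(1.0 + deficit / C, hi)
                deficit -= (mr - 1.0) * C
            if deficit > 1e-9 and A > 0:
                me = max(1.0 - deficit / A, lo)
                deficit -= (1.0 - me) * A
            extra = -deficit
        if abs(extra) > 1e-9 and abs(extra) > 1e-6 * max(A + C, 1.0):
            warnings.warn(
                f"prevalence controller for {FACTORS[k]} saturated; residual "
                f"net flow {extra:.3g} persons/year unmet",
                ControllerSaturationWarning,
                stacklevel=3,
            )
        return me, mr


def prevalence_controller(
    counts: np.ndarray,
    factor: str,
    target: float,
    params: ParameterSet,
    *,
    t: float = 2016.0,
    dt: float = 0.5,
    target_bands: tuple = (3, 12),
    denominator: str = "population",
) -> tuple[float, float]:
    """One-off controller step: (eta, rho) multipliers steering the aggregate
    prevalence of ``factor`` toward ``target`` over a step of length ``dt``."""
    if not 0.0 <= target <= 1.0:
        raise ValueError("target must be a fraction")
    forcing = ScenarioForcing(
        factor_targets={factor: lambda tt: target},
        target_bands=target_bands,
        denominator=denominator,
    )
    controls = forcing.step_controls(t, dt, counts, params)
    k = FACTORS.index(factor)
    b = target_bands[0]
    return float(controls.eta_mult[k][0, b]), float(controls.rho_mult[k][0, b])


def build_forcing(
    spec: ScenarioSpec,
    baseline_2016: dict[str, float],
    *,
    denominator: str = "population",
) -> ScenarioForcing | None:
    """Instantiate the forcing for one scenario.

    ``baseline_2016`` maps factor name to its 2016 aggregate prevalence in
    the targeted age range.  Returns ``None`` for an empty (baseline) spec.
    """
    targets: dict[str, Callable[[float], float]] = {}
    for k, F in spec.factor_reductions.items():
        p0 = baseline_2016[k]
        if not 0.0 <= p0 <= 1.0:
            raise ValueError(f"baseline prevalence for {k} must be a fraction")
        targets[k] = _make_ramp(p0, F, spec.ramp_start, spec.ramp_end)

    pa_fn = None
    rr_pa = 1.0
    if spec.pa_intensity is not None:
        rr_pa = PA_RELATIVE_RISK[spec.pa_intensity]
        pa_fn = _make_ramp_up(spec.pa_coverage, spec.ramp_start, spec.ramp_end)

    if not targets and pa_fn is None:
        return None
    return ScenarioForcing(
        factor_targets=targets,
        pa_coverage_fn=pa_fn,
        rr_pa=rr_pa,
        target_bands=spec.target_bands,
        denominator=denominator,
    )


def _make_ramp(p0: float, F: float, rs: float, re: float):
    def fn(t: float) -> float:
        return ramp_target(p0, F, t, rs, re)

    return fn


def _make_ramp_up(cov: float, rs: float, re: float):
    def fn(t: float) -> float:
        if t <= rs:
            return 0.0
        if t >= re:
            return cov
        return cov * (t - rs) / (re - rs)

    return fn


def scale_up_variants(spec: ScenarioSpec, durations: list[float]) -> list[ScenarioSpec]:
    """Clones of ``spec`` with ramp duration varied (ramp_end moved)."""
    out = []
    for d in durations:
        if d <= 0:
            raise ValueError("durations must be positive")
        end = spec.ramp_start + d
        if end > spec.hold_until:
            raise ValueError(
                f"duration {d} puts ramp_end {end} beyond hold_until {spec.hold_until}"
            )
        out.append(
            dataclasses.replace(spec, name=f"{spec.name}_ramp{int(d)}y", ramp_end=end)
        )
    return out


def scenario_library() -> dict[str, ScenarioSpec]:
    """The bundled scenario set: WHO action plan, per-factor halt/10-50%
    reductions, the combined 50% reduction, the five PA intensities, the
    combined+PA scenario, and the obesity-40% scale-up duration variants."""
    lib: dict[str, ScenarioSpec] = {}
    lib["who_action_plan"] = ScenarioSpec(
        name="who_action_plan",
        factor_reductions={"obesity": 0.0, "smoking": 0.30, "inactivity": 0.10},
    )
    for factor in FACTORS:
        lib[f"{factor}_halt"] = ScenarioSpec(
            name=f"{factor}_halt", factor_reductions={factor: 0.0}
        )
        for pct in (10, 20, 30, 40, 50):
            name = f"{factor}_minus_{pct}"
            lib[name] = ScenarioSpec(
                name=name, factor_reductions={factor: pct / 100.0}
            )
    lib["combined_minus_50"] = ScenarioSpec(
        name="combined_minus_50",
        factor_reductions={"obesity": 0.5, "smoking": 0.5, "inactivity": 0.5},
    )
    for intensity in PA_RELATIVE_RISK:
        name = f"pa_{intensity}"
        lib[name] = ScenarioSpec(name=name, pa_intensity=intensity)
    lib["combined_minus_50_pa_vigorous"] = ScenarioSpec(
        name="combined_minus_50_pa_vigorous",
        factor_reductions={"obesity": 0.5, "smoking": 0.5, "inactivity": 0.5},
        pa_intensity="vigorous",
    )
    base40 = ScenarioSpec(name="obesity_minus_40", factor_reductions={"obesity": 0.4})
    for v in scale_up_variants(base40, [5, 10, 15, 20]):
        lib[v.name] = v
    return lib


def dump_library(path) -> None:
    lib = scenario_library()
    with open(path, "w") as fh:
        yaml.safe_dump(
            {"scenarios": [s.to_dict() for s in lib.values()]}, fh, sort_keys=False
        )


def load_library(path) -> dict[str, ScenarioSpec]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    specs = [ScenarioSpec.from_dict(d) for d in doc["scenarios"]]
    return {s.name: s for s in specs}
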