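"""Synthetic Qatar-like inputs: demography, prevalence targets, parameters.

The generator emulates the statistical structure the analysis assumes — a
young, rapidly aging national population (15-64 totals near 144,066 in 2016
growing toward 221,627 by 2050), 2016 aggregate risk-factor prevalences of
41.4% (obesity), 16.2% (smoking) and 46.0% (physical inactivity), and a 2016
T2DM prevalence of 16.7% that rises toward the mid-20s% by 2050 purely through
demographic aging under constant age-specific risk-factor prevalence.

Age gradients are logistic curves (midpoint/steepness per quantity, sex
multipliers exposed in the config) rescaled so the 15-64 aggregates match the
configured values exactly.  The reference parameter set is constructed by a
quasi-stationarity balance: acquisition hazards and baseline incidence hazards
are solved per (sex, age band) so that the 2016 age-specific prevalence
profiles are approximately invariant under aging, cessation, incidence and
excess mortality — which reproduces the constant-age-specific-prevalence
baseline with aggregate drift driven by the shifting age pyramid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .calibration import CalibrationTargets
from .dynamics import PopulationState, simulate
from .parameters import ParameterSet, default_aging_rate
from .strata import (
    ADULT_BANDS,
    ADULT_LABEL,
    AGE_BANDS,
    AGE_MID,
    COMBO_BITS,
    FACTORS,
    N_AGE,
    N_COMBO,
    N_SEX,
    SEXES,
    SHAPE,
    SUSCEPTIBLE_NONE,
    T2DM,
)

QUANTITIES = ("t2dm",) + FACTORS


@dataclass
class AgeCurve:
    """Logistic-in-age prevalence shape with a per-sex multiplier.

    ``female_mult`` is the female:male prevalence ratio before rescaling; the
    overall level is set by matching the configured 15-64 aggregate exactly.
    """

    midpoint: float
    steepness: float
    female_mult: float = 1.0

    def shape(self) -> np.ndarray:
        """(2, 16) unnormalised prevalence shape."""
        logistic = 1.0 / (1.0 + np.exp(-(AGE_MID - self.midpoint) / self.steepness))
        mult = np.array([self.female_mult, 1.0])
        return mult[:, None] * logistic[None, :]


def _default_curves() -> dict:
    return {
        "t2dm": AgeCurve(midpoint=52.0, steepness=7.0, female_mult=1.0),
        "obesity": AgeCurve(midpoint=30.0, steepness=8.0, female_mult=1.15),
        "smoking": AgeCurve(midpoint=20.0, steepness=3.0, female_mult=0.15),
        "inactivity": AgeCurve(midpoint=32.0, steepness=14.0, female_mult=1.3),
    }


def _default_prev() -> dict:
    return {"obesity": 0.414, "smoking": 0.162, "inactivity": 0.460}


def _default_rho() -> dict:
    # slow remission/cessation hazards, /year
    return {"obesity": 0.02, "smoking": 0.03, "inactivity": 0.04}


@dataclass
class SyntheticConfig:
    seed: int = 0
    pop_15_64_2016: float = 144_066.0
    pop_15_64_2050: float = 221_627.0
    prev_2016: dict = field(default_factory=_default_prev)
    t2dm_prev_2016: float = 0.167
    age_curves: dict = field(default_factory=_default_curves)
    noise_sd: float = 0.0  # percentage points on prevalence targets
    pyramid_decay: float = 0.03  # /year of age; smaller = older pyramid
    child_deficit: float = 0.5  # fractional thinning of the youngest bands
    child_deficit_mid: float = 12.0  # age where the thinning fades out
    child_deficit_steep: float = 4.0
    female_share: float = 0.49
    mortality_scale: float = 6e-5  # Gompertz level at age 0, /year
    mortality_slope: float = 0.082  # Gompertz shape, /year of age
    male_mortality_mult: float = 1.1
    cfr_2016: float = 0.0086  # T2DM excess deaths per prevalent case /year
    nu_age_slope: float = 0.05  # /year of age, excess-mortality gradient
    rho: dict = field(default_factory=_default_rho)
    rr_obesity: float = 4.3
    rr_smoking: float = 1.37
    rr_inactivity: float = 1.5

    def __post_init__(self) -> None:
        for k, v in {**self.prev_2016, "t2dm": self.t2dm_prev_2016}.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"prevalence for {k} must be a fraction")
        if self.pop_15_64_2016 <= 0 or self.pop_15_64_2050 <= 0:
            raise ValueError("population totals must be positive")


@dataclass
class Demography:
    pyramid: np.ndarray  # (2, 16) persons at 2016
    entry_rate: np.ndarray  # (2,) persons/year at 2016
    entry_growth: float  # /year
    mu: np.ndarray  # (2, 16) background mortality

    def adult_total(self) -> float:
        return float(self.pyramid[:, ADULT_BANDS].sum())


def _project_adults(
    pyramid: np.ndarray,
    entry: np.ndarray,
    growth: float,
    mu: np.ndarray,
    years: float,
    dt: float = 0.1,
) -> float:
    """Demography-only 15-64 total after ``years`` (RK4, sex x age only)."""
    ar = default_aging_rate()

    def deriv(t, n):
        d = -ar[None, :] * n - mu * n
        d[:, 1:] += ar[None, :-1] * n[:, :-1]
        d[:, 0] += entry * np.exp(growth * t)
        return d

    n = pyramid.copy()
    steps = int(round(years / dt))
    for i in range(steps):
        t = i * dt
        k1 = deriv(t, n)
        k2 = deriv(t + dt / 2, n + dt / 2 * k1)
        k3 = deriv(t + dt / 2, n + dt / 2 * k2)
        k4 = deriv(t + dt, n + dt * k3)
        n = n + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    return float(n[:, ADULT_BANDS].sum())


def generate_demography(cfg: SyntheticConfig) -> Demography:
    """Young age pyramid, mortality schedule and entry stream.

    The 2016 pyramid decays exponentially in age (median age < 30); the entry
    stream grows exponentially at a rate solved so the demography-only
    projection reaches the configured 2050 15-64 total.
    """
    w = np.exp(-cfg.pyramid_decay * AGE_MID)
    # thin the child bands: the adult population then ages monotonically
    # upward as the pre-2016 bulge cohorts move through 15-64
    w *= 1.0 - cfg.child_deficit / (
        1.0 + np.exp(-(cfg.child_deficit_mid - AGE_MID) / cfg.child_deficit_steep)
    )
    sex_w = np.array([cfg.female_share, 1.0 - cfg.female_share])
    pyramid = sex_w[:, None] * w[None, :]
    pyramid *= cfg.pop_15_64_2016 / pyramid[:, ADULT_BANDS].sum()

    mu = cfg.mortality_scale * np.exp(cfg.mortality_slope * AGE_MID)
    mu = np.vstack([mu, cfg.male_mortality_mult * mu])

    entry = pyramid[:, 0] / 5.0  # replacement-level inflow to band 0-4

    def gap(g: float) -> float:
        return _project_adults(pyramid, entry, g, mu, 2050.0 - 2016.0) - cfg.pop_15_64_2050

    lo, hi = -0.15, 0.15
    if gap(lo) * gap(hi) > 0:
        raise ValueError(
            "population anchors infeasible under zero migration: no entry "
            "growth rate in [-0.15, 0.15] reaches the 2050 total"
        )
    growth = brentq(gap, lo, hi, xtol=1e-10)
    return Demography(pyramid=pyramid, entry_rate=entry, entry_growth=growth, mu=mu)


def _scaled_profile(
    curve: AgeCurve, aggregate: float, pyramid: np.ndarray
) -> np.ndarray:
    """(2, 16) prevalence profile whose 15-64 aggregate equals ``aggregate``."""
    sh = curve.shape()
    w = pyramid[:, ADULT_BANDS]
    k = aggregate * w.sum() / (sh[:, ADULT_BANDS] * w).sum()
    prof = k * sh
    if prof.max() > 0.95:
        raise ValueError(
            "scaled prevalence profile exceeds 0.95; adjust the age curve"
        )
    return prof


def generate_targets(
    cfg: SyntheticConfig, demography: Demography | None = None
) -> CalibrationTargets:
    """Sex/age-specific 2016 prevalence targets (survey-like inputs).

    With ``noise_sd = 0`` the 15-64 aggregates equal the configured values
    exactly; with noise, independent Gaussian perturbations (sd in percentage
    points, seeded) are added per target, so aggregates match in expectation.
    """
    demo = demography or generate_demography(cfg)
    rng = np.random.default_rng(cfg.seed)
    aggregates = {"t2dm": cfg.t2dm_prev_2016, **cfg.prev_2016}
    rows = []
    for q in QUANTITIES:
        prof = _scaled_profile(cfg.age_curves[q], aggregates[q], demo.pyramid)
        if cfg.noise_sd > 0:
            prof = np.clip(prof + rng.normal(0, cfg.noise_sd / 100.0, prof.shape), 0, 1)
        for s, sex in enumerate(SEXES):
            for a, band in enumerate(AGE_BANDS):
                rows.append((q, sex, band, 2016, prof[s, a], 1.0))
    df = pd.DataFrame(
        rows, columns=["quantity", "sex", "age_band", "year", "value", "weight"]
    )
    return CalibrationTargets(df)


def _profiles_from_targets(targets: CalibrationTargets, year: int = 2016) -> dict:
    """quantity -> (2, 16) prevalence profile from a target table."""
    out = {}
    df = targets.frame
    for q in QUANTITIES:
        prof = np.zeros((N_SEX, N_AGE))
        sub = df[(df.quantity == q) & (df.year == year)]
        for _, r in sub.iterrows():
            prof[SEXES.index(r.sex), AGE_BANDS.index(r.age_band)] = r.value
        out[q] = prof
    return out


def reference_params(
    cfg: SyntheticConfig,
    demography: Demography | None = None,
    targets: CalibrationTargets | None = None,
) -> ParameterSet:
    """Stand-in 'true' parameter set balanced against the 2016 profiles.

    Acquisition hazards solve ``eta (1-p) = rho p + aging-dilution`` and
    baseline incidence solves ``lambda_bar (1-p) = nu p + aging-dilution``
    per (sex, age band), where the aging-dilution term is the prevalence drag
    from younger cohorts flowing in.  ``lambda_bar`` is deflated by the mean
    joint relative risk implied by factor independence to give ``lambda0``.
    """
    demo = demography or generate_demography(cfg)
    tgt = targets or generate_targets(cfg, demo)
    prof = _profiles_from_targets(tgt)
    N = demo.pyramid
    ar = default_aging_rate()

    def inflow_term(p: np.ndarray) -> np.ndarray:
        """Per-band prevalence drag from aging inflow (and entry at band 0)."""
        out = np.zeros_like(p)
        out[:, 1:] = ar[:-1][None, :] * (N[:, :-1] / N[:, 1:]) * (p[:, 1:] - p[:, :-1])
        out[:, 0] = (demo.entry_rate / N[:, 0]) * (p[:, 0] - 0.0)
        return out

    eta = np.zeros((3, N_SEX, N_AGE))
    rho = np.zeros((3, N_SEX, N_AGE))
    for k, f in enumerate(FACTORS):
        p = prof[f]
        rho[k] = cfg.rho[f]
        eta[k] = np.clip((rho[k] * p + inflow_term(p)) / (1.0 - p), 0.0, None)

    pD = prof["t2dm"]
    nu_shape = np.exp(cfg.nu_age_slope * (AGE_MID - 40.0))[None, :] * np.ones((2, 1))
    w = (pD * N)[:, ADULT_BANDS]
    nu_base = cfg.cfr_2016 * w.sum() / (nu_shape[:, ADULT_BANDS] * w).sum()
    nu = nu_base * nu_shape

    rr = np.array([cfg.rr_obesity, cfg.rr_smoking, cfg.rr_inactivity])
    mean_rr = np.ones((N_SEX, N_AGE))
    for k, f in enumerate(FACTORS):
        mean_rr *= 1.0 - prof[f] + prof[f] * rr[k]
    lam_bar = np.clip((nu * pD + inflow_term(pD)) / (1.0 - pD), 0.0, None)
    lambda0 = lam_bar / mean_rr

    return ParameterSet(
        entry_rate=demo.entry_rate,
        entry_growth=demo.entry_growth,
        mu=demo.mu,
        lambda0=lambda0,
        eta=eta,
        rho=rho,
        nu=nu,
        rr_obesity=cfg.rr_obesity,
        rr_smoking=cfg.rr_smoking,
        rr_inactivity=cfg.rr_inactivity,
        rr_pa=1.0,
    )


def generate_initial_state(
    cfg: SyntheticConfig,
    targets: CalibrationTargets,
    demography: Demography | None = None,
) -> PopulationState:
    """2016 compartment occupancy matching pyramid and target prevalences.

    Risk-factor combinations are filled by per-factor independence within
    each (sex, age band); disease status is independent of factor status at
    initialisation; all PA-intervention compartments start empty.
    """
    demo = demography or generate_demography(cfg)
    prof = _profiles_from_targets(targets)
    counts = np.zeros(SHAPE)
    pk = np.stack([prof[f] for f in FACTORS])  # (3, 2, 16)
    if np.any(pk < 0) or np.any(pk > 1) or np.any(prof["t2dm"] < 0):
        raise ValueError("target prevalences imply negative occupancy")
    for c in range(N_COMBO):
        bits = COMBO_BITS[c].astype(bool)
        joint = np.prod(np.where(bits[:, None, None], pk, 1.0 - pk), axis=0)
        counts[:, :, c, SUSCEPTIBLE_NONE] = demo.pyramid * (1 - prof["t2dm"]) * joint
        counts[:, :, c, T2DM] = demo.pyramid * prof["t2dm"] * joint
    return PopulationState(counts=counts, time=2016.0)


@dataclass
class SyntheticDataset:
    """A complete worked-example input bundle."""

    config: SyntheticConfig
    demography: Demography
    targets: CalibrationTargets  # 2016 survey-like prevalence targets
    params: ParameterSet  # reference ('true') parameter set
    initial: PopulationState
    calibration_targets: CalibrationTargets  # incl. 2031 prevalence + totals


def make_calibration_targets(
    cfg: SyntheticConfig,
    demo: Demography,
    targets: CalibrationTargets,
    params: ParameterSet,
    initial: PopulationState,
    *,
    fit_year: int = 2031,
    rng: np.random.Generator | None = None,
) -> CalibrationTargets:
    """Targets that identify the fitted rates: reference-model prevalences at
    ``fit_year`` (adult bands) plus 15-64 population totals at 2016/2031/2050.

    Optional noise (``cfg.noise_sd`` percentage points, from ``rng``) applies
    to the prevalence rows only.
    """
    traj = simulate(params, None, initial, 2016.0, 2050.0, method="rk4", rk4_dt=0.1)
    ti = traj.year_index(fit_year)
    rows = []
    adult = range(ADULT_BANDS.start, ADULT_BANDS.stop)
    for q in QUANTITIES:
        for s, sex in enumerate(SEXES):
            for a in adult:
                sub = traj.counts[ti][s, a]
                if q == "t2dm":
                    v = sub[:, T2DM].sum() / sub.sum()
                else:
                    from .strata import FACTOR_ON

                    on = list(FACTOR_ON[FACTORS.index(q)])
                    v = sub[on, :].sum() / sub.sum()
                if rng is not None and cfg.noise_sd > 0:
                    v = float(np.clip(v + rng.normal(0, cfg.noise_sd / 100.0), 0, 1))
                rows.append((q, sex, AGE_BANDS[a], fit_year, v, 1.0))
    for year in (2016, 2031, 2050):
        tj = traj.year_index(year)
        total = traj.counts[tj][:, ADULT_BANDS].sum()
        rows.append(("population", "all", ADULT_LABEL, year, total, 1.0 / total**2))
    df = pd.DataFrame(
        rows, columns=["quantity", "sex", "age_band", "year", "value", "weight"]
    )
    return CalibrationTargets(df)


def generate_dataset(cfg: SyntheticConfig | None = None) -> SyntheticDataset:
    """Materialise demography, targets, reference parameters, initial state
    and calibration targets in one call (deterministic given ``cfg.seed``)."""
    cfg = cfg or SyntheticConfig()
    demo = generate_demography(cfg)
    noiseless = SyntheticConfig(**{**cfg.__dict__, "noise_sd": 0.0})
    targets = generate_targets(noiseless, demo)
    params = reference_params(cfg, demo, targets)
    initial = generate_initial_state(cfg, targets, demo)
    rng = np.random.default_rng(cfg.seed) if cfg.noise_sd > 0 else None
    cal = make_calibration_targets(cfg, demo, targets, params, initial, rng=rng)
    return SyntheticDataset(
        config=cfg,
        demography=demo,
        targets=targets,
        params=params,
        initial=initial,
        calibration_targets=cal,
    )
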