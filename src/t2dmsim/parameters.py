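"""Rate parameters of the compartmental model.

All hazards are per person-year.  Relative risks for the three risk factors
multiply the baseline T2DM incidence hazard (assumed independent, so the joint
effect of a risk combination is the product of the single-factor relative
risks).  The physical-activity intervention multiplies the hazard by an
intensity-specific relative risk <= 1.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .strata import BAND_WIDTH, COMBO_BITS, N_AGE, N_FACTOR, N_SEX

#: relative risk of developing T2DM under the PA intervention, by intensity
PA_RELATIVE_RISK = {
    "vigorous": 0.61,
    "low": 0.66,
    "moderate": 0.68,
    "leisure": 0.74,
    "walking": 0.85,
}


def default_aging_rate() -> np.ndarray:
    ar = np.full(N_AGE, 1.0 / BAND_WIDTH)
    ar[-1] = 0.0  # open-ended terminal band
    return ar


@dataclass
class ParameterSet:
    """All demographic and epidemiological rates.

    Attributes
    ----------
    entry_rate : (2,) array
        Persons/year entering the youngest band at ``entry_ref_year``
        (female, male), susceptible, risk-free, no intervention.
    entry_growth : float
        Exponential growth rate of the entry stream, /year.
    aging_rate : (16,) array
        1/(band width) per year; 0 in the terminal band.
    mu : (2, 16) array
        Background (all-cause, non-T2DM) mortality hazard, /year.
    lambda0 : (2, 16) array
        T2DM incidence hazard for risk-free, non-intervention susceptibles.
    rr_obesity, rr_smoking, rr_inactivity : float
        Relative risks (>= 1) multiplying ``lambda0``.
    rr_pa : float
        Relative risk (0 < rr_pa <= 1) for the PA intervention stratum.
    eta : (3, 2, 16) array
        Risk-factor acquisition hazards (obesity, smoking, inactivity).
    rho : (3, 2, 16) array
        Risk-factor cessation/remission hazards.
    nu : (2, 16) array
        T2DM-related excess mortality hazard among t2dm strata.
    """

    entry_rate: np.ndarray
    mu: np.ndarray
    lambda0: np.ndarray
    eta: np.ndarray
    rho: np.ndarray
    nu: np.ndarray
    rr_obesity: float = 1.0
    rr_smoking: float = 1.0
    rr_inactivity: float = 1.0
    rr_pa: float = 1.0
    entry_growth: float = 0.0
    entry_ref_year: float = 2016.0
    aging_rate: np.ndarray = field(default_factory=default_aging_rate)

    def __post_init__(self) -> None:
        self.entry_rate = np.asarray(self.entry_rate, dtype=float).reshape(N_SEX)
        self.aging_rate = np.asarray(self.aging_rate, dtype=float).reshape(N_AGE)
        self.mu = np.asarray(self.mu, dtype=float).reshape(N_SEX, N_AGE)
        self.lambda0 = np.asarray(self.lambda0, dtype=float).reshape(N_SEX, N_AGE)
        self.eta = np.asarray(self.eta, dtype=float).reshape(N_FACTOR, N_SEX, N_AGE)
        self.rho = np.asarray(self.rho, dtype=float).reshape(N_FACTOR, N_SEX, N_AGE)
        self.nu = np.asarray(self.nu, dtype=float).reshape(N_SEX, N_AGE)
        self.validate()

    def validate(self) -> None:
        for name in ("entry_rate", "aging_rate", "mu", "lambda0", "eta", "rho", "nu"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"{name} must be finite and nonnegative")
        for name in ("rr_obesity", "rr_smoking", "rr_inactivity"):
            if getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 < self.rr_pa <= 1.0:
            raise ValueError("rr_pa must be in (0, 1]")

    @property
    def rr_combo(self) -> np.ndarray:
        """(8,) joint relative risk per risk combination (multiplicative)."""
        rr = np.array([self.rr_obesity, self.rr_smoking, self.rr_inactivity])
        return np.prod(np.where(COMBO_BITS.astype(bool), rr, 1.0), axis=1)

    def entry_at(self, t: float) -> np.ndarray:
        """Entry stream (female, male), persons/year, at calendar year ``t``."""
        return self.entry_rate * np.exp(self.entry_growth * (t - self.entry_ref_year))

    def replace(self, **overrides) -> "ParameterSet":
        """Copy with fields replaced (arrays are copied)."""
        kw = {
            f.name: np.array(getattr(self, f.name))
            if isinstance(getattr(self, f.name), np.ndarray)
            else getattr(self, f.name)
            for f in dataclasses.fields(self)
        }
        kw.update(overrides)
        return ParameterSet(**kw)

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            out[f.name] = v.tolist() if isinstance(v, np.ndarray) else float(v)
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"units": "per person-year unless noted; entry_rate persons/year",
                 "parameters": self.to_dict()},
                fh,
                sort_keys=False,
            )

    @classmethod
    def from_yaml(cls, path) -> "ParameterSet":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc["parameters"])
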