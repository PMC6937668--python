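"""Compartmental state space: sex x age band x risk-factor combination x disease/intervention.

The population is stratified by sex (female, male), sixteen 5-year age bands
(0-4 ... 70-74, 75+), the joint on/off status of three modifiable risk factors
(obesity, current smoking, physical inactivity), and disease status.  Every
susceptible (diabetes-free) stratum is further split by physical-activity
intervention status; strata with T2DM carry no intervention label.  This gives

    2 sexes x 16 bands x 8 risk combinations x 3 effective states = 768

compartments.  The flat ordering is row-major over (sex, age band, risk combo,
state) with females first, youngest band first, the risk-free combination
first, and states ordered (susceptible/none, susceptible/pa_active, t2dm).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

SEXES = ("female", "male")
N_SEX = 2

N_AGE = 16
AGE_BANDS = tuple(f"{5 * i}-{5 * i + 4}" for i in range(15)) + ("75+",)
AGE_MID = np.array([2.5 + 5.0 * i for i in range(15)] + [77.5])
BAND_WIDTH = 5.0
#: age bands covering ages 15-64 (the adult reporting window)
ADULT_BANDS = slice(3, 13)
ADULT_LABEL = "15-64"

FACTORS = ("obesity", "smoking", "inactivity")
N_FACTOR = 3
N_COMBO = 8
#: combo index c encodes (obese, smoker, inactive) as bits 4, 2, 1
COMBO_BITS = np.array(
    [[(c >> 2) & 1, (c >> 1) & 1, c & 1] for c in range(N_COMBO)], dtype=int
)
#: per factor: combo indices with the factor off / on (paired by position)
FACTOR_OFF = tuple(
    tuple(c for c in range(N_COMBO) if not (c >> (2 - k)) & 1) for k in range(N_FACTOR)
)
FACTOR_ON = tuple(
    tuple(c | (1 << (2 - k)) for c in off) for k, off in enumerate(FACTOR_OFF)
)

DISEASE_STATES = ("susceptible", "t2dm")
INTERVENTION_STATES = ("none", "pa_active")
#: effective (disease, intervention) states along the last axis
STATES = (("susceptible", "none"), ("susceptible", "pa_active"), ("t2dm", "none"))
N_STATE = 3
SUSCEPTIBLE_NONE, SUSCEPTIBLE_PA, T2DM = 0, 1, 2

SHAPE = (N_SEX, N_AGE, N_COMBO, N_STATE)
N_COMPARTMENTS = N_SEX * N_AGE * N_COMBO * N_STATE  # 768


@dataclass(frozen=True)
class StratumIndex:
    """One compartment label.

    ``intervention`` may be ``pa_active`` only for susceptible strata:
    individuals developing T2DM leave the intervention stratification.
    """

    sex: str
    age_band: str
    obese: bool
    smoker: bool
    inactive: bool
    disease: str
    intervention: str

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.age_band not in AGE_BANDS:
            raise ValueError(f"unknown age band {self.age_band!r}")
        if self.disease not in DISEASE_STATES:
            raise ValueError(f"unknown disease state {self.disease!r}")
        if self.intervention not in INTERVENTION_STATES:
            raise ValueError(f"unknown intervention state {self.intervention!r}")
        if self.disease == "t2dm" and self.intervention == "pa_active":
            raise ValueError("t2dm strata carry no intervention label")

    @property
    def risk_combo(self) -> int:
        return (int(self.obese) << 2) | (int(self.smoker) << 1) | int(self.inactive)

    @property
    def state(self) -> int:
        if self.disease == "t2dm":
            return T2DM
        return SUSCEPTIBLE_PA if self.intervention == "pa_active" else SUSCEPTIBLE_NONE


def enumerate_strata() -> list[StratumIndex]:
    """All 768 compartments in flat order."""
    out = []
    for s, a, c, d in product(range(N_SEX), range(N_AGE), range(N_COMBO), range(N_STATE)):
        disease, intervention = STATES[d]
        out.append(
            StratumIndex(
                sex=SEXES[s],
                age_band=AGE_BANDS[a],
                obese=bool(COMBO_BITS[c, 0]),
                smoker=bool(COMBO_BITS[c, 1]),
                inactive=bool(COMBO_BITS[c, 2]),
                disease=disease,
                intervention=intervention,
            )
        )
    return out


def flatten(idx: StratumIndex) -> int:
    """Flat position of a stratum in the state vector."""
    s = SEXES.index(idx.sex)
    a = AGE_BANDS.index(idx.age_band)
    return ((s * N_AGE + a) * N_COMBO + idx.risk_combo) * N_STATE + idx.state


def unflatten(pos: int) -> StratumIndex:
    """Inverse of :func:`flatten`."""
    if not 0 <= pos < N_COMPARTMENTS:
        raise IndexError(f"flat position {pos} out of range")
    pos, d = divmod(pos, N_STATE)
    pos, c = divmod(pos, N_COMBO)
    s, a = divmod(pos, N_AGE)
    disease, intervention = STATES[d]
    return StratumIndex(
        sex=SEXES[s],
        age_band=AGE_BANDS[a],
        obese=bool(COMBO_BITS[c, 0]),
        smoker=bool(COMBO_BITS[c, 1]),
        inactive=bool(COMBO_BITS[c, 2]),
        disease=disease,
        intervention=intervention,
    )


def band_index(label: str) -> int:
    try:
        return AGE_BANDS.index(label)
    except ValueError:
        raise KeyError(f"unknown age band {label!r}") from None
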