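import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import t2dmsim as tm

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def dataset():
    """Default synthetic Qatar-like dataset (noiseless)."""
    return tm.generate_dataset()


@pytest.fixture(scope="session")
def baseline(dataset):
    """No-intervention baseline trajectory, 2016-2050, adaptive solver."""
    return tm.simulate(dataset.params, None, dataset.initial, 2016.0, 2050.0)


@pytest.fixture(scope="session")
def baseline_prev(baseline):
    """2016 aggregate risk-factor prevalences (forcing anchors)."""
    return {
        k: tm.factor_prevalence(baseline, 2016.0, k)
        for k in ("obesity", "smoking", "inactivity")
    }


def uniform_params_and_state(
    lambda0=0.01, p_factors=(0.414, 0.162, 0.46), p_t2dm=0.167,
    rho=(0.02, 0.03, 0.04), entry=0.0, mu=0.0, nu=0.0, band_pop=1000.0,
    aging=True,
):
    """Drift-free configuration: uniform prevalence profiles with balanced
    acquisition/cessation, optional zeroed demography, for identity tests."""
    from t2dmsim.parameters import ParameterSet
    from t2dmsim.strata import COMBO_BITS, SHAPE, SUSCEPTIBLE_NONE, T2DM

    eta = np.zeros((3, 2, 16))
    rho_arr = np.zeros((3, 2, 16))
    for k in range(3):
        rho_arr[k] = rho[k]
        eta[k] = rho[k] * p_factors[k] / (1 - p_factors[k])
    kw = {} if aging else {"aging_rate": np.zeros(16)}
    params = ParameterSet(
        entry_rate=np.full(2, entry),
        mu=np.full((2, 16), mu),
        lambda0=np.full((2, 16), lambda0),
        eta=eta,
        rho=rho_arr,
        nu=np.full((2, 16), nu),
        rr_obesity=4.3, rr_smoking=1.37, rr_inactivity=1.5,
        **kw,
    )
    pk = np.array(p_factors)
    counts = np.zeros(SHAPE)
    for c in range(8):
        bits = COMBO_BITS[c].astype(bool)
        joint = np.prod(np.where(bits, pk, 1 - pk))
        counts[:, :, c, SUSCEPTIBLE_NONE] = band_pop * (1 - p_t2dm) * joint
        counts[:, :, c, T2DM] = band_pop * p_t2dm * joint
    state = tm.PopulationState(counts, 2016.0)
    return params, state
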