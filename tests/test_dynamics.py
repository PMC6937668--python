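import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.linalg import expm

import t2dmsim as tm
from t2dmsim.dynamics import StepControls, rhs, simulate
from t2dmsim.parameters import ParameterSet
from t2dmsim.strata import SHAPE, StratumIndex, T2DM

from conftest import uniform_params_and_state


def _stratum(**kw):
    base = dict(sex="female", age_band="40-44", obese=False, smoker=False,
                inactive=False, disease="susceptible", intervention="none")
    base.update(kw)
    return StratumIndex(**base)


def _params(**kw):
    base = dict(
        entry_rate=np.zeros(2), mu=np.zeros((2, 16)),
        lambda0=np.full((2, 16), 0.01), eta=np.zeros((3, 2, 16)),
        rho=np.zeros((3, 2, 16)), nu=np.zeros((2, 16)),
    )
    base.update(kw)
    return ParameterSet(**base)


class TestIncidenceHazard:
    def test_risk_free_equals_lambda0(self):
        p = _params(rr_obesity=4.0, rr_smoking=1.4, rr_inactivity=1.5)
        assert tm.incidence_hazard(_stratum(), p) == pytest.approx(0.01)

    def test_obese_with_vigorous_pa(self):
        # 0.010 x 5.0 x 0.61 = 0.0305
        p = _params(rr_obesity=5.0, rr_pa=0.61)
        h = tm.incidence_hazard(_stratum(obese=True, intervention="pa_active"), p)
        assert h == pytest.approx(0.0305)

    @given(a=st.floats(1.0, 10.0), b=st.floats(1.0, 10.0), c=st.floats(1.0, 10.0))
    def test_multiplicativity_identity(self, a, b, c):
        # joint hazard = product of single-factor hazards / lambda0^2
        p = _params(rr_obesity=a, rr_smoking=b, rr_inactivity=c)
        lam = 0.01
        singles = [
            tm.incidence_hazard(_stratum(obese=True), p),
            tm.incidence_hazard(_stratum(smoker=True), p),
            tm.incidence_hazard(_stratum(inactive=True), p),
        ]
        joint = tm.incidence_hazard(
            _stratum(obese=True, smoker=True, inactive=True), p
        )
        assert joint == pytest.approx(np.prod(singles) / lam**2, rel=1e-12)

    @given(rr=st.floats(1.0, 20.0))
    def test_monotone_in_relative_risk(self, rr):
        low = _params(rr_obesity=1.0)
        high = _params(rr_obesity=rr)
        s = _stratum(obese=True)
        assert tm.incidence_hazard(s, high) >= tm.incidence_hazard(s, low)

    def test_error_on_t2dm_stratum(self):
        with pytest.raises(ValueError, match="susceptible"):
            tm.incidence_hazard(_stratum(disease="t2dm"), _params())


class TestRhs:
    def test_all_zero_flows_give_zero_derivative(self):
        p = _params(lambda0=np.zeros((2, 16)), aging_rate=np.zeros(16))
        counts = np.random.default_rng(0).uniform(0, 100, SHAPE)
        dc, dca, dde = rhs(2016.0, counts, p)
        assert np.allclose(dc, 0) and np.allclose(dca, 0) and np.allclose(dde, 0)

    def test_pure_mortality_is_exponential_decay(self):
        mu = np.zeros((2, 16))
        mu[0, 8] = 0.3
        p = _params(mu=mu, lambda0=np.zeros((2, 16)),
                    aging_rate=np.zeros(16))
        counts = np.zeros(SHAPE)
        counts[0, 8, 0, 0] = 500.0
        traj = simulate(p, None, tm.PopulationState(counts, 2016.0), 2016.0, 2026.0)
        expected = 500.0 * np.exp(-0.3 * (traj.years - 2016.0))
        assert np.allclose(traj.counts[:, 0, 8, 0, 0], expected, rtol=1e-6)

    def test_population_balance_ledger(self, dataset):
        # sum of derivative = entry - background deaths - excess deaths
        counts = dataset.initial.counts
        p = dataset.params
        dc, _, dde = rhs(2016.0, counts, p)
        expected = (
            p.entry_at(2016.0).sum()
            - (p.mu[:, :, None, None] * counts).sum()
            - (p.nu[:, :, None] * counts[..., T2DM]).sum()
        )
        assert dc.sum() == pytest.approx(expected, rel=1e-12)
        assert dde.sum() == pytest.approx(
            (p.nu[:, :, None] * counts[..., T2DM]).sum(), rel=1e-12
        )


class TestSimulate:
    def test_zero_flow_system_is_constant(self):
        p = _params(lambda0=np.zeros((2, 16)), aging_rate=np.zeros(16))
        counts = np.full(SHAPE, 7.0)
        traj = simulate(p, None, tm.PopulationState(counts, 2016.0), 2016.0, 2020.0)
        assert np.allclose(traj.counts, 7.0)

    def test_two_compartment_constant_hazard_closed_form(self):
        # susceptible -> t2dm at constant hazard h: prevalence 1 - exp(-h t)
        h = 0.05
        p = _params(lambda0=np.full((2, 16), h), aging_rate=np.zeros(16))
        counts = np.zeros(SHAPE)
        counts[1, 5, 0, 0] = 1000.0
        traj = simulate(p, None, tm.PopulationState(counts, 2016.0), 2016.0, 2046.0)
        t = traj.years - 2016.0
        prev = traj.counts[:, 1, 5, 0, T2DM] / 1000.0
        assert np.allclose(prev, 1 - np.exp(-h * t), atol=1e-6)

    def test_matrix_exponential_oracle_small_system(self):
        # one (sex, band), obesity only, aging off: 4 coupled compartments
        lam, rr, e, r, mu, nu = 0.02, 4.3, 0.05, 0.02, 0.01, 0.03
        mu_arr = np.full((2, 16), mu)
        nu_arr = np.full((2, 16), nu)
        eta = np.zeros((3, 2, 16)); eta[0] = e
        rho = np.zeros((3, 2, 16)); rho[0] = r
        p = _params(lambda0=np.full((2, 16), lam), mu=mu_arr, nu=nu_arr,
                    eta=eta, rho=rho, rr_obesity=rr,
                    aging_rate=np.zeros(16))
        counts = np.zeros(SHAPE)
        # order: (lean, sus), (lean, t2dm), (obese, sus), (obese, t2dm)
        x0 = np.array([600.0, 100.0, 250.0, 50.0])
        counts[0, 7, 0, 0], counts[0, 7, 0, T2DM] = x0[0], x0[1]
        counts[0, 7, 4, 0], counts[0, 7, 4, T2DM] = x0[2], x0[3]
        M = np.array([
            [-(lam + e + mu), 0.0, r, 0.0],
            [lam, -(mu + nu + e), 0.0, r],
            [e, 0.0, -(lam * rr + r + mu), 0.0],
            [0.0, e, lam * rr, -(mu + nu + r)],
        ])
        traj = simulate(p, None, tm.PopulationState(counts, 2016.0), 2016.0, 2026.0)
        for ti, t in enumerate(traj.years):
            ref = expm(M * (t - 2016.0)) @ x0
            got = np.array([
                traj.counts[ti, 0, 7, 0, 0], traj.counts[ti, 0, 7, 0, T2DM],
                traj.counts[ti, 0, 7, 4, 0], traj.counts[ti, 0, 7, 4, T2DM],
            ])
            assert np.allclose(got, ref, rtol=1e-6, atol=1e-6 * x0.sum())

    def test_adaptive_matches_fixed_step_rk4_on_full_system(self, dataset):
        a = simulate(dataset.params, None, dataset.initial, 2016.0, 2021.0)
        b = simulate(dataset.params, None, dataset.initial, 2016.0, 2021.0,
                     method="rk4", rk4_dt=0.01)
        scale = np.abs(b.counts).max()
        assert np.abs(a.counts - b.counts).max() / scale < 1e-4

    def test_transitions_preserve_totals(self):
        # risk-factor churn + PA recruitment only: no demography, no disease
        params, state = uniform_params_and_state(lambda0=0.0, aging=False)
        forcing = tm.ScenarioForcing(
            pa_coverage_fn=lambda t: min(0.25, 0.25 * (t - 2016) / 15), rr_pa=1.0
        )
        traj = simulate(params, forcing, state, 2016.0, 2030.0)
        totals = traj.counts.sum(axis=(1, 2, 3, 4))
        assert np.allclose(totals, totals[0], rtol=1e-8)
        by_sex_age = traj.counts.sum(axis=(3, 4))
        assert np.allclose(by_sex_age, by_sex_age[0], rtol=1e-8)
        disease = traj.counts[..., T2DM].sum(axis=(1, 2, 3))
        assert np.allclose(disease, disease[0], rtol=1e-8)

    def test_cumulative_flows_nondecreasing(self, baseline):
        assert (np.diff(baseline.cum_cases.sum(axis=(1, 2))) >= 0).all()
        assert (np.diff(baseline.cum_deaths.sum(axis=(1, 2))) >= 0).all()

    def test_reporting_grid_covers_horizon(self, baseline):
        assert baseline.years[0] == 2016.0 and baseline.years[-1] == 2050.0
        assert len(baseline.years) == 35

    def test_negative_initial_state_rejected(self, dataset):
        bad = dataset.initial.counts.copy()
        bad[0, 0, 0, 0] = -1.0
        with pytest.raises(ValueError, match="nonnegative"):
            simulate(dataset.params, None, tm.PopulationState(bad, 2016.0),
                     2016.0, 2020.0)

    def test_bad_horizon_rejected(self, dataset):
        with pytest.raises(ValueError, match="t0 < t1"):
            simulate(dataset.params, None, dataset.initial, 2020.0, 2016.0)


def test_trajectory_export_shapes(baseline):
    df = baseline.to_frame()
    assert set(df.columns) == {
        "year", "sex", "age_band", "obese", "smoker", "inactive",
        "disease", "intervention", "count",
    }
    assert len(df) == 35 * 768
    fl = baseline.flows_frame()
    assert {"cum_cases", "cum_deaths"} <= set(fl.columns)
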