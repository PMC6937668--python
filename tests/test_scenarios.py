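import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import t2dmsim as tm
from t2dmsim.scenarios import (
    ScenarioSpec,
    build_forcing,
    load_library,
    prevalence_controller,
    ramp_target,
    scale_up_variants,
    scenario_library,
)

from conftest import uniform_params_and_state


class TestRampTarget:
    @pytest.mark.parametrize(
        "p0, F, expected",
        [
            (0.414, 0.5, 20.7),  # obesity halved
            (0.162, 0.3, 11.3),  # smoking -30% (WHO plan)
            (0.460, 0.1, 41.4),  # inactivity -10% (WHO plan)
            (0.162, 0.5, 8.1),
            (0.460, 0.5, 23.0),
        ],
    )
    def test_ramp_endpoints_match_published_levels(self, p0, F, expected):
        got = 100 * ramp_target(p0, F, 2031.0, 2016.0, 2031.0)
        assert round(got, 1) == expected

    def test_halt_is_identity(self):
        for t in (2010.0, 2016.0, 2023.5, 2031.0, 2050.0):
            assert ramp_target(0.414, 0.0, t, 2016.0, 2031.0) == 0.414

    def test_midpoint_linear_interpolation(self):
        # 46.0% halved: midway through the ramp -> 34.5%
        got = ramp_target(0.46, 0.5, 2023.5, 2016.0, 2031.0)
        assert got == pytest.approx(0.345)

    @given(
        p0=st.floats(0.01, 0.99), F=st.floats(0.0, 1.0),
        t=st.floats(2000.0, 2060.0),
    )
    def test_continuous_and_bounded(self, p0, F, t):
        v = ramp_target(p0, F, t, 2016.0, 2031.0)
        eps = 1e-6
        v2 = ramp_target(p0, F, t + eps, 2016.0, 2031.0)
        assert abs(v2 - v) < p0 * F * eps / 15 + 1e-9  # Lipschitz in t
        assert p0 * (1 - F) - 1e-12 <= v <= p0 + 1e-12

    @given(p0=st.floats(0.01, 0.99), f1=st.floats(0, 1), f2=st.floats(0, 1))
    def test_monotone_in_reduction(self, p0, f1, f2):
        lo, hi = sorted((f1, f2))
        for t in (2020.0, 2031.0, 2040.0):
            assert ramp_target(p0, hi, t, 2016.0, 2031.0) <= ramp_target(
                p0, lo, t, 2016.0, 2031.0
            )


class TestBuildForcing:
    def test_who_plan_2031_levels(self):
        spec = ScenarioSpec(
            name="who",
            factor_reductions={"obesity": 0.0, "smoking": 0.3, "inactivity": 0.1},
        )
        f = build_forcing(spec, {"obesity": 0.414, "smoking": 0.162, "inactivity": 0.460})
        assert round(100 * f.factor_targets["obesity"](2031.0), 1) == 41.4
        assert round(100 * f.factor_targets["smoking"](2031.0), 1) == 11.3
        assert round(100 * f.factor_targets["inactivity"](2031.0), 1) == 41.4

    def test_empty_spec_gives_no_forcing(self):
        spec = ScenarioSpec(name="none")
        assert build_forcing(spec, {}) is None

    def test_combined_with_vigorous_pa(self):
        spec = ScenarioSpec(
            name="combo",
            factor_reductions={"obesity": 0.5, "smoking": 0.5, "inactivity": 0.5},
            pa_intensity="vigorous",
        )
        f = build_forcing(spec, {"obesity": 0.414, "smoking": 0.162, "inactivity": 0.460})
        assert round(100 * f.factor_targets["obesity"](2031.0), 1) == 20.7
        assert round(100 * f.factor_targets["smoking"](2031.0), 1) == 8.1
        assert round(100 * f.factor_targets["inactivity"](2031.0), 1) == 23.0
        assert f.pa_coverage_fn(2031.0) == pytest.approx(0.25)
        assert f.rr_pa == 0.61

    def test_unknown_intensity_lists_valid_labels(self):
        with pytest.raises(ValueError, match="leisure"):
            ScenarioSpec(name="bad", pa_intensity="extreme")

    def test_pure_identical_specs_identical_forcings(self):
        spec = ScenarioSpec(name="x", factor_reductions={"obesity": 0.2})
        p0 = {"obesity": 0.414}
        f1, f2 = build_forcing(spec, p0), build_forcing(spec, p0)
        for t in np.linspace(2016, 2050, 69):
            assert f1.factor_targets["obesity"](t) == f2.factor_targets["obesity"](t)


class TestScaleUpVariants:
    def test_construction(self):
        spec = ScenarioSpec(name="ob40", factor_reductions={"obesity": 0.4})
        variants = scale_up_variants(spec, [5, 10, 15, 20])
        assert [v.ramp_end for v in variants] == [2021.0, 2026.0, 2031.0, 2036.0]
        assert all(v.hold_until == 2050.0 for v in variants)

    def test_short_ramp_endpoint(self):
        spec = ScenarioSpec(name="ob40", factor_reductions={"obesity": 0.4})
        v = scale_up_variants(spec, [5])[0]
        f = build_forcing(v, {"obesity": 0.414})
        assert f.factor_targets["obesity"](2021.0) == pytest.approx(0.414 * 0.6)

    def test_duration_beyond_hold_rejected(self):
        spec = ScenarioSpec(name="ob40", factor_reductions={"obesity": 0.4})
        with pytest.raises(ValueError, match="hold_until"):
            scale_up_variants(spec, [40])


class TestController:
    def test_no_correction_when_on_target(self):
        params, state = uniform_params_and_state()
        me, mr = prevalence_controller(state.counts, "obesity", 0.414, params)
        assert me == pytest.approx(1.0, abs=1e-6)
        assert mr == pytest.approx(1.0, abs=1e-6)

    def test_halt_on_drifting_baseline_corrects_downward(self, dataset, baseline):
        # baseline obesity drifts up with aging; halting must damp acquisition
        counts = baseline.counts[baseline.year_index(2030.0)]
        me, mr = prevalence_controller(
            counts, "obesity", 0.414, dataset.params, dt=1.0
        )
        assert me < 1.0 or mr > 1.0

    def test_unattainable_target_saturates_with_warning(self):
        params, state = uniform_params_and_state()
        with pytest.warns(tm.scenarios.ControllerSaturationWarning):
            prevalence_controller(state.counts, "obesity", 0.0, params, dt=0.1)

    def test_tracking_all_library_prevalence_scenarios(self, dataset, baseline_prev):
        # every prevalence-targeting scenario holds its linear trajectory
        # within 0.2 percentage points at all reporting years
        lib = scenario_library()
        worst = 0.0
        for name, spec in lib.items():
            if not spec.factor_reductions:
                continue
            forcing = build_forcing(spec, baseline_prev)
            traj = tm.simulate(dataset.params, forcing, dataset.initial,
                               2016.0, 2050.0)
            for year in range(2016, 2051):
                for k, fn in forcing.factor_targets.items():
                    err = abs(tm.factor_prevalence(traj, float(year), k) - fn(year))
                    worst = max(worst, err)
        assert worst < 0.002

    def test_pa_coverage_reaches_target(self, dataset):
        spec = scenario_library()["pa_moderate"]
        forcing = build_forcing(spec, {})
        traj = tm.simulate(dataset.params, forcing, dataset.initial, 2016.0, 2050.0)
        for year in (2031.0, 2040.0, 2050.0):
            sus = traj.counts[traj.year_index(year)][:, 3:13, :, :2]
            cov = sus[..., 1].sum() / sus.sum()
            assert abs(cov - 0.25) < 0.005


def test_bundled_library_matches_programmatic(tmp_path):
    import importlib.resources as res

    with res.as_file(res.files("t2dmsim") / "data" / "scenario_library.yaml") as p:
        lib = load_library(p)
    assert lib == scenario_library()
    assert len(lib) == 30
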