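"""Forward model: geometry, profile evaluation, exact ODE propagation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from nbdgkin import (
    CellGeometry,
    ExperimentDesign,
    ExternalProfile,
    KineticParams,
    analytic_step_solution,
    cell_volume,
    eval_profile,
    make_external_profile,
    propagate_segment,
    solve_trace,
)
from nbdgkin.model import InvalidGeometryError, compile_grid


class TestCellVolume:
    @pytest.mark.parametrize(
        "width,length,expected",
        [
            (1.0, 1.0, math.pi / 6),                      # sphere limit
            (2.0, 2.0, 4 * math.pi / 3),                  # sphere limit
            (1.0, 25.0, 6 * math.pi + math.pi / 6),       # hosting-channel rod
        ],
    )
    def test_spherocylinder_values(self, width, length, expected):
        assert cell_volume(CellGeometry(width, length)) == pytest.approx(
            expected, rel=1e-12
        )

    def test_cylinder_option(self):
        geom = CellGeometry(1.0, 4.0)
        assert cell_volume(geom, shape="cylinder") == pytest.approx(math.pi)

    @pytest.mark.parametrize("width,length", [(0.0, 1.0), (-1.0, 2.0), (1.0, 0.5)])
    def test_invalid_geometry_rejected(self, width, length):
        with pytest.raises(InvalidGeometryError):
            CellGeometry(width, length)


class TestProfile:
    def test_linear_interpolation_and_clamping(self):
        prof = ExternalProfile.from_knots([(0, 0), (60, 30)])
        assert eval_profile(prof, 30) == pytest.approx(15.0)
        assert eval_profile(prof, -10) == 0.0
        assert eval_profile(prof, 1000) == 30.0

    def test_empty_knots_rejected(self):
        with pytest.raises(ValueError):
            ExternalProfile.from_knots([])

    def test_step_profile_right_continuous(self):
        prof = make_external_profile(ExperimentDesign(rise_time=0, fall_time=0))
        assert eval_profile(prof, 0.0) == 30.0
        assert eval_profile(prof, -1.0) == 0.0
        assert eval_profile(prof, 1200.0) == 0.0
        assert eval_profile(prof, 1199.9) == 30.0


class TestPropagateSegment:
    def test_steady_state(self):
        # constant forcing, long time: u_over_V * a / d
        val = propagate_segment(0.0, 0.01, 0.5, 30.0, 0.0, 1e6)
        assert val == pytest.approx(0.5 * 30.0 / 0.01, rel=1e-12)

    def test_pure_decay(self):
        val = propagate_segment(7.0, 0.02, 0.0, 5.0, 1.0, 50.0)
        assert val == pytest.approx(7.0 * math.exp(-1.0), rel=1e-12)

    def test_matches_quadrature_on_random_segments(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            y0 = rng.uniform(0, 100)
            d = 10 ** rng.uniform(-4, 0)
            uV = 10 ** rng.uniform(-3, 0)
            a, b = rng.uniform(0, 30), rng.uniform(-0.5, 0.5)
            dt = rng.uniform(0, 100)
            res = solve_ivp(
                lambda t, y: -d * y + uV * (a + b * t), (0, dt), [y0],
                rtol=1e-11, atol=1e-12,
            )
            assert propagate_segment(y0, d, uV, a, b, dt) == pytest.approx(
                res.y[0, -1], rel=1e-6, abs=1e-9
            )


class TestSolveTrace:
    def test_zero_uptake_stays_zero(self, profile, design):
        with pytest.raises(ValueError):
            KineticParams(0.0, 0.01)  # u must be strictly positive
        sol = solve_trace(KineticParams(1e-300, 0.01), 1.0, profile, design.t_grid)
        assert np.allclose(sol.conc, 0.0)

    def test_constant_profile_reaches_analytic_plateau(self):
        prof = ExternalProfile.from_knots([(0.0, 30.0), (1e7, 30.0)])
        t = np.linspace(0, 5e6, 50)
        sol = solve_trace(KineticParams(1.0, 0.01), 1.0, prof, t)
        assert sol.conc[-1] == pytest.approx(3000.0, rel=1e-9)

    def test_step_profile_matches_closed_form(self, step_profile, step_design,
                                              typical_params):
        t = step_design.t_grid
        V = 2.0
        sol = solve_trace(typical_params, V, step_profile, t)
        ana = analytic_step_solution(typical_params, V, 30.0, t, 1200.0)
        assert np.max(np.abs(sol.conc - ana)) < 1e-9 * np.max(ana)

    def test_matches_runge_kutta_on_random_instances(self):
        """Exact per-segment propagation vs adaptive RK on 100 random
        (parameter, profile) draws, relative tolerance 1e-6."""
        rng = np.random.default_rng(17)
        t = np.arange(0.0, 2101.0, 20.0)
        for _ in range(100):
            p = KineticParams(
                float(np.exp(rng.uniform(-3, 1))), float(np.exp(rng.uniform(-7, -2)))
            )
            V = rng.uniform(0.5, 5.0)
            design = ExperimentDesign(
                rise_time=rng.uniform(0, 300), fall_time=rng.uniform(0, 300),
                washout_time=rng.uniform(600, 1500),
            )
            prof = make_external_profile(design)
            mine = solve_trace(p, V, prof, t).conc
            ref = solve_ivp(
                lambda tt, y: -p.d_gluc * y
                + p.u_gluc / V * np.interp(tt, prof.times, prof.conc),
                (0, 2100), [0.0], t_eval=t, rtol=1e-10, atol=1e-12, max_step=20.0,
            ).y[0]
            scale = np.maximum(np.abs(ref), 1e-6 * ref.max())
            assert np.max(np.abs(mine - ref) / scale) < 1e-6

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        log_u=st.floats(-3, 1),
        log_d=st.floats(-6, -2),
        factor=st.floats(0.1, 10),
    )
    def test_scaling_identifiability(self, profile, design, log_u, log_d, factor):
        """Only u_gluc / V_c enters the dynamics: scaling both leaves the
        solution unchanged."""
        p1 = KineticParams(math.exp(log_u), math.exp(log_d))
        p2 = KineticParams(factor * p1.u_gluc, p1.d_gluc)
        t = design.t_grid
        s1 = solve_trace(p1, 1.7, profile, t).conc
        s2 = solve_trace(p2, factor * 1.7, profile, t).conc
        np.testing.assert_allclose(s1, s2, rtol=1e-12, atol=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(log_u=st.floats(-3, 1), log_d=st.floats(-6, -2))
    def test_nonnegativity(self, profile, design, log_u, log_d):
        sol = solve_trace(
            KineticParams(math.exp(log_u), math.exp(log_d)), 2.0, profile,
            design.t_grid,
        )
        assert np.all(sol.conc >= 0.0)


class TestAnalyticStep:
    def test_initial_condition_zero(self, typical_params):
        assert analytic_step_solution(typical_params, 2.0, 30.0, 0.0, 1200.0) == 0.0

    def test_plateau_limit(self, typical_params):
        u, d, V, g = typical_params.u_gluc, typical_params.d_gluc, 2.0, 30.0
        val = analytic_step_solution(typical_params, V, g, 1190.0, 1200.0)
        assert val == pytest.approx(u * g / (d * V), rel=1e-2)

    def test_full_degradation(self, typical_params):
        assert analytic_step_solution(typical_params, 2.0, 30.0, 1e7, 1200.0) == (
            pytest.approx(0.0, abs=1e-12)
        )

    def test_negative_time_rejected(self, typical_params):
        with pytest.raises(ValueError):
            analytic_step_solution(typical_params, 2.0, 30.0, -1.0, 1200.0)


def test_compiled_grid_handles_knots_between_grid_points(typical_params):
    """Profile knots that fall between output samples still shape the exact
    solution (the compiled union grid splits segments at every knot)."""
    prof = ExternalProfile.from_knots([(0, 0), (7, 30), (50, 30), (57, 0), (100, 0)])
    t_coarse = np.array([0.0, 20.0, 40.0, 60.0, 80.0, 100.0])
    mine = solve_trace(typical_params, 2.0, prof, t_coarse).conc
    ref = solve_ivp(
        lambda tt, y: -typical_params.d_gluc * y
        + typical_params.u_gluc / 2.0 * np.interp(tt, prof.times, prof.conc),
        (0, 100), [0.0], t_eval=t_coarse, rtol=1e-11, atol=1e-13, max_step=1.0,
    ).y[0]
    np.testing.assert_allclose(mine, ref, rtol=1e-6, atol=1e-9)
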