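"""Core ODE model: regulatory functions, right-hand side, integration."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from tibd import (
    ModelParameters,
    SimulationError,
    compute_pi_C,
    compute_pi_L,
    compute_pi_P,
    effective_pthrp_injection,
    ode_rhs,
    per_cell_hill_rate,
    simulate,
)
from tibd.model import bone_formation_flux, bone_resorption_flux
from tibd.synthetic import default_truth_overrides


# ---------------------------------------------------------------------------
# receptor-occupancy functions
# ---------------------------------------------------------------------------

class TestPiC:
    def test_half_saturation_definition(self, params):
        # Cs is defined as the OC level where pi_C = (1 + fO) / 2
        assert compute_pi_C(params.Cs, params) == pytest.approx(0.525, abs=1e-12)

    def test_limits(self, params):
        assert compute_pi_C(0.0, params) == pytest.approx(params.fO)
        assert compute_pi_C(1e9, params) == pytest.approx(1.0, abs=1e-6)

    def test_negative_rejected(self, params):
        with pytest.raises(ValueError):
            compute_pi_C(-0.1, params)

    @given(st.floats(min_value=0.0, max_value=1e3), st.floats(min_value=0.0, max_value=1e3))
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_increasing(self, c1, c2):
        p = ModelParameters()
        v1, v2 = compute_pi_C(c1, p), compute_pi_C(c2, p)
        assert p.fO <= v1 <= 1.0
        if c1 < c2:
            assert v1 <= v2
        if c2 > c1 + 1e-9 * (1.0 + c1):  # strict once separation beats rounding
            assert v1 < v2


class TestPiP:
    def test_baseline_occupancy(self, params):
        # (250/86) / ((250/86) + 150) with no injected hormone
        assert compute_pi_P(0.0, params) == pytest.approx(0.019011, abs=1e-6)

    def test_limits(self, params):
        assert compute_pi_P(1e12, params) == pytest.approx(1.0, abs=1e-6)
        no_pth = params.replace(SP=0.0)
        assert compute_pi_P(0.0, no_pth) == 0.0

    def test_monotone_in_injection(self, params):
        vals = [compute_pi_P(x, params) for x in (0.0, 10.0, 100.0, 1e4)]
        assert all(a < b for a, b in zip(vals, vals[1:]))
        assert all(0 <= v < 1 for v in vals)


class TestPiL:
    def test_zero_without_active_obs(self, params):
        assert compute_pi_L((1e-3, 0.0), 0.02, params) == 0.0

    def test_rankl_injection_doubles(self, params):
        base = compute_pi_L((1e-3, 1e-3), 0.02, params)
        boosted = compute_pi_L((1e-3, 1e-3), 0.02, params.replace(IL=params.rL))
        assert boosted == pytest.approx(2 * base)

    def test_singularity_guard(self, params):
        with pytest.raises(ZeroDivisionError):
            compute_pi_L((1e-3, 1e-3), 0.0, params)

    def test_increasing_in_b_and_pip(self, params):
        lo = compute_pi_L((1e-3, 1e-3), 0.02, params)
        assert compute_pi_L((1e-3, 2e-3), 0.02, params) > lo
        assert compute_pi_L((1e-3, 1e-3), 0.04, params) > lo


class TestPTHrP:
    def test_baseline_only_without_tumor(self, params):
        assert effective_pthrp_injection(0.0, 0.5, params) == params.IP

    def test_linear_in_burden(self, params):
        p = params.replace(kTpthrp=500.0)
        v = effective_pthrp_injection(0.1, 0.5, p)
        assert v == pytest.approx(25.0)
        assert effective_pthrp_injection(0.2, 0.5, p) == pytest.approx(2 * v)

    def test_domain_checks(self, params):
        with pytest.raises(ValueError):
            effective_pthrp_injection(-1.0, 0.5, params)
        with pytest.raises(ValueError):
            effective_pthrp_injection(1.0, 1.5, params)


# ---------------------------------------------------------------------------
# Hill-compensated rates
# ---------------------------------------------------------------------------

class TestHillRate:
    def test_doubles_at_k2(self):
        assert per_cell_hill_rate(0.1, 3.36e6, 0.1, 1.0) == pytest.approx(2 * 3.36e6)

    def test_mass_action_limit(self):
        assert per_cell_hill_rate(1e9, 5.0, 0.1, 1.0) == pytest.approx(5.0, rel=1e-6)

    def test_arithmetic_example(self):
        # k1*(k2^n + X^n)/X^n with n=1, k1=2, k2=3, X=1
        assert per_cell_hill_rate(1.0, 2.0, 3.0, 1.0) == pytest.approx(8.0)

    def test_zero_population_is_domain_error(self):
        with pytest.raises(ValueError):
            per_cell_hill_rate(0.0, 1.0, 1.0, 1.0)

    @given(st.floats(min_value=1e-6, max_value=1e3), st.floats(min_value=1e-6, max_value=1e3))
    @settings(max_examples=50, deadline=None)
    def test_decreasing_and_bounded_below(self, x1, x2):
        k1, k2, n = 2.0, 0.5, 1.0
        r1, r2 = per_cell_hill_rate(x1, k1, k2, n), per_cell_hill_rate(x2, k1, k2, n)
        assert r1 >= k1 and r2 >= k1
        if x1 < x2:
            assert r1 > r2

    def test_total_flux_increasing_and_finite_at_zero(self, params):
        fluxes = [bone_formation_flux(b, params) for b in (0.0, 0.05, 0.1, 1.0)]
        assert all(a < b for a, b in zip(fluxes, fluxes[1:]))
        assert bone_formation_flux(0.0, params) == pytest.approx(params.k1B * params.k2B)
        assert bone_resorption_flux(0.0, params) == pytest.approx(params.k1C * params.K2C)


# ---------------------------------------------------------------------------
# right-hand side
# ---------------------------------------------------------------------------

class TestOdeRhs:
    def test_all_zero_state(self, params):
        dy = ode_rhs(0.0, np.zeros(6), params)
        # dR/dt = DR * fO at the empty state
        assert dy[0] == pytest.approx(3.5e-5)
        assert dy[1] == 0.0 and dy[2] == 0.0
        assert dy[4] == 0.0 and dy[5] == 0.0

    def test_tumor_free_reduction(self, params, steady_state):
        state = steady_state.copy()
        dy = ode_rhs(0.0, state, params)
        assert dy[4] == 0.0  # no tumor, no tumor dynamics
        # the tumor-kill term vanishes: dB/dt identical with kTB = 0
        dy2 = ode_rhs(0.0, state, params.replace(kTB=0.0))
        assert dy[1] == pytest.approx(dy2[1])

    def test_drug_free_reduction(self, params, steady_state):
        dy = ode_rhs(0.0, steady_state, params)
        dy2 = ode_rhs(0.0, steady_state, params.replace(kZC=0.0))
        np.testing.assert_allclose(dy, dy2)

    def test_validation(self, params):
        with pytest.raises(ValueError):
            ode_rhs(0.0, np.zeros(5), params)
        with pytest.raises(ValueError):
            ode_rhs(0.0, -np.ones(6), params)


def _lemaire_oracle_rhs(t, y, p):
    """Independently coded osteoblast/osteoclast regulatory core (R, B, C)."""
    R, B, C = y
    pi_C = (C + p["fO"] * p["Cs"]) / (C + p["Cs"])
    P = (p["IP"] + p["SP"]) / p["kP"]
    pi_P = P / (P + p["k6"] / p["k5"])
    pi_L = (
        (p["k3"] / p["k4"]) * p["KLP"] * pi_P * B * (1 + p["IL"] / p["rL"])
    ) / (
        1
        + p["k3"] * p["K"] / p["k4"]
        + (p["k1"] / (p["k2"] * p["kO"])) * (p["KOP"] * R / pi_P + p["IO"])
    )
    return [
        p["DR"] * pi_C - p["dB"] * R / pi_C,
        p["dB"] * R / pi_C - p["kB"] * B,
        p["DC"] * pi_L - p["DA"] * pi_C * C,
    ]


def test_lemaire_reduction_matches_independent_integration(params):
    """With tumor and drug absent, (R, B, C) reproduce the homeostasis core."""
    t_grid = np.linspace(0.0, 500.0, 101)
    y0 = np.array([1e-4, 1e-4, 1e-4, 100.0, 0.0, 0.0])
    full = simulate(params.replace(kTB=0.0), y0, t_grid, rtol=1e-11, atol=1e-13)
    pdict = params.as_dict()
    oracle = solve_ivp(
        _lemaire_oracle_rhs,
        (0.0, 500.0),
        y0[:3],
        args=(pdict,),
        method="LSODA",
        t_eval=t_grid,
        rtol=1e-11,
        atol=1e-13,
    )
    assert oracle.success
    for k in range(3):
        ours = full[:, k]
        ref = oracle.y[k]
        rel = np.abs(ours - ref) / np.maximum(np.abs(ref), 1e-12)
        assert rel.max() < 1e-8


def test_finite_difference_matches_rhs(params, steady_state):
    """Central differences of a smooth trajectory reproduce the derivative."""
    p = params.with_overrides(default_truth_overrides()["bone_adapted"])
    y0 = steady_state.copy()
    y0[4] = 1e-3  # inject tumor
    t0, h = 10.0, 0.005
    t_grid = np.array([t0 - h, t0, t0 + h])
    traj = simulate(p, y0, np.concatenate([[0.0], t_grid]), rtol=1e-11, atol=1e-13)
    fd = (traj[3] - traj[1]) / (2 * h)
    dy = ode_rhs(t0, np.maximum(traj[2], 0.0), p)
    scale = np.maximum(np.abs(dy), 1e-6)
    assert np.max(np.abs(fd - dy) / scale) < 1e-3


# ---------------------------------------------------------------------------
# integration contracts
# ---------------------------------------------------------------------------

class TestSimulate:
    def test_steady_state_invariance(self, params, steady_state):
        t = np.linspace(0.0, 21.0, 22)
        traj = simulate(params, steady_state, t)
        for k in range(3):
            drift = np.abs(traj[:, k] / traj[0, k] - 1.0)
            assert drift.max() < 1e-3

    def test_dense_and_coarse_grids_agree(self, params, steady_state):
        y0 = steady_state.copy()
        events = [(0.0, "T", 1e-3)]
        p = params.with_overrides(default_truth_overrides()["bone_adapted"])
        coarse = simulate(p, y0, [0.0, 7.0, 14.0, 21.0], events=events)
        dense = simulate(p, y0, np.linspace(0.0, 21.0, 211), events=events)
        for i, day in enumerate([0.0, 7.0, 14.0, 21.0]):
            j = np.argmin(np.abs(np.linspace(0.0, 21.0, 211) - day))
            np.testing.assert_allclose(coarse[i], dense[j], rtol=1e-6, atol=1e-12)

    def test_tolerance_refinement_converges(self, params, steady_state):
        y0 = steady_state.copy()
        p = params.with_overrides(default_truth_overrides()["bone_adapted"])
        events = [(0.0, "T", 1e-3)]
        a = simulate(p, y0, [0.0, 21.0], events=events, rtol=1e-8, atol=1e-10)[-1]
        b = simulate(p, y0, [0.0, 21.0], events=events, rtol=5e-9, atol=5e-11)[-1]
        rel = np.abs(a - b) / np.maximum(np.abs(b), 1e-12)
        assert rel[:5].max() < 1e-3

    def test_event_injection_recorded_post_jump(self, params, steady_state):
        traj = simulate(params, steady_state, [0.0, 6.0, 7.0], events=[(6.0, "Z", 1.0)])
        assert traj[0, 5] == 0.0
        assert traj[1, 5] == pytest.approx(1.0)
        assert traj[2, 5] == pytest.approx(1.0)

    def test_bad_grid_rejected(self, params, steady_state):
        with pytest.raises(ValueError):
            simulate(params, steady_state, [0.0, 2.0, 1.0])
        with pytest.raises(ValueError):
            simulate(params, steady_state, [0.0, 1.0], events=[(5.0, "T", 1e-3)])

    def test_non_negativity_on_protocol(self, params, steady_state):
        p = params.with_overrides(default_truth_overrides()["bone_adapted"])
        y0 = steady_state.copy()
        traj = simulate(
            p, y0, np.linspace(0, 28, 281),
            events=[(0.0, "T", 1e-3), (6.0, "Z", 1.0)],
            rtol=1e-8, atol=1e-10,
        )
        assert traj.min() > -10 * 1e-10

    def test_solver_failure_carries_time(self, params, steady_state):
        crazy = params.replace(kTpthrp=1e30, kTdiv=1e8)
        y0 = steady_state.copy()
        y0[4] = 1e-3
        with pytest.raises(SimulationError):
            simulate(crazy, y0, [0.0, 21.0], max_steps=200)


def test_vicious_cycle_lowers_bone(params, steady_state):
    """Injected tumor can only reduce day-21 bone relative to tumor-free."""
    p = params.with_overrides(default_truth_overrides()["bone_adapted"])
    t = [0.0, 21.0]
    free = simulate(p, steady_state, t)[-1, 3]
    with_tumor = simulate(p, steady_state, t, events=[(0.0, "T", 1e-3)])[-1, 3]
    assert with_tumor <= free
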