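"""Shape-equation solver: equations, limits, boundary conditions, energetics."""

import numpy as np
import pytest

from conftest import cached_solution
from oracles import (el_theta_ddot, discrete_elastic_energy,
                     profile_constraints)

from phagoshape.shape_model import (MaterialParams, shape_rhs, pole_series,
                                    solve_equilibrium, free_energy,
                                    boundary_gamma_L, aspect_ratio,
                                    rim_curvature_sweep,
                                    line_tension_from_torus, torus_rim_energy,
                                    _integrate)


# ------------------------------------------------------------- the equations

def test_flat_state_is_equilibrium():
    """A flat profile has theta'' = 0 for any gamma_A (plane solution)."""
    for gA in (-5.0, 0.0, 3.0):
        _, th_dd, _, _ = shape_rhs((0.0, 0.0, 0.7, 0.0), gA)
        assert th_dd == pytest.approx(0.0, abs=1e-14)


def test_sphere_solves_shape_equation():
    """A sphere with J0 = 2/R and gamma_A = 0 satisfies the shape equation."""
    R = 0.7
    for s in (0.2, 0.5, 1.0, 1.6):
        th = s / R
        state = (th, 1.0 / R, R * np.sin(th), R * (1 - np.cos(th)))
        _, th_dd, _, _ = shape_rhs(state, 0.0, J0=2.0 / R)
        assert th_dd == pytest.approx(0.0, abs=1e-12)


def test_shape_rhs_matches_lagrangian_euler_lagrange(rng):
    """theta'' from the printed equation equals the numeric EL derivative of
    the constrained Lagrangian density at random admissible states."""
    for _ in range(30):
        th = rng.uniform(-1.2, 1.2)
        thdot = rng.uniform(-3, 3)
        x = rng.uniform(0.2, 1.5)
        gA = rng.uniform(-6, 2)
        J0 = rng.choice([0.0, 0.5])
        _, th_dd, _, _ = shape_rhs((th, thdot, x, 0.0), gA, J0=J0)
        oracle = el_theta_ddot(th, thdot, x, gA, J0=J0)
        assert th_dd == pytest.approx(oracle, abs=1e-8 * max(1.0, abs(th_dd)))


def test_augmented_system_reproduces_tan_form():
    """The gamma_x-augmented integration satisfies the tan(theta) equation
    wherever cos(theta) != 0 (the two formulations are equivalent)."""
    sol = _integrate(2.0, -4.0, dense=True)
    for s in (0.3, 0.6, 0.9):
        th, psi, x, z, gx, a = sol.sol(s)
        ds = 1e-6
        psi_p = sol.sol(s + ds)[1]
        psi_m = sol.sol(s - ds)[1]
        th_dd_num = (psi_p - psi_m) / (2 * ds)
        _, th_dd, _, _ = shape_rhs((th, psi, x, z), -4.0)
        assert th_dd_num == pytest.approx(th_dd, rel=1e-5, abs=1e-6)


# -------------------------------------------------------------- pole series

def test_pole_series_flat_and_sphere_limits():
    eps = 1e-3
    th, psi, x, z, gx, a = pole_series(0.0, eps)
    assert th == 0.0 and x == pytest.approx(eps)
    R = 0.5
    th, psi, x, z, gx, a = pole_series(1.0 / R, eps, gamma_A=0.0, J0=0.0)
    assert th == pytest.approx(eps / R, abs=eps ** 3 / R)
    # both principal curvatures at the pole equal theta_dot0
    assert psi == pytest.approx(1.0 / R, rel=1e-5)


def test_pole_offset_robustness():
    """Starting the integration at eps and eps/10 gives the same rim state."""
    outs = []
    for eps in (1e-4, 1e-5):
        sol = _integrate(2.0, -4.0, eps=eps)
        outs.append(sol.y[:4, -1])
    assert np.allclose(outs[0], outs[1], atol=1e-7)


# --------------------------------------------------------------- equilibria

def test_solve_converges_and_scales():
    sol = cached_solution(0.5)
    assert sol.converged
    assert sol.x_r == pytest.approx(0.5, abs=1e-7)
    assert sol.A == pytest.approx(2 * np.pi)
    # profile obeys the tangent constraints after rescaling
    dx = np.gradient(sol.x, sol.s_grid)
    dz = np.gradient(sol.z, sol.s_grid)
    interior = slice(10, -10)
    assert np.allclose(dx[interior], np.cos(sol.theta[interior]), atol=1e-4)
    assert np.allclose(dz[interior], np.sin(sol.theta[interior]), atol=1e-4)


def test_rim_moment_balance_holds():
    """At the rim, J_m = J0 - (1 + kG) J_p, i.e. kG = -J/J_p exactly."""
    for l in (0.7, 0.3):
        sol = cached_solution(l)
        assert sol.Jm[-1] == pytest.approx(-0.8 * sol.Jp[-1], rel=1e-6)


def test_near_flat_limit():
    """l -> 1: the cup flattens and the bending energy falls toward zero."""
    s99 = cached_solution(0.99)
    s90 = cached_solution(0.90)
    assert np.max(np.abs(s99.theta)) < 0.35
    assert s99.F_bend < s90.F_bend / 5
    assert s99.F_bend < 1.0


def test_closed_limit_gauss_bonnet():
    """l -> 0: elastic energy approaches the closed double sphere,
    F = 16 pi kb + 8 pi kG (Gauss-Bonnet)."""
    sol = cached_solution(0.02)
    target = 16 * np.pi + 8 * np.pi * (-0.2)
    assert sol.F == pytest.approx(target, rel=0.01)


def test_gamma_A_always_negative():
    """Every converged cup has negative area multiplier (growth is downhill)."""
    for l in (0.9, 0.6, 0.3, 0.1):
        assert cached_solution(l).gamma_A < 0


def test_free_energy_grid_convergence():
    fine = solve_equilibrium(0.5, MaterialParams(), n_grid=4001)
    coarse = solve_equilibrium(0.5, MaterialParams(), n_grid=2001)
    assert free_energy(fine) == pytest.approx(free_energy(coarse), rel=1e-6)


def test_stationarity_under_constrained_perturbations(rng):
    """200 random smooth perturbations of theta(s) preserving area and rim
    radius never lower the discrete elastic energy beyond tolerance."""
    from scipy.optimize import fsolve
    sol = cached_solution(0.5)
    n = 4001
    s = np.linspace(0.0, sol.s1, n)
    theta0 = np.interp(s, sol.s_grid, sol.theta)
    theta0[0] = 0.0
    A0, xr0 = profile_constraints(theta0, s)
    F0 = discrete_elastic_energy(theta0, s)
    u1 = np.sin(np.pi * s / sol.s1)
    u2 = np.sin(0.5 * np.pi * s / sol.s1)
    t = s / sol.s1
    losses = []
    for _ in range(200):
        k1, k2 = rng.integers(2, 7, size=2)
        amp = 1e-3
        d = amp * (rng.normal() * np.sin(k1 * np.pi * t)
                   + rng.normal() * np.sin((k2 - 0.5) * np.pi * t))

        def restore(ab):
            th = theta0 + d + ab[0] * u1 + ab[1] * u2
            A, xr = profile_constraints(th, s)
            return [A - A0, xr - xr0]

        ab, info, ok, _ = fsolve(restore, [0.0, 0.0], xtol=1e-12,
                                 full_output=True)
        if max(abs(r) for r in restore(ab)) > 1e-10:
            continue          # constraint restoration failed for this draw
        th = theta0 + d + ab[0] * u1 + ab[1] * u2
        losses.append(discrete_elastic_energy(th, s) - F0)
    assert len(losses) > 150
    assert min(losses) > -1e-8 * abs(F0)


# ------------------------------------------------------- boundary quantities

def test_gamma_L_matches_printed_force_balance():
    """-gamma_x(s1) equals the printed rim force-balance formula where
    cos(theta(s1)) != 0."""
    for l in (0.85, 0.6):
        sol = cached_solution(l)
        th_r = sol.theta[-1]
        assert abs(np.cos(th_r)) > 0.1
        kG = -0.2
        Jp = sol.Jp[-1]
        bracket = (1 + kG / 2) * kG * Jp ** 2 - sol.gamma_A
        gL_printed = bracket * 2 * sol.x_r / np.cos(th_r)
        assert boundary_gamma_L(sol) == pytest.approx(gL_printed, rel=1e-5)


def test_gamma_L_smooth_and_kG_trend():
    """gamma_L varies smoothly with l; at fixed l, kG increases with gamma_L."""
    gLs = [cached_solution(l).gamma_L for l in (0.9, 0.85, 0.8, 0.75, 0.7)]
    diffs = np.diff(gLs)
    assert np.all(np.abs(diffs) < 2.0)
    by_kG = [(kg, cached_solution(0.6, kappaG_ratio=kg).gamma_L)
             for kg in (-0.3, -0.2, -0.1)]
    gl = [g for _, g in by_kG]
    assert gl[0] < gl[1] < gl[2]


# -------------------------------------------------------------- sweeps/shape

def test_rim_curvature_trends_and_identity():
    table = rim_curvature_sweep([0.8, 0.6, 0.4, 0.2])
    Jp = [r["Jp"] for r in table]
    Jm = [r["Jm"] for r in table]
    assert all(np.diff(Jp) > 0)          # Jp grows as l decreases
    assert all(np.diff(Jm) < 0)          # Jm more negative as l decreases
    for r in table:
        assert -r["J"] / r["Jp"] == pytest.approx(-0.2, abs=1e-6)


def test_elongation_and_spontaneous_curvature():
    for l in (0.3, 0.4, 0.5):
        assert aspect_ratio(cached_solution(l)) > 1.0
    ratios = [aspect_ratio(cached_solution(0.4, J0=j)) for j in (0.0, 0.5, 1.0)]
    assert ratios[0] > ratios[1] > ratios[2]


def test_rim_recurvature_vanishes_with_saddle_splay():
    """|J_m(rim)| shrinks as kG/kb -> -1 and vanishes at -1."""
    for l in (0.6, 0.3):
        mags = [abs(cached_solution(l, kappaG_ratio=kg).Jm[-1])
                for kg in (0.0, -0.5, -1.0)]
        assert mags[0] > mags[1] > mags[2]
        assert mags[2] < 1e-6


# --------------------------------------------------------------- torus model

def test_torus_line_tension_closed_forms():
    assert line_tension_from_torus(0.1, 10.0).gamma_L == pytest.approx(0.0)
    r = 0.05
    assert line_tension_from_torus(r, 0.0).gamma_L == \
        pytest.approx(np.pi / (2 * r))
    with pytest.raises(ValueError):
        line_tension_from_torus(-1.0, 0.0)


def test_torus_integral_reproduces_thin_limit():
    """Exact half-torus quadrature matches gamma_L * L within 1% at l = 100 r."""
    r, Jr0 = 0.01, 20.0
    l_rim = 100 * r
    exact = torus_rim_energy(r, l_rim, Jr0)
    thin = line_tension_from_torus(r, Jr0, l_rim=l_rim).F_r
    assert exact == pytest.approx(thin, rel=0.01)
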