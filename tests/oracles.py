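"""Independent numerical oracles used by the test suite.

These deliberately avoid the algebra of the production code: curvatures come
from finite differences of the plane curve, the shape equation from
derivatives of the Lagrangian density, areas from polyline sums, and
stationarity from direct evaluation of a discretized energy functional.
"""

import numpy as np


# --------------------------------------------------- curvature by central FD

def fd_curvatures(coef, v, h=5e-5):
    """Meridional/parallel curvature of the revolved curve (f(v), v) by FD."""
    f = lambda u: np.sqrt(np.polyval(coef, u))
    fp = (f(v + h) - f(v - h)) / (2 * h)
    fpp = (f(v + h) - 2 * f(v) + f(v - h)) / h ** 2
    Jm = -fpp / (1 + fp ** 2) ** 1.5
    Jp = 1.0 / (f(v) * np.sqrt(1 + fp ** 2))
    return Jm, Jp


# ------------------------------------------------------- polyline area oracle

def polyline_area(coef, lo, hi, n=200001):
    """Doubled surface-of-revolution area from a dense polyline sum."""
    v = np.linspace(lo, hi, n)
    f = np.sqrt(np.clip(np.polyval(coef, v), 0.0, None))
    darc = np.hypot(np.diff(v), np.diff(f))
    fm = 0.5 * (f[1:] + f[:-1])
    return 4.0 * np.pi * np.sum(fm * darc)


# ------------------------------------- Euler-Lagrange oracle for the shape eq

def _lagrangian_density(th, thdot, x, gA, J0, kG, gx):
    """Integrand of the constrained action (xdot-dependent terms dropped:
    they do not enter the theta equation)."""
    u = thdot + np.sin(th) / x - J0
    return x * u ** 2 + 2.0 * kG * thdot * np.sin(th) + 2.0 * gA * x \
        - gx * np.cos(th)


def _gamma_x_from_H(th, thdot, x, gA, J0):
    """Multiplier of the xdot constraint from the vanishing Hamiltonian."""
    u = thdot + np.sin(th) / x - J0
    return (x * u ** 2 + 2.0 * gA * x - 2.0 * x * thdot * u) / np.cos(th)


def el_theta_ddot(th, thdot, x, gA, J0=0.0, kG=-0.2, h=1e-6):
    """theta'' from the Euler-Lagrange equation of the Lagrangian density.

    d/ds (dL/d thdot) = dL/d theta, expanded as
    p_th*thdot + p_thdot*thddot + p_x*cos(th) = L_th, where p = dL/d thdot.
    First derivatives use complex-step differentiation (machine precision);
    the outer derivatives of p use central differences.
    """
    gx = _gamma_x_from_H(th, thdot, x, gA, J0)
    e = 1e-30

    def p(th_, td_, x_):
        # dL/d thdot, complex step (machine precision)
        return (_lagrangian_density(th_, td_ + 1j * e, x_, gA, J0, kG, gx)
                .imag / e)

    L_th = _lagrangian_density(th + 1j * e, thdot, x, gA, J0, kG, gx).imag / e
    p_th = (p(th + h, thdot, x) - p(th - h, thdot, x)) / (2 * h)
    p_x = (p(th, thdot, x + h) - p(th, thdot, x - h)) / (2 * h)
    p_thdot = (p(th, thdot + h, x) - p(th, thdot - h, x)) / (2 * h)
    return (L_th - p_th * thdot - p_x * np.cos(th)) / p_thdot


# ------------------------------------------------ discrete energy functional

def discrete_elastic_energy(theta, s, kG=-0.2, J0=0.0):
    """Doubled-membrane elastic energy of a profile given only theta(s).

    x and z are reconstructed from the tangent-angle constraint; the
    integrand is expanded so the pole (x -> 0) stays finite.
    """
    import numpy as np
    from scipy.integrate import cumulative_trapezoid
    x = cumulative_trapezoid(np.cos(theta), s, initial=0.0)
    thdot = np.gradient(theta, s)
    sth = np.sin(theta)
    with np.errstate(divide="ignore", invalid="ignore"):
        # x*(thdot + sin/x - J0)^2 + 2 kG thdot sin
        integrand = (thdot - J0) ** 2 * x + 2.0 * (thdot - J0) * sth \
            + np.where(x > 0, sth ** 2 / np.where(x > 0, x, 1.0), 0.0) \
            + 2.0 * kG * thdot * sth
    integrand[0] = 4.0 * thdot[0] ** 2 * 0.0   # pole limit of the density is 0
    return 2.0 * np.pi * np.trapezoid(integrand, s)


def profile_constraints(theta, s):
    """(area integral, rim radius) of the profile defined by theta(s)."""
    from scipy.integrate import cumulative_trapezoid
    x = cumulative_trapezoid(np.cos(theta), s, initial=0.0)
    return np.trapezoid(x, s), x[-1]
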