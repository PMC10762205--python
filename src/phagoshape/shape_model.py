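"""Axisymmetric elastic-bending-energy (Helfrich) shape equations for open cups.

A phagophore is modeled as a single axisymmetric surface of revolution (the
closely juxtaposed inner and outer membranes counted together) with a free
circular rim.  The meridian is parametrized by arc length ``s`` from the pole
(``s=0``, on the symmetry axis) to the rim (``s=s1``); ``theta(s)`` is the
tilt angle between the tangent and the radial plane, ``x(s)`` the radial and
``z(s)`` the axial coordinate, so ``xdot = cos(theta)``, ``zdot = sin(theta)``.
The principal curvatures are ``J_m = thetadot`` (meridional) and
``J_p = sin(theta)/x`` (parallel); ``J = J_m + J_p``, ``K = J_m * J_p``.

The free energy of the doubled membrane is

    F = 2*pi * int_0^s1 [ kb*x*(J - J0)^2 + 2*kG*thetadot*sin(theta)
                          + 2*gA*x + gL*xdot ] ds

with bending modulus ``kb`` (internal unit, kb=1), Gaussian (saddle-splay)
modulus ``kG``, spontaneous curvature ``J0``, and Lagrange multipliers ``gA``
(conjugate to the fixed area A = 4*pi*int x ds) and ``gL`` (the rim line
tension, conjugate to the rim length L = 2*pi*x_r).

Stationarity gives a second-order shape equation for theta (``shape_rhs``)
plus two rim conditions: a moment balance

    thetadot - J0 + (1 + kG/kb) * sin(theta)/x = 0     at s = s1

and a force balance that determines gL.  Instead of integrating the
tan(theta) form of the shape equation (singular where theta = pi/2), the
solver integrates the equivalent regular system in which the multiplier
gamma_x conjugate to the constraint xdot = cos(theta) is kept as a dynamical
variable; the conserved Hamiltonian of the reduced problem vanishes
identically when gamma_x(0) = 0, which reproduces the tan(theta) equation
wherever cos(theta) != 0 and stays finite where it does not.  The rim force
balance then reads simply ``gL = -gamma_x(s1)``.

All solutions are reported in units where sqrt(A/(2*pi)) = 1, so the
dimensionless rim radius is l = x_r in (0, 1): l = 1 is a flat cisterna,
l -> 0 a closed sphere (stomatocyte).  Equilibria at given ``l`` are found by
shooting on the pole curvature ``theta_dot0`` and on ``gA`` with ``s1 = 1``
fixed (scale invariance), warm-started by continuation from the near-flat
limit; where several stationary families coexist the branch continued from
the flat cisterna is returned, which is also the one of minimal energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root
from scipy.special import j0 as _bessel_j0, j1 as _bessel_j1

__all__ = [
    "MaterialParams",
    "ShapeSolution",
    "RimTorus",
    "shape_rhs",
    "pole_series",
    "solve_equilibrium",
    "free_energy",
    "boundary_gamma_L",
    "line_tension_from_torus",
    "rim_curvature_sweep",
    "aspect_ratio",
    "clear_branch_cache",
]

_POLE_EPS = 1e-4
_GRID_N = 2001


@dataclass(frozen=True)
class MaterialParams:
    """Material constants of the membrane.

    kappa_b is kept only for reporting energies in kBT; all internal
    computations use kappa_b = 1.  kappaG_ratio = kappa_G / kappa_b is
    physically expected in (-1, 0) for lipid bilayers; values outside are
    accepted but flagged by consumers.
    """

    kappa_b: float = 20.0          # bending modulus, kBT
    kappaG_ratio: float = -0.2     # kappa_G / kappa_b
    J0: float = 0.0                # spontaneous curvature, 1 / sqrt(A/2pi)

    def __post_init__(self):
        if self.kappa_b <= 0:
            raise ValueError("kappa_b must be positive")

    @property
    def physical(self) -> bool:
        """Whether kappa_G/kappa_b lies in the range reported for biomembranes."""
        return -1.0 < self.kappaG_ratio < 0.0


@dataclass
class ShapeSolution:
    """A converged equilibrium profile in units where sqrt(A/2pi) = 1."""

    s_grid: np.ndarray
    theta: np.ndarray
    x: np.ndarray
    z: np.ndarray
    theta_dot: np.ndarray
    gamma_x: np.ndarray            # internal multiplier for xdot = cos(theta)
    theta_dot0: float              # pole curvature (rescaled units)
    gamma_A: float                 # kappa_b / length^2
    gamma_L: float                 # kappa_b / length (rim line tension)
    s1: float                      # rim arc length (rescaled units)
    A: float                       # total doubled-membrane area (= 2*pi)
    x_r: float                     # rim radius (= l)
    l: float                       # dimensionless rim radius
    F: float                       # elastic free energy (bending+Gaussian), kappa_b units
    F_bend: float
    F_gauss: float
    Jm: np.ndarray
    Jp: np.ndarray
    residuals: dict
    params: MaterialParams
    shoot_a1: float = 0.0          # raw shooting unknowns (s1=1 frame), for warm starts
    shoot_gA: float = 0.0
    converged: bool = True

    @property
    def J(self) -> np.ndarray:
        return self.Jm + self.Jp


@dataclass
class RimTorus:
    """Torus approximation of the rim carrying the line-tension parameters."""

    r: float                       # intermembrane (tube) radius
    l_rim: float                   # rim radius
    Jr_bar: float                  # mean rim spontaneous curvature
    gamma_L: float                 # line tension, kappa_b / length
    L: float                       # rim length = 2*pi*l_rim
    thin: bool = True              # l_rim >> r assumption satisfied

    @property
    def F_r(self) -> float:
        """Rim line energy gamma_L * L."""
        return self.gamma_L * self.L


# ----------------------------------------------------------------- equations

def shape_rhs(state, gamma_A: float, J0: float = 0.0):
    """Second derivative of theta from the tan(theta) form of the shape equation.

    ``state`` is (theta, theta_dot, x, z).  Returns the 4-tuple of
    derivatives (theta_dot, theta_ddot, cos(theta), sin(theta)).  This is the
    textbook Euler-Lagrange reduction; it is singular at theta = +-pi/2, so
    the solver itself uses the augmented regular system (`_rhs_augmented`),
    which agrees with this expression wherever cos(theta) != 0.
    """
    th, psi, x, _z = state
    t = math.tan(th)
    u = math.sin(th) / x - J0
    th_dd = (-0.5 * t * psi ** 2 - psi * math.cos(th) / x
             + math.sin(2 * th) / (2 * x ** 2) + gamma_A * t + 0.5 * t * u ** 2)
    return (psi, th_dd, math.cos(th), math.sin(th))


def _rhs_augmented(s, y, gA, J0):
    """Regular first-order system: y = (theta, psi, x, z, gamma_x, a).

    a' = x accumulates the area integral (A = 4*pi*a).  Valid for x > 0;
    the pole is entered through `pole_series`.
    """
    th, psi, x, z, gx, a = y
    sth = np.sin(th)
    cth = np.cos(th)
    u = psi + sth / x - J0
    dpsi = (0.5 * gx * sth - psi * cth + sth * cth / x) / x
    dgx = u * u - 2.0 * (sth / x) * u + 2.0 * gA
    return [psi, dpsi, cth, sth, dgx, x]


def pole_series(theta_dot0: float, epsilon: float, gamma_A: float = 0.0,
                J0: float = 0.0):
    """Series start of the regular solution at the pole.

    Near s = 0 the regular solution has theta = a1*s + a3*s^3 + O(s^5) with
    a1 = theta_dot0 and 16*a3 = a1*(2*gamma_A - J0*(2*a1 - J0)); both
    principal curvatures equal theta_dot0 at the pole.  Returns the full
    augmented state (theta, psi, x, z, gamma_x, a) at s = epsilon.
    """
    a1 = theta_dot0
    g1 = 2.0 * gamma_A - J0 * (2.0 * a1 - J0)
    a3 = a1 * g1 / 16.0
    e = epsilon
    return [a1 * e + a3 * e ** 3,
            a1 + 3.0 * a3 * e ** 2,
            e - a1 ** 2 * e ** 3 / 6.0,
            0.5 * a1 * e ** 2,
            g1 * e,
            0.5 * e ** 2]


def _integrate(a1, gA, J0=0.0, s1=1.0, rtol=1e-9, dense=False,
               eps=_POLE_EPS):
    y0 = pole_series(a1, eps * s1, gamma_A=gA, J0=J0)
    sol = solve_ivp(_rhs_augmented, (eps * s1, s1), y0, args=(gA, J0),
                    method="RK45", rtol=rtol, atol=rtol * 1e-2,
                    dense_output=dense)
    if (not sol.success) or sol.y[2, -1] <= 1e-8 or np.any(sol.y[2] <= 0):
        return None
    return sol


def _rim_state(a1, gA, kG, J0, s1=1.0, rtol=1e-9, dense=False):
    sol = _integrate(a1, gA, J0=J0, s1=s1, rtol=rtol, dense=dense)
    if sol is None:
        return None
    th, psi, x, z, gx, a = sol.y[:, -1]
    bc = psi - J0 + (1.0 + kG) * np.sin(th) / x
    l = x / np.sqrt(2.0 * a)
    return dict(sol=sol, bc=bc, l=l, th=th, psi=psi, x=x, z=z, gx=gx, a=a,
                gA=gA, J0=J0)


class ShootingError(RuntimeError):
    """Raised when the two-parameter shooting fails to converge."""

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals


# ------------------------------------------------------- branch continuation

# cache: (kG, J0) -> list of (l, a1, gA) sorted by decreasing l
_BRANCH_CACHE: dict = {}


def clear_branch_cache():
    _BRANCH_CACHE.clear()


def _flat_bifurcation_mu(kG):
    """First bifurcation of cup solutions off the flat disk: mu*J0(mu)+kG*J1(mu)=0."""
    return brentq(lambda m: m * _bessel_j0(m) + kG * _bessel_j1(m), 1.2, 3.8)


def _shoot_pair(p, l_target, kG, J0, rtol=1e-9):
    st = _rim_state(abs(p[0]), p[1], kG, J0, rtol=rtol)
    if st is None:
        return [10.0, 10.0]
    return [st["bc"], st["l"] - l_target]


def _refine(l_target, guess, kG, J0, rtol=1e-9):
    res = root(_shoot_pair, guess, args=(l_target, kG, J0, rtol),
               method="hybr", options={"xtol": 1e-12})
    p = res.x
    st = _rim_state(abs(p[0]), p[1], kG, J0, rtol=rtol)
    if st is None or abs(st["bc"]) > 1e-7 or abs(st["l"] - l_target) > 1e-7:
        raise ShootingError(
            f"shooting did not converge at l={l_target} (kG={kG}, J0={J0})",
            residuals=None if st is None else (st["bc"], st["l"] - l_target))
    return (abs(p[0]), p[1]), st


def _branch(kG, J0):
    return _BRANCH_CACHE.setdefault((round(kG, 9), round(J0, 9)), [])


def _extend_branch_to(l_target, kG, J0=0.0):
    """March the principal branch (continued from the flat disk) down to l_target.

    Returns the cached branch list.  Steps of 0.04 in l with linear
    extrapolation warm starts; steps are halved on failure.
    """
    br = _branch(kG, J0)
    if not br:
        if J0 == 0.0:
            mu = _flat_bifurcation_mu(kG)
            l0 = 0.99
            guess = (0.25, -mu ** 2)
            (a1, gA), _ = _refine(l0, guess, kG, J0)
            br.append((l0, a1, gA))
        else:
            # reach the J0 != 0 branch by continuation in J0 at fixed l
            base = _extend_branch_to(l_target, kG, 0.0)
            l0 = l_target
            a1, gA = _interp_guess(base, l0)
            steps = max(2, int(abs(J0) / 0.2) + 1)
            for J in np.linspace(0.0, J0, steps + 1)[1:]:
                (a1, gA), _ = _refine(l0, (a1, gA), kG, J)
            br.append((l0, a1, gA))
            return br
    while br[-1][0] > l_target + 1e-12:
        l_prev, a1, gA = br[-1]
        dl = min(0.04, l_prev - l_target)
        while True:
            l_next = l_prev - dl
            if len(br) >= 2:
                l2, a12, gA2 = br[-2]
                w = (l_next - l_prev) / (l_prev - l2) if l_prev != l2 else 0.0
                guess = (a1 + w * (a1 - a12), gA + w * (gA - gA2))
            else:
                guess = (a1, gA)
            try:
                (a1n, gAn), _ = _refine(l_next, guess, kG, J0)
                br.append((l_next, a1n, gAn))
                break
            except ShootingError:
                dl /= 2.0
                if dl < 1e-4:
                    raise
    return br


def _interp_guess(branch, l_target):
    ls = np.array([b[0] for b in branch])
    order = np.argsort(ls)
    a1 = np.interp(l_target, ls[order], np.array([b[1] for b in branch])[order])
    gA = np.interp(l_target, ls[order], np.array([b[2] for b in branch])[order])
    return a1, gA


# ------------------------------------------------------------------- solving

def solve_equilibrium(l_target: float, params: MaterialParams | None = None,
                      n_grid: int = _GRID_N) -> ShapeSolution:
    """Equilibrium cup shape at dimensionless rim radius ``l_target``.

    Shooting on (theta_dot0, gamma_A) with s1 = 1 fixed, warm-started by
    continuation from the near-flat limit, then rescaled so that
    sqrt(A/2pi) = 1.  Raises ShootingError on non-convergence.
    """
    params = params or MaterialParams()
    if not 0.0 < l_target < 1.0:
        raise ValueError("l_target must lie in (0, 1)")
    kG, J0 = params.kappaG_ratio, params.J0
    br = _extend_branch_to(l_target, kG, J0)
    guess = _interp_guess(br, l_target)
    (a1, gA), _ = _refine(l_target, guess, kG, J0, rtol=1e-10)
    return _build_solution(a1, gA, params, n_grid=n_grid)


def _build_solution(a1, gA, params, n_grid=_GRID_N, rtol=1e-10):
    kG, J0 = params.kappaG_ratio, params.J0
    st = _rim_state(a1, gA, kG, J0, rtol=rtol, dense=True)
    s = np.linspace(_POLE_EPS, 1.0, n_grid)
    th, psi, x, z, gx, a = st["sol"].sol(s)
    lam = 1.0 / np.sqrt(2.0 * a[-1])     # rescale so sqrt(A/2pi) = 1
    Jm = psi / lam
    Jp = np.sin(th) / (x * lam)
    Fb = 2.0 * np.pi * np.trapezoid(x * lam * ((Jm + Jp - J0 / 1.0) ** 2), s * lam)
    # note: J0 is specified in rescaled units, consistent with Jm, Jp above
    Fg = 2.0 * np.pi * np.trapezoid(2.0 * kG * Jm * np.sin(th), s * lam)
    l = st["l"]
    sol = ShapeSolution(
        s_grid=s * lam, theta=th, x=x * lam, z=z * lam, theta_dot=Jm,
        gamma_x=gx / lam, theta_dot0=a1 / lam, gamma_A=gA / lam ** 2,
        gamma_L=-gx[-1] / lam, s1=lam, A=2.0 * np.pi, x_r=l, l=l,
        F=Fb + Fg, F_bend=Fb, F_gauss=Fg, Jm=Jm, Jp=Jp,
        residuals={"rim_bc": st["bc"],
                   "hamiltonian": _hamiltonian_residual(st)},
        params=params, shoot_a1=a1, shoot_gA=gA, converged=True)
    return sol


def _hamiltonian_residual(st):
    """|H| at the rim (solver frame); H vanishes identically on the branch."""
    th, psi, x, gx = st["th"], st["psi"], st["x"], st["gx"]
    gA, J0 = st["gA"], st["J0"]
    u = psi + np.sin(th) / x - J0
    H = 2.0 * x * psi * u + np.cos(th) * gx - x * u * u - 2.0 * gA * x
    return abs(float(H))


def free_energy(solution: ShapeSolution, params: MaterialParams | None = None,
                include_constraints: bool = False, in_kBT: bool = False) -> float:
    """Elastic free energy of a converged profile by quadrature on its grid.

    The canonical doubled-membrane form is used: bending
    2*pi*int kb*x*(J-J0)^2 ds plus Gaussian 2*pi*int 2*kG*Jm*sin(theta) ds.
    With ``include_constraints`` the multiplier terms gamma_A*A + gamma_L*L
    are added.  Energies are in kappa_b units unless ``in_kBT``.
    """
    params = params or solution.params
    s, x, th = solution.s_grid, solution.x, solution.theta
    J0, kG = params.J0, params.kappaG_ratio
    J = solution.Jm + solution.Jp
    F = 2.0 * np.pi * np.trapezoid(x * (J - J0) ** 2
                                   + 2.0 * kG * solution.Jm * np.sin(th), s)
    if include_constraints:
        F += solution.gamma_A * solution.A + solution.gamma_L * 2.0 * np.pi * solution.x_r
    return F * params.kappa_b if in_kBT else F


def boundary_gamma_L(solution: ShapeSolution,
                     params: MaterialParams | None = None) -> float:
    """Rim line tension gamma_L from the force balance at s = s1.

    Computed as -gamma_x(s1), the regular form of the rim boundary condition;
    equivalent to the printed force-balance formula

        (1 + kG/2)*kG*Jp^2 - kG*J0*Jp - gA - (gL/2)*cos(theta)/x = 0

    wherever cos(theta(s1)) != 0 (tested), and finite where it is not.
    """
    return -solution.gamma_x[-1]


def aspect_ratio(solution: ShapeSolution) -> float:
    """Axial extent over twice the maximal radial extent (sphere -> 1)."""
    return float(np.ptp(solution.z) / (2.0 * solution.x.max()))


def rim_curvature_sweep(l_values, params: MaterialParams | None = None):
    """Rim curvatures along the principal continuation branch.

    Returns a list of dicts with keys l, Jm, Jp, J, gamma_A, gamma_L, F,
    theta_dot0, aspect.  l_values are visited from largest to smallest so the
    continuation warm starts stay on one branch.
    """
    params = params or MaterialParams()
    out = []
    for l in sorted(l_values, reverse=True):
        sol = solve_equilibrium(l, params)
        out.append(dict(l=l, Jm=sol.Jm[-1], Jp=sol.Jp[-1],
                        J=sol.Jm[-1] + sol.Jp[-1], gamma_A=sol.gamma_A,
                        gamma_L=sol.gamma_L, F=sol.F,
                        theta_dot0=sol.theta_dot0, aspect=aspect_ratio(sol)))
    return out


# ------------------------------------------------------------------ rim torus

def line_tension_from_torus(r: float, Jr_bar: float,
                            l_rim: float = 1.0, kappa_b: float = 1.0) -> RimTorus:
    """Line tension of the rim modeled as a thin half-torus.

    In the thin-rim limit (l_rim >> r) the rim bending energy
    (kb/2) * int (Jr - Jr0)^2 dA_r over the half-torus reduces to a line
    energy gamma_L * L with

        gamma_L = (kb/2) * pi * r * (1/r - Jr_bar)^2 ,   L = 2*pi*l_rim.
    """
    if r <= 0:
        raise ValueError("intermembrane radius r must be positive")
    gL = 0.5 * kappa_b * math.pi * r * (1.0 / r - Jr_bar) ** 2
    return RimTorus(r=r, l_rim=l_rim, Jr_bar=Jr_bar, gamma_L=gL,
                    L=2.0 * math.pi * l_rim, thin=l_rim >= 10.0 * r)


def torus_rim_energy(r: float, l_rim: float, Jr0: float, theta: float = math.pi / 2,
                     kappa_b: float = 1.0, n: int = 20001) -> float:
    """Exact half-torus bending energy by quadrature (oracle for the thin limit).

    F_r = (kb/2) * int (Jr - Jr0)^2 dA_r over phi in [theta-pi/2, theta+pi/2]
    with Jr = 1/r + cos(phi)/(l + r*cos(phi)) and dA_r = 2*pi*r*(l+r*cos(phi)) dphi.
    """
    phi = np.linspace(theta - math.pi / 2, theta + math.pi / 2, n)
    Jr = 1.0 / r + np.cos(phi) / (l_rim + r * np.cos(phi))
    dA = 2.0 * math.pi * r * (l_rim + r * np.cos(phi))
    return 0.5 * kappa_b * np.trapezoid((Jr - Jr0) ** 2 * dA, phi)
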