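"""Axisymmetric polynomial profile fits, curvatures, area and Gaussian modulus.

The average shape of a stage is summarized by fitting the squared radius of
the projected (radial, axial) point cloud with a cubic in the axial
coordinate,

    r^2 = a*z^3 + b*z^2 + c*z + d,

an ordinary linear least-squares problem.  The surface of revolution
(f(v) cos u, f(v) sin u, v) with f = sqrt(cubic) then yields the meridional
and parallel curvatures

    J_m = -f'' / (1 + f'^2)^(3/2),    J_p = 1 / (f * sqrt(1 + f'^2)),

and the doubled-membrane area A = 4*pi * int f * sqrt(1 + f'^2) dv.

The Gaussian (saddle-splay) modulus is estimated from the moment balance at
the free rim: an open edge carries no external torque, so the meridional
bending moment M_m = kb*J + kG*J_p must vanish there, giving
kG/kb = -J/J_p evaluated at the rim.  Because the exact ratio -J/J_p varies
steeply across the rim boundary layer (it is -0.20 at the rim and already
about -0.25 one percent of arc inside, for a kG = -0.2*kb equilibrium), the
estimator fits the same cubic family to the rim neighbourhood of the profile
(default: the top 5% of the axial extent) and evaluates the ratio at the rim
itself.  A global fit of the whole profile is available too, but it smooths
the boundary layer away and is biased toward more negative ratios; this bias
is quantified in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

__all__ = [
    "PolyProfile",
    "CurvatureSample",
    "GaussianModulusEstimate",
    "fit_profile",
    "curvatures",
    "membrane_area",
    "estimate_gaussian_modulus",
    "gaussian_modulus_from_points",
    "rim_meridional_curvature",
]


@dataclass
class PolyProfile:
    """Fitted profile r^2 = a z^3 + b z^2 + c z + d with its validity domain."""

    a: float
    b: float
    c: float
    d: float
    z_domain: tuple          # maximal interval containing the data with r^2 >= 0
    stderr: tuple            # OLS standard errors of (a, b, c, d)
    z_rim: float             # rim axial position
    n_points: int = 0
    rss: float = 0.0

    @property
    def coefficients(self):
        return np.array([self.a, self.b, self.c, self.d])

    def __call__(self, z):
        """Squared radius at axial position z."""
        return np.polyval(self.coefficients, z)

    def radius(self, z):
        return np.sqrt(np.clip(self(z), 0.0, None))


@dataclass(frozen=True)
class CurvatureSample:
    v: float
    J_m: float
    J_p: float

    @property
    def J(self) -> float:
        return self.J_m + self.J_p


@dataclass(frozen=True)
class GaussianModulusEstimate:
    kappaG_ratio: float
    v_eval: float
    M_m_residual: float      # kb*J + kG*J_p at the estimate (0 by construction)
    in_range: bool           # within the biomembrane range (-1, 0)


class FitError(ValueError):
    pass


def fit_profile(points2d, z_rim: float | None = None) -> PolyProfile:
    """Ordinary least squares of squared radius on (z^3, z^2, z, 1).

    ``points2d`` is an (n, 2) array of (radial, axial) pairs, n >= 10 with at
    least 3 distinct axial values.  Coefficient standard errors come from the
    least-squares covariance.  ``z_rim`` defaults to the maximal axial value
    (use the mean axial coordinate of edge-flagged points when available).
    """
    pts = np.asarray(points2d, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise FitError("points2d must be an (n, 2) array of (radial, axial)")
    if len(pts) < 10:
        raise FitError("need at least 10 points")
    r, z = pts[:, 0], pts[:, 1]
    if len(np.unique(np.round(z, 12))) < 3:
        raise FitError("need at least 3 distinct axial values (rank-deficient)")
    X = np.vander(z, 4)
    y = r ** 2
    coef, rss_arr, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 4:
        # nearly collinear axial values: fall back to pinv but report it
        coef = np.linalg.pinv(X) @ y
    resid = y - X @ coef
    rss = float(resid @ resid)
    dof = max(len(pts) - 4, 1)
    try:
        cov = np.linalg.inv(X.T @ X) * rss / dof
        se = tuple(np.sqrt(np.clip(np.diag(cov), 0.0, None)))
    except np.linalg.LinAlgError:
        se = (np.nan,) * 4
    dom = _positivity_domain(coef, z.min(), z.max())
    if z_rim is None:
        z_rim = float(z.max())
    return PolyProfile(a=coef[0], b=coef[1], c=coef[2], d=coef[3],
                       z_domain=dom, stderr=se, z_rim=z_rim,
                       n_points=len(pts), rss=rss)


def _positivity_domain(coef, z_lo, z_hi):
    """Maximal interval containing the data midpoint on which the cubic >= 0."""
    mid = 0.5 * (z_lo + z_hi)
    if np.polyval(coef, mid) < 0 and np.polyval(coef, z_lo) < 0 \
            and np.polyval(coef, z_hi) < 0:
        raise FitError("fitted cubic is negative over the data range")
    # drop numerically-zero leading coefficients so a fitted cylinder or
    # paraboloid does not acquire spurious far-away roots
    trimmed = np.array(coef, float)
    scale = np.max(np.abs(trimmed))
    while len(trimmed) > 1 and abs(trimmed[0]) < 1e-10 * scale:
        trimmed = trimmed[1:]
    roots = np.roots(trimmed) if len(trimmed) > 1 else np.array([])
    roots = np.sort(roots[np.abs(roots.imag) < 1e-9].real)
    anchor = mid if np.polyval(coef, mid) >= 0 else \
        (z_lo if np.polyval(coef, z_lo) >= 0 else z_hi)
    lo = max([r for r in roots if r <= anchor], default=-np.inf)
    hi = min([r for r in roots if r >= anchor], default=np.inf)
    # unbounded positivity (e.g. a cylinder) is truncated at the data range
    return (float(lo) if np.isfinite(lo) else float(z_lo),
            float(hi) if np.isfinite(hi) else float(z_hi))


def _f_derivatives(coef, v):
    g = np.polyval(coef, v)
    if np.any(np.asarray(g) <= 0):
        raise FitError(f"profile radius vanishes at v={v} (pole of J_p)")
    a, b, c, _d = coef
    gp = 3 * a * v ** 2 + 2 * b * v + c
    gpp = 6 * a * v + 2 * b
    f = np.sqrt(g)
    fp = gp / (2.0 * f)
    fpp = (2.0 * g * gpp - gp ** 2) / (4.0 * g ** 1.5)
    return f, fp, fpp


def curvatures(profile: PolyProfile, v: float) -> CurvatureSample:
    """Meridional and parallel curvature of the fitted surface at z = v."""
    f, fp, fpp = _f_derivatives(profile.coefficients, v)
    Jm = -fpp / (1.0 + fp ** 2) ** 1.5
    Jp = 1.0 / (f * np.sqrt(1.0 + fp ** 2))
    return CurvatureSample(v=float(v), J_m=float(Jm), J_p=float(Jp))


def membrane_area(profile: PolyProfile) -> float:
    """Doubled-membrane area 4*pi * int f sqrt(1 + f'^2) dv over z_domain.

    The integrand stays finite where f -> 0 (it tends to |g'|/2), but its
    derivative blows up there; adaptive quadrature with the domain endpoints
    as break points handles it.
    """
    lo, hi = profile.z_domain
    coef = profile.coefficients

    def integrand(v):
        g = np.polyval(coef, v)
        if g <= 0:
            gp = np.polyval(np.polyder(coef), v)
            return abs(gp) / 2.0
        f, fp, _ = _f_derivatives(coef, v)
        return f * np.sqrt(1.0 + fp ** 2)

    val, err = quad(integrand, lo, hi, limit=200)
    if not np.isfinite(val) or (val > 0 and err / val > 1e-6):
        raise FitError(f"area quadrature did not converge (err={err:g})")
    return 4.0 * np.pi * val


def estimate_gaussian_modulus(profile: PolyProfile,
                              v_eval: float | None = None) -> GaussianModulusEstimate:
    """kappa_G/kappa_b = -J/J_p from the rim moment balance M_m = 0.

    Evaluated at the rim itself (``z_rim``) whenever the fitted radius is
    positive there; if f(z_rim) = 0 (the cubic closes exactly at the rim) the
    evaluation point is moved inward by small steps until the radius is
    positive.  Out-of-range estimates are flagged, never clipped.
    """
    if v_eval is None:
        v_eval = profile.z_rim
        span = profile.z_domain[1] - profile.z_domain[0]
        step = 1e-3 * span
        for _ in range(100):
            if np.polyval(profile.coefficients, v_eval) > 0:
                break
            v_eval -= step
        else:
            raise FitError("could not find a positive-radius point near the rim")
    cs = curvatures(profile, v_eval)
    if cs.J_p <= 0:
        raise FitError(f"J_p <= 0 at v={v_eval}; moment balance undefined")
    ratio = -cs.J / cs.J_p
    return GaussianModulusEstimate(kappaG_ratio=float(ratio),
                                   v_eval=float(v_eval),
                                   M_m_residual=float(cs.J + ratio * cs.J_p),
                                   in_range=-1.0 < ratio < 0.0)


def gaussian_modulus_from_points(points2d, z_rim: float | None = None,
                                 window: float = 0.05) -> GaussianModulusEstimate:
    """Rim-local Gaussian-modulus estimate from a projected point cloud.

    Fits the cubic family to the points whose axial coordinate lies within
    ``window`` times the axial extent below ``z_rim`` (default: the maximal
    axial value), then applies the moment balance at the rim.  The local fit
    resolves the rim boundary layer that a whole-shape fit smooths away.
    """
    pts = np.asarray(points2d, float)
    z = pts[:, 1]
    if z_rim is None:
        z_rim = float(z.max())
    span = float(z.max() - z.min())
    mask = z >= z_rim - window * span
    if mask.sum() < 10:
        # widen until enough points support the cubic
        for w in (2, 3, 4, 6, 8):
            mask = z >= z_rim - w * window * span
            if mask.sum() >= 10:
                break
    prof = fit_profile(pts[mask], z_rim=z_rim)
    return estimate_gaussian_modulus(prof)


def rim_meridional_curvature(profile: PolyProfile,
                             v_eval: float | None = None) -> float:
    """J_m near the rim; negative values indicate outward recurvature."""
    if v_eval is None:
        v_eval = profile.z_rim
        span = profile.z_domain[1] - profile.z_domain[0]
        while np.polyval(profile.coefficients, v_eval) <= 0:
            v_eval -= 1e-3 * span
    return curvatures(profile, v_eval).J_m
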