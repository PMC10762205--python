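"""Theory-experiment comparison in the common normalized frame.

The experimental morphometry normalizes every point cloud to zero centroid
and unit RMS spread; theoretical equilibrium shapes are put through the same
normalization before being compared (overlay of the meridian over pooled
projected point clouds, sigma_e <-> l mapping, relative profile error).

The normalization moments of a theoretical surface of revolution are
computed by deterministic quadrature along the meridian rather than by point
sampling, so the sigma_e <-> l mapping carries no Monte-Carlo jitter.  Two
measures are supported:

``meridian`` (default)
    every arc-length element of the profile carries equal weight, i.e. the
    point cloud is built by revolving an evenly spaced profile polyline with
    the same number of points on every ring.  This is the measure that
    reproduces the published mapping (a near-flat cup at l = 0.8 has
    sigma_e = 1.46 > sqrt(2), which no area-uniform cloud can reach).
``area``
    weight proportional to the ring circumference, i.e. points distributed
    uniformly over the surface area, the convention of the experimental
    clouds themselves (and of the synthetic generator).

The rim circle is a one-dimensional set of measure zero and is excluded from
the moments, matching experimental clouds where edge points are a vanishing
fraction.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from .shape_model import MaterialParams, ShapeSolution, solve_equilibrium
from .profile_fit import PolyProfile

__all__ = [
    "normalization_moments",
    "sigma_e_of_solution",
    "l_of_sigma_e",
    "relative_error",
    "overlay_report",
    "sample_solution_cloud",
]


def normalization_moments(x, z, measure: str = "meridian"):
    """Centroid height and RMS spread of a surface of revolution.

    The surface is the revolution of the meridian polyline (x(s), z(s));
    by symmetry the centroid lies on the axis at height
    zbar = int z w ds / int w ds and the spread is
    sigma^2 = int (x^2 + (z - zbar)^2) w ds / int w ds,
    with w = 1 ("meridian" measure) or w = x ("area" measure).
    """
    x = np.asarray(x, float)
    z = np.asarray(z, float)
    s = np.concatenate([[0.0], np.cumsum(np.hypot(np.diff(x), np.diff(z)))])
    if measure == "meridian":
        w = np.ones_like(x)
    elif measure == "area":
        w = x
    else:
        raise ValueError(f"unknown measure {measure!r}")
    W = np.trapezoid(w, s)
    zbar = np.trapezoid(z * w, s) / W
    var = np.trapezoid((x ** 2 + (z - zbar) ** 2) * w, s) / W
    return float(zbar), float(np.sqrt(var))


def sigma_e_of_solution(solution: ShapeSolution, measure: str = "meridian") -> float:
    """Normalized rim size sigma_e of an equilibrium shape.

    After normalizing the surface to zero centroid and unit RMS spread, the
    rim circle sits at radius x_r / sigma; the RMS deviation of the rim
    points from their own mean is exactly that radius, so
    sigma_e = x_r / sigma.
    """
    if not solution.converged:
        raise ValueError("sigma_e requires a converged solution")
    _, sigma = normalization_moments(solution.x, solution.z, measure=measure)
    return float(solution.x_r / sigma)


def l_of_sigma_e(sigma_e_target: float, params: MaterialParams | None = None,
                 bracket=(0.02, 0.9), tol: float = 1e-6,
                 measure: str = "meridian") -> float:
    """Invert the sigma_e(l) mapping along the principal branch.

    Bracketed 1D root search; raises if the target is outside the attainable
    range of the bracket (sigma_e(l) is monotone on l in (0, ~0.85) and folds
    over near the flat limit, where the mapping is reported as multi-valued).
    """
    params = params or MaterialParams()

    def f(l):
        return sigma_e_of_solution(solve_equilibrium(l, params), measure) \
            - sigma_e_target

    lo, hi = bracket
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise ValueError(
            f"sigma_e={sigma_e_target} not bracketed on l in {bracket}: "
            f"attainable range [{sigma_e_target + flo:.3f}, "
            f"{sigma_e_target + fhi:.3f}]")
    return brentq(f, lo, hi, xtol=tol)


def _profile_radius_interp(solution: ShapeSolution, sigma: float, zbar: float):
    """Normalized-frame radius r(z) of a solution meridian (z must be monotone)."""
    zn = (solution.z - zbar) / sigma
    rn = solution.x / sigma
    return zn, rn


def relative_error(theory: ShapeSolution, experiment: PolyProfile,
                   n: int = 400, measure: str = "meridian") -> float:
    """Mean absolute radial deviation between theory and fitted profile, percent.

    Both curves are taken in the normalized frame (unit RMS spread); the
    deviation |r_theory(z) - r_fit(z)| is averaged over the overlapping axial
    range and reported as a percentage of the normalized length unit.
    """
    zbar, sigma = normalization_moments(theory.x, theory.z, measure=measure)
    zt, rt = _profile_radius_interp(theory, sigma, zbar)
    lo = max(zt.min(), experiment.z_domain[0])
    hi = min(zt.max(), experiment.z_domain[1])
    if hi <= lo:
        raise ValueError("theory and experiment have disjoint axial ranges")
    zz = np.linspace(lo, hi, n)
    r_th = np.interp(zz, zt, rt)
    r2 = experiment(zz)
    r_exp = np.sqrt(np.clip(r2, 0.0, None))
    return float(np.mean(np.abs(r_th - r_exp)) * 100.0)


def sample_solution_cloud(solution: ShapeSolution, n: int, rng,
                          measure: str = "meridian"):
    """Seeded point-cloud sampling of a solution surface (cross-check path)."""
    s = solution.s_grid
    if measure == "meridian":
        w = np.ones_like(solution.x)
    else:
        w = solution.x
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (w[1:] + w[:-1]) * np.diff(s))])
    cdf /= cdf[-1]
    u = rng.random(n)
    si = np.interp(u, cdf, s)
    r = np.interp(si, s, solution.x)
    z = np.interp(si, s, solution.z)
    phi = rng.random(n) * 2.0 * np.pi
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def overlay_report(stage_label: str, pooled_points2d, theory: ShapeSolution,
                   n_bins: int = 20, measure: str = "meridian",
                   figure_path=None):
    """Residuals of pooled projected points against the theory meridian.

    ``pooled_points2d`` are (radial, axial) pairs in the normalized frame.
    Returns a dict with per-axial-bin mean and SD of the radial residual
    (points minus theory) and overall summaries; optionally writes an
    overlay figure.
    """
    pts = np.asarray(pooled_points2d, float)
    zbar, sigma = normalization_moments(theory.x, theory.z, measure=measure)
    zt, rt = _profile_radius_interp(theory, sigma, zbar)
    lo, hi = zt.min(), zt.max()
    z = np.clip(pts[:, 1], lo, hi)
    resid = pts[:, 0] - np.interp(z, zt, rt)
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(z, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        m = idx == b
        rows.append(dict(z_lo=edges[b], z_hi=edges[b + 1], n=int(m.sum()),
                         mean=float(resid[m].mean()) if m.any() else np.nan,
                         sd=float(resid[m].std()) if m.any() else np.nan))
    report = dict(stage=stage_label, n_points=len(pts),
                  resid_mean=float(resid.mean()), resid_sd=float(resid.std()),
                  bins=rows)
    if figure_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.plot(pts[:, 0], pts[:, 1], ".", ms=1, color="crimson", alpha=0.4)
        ax.plot(rt, zt, "k-", lw=1.5)
        ax.plot(-rt, zt, "k-", lw=1.5)
        ax.plot(-pts[:, 0], pts[:, 1], ".", ms=1, color="crimson", alpha=0.4)
        ax.set_aspect("equal")
        ax.set_xlabel("radial (normalized)")
        ax.set_ylabel("axial (normalized)")
        ax.set_title(f"{stage_label}: theory over pooled cloud")
        fig.savefig(figure_path, dpi=120)
        plt.close(fig)
    return report
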