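"""Seeded synthetic serial-section point clouds with known ground truth.

The generator emulates array-tomography acquisition of a segmented
phagophore: an axisymmetric cup surface (either a solved equilibrium shape
or a parametric spherical cap) of known size and orientation is sampled
uniformly by surface area, sectioned at a fixed slice spacing along the lab
stack axis, optionally compressed along that axis (the embedding/sectioning
artifact), and perturbed by in-plane Gaussian segmentation noise.  Edge
points stand in for the manual rim annotation of real segmentations: by
default two contour endpoints per section, placed on the rim circle.

Every structure is reproducible from its integer seed, and ships with the
ground truth (orientation, normalized rim size, generating meridian, scale)
that the morphometry stages are expected to recover.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .morphometry import PhagophoreCloud, apply_z_compression
from .shape_model import ShapeSolution

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "MeridianProfile",
    "spherical_cap",
    "meridian_of_solution",
    "cap_angle_for_sigma_e",
    "generate_structure",
    "apply_z_compression",
]


@dataclass
class MeridianProfile:
    """Generating meridian (r(s), z(s)) of a surface of revolution, unit scale."""

    s: np.ndarray
    r: np.ndarray
    z: np.ndarray

    def __post_init__(self):
        self.s = np.asarray(self.s, float)
        self.r = np.asarray(self.r, float)
        self.z = np.asarray(self.z, float)

    @property
    def arc_length(self) -> float:
        return float(self.s[-1] - self.s[0])

    def sigma_e(self, measure: str = "area") -> float:
        """Normalized rim size of the surface under the given sampling measure."""
        w = self.r if measure == "area" else np.ones_like(self.r)
        W = np.trapezoid(w, self.s)
        zbar = np.trapezoid(self.z * w, self.s) / W
        var = np.trapezoid((self.r ** 2 + (self.z - zbar) ** 2) * w, self.s) / W
        return float(self.r[-1] / np.sqrt(var))


def spherical_cap(cap_angle: float, radius: float = 1.0,
                  n: int = 2001) -> MeridianProfile:
    """Spherical cap of half-opening angle ``cap_angle`` (rim at t = cap_angle).

    Its squared radius is exactly quadratic in the axial coordinate
    (r^2 = R^2 - (z - R)^2), which makes cap-generated clouds a closed-form
    target for the polynomial profile fit.
    """
    if not 0 < cap_angle < np.pi:
        raise ValueError("cap_angle must lie in (0, pi)")
    t = np.linspace(0.0, cap_angle, n)
    return MeridianProfile(s=radius * t, r=radius * np.sin(t),
                           z=radius * (1.0 - np.cos(t)))


def cap_angle_for_sigma_e(sigma_e: float) -> float:
    """Cap angle whose area-measure sigma_e equals the target (closed form).

    For a cap of half-angle alpha, sigma_e = sin(alpha)/sqrt(1 - m^2) with
    m = (1 + cos(alpha))/2; monotone decreasing from sqrt(2) (flat) to
    0 (full sphere), inverted by bisection.
    """
    if not 0 < sigma_e < np.sqrt(2.0):
        raise ValueError("attainable cap sigma_e lies in (0, sqrt(2))")
    from scipy.optimize import brentq

    def f(al):
        m = (1.0 + np.cos(al)) / 2.0
        return np.sin(al) / np.sqrt(1.0 - m ** 2) - sigma_e

    return brentq(f, 1e-6, np.pi - 1e-9)


def meridian_of_solution(solution: ShapeSolution) -> MeridianProfile:
    if not solution.converged:
        raise ValueError("profile source solution is not converged")
    return MeridianProfile(s=solution.s_grid, r=solution.x, z=solution.z)


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic serial-section structure.

    Defaults emulate the study conditions: 300-600 points per structure,
    25 nm section thickness, low-nanometre in-plane segmentation noise.
    """

    profile_source: MeridianProfile | ShapeSolution
    scale: float = 500.0             # nm per unit of the meridian profile
    orientation: tuple = (0.0, 0.0)  # polar, azimuth of the cup axis (rad)
    section_spacing: float = 25.0    # nm
    points_per_structure: int = 450
    noise_sd: float = 2.0            # nm, isotropic in-plane Gaussian
    z_compression: float = 1.0       # multiplicative, along the stack axis
    edge_band: float = 0.03          # arc-length fraction near the rim ("band" mode)
    edge_mode: str = "paired"        # "paired": 2 contour endpoints per section
    seed: int = 0
    structure_id: str = ""

    def __post_init__(self):
        if self.section_spacing <= 0:
            raise ValueError("section_spacing must be positive")
        if self.z_compression <= 0:
            raise ValueError("z_compression must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.points_per_structure < 3:
            raise ValueError("points_per_structure too small")
        if not 0 < self.edge_band < 1:
            raise ValueError("edge_band must be an arc fraction in (0, 1)")
        if self.edge_mode not in ("paired", "band"):
            raise ValueError("edge_mode must be 'paired' or 'band'")


@dataclass
class GroundTruth:
    """Recovery targets stored next to each generated cloud."""

    true_orientation: tuple          # (theta_e, phi_e)
    true_sigma_e: float              # area-measure normalized rim size
    true_profile: MeridianProfile
    true_scale: float                # nm per profile unit
    true_z_compression: float
    true_kappaG_ratio: float | None = None


def _orientation_matrix(theta, phi):
    """Rotation taking the +z axis to (sin t cos p, sin t sin p, cos t)."""
    cz, sz = np.cos(phi), np.sin(phi)
    cy, sy = np.cos(theta), np.sin(theta)
    Rz = np.array([[cz, -sz, 0.0], [sz, cz, 0.0], [0.0, 0.0, 1.0]])
    Ry = np.array([[cy, 0.0, sy], [0.0, 1.0, 0.0], [-sy, 0.0, cy]])
    return Rz @ Ry


def _rim_section_points(prof, R, scale, compression, spacing,
                        max_sections=60):
    """Contour endpoints: intersections of the rim circle with section planes.

    Real segmentations mark two edge dots per section, the endpoints of each
    traced contour, which lie on the rim circle.  The rim circle of radius
    rho at axial height z_rim is rotated, scaled and compressed into the lab
    frame, where its stack coordinate is sinusoidal in the azimuth:
    z(phi) = amp*sin(phi + delta) + z0.  Every section level inside the
    band cuts it at two azimuths.  Returns an (m, 3) array (possibly empty).
    """
    rho, z_rim = prof.r[-1] * scale, prof.z[-1] * scale
    e1, e2, axis = R[:, 0], R[:, 1], R[:, 2]
    centre = z_rim * axis
    # lab z of a rim point at azimuth phi, after compression
    A = rho * e1[2] * compression
    B = rho * e2[2] * compression
    z0 = centre[2] * compression
    amp = np.hypot(A, B)
    delta = np.arctan2(A, B)       # z = amp*sin(phi + delta) + z0
    k_lo = int(np.ceil((z0 - amp) / spacing))
    k_hi = int(np.floor((z0 + amp) / spacing))
    n_k = k_hi - k_lo + 1
    if n_k > max_sections:
        # near-continuous sectioning: keep an evenly spaced subset of levels
        ks = np.unique(np.round(np.linspace(k_lo, k_hi, max_sections))
                       .astype(np.int64))
    else:
        ks = np.arange(k_lo, k_hi + 1)
    pts = []
    for k in ks:
        u = (k * spacing - z0) / amp if amp > 0 else 2.0
        if abs(u) > 1:
            continue
        for phi in (np.arcsin(u) - delta, np.pi - np.arcsin(u) - delta):
            p = centre + rho * (np.cos(phi) * e1 + np.sin(phi) * e2)
            p[2] *= compression          # the section planes cut the
            pts.append(p)                # already-compressed structure
    return np.array(pts).reshape(-1, 3)


def generate_structure(spec: SyntheticSpec):
    """Sample one synthetic cloud; returns (PhagophoreCloud, GroundTruth).

    Body points are drawn uniformly by surface-area measure (inverse CDF of
    the cumulative area along the meridian, uniform azimuth), scaled to nm,
    rotated to the requested orientation, compressed along the lab stack
    axis, quantized to the section grid, and given in-plane noise.

    Edge points emulate manual contour-endpoint annotation: in the default
    "paired" mode two points per section are placed where the section plane
    cuts the rim circle (this per-section pairing is what makes the mean
    edge vector a usable orientation estimate; randomly flagged rim-band
    points would leave an azimuthal sampling error of order
    rim_radius/sqrt(2*M) that no realistic M can beat).  The "band" mode
    instead flags body points within ``edge_band`` of the rim arc.
    Deterministic given the seed.
    """
    prof = spec.profile_source
    if isinstance(prof, ShapeSolution):
        prof = meridian_of_solution(prof)
    rng = np.random.default_rng(spec.seed)
    theta_e, phi_e = spec.orientation
    R = _orientation_matrix(theta_e, phi_e)
    n = spec.points_per_structure

    s, r, z = prof.s, prof.r, prof.z
    w = 0.5 * (r[1:] + r[:-1]) * np.diff(s)
    cdf = np.concatenate([[0.0], np.cumsum(w)])
    cdf /= cdf[-1]

    if spec.edge_mode == "paired":
        # the annotation budget scales with the tracing density: at most
        # one point in six is an edge dot, as in real contour tracings
        rim_pts = _rim_section_points(prof, R, spec.scale,
                                      spec.z_compression,
                                      spec.section_spacing,
                                      max_sections=max(2, n // 12))
        if len(rim_pts) < 6:
            # rim circle nearly parallel to the sections: the whole mouth is
            # visible in one image and is annotated as a ring
            phi = np.linspace(0.0, 2.0 * np.pi, 9)[:-1]
            ring = np.column_stack([prof.r[-1] * np.cos(phi),
                                    prof.r[-1] * np.sin(phi),
                                    np.full(8, prof.z[-1])])
            rim_pts = (ring * spec.scale) @ R.T
            rim_pts[:, 2] *= spec.z_compression
        else:
            rim_pts = rim_pts.copy()
        n_body = max(n - len(rim_pts), 10)
        si = np.interp(rng.random(n_body), cdf, s)
        phi = rng.random(n_body) * 2.0 * np.pi
        body = np.column_stack([np.interp(si, s, r) * np.cos(phi),
                                np.interp(si, s, r) * np.sin(phi),
                                np.interp(si, s, z)])
        body = (body * spec.scale) @ R.T
        body[:, 2] *= spec.z_compression
        pts = np.vstack([body, rim_pts])
        edge = np.zeros(len(pts), bool)
        edge[n_body:] = True
    else:
        si = np.interp(rng.random(n), cdf, s)
        phi = rng.random(n) * 2.0 * np.pi
        pts = np.column_stack([np.interp(si, s, r) * np.cos(phi),
                               np.interp(si, s, r) * np.sin(phi),
                               np.interp(si, s, z)])
        edge = si >= s[-1] - spec.edge_band * prof.arc_length
        if edge.sum() < 3:
            edge[np.argsort(si)[-3:]] = True
        pts = (pts * spec.scale) @ R.T
        pts[:, 2] *= spec.z_compression

    pts[:, 2] = np.round(pts[:, 2] / spec.section_spacing) * spec.section_spacing
    if spec.noise_sd > 0:
        pts[:, :2] += rng.normal(0.0, spec.noise_sd, size=(len(pts), 2))

    if len(np.unique(pts[:, 2])) < 3:
        raise ValueError(
            f"structure spans fewer than 3 sections at spacing "
            f"{spec.section_spacing} nm; too small for the pipeline")

    cloud = PhagophoreCloud(
        structure_id=spec.structure_id or f"synthetic-{spec.seed}",
        points=pts, edge_mask=edge, section_spacing=spec.section_spacing)
    truth = GroundTruth(
        true_orientation=(theta_e, phi_e),
        true_sigma_e=prof.sigma_e(measure="area"),
        true_profile=prof, true_scale=spec.scale,
        true_z_compression=spec.z_compression,
        true_kappaG_ratio=(spec.profile_source.params.kappaG_ratio
                           if isinstance(spec.profile_source, ShapeSolution)
                           else None))
    return cloud, truth
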