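"""Normalization, orientation, staging and pooling of phagophore point clouds.

Each segmented phagophore is a labeled 3D point cloud with a boolean edge
mask marking points on the open rim.  The pipeline is:

1. z-score normalization: centre on the centroid and scale so the RMS
   distance from the centroid is one (``sigma_X`` is the structure size and
   becomes the length unit).
2. orientation: the mean of the edge-flagged points defines the cup axis;
   the cloud is rotated by Rz(-phi_e) then Ry(-theta_e) so that the mean
   edge vector lies on +z.
3. rim size ``sigma_e``: RMS distance of the edge points from their own
   mean; rotation-invariant, and the operative staging statistic.
4. staging by the published sigma_e thresholds (with the gaps between the
   printed ranges mapped to "unclassified"); k-means clustering is kept as
   an exploratory parallel, never as the classifier.
5. pooling per stage and projection onto the (radial, axial) plane.

A stack-axis scale factor distorted by sample compression can be recovered
with `estimate_z_scale`, which rescales the stack coordinate to maximize
axisymmetry of the aligned cloud.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "PhagophoreCloud",
    "NormalizedCloud",
    "StageLabel",
    "STAGE_THRESHOLDS",
    "zscore_normalize",
    "mean_edge_vector",
    "align_to_z",
    "rim_size",
    "classify_stage",
    "kmeans_stage_clusters",
    "stage_features",
    "superpose",
    "project_radial_axial",
    "estimate_z_scale",
    "apply_z_compression",
]


@dataclass
class PhagophoreCloud:
    """Raw labeled point cloud of one segmented structure (lab frame)."""

    structure_id: str
    points: np.ndarray           # (n, 3), length units (nm)
    edge_mask: np.ndarray        # (n,) bool
    section_spacing: float | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, float)
        self.edge_mask = np.asarray(self.edge_mask, bool)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        if len(self.points) < 3:
            raise ValueError(f"{self.structure_id}: need at least 3 points")
        if self.edge_mask.shape != (len(self.points),):
            raise ValueError("edge_mask length mismatch")
        if not np.all(np.isfinite(self.points)):
            raise ValueError(f"{self.structure_id}: non-finite coordinates")

    @property
    def n_points(self) -> int:
        return len(self.points)


@dataclass
class NormalizedCloud:
    """z-score-normalized (and possibly axis-aligned) point cloud."""

    structure_id: str
    points: np.ndarray           # (n, 3), dimensionless
    edge_mask: np.ndarray
    mu_X: np.ndarray             # original centroid (length units)
    sigma_X: float               # original RMS spread = the length unit
    theta_e: float = 0.0         # removed polar angle (rad)
    phi_e: float = 0.0           # removed azimuth (rad)
    mu_e: np.ndarray | None = None   # mean edge vector after rotation
    aligned: bool = False

    @property
    def n_points(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class StageLabel:
    label: str                   # very_early / early / middle / late / unclassified
    sigma_e: float


#: printed staging thresholds on sigma_e; values in the gaps are unclassified
STAGE_THRESHOLDS = {
    "very_early": (1.1, np.inf),
    "early": (0.8, 1.0),
    "middle": (0.5, 0.7),
    "late": (0.0, 0.4),
}


def zscore_normalize(cloud: PhagophoreCloud) -> NormalizedCloud:
    """Centre on the centroid and scale to unit RMS spread.

    sigma_X = sqrt(mean |X - mu|^2) is stored as the structure's length unit
    so positions can be mapped back to physical units.
    """
    mu = cloud.points.mean(axis=0)
    dev = cloud.points - mu
    sigma = float(np.sqrt(np.mean(np.sum(dev ** 2, axis=1))))
    if sigma == 0.0:
        raise ValueError(f"{cloud.structure_id}: all points coincident")
    return NormalizedCloud(structure_id=cloud.structure_id,
                           points=dev / sigma,
                           edge_mask=cloud.edge_mask.copy(),
                           mu_X=mu, sigma_X=sigma)


def mean_edge_vector(cloud: NormalizedCloud, pre_rotation: bool = True) -> np.ndarray:
    """Arithmetic mean of the edge-flagged points.

    With ``pre_rotation`` the mean is taken over the cloud as stored (the Y
    frame before axis alignment); otherwise the caller is expected to pass an
    aligned cloud (the Z frame).  Both are plain means over the flagged
    subset; the flag only documents which frame the caller is in.
    """
    if not cloud.edge_mask.any():
        raise ValueError(f"{cloud.structure_id}: no edge-flagged points")
    return cloud.points[cloud.edge_mask].mean(axis=0)


def _rotation_to_z(mu_e):
    norm = np.linalg.norm(mu_e)
    if norm == 0:
        raise ValueError("zero mean edge vector; orientation undefined")
    transverse = np.hypot(mu_e[0], mu_e[1])
    phi = 0.0 if transverse < 1e-12 * norm else float(np.arctan2(mu_e[1], mu_e[0]))
    theta = float(np.arctan2(transverse, mu_e[2]))
    cz, sz = np.cos(-phi), np.sin(-phi)
    Rz = np.array([[cz, -sz, 0.0], [sz, cz, 0.0], [0.0, 0.0, 1.0]])
    cy, sy = np.cos(-theta), np.sin(-theta)
    Ry = np.array([[cy, 0.0, sy], [0.0, 1.0, 0.0], [-sy, 0.0, cy]])
    return theta, phi, Ry @ Rz


def align_to_z(cloud: NormalizedCloud) -> NormalizedCloud:
    """Rotate so the mean edge vector lies on the +z axis.

    The composite rotation is Ry(-theta_e) Rz(-phi_e) applied to every point;
    phi_e is defined as 0 when the mean edge vector is already on the axis
    (rotation about z is a symmetry of everything downstream).
    """
    mu_e = mean_edge_vector(cloud, pre_rotation=True)
    theta, phi, R = _rotation_to_z(mu_e)
    pts = cloud.points @ R.T
    return replace(cloud, points=pts, theta_e=theta, phi_e=phi,
                   mu_e=R @ mu_e, aligned=True)


def rim_size(cloud: NormalizedCloud) -> float:
    """sigma_e: RMS distance of edge points from their own mean.

    Rotations are isometries, so the value is identical before and after
    `align_to_z`; it is computed frame-consistently from the cloud as given.
    """
    edge = cloud.points[cloud.edge_mask]
    if len(edge) < 3:
        raise ValueError(f"{cloud.structure_id}: need >= 3 edge points")
    dev = edge - edge.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(dev ** 2, axis=1))))


def classify_stage(sigma_e: float) -> StageLabel:
    """Stage label from the printed sigma_e threshold table (gaps unclassified)."""
    if sigma_e < 0:
        raise ValueError("sigma_e must be non-negative")
    if sigma_e > 1.1:
        return StageLabel("very_early", sigma_e)
    if 0.8 < sigma_e < 1.0:
        return StageLabel("early", sigma_e)
    if 0.5 < sigma_e < 0.7:
        return StageLabel("middle", sigma_e)
    if sigma_e < 0.4:
        return StageLabel("late", sigma_e)
    return StageLabel("unclassified", sigma_e)


def stage_features(cloud: NormalizedCloud, n_bins: int = 10) -> np.ndarray:
    """Feature vector for exploratory clustering: (sigma_e, radial profile).

    The radial profile is the mean cylindrical radius in ``n_bins`` equal
    axial bins of the aligned cloud, normalized to unit sum.
    """
    se = rim_size(cloud)
    pts = cloud.points
    r = np.hypot(pts[:, 0], pts[:, 1])
    z = pts[:, 2]
    edges = np.linspace(z.min(), z.max() + 1e-12, n_bins + 1)
    idx = np.clip(np.digitize(z, edges) - 1, 0, n_bins - 1)
    prof = np.array([r[idx == b].mean() if (idx == b).any() else 0.0
                     for b in range(n_bins)])
    tot = prof.sum()
    if tot > 0:
        prof = prof / tot
    return np.concatenate([[se], prof])


def kmeans_stage_clusters(features, k: int, seed: int) -> np.ndarray:
    """k-means labels over per-structure feature vectors (deterministic by seed)."""
    from sklearn.cluster import KMeans
    X = np.asarray(features, float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(X):
        raise ValueError(f"k={k} exceeds the number of structures ({len(X)})")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(X)


def superpose(clouds):
    """Pool aligned normalized clouds, keeping per-point structure provenance.

    Returns (points, provenance) where provenance is an array of structure
    ids, one per pooled point.
    """
    clouds = list(clouds)
    if not clouds:
        raise ValueError("cannot superpose an empty list of clouds")
    pts = np.vstack([c.points for c in clouds])
    prov = np.concatenate([[c.structure_id] * c.n_points for c in clouds])
    return pts, prov


def project_radial_axial(points) -> np.ndarray:
    """(x, y, z) -> (sqrt(x^2 + y^2), z)."""
    pts = np.asarray(points, float)
    return np.column_stack([np.hypot(pts[:, 0], pts[:, 1]), pts[:, 2]])


def apply_z_compression(cloud: PhagophoreCloud, factor: float) -> PhagophoreCloud:
    """Multiply the stack-axis coordinate by ``factor`` (edge flags preserved)."""
    if factor <= 0:
        raise ValueError("compression factor must be positive")
    pts = cloud.points.copy()
    pts[:, 2] *= factor
    return PhagophoreCloud(structure_id=cloud.structure_id, points=pts,
                           edge_mask=cloud.edge_mask.copy(),
                           section_spacing=cloud.section_spacing)


def _axisymmetry_cost(cloud: PhagophoreCloud, lam: float,
                      n_sectors: int = 8, n_zbins: int = 10) -> float:
    """Azimuth-sector variance of the radius after trial stack rescaling."""
    trial = apply_z_compression(cloud, lam)
    norm = align_to_z(zscore_normalize(trial))
    pts = norm.points
    r = np.hypot(pts[:, 0], pts[:, 1])
    phi = np.arctan2(pts[:, 1], pts[:, 0])
    z = pts[:, 2]
    # equal-count axial bins; within each, remove the quadratic axial trend
    # of r so that uneven z sampling across sectors does not masquerade as
    # asymmetry
    qs = np.quantile(z, np.linspace(0, 1, n_zbins + 1))
    qs[-1] += 1e-9
    zi = np.clip(np.digitize(z, qs) - 1, 0, n_zbins - 1)
    pedges = np.linspace(-np.pi, np.pi + 1e-12, n_sectors + 1)
    pi_ = np.clip(np.digitize(phi, pedges) - 1, 0, n_sectors - 1)
    cost = 0.0
    for b in range(n_zbins):
        mb = zi == b
        if mb.sum() < 2 * n_sectors:
            continue
        A = np.vander(z[mb], 3)
        coef, *_ = np.linalg.lstsq(A, r[mb], rcond=None)
        resid = r[mb] - A @ coef
        sec = pi_[mb]
        means = [resid[sec == s].mean()
                 for s in range(n_sectors) if (sec == s).sum() >= 3]
        if len(means) >= 2:
            cost += float(np.var(means))
    return cost


def estimate_z_scale(cloud: PhagophoreCloud, bounds=(0.5, 2.0)) -> float:
    """Stack-axis scale factor that maximizes axisymmetry of the aligned cloud.

    Serial sectioning compresses structures along the stack axis; assuming
    the true structure is axisymmetric, the inverse factor is recovered by a
    bounded 1D search minimizing the azimuth-sector radial variance.  Returns
    1.0 with a warning flag if the optimization fails.
    """
    z = cloud.points[:, 2]
    if len(np.unique(np.round(z, 9))) < 3:
        raise ValueError("need >= 3 sections to estimate the stack scale")
    try:
        res = minimize_scalar(lambda lam: _axisymmetry_cost(cloud, lam),
                              bounds=bounds, method="bounded",
                              options={"xatol": 1e-7})
        if not res.success:
            import warnings
            warnings.warn("stack-scale optimization failed; returning 1.0")
            return 1.0
        return float(res.x)
    except Exception:
        import warnings
        warnings.warn("stack-scale optimization failed; returning 1.0")
        return 1.0
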