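"""File formats, configuration and pipeline orchestration.

Contour tables are TSV files with a commented two-line header declaring the
length unit and section spacing, one row per traced point:

    # phagoshape contour table v1
    # unit: nm  section_spacing: 25
    structure_id  section  z  x  y  edge

``z`` is the stack coordinate; if a row leaves it empty it is reconstructed
as section * spacing.  ``edge`` is 0/1.  Writing is canonical (floats via
%.10g), so write -> read -> write round trips byte-identically.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

from .morphometry import (PhagophoreCloud, zscore_normalize, align_to_z,
                          rim_size, classify_stage, stage_features,
                          kmeans_stage_clusters, superpose,
                          project_radial_axial)

log = logging.getLogger("phagoshape")

__all__ = [
    "read_contours",
    "write_contours",
    "write_ply",
    "PipelineConfig",
    "load_config",
    "save_config",
    "run_pipeline",
]

_HEADER0 = "# phagoshape contour table v1"


class ContourFormatError(ValueError):
    pass


def _fmt(x: float) -> str:
    return "%.10g" % x


def write_contours(path, clouds, unit: str = "nm",
                   section_spacing: float | None = None) -> None:
    path = Path(path)
    clouds = list(clouds)
    if section_spacing is None:
        spacings = {c.section_spacing for c in clouds if c.section_spacing}
        section_spacing = spacings.pop() if len(spacings) == 1 else 0.0
    lines = [_HEADER0,
             f"# unit: {unit}  section_spacing: {_fmt(section_spacing)}",
             "structure_id\tsection\tz\tx\ty\tedge"]
    for c in clouds:
        sp = c.section_spacing or section_spacing or 1.0
        sec = np.round(c.points[:, 2] / sp).astype(int) if sp else \
            np.zeros(len(c.points), int)
        for j in range(len(c.points)):
            x, y, z = c.points[j]
            lines.append("\t".join([c.structure_id, str(int(sec[j])),
                                    _fmt(z), _fmt(x), _fmt(y),
                                    str(int(c.edge_mask[j]))]))
    path.write_text("\n".join(lines) + "\n")


def read_contours(path):
    """Parse a contour table into one PhagophoreCloud per structure id."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0] != _HEADER0:
        raise ContourFormatError(f"{path}: missing contour-table header")
    import re
    m = re.search(r"section_spacing:\s*([0-9.eE+-]+)", lines[1])
    spacing = float(m.group(1)) if m else None
    cols = lines[2].split("\t")
    if "edge" not in cols:
        raise ContourFormatError(f"{path}: missing edge column")
    order = {}
    data: dict = {}
    for ln, line in enumerate(lines[3:], start=4):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 6:
            raise ContourFormatError(f"{path}:{ln}: expected 6 fields, "
                                     f"got {len(parts)}")
        sid, sec, z, x, y, edge = parts
        try:
            sec_i = int(sec)
            x_f, y_f = float(x), float(y)
            z_f = float(z) if z != "" else (sec_i * (spacing or 0.0))
            edge_i = int(edge)
        except ValueError as exc:
            raise ContourFormatError(f"{path}:{ln}: malformed row "
                                     f"({exc})") from None
        if edge_i not in (0, 1):
            raise ContourFormatError(f"{path}:{ln}: edge must be 0/1")
        rec = data.setdefault(sid, {"pts": [], "edge": [], "sec": []})
        order.setdefault(sid, len(order))
        rec["pts"].append((x_f, y_f, z_f))
        rec["edge"].append(bool(edge_i))
        rec["sec"].append(sec_i)
    clouds = []
    for sid in sorted(data, key=order.get):
        rec = data[sid]
        if len(set(rec["sec"])) < 3:
            raise ContourFormatError(
                f"{path}: structure {sid!r} spans fewer than 3 sections")
        clouds.append(PhagophoreCloud(structure_id=sid,
                                      points=np.array(rec["pts"]),
                                      edge_mask=np.array(rec["edge"]),
                                      section_spacing=spacing))
    return clouds


def write_ply(path, cloud: PhagophoreCloud) -> None:
    """ASCII PLY export with an integer ``edge`` vertex property."""
    path = Path(path)
    n = cloud.n_points
    header = ["ply", "format ascii 1.0",
              f"comment phagoshape structure {cloud.structure_id}",
              f"element vertex {n}",
              "property float x", "property float y", "property float z",
              "property uchar edge", "end_header"]
    rows = [f"{_fmt(p[0])} {_fmt(p[1])} {_fmt(p[2])} {int(e)}"
            for p, e in zip(cloud.points, cloud.edge_mask)]
    path.write_text("\n".join(header + rows) + "\n")


# ------------------------------------------------------------- configuration

@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "results/pipeline"
    stages: tuple = ("simulate", "normalize", "classify", "fit",
                     "solve", "compare")
    # synthetic study design: cap-based structures around the four stages
    n_structures: int = 12
    sigma_e_targets: tuple = (1.3, 0.9, 0.6, 0.3)
    scale_nm: tuple = (300.0, 800.0)
    points_range: tuple = (300, 600)
    noise_sd: float = 2.0
    section_spacing: float = 25.0
    edge_band: float = 0.03
    # material / solver
    kappa_b: float = 20.0
    kappaG_ratio: float = -0.2
    J0: float = 0.0
    l_values: tuple = (0.8, 0.39, 0.24, 0.13)
    shoot_tol: float = 1e-8
    # clustering
    kmeans_k: int = 4

    def __post_init__(self):
        if self.shoot_tol <= 0:
            raise ValueError("tolerances must be positive")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = PipelineConfig(**{k: tuple(v) if isinstance(v, list) else v
                            for k, v in raw.items()})
    return cfg


def save_config(cfg: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in asdict(cfg).items()}, fh,
                       sort_keys=False)


# ------------------------------------------------------------------ pipeline

def _file_hash(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig):
    """Execute the requested stages in order; returns a result-bundle dict.

    simulate -> normalize -> classify -> fit -> solve -> compare, each stage
    reading the artifacts of the previous one from ``cfg.outdir``.
    """
    import pandas as pd
    from . import synthetic_em, profile_fit, shape_model, compare

    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"outdir": str(out)}
    log.info("pipeline start: stages=%s seed=%d outdir=%s",
             cfg.stages, cfg.seed, out)

    contours = out / "contours.tsv"
    percloud = out / "structures.csv"

    for stage in cfg.stages:
        log.info("stage %s", stage)
        try:
            if stage == "simulate":
                rng = np.random.default_rng(cfg.seed)
                clouds = []
                for i in range(cfg.n_structures):
                    target = cfg.sigma_e_targets[i % len(cfg.sigma_e_targets)]
                    alpha = synthetic_em.cap_angle_for_sigma_e(target)
                    spec = synthetic_em.SyntheticSpec(
                        profile_source=synthetic_em.spherical_cap(alpha),
                        scale=float(rng.uniform(*cfg.scale_nm)),
                        orientation=(float(np.arccos(rng.uniform(-1, 1))),
                                     float(rng.uniform(0, 2 * np.pi))),
                        section_spacing=cfg.section_spacing,
                        points_per_structure=int(rng.integers(*cfg.points_range)),
                        noise_sd=cfg.noise_sd, edge_band=cfg.edge_band,
                        seed=int(rng.integers(0, 2 ** 31 - 1)),
                        structure_id=f"syn{i:03d}")
                    cloud, _truth = synthetic_em.generate_structure(spec)
                    clouds.append(cloud)
                write_contours(contours, clouds,
                               section_spacing=cfg.section_spacing)
                bundle["contours"] = str(contours)

            elif stage == "normalize":
                clouds = read_contours(contours)
                rows, aligned = [], {}
                for c in clouds:
                    nc = align_to_z(zscore_normalize(c))
                    se = rim_size(nc)
                    rows.append(dict(structure_id=c.structure_id,
                                     n_points=c.n_points,
                                     sigma_X=nc.sigma_X, theta_e=nc.theta_e,
                                     phi_e=nc.phi_e, sigma_e=se,
                                     stage=classify_stage(se).label))
                    aligned[c.structure_id] = nc
                pd.DataFrame(rows).to_csv(percloud, index=False)
                bundle["structures"] = rows
                bundle["aligned"] = aligned
                # pooled projected points per stage
                for st in ("very_early", "early", "middle", "late"):
                    ids = [r["structure_id"] for r in rows if r["stage"] == st]
                    if not ids:
                        continue
                    pts, prov = superpose([aligned[i] for i in ids])
                    proj = project_radial_axial(pts)
                    pd.DataFrame({"radial": proj[:, 0], "axial": proj[:, 1],
                                  "structure_id": prov}).to_csv(
                        out / f"pooled_{st}.csv", index=False)

            elif stage == "classify":
                aligned = bundle.get("aligned")
                if aligned is None:
                    raise RuntimeError("classify requires the normalize stage")
                feats = [stage_features(nc) for nc in aligned.values()]
                labels = kmeans_stage_clusters(feats, cfg.kmeans_k, cfg.seed)
                df = pd.DataFrame({"structure_id": list(aligned),
                                   "kmeans_label": labels})
                df.to_csv(out / "kmeans.csv", index=False)
                bundle["kmeans"] = df

            elif stage == "fit":
                rows = []
                for st in ("very_early", "early", "middle", "late"):
                    f = out / f"pooled_{st}.csv"
                    if not f.exists():
                        continue
                    df = pd.read_csv(f)
                    pts = df[["radial", "axial"]].to_numpy()
                    prof = profile_fit.fit_profile(pts)
                    est = profile_fit.gaussian_modulus_from_points(pts)
                    rows.append(dict(stage=st, a=prof.a, b=prof.b, c=prof.c,
                                     d=prof.d, se_a=prof.stderr[0],
                                     se_b=prof.stderr[1], se_c=prof.stderr[2],
                                     se_d=prof.stderr[3],
                                     area=profile_fit.membrane_area(prof),
                                     kappaG_ratio=est.kappaG_ratio,
                                     kG_in_range=est.in_range))
                pd.DataFrame(rows).to_csv(out / "profile_fits.csv", index=False)
                bundle["fits"] = rows

            elif stage == "solve":
                params = shape_model.MaterialParams(
                    kappa_b=cfg.kappa_b, kappaG_ratio=cfg.kappaG_ratio,
                    J0=cfg.J0)
                rows = []
                sols = {}
                for l in sorted(cfg.l_values, reverse=True):
                    sol = shape_model.solve_equilibrium(l, params)
                    sols[l] = sol
                    rows.append(dict(
                        l=l, theta_dot0=sol.theta_dot0, gamma_A=sol.gamma_A,
                        gamma_L=sol.gamma_L, F=sol.F, F_bend=sol.F_bend,
                        F_gauss=sol.F_gauss,
                        Jm_rim=sol.Jm[-1], Jp_rim=sol.Jp[-1],
                        aspect=shape_model.aspect_ratio(sol),
                        sigma_e=compare.sigma_e_of_solution(sol)))
                    pd.DataFrame({"s": sol.s_grid, "x": sol.x, "z": sol.z,
                                  "theta": sol.theta, "Jm": sol.Jm,
                                  "Jp": sol.Jp}).to_csv(
                        out / f"solution_l{l:g}.csv", index=False)
                pd.DataFrame(rows).to_csv(out / "branch_summary.csv",
                                          index=False)
                bundle["solutions"] = sols
                bundle["branch"] = rows

            elif stage == "compare":
                sols = bundle.get("solutions", {})
                rows = bundle.get("branch", [])
                if rows:
                    pd.DataFrame(rows)[["l", "sigma_e", "gamma_A",
                                        "gamma_L", "F"]].to_csv(
                        out / "mapping.csv", index=False)
                # overlay the synthetic pooled clouds where present
                stage_map = {"very_early": 0, "early": 1, "middle": 2,
                             "late": 3}
                reports = []
                for st, k in stage_map.items():
                    f = out / f"pooled_{st}.csv"
                    if not f.exists() or not sols:
                        continue
                    ls = sorted(sols, reverse=True)
                    l = ls[min(k, len(ls) - 1)]
                    df = pd.read_csv(f)
                    rep = compare.overlay_report(
                        st, df[["radial", "axial"]].to_numpy(), sols[l],
                        figure_path=out / f"overlay_{st}.png")
                    pd.DataFrame(rep["bins"]).to_csv(
                        out / f"residuals_{st}.csv", index=False)
                    reports.append(rep)
                bundle["overlays"] = reports
            else:
                raise ValueError(f"unknown stage {stage!r}")
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {p.name: _file_hash(p) for p in sorted(out.iterdir())
                if p.is_file() and p.suffix in {".csv", ".tsv"}}
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest))
    bundle["manifest"] = manifest
    log.info("pipeline done: %d artifacts", len(manifest))
    return bundle
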