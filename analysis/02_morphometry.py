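"""Normalize, orient, stage and pool the synthetic structures.

Reads results/synthetic/contours.tsv; writes per-structure morphometry
(size unit sigma_X, orientation, rim size sigma_e, stage label), k-means
labels as an exploratory parallel, and per-stage pooled projected clouds to
results/morphometry/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from phagoshape.io import read_contours
from phagoshape.morphometry import (zscore_normalize, align_to_z, rim_size,
                                    classify_stage, stage_features,
                                    kmeans_stage_clusters, superpose,
                                    project_radial_axial)

SRC = Path("results/synthetic/contours.tsv")
OUT = Path("results/morphometry")
OUT.mkdir(parents=True, exist_ok=True)

clouds = read_contours(SRC)
rows, aligned = [], {}
for c in clouds:
    nc = align_to_z(zscore_normalize(c))
    se = rim_size(nc)
    aligned[c.structure_id] = nc
    rows.append(dict(structure_id=c.structure_id, n_points=c.n_points,
                     sigma_X_nm=nc.sigma_X, theta_e=nc.theta_e,
                     phi_e=nc.phi_e, sigma_e=se,
                     stage=classify_stage(se).label))
df = pd.DataFrame(rows)
df.to_csv(OUT / "structures.csv", index=False)

feats = [stage_features(aligned[r["structure_id"]]) for r in rows]
df["kmeans"] = kmeans_stage_clusters(feats, k=4, seed=0)
df[["structure_id", "stage", "kmeans"]].to_csv(OUT / "kmeans.csv", index=False)

print(df["stage"].value_counts().to_string())
for stage in ("very_early", "early", "middle", "late"):
    ids = df.loc[df.stage == stage, "structure_id"]
    if ids.empty:
        continue
    pts, prov = superpose([aligned[i] for i in ids])
    proj = project_radial_axial(pts)
    pd.DataFrame({"radial": proj[:, 0], "axial": proj[:, 1],
                  "structure_id": prov}).to_csv(OUT / f"pooled_{stage}.csv",
                                                index=False)
    print(f"pooled {stage}: {len(ids)} structures, {len(pts)} points")
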