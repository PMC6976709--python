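"""Water-mass delineation from transect velocity fields.

Zonal/meridional velocities become current speed and flow-toward direction;
k-means on standardized (|u|, |v|, speed) features splits the grid into
water masses, ranked by mean speed — slowest is eddy water (ED), fastest is
boundary-current water (FC), intermediate the interface (IF).  Distance from
every grid cell to the FC water mass, the mixed layer depth from a density
threshold criterion, and per-depth-level anomalies complete the physical
context used by the driver models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

__all__ = [
    "WaterMassLabels",
    "uv_to_speed_dir",
    "cluster_water_masses",
    "distance_to_fc",
    "mixed_layer_depth",
    "anomaly",
]

WM_NAMES_K3 = ("ED", "IF", "FC")  # slowest -> fastest


def uv_to_speed_dir(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Current speed and flow-toward direction from velocity components.

    Direction is oceanographic (the direction the water flows toward),
    degrees clockwise from north: (u=0, v>0) -> 0 (northward),
    (u>0, v=0) -> 90 (eastward).  Zero velocity has undefined direction,
    reported as 0.
    """
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    if not (np.isfinite(u).all() and np.isfinite(v).all()):
        raise ValueError("u and v must be finite")
    speed = np.hypot(u, v)
    direction = np.degrees(np.arctan2(u, v)) % 360.0
    direction = np.where(direction >= 360.0, 0.0, direction)  # -eps % 360 rounds to 360
    direction = np.where(speed == 0, 0.0, direction)
    return speed, direction


@dataclass
class WaterMassLabels:
    """Result of velocity clustering on a transect grid."""

    labels: np.ndarray  # str per cell, e.g. {'ED','IF','FC'}; shape of grid
    k: int
    centers: pd.DataFrame  # per cluster: mean |u|, |v|, speed (original units)
    variance_explained: float  # between-cluster SS / total SS on features
    within_ss_by_k: pd.Series  # total within-SS per candidate k (elbow data)

    def share(self, name: str) -> float:
        return float((self.labels == name).mean())


def _elbow_k(within_ss: pd.Series) -> int:
    """k at the maximum second difference of total within-SS."""
    ks = within_ss.index.to_numpy()
    w = within_ss.to_numpy()
    if len(ks) < 3:
        return int(ks[0])
    second = w[:-2] - 2 * w[1:-1] + w[2:]
    return int(ks[1:-1][np.argmax(second)])


def cluster_water_masses(
    u: np.ndarray,
    v: np.ndarray,
    k_range: range = range(2, 9),
    k: int | None = None,
    n_init: int = 25,
    seed: int = 0,
    signed: bool = False,
) -> WaterMassLabels:
    """K-means water-mass delineation on (|u|, |v|, speed) features.

    Features are standardized before clustering.  For each candidate k the
    total within-cluster sum of squares is recorded; unless ``k`` is forced,
    the elbow (maximum second difference of within-SS) picks it.  Clusters
    are then ranked by mean current speed: slowest -> ED (eddy), fastest ->
    FC (boundary current), intermediate -> IF for k = 3; for other k the
    names are ``WM1..WMk`` in increasing speed order.  ``signed=True``
    clusters on (u, v, speed) instead of magnitudes.
    """
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    speed = np.hypot(u, v)
    shape = u.shape
    feats = np.column_stack([
        (u if signed else np.abs(u)).ravel(),
        (v if signed else np.abs(v)).ravel(),
        speed.ravel(),
    ])
    if np.unique(feats, axis=0).shape[0] < max(k_range):
        raise ValueError("fewer distinct feature rows than clusters requested")
    mu, sd = feats.mean(axis=0), feats.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    z = (feats - mu) / sd

    within = {}
    fits = {}
    for kk in (list(k_range) if k is None else sorted(set(list(k_range) + [k]))):
        km = KMeans(n_clusters=kk, n_init=n_init, random_state=seed).fit(z)
        within[kk] = km.inertia_
        fits[kk] = km
    within_ss = pd.Series(within).sort_index()
    chosen = k if k is not None else _elbow_k(within_ss)
    km = fits[chosen]

    total_ss = float(((z - z.mean(axis=0)) ** 2).sum())
    var_explained = 1.0 - km.inertia_ / total_ss

    # rank clusters by mean speed and name them
    cell_speed = speed.ravel()
    mean_speed = np.array([cell_speed[km.labels_ == c].mean() for c in range(chosen)])
    order = np.argsort(mean_speed)  # slowest first
    if chosen == 3:
        names = WM_NAMES_K3
    else:
        names = tuple(f"WM{i + 1}" for i in range(chosen))
    name_of = {int(cluster): names[rank] for rank, cluster in enumerate(order)}
    labels = np.array([name_of[c] for c in km.labels_]).reshape(shape)

    centers = pd.DataFrame(
        {
            "u_feat": [feats[km.labels_ == c, 0].mean() for c in order],
            "v_feat": [feats[km.labels_ == c, 1].mean() for c in order],
            "speed": mean_speed[order],
            "n_cells": [(km.labels_ == c).sum() for c in order],
        },
        index=pd.Index([names[r] for r in range(chosen)], name="water_mass"),
    )
    return WaterMassLabels(labels, chosen, centers, float(var_explained), within_ss)


def distance_to_fc(
    labels: np.ndarray,
    x_m: np.ndarray,
    z_m: np.ndarray,
    fc_name: str = "FC",
) -> np.ndarray:
    """Minimum Euclidean distance (km) from each cell to any FC cell.

    Computed in (along-track km, depth km) coordinates — the vertical
    contribution is retained but negligible at transect scales.  FC cells
    get 0.  Raises if no FC cell exists.
    """
    labels = np.asarray(labels)
    if labels.shape != (len(z_m), len(x_m)):
        raise ValueError("labels must have shape (n_depth, n_alongtrack)")
    fc_mask = labels == fc_name
    if not fc_mask.any():
        raise ValueError(f"no {fc_name!r} cells in the label grid")
    xx, zz = np.meshgrid(np.asarray(x_m, float) / 1000.0, np.asarray(z_m, float) / 1000.0)
    pts = np.column_stack([xx.ravel(), zz.ravel()])
    fc_pts = pts[fc_mask.ravel()]
    # chunked min-distance to keep memory bounded on large grids
    out = np.empty(pts.shape[0])
    step = 4096
    for i in range(0, pts.shape[0], step):
        out[i : i + step] = cdist(pts[i : i + step], fc_pts).min(axis=1)
    out[fc_mask.ravel()] = 0.0
    return out.reshape(labels.shape)


def mixed_layer_depth(
    depth_m: np.ndarray,
    sigma_t: np.ndarray,
    reference_depth_m: float = 5.0,
    delta: float = 0.125,
) -> tuple[float, bool]:
    """Mixed layer depth by the density-threshold criterion.

    The MLD is the shallowest depth at or below the reference depth where
    sigma-t exceeds its reference value by ``delta`` (kg m^-3), with linear
    interpolation between samples.  If the threshold is never exceeded the
    deepest sampled depth is returned with ``capped=True``.

    Returns ``(mld_m, capped)``.
    """
    z = np.asarray(depth_m, float)
    s = np.asarray(sigma_t, float)
    if not np.isfinite(s).all():
        raise ValueError("densities must be finite")
    if z.min() > reference_depth_m or z.max() < reference_depth_m:
        raise ValueError("profile must cover the reference depth")
    order = np.argsort(z)
    z, s = z[order], s[order]
    s_ref = np.interp(reference_depth_m, z, s)
    if delta <= 0:
        return float(reference_depth_m), False
    below = z >= reference_depth_m
    zb, sb = z[below], s[below]
    excess = sb - s_ref - delta
    idx = np.where(excess >= 0)[0]
    if idx.size == 0:
        return float(z.max()), True
    i = idx[0]
    if i == 0:
        return float(zb[0]), False
    # linear interpolation of the crossing between samples i-1 and i
    frac = -excess[i - 1] / (excess[i] - excess[i - 1])
    return float(zb[i - 1] + frac * (zb[i] - zb[i - 1])), False


def anomaly(field: np.ndarray, axis: int = 1) -> np.ndarray:
    """Remove the per-depth-level mean: anomaly(x, z) = v(x, z) - mean_x v(., z).

    With the package's (depth, along-track) layout the along-track mean is
    removed along ``axis=1``.
    """
    field = np.asarray(field, float)
    return field - field.mean(axis=axis, keepdims=True)
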