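"""Concentrations on 1-m depth bins and ordinary kriging onto a transect grid.

Classified vignettes are merged with the tow's sensor stream and binned into
1-m vertical strata per profile (one down- or up-cast of the undulating
tow); the imaged volume of a stratum is ``volume_rate x residence time``.
Counts become concentrations (ind m^-3) after division by imaged volume and
multiplication by the group's correction factor CF = P/R.  Binned values are
then interpolated onto a regular grid (500 m along-track x 1 m depth by
default) with ordinary kriging under a variogram fitted by weighted least
squares to the empirical semivariogram.

Anisotropy is handled by scaling coordinates by the target resolution
(along-track / 500 m, depth / 1 m) so a single isotropic variogram acts in
scaled space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = [
    "GriddedField",
    "VariogramModel",
    "bin_vignettes",
    "to_concentration",
    "empirical_variogram",
    "fit_variogram",
    "krige_points",
    "krige_field",
]

SENSOR_COLS = ("temperature", "salinity", "sigma_t", "chlorophyll", "oxygen")


@dataclass
class GriddedField:
    """A scalar on a regular transect grid (depth x along-track)."""

    x_m: np.ndarray  # along-track cell centers, strictly increasing
    z_m: np.ndarray  # depth cell centers, strictly increasing
    values: np.ndarray  # shape (nz, nx)
    units: str = ""

    def __post_init__(self) -> None:
        self.x_m = np.asarray(self.x_m, float)
        self.z_m = np.asarray(self.z_m, float)
        self.values = np.asarray(self.values, float)
        if np.any(np.diff(self.x_m) <= 0) or np.any(np.diff(self.z_m) <= 0):
            raise ValueError("grid coordinates must be strictly increasing")
        if self.values.shape != (self.z_m.size, self.x_m.size):
            raise ValueError("values must have shape (n_depth, n_alongtrack)")

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns along_track_m, depth_m, value."""
        xx, zz = np.meshgrid(self.x_m, self.z_m)
        return pd.DataFrame(
            {"along_track_m": xx.ravel(), "depth_m": zz.ravel(), "value": self.values.ravel()}
        )


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def _profile_ids(depth: np.ndarray) -> np.ndarray:
    """Label monotone down/up legs of the undulating tow."""
    d = np.sign(np.diff(depth))
    d[d == 0] = 1
    turns = np.abs(np.diff(d)) > 0
    ids = np.zeros(depth.size, dtype=int)
    ids[2:] = np.cumsum(turns)
    ids[1] = ids[2] if depth.size > 2 else 0
    return ids


def bin_vignettes(
    vignettes: pd.DataFrame,
    sensor_stream: pd.DataFrame,
    volume_rate_m3_per_s: float = 0.168,
    max_depth_m: float = 100.0,
    group_col: str = "group",
) -> pd.DataFrame:
    """Bin classified vignettes into 1-m strata along the tow.

    Parameters
    ----------
    vignettes : table with ``depth_m``, ``time_s`` and a group label column.
    sensor_stream : regularly sampled tow record with ``time_s, depth_m,
        along_track_m`` and any of the sensor columns
        (temperature/salinity/sigma_t/chlorophyll/oxygen).
    volume_rate_m3_per_s : imaged volume per second of tow.

    Returns
    -------
    One row per (profile, 1-m stratum) visited by the tow — including
    strata with zero vignettes — with per-group counts (``n_<group>``),
    ``imaged_volume_m3``, mean sensor values and the mean along-track
    position of the stratum crossing.
    """
    if volume_rate_m3_per_s <= 0:
        raise ValueError("volume_rate must be positive")
    ss = sensor_stream.sort_values("time_s").reset_index(drop=True)
    t = ss["time_s"].to_numpy(float)
    if t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("sensor stream must have strictly increasing time")
    dt = float(np.median(np.diff(t)))

    ss = ss.assign(
        profile=_profile_ids(ss["depth_m"].to_numpy(float)),
        stratum=np.floor(ss["depth_m"].to_numpy(float)).astype(int),
    )
    agg = {"along_track_m": "mean", "time_s": ["min", "max", "count"]}
    for c in SENSOR_COLS:
        if c in ss.columns:
            agg[c] = "mean"
    g = ss.groupby(["profile", "stratum"]).agg(agg)
    g.columns = ["_".join(filter(None, map(str, c))) if isinstance(c, tuple) else c for c in g.columns]
    g = g.rename(columns={
        "along_track_m_mean": "along_track_m",
        "time_s_min": "t0", "time_s_max": "t1", "time_s_count": "n_samples",
        **{f"{c}_mean": c for c in SENSOR_COLS},
    })
    g["imaged_volume_m3"] = g.pop("n_samples") * dt * volume_rate_m3_per_s

    # assign vignettes to (profile, stratum) by time and depth
    vg = vignettes.copy()
    bad = ~vg["depth_m"].between(0, max_depth_m)
    if bad.any():
        logger.warning("rejecting %d vignette(s) with depth outside [0, %g] m", bad.sum(), max_depth_m)
        vg = vg[~bad]
    sample_idx = np.clip(np.searchsorted(t, vg["time_s"].to_numpy(float)), 0, t.size - 1)
    vg = vg.assign(
        profile=ss["profile"].to_numpy()[sample_idx],
        stratum=np.floor(vg["depth_m"].to_numpy(float)).astype(int),
    )
    counts = (
        vg.groupby(["profile", "stratum", group_col]).size().unstack(fill_value=0)
    )
    counts.columns = [f"n_{c}" for c in counts.columns]
    out = g.join(counts).fillna({c: 0 for c in counts.columns})
    for c in counts.columns:
        out[c] = out[c].astype(int)
    return out.reset_index()


def to_concentration(
    bins: pd.DataFrame,
    correction: pd.DataFrame | dict | None = None,
) -> pd.DataFrame:
    """Per-taxon concentration (ind m^-3) per bin: count / volume x CF.

    ``correction`` maps group -> correction factor (the ``correction_factor``
    column of :func:`planktransect.classify.correction_factors` output, a
    dict, or None for CF = 1).  Uncorrectable groups (NaN factor) are passed
    through uncorrected and flagged in the returned frame's
    ``attrs['uncorrected_groups']``.
    """
    vol = bins["imaged_volume_m3"].to_numpy(float)
    count_cols = [c for c in bins.columns if c.startswith("n_")]
    if ((vol <= 0) & (bins[count_cols].sum(axis=1) > 0)).any():
        raise ValueError("bin with zero imaged volume but nonzero count")
    if isinstance(correction, pd.DataFrame):
        cf_map = correction["correction_factor"].to_dict()
    elif correction is None:
        cf_map = {}
    else:
        cf_map = dict(correction)

    out = bins.copy()
    uncorrected = []
    for c in count_cols:
        taxon = c[2:]
        cf = cf_map.get(taxon, 1.0)
        if cf is None or (isinstance(cf, float) and np.isnan(cf)):
            cf = 1.0
            uncorrected.append(taxon)
        with np.errstate(divide="ignore", invalid="ignore"):
            conc = np.where(vol > 0, bins[c].to_numpy(float) / vol * cf, 0.0)
        out[f"conc_{taxon}"] = conc
    out.attrs["uncorrected_groups"] = uncorrected
    if uncorrected:
        logger.warning("groups passed through uncorrected: %s", uncorrected)
    return out


# ---------------------------------------------------------------------------
# variograms
# ---------------------------------------------------------------------------

_FAMILIES = ("spherical", "exponential", "gaussian")


def _gamma_model(family: str, h: np.ndarray, nugget: float, psill: float, rng: float) -> np.ndarray:
    h = np.asarray(h, float)
    hr = h / rng
    if family == "spherical":
        f = np.where(hr < 1.0, 1.5 * hr - 0.5 * hr**3, 1.0)
    elif family == "exponential":
        f = 1.0 - np.exp(-hr)
    elif family == "gaussian":
        f = 1.0 - np.exp(-(hr**2))
    else:
        raise ValueError(f"unknown variogram family {family!r}")
    out = nugget + psill * f
    return np.where(h == 0, 0.0, out)  # gamma(0) = 0 by definition


@dataclass
class VariogramModel:
    """Semivariogram gamma(h) = nugget + partial_sill * f(h / range).

    ``f`` is the unit spherical/exponential/gaussian structure function; the
    distance ``h`` lives in scaled coordinates (see module docstring).  The
    total sill is ``nugget + partial_sill``.
    """

    family: str
    nugget: float
    partial_sill: float
    range_: float
    weak_structure: bool = False

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"family must be one of {_FAMILIES}")
        if self.nugget < 0 or self.partial_sill < 0 or self.range_ <= 0:
            raise ValueError("require nugget >= 0, partial_sill >= 0, range > 0")

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    def __call__(self, h: np.ndarray) -> np.ndarray:
        return _gamma_model(self.family, h, self.nugget, self.partial_sill, self.range_)


def empirical_variogram(
    coords: np.ndarray,
    values: np.ndarray,
    n_lags: int = 15,
    max_pairs_points: int = 3000,
    seed: int = 0,
) -> pd.DataFrame:
    """Binned empirical semivariogram: lag center, gamma, pair count.

    Uses all pairs up to half the maximum separation; for large inputs the
    points are randomly subsampled to ``max_pairs_points`` first.
    """
    coords = np.asarray(coords, float)
    values = np.asarray(values, float)
    if coords.shape[0] != values.size:
        raise ValueError("coords and values must align")
    if coords.shape[0] > max_pairs_points:
        idx = np.random.default_rng(seed).choice(coords.shape[0], max_pairs_points, replace=False)
        coords, values = coords[idx], values[idx]
    d = cdist(coords, coords)
    iu = np.triu_indices_from(d, k=1)
    h = d[iu]
    sq = 0.5 * (values[:, None] - values[None, :])[iu] ** 2
    hmax = h.max() / 2.0
    edges = np.linspace(0.0, hmax, n_lags + 1)
    which = np.digitize(h, edges) - 1
    rows = []
    for i in range(n_lags):
        m = which == i
        if m.sum() == 0:
            continue
        rows.append(dict(lag=0.5 * (edges[i] + edges[i + 1]), gamma=sq[m].mean(), n_pairs=int(m.sum())))
    return pd.DataFrame(rows)


def fit_variogram(
    coords: np.ndarray,
    values: np.ndarray,
    family: str = "spherical",
    n_lags: int = 15,
    seed: int = 0,
) -> VariogramModel:
    """Fit a variogram model to the empirical semivariogram by WLS.

    Weights are Cressie's N(h) / gamma_model(h)^2, iterated inside the least
    squares residual.  Requires >= 30 points.  A constant field returns a
    zero-sill model flagged ``weak_structure``; so does a fit whose partial
    sill is dominated by the nugget (pure-noise data).
    """
    values = np.asarray(values, float)
    if values.size < 30:
        raise ValueError("need at least 30 points to fit a variogram")
    if np.ptp(values) < 1e-12:
        logger.warning("constant field: returning zero-sill variogram")
        return VariogramModel(family, 0.0, 0.0, 1.0, weak_structure=True)
    emp = empirical_variogram(coords, values, n_lags=n_lags, seed=seed)
    h, g, npairs = emp["lag"].to_numpy(), emp["gamma"].to_numpy(), emp["n_pairs"].to_numpy()

    var = values.var()
    p0 = np.array([0.1 * var + 1e-12, 0.9 * var + 1e-12, max(h.max() / 2, 1e-6)])

    def resid(params):
        nug, psill, rng_ = params
        mod = _gamma_model(family, h, nug, psill, rng_)
        w = np.sqrt(npairs) / np.maximum(mod, 1e-12)
        return w * (g - mod)

    sol = optimize.least_squares(
        resid, p0, bounds=([0.0, 0.0, 1e-9], [np.inf, np.inf, np.inf]), max_nfev=2000
    )
    nug, psill, rng_ = sol.x
    weak = psill < 0.1 * (nug + psill)
    if weak:
        logger.warning("weak spatial structure: nugget dominates the sill")
    return VariogramModel(family, float(nug), float(psill), float(rng_), weak_structure=weak)


# ---------------------------------------------------------------------------
# ordinary kriging
# ---------------------------------------------------------------------------

def krige_points(
    coords: np.ndarray,
    values: np.ndarray,
    targets: np.ndarray,
    variogram: VariogramModel,
    return_weights: bool = False,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Ordinary-kriging prediction at target coordinates.

    Solves the standard OK system with the unbiasedness constraint
    (weights sum to 1, enforced by a Lagrange multiplier):

        [ Gamma  1 ] [ lambda ]   [ gamma_0 ]
        [ 1^T    0 ] [ mu     ] = [ 1       ]

    With zero nugget the predictor is exact at data points.  A singular
    system is retried once with a tiny diagonal jitter, then raises.
    """
    coords = np.asarray(coords, float)
    values = np.asarray(values, float)
    targets = np.asarray(targets, float)
    n = coords.shape[0]
    gamma = variogram(cdist(coords, coords))
    a = np.empty((n + 1, n + 1))
    a[:n, :n] = gamma
    a[:n, n] = 1.0
    a[n, :n] = 1.0
    a[n, n] = 0.0
    b = np.empty((n + 1, targets.shape[0]))
    b[:n, :] = variogram(cdist(coords, targets))
    b[n, :] = 1.0
    try:
        lu = linalg.lu_factor(a)
        sol = linalg.lu_solve(lu, b)
    except (linalg.LinAlgError, ValueError):
        sol = None
    if sol is None or not np.isfinite(sol).all():
        logger.warning("singular kriging system; retrying with diagonal jitter")
        a[:n, :n] += 1e-10 * np.eye(n)
        sol = linalg.solve(a, b)
        if not np.isfinite(sol).all():
            raise linalg.LinAlgError("kriging system singular even after jitter")
    weights = sol[:n, :]  # (n, n_targets)
    preds = weights.T @ values
    if return_weights:
        return preds, weights.T
    return preds


def krige_field(
    along_track_m: np.ndarray,
    depth_m: np.ndarray,
    values: np.ndarray,
    variogram: VariogramModel | None = None,
    grid_dx_m: float = 500.0,
    grid_dz_m: float = 1.0,
    x_extent_m: tuple[float, float] | None = None,
    z_extent_m: tuple[float, float] | None = None,
    family: str = "spherical",
    clip_negative: bool = False,
    units: str = "",
    max_points: int = 2500,
    seed: int = 0,
) -> GriddedField:
    """Krige scattered bin values onto the regular transect grid.

    Coordinates are scaled by the target resolution (x / ``grid_dx_m``,
    z / ``grid_dz_m``) before variogram fitting and kriging so a single
    isotropic variogram acts in scaled space.  Grid cell centers sit at
    ``dx/2 + k*dx`` along-track (250 m + k*500 m at default resolution) and
    ``dz/2 + k*dz`` in depth.  If ``variogram`` is None one is fitted from
    the data.  Negative predictions are clipped to zero (with a logged
    count) when ``clip_negative`` — concentrations cannot be negative.
    """
    x = np.asarray(along_track_m, float)
    z = np.asarray(depth_m, float)
    v = np.asarray(values, float)
    if not (x.size == z.size == v.size):
        raise ValueError("coordinate and value arrays must align")
    if x.size > max_points:
        idx = np.random.default_rng(seed).choice(x.size, max_points, replace=False)
        x, z, v = x[idx], z[idx], v[idx]
    coords = np.column_stack([x / grid_dx_m, z / grid_dz_m])
    if variogram is None:
        variogram = fit_variogram(coords, v, family=family, seed=seed)

    x0, x1 = x_extent_m if x_extent_m is not None else (0.0, x.max())
    z0, z1 = z_extent_m if z_extent_m is not None else (0.0, z.max())
    gx = np.arange(x0 + grid_dx_m / 2, x1, grid_dx_m)
    gz = np.arange(z0 + grid_dz_m / 2, z1, grid_dz_m)
    xx, zz = np.meshgrid(gx / grid_dx_m, gz / grid_dz_m)
    targets = np.column_stack([xx.ravel(), zz.ravel()])

    if variogram.sill == 0:  # constant field: kriging surface is that constant
        preds = np.full(targets.shape[0], v.mean())
    else:
        preds = krige_points(coords, v, targets, variogram)
    if clip_negative:
        neg = preds < 0
        if neg.any():
            logger.info("clipped %d negative prediction(s) to zero", int(neg.sum()))
            preds = np.where(neg, 0.0, preds)
    return GriddedField(gx, gz, preds.reshape(len(gz), len(gx)), units=units)
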