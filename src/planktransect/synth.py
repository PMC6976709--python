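"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators mirror the three data streams of a towed shadowgraph
imaging survey:

* :func:`gen_frames` — planted-blob shadowgraph frames (dark organisms on a
  bright, unevenly lit background) with the true ROI boxes recorded;
* :func:`gen_classified_vignettes` — classifier output tables with a
  controllable fine-class confusion matrix and confidence distributions, so
  per-group precision/recall are tunable and known in closed form;
* :func:`gen_transect` — a transect scenario with a mesoscale eddy embedded
  in a boundary current, giving velocity/hydrography fields, true water-mass
  labels and taxa concentration fields built from known response functions.

All randomness flows from a single seed per spec; child generators are
spawned from it so the three streams are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "BlobClass",
    "SceneSpec",
    "ConfusionSpec",
    "TaxonResponse",
    "TransectSpec",
    "TransectScenario",
    "gen_frames",
    "gen_classified_vignettes",
    "gen_transect",
    "simulate_tow",
    "misclassify_counts",
]


# ---------------------------------------------------------------------------
# frames
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlobClass:
    """Shape parameters of one planted organism class."""

    class_id: int
    axis_major_px: float
    axis_minor_px: float
    contrast: float  # intensity drop in [0, 1] relative to background

    def __post_init__(self) -> None:
        if not (0.0 < self.contrast <= 1.0):
            raise ValueError(f"contrast must be in (0, 1], got {self.contrast}")
        if self.axis_major_px < self.axis_minor_px:
            raise ValueError("axis_major_px must be >= axis_minor_px")


@dataclass(frozen=True)
class SceneSpec:
    """Specification of a stack of synthetic shadowgraph frames."""

    frame_height_px: int = 256
    frame_width_px: int = 256
    n_frames: int = 10
    blob_count_per_frame: float = 5.0  # Poisson mean
    blob_classes: Sequence[BlobClass] = (
        BlobClass(0, 14.0, 6.0, 0.5),
        BlobClass(1, 8.0, 8.0, 0.4),
    )
    illumination_amplitude: float = 0.2  # peak-to-peak multiplicative ramp
    background_level: float = 0.85
    noise_sd: float = 0.02
    edge_blur_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.blob_count_per_frame < 0:
            raise ValueError("blob_count_per_frame must be >= 0")
        for bc in self.blob_classes:
            # padded box must fit fully inside the frame
            ext = 2 * int(np.ceil(bc.axis_major_px + 3 * self.edge_blur_sigma)) + 1
            if ext >= self.frame_height_px or ext >= self.frame_width_px:
                raise ValueError(
                    f"blob class {bc.class_id} (major axis {bc.axis_major_px}px) "
                    f"does not fit in a {self.frame_height_px}x{self.frame_width_px} frame"
                )


def _illumination(spec: SceneSpec) -> np.ndarray:
    """Smooth multiplicative lighting field: a diagonal linear ramp."""
    rows = np.linspace(-0.5, 0.5, spec.frame_height_px)[:, None]
    cols = np.linspace(-0.5, 0.5, spec.frame_width_px)[None, :]
    return 1.0 + spec.illumination_amplitude * (0.7 * cols + 0.3 * rows)


def gen_frames(spec: SceneSpec) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Render planted-blob frames and return them with the truth table.

    Returns
    -------
    frames : list of 2-D float arrays in [0, 1]
    truth : DataFrame with columns ``frame, class_id, row0, col0, row1, col1,
        depth_m, along_track_m, time_s`` — one row per planted blob, boxes
        0-based half-open and fully inside the frame.
    """
    rng = np.random.default_rng(spec.seed)
    illum = _illumination(spec)
    frames: list[np.ndarray] = []
    records: list[dict] = []

    for fi in range(spec.n_frames):
        canvas = np.zeros((spec.frame_height_px, spec.frame_width_px))
        n_blobs = rng.poisson(spec.blob_count_per_frame)
        depth = 3.0 + 0.5 * fi
        along = 12.5 * fi
        for _ in range(n_blobs):
            bc = spec.blob_classes[rng.integers(len(spec.blob_classes))]
            half = int(np.ceil(bc.axis_major_px + 3 * spec.edge_blur_sigma))
            r0 = int(rng.integers(half, spec.frame_height_px - half))
            c0 = int(rng.integers(half, spec.frame_width_px - half))
            theta = rng.uniform(0, np.pi)
            rr, cc = np.mgrid[-half : half + 1, -half : half + 1]
            ca, sa = np.cos(theta), np.sin(theta)
            u = ca * cc + sa * rr
            w = -sa * cc + ca * rr
            ellipse = ((u / bc.axis_major_px) ** 2 + (w / bc.axis_minor_px) ** 2) <= 1.0
            stamp = bc.contrast * ellipse.astype(float)
            canvas[r0 - half : r0 + half + 1, c0 - half : c0 + half + 1] = np.maximum(
                canvas[r0 - half : r0 + half + 1, c0 - half : c0 + half + 1], stamp
            )
            # truth box = tight ellipse bounding box (pre-blur support)
            rows_any = ellipse.any(axis=1).nonzero()[0]
            cols_any = ellipse.any(axis=0).nonzero()[0]
            records.append(
                dict(
                    frame=fi,
                    class_id=bc.class_id,
                    row0=r0 - half + rows_any[0],
                    col0=c0 - half + cols_any[0],
                    row1=r0 - half + rows_any[-1] + 1,
                    col1=c0 - half + cols_any[-1] + 1,
                    depth_m=depth,
                    along_track_m=along,
                    time_s=5.0 * fi,
                )
            )
        if spec.edge_blur_sigma > 0:
            canvas = ndimage.gaussian_filter(canvas, spec.edge_blur_sigma)
        img = spec.background_level * illum * (1.0 - canvas)
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
        frames.append(np.clip(img, 0.0, 1.0))

    cols = ["frame", "class_id", "row0", "col0", "row1", "col1",
            "depth_m", "along_track_m", "time_s"]
    truth = pd.DataFrame.from_records(records, columns=cols)
    return frames, truth


# ---------------------------------------------------------------------------
# classifier outputs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionSpec:
    """Controllable fine-class confusion structure for classifier emulation.

    ``confusion[i, j]`` is P(predicted fine class j | true fine class i);
    rows must be stochastic.  Confidence of the winning class is drawn from
    one of two Beta distributions depending on whether the prediction is
    correct, which makes probability-threshold filtering informative.
    """

    n_fine_classes: int
    n_groups: int
    mapping: tuple[int, ...]  # fine class index -> group index
    confusion: np.ndarray
    class_abundances: np.ndarray  # expected count per true fine class
    beta_correct: tuple[float, float] = (18.0, 3.0)  # mode ~0.89
    beta_incorrect: tuple[float, float] = (7.0, 5.0)  # mode 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        conf = np.asarray(self.confusion, dtype=float)
        ab = np.asarray(self.class_abundances, dtype=float)
        if conf.shape != (self.n_fine_classes, self.n_fine_classes):
            raise ValueError("confusion must be square over fine classes")
        if not np.allclose(conf.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("confusion rows must each sum to 1 (±1e-9)")
        if (conf < 0).any():
            raise ValueError("confusion entries must be non-negative")
        if len(self.mapping) != self.n_fine_classes:
            raise ValueError("mapping must cover every fine class")
        if any(not (0 <= g < self.n_groups) for g in self.mapping):
            raise ValueError("mapping targets must be valid group indices")
        if ab.shape != (self.n_fine_classes,) or (ab < 0).any():
            raise ValueError("class_abundances must be non-negative, one per fine class")
        for a, b in (self.beta_correct, self.beta_incorrect):
            if a <= 0 or b <= 0:
                raise ValueError("Beta parameters must be positive (support must be (0,1))")
        object.__setattr__(self, "confusion", conf)
        object.__setattr__(self, "class_abundances", ab)

    def group_confusion(self) -> np.ndarray:
        """Group-level confusion M[g, h] = P(pred group h | true group g),
        marginalised over the fine-class abundances."""
        m = np.zeros((self.n_groups, self.n_groups))
        mapping = np.asarray(self.mapping)
        w = self.class_abundances
        for g in range(self.n_groups):
            rows = np.where(mapping == g)[0]
            if len(rows) == 0 or w[rows].sum() == 0:
                m[g, g] = 1.0
                continue
            row = (w[rows, None] * self.confusion[rows]).sum(axis=0) / w[rows].sum()
            for h in range(self.n_groups):
                m[g, h] = row[mapping == h].sum()
        return m

    def expected_group_metrics(self) -> pd.DataFrame:
        """Closed-form precision/recall per group implied by the spec.

        Serves as the independent oracle for the empirical metrics computed
        from a generated table.
        """
        mapping = np.asarray(self.mapping)
        n_true_fine = self.class_abundances
        # expected count predicted as fine class j with true fine class i
        joint_fine = n_true_fine[:, None] * self.confusion
        groups = np.arange(self.n_groups)
        rows = []
        for g in groups:
            true_in_g = mapping == g
            pred_in_g = mapping == g
            tp = joint_fine[np.ix_(true_in_g, pred_in_g)].sum()
            fp = joint_fine[np.ix_(~true_in_g, pred_in_g)].sum()
            fn = joint_fine[np.ix_(true_in_g, ~pred_in_g)].sum()
            prec = tp / (tp + fp) if tp + fp > 0 else np.nan
            rec = tp / (tp + fn) if tp + fn > 0 else np.nan
            rows.append(dict(group=g, precision=prec, recall=rec))
        return pd.DataFrame(rows).set_index("group")


def gen_classified_vignettes(
    spec: ConfusionSpec,
    n_total: int | None = None,
    return_prob_vectors: bool = False,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw a table of classified vignettes from a :class:`ConfusionSpec`.

    Each vignette gets a true fine class (drawn with probability proportional
    to ``class_abundances``), a predicted fine class (drawn from the true
    class's confusion row) and a winning-class confidence ``max_prob`` drawn
    from the correct/incorrect Beta distribution.  With
    ``return_prob_vectors=True`` the full simplex is materialised (columns
    ``p0..p{K-1}``) with the remaining mass spread over the losing classes so
    that the argmax is always the predicted class.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    k = spec.n_fine_classes
    if n_total is None:
        n_total = int(round(spec.class_abundances.sum()))
    p_true = spec.class_abundances / spec.class_abundances.sum()
    true = rng.choice(k, size=n_total, p=p_true)

    # vectorised draw from each true class's confusion row via inverse CDF
    cdf = np.cumsum(spec.confusion, axis=1)
    u = rng.random(n_total)
    pred = (u[:, None] > cdf[true]).sum(axis=1)

    correct = pred == true
    a_c, b_c = spec.beta_correct
    a_i, b_i = spec.beta_incorrect
    max_prob = np.where(
        correct,
        rng.beta(a_c, b_c, size=n_total),
        rng.beta(a_i, b_i, size=n_total),
    )
    # winning probability must exceed a uniform split so argmax == pred
    lo = 1.0 / k + 1e-6
    max_prob = np.clip(max_prob, lo, 1.0 - 1e-9)

    out = pd.DataFrame(
        {
            "id": np.arange(n_total),
            "true_fine": true,
            "pred_fine": pred,
            "max_prob": max_prob,
            "depth_m": rng.uniform(3.0, 80.0, n_total),
            "along_track_m": rng.uniform(0.0, 60_000.0, n_total),
        }
    )
    if return_prob_vectors:
        rest = rng.dirichlet(np.ones(k - 1), size=n_total) * (1.0 - max_prob)[:, None]
        # cap losing entries strictly below the winner; push any clipped mass
        # back onto the winner so rows still sum to 1
        cap = np.minimum(rest, max_prob[:, None] * (1.0 - 1e-9))
        deficit = (rest - cap).sum(axis=1)
        probs = np.zeros((n_total, k))
        probs[np.arange(n_total), pred] = max_prob + deficit
        losers = np.ones((n_total, k), dtype=bool)
        losers[np.arange(n_total), pred] = False
        probs[losers] = cap.ravel()
        out["max_prob"] = probs[np.arange(n_total), pred]
        for j in range(k):
            out[f"p{j}"] = probs[:, j]
    return out


# ---------------------------------------------------------------------------
# transect scenario
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaxonResponse:
    """Additive log-concentration response of one taxon to the drivers.

    log E[conc] = base + wm_effect(label) + speed_coef * speed
                  + dist_coef * dist_to_fc + prey_coef * log1p(prey_conc)
    with multiplicative lognormal noise on top.
    """

    name: str
    base_log_conc: float = 1.0
    wm_effects: Mapping[str, float] = field(
        default_factory=lambda: {"FC": 0.0, "IF": 0.5, "ED": 1.0}
    )
    speed_coef: float = -1.0  # per m/s
    dist_coef: float = 0.0  # per km from FC water
    prey: str | None = None
    prey_coef: float = 0.0


@dataclass(frozen=True)
class TransectSpec:
    """An eddy embedded in a boundary current, crossed by one transect."""

    length_km: float = 60.0
    depth_m: float = 80.0
    dx_m: float = 500.0
    dz_m: float = 1.0
    fc_speed: float = 1.0  # m/s
    fc_direction_deg: float = 20.0  # flow-toward, clockwise from north
    eddy_center_km: float = 22.0
    eddy_center_depth_m: float = 40.0
    eddy_radius_km: float = 12.0
    tangential_speed: float = 0.3  # m/s at the eddy rim
    interface_width_km: float = 6.0
    current_noise_sd: float = 0.02  # m/s
    sensor_noise_sd: float = 0.01
    shoaling_amplitude: float = 0.6  # sigma-t units at the interface
    taxa: Sequence[TaxonResponse] = (
        TaxonResponse("oithona", base_log_conc=3.0, speed_coef=-1.5),
        TaxonResponse(
            "larval_fish",
            base_log_conc=0.5,
            wm_effects={"FC": 0.0, "IF": 0.3, "ED": 0.6},
            speed_coef=-1.0,
            prey="oithona",
            prey_coef=0.4,
        ),
    )
    lognormal_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fc_speed < 0 or self.tangential_speed < 0:
            raise ValueError("speeds must be non-negative")
        if self.eddy_radius_km <= 0:
            raise ValueError("eddy radius must be positive")
        outer = self.eddy_radius_km + self.interface_width_km / 2
        if not (0 <= self.eddy_center_km <= self.length_km):
            raise ValueError("eddy center must lie on the transect")
        if self.eddy_center_km - outer <= 0 and self.eddy_center_km + outer >= self.length_km:
            raise ValueError("eddy (plus interface band) must leave boundary-current water on the transect")
        names = [t.name for t in self.taxa]
        if len(set(names)) != len(names):
            raise ValueError("taxa names must be unique")
        for t in self.taxa:
            if t.prey is not None and t.prey not in names:
                raise ValueError(f"prey taxon {t.prey!r} of {t.name!r} not in taxa")


@dataclass
class TransectScenario:
    """Gridded truth for one synthetic transect (depth x along-track)."""

    x_m: np.ndarray  # along-track cell centers, shape (nx,)
    z_m: np.ndarray  # depth cell centers, shape (nz,)
    u: np.ndarray  # zonal velocity m/s, shape (nz, nx)
    v: np.ndarray
    speed: np.ndarray
    labels: np.ndarray  # {'FC','IF','ED'} per cell, shape (nz, nx)
    temperature: np.ndarray
    salinity: np.ndarray
    sigma_t: np.ndarray
    chlorophyll: np.ndarray
    oxygen: np.ndarray
    dist_fc_km: np.ndarray  # true distance to nearest FC cell
    taxa: dict[str, np.ndarray]  # taxon -> concentration field (ind m^-3)
    spec: TransectSpec


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def gen_transect(spec: TransectSpec) -> TransectScenario:
    """Build the full gridded scenario from a :class:`TransectSpec`.

    Flow is solid-body rotation inside the eddy radius and uniform
    boundary-current flow outside, blended smoothly across the interface
    band; hydrography carries an isopycnal-shoaling signature at the
    interface; taxa fields follow the stated additive log-linear response
    functions plus lognormal noise.  True labels, distance-to-FC and the
    response coefficients are returned for recovery tests.
    """
    rng = np.random.default_rng(spec.seed)
    x = np.arange(spec.dx_m / 2, spec.length_km * 1000.0, spec.dx_m)
    z = np.arange(spec.dz_m / 2, spec.depth_m, spec.dz_m)
    nx, nz = len(x), len(z)
    xk = x / 1000.0  # km

    r = xk - spec.eddy_center_km  # signed along-track offset, km
    absr = np.abs(r)
    R, W = spec.eddy_radius_km, spec.interface_width_km

    # blend weight: 0 inside the eddy, 1 in the boundary current, with a
    # plateau at 0.5 across the interface band so the interface is a genuine
    # third (intermediate-speed) flow regime rather than a pure gradient
    wt = W / 5.0  # width of each transition ramp
    w_fc = 0.5 * _smoothstep((absr - (R - W / 2)) / wt) + 0.5 * _smoothstep(
        (absr - (R + W / 2) + wt) / wt
    )

    theta = np.deg2rad(spec.fc_direction_deg)
    u_fc = spec.fc_speed * np.sin(theta)
    v_fc = spec.fc_speed * np.cos(theta)
    # cyclonic (NH) solid-body rotation: meridional flow on a zonal section
    v_eddy = spec.tangential_speed * np.clip(r / R, -1.0, 1.0)

    u1 = w_fc * u_fc
    v1 = w_fc * v_fc + (1.0 - w_fc) * v_eddy
    u = np.broadcast_to(u1, (nz, nx)).copy()
    v = np.broadcast_to(v1, (nz, nx)).copy()
    u += rng.normal(0.0, spec.current_noise_sd, u.shape)
    v += rng.normal(0.0, spec.current_noise_sd, v.shape)
    speed = np.hypot(u, v)

    # truth label = nearest flow regime (ED: w=0, IF: w=0.5, FC: w=1)
    labels1 = np.where(w_fc < 0.25, "ED", np.where(w_fc > 0.75, "FC", "IF"))
    labels = np.broadcast_to(labels1, (nz, nx)).copy()

    # hydrography: linear stratification + gaussian interface bump (shoaling)
    zz = z[:, None]
    bump = np.exp(-((absr - R) ** 2) / (2 * (W / 2) ** 2))[None, :]
    depth_shape = np.clip(zz / spec.depth_m, 0.0, 1.0)
    sigma_t = 22.0 + 0.05 * zz + spec.shoaling_amplitude * bump * (1.0 - depth_shape)
    temperature = 28.0 - 0.12 * zz - 1.5 * bump * (1.0 - depth_shape)
    salinity = 36.0 + 0.004 * zz + 0.15 * bump * (1.0 - depth_shape)
    chl_depth = np.exp(-((zz - 55.0) ** 2) / (2 * 12.0**2))
    chlorophyll = 0.15 + 0.45 * bump * chl_depth
    oxygen = 4.2 + 1.0 * (chlorophyll - 0.15)
    sigma_t = sigma_t + rng.normal(0, spec.sensor_noise_sd, (nz, nx))
    temperature = temperature + rng.normal(0, spec.sensor_noise_sd, (nz, nx))
    salinity = salinity + rng.normal(0, spec.sensor_noise_sd, (nz, nx))
    chlorophyll = np.clip(chlorophyll + rng.normal(0, spec.sensor_noise_sd, (nz, nx)), 0, None)
    oxygen = oxygen + rng.normal(0, spec.sensor_noise_sd, (nz, nx))

    # true distance to FC water (km; vertical term retained but negligible)
    fc_cols = np.where(labels1 == "FC")[0]
    dist1 = np.min(np.abs(xk[:, None] - xk[None, fc_cols]), axis=1)
    dist_fc_km = np.broadcast_to(dist1, (nz, nx)).copy()

    # taxa response surfaces (order respects prey dependencies)
    taxa: dict[str, np.ndarray] = {}
    remaining = list(spec.taxa)
    while remaining:
        progressed = False
        for t in list(remaining):
            if t.prey is not None and t.prey not in taxa:
                continue
            wm = np.vectorize(t.wm_effects.__getitem__)(labels)
            log_mu = (
                t.base_log_conc
                + wm
                + t.speed_coef * speed
                + t.dist_coef * dist_fc_km
            )
            if t.prey is not None and t.prey_coef != 0.0:
                log_mu = log_mu + t.prey_coef * np.log1p(taxa[t.prey])
            noise = rng.normal(0.0, spec.lognormal_sd, (nz, nx))
            taxa[t.name] = np.exp(log_mu + noise)
            remaining.remove(t)
            progressed = True
        if not progressed:  # circular prey definitions
            raise ValueError("circular prey coupling in taxa responses")

    return TransectScenario(
        x_m=x, z_m=z, u=u, v=v, speed=speed, labels=labels,
        temperature=temperature, salinity=salinity, sigma_t=sigma_t,
        chlorophyll=chlorophyll, oxygen=oxygen, dist_fc_km=dist_fc_km,
        taxa=taxa, spec=spec,
    )


# ---------------------------------------------------------------------------
# tow sampling on a scenario
# ---------------------------------------------------------------------------

def simulate_tow(
    scenario: TransectScenario,
    volume_rate_m3_per_s: float = 0.168,
    ship_speed_m_per_s: float = 2.5,
    vertical_speed_m_per_s: float = 0.2,
    depth_range_m: tuple[float, float] = (3.0, 79.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Sample the scenario along an undulating tow path into 1-m depth bins.

    The imager descends and ascends between ``depth_range_m`` while the ship
    advances; each 1-m stratum crossing becomes one bin whose per-taxon count
    is Poisson with mean ``true concentration x imaged volume``.  Sensor
    fields are sampled at the bin midpoint.  Columns: ``along_track_m,
    depth_m`` (stratum floor), ``time_s, imaged_volume_m3``, one count column
    per taxon (``n_<taxon>``), and the sensor values.
    """
    rng = np.random.default_rng(seed)
    zmin, zmax = depth_range_m
    dt_per_m = 1.0 / vertical_speed_m_per_s
    dx_per_m = ship_speed_m_per_s * dt_per_m
    vol = volume_rate_m3_per_s * dt_per_m

    x_max = scenario.x_m[-1] + scenario.spec.dx_m / 2
    records: list[dict] = []
    xpos, t, direction = 0.0, 0.0, +1
    while xpos < x_max:
        if direction > 0:
            strata = np.arange(np.floor(zmin), np.floor(zmax))
        else:
            strata = np.arange(np.floor(zmax) - 1, np.floor(zmin) - 1, -1)
        for s in strata:
            zmid = s + 0.5
            ix = np.clip(
                np.searchsorted(scenario.x_m, xpos) , 0, len(scenario.x_m) - 1
            )
            iz = np.clip(
                np.searchsorted(scenario.z_m, zmid), 0, len(scenario.z_m) - 1
            )
            rec = dict(
                along_track_m=xpos,
                depth_m=float(s),
                time_s=t,
                imaged_volume_m3=vol,
                temperature=scenario.temperature[iz, ix],
                salinity=scenario.salinity[iz, ix],
                sigma_t=scenario.sigma_t[iz, ix],
                chlorophyll=scenario.chlorophyll[iz, ix],
                oxygen=scenario.oxygen[iz, ix],
            )
            for name, fld in scenario.taxa.items():
                rec[f"n_{name}"] = rng.poisson(fld[iz, ix] * vol)
            records.append(rec)
            xpos += dx_per_m
            t += dt_per_m
            if xpos >= x_max:
                break
        direction *= -1
    return pd.DataFrame.from_records(records)


def misclassify_counts(
    bins: pd.DataFrame,
    group_confusion: np.ndarray,
    groups: Sequence[str],
    seed: int = 0,
) -> pd.DataFrame:
    """Scatter true per-bin counts through a group-level confusion matrix.

    Each individual of true group g is predicted as group h with probability
    ``group_confusion[g, h]`` independently; returns a copy of ``bins`` with
    the ``n_<group>`` columns replaced by predicted counts.
    """
    m = np.asarray(group_confusion, float)
    if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("group confusion rows must sum to 1")
    rng = np.random.default_rng(seed)
    out = bins.copy()
    cols = [f"n_{g}" for g in groups]
    true_counts = bins[cols].to_numpy()
    pred_counts = np.zeros_like(true_counts)
    for gi in range(len(groups)):
        scattered = rng.multinomial(true_counts[:, gi], m[gi])
        pred_counts += scattered
    out[cols] = pred_counts
    return out
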