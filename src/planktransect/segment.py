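"""Frame segmentation: flat-fielding, k-harmonic-means foreground detection
and connected-region vignette extraction.

A towed line-scan shadowgraph imager produces frames whose illumination
varies smoothly along the scan line but is stable frame-to-frame, so the
background is estimated as a per-column running mean over a window of frames
and divided out (:func:`flat_field`).  Organisms are darker than the
background; a k-harmonic-means (KHM) clustering of the corrected intensities
separates a dark foreground cluster from the background
(:func:`khm_cluster`), and 8-connected components of the foreground mask
above a minimum area become ROIs (:func:`detect_rois`), which are cropped
into vignettes carrying the frame's depth/along-track/time metadata
(:func:`extract_vignettes`).

KHM minimises the harmonic-mean objective

    KHM(X, C) = sum_i  k / sum_j ||x_i - c_j||^(-p)

which is far less sensitive to initialisation than k-means; ``p > 2`` is
required for the weights to be well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "Frame",
    "ROI",
    "background_profile",
    "flat_field",
    "khm_cluster",
    "detect_rois",
    "extract_vignettes",
]


@dataclass(frozen=True)
class Frame:
    """One grayscale frame with its tow metadata."""

    pixels: np.ndarray  # 2-D, values in [0, 1] (up to 1.5 after flat-fielding)
    depth_m: float = 0.0
    along_track_m: float = 0.0
    time_s: float = 0.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if not np.isfinite(px).all():
            raise ValueError("pixels must be finite")
        if self.depth_m < 0:
            raise ValueError("depth_m must be >= 0")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class ROI:
    """A detected region of interest: 0-based, half-open bounding box."""

    frame_id: int
    row0: int
    col0: int
    row1: int
    col1: int
    area_px: int
    centroid: tuple[float, float]  # (row, col)

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        return (self.row0, self.col0, self.row1, self.col1)


def background_profile(frames: list[np.ndarray] | np.ndarray, window: int = 100) -> np.ndarray:
    """Per-column mean intensity over (up to) the last ``window`` frames.

    The line-scan geometry makes illumination a function of the scan column,
    so the background is one value per column.  Updated causally: callers
    pass the trailing window of already-seen frames.
    """
    stack = np.asarray(frames[-window:], dtype=float)
    if stack.ndim != 3:
        raise ValueError("expected a list/stack of 2-D frames")
    return stack.mean(axis=(0, 1))  # average over frames and rows -> per column


def flat_field(frame: Frame | np.ndarray, profile: np.ndarray) -> Frame:
    """Divide a frame by its per-column background profile.

    Corrected pixels are clipped to [0, 1.5]; a frame identical to its
    background maps to all-ones.  A zero (or negative) background column is
    an error naming the offending column.
    """
    if isinstance(frame, Frame):
        px, meta = frame.pixels, frame
    else:
        px = np.asarray(frame, dtype=float)
        meta = None
    profile = np.asarray(profile, dtype=float)
    if profile.shape != (px.shape[1],):
        raise ValueError(
            f"profile length {profile.shape} does not match frame width {px.shape[1]}"
        )
    bad = np.where(profile <= 0)[0]
    if bad.size:
        raise ValueError(f"background profile is non-positive at column(s) {bad.tolist()}")
    corrected = np.clip(px / profile[None, :], 0.0, 1.5)
    if meta is None:
        return Frame(corrected)
    return Frame(corrected, meta.depth_m, meta.along_track_m, meta.time_s)


def khm_cluster(
    values: np.ndarray,
    k: int = 2,
    p: float = 3.5,
    max_iter: int = 100,
    tol: float = 1e-6,
    init: np.ndarray | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """K-harmonic-means clustering of 1-D values.

    Returns ``(centers, assignments, objective_trace)``.  Centers follow the
    harmonic-mean weighted recursion; because the raw fixed-point step can
    overshoot, each update is backtracked (the step toward the proposed
    centers is halved until the objective does not increase), so the
    recorded objective trace is monotone non-increasing by construction.
    Iteration stops when the objective improves by less than ``tol``
    (relative), after ``max_iter`` sweeps, or when no step length yields an
    improvement.

    Degenerate input (all values identical) collapses to a single effective
    center; the duplicates are flagged by returning identical centers.
    """
    x = np.asarray(values, dtype=float).ravel()
    if k < 2:
        raise ValueError("k must be >= 2")
    if p <= 2:
        raise ValueError("p must be > 2")
    if x.size < k:
        raise ValueError("need at least k values")

    rng = np.random.default_rng(seed)
    if init is not None:
        centers = np.asarray(init, dtype=float).copy()
        if centers.shape != (k,):
            raise ValueError("init must have shape (k,)")
    else:
        # spread initial centers over the value range by quantiles
        qs = (np.arange(k) + 0.5) / k
        centers = np.quantile(x, qs)
        if np.unique(centers).size < k:
            centers = centers + rng.normal(0, 1e-3 * (np.ptp(x) + 1e-12), k)

    eps = 1e-12

    def objective(c: np.ndarray) -> float:
        d = np.abs(x[:, None] - c[None, :]) + eps
        return float(np.sum(k / np.sum(d ** (-p), axis=1)))

    trace = [objective(centers)]
    for _ in range(max_iter):
        d = np.abs(x[:, None] - centers[None, :]) + eps
        dm_p2 = d ** (-p - 2)
        dm_p = d ** (-p)
        denom = dm_p.sum(axis=1)
        # membership * weight, combined:  q_ij = d_ij^(-p-2) / (sum_j d_ij^(-p))^2
        q = dm_p2 / (denom**2)[:, None]
        qsum = q.sum(axis=0)
        proposed = np.where(qsum > 0, (q * x[:, None]).sum(axis=0) / np.maximum(qsum, eps), centers)
        # backtrack toward the current centers until the objective decreases
        alpha, accepted = 1.0, False
        for _try in range(20):
            cand = centers + alpha * (proposed - centers)
            cand_obj = objective(cand)
            if cand_obj <= trace[-1]:
                centers, accepted = cand, True
                trace.append(cand_obj)
                break
            alpha *= 0.5
        if not accepted:
            break
        if trace[-2] - trace[-1] <= tol * max(abs(trace[-2]), 1e-30):
            break

    order = np.argsort(centers)
    centers = centers[order]
    assignments = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
    return centers, assignments, np.asarray(trace)


def detect_rois(
    frame: Frame | np.ndarray,
    k: int = 2,
    p: float = 3.5,
    min_area_px: int = 25,
    max_khm_pixels: int = 20000,
    seed: int = 0,
) -> list[ROI]:
    """Detect dark ROIs in a flat-fielded frame.

    Pixel intensities are clustered with KHM (``k`` clusters, intensity-only
    feature space); the cluster with the lowest center is foreground (dark
    organisms on a bright shadowgraph background).  8-connected components
    of the foreground mask with area >= ``min_area_px`` become ROIs.  For
    large frames the KHM centers are estimated on a random subsample of
    ``max_khm_pixels`` pixels and all pixels are then assigned to the
    nearest center.

    A frame with no intensity structure (uniform) yields no ROIs.
    """
    px = frame.pixels if isinstance(frame, Frame) else np.asarray(frame, float)
    flat = px.ravel()
    if np.ptp(flat) < 1e-9:
        return []
    rng = np.random.default_rng(seed)
    sample = flat if flat.size <= max_khm_pixels else rng.choice(flat, max_khm_pixels, replace=False)
    centers, _, _ = khm_cluster(sample, k=k, p=p, seed=seed)
    # assign every pixel to its nearest center; lowest center = foreground
    assign = np.argmin(np.abs(flat[:, None] - centers[None, :]), axis=1)
    mask = (assign == 0).reshape(px.shape)

    structure = np.ones((3, 3), dtype=int)  # 8-connectivity
    labeled, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return []
    rois: list[ROI] = []
    slices = ndimage.find_objects(labeled)
    areas = ndimage.sum_labels(mask, labeled, index=np.arange(1, n + 1))
    coms = ndimage.center_of_mass(mask, labeled, index=np.arange(1, n + 1))
    fid = 0
    for i, sl in enumerate(slices):
        if areas[i] < min_area_px:
            continue
        rois.append(
            ROI(
                frame_id=fid,
                row0=sl[0].start,
                col0=sl[1].start,
                row1=sl[0].stop,
                col1=sl[1].stop,
                area_px=int(areas[i]),
                centroid=(float(coms[i][0]), float(coms[i][1])),
            )
        )
    return rois


def extract_vignettes(
    frame: Frame,
    rois: list[ROI],
    pad_px: int = 5,
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Crop padded vignettes for each ROI, clipping at frame edges.

    Returns the crops and a manifest carrying each vignette's bounding box
    and the source frame's depth/along-track/time metadata.
    """
    h, w = frame.pixels.shape
    crops: list[np.ndarray] = []
    rows = []
    for i, roi in enumerate(rois):
        r0 = max(roi.row0 - pad_px, 0)
        c0 = max(roi.col0 - pad_px, 0)
        r1 = min(roi.row1 + pad_px, h)
        c1 = min(roi.col1 + pad_px, w)
        crops.append(frame.pixels[r0:r1, c0:c1].copy())
        rows.append(
            dict(
                vignette=i, row0=r0, col0=c0, row1=r1, col1=c1,
                area_px=roi.area_px,
                depth_m=frame.depth_m,
                along_track_m=frame.along_track_m,
                time_s=frame.time_s,
            )
        )
    manifest = pd.DataFrame(
        rows,
        columns=["vignette", "row0", "col0", "row1", "col1", "area_px",
                 "depth_m", "along_track_m", "time_s"],
    )
    return crops, manifest
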