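"""Post-processing of plankton-classifier output tables.

The classifier assigns each vignette a fine class (the argmax of its
probability vector) plus the winning probability ``max_prob``.  Fine classes
are mapped onto broader ecological groups; per-group precision
P = TP/(TP+FP), recall R = TP/(TP+FN) and F1 = 2PR/(P+R) are computed from a
labelled test set; a per-fine-class probability threshold is fitted so that
each group reaches a target precision (vignettes at or below their class
threshold are re-labelled "unknown"); and a correction factor CF = P/R per
group rescales filtered counts toward true abundance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger(__name__)

UNKNOWN = "unknown"

__all__ = [
    "UNKNOWN",
    "ClassMap",
    "harmonic_f1",
    "map_to_groups",
    "confusion_and_metrics",
    "weighted_summary",
    "fit_thresholds",
    "apply_thresholds",
    "correction_factors",
]


def harmonic_f1(precision: float, recall: float) -> float:
    """F1 = 2PR / (P + R), the harmonic mean of precision and recall."""
    if precision + recall == 0:
        return float("nan")
    return 2.0 * precision * recall / (precision + recall)


@dataclass(frozen=True)
class ClassMap:
    """Total mapping from fine classes to broader groups.

    The reserved group :data:`UNKNOWN` may never be the target of a fine
    class; it is produced only by threshold filtering.
    """

    mapping: Mapping[object, object]

    def __post_init__(self) -> None:
        if any(g == UNKNOWN for g in self.mapping.values()):
            raise ValueError(f"{UNKNOWN!r} is reserved and cannot be a mapping target")
        object.__setattr__(self, "mapping", dict(self.mapping))

    def __getitem__(self, fine):
        try:
            return self.mapping[fine]
        except KeyError:
            raise KeyError(f"fine class {fine!r} is not in the class map") from None

    @property
    def groups(self) -> list:
        return sorted(set(self.mapping.values()), key=str)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, fine_col: str = "fine", group_col: str = "group") -> "ClassMap":
        return cls(dict(zip(df[fine_col], df[group_col])))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fine": list(self.mapping), "group": list(self.mapping.values())}
        )


def map_to_groups(labels: pd.Series | np.ndarray, class_map: ClassMap) -> pd.Series:
    """Relabel fine classes to groups; unmapped labels raise, naming the id."""
    s = pd.Series(labels)
    unmapped = set(s.unique()) - set(class_map.mapping)
    if unmapped:
        raise KeyError(f"unmapped fine class(es): {sorted(unmapped, key=str)}")
    return s.map(class_map.mapping)


def confusion_and_metrics(
    vignettes: pd.DataFrame,
    class_map: ClassMap,
    true_col: str = "true_fine",
    pred_col: str = "pred_fine",
    pred_is_group: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group-level confusion matrix and per-group P/R/F1 from a labelled set.

    Parameters
    ----------
    vignettes : table with true and predicted labels; rows whose predicted
        group is :data:`UNKNOWN` count as false negatives for their true
        group (they are never true positives for any group).
    pred_is_group : if True, ``pred_col`` already holds group labels
        (e.g. after :func:`apply_thresholds`).

    Returns
    -------
    confusion : DataFrame (true group x predicted group) of counts.
    metrics : per-group DataFrame with columns ``tp, fp, fn, precision,
        recall, f1, support`` (support = true-label count).  A group with
        TP+FP = 0 has undefined precision, reported as NaN.
    """
    if vignettes[true_col].isna().any():
        raise ValueError("true labels must be present for every vignette")
    true_g = map_to_groups(vignettes[true_col], class_map)
    if pred_is_group:
        pred_g = pd.Series(vignettes[pred_col]).reset_index(drop=True)
        true_g = true_g.reset_index(drop=True)
    else:
        pred_g = map_to_groups(vignettes[pred_col], class_map)

    groups = class_map.groups
    conf = pd.crosstab(true_g, pred_g, dropna=False)
    conf = conf.reindex(index=groups, columns=sorted(set(groups) | set(conf.columns), key=str), fill_value=0)
    conf.index.name = "true_group"
    conf.columns.name = "pred_group"

    rows = []
    for g in groups:
        tp = int(conf.loc[g, g]) if g in conf.columns else 0
        fp = int(conf[g].sum() - tp) if g in conf.columns else 0
        fn = int(conf.loc[g].sum() - tp)
        prec = tp / (tp + fp) if (tp + fp) > 0 else np.nan
        rec = tp / (tp + fn) if (tp + fn) > 0 else np.nan
        if np.isnan(prec) or np.isnan(rec):
            f1 = np.nan
        else:
            f1 = harmonic_f1(prec, rec)
        rows.append(dict(group=g, tp=tp, fp=fp, fn=fn,
                         precision=prec, recall=rec, f1=f1, support=tp + fn))
    metrics = pd.DataFrame(rows).set_index("group")
    return conf, metrics


def weighted_summary(metrics: pd.DataFrame) -> pd.Series:
    """Support-weighted average precision/recall/F1 over groups.

    Groups with an undefined metric are excluded from that metric's mean
    (their support is dropped from the weights).
    """
    out = {}
    for col in ("precision", "recall", "f1"):
        ok = metrics[col].notna() & (metrics["support"] > 0)
        w = metrics.loc[ok, "support"]
        out[col] = float((metrics.loc[ok, col] * w).sum() / w.sum()) if w.sum() else np.nan
    return pd.Series(out)


# ---------------------------------------------------------------------------
# threshold filtering
# ---------------------------------------------------------------------------

def _precision_curve(
    max_prob: np.ndarray, correct: np.ndarray, grid: np.ndarray
) -> np.ndarray:
    """Raw precision of the kept set at each grid threshold (NaN if empty)."""
    prec = np.full(grid.size, np.nan)
    for i, t in enumerate(grid):
        kept = max_prob > t
        n = kept.sum()
        if n:
            prec[i] = correct[kept].mean()
    return prec


def _first_crossing(grid: np.ndarray, smoothed: np.ndarray, target: float) -> float | None:
    ok = np.where(np.nan_to_num(smoothed, nan=-1.0) >= target)[0]
    return float(grid[ok[0]]) if ok.size else None


def fit_thresholds(
    vignettes: pd.DataFrame,
    class_map: ClassMap,
    target_precision: float = 0.90,
    grid_step: float = 0.01,
    loess_span: float = 0.5,
    min_support: int = 20,
    true_col: str = "true_fine",
    pred_col: str = "pred_fine",
) -> pd.DataFrame:
    """Fit a per-fine-class probability threshold reaching a group-level
    precision target.

    For each fine class c (with group g), the precision of g restricted to
    c's vignettes is recomputed over a threshold grid t in {0, step, ...},
    keeping only vignettes with ``max_prob > t``; the precision-vs-t curve is
    smoothed with local (lowess) regression and the threshold is the smallest
    t where the smoothed curve reaches the target.  If the target is never
    reached the class is marked unattainable and its threshold is set to the
    class's maximum observed ``max_prob``, so every such vignette is filtered
    to "unknown" under the strict ``>`` keep rule.

    Classes predicted fewer than ``min_support`` times inherit the threshold
    of their group's pooled curve (a warning is logged).

    Returns a DataFrame indexed by fine class with columns ``threshold,
    attainable, group, n_pred, pooled``.
    """
    if not 0 < target_precision <= 1:
        raise ValueError("target_precision must be in (0, 1]")
    grid = np.arange(0.0, 1.0, grid_step)
    true_g = map_to_groups(vignettes[true_col], class_map).to_numpy()
    pred_fine = vignettes[pred_col].to_numpy()
    pred_g = map_to_groups(vignettes[pred_col], class_map).to_numpy()
    max_prob = vignettes["max_prob"].to_numpy(dtype=float)
    correct_all = true_g == pred_g

    def smooth(prec: np.ndarray) -> np.ndarray:
        valid = ~np.isnan(prec)
        if valid.sum() < 5:
            return prec
        sm = np.full_like(prec, np.nan)
        sm[valid] = lowess(prec[valid], grid[valid], frac=loess_span,
                           return_sorted=False)
        return np.clip(sm, 0.0, 1.0)

    def solve(mask: np.ndarray) -> tuple[float, bool]:
        mp, corr = max_prob[mask], correct_all[mask]
        prec = _precision_curve(mp, corr, grid)
        t = _first_crossing(grid, smooth(prec), target_precision)
        if t is None:
            return float(mp.max()), False
        return t, True

    # pooled per-group curves for low-support classes
    pooled: dict[object, tuple[float, bool]] = {}
    for g in class_map.groups:
        mask = pred_g == g
        if mask.any():
            pooled[g] = solve(mask)

    rows = []
    for fine, g in class_map.mapping.items():
        mask = pred_fine == fine
        n_pred = int(mask.sum())
        if n_pred == 0:
            rows.append(dict(fine=fine, group=g, threshold=0.0, attainable=True,
                             n_pred=0, pooled=False))
            continue
        if n_pred < min_support:
            if g in pooled:
                thr, att = pooled[g]
                logger.warning(
                    "fine class %r has %d predicted vignettes (< %d); "
                    "inheriting pooled threshold of group %r", fine, n_pred, min_support, g,
                )
                rows.append(dict(fine=fine, group=g, threshold=thr, attainable=att,
                                 n_pred=n_pred, pooled=True))
                continue
        thr, att = solve(mask)
        rows.append(dict(fine=fine, group=g, threshold=thr, attainable=att,
                         n_pred=n_pred, pooled=False))
    table = pd.DataFrame(rows).set_index("fine")
    if not table["threshold"].between(0, 1).all():
        raise AssertionError("thresholds must lie in [0, 1]")
    return table


def apply_thresholds(
    vignettes: pd.DataFrame,
    thresholds: pd.DataFrame | Mapping,
    class_map: ClassMap,
    pred_col: str = "pred_fine",
) -> pd.Series:
    """Map vignettes to group labels, re-labelling low-confidence ones unknown.

    A vignette is kept iff ``max_prob > threshold(pred_fine)`` (strict: a
    vignette exactly at its class threshold becomes "unknown"); kept
    vignettes are mapped to their predicted group.
    """
    thr = thresholds["threshold"] if isinstance(thresholds, pd.DataFrame) else pd.Series(thresholds)
    pred = vignettes[pred_col]
    missing = set(pred.unique()) - set(thr.index)
    if missing:
        raise KeyError(f"no threshold for predicted class(es): {sorted(missing, key=str)}")
    t = pred.map(thr).to_numpy(dtype=float)
    keep = vignettes["max_prob"].to_numpy(dtype=float) > t
    groups = map_to_groups(pred, class_map)
    out = groups.where(pd.Series(keep, index=groups.index), UNKNOWN)
    out.name = "group"
    return out


def correction_factors(metrics: pd.DataFrame) -> pd.DataFrame:
    """Per-group abundance correction factor CF = precision / recall.

    Counts of a group classified with precision P and recall R are biased by
    a factor R/P relative to truth, so multiplying by P/R corrects them.
    Groups with zero or undefined recall cannot be corrected: CF is NaN and
    ``correctable`` is False.
    """
    p = metrics["precision"]
    r = metrics["recall"]
    ok = r.notna() & (r > 0) & p.notna()
    cf = pd.Series(np.where(ok, p / r, np.nan), index=metrics.index, name="correction_factor")
    return pd.DataFrame({"correction_factor": cf, "correctable": ok})
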