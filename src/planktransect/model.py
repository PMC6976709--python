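"""Driver attribution for taxa concentration fields.

Two complementary analyses of the gridded transect data:

* :func:`compare_water_masses` — one-way ANOVA of each taxon's concentration
  across water masses, with Tukey HSD pairwise comparisons where the ANOVA
  is significant;
* :class:`TaxonDriverModel` — a random-forest regression of one taxon's
  concentration on the full predictor table (other taxa, current speed and
  direction, distance to boundary-current water, water-mass category and
  hydrographic sensors).  ``fit()`` returns a :class:`TaxonDriverResults`
  carrying the out-of-bag variance explained, both importance measures
  (impurity-based "node purity" and permutation MSE increase), accumulated
  local effects (ALE) curves, and predictor ablation.

ALE is the model-agnostic effect measure used throughout: within quantile
bins of a predictor the model's prediction difference between the bin's
upper and lower boundary is averaged over the observations in the bin (all
other variables untouched), accumulated across bins and centered so the
data-weighted mean effect is zero — robust to correlated predictors, unlike
partial dependence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "compare_water_masses",
    "fit_rf",
    "importance_ranking",
    "compute_ale",
    "ablate_predictor",
    "RFFit",
    "ALECurve",
    "TaxonDriverModel",
    "TaxonDriverResults",
]


# ---------------------------------------------------------------------------
# water-mass comparisons
# ---------------------------------------------------------------------------

def compare_water_masses(
    concentrations: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-way ANOVA per taxon across water masses + Tukey HSD follow-up.

    Parameters
    ----------
    concentrations : one column per taxon, one row per grid cell.
    labels : water-mass label per cell.

    Returns
    -------
    anova : per-taxon DataFrame with ``F, p, n_groups`` (groups with < 2
        observations are dropped and noted in ``groups_used``).
    tukey : long DataFrame of pairwise comparisons (taxon, group1, group2,
        meandiff, p_adj, reject) for taxa whose ANOVA p < alpha.
    """
    lab = np.asarray(labels).ravel()
    rows, pairs = [], []
    for taxon in concentrations.columns:
        y = concentrations[taxon].to_numpy(float)
        groups = [g for g in pd.unique(lab) if (lab == g).sum() >= 2]
        if len(groups) < 2:
            raise ValueError("need at least two water masses with >= 2 observations")
        samples = [y[lab == g] for g in groups]
        f, p = stats.f_oneway(*samples)
        rows.append(dict(taxon=taxon, F=float(f), p=float(p),
                         n_groups=len(groups), groups_used=",".join(map(str, groups))))
        if p < alpha:
            mask = np.isin(lab, groups)
            res = pairwise_tukeyhsd(y[mask], lab[mask], alpha=alpha)
            tbl = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
            for _, r in tbl.iterrows():
                pairs.append(dict(taxon=taxon, group1=r["group1"], group2=r["group2"],
                                  meandiff=float(r["meandiff"]), p_adj=float(r["p-adj"]),
                                  reject=bool(r["reject"])))
    anova = pd.DataFrame(rows).set_index("taxon")
    tukey = pd.DataFrame(pairs, columns=["taxon", "group1", "group2", "meandiff", "p_adj", "reject"])
    return anova, tukey


# ---------------------------------------------------------------------------
# random forest
# ---------------------------------------------------------------------------

def _encode(table: pd.DataFrame, categorical: Sequence[str]) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """One-hot encode categoricals; map original predictor -> design columns."""
    design = pd.get_dummies(table, columns=[c for c in categorical if c in table.columns])
    col_map: dict[str, list[str]] = {}
    for col in table.columns:
        if col in categorical:
            col_map[col] = [c for c in design.columns if c.startswith(f"{col}_")]
        else:
            col_map[col] = [col]
    return design.astype(float), col_map


@dataclass
class RFFit:
    """A fitted random-forest regression with its importance tables."""

    estimator: RandomForestRegressor
    predictors: list[str]
    col_map: dict[str, list[str]] = field(repr=False)
    response: str = ""
    variance_explained: float = float("nan")  # out-of-bag R^2
    importance: pd.DataFrame | None = None  # node_purity + mse_increase per predictor
    seed: int = 0

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        design, _ = _encode(table[self.predictors], [c for c, cols in self.col_map.items() if cols != [c]])
        design = design.reindex(columns=self.estimator.feature_names_in_, fill_value=0.0)
        return self.estimator.predict(design)


def fit_rf(
    table: pd.DataFrame,
    response: str,
    predictors: Sequence[str] | None = None,
    n_trees: int = 500,
    mtry: int = 14,
    categorical: Sequence[str] = ("water_mass",),
    seed: int = 0,
    n_permutation_repeats: int = 5,
    compute_importance: bool = True,
) -> RFFit:
    """Fit the bagged regression-tree ensemble of the driver analysis.

    ``n_trees`` trees, ``mtry`` candidate predictors per split, out-of-bag
    variance explained 1 - MSE_OOB / Var(y).  Categorical predictors are
    one-hot encoded; their importances are summed over the indicator columns
    so the table reports one row per original predictor.  Two importance
    measures: total impurity (node-purity) decrease, and the increase in MSE
    when a predictor is permuted.
    """
    if predictors is None:
        predictors = [c for c in table.columns if c != response]
    predictors = list(predictors)
    if table[predictors + [response]].isna().any().any():
        raise ValueError("predictor table must have no missing values")
    design, col_map = _encode(table[predictors], categorical)
    if mtry > design.shape[1]:
        raise ValueError(
            f"mtry={mtry} exceeds the {design.shape[1]} design columns available"
        )
    y = table[response].to_numpy(float)
    est = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=mtry,
        oob_score=True,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    ).fit(design, y)
    ve = float(est.oob_score_)  # R^2 on out-of-bag samples
    if not compute_importance:
        return RFFit(est, predictors, col_map, response, ve, None, seed)

    mdi = pd.Series(est.feature_importances_, index=design.columns)
    perm = permutation_importance(
        est, design, y,
        scoring="neg_mean_squared_error",
        n_repeats=n_permutation_repeats,
        random_state=seed,
        n_jobs=1,
    )
    pim = pd.Series(perm.importances_mean, index=design.columns)

    rows = []
    for pred in predictors:
        cols = col_map[pred]
        rows.append(dict(predictor=pred,
                         node_purity=float(mdi[cols].sum()),
                         mse_increase=float(pim[cols].sum())))
    importance = pd.DataFrame(rows).set_index("predictor")
    return RFFit(est, predictors, col_map, response, ve, importance, seed)


def importance_ranking(fit: RFFit, top: int | None = None) -> pd.DataFrame:
    """Predictors ordered by importance: MSE reduction first, node purity
    as the tie-break.  ``top`` truncates (e.g. top=5 for the headline set)."""
    imp = fit.importance.sort_values(
        ["mse_increase", "node_purity"], ascending=False
    ).copy()
    imp["rank"] = np.arange(1, len(imp) + 1)
    return imp.head(top) if top else imp


def ablate_predictor(
    table: pd.DataFrame,
    response: str,
    predictor: str,
    predictors: Sequence[str] | None = None,
    n_trees: int = 500,
    mtry: int = 14,
    categorical: Sequence[str] = ("water_mass",),
    seed: int = 0,
) -> dict[str, float]:
    """Refit without one predictor under identical settings and seed.

    Returns ``{'ve_with', 've_without', 'delta'}`` where
    ``delta = ve_with - ve_without`` — the out-of-bag variance explained
    attributable to the predictor on top of all others.  ``mtry`` is capped
    at the number of remaining design columns in the reduced fit.
    """
    if predictors is None:
        predictors = [c for c in table.columns if c != response]
    predictors = list(predictors)
    if predictor not in predictors:
        raise ValueError(f"{predictor!r} is not among the predictors")
    full = fit_rf(table, response, predictors, n_trees, mtry, categorical, seed,
                  compute_importance=False)
    reduced_preds = [p for p in predictors if p != predictor]
    design_cols = _encode(table[reduced_preds], categorical)[0].shape[1]
    reduced = fit_rf(table, response, reduced_preds, n_trees, min(mtry, design_cols),
                     categorical, seed, compute_importance=False)
    return {
        "ve_with": full.variance_explained,
        "ve_without": reduced.variance_explained,
        "delta": full.variance_explained - reduced.variance_explained,
    }


# ---------------------------------------------------------------------------
# accumulated local effects
# ---------------------------------------------------------------------------

@dataclass
class ALECurve:
    """A centered ALE curve for one predictor.

    For continuous predictors ``grid`` holds the bin boundaries and
    ``effect`` the accumulated, centered effect at each boundary; for
    categorical predictors ``grid`` holds the ordered levels and ``effect``
    one centered value per level.  ``counts`` are the data weights used for
    centering.
    """

    predictor: str
    grid: np.ndarray
    effect: np.ndarray
    counts: np.ndarray
    categorical: bool = False

    def interpolate(self, x: np.ndarray) -> np.ndarray:
        if self.categorical:
            lut = {lvl: e for lvl, e in zip(self.grid, self.effect)}
            return np.array([lut[v] for v in x])
        return np.interp(np.asarray(x, float), self.grid, self.effect)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.categorical:
            ax.bar(range(len(self.grid)), self.effect)
            ax.set_xticks(range(len(self.grid)), [str(g) for g in self.grid])
        else:
            ax.plot(self.grid, self.effect)
        ax.axhline(0.0, color="k", lw=0.5)
        ax.set_xlabel(self.predictor)
        ax.set_ylabel("ALE (response units)")
        return ax


def _ks_distance(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) == 0 or len(b) == 0:
        return 1.0
    return float(stats.ks_2samp(a, b).statistic)


def _order_levels(table: pd.DataFrame, predictor: str, levels: list) -> list:
    """Order categorical levels by similarity of the other covariates'
    distributions (mean Kolmogorov distance), nearest-neighbour chained."""
    others = [c for c in table.columns
              if c != predictor and pd.api.types.is_numeric_dtype(table[c])]
    if len(levels) <= 2 or not others:
        return sorted(levels, key=str)
    d = pd.DataFrame(0.0, index=levels, columns=levels)
    for i, la in enumerate(levels):
        for lb in levels[i + 1:]:
            ds = [
                _ks_distance(
                    table.loc[table[predictor] == la, c].to_numpy(float),
                    table.loc[table[predictor] == lb, c].to_numpy(float),
                )
                for c in others
            ]
            d.loc[la, lb] = d.loc[lb, la] = float(np.mean(ds))
    # start from the level with the largest total distance (an extreme)
    current = d.sum(axis=1).idxmax()
    ordering = [current]
    rest = set(levels) - {current}
    while rest:
        current = min(rest, key=lambda l: d.loc[ordering[-1], l])
        ordering.append(current)
        rest.discard(current)
    return ordering


def compute_ale(
    predict_fn: Callable[[pd.DataFrame], np.ndarray],
    table: pd.DataFrame,
    predictor: str,
    n_bins: int = 20,
) -> ALECurve:
    """Accumulated local effects of one predictor on the model prediction.

    Continuous predictors: quantile bin boundaries over the observed range;
    within each bin the prediction difference between the predictor set to
    the bin's upper vs lower boundary (other variables untouched) is
    averaged, the local effects are accumulated across bins, and the curve
    is centered so its data-weighted mean is zero.  Empty bins (duplicate
    quantiles) are merged with their neighbour.  Categorical predictors:
    pairwise effects between consecutive levels of a similarity ordering,
    accumulated and centered by level frequency.
    """
    x = table[predictor]
    if not pd.api.types.is_numeric_dtype(x):
        levels = list(pd.unique(x))
        ordering = _order_levels(table, predictor, levels)
        deltas = [0.0]
        for a, b in zip(ordering[:-1], ordering[1:]):
            sub = table[x.isin([a, b])]
            hi = sub.copy()
            hi[predictor] = b
            lo = sub.copy()
            lo[predictor] = a
            deltas.append(float(np.mean(predict_fn(hi) - predict_fn(lo))))
        eff = np.cumsum(deltas)
        counts = np.array([(x == l).sum() for l in ordering], dtype=float)
        eff = eff - np.average(eff, weights=counts)
        return ALECurve(predictor, np.array(ordering, dtype=object), eff, counts, categorical=True)

    xv = x.to_numpy(float)
    edges = np.unique(np.quantile(xv, np.linspace(0.0, 1.0, n_bins + 1)))
    if edges.size < 2:
        return ALECurve(predictor, edges, np.zeros_like(edges), np.array([len(xv)], float))
    which = np.clip(np.searchsorted(edges, xv, side="right") - 1, 0, edges.size - 2)
    local = np.zeros(edges.size - 1)
    counts = np.zeros(edges.size - 1)
    for j in range(edges.size - 1):
        m = which == j
        counts[j] = m.sum()
        if counts[j] == 0:
            continue  # merged below: zero local effect, weight carried by neighbours
        hi = table.loc[m].copy()
        hi[predictor] = edges[j + 1]
        lo = table.loc[m].copy()
        lo[predictor] = edges[j]
        local[j] = float(np.mean(predict_fn(hi) - predict_fn(lo)))
    eff = np.concatenate([[0.0], np.cumsum(local)])
    # data-weighted centering: each observation sits mid-bin
    mid = 0.5 * (eff[:-1] + eff[1:])
    eff = eff - np.average(mid, weights=np.maximum(counts, 1e-12))
    return ALECurve(predictor, edges, eff, counts)


# ---------------------------------------------------------------------------
# model / results facade
# ---------------------------------------------------------------------------

class TaxonDriverModel:
    """Random-forest driver model of one taxon's concentration.

    A thin, statsmodels-flavoured front end over :func:`fit_rf`: build from
    a predictor table and a response column, call :meth:`fit` to obtain a
    :class:`TaxonDriverResults`.

    Examples
    --------
    >>> m = TaxonDriverModel(table, response="larval_fish")   # doctest: +SKIP
    >>> res = m.fit(seed=0)                                   # doctest: +SKIP
    >>> res.variance_explained                                # doctest: +SKIP
    >>> res.importance(top=5)                                 # doctest: +SKIP
    """

    def __init__(
        self,
        table: pd.DataFrame,
        response: str,
        predictors: Sequence[str] | None = None,
        n_trees: int = 500,
        mtry: int = 14,
        categorical: Sequence[str] = ("water_mass",),
    ) -> None:
        if response not in table.columns:
            raise ValueError(f"response {response!r} not in table")
        self.table = table
        self.response = response
        self.predictors = list(predictors) if predictors is not None else [
            c for c in table.columns if c != response
        ]
        self.n_trees = n_trees
        self.mtry = mtry
        self.categorical = tuple(categorical)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, response: str, **kwargs) -> "TaxonDriverModel":
        return cls(df, response, **kwargs)

    def fit(self, seed: int = 0) -> "TaxonDriverResults":
        rf = fit_rf(self.table, self.response, self.predictors,
                    self.n_trees, self.mtry, self.categorical, seed)
        return TaxonDriverResults(self, rf)


class TaxonDriverResults:
    """Results of a fitted :class:`TaxonDriverModel`."""

    def __init__(self, model: TaxonDriverModel, rf: RFFit) -> None:
        self.model = model
        self.rf = rf

    @property
    def variance_explained(self) -> float:
        """Out-of-bag variance explained, 1 - MSE_OOB / Var(y)."""
        return self.rf.variance_explained

    def predict(self, table: pd.DataFrame | None = None) -> np.ndarray:
        return self.rf.predict(self.model.table if table is None else table)

    def importance(self, top: int | None = None) -> pd.DataFrame:
        return importance_ranking(self.rf, top=top)

    def ale(self, predictor: str, n_bins: int = 20) -> ALECurve:
        tab = self.model.table[self.model.predictors]
        return compute_ale(self.rf.predict, tab, predictor, n_bins=n_bins)

    def ablate(self, predictor: str, seed: int | None = None) -> dict[str, float]:
        m = self.model
        return ablate_predictor(
            m.table, m.response, predictor, m.predictors,
            m.n_trees, m.mtry, m.categorical,
            seed=self.rf.seed if seed is None else seed,
        )

    def summary(self, top: int = 5) -> str:
        m = self.model
        lines = [
            "Taxon driver model (random-forest regression)",
            "=" * 46,
            f"response:            {m.response}",
            f"observations:        {len(m.table)}",
            f"predictors:          {len(m.predictors)}",
            f"trees:               {m.n_trees}",
            f"predictors per split:{m.mtry:>4}",
            f"OOB variance explained: {self.variance_explained:.3f}",
            "",
            f"top {top} predictors (by permutation MSE increase):",
        ]
        imp = self.importance(top=top)
        lines.append(f"{'rank':>4}  {'predictor':<24}{'mse_increase':>14}{'node_purity':>13}")
        for pred, row in imp.iterrows():
            lines.append(
                f"{int(row['rank']):>4}  {pred:<24}{row['mse_increase']:>14.4g}{row['node_purity']:>13.4g}"
            )
        return "\n".join(lines)
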