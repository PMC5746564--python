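"""Random-forest dasymetric population modelling.

The three-step procedure: (i) iterative covariate selection driven by
out-of-bag (OOB) permutation importance, (ii) fitting a bagged ensemble
of unpruned regression trees to admin-unit-level covariate summaries
with log population density as the response, and (iii) dasymetric
redistribution of census counts to pixels using the exponentiated
pixel-level prediction as a density weighting layer.

Bagging is implemented here (around scikit-learn regression trees) so
that each tree's bootstrap membership — and hence its OOB set — is
explicit: the importance statistic needs per-tree OOB errors before and
after permuting one covariate's OOB values, averaged only over the trees
that actually used the covariate as a split variable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import sklearn
from sklearn.tree import DecisionTreeRegressor

from .grids import CovariateStack, ZoneMap

__all__ = [
    "ForestParams",
    "ForestModel",
    "SelectionTrace",
    "zonal_summarize",
    "make_response",
    "build_feature_table",
    "fit_forest",
    "oob_permutation_importance",
    "iterative_covariate_selection",
    "predict_weight_grid",
    "dasymetric_redistribute",
    "variance_explained",
]

log = logging.getLogger(__name__)

DENSITY_FLOOR = 1e-8  # people / km^2 added before the log transform

# covariate kinds summarized as a proportion rather than a mean
_PROPORTION_KINDS = {"binary-extent"}


def zonal_summarize(stack: CovariateStack, zones: ZoneMap) -> pd.DataFrame:
    """Per-admin-unit covariate summaries.

    Continuous covariates are averaged over the unit's valid pixels;
    binary extents become the covered proportion (identical arithmetic —
    the mean of a 0/1 grid — but reported as such).  Units with zero
    valid pixels are dropped with a warning.

    Returns a DataFrame indexed by ``unit_id`` with one column per
    covariate plus ``n_pixels`` and ``area_km2``.
    """
    if stack.shape != zones.labels.shape:
        raise ValueError("stack and zone grids are misaligned")
    valid = stack.mask & zones.mask
    labels = np.where(valid, zones.labels, 0)
    n_max = int(zones.labels.max()) + 1
    counts = np.bincount(labels.ravel(), minlength=n_max)[1:]
    all_ids = np.arange(1, n_max)
    present = np.unique(zones.labels[zones.labels > 0])
    keep = counts[present - 1] > 0
    if not keep.all():
        dropped = present[~keep]
        log.warning("dropping %d unit(s) with no valid pixels: %s",
                    dropped.size, dropped.tolist())
    ids = present[keep]

    cols = {}
    for name in stack.names:
        sums = np.bincount(labels.ravel(), weights=stack.grid(name).ravel(),
                           minlength=n_max)[1:]
        with np.errstate(invalid="ignore", divide="ignore"):
            means = sums / counts
        cols[name] = means[ids - 1]
    out = pd.DataFrame(cols, index=pd.Index(ids, name="unit_id"))
    out["n_pixels"] = counts[ids - 1]
    out["area_km2"] = out["n_pixels"] * zones.pixel_area
    return out


def make_response(census: pd.DataFrame, zones: ZoneMap,
                  floor: float = DENSITY_FLOOR) -> pd.Series:
    """Log population density per admin unit.

    density = count / (pixel_area × valid-pixel count); the response is
    ``ln(density + floor)`` so zero-count units stay finite.  Units that
    have no pixels in the zone map are dropped with a warning.
    """
    if (census["count"] < 0).any():
        raise ValueError("census counts must be non-negative")
    n_max = int(zones.labels.max()) + 1
    counts = np.bincount(zones.labels.ravel(), minlength=n_max)[1:]
    areas = pd.Series(counts * zones.pixel_area,
                      index=np.arange(1, n_max), name="area_km2")
    area = areas.reindex(census["unit_id"].to_numpy())
    missing = area.isna() | (area <= 0)
    if missing.any():
        log.warning("dropping %d census unit(s) with no pixels",
                    int(missing.sum()))
    dens = census.loc[~missing.to_numpy(), "count"].to_numpy() / \
        area[~missing].to_numpy()
    return pd.Series(np.log(dens + floor),
                     index=pd.Index(census.loc[~missing.to_numpy(),
                                               "unit_id"], name="unit_id"),
                     name="log_density")


def build_feature_table(stack: CovariateStack, zones: ZoneMap,
                        census: pd.DataFrame,
                        floor: float = DENSITY_FLOOR
                        ) -> tuple[pd.DataFrame, pd.Series]:
    """Aligned (X, y) at the admin-unit level: summaries and log density."""
    summ = zonal_summarize(stack, zones)
    y = make_response(census, zones, floor=floor)
    ids = summ.index.intersection(y.index)
    X = summ.loc[ids, stack.names]
    return X, y.loc[ids]


@dataclass
class ForestParams:
    """Ensemble settings: regression-forest defaults of the RF literature."""

    n_trees: int = 500
    max_features: int | None = None  # default: max(1, p // 3)
    min_samples_leaf: int = 5
    seed: int = 0

    def mtry(self, p: int) -> int:
        return self.max_features if self.max_features else max(1, p // 3)


@dataclass
class ForestModel:
    """A bagged ensemble with explicit bootstrap membership.

    ``oob_mse`` is the mean squared error of the ensemble-aggregated OOB
    predictions (each unit predicted only by trees not trained on it);
    ``variance_explained`` is the pseudo-R² 100·(1 − oob_mse/Var(y)),
    which may be negative.  ``zero_variance_response`` flags the
    degenerate constant-response case where the pseudo-R² is undefined.
    """

    trees: list[DecisionTreeRegressor]
    oob_indices: list[np.ndarray]
    features_used: list[np.ndarray]
    feature_names: list[str]
    oob_mse: float
    variance_explained: float | None
    zero_variance_response: bool
    params: ForestParams
    oob_prediction: np.ndarray = field(repr=False, default=None)

    @property
    def n_trees(self) -> int:
        return len(self.trees)


def _as_matrix(X: pd.DataFrame | np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(np.asarray(X, dtype=np.float32))


def fit_forest(X: pd.DataFrame, y: pd.Series | np.ndarray,
               params: ForestParams | None = None) -> ForestModel:
    """Fit a bagged forest of unpruned regression trees.

    Each tree is grown on n draws with replacement; the ~1/3 of units
    left out of a tree's bootstrap sample form its OOB set, used for the
    honest error estimate and for permutation importance.
    """
    params = params or ForestParams()
    Xm = _as_matrix(X)
    yv = np.asarray(y, dtype=float)
    n, p = Xm.shape
    if n < max(5, params.min_samples_leaf):
        raise ValueError(f"too few units (n={n}) to fit a forest")
    if p < 1:
        raise ValueError("at least one covariate required")
    if not (np.isfinite(Xm).all() and np.isfinite(yv).all()):
        raise ValueError("non-finite values in the feature table")

    rng = np.random.default_rng(np.random.SeedSequence(entropy=params.seed))
    names = list(X.columns) if isinstance(X, pd.DataFrame) else \
        [f"x{j}" for j in range(p)]

    trees, oob_sets, used = [], [], []
    oob_sum = np.zeros(n)
    oob_cnt = np.zeros(n, dtype=np.int64)
    # inputs are validated once above; skip sklearn's per-tree re-checks
    with sklearn.config_context(assume_finite=True,
                                skip_parameter_validation=True):
        for _ in range(params.n_trees):
            boot = rng.integers(0, n, size=n)
            in_bag = np.zeros(n, dtype=bool)
            in_bag[boot] = True
            oob = np.flatnonzero(~in_bag)
            tree = DecisionTreeRegressor(
                max_features=params.mtry(p),
                min_samples_leaf=params.min_samples_leaf,
                random_state=int(rng.integers(2 ** 31)),
            ).fit(Xm[boot], yv[boot])
            feats = tree.tree_.feature
            used.append(np.unique(feats[feats >= 0]))
            trees.append(tree)
            oob_sets.append(oob)
            if oob.size:
                oob_sum[oob] += tree.tree_.predict(Xm[oob]).ravel()
                oob_cnt[oob] += 1

    covered = oob_cnt > 0
    if not covered.all():
        log.warning("%d unit(s) never out-of-bag; excluded from OOB error",
                    int((~covered).sum()))
    oob_pred = np.full(n, np.nan)
    oob_pred[covered] = oob_sum[covered] / oob_cnt[covered]
    oob_mse = float(np.mean((yv[covered] - oob_pred[covered]) ** 2)) \
        if covered.any() else float("nan")

    var_y = float(np.var(yv))  # population variance, R convention
    if var_y > 0:
        ve = 100.0 * (1.0 - oob_mse / var_y)
        zero_var = False
    else:
        ve = None
        zero_var = True
    return ForestModel(trees=trees, oob_indices=oob_sets, features_used=used,
                       feature_names=names, oob_mse=oob_mse,
                       variance_explained=ve, zero_variance_response=zero_var,
                       params=params, oob_prediction=oob_pred)


def variance_explained(model: ForestModel) -> float | None:
    """Pseudo-R² in percent: 100·(1 − OOB MSE / Var(response)).

    ``None`` when the response had zero variance (flagged on the model).
    """
    return model.variance_explained


def oob_permutation_importance(model: ForestModel,
                               X: pd.DataFrame, y: pd.Series | np.ndarray,
                               seed: int = 0,
                               se_scaled: bool = False) -> pd.DataFrame:
    """Per-covariate average percent increase in OOB MSE (Per.Inc.m.s.e.).

    For every tree that used covariate j as a split variable, the tree's
    OOB MSE is recomputed after permuting j's values within the OOB set;
    the percent increases (e_perm − e)/e are averaged over those trees
    and scaled by 100.  A covariate used by no tree scores exactly 0.
    Trees whose OOB set has fewer than 2 rows, or whose baseline OOB MSE
    is zero, are skipped (with a warning for the former).

    ``se_scaled=True`` instead divides the mean raw increase by its
    standard error over trees (the R-package ``scale=TRUE`` variant);
    the default matches the plain percent-increase definition, which is
    all the rank-based downstream analysis needs.

    Returns a DataFrame with columns ``covariate, per_inc_mse,
    n_trees_used`` sorted by descending importance.
    """
    Xm = _as_matrix(X)
    yv = np.asarray(y, dtype=float)
    n, p = Xm.shape
    names = list(X.columns) if isinstance(X, pd.DataFrame) else \
        model.feature_names
    if names != model.feature_names:
        raise ValueError("table columns do not match the fitted model")

    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(7,)))
    inc_sum = np.zeros(p)
    inc_sq = np.zeros(p)
    n_used = np.zeros(p, dtype=np.int64)
    skipped_small = 0
    for tree, oob, feats in zip(model.trees, model.oob_indices,
                                model.features_used):
        if feats.size == 0:
            continue
        if oob.size < 2:
            skipped_small += 1
            continue
        Xo = Xm[oob]
        yo = yv[oob]
        e_b = float(np.mean((yo - tree.tree_.predict(Xo).ravel()) ** 2))
        # one stacked predict per tree: all permuted copies at once
        perm_rows = np.stack([rng.permutation(oob.size)
                              for _ in range(feats.size)])
        big = np.repeat(Xo[None, :, :], feats.size, axis=0)
        for i, j in enumerate(feats):
            big[i, :, j] = Xo[perm_rows[i], j]
        preds = tree.tree_.predict(
            np.ascontiguousarray(big.reshape(-1, p))).reshape(feats.size, -1)
        e_perm = np.mean((yo[None, :] - preds) ** 2, axis=1)
        if e_b == 0.0:
            continue  # percent increase undefined on a perfect tree
        rel = (e_perm - e_b) / e_b
        inc_sum[feats] += rel
        inc_sq[feats] += rel ** 2
        n_used[feats] += 1
    if skipped_small:
        warnings.warn(f"{skipped_small} tree(s) skipped: OOB set too small "
                      "to permute", stacklevel=2)

    per_inc = np.zeros(p)
    usedmask = n_used > 0
    mean_rel = inc_sum[usedmask] / n_used[usedmask]
    if se_scaled:
        var_rel = inc_sq[usedmask] / n_used[usedmask] - mean_rel ** 2
        se = np.sqrt(np.maximum(var_rel, 0) / n_used[usedmask])
        per_inc[usedmask] = np.where(se > 0, mean_rel / se, mean_rel)
    else:
        per_inc[usedmask] = 100.0 * mean_rel

    out = pd.DataFrame({"covariate": names, "per_inc_mse": per_inc,
                        "n_trees_used": n_used})
    return out.sort_values("per_inc_mse", ascending=False,
                           ignore_index=True)


@dataclass
class SelectionTrace:
    """Record of the iterative covariate-elimination loop."""

    iterations: list[dict] = field(default_factory=list)

    def append(self, iteration: int, covariates: list[str],
               importance: pd.DataFrame, model: ForestModel) -> None:
        self.iterations.append({
            "iteration": iteration,
            "covariates": list(covariates),
            "importance": importance,
            "model": model,
        })

    @property
    def final(self) -> dict:
        return self.iterations[-1]

    @property
    def final_covariates(self) -> list[str]:
        return self.final["covariates"]

    @property
    def final_importance(self) -> pd.DataFrame:
        return self.final["importance"]

    @property
    def final_model(self) -> ForestModel:
        return self.final["model"]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for it in self.iterations:
            df = it["importance"].copy()
            df.insert(0, "iteration", it["iteration"])
            rows.append(df)
        return pd.concat(rows, ignore_index=True)


def iterative_covariate_selection(X: pd.DataFrame, y: pd.Series,
                                  params: ForestParams | None = None,
                                  seed: int = 0) -> SelectionTrace:
    """Drop all negatively-important covariates; refit; repeat.

    The loop stops when no retained covariate has a negative
    Per.Inc.m.s.e. or when a single covariate remains.  Each iteration
    gets a fresh seed derived deterministically from ``seed``.
    """
    if X.shape[1] < 1:
        raise ValueError("at least one covariate required")
    params = params or ForestParams()
    cols = list(X.columns)
    trace = SelectionTrace()
    iteration = 0
    while True:
        it_seed = int(np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(iteration,))
        ).integers(2 ** 31))
        it_params = ForestParams(n_trees=params.n_trees,
                                 max_features=params.max_features,
                                 min_samples_leaf=params.min_samples_leaf,
                                 seed=it_seed)
        model = fit_forest(X[cols], y, it_params)
        imp = oob_permutation_importance(model, X[cols], y, seed=it_seed)
        trace.append(iteration, cols, imp, model)
        negative = imp.loc[imp["per_inc_mse"] < 0, "covariate"].tolist()
        if not negative or len(cols) == 1:
            break
        remaining = [c for c in cols if c not in negative]
        if not remaining:  # everything negative: keep the least bad one
            remaining = [imp.iloc[0]["covariate"]]
        log.info("iteration %d: dropping %s", iteration, negative)
        cols = remaining
        if len(cols) == 1:
            it_seed = int(np.random.default_rng(
                np.random.SeedSequence(entropy=seed,
                                       spawn_key=(iteration + 1,))
            ).integers(2 ** 31))
            final_params = ForestParams(n_trees=params.n_trees,
                                        max_features=params.max_features,
                                        min_samples_leaf=params.min_samples_leaf,
                                        seed=it_seed)
            model = fit_forest(X[cols], y, final_params)
            imp = oob_permutation_importance(model, X[cols], y, seed=it_seed)
            trace.append(iteration + 1, cols, imp, model)
            break
        iteration += 1
    return trace


def _ensemble_predict(model: ForestModel, Xm: np.ndarray) -> np.ndarray:
    pred = np.zeros(Xm.shape[0])
    for tree in model.trees:
        pred += tree.tree_.predict(Xm).ravel()
    return pred / len(model.trees)


def predict_weight_grid(model: ForestModel,
                        stack: CovariateStack) -> np.ndarray:
    """Pixel-level density weighting layer.

    Predicts log density at every valid pixel from the pixel's covariate
    values and exponentiates, giving a strictly positive weight; nodata
    pixels get weight 0.  (The model is trained on zonal summaries and
    applied to pixels — the scale mismatch is inherent to the method.)
    """
    missing = [n for n in model.feature_names if n not in stack.names]
    if missing:
        raise ValueError(f"stack lacks model covariates: {missing}")
    rows, cols = stack.shape
    valid = stack.mask
    Xpix = np.column_stack([stack.grid(n)[valid]
                            for n in model.feature_names])
    weights = np.zeros((rows, cols))
    if Xpix.shape[0]:
        weights[valid] = np.exp(_ensemble_predict(model, _as_matrix(Xpix)))
    return weights


def dasymetric_redistribute(weights: np.ndarray, zones: ZoneMap,
                            census: pd.DataFrame) -> np.ndarray:
    """Redistribute census counts to pixels proportionally to weights.

    ``pop[pixel] = count[zone] * w[pixel] / sum(w over zone)``.  Zones
    whose weights sum to zero fall back to uniform allocation over their
    valid pixels, so per-zone sums always equal the census counts.
    Returns a people-per-pixel grid (0 outside zones).
    """
    weights = np.asarray(weights, dtype=float)
    if weights.shape != zones.labels.shape:
        raise ValueError("weight and zone grids are misaligned")
    labels = zones.labels
    n_max = int(labels.max()) + 1
    counts_map = dict(zip(census["unit_id"].to_numpy(),
                          census["count"].to_numpy()))
    present = set(np.unique(labels[labels > 0]).tolist())
    absent = [u for u in counts_map if u not in present]
    if absent:
        raise ValueError(f"census unit(s) {absent} absent from zone map")

    w = np.where(labels > 0, weights, 0.0)
    wsum = np.bincount(labels.ravel(), weights=w.ravel(), minlength=n_max)
    npix = np.bincount(labels.ravel(), minlength=n_max)

    count_arr = np.zeros(n_max)
    for uid, cnt in counts_map.items():
        count_arr[uid] = cnt

    # per-zone scale for weighted allocation; uniform fallback where w==0
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(wsum > 0, count_arr / np.where(wsum > 0, wsum, 1),
                         0.0)
        uniform = np.where((wsum == 0) & (npix > 0),
                           count_arr / np.where(npix > 0, npix, 1), 0.0)
    pop = w * scale[labels]
    fallback_zones = (wsum == 0) & (count_arr > 0) & (npix > 0)
    if fallback_zones.any():
        log.info("uniform fallback in %d zero-weight zone(s)",
                 int(fallback_zones.sum()))
        pop += np.where(fallback_zones[labels], uniform[labels], 0.0)
    pop[labels == 0] = 0.0
    return pop
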