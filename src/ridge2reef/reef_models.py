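"""Boosted-tree reef indicator models.

Per-indicator Gaussian boosted regression trees, tuned by ten-fold
cross-validation over learning rate, tree complexity, and bag fraction,
with stagewise selection of the tree count.  Benthic indicators (% cover,
square-root transformed) are fitted first; fish indicators (kg/ha, fourth
root) additionally use benthic covers as predictors and consume predicted
benthic maps at prediction time.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import map_coordinates
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.model_selection import KFold

from ridge2reef.core_io.config import BrtConfig
from ridge2reef.core_io.grid import Grid, PointTable

BENTHIC_INDICATORS = ("cca", "coral", "macroalgae", "turf")
FISH_INDICATORS = ("browsers", "grazers", "scrapers", "predators")

SQRT = "sqrt"
FOURTH_ROOT = "fourth_root"


def transform_response(y: np.ndarray, tag: str) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if np.nanmin(y) < 0:
        raise ValueError("responses must be nonnegative before transforming")
    if tag == SQRT:
        return np.sqrt(y)
    if tag == FOURTH_ROOT:
        return y**0.25
    raise ValueError(f"unknown transform {tag!r}")


def back_transform(z: np.ndarray, tag: str) -> np.ndarray:
    z = np.maximum(np.asarray(z, dtype=float), 0.0)
    if tag == SQRT:
        return z**2
    if tag == FOURTH_ROOT:
        return z**4
    raise ValueError(f"unknown transform {tag!r}")


@dataclass
class ModelTable:
    """Per-survey response and predictor values for one indicator."""

    indicator: str
    transform: str
    frame: pd.DataFrame  # columns: response + predictors
    predictors: list[str]
    x: np.ndarray
    y: np.ndarray

    @property
    def response(self) -> np.ndarray:
        return self.frame[self.indicator].to_numpy(dtype=float)

    def digest(self) -> str:
        payload = self.frame[[self.indicator] + self.predictors].to_csv().encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class FittedIndicatorModel:
    indicator: str
    transform: str
    predictors: list[str]
    learning_rate: float
    tree_complexity: int
    bag_fraction: float
    n_trees: int
    pde: float
    cv_pde: float
    relative_influence: dict[str, float]
    response_curves: pd.DataFrame  # columns: predictor, x, partial
    training_digest: str
    estimator: GradientBoostingRegressor = field(repr=False, default=None)

    def curve_direction(self, predictor: str) -> int:
        """Sign of the fitted partial-dependence trend (+1, −1, or 0)."""
        sub = self.response_curves[self.response_curves["predictor"] == predictor]
        if len(sub) < 2:
            return 0
        slope = np.polyfit(sub["x"].to_numpy(), sub["partial"].to_numpy(), 1)[0]
        span = sub["partial"].max() - sub["partial"].min()
        if span <= 1e-12:
            return 0
        return int(np.sign(slope))


# ---------------------------------------------------------------------------
# Sampling and filtering
# ---------------------------------------------------------------------------


def bilinear_sample(grid: Grid, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Weighted average of the four nearest cell centers (nearest neighbor
    for class grids).

    Nodata neighbors drop out and the remaining weights renormalize, so
    points near a coverage edge stay usable; NaN only where all four
    neighbors are nodata or the point is off-grid.
    """
    col = (np.asarray(x, float) - grid.origin[0]) / grid.cell_size - 0.5
    row = (grid.origin[1] - np.asarray(y, float)) / grid.cell_size - 0.5
    if grid.is_class_grid:
        return map_coordinates(
            grid.values.astype(float), [row, col], order=0,
            mode="constant", cval=np.nan,
        )
    nrow, ncol = grid.shape
    r0 = np.floor(row).astype(int)
    c0 = np.floor(col).astype(int)
    fr = row - r0
    fc = col - c0
    num = np.zeros(len(r0))
    den = np.zeros(len(r0))
    vals = grid.values.astype(float)
    for dr, dc, w in (
        (0, 0, (1 - fr) * (1 - fc)),
        (0, 1, (1 - fr) * fc),
        (1, 0, fr * (1 - fc)),
        (1, 1, fr * fc),
    ):
        rr = r0 + dr
        cc = c0 + dc
        ok = (rr >= 0) & (rr < nrow) & (cc >= 0) & (cc < ncol)
        v = np.full(len(r0), np.nan)
        v[ok] = vals[rr[ok], cc[ok]]
        good = np.isfinite(v)
        num[good] += w[good] * v[good]
        den[good] += w[good]
    with np.errstate(invalid="ignore"):
        return np.where(den > 1e-12, num / den, np.nan)


def sample_predictors(
    grids: dict[str, Grid],
    surveys: PointTable,
    max_dropped_frac: float = 0.10,
) -> pd.DataFrame:
    """Sample every predictor grid at the survey coordinates.

    Rows with nodata in any predictor are dropped with a warning; losing
    more than ``max_dropped_frac`` of rows signals misaligned inputs.
    """
    out = surveys.to_frame()
    for name, grid in grids.items():
        out[name] = bilinear_sample(grid, surveys.x, surveys.y)
    pred_cols = list(grids)
    good = out[pred_cols].notna().all(axis=1)
    n_drop = int((~good).sum())
    if n_drop:
        warnings.warn(f"dropped {n_drop} survey rows with nodata predictors",
                      stacklevel=2)
    if len(out) and n_drop / len(out) > max_dropped_frac:
        raise ValueError(
            f"{n_drop}/{len(out)} survey rows fell on nodata predictors; "
            "inputs are likely misaligned"
        )
    return out[good].reset_index(drop=True)


def filter_correlated(
    frame: pd.DataFrame, predictors: list[str], r_max: float = 0.7
) -> list[str]:
    """Greedy de-correlation: while any pair exceeds ``r_max`` in absolute
    Pearson correlation, drop the member with the larger mean absolute
    correlation to all remaining predictors (deterministic order)."""
    if len(predictors) < 2:
        raise ValueError("need at least two predictors")
    kept = list(predictors)
    while True:
        corr = frame[kept].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        if np.nanmax(corr) <= r_max:
            break
        i, j = np.unravel_index(np.nanargmax(corr), corr.shape)
        i, j = sorted((int(i), int(j)))
        mean_i = np.nanmean(corr[i])
        mean_j = np.nanmean(corr[j])
        drop = kept[j] if mean_j >= mean_i else kept[i]
        kept.remove(drop)
        if len(kept) < 2:
            raise ValueError("fewer than two predictors survive the r filter")
    return kept


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _cv_deviance_curve(
    X: np.ndarray,
    z: np.ndarray,
    lr: float,
    tc: int,
    bag: float,
    config: BrtConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean held-out squared-error per tree count, plus the held-out
    predictions at each stage (for CV PDE)."""
    kf = KFold(n_splits=config.folds, shuffle=True, random_state=config.seed)
    n = len(z)
    sse = np.zeros(config.max_trees)
    stage_preds = np.zeros((config.max_trees, n))
    for fold, (tr, va) in enumerate(kf.split(X)):
        est = GradientBoostingRegressor(
            loss="squared_error",
            learning_rate=lr,
            n_estimators=config.max_trees,
            max_depth=tc,
            subsample=bag,
            random_state=config.seed + fold,
        )
        est.fit(X[tr], z[tr])
        for s, pred in enumerate(est.staged_predict(X[va])):
            sse[s] += np.sum((z[va] - pred) ** 2)
            stage_preds[s, va] = pred
    return sse / n, stage_preds


def fit_brt(table: ModelTable, config: BrtConfig | None = None) -> FittedIndicatorModel:
    """Tune and fit one indicator model.

    For every (lr, tc, bag) combination, trees are grown stagewise and the
    tree count minimizing mean CV deviance is selected; the combination with
    the highest CV PDE wins (ties break toward smaller tree complexity,
    then smaller learning rate).  The final model is refit on all rows.
    """
    config = config or BrtConfig()
    z = transform_response(table.response, table.transform)
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite response values")
    X = table.frame[table.predictors].to_numpy(dtype=float)
    if len(z) < 5 * config.folds:
        raise ValueError(
            f"need at least {5 * config.folds} rows for {config.folds}-fold CV"
        )
    null_dev = float(np.sum((z - z.mean()) ** 2))
    degenerate = null_dev <= 1e-12

    best = None  # (cv_pde, -tc, -lr, bag, n_trees, cv_preds)
    for lr in config.learning_rates:
        for tc in config.tree_complexities:
            for bag in config.bag_fractions:
                if degenerate:
                    continue
                dev, stage_preds = _cv_deviance_curve(X, z, lr, tc, bag, config)
                n_trees = int(np.argmin(dev)) + 1
                cv_sse = dev[n_trees - 1] * len(z)
                cv_pde = 1.0 - cv_sse / null_dev
                key = (cv_pde, -tc, -lr, bag)
                if best is None or key > best[0]:
                    best = (key, lr, tc, bag, n_trees, stage_preds[n_trees - 1])

    if degenerate or best is None:
        # constant response: null model
        lr, tc, bag, n_trees = config.learning_rates[0], 1, config.bag_fractions[0], 1
        cv_pde, pde = 0.0, 0.0
        est = GradientBoostingRegressor(
            loss="squared_error", learning_rate=lr, n_estimators=1,
            max_depth=1, subsample=bag, random_state=config.seed,
        ).fit(X, z)
        influence = {p: 100.0 / len(table.predictors) for p in table.predictors}
        warnings.warn(f"{table.indicator}: constant response; null model fitted",
                      stacklevel=2)
    else:
        _, lr, tc, bag, n_trees, cv_pred = best
        cv_pde = best[0][0]
        est = GradientBoostingRegressor(
            loss="squared_error", learning_rate=lr, n_estimators=n_trees,
            max_depth=tc, subsample=bag, random_state=config.seed,
        ).fit(X, z)
        resid = z - est.predict(X)
        pde = 1.0 - float(np.sum(resid**2)) / null_dev
        imp = est.feature_importances_
        total = imp.sum()
        if total <= 0:
            influence = {p: 100.0 / len(table.predictors) for p in table.predictors}
        else:
            influence = {
                p: 100.0 * float(v) / total
                for p, v in zip(table.predictors, imp)
            }

    curves = partial_dependence_curves(est, X, table.predictors)
    return FittedIndicatorModel(
        indicator=table.indicator,
        transform=table.transform,
        predictors=list(table.predictors),
        learning_rate=lr,
        tree_complexity=tc,
        bag_fraction=bag,
        n_trees=n_trees,
        pde=float(pde),
        cv_pde=float(cv_pde),
        relative_influence=influence,
        response_curves=curves,
        training_digest=table.digest(),
        estimator=est,
    )


def partial_dependence_curves(
    est: GradientBoostingRegressor,
    X: np.ndarray,
    predictors: list[str],
    n_points: int = 100,
) -> pd.DataFrame:
    """Per-predictor partial dependence evaluated at quantile-spaced points."""
    rows = []
    for j, name in enumerate(predictors):
        qs = np.linspace(0.0, 1.0, n_points)
        xs = np.unique(np.quantile(X[:, j], qs))
        for xv in xs:
            Xj = X.copy()
            Xj[:, j] = xv
            rows.append({"predictor": name, "x": float(xv),
                         "partial": float(est.predict(Xj).mean())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def moran_residuals(
    residuals: np.ndarray, x: np.ndarray, y: np.ndarray
) -> tuple[float, float]:
    """Moran's I with row-standardized inverse-distance weights and the
    normal-approximation p-value (two-sided)."""
    z = np.asarray(residuals, dtype=float)
    n = len(z)
    if n < 10:
        raise ValueError("need at least 10 points for Moran's I")
    dx = np.subtract.outer(np.asarray(x, float), np.asarray(x, float))
    dy = np.subtract.outer(np.asarray(y, float), np.asarray(y, float))
    d = np.hypot(dx, dy)
    off = ~np.eye(n, dtype=bool)
    if np.any(d[off] == 0):
        raise ValueError("coincident coordinates collapse the weight matrix")
    w = np.zeros((n, n))
    w[off] = 1.0 / d[off]
    w /= w.sum(axis=1, keepdims=True)
    zc = z - z.mean()
    s0 = w.sum()
    i_stat = (n / s0) * float(zc @ w @ zc) / float(zc @ zc)
    e_i = -1.0 / (n - 1)
    s1 = 0.5 * np.sum((w + w.T) ** 2)
    s2 = np.sum((w.sum(axis=1) + w.sum(axis=0)) ** 2)
    b2 = n * np.sum(zc**4) / (np.sum(zc**2) ** 2)
    var_num = n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2) - b2 * (
        (n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2
    )
    var_den = (n - 1) * (n - 2) * (n - 3) * s0**2
    var_i = var_num / var_den - e_i**2
    zscore = (i_stat - e_i) / np.sqrt(var_i)
    p = 2.0 * stats.norm.sf(abs(zscore))
    return float(i_stat), float(p)


# ---------------------------------------------------------------------------
# Hierarchy and prediction
# ---------------------------------------------------------------------------


def build_model_table(
    frame: pd.DataFrame,
    indicator: str,
    predictors: list[str],
    transform: str,
) -> ModelTable:
    cols = [indicator] + predictors
    sub = frame.dropna(subset=cols).reset_index(drop=True)
    return ModelTable(
        indicator=indicator,
        transform=transform,
        frame=sub[cols + [c for c in ("x", "y") if c in sub.columns]],
        predictors=list(predictors),
        x=sub["x"].to_numpy(float) if "x" in sub.columns else np.array([]),
        y=sub["y"].to_numpy(float) if "y" in sub.columns else np.array([]),
    )


def fit_hierarchy(
    survey_frame: pd.DataFrame,
    driver_names: list[str],
    config: BrtConfig | None = None,
    r_max: float = 0.7,
    benthic_indicators: tuple[str, ...] = BENTHIC_INDICATORS,
    fish_indicators: tuple[str, ...] = FISH_INDICATORS,
) -> dict[str, FittedIndicatorModel]:
    """Fit all benthic models, then fish models with observed benthic covers
    as extra predictors."""
    config = config or BrtConfig()
    kept = filter_correlated(survey_frame, list(driver_names), r_max)
    models: dict[str, FittedIndicatorModel] = {}
    for ind in benthic_indicators:
        table = build_model_table(survey_frame, ind, kept, SQRT)
        models[ind] = fit_brt(table, config)
    missing = [b for b in benthic_indicators if b not in models]
    if missing:
        raise ValueError(f"missing benthic models: {missing}")
    fish_predictors = kept + list(benthic_indicators)
    for ind in fish_indicators:
        table = build_model_table(survey_frame, ind, fish_predictors, FOURTH_ROOT)
        models[ind] = fit_brt(table, config)
    return models


def predict_map(
    model: FittedIndicatorModel,
    grids: dict[str, Grid],
    max_depth: float = 22.0,
) -> Grid:
    """Evaluate the model cell-by-cell over the reef domain (depth ≤
    ``max_depth``), invert the transform, and clip to the valid range."""
    missing = [p for p in model.predictors if p not in grids]
    if missing:
        raise KeyError(f"predictor grids missing for {model.indicator}: {missing}")
    ref = grids[model.predictors[0]]
    domain = np.ones(ref.shape, dtype=bool)
    if "depth" in grids:
        depth_vals = grids["depth"].values
        domain &= np.isfinite(depth_vals) & (depth_vals <= max_depth)
    cols = []
    for p in model.predictors:
        ref.require_aligned(grids[p], "predictor grids")
        vals = grids[p].values.astype(float)
        domain &= np.isfinite(vals)
        cols.append(vals)
    X = np.column_stack([c[domain] for c in cols])
    out = np.full(ref.shape, np.nan)
    if len(X):
        z = model.estimator.predict(X)
        vals = back_transform(z, model.transform)
        if model.indicator in BENTHIC_INDICATORS:
            vals = np.clip(vals, 0.0, 100.0)
        else:
            vals = np.maximum(vals, 0.0)
        out[domain] = vals
    return ref.like(out)


def evaluate_predictions(
    predicted: Grid, surveys: PointTable, indicator: str
) -> tuple[float, float]:
    """OLS of observed on bilinear-sampled predictions: (R², slope p-value)."""
    pred = bilinear_sample(predicted, surveys.x, surveys.y)
    obs = surveys.attributes[indicator].to_numpy(dtype=float)
    good = np.isfinite(pred) & np.isfinite(obs)
    if good.sum() < 10:
        raise ValueError("need >= 10 survey points inside the map domain")
    if np.std(pred[good]) <= 1e-12:
        warnings.warn("zero-variance predictions; R² is 0 by definition",
                      stacklevel=2)
        return 0.0, 1.0
    res = stats.linregress(pred[good], obs[good])
    return float(res.rvalue**2), float(res.pvalue)
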