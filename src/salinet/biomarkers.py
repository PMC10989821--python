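"""Random-forest salinity biomarkers.

A regression forest is refit many times with distinct seeds; taxa are
ranked by their average out-of-bag permutation importance (the increase in
OOB mean-squared error when a feature is permuted, the randomForest-style
importance).  The number of biomarkers to keep is chosen from a repeated
k-fold cross-validation error curve over increasing prefixes of the
ranking, using the one-standard-error rule: the smallest prefix whose mean
CV error is within one SE of the curve's minimum.  Selected biomarkers are
then labelled as low-salinity colonizers (significant negative abundance
trend vs salinity), high-salinity colonizers (significant positive trend),
or complex (no significant monotone trend).

`SalinityBiomarkerSelector` packages the procedure as a scikit-learn
estimator; the module-level functions are thin wrappers over it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import RepeatedKFold

from .gradient import linear_trend

LOW = "low_salinity"
HIGH = "high_salinity"
COMPLEX = "complex"


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])


def _oob_permutation_importance(
    forest: RandomForestRegressor, X: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Per-feature mean (over trees) increase in OOB MSE when the feature is
    permuted among each tree's out-of-bag samples."""
    n, p = X.shape
    imp = np.zeros(p)
    used = np.zeros(p)
    for tree, sampled in zip(forest.estimators_, forest.estimators_samples_):
        oob = np.setdiff1d(np.arange(n), sampled)
        if oob.size < 2:
            continue
        xo = X[oob]
        yo = y[oob]
        base_mse = float(np.mean((tree.predict(xo) - yo) ** 2))
        # batched predicts per tree: stack a permuted copy per feature,
        # chunked so memory stays modest for wide tables
        chunk = max(1, min(p, 20_000_000 // (8 * oob.size * p)))
        for start in range(0, p, chunk):
            feats = range(start, min(start + chunk, p))
            stacked = np.tile(xo, (len(feats), 1))
            for k, j in enumerate(feats):
                stacked[k * oob.size : (k + 1) * oob.size, j] = xo[
                    rng.permutation(oob.size), j
                ]
            preds = tree.predict(stacked).reshape(len(feats), oob.size)
            imp[list(feats)] += ((preds - yo) ** 2).mean(axis=1) - base_mse
        used += 1
    if (used == 0).any():
        raise RuntimeError("no out-of-bag samples; increase the sample size")
    return imp / used


class SalinityBiomarkerSelector(BaseEstimator):
    """Rank taxa by averaged OOB permutation importance of a regression
    forest predicting salinity, select how many to keep by repeated-CV with
    the one-SE rule, and label the selected biomarkers by the sign of their
    abundance-vs-salinity trend.

    Parameters
    ----------
    n_iterations : forest refits averaged for the ranking.
    n_estimators : trees per forest.
    cv_folds, cv_repeats : the repeated k-fold scheme for the error curve.
    n_grid : candidate biomarker counts (default: 1..min(20, n_features)).
    alpha : significance level for the colonizer labels.
    random_state : seed for all stochastic steps.

    Attributes (after fit)
    ----------------------
    ranking_ : list of feature names, descending mean importance.
    importances_ : pd.Series of mean importances, aligned with ranking_.
    cv_error_curve_ : DataFrame (n_top, mean_error, se).
    selected_n_ : chosen biomarker count.
    biomarkers_ : the selected_n_ top-ranked feature names.
    colonizer_labels_ : dict feature -> low_salinity | high_salinity | complex.
    """

    def __init__(
        self,
        n_iterations: int = 1000,
        n_estimators: int = 500,
        cv_folds: int = 10,
        cv_repeats: int = 5,
        n_grid=None,
        alpha: float = 0.05,
        random_state: int | None = None,
    ):
        self.n_iterations = n_iterations
        self.n_estimators = n_estimators
        self.cv_folds = cv_folds
        self.cv_repeats = cv_repeats
        self.n_grid = n_grid
        self.alpha = alpha
        self.random_state = random_state

    # -- pipeline pieces ----------------------------------------------------
    def _rank(self, X: pd.DataFrame, y: np.ndarray, rng: np.random.Generator) -> None:
        xv = X.to_numpy(dtype=float)
        total = np.zeros(X.shape[1])
        for _ in range(self.n_iterations):
            forest = RandomForestRegressor(
                n_estimators=self.n_estimators,
                random_state=int(rng.integers(2**31 - 1)),
                n_jobs=1,
            )
            forest.fit(xv, y)
            total += _oob_permutation_importance(forest, xv, y, rng)
        mean_imp = pd.Series(total / self.n_iterations, index=X.columns)
        mean_imp = mean_imp.sort_values(ascending=False, kind="mergesort")
        self.importances_ = mean_imp
        self.ranking_ = list(mean_imp.index)

    def _cv_curve(self, X: pd.DataFrame, y: np.ndarray, rng: np.random.Generator) -> None:
        if len(y) < self.cv_folds:
            raise ValueError(f"fewer samples ({len(y)}) than CV folds ({self.cv_folds})")
        grid = self.n_grid
        if grid is None:
            grid = range(1, min(20, X.shape[1]) + 1)
        grid = sorted({int(n) for n in grid})
        if grid[0] < 1 or grid[-1] > X.shape[1]:
            raise ValueError("n_grid entries must lie in [1, n_features]")
        rows = []
        for n_top in grid:
            feats = X[self.ranking_[:n_top]].to_numpy(dtype=float)
            cv = RepeatedKFold(
                n_splits=self.cv_folds,
                n_repeats=self.cv_repeats,
                random_state=int(rng.integers(2**31 - 1)),
            )
            errs = []
            for train, test in cv.split(feats):
                forest = RandomForestRegressor(
                    n_estimators=self.n_estimators,
                    random_state=int(rng.integers(2**31 - 1)),
                    n_jobs=1,
                )
                forest.fit(feats[train], y[train])
                errs.append(float(np.mean((forest.predict(feats[test]) - y[test]) ** 2)))
            errs = np.asarray(errs)
            rows.append(
                {"n_top": n_top, "mean_error": errs.mean(), "se": errs.std(ddof=1) / np.sqrt(errs.size)}
            )
        curve = pd.DataFrame(rows)
        best = curve["mean_error"].idxmin()
        cutoff = curve.loc[best, "mean_error"] + curve.loc[best, "se"]
        self.cv_error_curve_ = curve
        self.selected_n_ = int(curve.loc[curve["mean_error"] <= cutoff, "n_top"].min())

    def fit(self, X, y):
        X = _as_frame(X)
        y = np.asarray(y, dtype=float)
        if X.shape[0] != y.size:
            raise ValueError("X and y disagree on the number of samples")
        if X.shape[1] < 2 or X.shape[0] < 10:
            raise ValueError("need at least 2 features and 10 samples")
        if np.ptp(y) == 0:
            raise ValueError("salinity is constant; nothing to rank against")
        rng = np.random.default_rng(self.random_state)
        self._rank(X, y, rng)
        self._cv_curve(X, y, rng)
        self.biomarkers_ = self.ranking_[: self.selected_n_]
        self.colonizer_labels_ = classify_colonizers(X, y, self.biomarkers_, alpha=self.alpha)
        final_seed = int(rng.integers(2**31 - 1))
        self.model_ = RandomForestRegressor(
            n_estimators=self.n_estimators, random_state=final_seed, n_jobs=1
        ).fit(X[self.biomarkers_].to_numpy(dtype=float), y)
        return self

    def predict(self, X):
        X = _as_frame(X)
        return self.model_.predict(X[self.biomarkers_].to_numpy(dtype=float))


def rank_biomarkers(
    features, salinity, n_iterations: int = 1000, n_estimators: int = 500, seed: int | None = None
) -> pd.Series:
    """Mean OOB permutation importance per taxon, descending."""
    X = _as_frame(features)
    y = np.asarray(salinity, dtype=float)
    sel = SalinityBiomarkerSelector(
        n_iterations=n_iterations, n_estimators=n_estimators, random_state=seed
    )
    if X.shape[1] < 2 or X.shape[0] < 10:
        raise ValueError("need at least 2 features and 10 samples")
    if np.ptp(y) == 0:
        raise ValueError("salinity is constant")
    rng = np.random.default_rng(seed)
    sel._rank(X, y, rng)
    return sel.importances_


def select_biomarker_count(
    features,
    salinity,
    ranked_taxa,
    folds: int = 10,
    repeats: int = 5,
    n_grid=None,
    n_estimators: int = 500,
    seed: int | None = None,
) -> tuple[pd.DataFrame, int]:
    """CV error curve over ranking prefixes and the one-SE-rule count."""
    X = _as_frame(features)
    sel = SalinityBiomarkerSelector(
        cv_folds=folds, cv_repeats=repeats, n_grid=n_grid, n_estimators=n_estimators
    )
    sel.ranking_ = list(ranked_taxa)
    sel._cv_curve(X, np.asarray(salinity, dtype=float), np.random.default_rng(seed))
    return sel.cv_error_curve_, sel.selected_n_


def classify_colonizers(features, salinity, biomarkers, alpha: float = 0.05) -> dict[str, str]:
    """Label each biomarker by its abundance-vs-salinity linear trend:
    significant negative slope -> low-salinity colonizer, significant
    positive slope -> high-salinity colonizer, otherwise complex."""
    X = _as_frame(features)
    y = np.asarray(salinity, dtype=float)
    missing = [b for b in biomarkers if b not in X.columns]
    if missing:
        raise ValueError(f"biomarkers absent from features: {missing}")
    labels = {}
    for b in biomarkers:
        trend = linear_trend(y, X[b].to_numpy(dtype=float))
        if trend.p_value < alpha and trend.slope < 0:
            labels[b] = LOW
        elif trend.p_value < alpha and trend.slope > 0:
            labels[b] = HIGH
        else:
            labels[b] = COMPLEX
    return labels


def aggregate_taxonomy(table: pd.DataFrame, lineage: pd.Series) -> pd.DataFrame:
    """Sum a taxon x sample count table into taxonomic groups given a
    taxon -> group label mapping (e.g. class-level lineages)."""
    labels = lineage.reindex(table.index)
    if labels.isna().any():
        raise ValueError("taxonomy is missing labels for some taxa")
    return table.groupby(labels).sum()
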