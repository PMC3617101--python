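"""Consensus model: penalized logistic regression over the four method
scores, trained and evaluated by stratified 5-fold cross-validation with
out-of-fold aggregation.

One model is fitted per disease. Rows are network objects, the four feature
columns are the method scores in fixed order (propagation, random_walk,
interconnectivity, neighborhood), and the label marks known drug targets.
Because targets are rare, folds are stratified so every fold's positive
fraction stays within one sample of the global fraction; every node appears
in exactly one test fold and its out-of-fold probability defines the final
ranking. The penalty strength is tuned per training fold by out-of-bag AUC
over bootstrap resamples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .prioritizers import METHODS

__all__ = [
    "ConsensusClassifier",
    "assemble_features",
    "stratified_folds",
    "cross_validated_predict",
    "feature_importance",
    "DEFAULT_PENALTY_GRID",
]

DEFAULT_PENALTY_GRID = tuple(10.0 ** k for k in range(-4, 3))  # lambda grid


def assemble_features(scores: Mapping[str, Mapping[str, float] | Sequence[float]],
                      labels: Mapping[str, int],
                      nodes: Sequence[str] | None = None) -> pd.DataFrame:
    """Build the node x method feature matrix with a binary ``label`` column.

    ``scores`` maps each method name to either a node->score mapping or a
    vector aligned with ``nodes``. All four methods must cover the same
    node set; nodes missing from ``labels`` default to negative. At least
    two positives are required, mirroring the constraint that a disease
    must have at least two known drug targets.
    """
    missing = set(METHODS) - set(scores)
    if missing:
        raise ValueError(f"missing method scores: {sorted(missing)}")
    columns = {}
    for method in METHODS:
        vec = scores[method]
        if isinstance(vec, Mapping):
            vec = pd.Series(vec, dtype=float)
        else:
            if nodes is None:
                raise ValueError("array-valued scores require `nodes`")
            vec = pd.Series(np.asarray(vec, dtype=float), index=list(nodes))
        columns[method] = vec
    fm = pd.DataFrame(columns)
    if fm.isna().any().any():
        raise ValueError("method score vectors cover different node sets")
    if not np.all(np.isfinite(fm.to_numpy())):
        raise ValueError("non-finite feature values")
    fm = fm[list(METHODS)]
    y = pd.Series(0, index=fm.index, dtype=int)
    for node, lab in labels.items():
        if node in y.index:
            y[node] = int(lab)
    if y.sum() < 2:
        raise ValueError(
            "at least two known targets are required as true positives "
            f"(got {int(y.sum())})")
    fm["label"] = y
    return fm


def stratified_folds(labels: Sequence[int] | pd.Series, k: int = 5,
                     seed: int = 0) -> np.ndarray:
    """Random stratified partition into k folds (fold ids 1..k).

    Per-fold positive counts differ by at most one from a perfectly
    proportional split; every node lands in exactly one fold. With fewer
    positives than folds some folds hold no positive (a warning is issued).
    """
    y = np.asarray(pd.Series(labels).to_numpy(), dtype=int)
    n = len(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds number of nodes n={n}")
    n_pos = int(y.sum())
    if 0 < n_pos < k:
        warnings.warn(f"fewer positives ({n_pos}) than folds ({k}); "
                      "some folds will hold no positive", stacklevel=2)
    assignment = np.empty(n, dtype=int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for fold_id, (_, test_idx) in enumerate(skf.split(np.zeros((n, 1)), y),
                                            start=1):
        assignment[test_idx] = fold_id
    return assignment


class ConsensusClassifier(BaseEstimator, ClassifierMixin):
    """L2-penalized logistic regression with bootstrap-tuned penalty.

    Features are standardized on the training data (zero-variance features
    are effectively dropped by zeroing their standardized column). When
    ``tune`` is true the penalty strength lambda is selected from
    ``penalty_grid`` by the mean out-of-bag AUC over ``n_bootstrap``
    bootstrap resamples of the training data, mimicking a resampling-based
    tuning procedure; ties prefer the stronger penalty. With ``tune=False``
    the fixed ``penalty`` is used.

    Attributes (after ``fit``): ``coef_``, ``intercept_``, ``lambda_``,
    ``mean_``, ``scale_``, ``zstats_`` (|coef|/se from the penalized
    observed information).
    """

    def __init__(self, penalty_grid: Sequence[float] = DEFAULT_PENALTY_GRID,
                 n_bootstrap: int = 25, tune: bool = True,
                 penalty: float = 1.0, random_state: int | None = None):
        self.penalty_grid = penalty_grid
        self.n_bootstrap = n_bootstrap
        self.tune = tune
        self.penalty = penalty
        self.random_state = random_state

    # -- helpers -------------------------------------------------------
    def _standardize(self, X: np.ndarray) -> np.ndarray:
        Xs = (X - self.mean_) / self.scale_
        Xs[:, self.scale_original_ == 0] = 0.0
        return Xs

    @staticmethod
    def _fit_lr(Xs: np.ndarray, y: np.ndarray, lam: float) -> LogisticRegression:
        lr = LogisticRegression(C=1.0 / lam, solver="lbfgs", max_iter=1000)
        lr.fit(Xs, y)
        return lr

    def _oob_auc(self, Xs: np.ndarray, y: np.ndarray, lam: float,
                 rng: np.random.Generator) -> float:
        from .evaluation import mann_whitney_auc
        n = len(y)
        aucs = []
        for _ in range(self.n_bootstrap):
            boot = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), boot)
            if len(np.unique(y[boot])) < 2 or len(np.unique(y[oob])) < 2:
                continue
            lr = self._fit_lr(Xs[boot], y[boot], lam)
            prob = lr.predict_proba(Xs[oob])[:, 1]
            aucs.append(mann_whitney_auc(prob, y[oob]))
        return float(np.mean(aucs)) if aucs else 0.5

    # -- sklearn API ---------------------------------------------------
    def fit(self, X, y) -> "ConsensusClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training data contains a single class")
        self.classes_ = classes
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        # guard against float cancellation on constant columns
        sd[sd <= 1e-12 * np.maximum(1.0, np.abs(self.mean_))] = 0.0
        self.scale_original_ = sd
        self.scale_ = np.where(sd > 0, sd, 1.0)
        Xs = self._standardize(X)

        if self.tune:
            rng = np.random.default_rng(self.random_state)
            grid = sorted(self.penalty_grid)
            oob = [self._oob_auc(Xs, y, lam, rng) for lam in grid]
            # prefer the strongest penalty among (near-)ties
            best = max(range(len(grid)),
                       key=lambda i: (round(oob[i], 12), grid[i]))
            self.lambda_ = float(grid[best])
            self.oob_auc_ = float(oob[best])
        else:
            self.lambda_ = float(self.penalty)
        lr = self._fit_lr(Xs, y, self.lambda_)
        self.coef_ = lr.coef_.ravel()
        self.intercept_ = float(lr.intercept_[0])
        self._lr = lr
        self.zstats_ = self._z_statistics(Xs, y)
        return self

    def _z_statistics(self, Xs: np.ndarray, y: np.ndarray) -> np.ndarray:
        """|coef| / se, with se from the penalized observed information
        (X'WX + 2*lambda*I on the standardized scale)."""
        eta = Xs @ self.coef_ + self.intercept_
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1 - p)
        Xd = np.hstack([np.ones((len(y), 1)), Xs])
        info = Xd.T @ (Xd * w[:, None])
        penalty = np.eye(Xd.shape[1]) * 2.0 * self.lambda_
        penalty[0, 0] = 0.0  # intercept unpenalized
        cov = np.linalg.pinv(info + penalty)
        se = np.sqrt(np.maximum(np.diag(cov)[1:], 1e-300))
        return np.abs(self.coef_) / se

    def decision_function(self, X) -> np.ndarray:
        Xs = self._standardize(np.asarray(X, dtype=float))
        return Xs @ self.coef_ + self.intercept_

    def predict_proba(self, X) -> np.ndarray:
        p = 1.0 / (1.0 + np.exp(-self.decision_function(X)))
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def cross_validated_predict(fm: pd.DataFrame, k: int = 5, seed: int = 0,
                            estimator: ConsensusClassifier | None = None,
                            return_models: bool = False):
    """Stratified k-fold out-of-fold prediction and ranking.

    For each fold the model is fitted on the other k-1 folds and scores the
    held-out nodes, so every node receives exactly one out-of-fold
    probability. The returned DataFrame has columns ``probability``,
    ``rank`` (1 = best) and ``known_target``, sorted by descending
    probability with lexicographic node-id tie-break.
    """
    X = fm[list(METHODS)].to_numpy(dtype=float)
    y = fm["label"].to_numpy(dtype=int)
    base = estimator if estimator is not None else ConsensusClassifier()
    folds = stratified_folds(y, k=k, seed=seed)
    prob = np.full(len(y), np.nan)
    models = []
    for fold_id in range(1, k + 1):
        test = folds == fold_id
        train = ~test
        model = clone(base)
        model.set_params(random_state=_fold_seed(seed, fold_id))
        model.fit(X[train], y[train])
        prob[test] = model.predict_proba(X[test])[:, 1]
        models.append(model)
    assert not np.isnan(prob).any()
    out = pd.DataFrame({
        "probability": prob,
        "known_target": y.astype(bool),
    }, index=fm.index)
    # deterministic tie-break: descending probability, then node id ascending
    order = sorted(out.index, key=lambda n: (-out.at[n, "probability"], str(n)))
    out = out.loc[order]
    out["rank"] = np.arange(1, len(out) + 1)
    out = out[["probability", "rank", "known_target"]]
    if return_models:
        return out, models
    return out


def _fold_seed(seed: int, fold_id: int) -> int:
    return int((seed * 1000003 + fold_id) % (2 ** 31 - 1))


def feature_importance(models: Iterable[ConsensusClassifier]) -> dict[str, float]:
    """Table-style 0-100 importances from fold-averaged |z| statistics.

    The mean absolute z-statistic of each coefficient across folds is
    affinely rescaled so the largest maps to 100 and the smallest to 0;
    if all four are equal the degenerate rescale reports 100 for each.
    """
    models = list(models)
    if not models:
        raise ValueError("need at least one fitted model")
    z = np.mean([m.zstats_ for m in models], axis=0)
    lo, hi = z.min(), z.max()
    if hi == lo:
        scaled = np.full_like(z, 100.0)
    else:
        scaled = 100.0 * (z - lo) / (hi - lo)
    return dict(zip(METHODS, (float(v) for v in scaled)))
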