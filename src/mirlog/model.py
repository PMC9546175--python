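"""MiRLog: imbalance-aware bagged logistic regression over PCA-derived features.

The classifier chains, in order: per-column standardization of the ten
continuous scores, a full-rank PCA that orthogonalizes them, appending the
autosomal boolean, a degree-2 polynomial expansion of the result, and a bag
of L2-regularized logistic regressions. Because deleterious training
variants are scarce, the bootstrap is asymmetric: every base learner sees
all deleterious rows once, plus ``round(ratio * n_deleterious)`` neutral
rows drawn with replacement, on a random subset of the derived features.
The ensemble score is the mean logistic probability of the deleterious
class, in [0, 1] with 0.5 as the decision threshold.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.preprocessing import PolynomialFeatures, StandardScaler
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "MirlogClassifier",
    "MinorityStratifiedKFold",
    "rank_auc",
    "cross_validate",
    "grid_search",
    "score_all",
    "save_model",
    "load_model",
    "DEFAULT_GRID",
]

#: hyperparameter grid used when none is supplied
DEFAULT_GRID = {
    "l2_strength": [0.01, 0.1, 1.0, 10.0],
    "neutral_ratio": [1.0, 2.0, 4.0, 8.0],
    "feature_fraction": [0.3, 0.6, 1.0],
}


def rank_auc(y_true: Sequence[int], scores: Sequence[float]) -> float:
    """ROC AUC via the rank statistic (Mann-Whitney U / (n1 * n0)).

    Ties receive average ranks, so equal scores across both classes give 0.5.
    """
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


class MirlogClassifier(ClassifierMixin, BaseEstimator):
    """Bagged L2 logistic regression for imbalanced variant classification.

    Parameters
    ----------
    n_estimators : int
        Number of base logistic regressions (default 200).
    l2_strength : float
        L2 regularization strength; the logistic regressions use
        ``C = 1 / l2_strength``.
    neutral_ratio : float
        Neutral-to-deleterious ratio of each bootstrap sample: each learner
        trains on all deleterious rows plus ``round(neutral_ratio * n_del)``
        neutral rows drawn with replacement.
    feature_fraction : float in (0, 1]
        Fraction of the derived (post-polynomial) features drawn without
        replacement for each learner.
    passthrough_last : bool
        When True (default) the last input column is treated as the
        autosomal boolean: excluded from standardization and PCA, appended
        to the components before the polynomial expansion.
    random_state : int
        Seed; (X, y, params, random_state) fully determine the fit.

    Attributes
    ----------
    scaler_, pca_, poly_ : fitted transform steps.
    estimators_ : list of dicts with keys ``lr`` (fitted LogisticRegression),
        ``feature_idx`` and ``sample_idx``.
    classes_ : array([0, 1]).
    """

    def __init__(
        self,
        n_estimators: int = 200,
        l2_strength: float = 1.0,
        neutral_ratio: float = 4.0,
        feature_fraction: float = 0.6,
        passthrough_last: bool = True,
        random_state: int = 0,
    ):
        self.n_estimators = n_estimators
        self.l2_strength = l2_strength
        self.neutral_ratio = neutral_ratio
        self.feature_fraction = feature_fraction
        self.passthrough_last = passthrough_last
        self.random_state = random_state

    # -- internal ---------------------------------------------------------
    def _validate_params_strict(self) -> None:
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if self.l2_strength <= 0:
            raise ValueError("l2_strength must be positive")
        if self.neutral_ratio <= 0:
            raise ValueError("neutral_ratio must be positive")
        if not 0 < self.feature_fraction <= 1:
            raise ValueError("feature_fraction must be in (0, 1]")

    def _split_input(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
        if self.passthrough_last:
            return X[:, :-1], X[:, -1:]
        return X, None

    def _transform(self, X: np.ndarray) -> np.ndarray:
        cont, flag = self._split_input(X)
        Z = self.pca_.transform(self.scaler_.transform(cont))
        if flag is not None:
            Z = np.column_stack([Z, flag])
        return self.poly_.transform(Z)

    # -- estimator API ----------------------------------------------------
    def fit(self, X, y) -> "MirlogClassifier":
        self._validate_params_strict()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if np.isnan(X).any():
            raise ValueError("X contains missing values; impute first")
        classes = np.unique(y)
        if not np.array_equal(classes, [0, 1]):
            raise ValueError("y must contain both classes, coded 0 (neutral) and 1 (deleterious)")
        if (y == 1).sum() < 2 or (y == 0).sum() < 2:
            raise ValueError("need at least 2 rows per class")
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]

        cont, flag = self._split_input(X)
        self.scaler_ = StandardScaler().fit(cont)
        self.pca_ = PCA(n_components=None, svd_solver="full").fit(self.scaler_.transform(cont))
        Z = self.pca_.transform(self.scaler_.transform(cont))
        if flag is not None:
            Z = np.column_stack([Z, flag])
        self.poly_ = PolynomialFeatures(degree=2, include_bias=False).fit(Z)
        D = self.poly_.transform(Z)
        n_derived = D.shape[1]
        self.n_derived_features_ = n_derived

        del_idx = np.flatnonzero(y == 1)
        neu_idx = np.flatnonzero(y == 0)
        n_boot = int(round(self.neutral_ratio * len(del_idx)))
        if n_boot < 1:
            raise ValueError("neutral_ratio too small: empty neutral bootstrap")
        k_feat = math.ceil(self.feature_fraction * n_derived)

        rng = np.random.default_rng(self.random_state)
        self.estimators_ = []
        for _ in range(self.n_estimators):
            sample_idx = np.concatenate([del_idx, rng.choice(neu_idx, size=n_boot, replace=True)])
            feature_idx = np.sort(rng.choice(n_derived, size=k_feat, replace=False))
            lr = LogisticRegression(C=1.0 / self.l2_strength, solver="lbfgs", max_iter=2000)
            lr.fit(D[np.ix_(sample_idx, feature_idx)], y[sample_idx])
            self.estimators_.append({"lr": lr, "feature_idx": feature_idx, "sample_idx": sample_idx})
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "estimators_")
        X = np.asarray(X, dtype=float)
        if np.isnan(X).any():
            raise ValueError("X contains missing values; impute first")
        D = self._transform(X)
        p = np.zeros(len(X))
        for est in self.estimators_:
            p += est["lr"].predict_proba(D[:, est["feature_idx"]])[:, 1]
        p /= len(self.estimators_)
        return np.column_stack([1 - p, p])

    def predict_score(self, X) -> np.ndarray:
        """Ensemble deleteriousness score in [0, 1] per row."""
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        return (self.predict_score(X) > 0.5).astype(int)


class MinorityStratifiedKFold:
    """Repeated K-fold CV that deals the minority (deleterious) class evenly.

    After shuffling, deleterious rows are dealt round-robin across folds (so
    24 deleterious over 12 folds gives exactly 2 per fold) and neutral rows
    are dealt to balance total fold sizes. sklearn-style splitter:
    ``split(X, y)`` yields ``(train_idx, test_idx)`` per fold and repeat.
    """

    def __init__(self, n_splits: int = 12, n_repeats: int = 4, random_state: int = 0):
        self.n_splits = n_splits
        self.n_repeats = n_repeats
        self.random_state = random_state

    def get_n_splits(self, X=None, y=None, groups=None) -> int:
        return self.n_splits * self.n_repeats

    def _fold_assignment(self, y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        k = self.n_splits
        pos = rng.permutation(np.flatnonzero(y == 1))
        neg = rng.permutation(np.flatnonzero(y == 0))
        if len(pos) < k:
            raise ValueError(
                f"only {len(pos)} deleterious rows for {k} folds; use fewer folds"
            )
        fold = np.empty(len(y), dtype=int)
        fold[pos] = np.arange(len(pos)) % k
        # fill neutral rows so total fold sizes are balanced
        sizes = np.bincount(fold[pos], minlength=k)
        n_total = len(y)
        target = np.full(k, n_total // k)
        target[: n_total % k] += 1
        order = []
        remaining = target - sizes
        f = 0
        for idx in neg:
            while remaining[f] <= 0:
                f = (f + 1) % k
            order.append(f)
            remaining[f] -= 1
        fold[neg] = order
        return fold

    def split(self, X, y, groups=None) -> Iterator[tuple[np.ndarray, np.ndarray]]:
        y = np.asarray(y)
        ss = np.random.SeedSequence(self.random_state)
        for child in ss.spawn(self.n_repeats):
            rng = np.random.default_rng(child)
            fold = self._fold_assignment(y, rng)
            for f in range(self.n_splits):
                test = np.flatnonzero(fold == f)
                train = np.flatnonzero(fold != f)
                yield train, test


@dataclass
class CVResult:
    """Out-of-fold evaluation summary of one hyperparameter setting."""

    per_repeat_auc: list[float]
    mean_auc: float
    pooled_auc: float
    oof_scores: np.ndarray  # (n_repeats, n_samples)
    roc_curve: tuple[np.ndarray, np.ndarray, np.ndarray]
    skipped_folds: list[tuple[int, int]] = field(default_factory=list)


def cross_validate(
    model: MirlogClassifier,
    X,
    y,
    n_splits: int = 12,
    n_repeats: int = 4,
    random_state: int = 0,
) -> CVResult:
    """Repeated minority-stratified K-fold evaluation with no leakage.

    Every transform (scaler, PCA, polynomial map) is re-fit inside each
    training fold; a row's out-of-fold score never comes from a model that
    saw it. AUC is computed per repeat from the pooled out-of-fold scores
    (rank statistic) and also pooled over all repeats; the pooled ROC curve
    is returned. A fold containing a single class is skipped and reported.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    splitter = MinorityStratifiedKFold(n_splits, n_repeats, random_state)
    oof = np.full((n_repeats, len(y)), np.nan)
    skipped: list[tuple[int, int]] = []
    seed_seq = np.random.SeedSequence((random_state, 1))
    fold_seeds = seed_seq.generate_state(n_repeats * n_splits) % (2**31 - 1)
    for i, (train, test) in enumerate(splitter.split(X, y)):
        repeat, fold_no = divmod(i, n_splits)
        if len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 1:
            skipped.append((repeat, fold_no))
            continue
        m = clone(model)
        m.set_params(random_state=int(fold_seeds[i]))
        m.fit(X[train], y[train])
        oof[repeat, test] = m.predict_score(X[test])
    per_repeat = [rank_auc(y[~np.isnan(oof[r])], oof[r][~np.isnan(oof[r])]) for r in range(n_repeats)]
    pooled_scores = oof.ravel()
    pooled_y = np.tile(y, n_repeats)
    ok = ~np.isnan(pooled_scores)
    pooled = rank_auc(pooled_y[ok], pooled_scores[ok])
    fpr, tpr, thr = roc_curve(pooled_y[ok], pooled_scores[ok])
    return CVResult(
        per_repeat_auc=per_repeat,
        mean_auc=float(np.mean(per_repeat)),
        pooled_auc=pooled,
        oof_scores=oof,
        roc_curve=(fpr, tpr, thr),
        skipped_folds=skipped,
    )


def grid_search(
    X,
    y,
    grid: dict[str, Sequence[float]] | None = None,
    n_estimators: int = 200,
    n_splits: int = 12,
    n_repeats: int = 4,
    random_state: int = 0,
) -> tuple[dict, pd.DataFrame]:
    """Grid-search the L2 strength and bootstrap hyperparameters by CV AUC.

    Each grid point is scored by repeated minority-stratified K-fold CV
    (same seed for every point). Ties in mean AUC are broken toward
    stronger regularization, then lower neutral ratio, then lower feature
    fraction. Returns (best params, full CV table).
    """
    grid = dict(DEFAULT_GRID if grid is None else grid)
    rows = []
    for l2 in grid.get("l2_strength", [1.0]):
        for ratio in grid.get("neutral_ratio", [4.0]):
            for frac in grid.get("feature_fraction", [1.0]):
                model = MirlogClassifier(
                    n_estimators=n_estimators,
                    l2_strength=l2,
                    neutral_ratio=ratio,
                    feature_fraction=frac,
                    random_state=random_state,
                )
                res = cross_validate(model, X, y, n_splits, n_repeats, random_state)
                rows.append(
                    {
                        "l2_strength": l2,
                        "neutral_ratio": ratio,
                        "feature_fraction": frac,
                        "mean_auc": res.mean_auc,
                        "pooled_auc": res.pooled_auc,
                        **{f"auc_repeat_{r + 1}": a for r, a in enumerate(res.per_repeat_auc)},
                    }
                )
    table = pd.DataFrame(rows)
    ranked = table.sort_values(
        by=["mean_auc", "l2_strength", "neutral_ratio", "feature_fraction"],
        ascending=[False, False, True, True],
        kind="mergesort",
    )
    best = ranked.iloc[0]
    params = {
        "l2_strength": float(best["l2_strength"]),
        "neutral_ratio": float(best["neutral_ratio"]),
        "feature_fraction": float(best["feature_fraction"]),
        "n_estimators": n_estimators,
    }
    return params, table.reset_index(drop=True)


def score_all(model: MirlogClassifier, matrix: pd.DataFrame) -> pd.DataFrame:
    """Score every SNV of a wide feature table; returns keys + mirlog_score."""
    from .features import KEY_COLUMNS, SCORE_COLUMNS

    X = np.column_stack(
        [
            matrix[list(SCORE_COLUMNS)].to_numpy(dtype=float),
            matrix["autosomal"].to_numpy(dtype=float),
        ]
    )
    out = matrix[KEY_COLUMNS].copy()
    out["mirlog_score"] = model.predict_score(X)
    return out


# -- serialization --------------------------------------------------------

MODEL_SCHEMA_VERSION = 1


def save_model(model: MirlogClassifier, path: str | Path) -> None:
    """Serialize a fitted model to a versioned JSON file."""
    check_is_fitted(model, "estimators_")
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "params": model.get_params(),
        "n_features_in": int(model.n_features_in_),
        "scaler": {
            "mean": model.scaler_.mean_.tolist(),
            "scale": model.scaler_.scale_.tolist(),
        },
        "pca": {
            "components": model.pca_.components_.tolist(),
            "mean": model.pca_.mean_.tolist(),
            "explained_variance": model.pca_.explained_variance_.tolist(),
        },
        "poly": {"degree": 2, "n_input": int(model.poly_.n_features_in_)},
        "estimators": [
            {
                "coef": est["lr"].coef_[0].tolist(),
                "intercept": float(est["lr"].intercept_[0]),
                "feature_idx": est["feature_idx"].tolist(),
                "sample_idx": est["sample_idx"].tolist(),
            }
            for est in model.estimators_
        ],
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True))


def load_model(path: str | Path) -> MirlogClassifier:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema version: {doc.get('schema_version')}")
    model = MirlogClassifier(**doc["params"])
    model.classes_ = np.array([0, 1])
    model.n_features_in_ = doc["n_features_in"]
    n_cont = model.n_features_in_ - (1 if model.passthrough_last else 0)
    scaler = StandardScaler()
    scaler.mean_ = np.array(doc["scaler"]["mean"])
    scaler.scale_ = np.array(doc["scaler"]["scale"])
    scaler.var_ = scaler.scale_**2
    scaler.n_features_in_ = n_cont
    model.scaler_ = scaler
    pca = PCA(n_components=None)
    pca.components_ = np.array(doc["pca"]["components"])
    pca.mean_ = np.array(doc["pca"]["mean"])
    pca.explained_variance_ = np.array(doc["pca"]["explained_variance"])
    pca.n_components_ = pca.components_.shape[0]
    pca.n_features_in_ = n_cont
    model.pca_ = pca
    n_input = doc["poly"]["n_input"]
    model.poly_ = PolynomialFeatures(degree=2, include_bias=False).fit(np.zeros((1, n_input)))
    model.estimators_ = []
    for e in doc["estimators"]:
        lr = LogisticRegression(C=1.0 / model.l2_strength, solver="lbfgs")
        lr.coef_ = np.array([e["coef"]])
        lr.intercept_ = np.array([e["intercept"]])
        lr.classes_ = np.array([0, 1])
        lr.n_features_in_ = len(e["coef"])
        model.estimators_.append(
            {
                "lr": lr,
                "feature_idx": np.array(e["feature_idx"], dtype=int),
                "sample_idx": np.array(e["sample_idx"], dtype=int),
            }
        )
    model.n_derived_features_ = model.poly_.transform(np.zeros((1, n_input))).shape[1]
    return model
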