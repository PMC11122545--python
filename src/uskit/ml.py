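"""Supervised classification of ustekinumab response from baseline expression.

Protocol: one stratified 60/40 split of the cohort (training size rounded up
per class, so a 22+14 cohort yields 23 training and 13 test samples), 5-fold
stratified cross-validation on the training set for light hyperparameter
tuning, a single scoring pass on the held-out test set, and a rank-based AUC.
Non-response is the positive class — the event being predicted is treatment
failure.

Five learners mirror the usual ensemble line-up for small tabular omics
cohorts: two gradient-boosting variants (``gbm``, ``xgboost``), two
randomized-forest variants (``drf``, ``xrt``) and a penalized logistic model
(``glm``).  All panel genes are supplied as features; per-model importances
are normalized to sum to one so a cross-algorithm consensus ranking is
scale-free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import (
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier

from .dgea import NormalizedExpression
from .io import NON_RESPONDER

__all__ = [
    "SplitSpec",
    "ModelReport",
    "ALGORITHMS",
    "split_cohort",
    "train_models",
    "compute_auc",
    "consensus_features",
]

ALGORITHMS = ("gbm", "xgboost", "xrt", "glm", "drf")
TRAIN_FRACTION = 0.6
N_FOLDS = 5
TOP_K_FEATURES = 10

_STAGE_SPLIT = 201
_STAGE_MODEL = 202


@dataclass(frozen=True)
class SplitSpec:
    """Stratified train/test partition with a 5-fold assignment.

    ``folds`` maps each training sample id to a fold index in
    ``0..n_folds-1``; folds are stratified by response label.
    """

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    folds: dict[str, int]
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test sets overlap")
        if set(self.folds) != set(self.train_ids):
            raise ValueError("fold assignment must cover exactly the training set")


@dataclass
class ModelReport:
    """Fit summary for one algorithm."""

    algorithm: str
    test_auc: float
    cv_auc_mean: float
    cv_auc_per_fold: tuple[float, ...]
    importances: pd.Series  # all features, normalized to sum 1
    chosen_params: dict = field(default_factory=dict)

    @property
    def top_features(self) -> pd.Series:
        """Top-10 features by normalized importance (ties: alphabetical)."""
        ordered = self.importances.sort_values(ascending=False, kind="stable")
        return ordered.iloc[:TOP_K_FEATURES]


def split_cohort(
    norm: NormalizedExpression,
    fraction: float = TRAIN_FRACTION,
    seed: int = 0,
    n_folds: int = N_FOLDS,
) -> SplitSpec:
    """Stratified random train/test split with per-class round-up.

    Taking the ceiling of ``fraction * n`` within each class keeps both
    classes represented on both sides and reproduces the 23/13 partition of
    a 22-responder / 14-non-responder cohort at the default 60% fraction.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STAGE_SPLIT,))
    )
    train_ids: list[str] = []
    test_ids: list[str] = []
    for group in sorted(norm.groups.unique()):
        ids = np.array(sorted(norm.groups.index[norm.groups == group]))
        if len(ids) < n_folds:
            raise ValueError(
                f"class {group!r} needs at least {n_folds} samples for "
                f"{n_folds}-fold CV"
            )
        n_train = int(np.ceil(fraction * len(ids)))
        if n_train >= len(ids):
            raise ValueError("empty test set for a class; lower the fraction")
        perm = rng.permutation(len(ids))
        train_ids.extend(ids[perm[:n_train]])
        test_ids.extend(ids[perm[n_train:]])
    train_ids.sort()
    test_ids.sort()
    y = (norm.groups.loc[train_ids] == NON_RESPONDER).to_numpy(int)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=int(seed) % (2**31))
    folds = {}
    for fold_idx, (_, val_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        for i in val_idx:
            folds[train_ids[i]] = fold_idx
    return SplitSpec(tuple(train_ids), tuple(test_ids), folds, int(seed))


def compute_auc(scores, labels) -> float:
    """Rank-based AUC: P(random positive outscores random negative).

    Ties in score count one half.  Equivalent to the Mann-Whitney U
    statistic scaled by ``n_pos * n_neg``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)  # average ranks handle ties at 1/2
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def _make_estimator(algorithm: str, params: dict, seed: int):
    if algorithm == "gbm":
        return GradientBoostingClassifier(
            n_estimators=100, random_state=seed, **params
        )
    if algorithm == "xgboost":
        return XGBClassifier(
            n_estimators=100,
            learning_rate=0.3,
            tree_method="exact",
            random_state=seed,
            n_jobs=1,
            eval_metric="logloss",
            **params,
        )
    if algorithm == "xrt":
        return ExtraTreesClassifier(n_estimators=200, random_state=seed, **params)
    if algorithm == "drf":
        return RandomForestClassifier(n_estimators=200, random_state=seed, **params)
    if algorithm == "glm":
        return make_pipeline(
            StandardScaler(),
            LogisticRegression(max_iter=2000, random_state=seed, **params),
        )
    raise ValueError(f"unknown algorithm {algorithm!r}")


_TUNING_GRID: dict[str, list[dict]] = {
    "gbm": [{"learning_rate": 0.1, "max_depth": 2}, {"learning_rate": 0.1, "max_depth": 3}],
    "xgboost": [{"max_depth": 2}, {"max_depth": 3}],
    "xrt": [{"max_features": "sqrt"}, {"max_features": 0.5}],
    "drf": [{"max_features": "sqrt"}, {"max_features": 0.5}],
    "glm": [{"C": 0.1}, {"C": 1.0}],
}


def _importances(algorithm: str, model, feature_names) -> pd.Series:
    if algorithm == "glm":
        coef = np.abs(model.named_steps["logisticregression"].coef_.ravel())
        raw = coef
    else:
        raw = np.asarray(model.feature_importances_, dtype=float)
    total = raw.sum()
    if total <= 0:  # degenerate constant model: uniform attribution
        raw = np.ones_like(raw)
        total = raw.sum()
    return pd.Series(raw / total, index=list(feature_names), name=algorithm)


def _predict_scores(algorithm: str, model, X: np.ndarray) -> np.ndarray:
    return model.predict_proba(X)[:, 1]


def train_models(
    norm: NormalizedExpression,
    split: SplitSpec,
    algorithms: tuple[str, ...] = ALGORITHMS,
) -> dict[str, ModelReport]:
    """Fit, tune (5-fold CV over a small grid) and score each algorithm.

    Every panel gene is a feature; the response label (non-responder = 1)
    is the target.  The held-out test set is scored exactly once per
    algorithm.  Deterministic given the split's seed.
    """
    unknown = set(algorithms) - set(ALGORITHMS)
    if unknown:
        raise ValueError(f"unknown algorithms: {sorted(unknown)}")
    X = norm.values
    y = (norm.groups == NON_RESPONDER).astype(int)
    X_train = X.loc[list(split.train_ids)].to_numpy()
    y_train = y.loc[list(split.train_ids)].to_numpy()
    X_test = X.loc[list(split.test_ids)].to_numpy()
    y_test = y.loc[list(split.test_ids)].to_numpy()
    fold_of = np.array([split.folds[s] for s in split.train_ids])
    model_seed = int(
        np.random.SeedSequence(
            entropy=split.seed, spawn_key=(_STAGE_MODEL,)
        ).generate_state(1)[0] % (2**31)
    )

    reports: dict[str, ModelReport] = {}
    for algorithm in algorithms:
        best: tuple[float, dict, tuple[float, ...]] | None = None
        for params in _TUNING_GRID[algorithm]:
            fold_aucs = []
            for fold in sorted(set(fold_of)):
                val = fold_of == fold
                if len(set(y_train[~val])) < 2 or len(set(y_train[val])) < 2:
                    continue  # degenerate fold: cannot score AUC
                est = _make_estimator(algorithm, params, model_seed)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    est.fit(X_train[~val], y_train[~val])
                fold_aucs.append(
                    compute_auc(_predict_scores(algorithm, est, X_train[val]), y_train[val])
                )
            mean_auc = float(np.mean(fold_aucs)) if fold_aucs else 0.5
            if best is None or mean_auc > best[0]:
                best = (mean_auc, params, tuple(fold_aucs))
        assert best is not None
        cv_mean, chosen, per_fold = best
        model = _make_estimator(algorithm, chosen, model_seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(X_train, y_train)
        test_auc = compute_auc(_predict_scores(algorithm, model, X_test), y_test)
        reports[algorithm] = ModelReport(
            algorithm=algorithm,
            test_auc=test_auc,
            cv_auc_mean=cv_mean,
            cv_auc_per_fold=per_fold,
            importances=_importances(algorithm, model, X.columns),
            chosen_params=dict(chosen),
        )
    return reports


def consensus_features(reports: dict[str, ModelReport] | list[ModelReport], k: int = 10) -> pd.DataFrame:
    """Genes ranked by mean normalized importance across algorithms.

    Returns the top-k genes with the consensus score and each algorithm's
    contribution, mirroring how ensemble feature agreement is read off a
    multi-model report.
    """
    if isinstance(reports, dict):
        reports = list(reports.values())
    if len(reports) < 2:
        raise ValueError("consensus needs at least two model reports")
    table = pd.concat([r.importances.rename(r.algorithm) for r in reports], axis=1)
    table["consensus"] = table.mean(axis=1)
    table = table.sort_values("consensus", ascending=False, kind="stable")
    table.index.name = "gene"
    return table.iloc[:k]
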