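"""Random-forest marker screening by recursive feature elimination.

The screening loop mirrors MetaboAnalyst-style random-forest biomarker
selection: build a forest of classification trees, estimate the model's
error on repeatedly held-out data, rank features by averaged variable
importance, drop the least important 20%, and repeat. Tracked over rounds,
the mean error typically falls to a plateau (often zero for well-separated
origins) and rises again once informative features start being discarded;
the marker panel is the smallest feature set attaining the minimal mean
error over the whole trajectory.

"Selecting one fifth of the data as out-of-bag data, repeating 10 times" is
implemented as a stratified 20% held-out evaluation set per repeat with the
error and importances averaged over repeats; per-tree bootstrap OOB scoring
is available as ``oob_mode="bagging"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedShuffleSplit

from .table import FeatureTable

__all__ = [
    "RFConfig",
    "RFERound",
    "RFETrajectory",
    "MarkerPanel",
    "evaluate_panel",
    "rfe",
]


@dataclass(frozen=True)
class RFConfig:
    """Forest and elimination-loop settings.

    ``importance_kind`` is ``"permutation_accuracy"`` (mean drop in held-out
    accuracy when a feature's column is shuffled, averaged over repeats) or
    ``"impurity"`` (mean decrease in Gini impurity).
    """

    n_trees: int = 1000
    holdout_fraction: float = 0.2
    n_repeats: int = 10
    elimination_fraction: float = 0.2
    min_features: int = 1
    importance_kind: str = "permutation_accuracy"
    oob_mode: str = "holdout"
    n_permutations: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must be in (0, 1)")
        if not 0 < self.elimination_fraction < 1:
            raise ValueError("elimination_fraction must be in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be at least 1")
        if self.importance_kind not in ("permutation_accuracy", "impurity"):
            raise ValueError(f"unknown importance_kind {self.importance_kind!r}")
        if self.oob_mode not in ("holdout", "bagging"):
            raise ValueError(f"unknown oob_mode {self.oob_mode!r}")


@dataclass
class RFERound:
    feature_ids: list[str]
    mean_error: float
    importance: pd.Series       # mean importance per feature
    rank: pd.Series             # 1 = most important

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)


@dataclass
class RFETrajectory:
    rounds: list[RFERound] = field(default_factory=list)

    def sizes(self) -> list[int]:
        return [r.n_features for r in self.rounds]

    def errors(self) -> list[float]:
        return [r.mean_error for r in self.rounds]

    def min_error(self) -> float:
        return min(self.errors())


@dataclass
class MarkerPanel:
    """Smallest feature set achieving the trajectory's minimal mean error.

    ``informative`` is judged on the full-feature first round, which is the
    only selection-free error estimate in the trajectory: later rounds
    re-evaluate features already chosen on the same samples, so even pure
    noise drifts below chance there. A panel is flagged "no informative
    minimum" when the first round cannot beat chance by two standard errors.
    """

    feature_ids: list[str]
    error: float
    chance_error: float
    informative: bool
    selection_rule: str = "smallest round with minimal mean holdout error"


def _design(table: FeatureTable, feature_subset) -> tuple[np.ndarray, np.ndarray, list[str]]:
    features = list(feature_subset)
    if not features:
        raise ValueError("feature subset is empty")
    samples = table.biological_samples
    X = table.values.loc[features, samples].to_numpy(dtype=float).T
    X = np.nan_to_num(X, nan=0.0)  # undetected cells count as zero signal
    y = np.asarray([table.groups[s] for s in samples])
    labels, counts = np.unique(y, return_counts=True)
    if labels.size < 2 or (counts < 2).any():
        raise ValueError("each group needs at least two samples")
    return X, y, features


def _permutation_importance(clf, X_test: np.ndarray, y_test: np.ndarray,
                            n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Batched permutation importance: drop in held-out accuracy per feature."""
    n_test, n_feat = X_test.shape
    baseline = float(np.mean(clf.predict(X_test) == y_test))
    imp = np.zeros(n_feat)
    block = max(1, 20000 // max(1, n_test * n_perm))  # features per predict call
    for start in range(0, n_feat, block):
        stop = min(start + block, n_feat)
        stacks = []
        for f in range(start, stop):
            for _ in range(n_perm):
                Xp = X_test.copy()
                Xp[:, f] = Xp[rng.permutation(n_test), f]
                stacks.append(Xp)
        big = np.vstack(stacks)
        pred = clf.predict(big)
        pos = 0
        for f in range(start, stop):
            accs = []
            for _ in range(n_perm):
                chunk = pred[pos: pos + n_test]
                accs.append(np.mean(chunk == y_test))
                pos += n_test
            imp[f] = baseline - float(np.mean(accs))
    return imp


def evaluate_panel(table: FeatureTable, feature_subset, config: RFConfig,
                   rng: np.random.Generator | None = None
                   ) -> tuple[float, pd.Series]:
    """Mean held-out misclassification error and mean importance of a panel.

    For each of ``n_repeats`` repeats a stratified ``holdout_fraction`` of
    biological samples is held out, a forest of ``n_trees`` is fit on the
    remainder, and the error plus per-feature importances are computed on
    the held-out set; outputs are means over repeats. Deterministic for a
    fixed (table, subset, config) — the stream is derived from config.seed.
    """
    X, y, features = _design(table, feature_subset)
    if rng is None:
        rng = np.random.default_rng(config.seed)

    if config.oob_mode == "bagging":
        errors = []
        imps = []
        for _ in range(config.n_repeats):
            rs = int(rng.integers(2**31 - 1))
            clf = RandomForestClassifier(
                n_estimators=config.n_trees, oob_score=True, bootstrap=True,
                random_state=rs, n_jobs=1).fit(X, y)
            errors.append(1.0 - float(clf.oob_score_))
            if config.importance_kind == "impurity":
                imps.append(clf.feature_importances_)
            else:
                imps.append(_permutation_importance(
                    clf, X, y, config.n_permutations, rng))
        return float(np.mean(errors)), pd.Series(np.mean(imps, axis=0),
                                                 index=features)

    errors = []
    imps = []
    for _ in range(config.n_repeats):
        rs = int(rng.integers(2**31 - 1))
        sss = StratifiedShuffleSplit(n_splits=1,
                                     test_size=config.holdout_fraction,
                                     random_state=rs)
        train_idx, test_idx = next(sss.split(X, y))
        clf = RandomForestClassifier(n_estimators=config.n_trees,
                                     random_state=rs, n_jobs=1)
        clf.fit(X[train_idx], y[train_idx])
        pred = clf.predict(X[test_idx])
        errors.append(float(np.mean(pred != y[test_idx])))
        if config.importance_kind == "impurity":
            imps.append(clf.feature_importances_)
        else:
            imps.append(_permutation_importance(
                clf, X[test_idx], y[test_idx], config.n_permutations, rng))
    return float(np.mean(errors)), pd.Series(np.mean(imps, axis=0),
                                             index=features)


def n_to_drop(n_features: int, fraction: float) -> int:
    """Features removed per round: the bottom ``fraction`` share, at least 1."""
    return max(1, math.floor(fraction * n_features))


def rfe(table: FeatureTable, config: RFConfig
        ) -> tuple[RFETrajectory, MarkerPanel]:
    """Recursive bottom-fraction elimination down to ``min_features``.

    Every round re-evaluates the current feature set from scratch, records
    (ids, mean error, ranked importances), and removes the lowest-importance
    bottom share (ties broken by feature id so runs are reproducible).
    """
    rng = np.random.default_rng(config.seed)
    features = list(table.feature_ids)
    trajectory = RFETrajectory()

    while True:
        error, importance = evaluate_panel(table, features, config, rng)
        order = sorted(features, key=lambda f: (-importance[f], f))
        rank = pd.Series({f: i + 1 for i, f in enumerate(order)})
        trajectory.rounds.append(RFERound(list(features), error,
                                          importance, rank))
        if len(features) <= config.min_features:
            break
        drop = n_to_drop(len(features), config.elimination_fraction)
        drop = min(drop, len(features) - config.min_features)
        # lowest importance first, ties resolved lexicographically
        worst = sorted(features, key=lambda f: (importance[f], f))[:drop]
        features = [f for f in features if f not in set(worst)]

    y = [table.groups[s] for s in table.biological_samples]
    _, counts = np.unique(y, return_counts=True)
    n_bio = int(counts.sum())
    chance = 1.0 - counts.max() / n_bio

    if config.oob_mode == "bagging":
        n_eval = config.n_repeats * n_bio
    else:
        n_eval = config.n_repeats * max(1, round(config.holdout_fraction * n_bio))
    se = math.sqrt(chance * (1.0 - chance) / n_eval)

    best_error = trajectory.min_error()
    best_round = min((r for r in trajectory.rounds
                      if r.mean_error == best_error),
                     key=lambda r: r.n_features)
    panel = MarkerPanel(
        feature_ids=list(best_round.feature_ids),
        error=best_error,
        chance_error=float(chance),
        informative=bool(trajectory.errors()[0] < chance - 2.0 * se),
    )
    return trajectory, panel


def trajectory_to_records(trajectory: RFETrajectory) -> list[dict]:
    """JSON-friendly view of a trajectory."""
    return [
        {
            "n_features": r.n_features,
            "mean_error": r.mean_error,
            "feature_ids": list(r.feature_ids),
            "importance": {f: float(v) for f, v in r.importance.items()},
        }
        for r in trajectory.rounds
    ]
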