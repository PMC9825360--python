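"""Label-cleaning baselines: deep k-NN editing and Rank Pruning.

Both operate on the same frozen patch features as the MIL predictors and
their outputs flow through the same post-processing, so the methods are
compared on identical supports.

* **DkNN** assumes same-class patches cluster in feature space: a patch
  whose label disagrees with the majority label of its k nearest neighbors
  is flagged as untrusted and relabeled by k-NN majority vote among the
  trusted patches.  The output is a binary label map (no threshold step).
* **Rank Pruning** fits a patch classifier with out-of-fold predictions,
  prunes instances whose score is inconsistent with their label relative to
  the per-class mean confident scores, retrains on the remainder, and emits
  the retrained classifier's scores as a heatmap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.neighbors import NearestNeighbors
from sklearn.neural_network import MLPClassifier

from .errors import ConfigError, InfeasibleError, LCMILError

__all__ = [
    "DkNNConfig",
    "RankPruneConfig",
    "dknn_relabel",
    "rank_prune_mask",
    "rank_prune_refine",
]


@dataclass
class DkNNConfig:
    """k-NN label-editing settings; ``k`` neighbors in feature space."""

    k: int = 10

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigError("k must be >= 1")


@dataclass
class RankPruneConfig:
    """Rank Pruning settings: fold count and the small classifier head."""

    n_folds: int = 3
    hidden_units: int = 16
    max_iter: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")


def _majority(labels: np.ndarray, fallback: int) -> int:
    """Majority label; an exact tie keeps the original label (conservative)."""
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 > n0:
        return 1
    if n0 > n1:
        return 0
    return fallback


def dknn_relabel(X: np.ndarray, y: np.ndarray, k: int = 10) -> np.ndarray:
    """Deep k-NN label editing in a given feature space.

    Flags points whose label disagrees with the majority label of their k
    nearest neighbors (Euclidean, self excluded); flagged points are
    relabeled by majority vote of their k nearest *trusted* (unflagged)
    points.  Ties keep the original label.  Falls back to voting over all
    points when fewer than k are trusted.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(np.int8)
    n = len(X)
    if not 1 <= k < n:
        raise ConfigError("need 1 <= k < number of patches")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    neighbor_ids = idx[:, 1:]  # drop self
    flagged = np.array(
        [_majority(y[neighbor_ids[i]], y[i]) != y[i] for i in range(n)], dtype=bool
    )
    out = y.copy()
    if not flagged.any():
        return out
    trusted = np.flatnonzero(~flagged)
    if len(trusted) < k:
        warnings.warn("fewer trusted patches than k; voting over all patches")
        trusted = np.arange(n)
    nn_t = NearestNeighbors(n_neighbors=k).fit(X[trusted])
    _, tidx = nn_t.kneighbors(X[flagged])
    for row, i in zip(tidx, np.flatnonzero(flagged)):
        out[i] = _majority(y[trusted[row]], y[i])
    return out


def rank_prune_mask(scores: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Confident-example pruning rule on out-of-fold scores.

    Prunes labeled-negative instances scoring strictly above the mean score
    of labeled-positives, and labeled-positive instances scoring strictly
    below the mean score of labeled-negatives.  Returns a boolean mask of
    pruned instances.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(np.int8)
    if not ((y == 1).any() and (y == 0).any()):
        raise InfeasibleError("both classes must be present")
    mean_pos = scores[y == 1].mean()
    mean_neg = scores[y == 0].mean()
    return ((y == 0) & (scores > mean_pos)) | ((y == 1) & (scores < mean_neg))


def _make_classifier(cfg: RankPruneConfig) -> MLPClassifier:
    return MLPClassifier(
        hidden_layer_sizes=(cfg.hidden_units,),
        max_iter=cfg.max_iter,
        random_state=cfg.seed,
    )


def rank_prune_refine(
    X: np.ndarray, y: np.ndarray, cfg: RankPruneConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Two-stage Rank Pruning over frozen features.

    Stage 1 fits a small classifier head by stratified n-fold cross-
    validation, giving every instance an out-of-fold probability score.
    Stage 2 prunes untrusted instances by :func:`rank_prune_mask`, retrains
    the head on the remainder, and scores all instances with it.

    Returns ``(scores, pruned)``: the retrained classifier's probability
    for every patch and the boolean prune mask.
    """
    cfg = cfg or RankPruneConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(np.int8)
    if not ((y == 1).any() and (y == 0).any()):
        raise InfeasibleError("both classes must be present")
    cv = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter from the small head
        oof = cross_val_predict(_make_classifier(cfg), X, y, cv=cv, method="predict_proba")[:, 1]
        pruned = rank_prune_mask(oof, y)
        keep = ~pruned
        for cls in (0, 1):
            if not ((y == cls) & keep).any():
                raise LCMILError(
                    f"rank pruning removed every class-{cls} instance "
                    f"(pruned {int(pruned.sum())}/{len(y)}); aborting"
                )
        clf = _make_classifier(cfg).fit(X[keep], y[keep])
        scores = clf.predict_proba(X)[:, 1]
    return scores, pruned
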