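"""Leave-one-out animal classification with LogitBoost trees.

Features are the residualized projection fractions (injection geometry
removed by a condition-free linear model fitted on the training animals),
optionally compacted by summing regions within Markov-stability clusters.
The classifier is LogitBoost: stagewise additive modelling by Newton steps
on the binomial deviance, each stage a small weighted-least-squares
regression tree (depth-1 stumps by default).  Significance of the error
count is the exact binomial cumulative probability at chance 0.5 — the
probability of doing at least this well by coin flipping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CONTROL, CSR, CohortError, CohortTable
from .glm import residualize_covariates
from .stability import PartitionHierarchy, merge_by_partition

SCALE_POLICIES = ("fixed", "inner", "per-scale")

_W_FLOOR = 1e-10
_Z_CLIP = 4.0


class ClassifierError(ValueError):
    """Raised for invalid training inputs."""


# -- weighted regression trees ------------------------------------------------


@dataclass(frozen=True)
class _Leaf:
    value: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.full(len(X), self.value)


@dataclass(frozen=True)
class _Split:
    feature: int
    threshold: float
    left: "_Split | _Leaf"
    right: "_Split | _Leaf"

    def predict(self, X: np.ndarray) -> np.ndarray:
        out = np.empty(len(X))
        mask = X[:, self.feature] <= self.threshold
        out[mask] = self.left.predict(X[mask])
        out[~mask] = self.right.predict(X[~mask])
        return out


def _best_stump(X: np.ndarray, z: np.ndarray, w: np.ndarray, order: np.ndarray):
    """Best weighted-least-squares split over all features.

    Ties break to the lowest feature index, then the lowest split
    position, which makes training fully deterministic.  Returns
    (feature, threshold, gain) or None when no valid split exists.
    """
    n, p = X.shape
    if n < 2:
        return None
    Xs = np.take_along_axis(X, order, axis=0)
    zs = z[order]
    ws = w[order]
    cw = np.cumsum(ws, axis=0)[:-1]  # (n-1, p): left weight
    cwz = np.cumsum(ws * zs, axis=0)[:-1]
    totw = cw[-1] + ws[-1]
    totwz = cwz[-1] + (ws[-1] * zs[-1])
    rw = totw - cw
    rwz = totwz - cwz
    valid = (Xs[1:] > Xs[:-1]) & (cw > 0) & (rw > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = cwz**2 / cw + rwz**2 / rw
    gain = np.where(valid, gain, -np.inf)
    # feature-major flattening => argmax ties resolve to lowest feature,
    # then lowest split position
    flat = gain.T.ravel()
    best = int(np.argmax(flat))
    if not np.isfinite(flat[best]):
        return None
    feature, pos = divmod(best, n - 1)
    threshold = 0.5 * (Xs[pos, feature] + Xs[pos + 1, feature])
    return feature, float(threshold), float(flat[best])


def _fit_tree(X: np.ndarray, z: np.ndarray, w: np.ndarray, depth: int):
    wsum = w.sum()
    mean = float((w * z).sum() / wsum) if wsum > 0 else 0.0
    if depth == 0 or len(X) < 2:
        return _Leaf(mean)
    order = np.argsort(X, axis=0, kind="stable")
    found = _best_stump(X, z, w, order)
    if found is None:
        return _Leaf(mean)
    feature, threshold, _ = found
    mask = X[:, feature] <= threshold
    left = _fit_tree(X[mask], z[mask], w[mask], depth - 1)
    right = _fit_tree(X[~mask], z[~mask], w[~mask], depth - 1)
    return _Split(feature, threshold, left, right)


# -- LogitBoost ---------------------------------------------------------------


@dataclass(frozen=True)
class BoostedTreesModel:
    """Additive tree ensemble F(x); predictions are sign(F(x)).

    A score of exactly 0 predicts the majority training class
    (``tie_class``), so prediction is deterministic.
    """

    trees: tuple
    tie_class: int
    n_features: int

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ClassifierError(
                f"expected (n, {self.n_features}) feature matrix, got {X.shape}"
            )
        F = np.zeros(len(X))
        for tree in self.trees:
            F += 0.5 * tree.predict(X)
        return F

    def predict(self, X: np.ndarray) -> np.ndarray:
        F = self.decision_function(X)
        out = np.where(F > 0, 1, np.where(F < 0, -1, self.tie_class))
        return out.astype(int)


def train_boosted_trees(
    X: np.ndarray, y: np.ndarray, rounds: int = 100, depth: int = 1
) -> BoostedTreesModel:
    """Fit LogitBoost with weighted regression trees as base learners.

    ``y`` holds ±1 labels; both classes must be present and ``rounds ≥ 1``.
    Each round computes class probabilities p = 1/(1+e^{−2F}), working
    weights w = p(1−p) and responses z = (y* − p)/w (y* the 0/1 label,
    z clipped at ±4, w floored), fits a depth-``depth`` tree to (z, w) and
    adds half its output to F.  No internal randomness; split ties break
    deterministically.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if rounds < 1:
        raise ClassifierError(f"rounds must be >= 1, got {rounds}")
    if depth < 1:
        raise ClassifierError(f"depth must be >= 1, got {depth}")
    if X.ndim != 2 or len(X) != len(y):
        raise ClassifierError(f"X {X.shape} and y {y.shape} are inconsistent")
    classes = set(np.unique(y).tolist())
    if not classes <= {-1, 1} or len(classes) != 2:
        raise ClassifierError("y must contain both classes, coded +1 and -1")
    y01 = (y + 1) / 2.0
    n_pos = int((y == 1).sum())
    n_neg = len(y) - n_pos
    tie_class = 1 if n_pos >= n_neg else -1

    F = np.zeros(len(y))
    trees = []
    for _ in range(rounds):
        p = 1.0 / (1.0 + np.exp(-2.0 * F))
        w = np.maximum(p * (1.0 - p), _W_FLOOR)
        z = np.clip((y01 - p) / w, -_Z_CLIP, _Z_CLIP)
        tree = _fit_tree(X, z, w, depth)
        trees.append(tree)
        F += 0.5 * tree.predict(X)
    return BoostedTreesModel(trees=tuple(trees), tie_class=tie_class, n_features=X.shape[1])


# -- binomial significance ----------------------------------------------------


def binomial_significance(errors: int, n: int, chance: float = 0.5) -> float:
    """Exact P(X ≤ errors) for X ~ Binomial(n, chance).

    Computed by exact rational summation of the probability mass function
    (no normal approximation); the binary-float value of ``chance`` is
    taken exactly.
    """
    if not (0 <= errors <= n):
        raise ClassifierError(f"errors must be in [0, {n}], got {errors}")
    if not (0 < chance < 1):
        raise ClassifierError(f"chance must be in (0, 1), got {chance}")
    p = Fraction(chance)
    q = 1 - p
    total = Fraction(0)
    for k in range(errors + 1):
        total += comb(n, k) * p**k * q ** (n - k)
    return float(total)


def accuracy_percent(n: int, errors: int) -> int:
    """Report-format accuracy: (N−E)/N as nearest-integer percent."""
    if n < 1 or not (0 <= errors <= n):
        raise ClassifierError(f"invalid (n, errors) = ({n}, {errors})")
    return int(round(100.0 * (n - errors) / n))


# -- leave-one-out harness ----------------------------------------------------


@dataclass(frozen=True)
class FoldPrediction:
    animal_id: str
    true_label: int
    predicted_label: int
    scale_index: int | None  # index into the hierarchy, None = raw regions


@dataclass(frozen=True)
class ClassificationReport:
    """Aggregate leave-one-out outcome.

    ``binomial_p`` is P(X ≤ error_count) for X ~ Binomial(n_animals, 0.5).
    ``per_scale_accuracy`` is populated by the per-scale policy.
    """

    predictions: tuple[FoldPrediction, ...]
    error_count: int
    n_animals: int
    accuracy: float
    binomial_p: float
    scale_policy: str | None
    per_scale_accuracy: dict | None = None

    @property
    def accuracy_pct(self) -> int:
        return accuracy_percent(self.n_animals, self.error_count)

    def to_dict(self) -> dict:
        return {
            "predictions": [
                {
                    "animal_id": p.animal_id,
                    "true_label": p.true_label,
                    "predicted_label": p.predicted_label,
                    "scale_index": p.scale_index,
                }
                for p in self.predictions
            ],
            "error_count": self.error_count,
            "n_animals": self.n_animals,
            "accuracy": self.accuracy,
            "accuracy_pct": self.accuracy_pct,
            "binomial_p": self.binomial_p,
            "scale_policy": self.scale_policy,
            "per_scale_accuracy": self.per_scale_accuracy,
        }


def _report(preds: list[FoldPrediction], scale_policy: str | None, per_scale=None) -> ClassificationReport:
    errors = sum(1 for p in preds if p.predicted_label != p.true_label)
    n = len(preds)
    return ClassificationReport(
        predictions=tuple(preds),
        error_count=errors,
        n_animals=n,
        accuracy=(n - errors) / n,
        binomial_p=binomial_significance(errors, n, 0.5),
        scale_policy=scale_policy,
        per_scale_accuracy=per_scale,
    )


def _fold_features(
    cohort: CohortTable,
    train_ids: list[str],
    hierarchy: PartitionHierarchy | None,
    residualize_once: bool,
    precomputed: pd.DataFrame | None,
) -> pd.DataFrame:
    if residualize_once:
        assert precomputed is not None
        return precomputed
    return residualize_covariates(cohort, fit_animals=train_ids)


def _train_predict(
    features: pd.DataFrame,
    labels: Mapping[str, int],
    train_ids: list[str],
    test_id: str,
    partition: Mapping[str, int] | None,
    rounds: int,
    depth: int,
) -> int:
    feats = merge_by_partition(features, partition) if partition is not None else features
    Xtr = feats.loc[train_ids].to_numpy(dtype=float)
    ytr = np.array([labels[a] for a in train_ids])
    model = train_boosted_trees(Xtr, ytr, rounds=rounds, depth=depth)
    return int(model.predict(feats.loc[[test_id]].to_numpy(dtype=float))[0])


def loocv_classify(
    cohort: CohortTable,
    hierarchy: PartitionHierarchy | None = None,
    rounds: int = 100,
    depth: int = 1,
    scale_policy: str = "inner",
    fixed_scale: int | None = None,
    residualize_once: bool = False,
) -> ClassificationReport:
    """Leave-one-out classification of animals from residualized features.

    For each held-out animal the condition-free geometry model is refitted
    on the remaining animals (no leakage; ``residualize_once=True``
    reproduces the fit-on-everyone reading), features are optionally
    compacted at a hierarchy scale, and a LogitBoost model trained on the
    rest predicts the held-out animal.

    ``scale_policy``:

    * ``'fixed'`` — use ``fixed_scale`` (or raw regions when the hierarchy
      is None);
    * ``'inner'`` — choose the scale per fold by a nested leave-one-out on
      the training animals (ties → fewer clusters, then lower index);
    * ``'per-scale'`` — run every scale, report per-scale accuracies, and
      use the best scale for the headline numbers (optimistic by
      construction; mirrors choosing granularity after the fact).
    """
    if cohort.stage != "unit_mean":
        raise CohortError(f"loocv_classify expects stage='unit_mean', got {cohort.stage!r}")
    if scale_policy not in SCALE_POLICIES:
        raise ClassifierError(f"scale_policy must be one of {SCALE_POLICIES}, got {scale_policy!r}")
    ids = cohort.animal_ids
    labels = {a.animal_id: a.condition for a in cohort.animals}
    n_pos = sum(1 for v in labels.values() if v == CONTROL)
    n_neg = len(ids) - n_pos
    if len(ids) < 4 or n_pos < 2 or n_neg < 2:
        raise ClassifierError(
            f"need >= 4 animals with >= 2 per condition, got {n_pos} control / {n_neg} CSR"
        )
    if hierarchy is None and scale_policy != "fixed":
        scale_policy = "fixed"  # no scales to choose between
        fixed_scale = None

    once = residualize_covariates(cohort) if residualize_once else None

    def partition_at(si: int | None) -> Mapping[str, int] | None:
        return None if si is None else hierarchy[si].labels

    if scale_policy == "per-scale":
        assert hierarchy is not None
        scale_indices: list[int | None] = list(range(len(hierarchy)))
        per_scale_preds: dict[int | None, list[FoldPrediction]] = {si: [] for si in scale_indices}
        for test_id in ids:
            train_ids = [a for a in ids if a != test_id]
            feats = _fold_features(cohort, train_ids, hierarchy, residualize_once, once)
            for si in scale_indices:
                pred = _train_predict(
                    feats, labels, train_ids, test_id, partition_at(si), rounds, depth
                )
                per_scale_preds[si].append(
                    FoldPrediction(test_id, labels[test_id], pred, si)
                )
        per_scale_acc = {
            si: sum(p.predicted_label == p.true_label for p in preds) / len(ids)
            for si, preds in per_scale_preds.items()
        }
        # headline = best scale after the fact (documented as optimistic);
        # ties → fewer clusters, then lower index
        best = min(
            scale_indices,
            key=lambda si: (-per_scale_acc[si], hierarchy[si].n_clusters, si),
        )
        return _report(
            per_scale_preds[best],
            "per-scale",
            per_scale={int(si): float(a) for si, a in per_scale_acc.items()},
        )

    preds: list[FoldPrediction] = []
    for test_id in ids:
        train_ids = [a for a in ids if a != test_id]
        feats = _fold_features(cohort, train_ids, hierarchy, residualize_once, once)
        if scale_policy == "fixed":
            si: int | None = fixed_scale
        else:  # inner-selection nested LOO on the training animals
            assert hierarchy is not None
            candidates = list(range(len(hierarchy)))
            inner_acc = {}
            for cand in candidates:
                part = partition_at(cand)
                hits = 0
                for inner_id in train_ids:
                    inner_train = [a for a in train_ids if a != inner_id]
                    ytr = {labels[a] for a in inner_train}
                    if len(ytr) < 2:
                        continue
                    p = _train_predict(
                        feats, labels, inner_train, inner_id, part, rounds, depth
                    )
                    hits += int(p == labels[inner_id])
                inner_acc[cand] = hits / len(train_ids)
            si = min(
                candidates,
                key=lambda c: (-inner_acc[c], hierarchy[c].n_clusters, c),
            )
        pred = _train_predict(feats, labels, train_ids, test_id, partition_at(si), rounds, depth)
        preds.append(FoldPrediction(test_id, labels[test_id], pred, si))
    return _report(preds, scale_policy)
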