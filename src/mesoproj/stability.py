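"""Region–region correlation graphs and multiscale Markov-stability
community detection.

The graph is built from the positive part of the region × region Pearson
correlation matrix (negatives and the diagonal zeroed).  Partition quality
at Markov time t is the continuous-time stability

    r(t, P) = Σ_clusters Σ_{i,j ∈ cluster} [ (Π e^{−tL})_{ij} − π_i π_j ]

with L = I − D⁻¹W the random-walk Laplacian, π = d / Σd the stationary
distribution and Π = diag(π).  Small t favours fine partitions (all
singletons as t → 0⁺), large t coarse ones; the all-in-one partition
scores exactly 0 at every t.  Optimization is Louvain-style greedy node
moves with aggregation, restarted from random node orders.  The full
matrix exponential is used rather than the linearized approximation —
graphs at this scale (a few hundred regions) make exactness affordable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm

_GAIN_TOL = 1e-14
_SCORE_TOL = 1e-12


class GraphError(ValueError):
    """Raised for malformed correlation graphs."""


@dataclass(frozen=True)
class CorrelationGraph:
    """Symmetric non-negative weight matrix over named regions."""

    nodes: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", W)
        n = len(self.nodes)
        if W.shape != (n, n):
            raise GraphError(f"weight matrix shape {W.shape} does not match {n} nodes")
        if not np.all(np.isfinite(W)):
            raise GraphError("non-finite edge weights")
        if not np.allclose(W, W.T):
            raise GraphError("weight matrix must be symmetric")
        if np.any(np.diag(W) != 0):
            raise GraphError("diagonal must be zero")
        if np.any(W < 0) or np.any(W > 1):
            raise GraphError("edge weights must lie in [0, 1]")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def degrees(self) -> np.ndarray:
        return self.weights.sum(axis=1)


@dataclass(frozen=True)
class ScalePartition:
    markov_time: float
    labels: dict[str, int]
    n_clusters: int
    stability: float


@dataclass(frozen=True)
class PartitionHierarchy:
    """Partitions found across a grid of Markov times (finest first)."""

    scales: tuple[ScalePartition, ...]

    def __len__(self) -> int:
        return len(self.scales)

    def __iter__(self):
        return iter(self.scales)

    def __getitem__(self, i: int) -> ScalePartition:
        return self.scales[i]

    def to_json(self, path: str | Path | None = None) -> str:
        doc = json.dumps(
            [
                {
                    "markov_time": s.markov_time,
                    "n_clusters": s.n_clusters,
                    "stability": s.stability,
                    "labels": s.labels,
                }
                for s in self.scales
            ],
            indent=2,
        )
        if path is not None:
            Path(path).write_text(doc + "\n", encoding="utf-8")
        return doc

    @classmethod
    def from_json(cls, text: str) -> "PartitionHierarchy":
        data = json.loads(text)
        return cls(
            tuple(
                ScalePartition(
                    markov_time=float(s["markov_time"]),
                    labels={str(k): int(v) for k, v in s["labels"].items()},
                    n_clusters=int(s["n_clusters"]),
                    stability=float(s["stability"]),
                )
                for s in data
            )
        )


def default_time_grid(n_times: int = 20, t_min: float = 1e-2, t_max: float = 1e2) -> np.ndarray:
    return np.logspace(np.log10(t_min), np.log10(t_max), n_times)


def region_correlation_graph(features: pd.DataFrame) -> CorrelationGraph:
    """Positive-part Pearson correlation graph of feature columns.

    ``features`` is animals × regions.  Negative correlations and the
    diagonal are set to zero.
    """
    if features.shape[0] < 3:
        raise GraphError(f"need >= 3 animals to correlate regions, got {features.shape[0]}")
    X = features.to_numpy(dtype=float)
    sds = X.std(axis=0)
    if np.any(sds == 0):
        bad = features.columns[int(np.argmax(sds == 0))]
        raise GraphError(f"region {bad!r} has zero variance across animals")
    C = np.corrcoef(X, rowvar=False)
    W = np.clip(C, 0.0, 1.0)
    np.fill_diagonal(W, 0.0)
    W = (W + W.T) / 2.0
    return CorrelationGraph(nodes=tuple(str(c) for c in features.columns), weights=W)


# -- stability ---------------------------------------------------------------


def _stability_matrix(W: np.ndarray, t: float) -> np.ndarray:
    """M(t) = Π e^{−tL} − π πᵀ on the positive-degree subgraph."""
    d = W.sum(axis=1)
    if np.any(d <= 0):
        raise GraphError("stability matrix undefined for isolated nodes; handle upstream")
    pi = d / d.sum()
    L = np.eye(len(W)) - W / d[:, None]
    M = pi[:, None] * expm(-t * L) - np.outer(pi, pi)
    return (M + M.T) / 2.0  # detailed balance makes M symmetric; enforce numerically


def partition_stability(graph: CorrelationGraph, t: float, labels: Mapping[str, int]) -> float:
    """Stability score of an arbitrary partition (isolated nodes contribute 0)."""
    missing = [a for a in graph.nodes if a not in labels]
    if missing:
        raise GraphError(f"labels missing for nodes: {missing}")
    d = graph.degrees()
    active = d > 0
    if not active.any():
        return 0.0
    M = _stability_matrix(graph.weights[np.ix_(active, active)], t)
    lab = np.array([labels[a] for a, keep in zip(graph.nodes, active) if keep])
    same = lab[:, None] == lab[None, :]
    return float(M[same].sum())


def _canonical(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters by order of first appearance."""
    out = np.empty_like(labels)
    mapping: dict[int, int] = {}
    for i, v in enumerate(labels):
        if v not in mapping:
            mapping[v] = len(mapping)
        out[i] = mapping[v]
    return out


def _greedy_moves(B: np.ndarray, labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Single-node move phase: move nodes while any move improves the score."""
    n = len(B)
    labels = labels.copy()
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            row = B[i].copy()
            row[i] = 0.0
            k = labels.max() + 1
            sums = np.zeros(k + 1)  # slot k: split off into a new singleton
            np.add.at(sums, labels, row)
            cur = labels[i]
            gains = 2.0 * (sums - sums[cur])
            best = int(np.argmax(gains))  # ties → lowest cluster id
            if gains[best] > _GAIN_TOL and best != cur:
                labels[i] = best
                improved = True
    return _canonical(labels)


def _aggregate(B: np.ndarray, labels: np.ndarray) -> np.ndarray:
    k = labels.max() + 1
    P = np.zeros((len(B), k))
    P[np.arange(len(B)), labels] = 1.0
    return P.T @ B @ P


def _score(B: np.ndarray, labels: np.ndarray) -> float:
    same = labels[:, None] == labels[None, :]
    return float(B[same].sum())


def _louvain(B: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Multi-level greedy maximization of Σ within-cluster B entries."""
    n = len(B)
    assign = np.arange(n)
    Bcur = B
    while True:
        start = np.arange(len(Bcur))
        labels = _greedy_moves(Bcur, start, rng)
        if labels.max() + 1 == len(Bcur):
            break
        assign = labels[assign]
        Bcur = _aggregate(Bcur, labels)
    return _canonical(assign)


def _merge_refine(B: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Greedy pairwise cluster merges while any merge improves the score."""
    labels = labels.copy()
    while True:
        k = labels.max() + 1
        if k == 1:
            break
        A = _aggregate(B, labels)
        off = A - np.diag(np.diag(A))
        gain = 2.0 * off  # merging clusters a,b adds 2·A_ab
        np.fill_diagonal(gain, -np.inf)
        a, b = np.unravel_index(int(np.argmax(gain)), gain.shape)
        if gain[a, b] <= _GAIN_TOL:
            break
        lo, hi = min(a, b), max(a, b)
        labels[labels == hi] = lo
        labels = _canonical(labels)
    return labels


def optimize_partition(
    B: np.ndarray, n_restarts: int, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """Best partition of a dense symmetric quality matrix over restarts.

    Ties on score break to fewer clusters, then to the lexicographically
    smallest canonical labelling, so the result is deterministic for a
    fixed seed.
    """
    best_labels: np.ndarray | None = None
    best_key: tuple | None = None
    for _ in range(max(1, n_restarts)):
        labels = _louvain(B, rng)
        labels = _merge_refine(B, labels)
        labels = _greedy_moves(B, labels, rng)
        score = _score(B, labels)
        key = (-score, labels.max() + 1, tuple(labels))
        if best_key is None or _tie_better(key, best_key):
            best_key, best_labels = key, labels
    assert best_labels is not None
    return best_labels, -best_key[0]


def _tie_better(key: tuple, best: tuple) -> bool:
    # scores within tolerance are ties; then fewer clusters, then lexicographic
    if key[0] < best[0] - _SCORE_TOL:
        return True
    if key[0] > best[0] + _SCORE_TOL:
        return False
    return key[1:] < best[1:]


def markov_stability_scan(
    graph: CorrelationGraph,
    times: Sequence[float] | None = None,
    n_restarts: int = 20,
    seed: int = 0,
) -> PartitionHierarchy:
    """Optimize stability at every Markov time in an ascending grid.

    Isolated nodes (zero degree after thresholding the correlations)
    remain singleton clusters at every scale and contribute nothing to the
    score.  Deterministic for fixed (graph, times, n_restarts, seed).
    """
    if graph.n_nodes == 0:
        raise GraphError("empty graph")
    ts = np.asarray(default_time_grid() if times is None else list(times), dtype=float)
    if np.any(ts <= 0) or not np.all(np.isfinite(ts)):
        raise GraphError("Markov times must be positive and finite")
    if np.any(np.diff(ts) < 0):
        raise GraphError("Markov times must be sorted ascending")

    d = graph.degrees()
    active = d > 0
    idx_active = np.flatnonzero(active)
    idx_isolated = np.flatnonzero(~active)
    rng = np.random.default_rng(int(seed))

    scales = []
    for t in ts:
        if active.any():
            M = _stability_matrix(graph.weights[np.ix_(active, active)], float(t))
            labels_active, score = optimize_partition(M, n_restarts, rng)
        else:
            labels_active, score = np.empty(0, dtype=int), 0.0
        k_active = int(labels_active.max() + 1) if len(labels_active) else 0
        full = np.empty(graph.n_nodes, dtype=int)
        full[idx_active] = labels_active
        for j, iso in enumerate(idx_isolated):
            full[iso] = k_active + j
        full = _canonical(full)
        labels = {a: int(c) for a, c in zip(graph.nodes, full)}
        scales.append(
            ScalePartition(
                markov_time=float(t),
                labels=labels,
                n_clusters=int(full.max() + 1),
                stability=float(score),
            )
        )
    return PartitionHierarchy(tuple(scales))


def merge_by_partition(features: pd.DataFrame, labels: Mapping[str, int]) -> pd.DataFrame:
    """Sum feature columns within each cluster.

    Output columns are cluster ids in first-appearance order over the
    feature columns; the per-animal total is conserved exactly.
    """
    missing = [c for c in features.columns if c not in labels]
    if missing:
        raise GraphError(f"partition labels missing for regions: {missing}")
    order: list[int] = []
    for c in features.columns:
        lab = labels[c]
        if lab not in order:
            order.append(lab)
    out = pd.DataFrame(
        0.0, index=features.index, columns=[f"cluster_{lab}" for lab in order]
    )
    for c in features.columns:
        out[f"cluster_{labels[c]}"] += features[c].to_numpy()
    return out


def graph_to_edgelist_csv(graph: CorrelationGraph, path: str | Path) -> Path:
    """Write the upper-triangle positive edges as source,target,weight CSV."""
    path = Path(path)
    lines = ["source,target,weight"]
    W = graph.weights
    for i in range(graph.n_nodes):
        for j in range(i + 1, graph.n_nodes):
            if W[i, j] > 0:
                lines.append(f"{graph.nodes[i]},{graph.nodes[j]},{W[i, j]!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
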